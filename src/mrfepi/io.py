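"""File formats: NIfTI image stacks and maps, HDF5 dictionaries and noise
banks, delimited schedule files, and npz model checkpoints."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .matching import BaselineStack, NoiseBank
from .sequence_sim import AcquisitionSchedule, Dictionary, GridSpec

__all__ = [
    "save_stack", "load_stack", "save_map", "load_map", "save_mask", "load_mask",
    "save_dictionary", "load_dictionary", "save_noise_bank", "load_noise_bank",
    "save_schedule", "save_checkpoint", "load_checkpoint",
]

_EYE4 = np.eye(4)


# -- NIfTI ------------------------------------------------------------------

def save_stack(stack: BaselineStack, data_path, mask_path=None) -> None:
    """Write the baseline stack as 4D NIfTI (X, Y, 1, n_timepoints)."""
    x, y, n = stack.data.shape
    nib.save(nib.Nifti1Image(stack.data.reshape(x, y, 1, n).astype(np.float32), _EYE4), str(data_path))
    if mask_path is not None:
        save_mask(stack.brain_mask, mask_path)


def load_stack(data_path, mask_path=None) -> BaselineStack:
    img = np.asarray(nib.load(str(data_path)).dataobj)
    if img.ndim == 4:
        img = img[:, :, 0, :] if img.shape[2] == 1 else img.reshape(img.shape[0], img.shape[1], -1)
    mask = load_mask(mask_path) if mask_path else np.ones(img.shape[:2], dtype=bool)
    return BaselineStack(data=img.astype(np.float64), brain_mask=mask)


def save_map(arr: np.ndarray, path) -> None:
    """Write a 2D parametric map as 3D NIfTI (X, Y, 1)."""
    nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32)[:, :, None], _EYE4), str(path))


def load_map(path) -> np.ndarray:
    arr = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
    return arr[:, :, 0] if arr.ndim == 3 else arr


def save_mask(mask: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8)[:, :, None], _EYE4), str(path))


def load_mask(path) -> np.ndarray:
    return load_map(path).astype(bool)


# -- HDF5 -------------------------------------------------------------------

def save_dictionary(dictionary: Dictionary, path) -> None:
    with h5py.File(str(path), "w") as f:
        f.create_dataset("params", data=dictionary.params)
        f.create_dataset("signals", data=dictionary.signals)
        for name in ("t1_index", "t2s_index", "b1_index"):
            value = getattr(dictionary, name)
            if value is not None:
                f.create_dataset(name, data=value)
        sched = dictionary.schedule
        f.attrs["flip_angle_deg"] = sched.flip_angle_deg
        f.attrs["te_ms"] = sched.te_ms
        f.attrs["tr_ms"] = sched.tr_ms
        f.attrs["grid_spec"] = json.dumps(asdict(dictionary.grid))


def load_dictionary(path) -> Dictionary:
    with h5py.File(str(path), "r") as f:
        schedule = AcquisitionSchedule(
            f.attrs["flip_angle_deg"], f.attrs["te_ms"], f.attrs["tr_ms"]
        )
        grid = GridSpec(**json.loads(f.attrs["grid_spec"]))
        kwargs = {
            name: f[name][...] for name in ("t1_index", "t2s_index", "b1_index") if name in f
        }
        return Dictionary(
            params=f["params"][...], signals=f["signals"][...],
            schedule=schedule, grid=grid, **kwargs,
        )


def save_noise_bank(bank: NoiseBank, path) -> None:
    with h5py.File(str(path), "w") as f:
        f.create_dataset("residuals", data=bank.residuals)
        f.create_dataset("pooled", data=bank.pooled_values)
        f.attrs["meta"] = json.dumps(bank.source_meta)


def load_noise_bank(path) -> NoiseBank:
    with h5py.File(str(path), "r") as f:
        return NoiseBank(residuals=f["residuals"][...], source_meta=json.loads(f.attrs["meta"]))


# -- text schedule ----------------------------------------------------------

def save_schedule(schedule: AcquisitionSchedule, path) -> None:
    table = np.column_stack([schedule.flip_angle_deg, schedule.te_ms, schedule.tr_ms])
    np.savetxt(str(path), table, header="flip_angle_deg te_ms tr_ms", fmt="%.6f")


# -- checkpoints ------------------------------------------------------------

def save_checkpoint(model, spec, path, extra: dict | None = None) -> None:
    """Persist model weights + spec (+ optional training log) as one npz."""
    payload = {f"state/{k}": v for k, v in model.state_dict().items()}
    payload["spec_json"] = np.frombuffer(json.dumps(asdict(spec)).encode(), dtype=np.uint8)
    if extra:
        payload["extra_json"] = np.frombuffer(json.dumps(extra).encode(), dtype=np.uint8)
    np.savez(str(path), **payload)


def load_checkpoint(path, builder):
    """Rebuild a model via ``builder(spec_dict)`` and load its weights.

    Returns (model, extra_dict).
    """
    archive = np.load(str(path))
    spec_dict = json.loads(archive["spec_json"].tobytes().decode())
    model = builder(spec_dict)
    state = {
        key[len("state/"):]: archive[key] for key in archive.files if key.startswith("state/")
    }
    model.load_state_dict(state)
    model.eval()
    extra = (
        json.loads(archive["extra_json"].tobytes().decode())
        if "extra_json" in archive.files else {}
    )
    return model, extra
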
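"""Digital brain-slice phantom for end-to-end testing without patient data.

The phantom is a concentric ellipse geometry: a CSF-filled ventricle
core, a WM interior, a GM cortical ribbon, and optional round WM lesions
mimicking MS plaques.  Per-voxel ground-truth T1/T2* values are drawn
from tissue-specific normal distributions whose defaults are typical
3T literature values for GM/WM/CSF and MS lesions (GM T1 ~1286 ms,
WM ~825 ms, CSF ~3003 ms, lesion ~1284 ms; T2* 53/54/268/86 ms), and a
baseline stack is rendered by running the Bloch simulator on the truth
maps and adding noise calibrated to a target SNR (the scanner data this
emulates sits near 21-22 dB per voxel).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matching import BaselineStack, NoiseBank, sample_noise
from .sequence_sim import AcquisitionSchedule, simulate_fingerprints

__all__ = ["TissueStats", "PhantomSpec", "PhantomTruth", "make_phantom", "render_stack", "LABELS"]

LABELS = {"background": 0, "GM": 1, "WM": 2, "CSF": 3, "lesion": 4}


@dataclass(frozen=True)
class TissueStats:
    t1_mean_ms: float
    t1_sd_ms: float
    t2s_mean_ms: float
    t2s_sd_ms: float


_DEFAULT_TISSUES = {
    "GM": TissueStats(1286.0, 42.0, 53.0, 2.0),
    "WM": TissueStats(825.0, 51.0, 54.0, 2.0),
    "CSF": TissueStats(3003.0, 224.0, 268.0, 101.0),
    "lesion": TissueStats(1284.0, 152.0, 86.0, 14.0),
}


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int] = (32, 32)
    tissue_values: dict = field(default_factory=lambda: dict(_DEFAULT_TISSUES))
    lesion_count: int = 2
    lesion_radius_range: tuple[float, float] = (1.5, 3.0)
    b1_mode: str = "uniform"          # "uniform" or "smooth"
    b1_amplitude: float = 0.1         # peak deviation from 1 in smooth mode
    t1_clip_ms: tuple[float, float] = (100.0, 4000.0)
    t2s_clip_ms: tuple[float, float] = (10.0, 3000.0)
    seed: int = 0

    def __post_init__(self):
        if min(self.shape) < 16:
            raise ValueError("phantom shape must be at least 16 x 16")
        for name, ts in self.tissue_values.items():
            if ts.t1_mean_ms <= 0 or ts.t2s_mean_ms <= 0 or ts.t1_sd_ms < 0 or ts.t2s_sd_ms < 0:
                raise ValueError(f"invalid tissue statistics for {name}")
        if self.b1_mode not in ("uniform", "smooth"):
            raise ValueError("b1_mode must be 'uniform' or 'smooth'")


@dataclass
class PhantomTruth:
    label_map: np.ndarray     # integer labels per LABELS
    t1_truth: np.ndarray      # ms, 0 outside the brain
    t2s_truth: np.ndarray
    b1_truth: np.ndarray
    spec: PhantomSpec

    @property
    def brain_mask(self) -> np.ndarray:
        return self.label_map > 0

    def tissue_mask(self, name: str) -> np.ndarray:
        return self.label_map == LABELS[name]

    def to_parametric_maps(self):
        """Ground-truth maps packaged for the evaluation module."""
        from .regressor import ParametricMaps

        return ParametricMaps(
            t1_map=self.t1_truth.copy(),
            t2s_map=self.t2s_truth.copy(),
            mask=self.brain_mask,
        )


def make_phantom(spec: PhantomSpec | None = None) -> PhantomTruth:
    """Build the labeled geometry and sample per-voxel ground truth."""
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    nx, ny = spec.shape
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx))
    cx, cy = (nx - 1) / 2, (ny - 1) / 2
    # normalized elliptical radius, 1 at the brain boundary
    r = np.sqrt(((xx - cx) / (0.45 * nx)) ** 2 + ((yy - cy) / (0.45 * ny)) ** 2)

    label = np.zeros(spec.shape, dtype=np.int8)
    label[r <= 1.0] = LABELS["GM"]           # outer cortical ribbon
    label[r <= 0.80] = LABELS["WM"]          # interior
    label[r <= 0.22] = LABELS["CSF"]         # ventricle core

    wm_rows, wm_cols = np.nonzero(label == LABELS["WM"])
    for _ in range(spec.lesion_count):
        radius = rng.uniform(*spec.lesion_radius_range)
        for _attempt in range(100):
            k = rng.integers(wm_rows.size)
            lx, ly = wm_rows[k], wm_cols[k]
            disk = (xx - lx) ** 2 + (yy - ly) ** 2 <= radius**2
            if np.all(label[disk] == LABELS["WM"]):   # lesions only inside WM
                label[disk] = LABELS["lesion"]
                break
        else:
            raise ValueError("lesion radius exceeds the available WM extent")

    t1 = np.zeros(spec.shape)
    t2s = np.zeros(spec.shape)
    for name, ts in spec.tissue_values.items():
        sel = label == LABELS[name]
        count = int(sel.sum())
        if count == 0:
            continue
        t1[sel] = np.clip(rng.normal(ts.t1_mean_ms, ts.t1_sd_ms, count), *spec.t1_clip_ms)
        t2s[sel] = np.clip(rng.normal(ts.t2s_mean_ms, ts.t2s_sd_ms, count), *spec.t2s_clip_ms)
    # keep truths physical: the simulator assumes T2* <= T1
    t2s = np.where(label > 0, np.minimum(t2s, t1), 0.0)

    if spec.b1_mode == "uniform":
        b1 = np.ones(spec.shape)
    else:
        phase = rng.uniform(0, 2 * np.pi)
        bump = np.cos(np.pi * (xx / nx - 0.5) + phase) * np.cos(np.pi * (yy / ny - 0.5))
        b1 = 1.0 + spec.b1_amplitude * bump / np.abs(bump).max()
        b1 = np.clip(b1, 0.6, 1.4)
    b1 = np.where(label > 0, b1, 0.0)

    return PhantomTruth(label, t1, t2s, b1, spec)


def render_stack(
    truth: PhantomTruth,
    schedule: AcquisitionSchedule,
    noise: str = "gaussian",
    target_snr_db: float = 21.78,
    bank: NoiseBank | None = None,
    seed: int | None = None,
) -> BaselineStack:
    """Simulate the baseline stack from the truth maps and add noise.

    Each brain voxel's fingerprint is simulated, L2-normalized, and
    corrupted so the expected residual energy matches ``target_snr_db``
    under the SNR definition 10*log10(signal energy / noise energy).
    ``noise`` is one of none / gaussian / bank / student_t (heavy-tailed,
    5 degrees of freedom, bridging Gaussian and empirical noise).
    """
    rng = np.random.default_rng(seed)
    mask = truth.brain_mask
    rows, cols = np.nonzero(mask)
    n_t = schedule.n_timepoints
    signals = simulate_fingerprints(
        schedule, truth.t1_truth[rows, cols], truth.t2s_truth[rows, cols],
        truth.b1_truth[rows, cols],
    )
    signals /= np.linalg.norm(signals, axis=1, keepdims=True)

    if noise != "none":
        # unit-norm signals: target noise energy per voxel is 10^(-SNR/10)
        noise_energy = 10.0 ** (-target_snr_db / 10.0)
        sd = np.sqrt(noise_energy / n_t)
        if noise == "gaussian":
            signals = signals + rng.normal(0.0, sd, size=signals.shape)
        elif noise == "student_t":
            dof = 5.0
            scale = sd / np.sqrt(dof / (dof - 2.0))
            signals = signals + scale * rng.standard_t(dof, size=signals.shape)
        elif noise == "bank":
            if bank is None:
                raise ValueError("noise='bank' requires a NoiseBank")
            draws = sample_noise(bank, n_t, mode="pooled_iid", rng=rng, size=signals.shape[0])
            pooled_var = float(np.mean(bank.pooled_values**2))
            draws *= sd / np.sqrt(pooled_var)
            signals = signals + draws
        else:
            raise ValueError(f"unknown noise model {noise!r}")

    data = np.zeros((*truth.label_map.shape, n_t))
    data[rows, cols] = signals
    return BaselineStack(data=data, brain_mask=mask)
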
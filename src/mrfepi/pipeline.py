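"""End-to-end pipeline orchestration.

Runs an ordered subset of stages against one working directory, with a
fixed artifact layout, per-stage manifests (config hash, seed, wall
time) for reproducibility, and named errors when a prerequisite
artifact is missing.  The synthetic workflow is:

    make-phantom -> simulate-dict -> match -> extract-noise
    -> train-denoiser -> train-regressor -> predict -> evaluate
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io
from .denoiser import StageITrainConfig, train_denoiser
from .evaluation import TissueMasks, evaluate_maps
from .matching import extract_noise_bank, match_stack
from .phantom import LABELS, PhantomSpec, make_phantom, render_stack
from .regressor import (
    ParametricMaps,
    RegressorSpec,
    Stage2TrainConfig,
    predict_two_stage,
    train_regressor,
)
from .sequence_sim import GridSpec, make_schedule, split_by_increment, split_by_range

log = logging.getLogger("mrfepi")

__all__ = ["RunConfig", "MissingArtifactError", "run_pipeline", "ARTIFACTS", "STAGES"]

ARTIFACTS = {
    "phantom": "phantom.npz",
    "stack": "stack.nii.gz",
    "mask": "brain_mask.nii.gz",
    "dictionary": "dictionary.h5",
    "noise_bank": "noise_bank.h5",
    "matched_t1": "matched_t1.nii.gz",
    "matched_t2s": "matched_t2s.nii.gz",
    "denoiser": "denoiser.npz",
    "regressor": "regressor.npz",
    "pred_t1": "predicted_t1.nii.gz",
    "pred_t2s": "predicted_t2s.nii.gz",
    "report": "report.csv",
}


class MissingArtifactError(FileNotFoundError):
    def __init__(self, stage: str, artifact: Path):
        super().__init__(
            f"stage {stage!r} requires missing artifact {artifact}; "
            "run its producing stage first"
        )


@dataclass
class RunConfig:
    workdir: str = "mrfepi_run"
    seed: int = 0
    n_timepoints: int = 35
    grid: dict = field(default_factory=dict)          # GridSpec overrides
    phantom: dict = field(default_factory=dict)       # PhantomSpec overrides
    noise: str = "gaussian"
    target_snr_db: float = 21.78
    split: dict = field(default_factory=lambda: {"kind": "increment", "interval": 2})
    stage1: dict = field(default_factory=dict)        # StageITrainConfig overrides
    stage2: dict = field(default_factory=dict)        # Stage2TrainConfig overrides
    regressor: dict = field(default_factory=dict)     # RegressorSpec overrides

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            payload = yaml.safe_load(f) or {}
        return cls(**payload)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def _path(cfg: RunConfig, name: str) -> Path:
    return Path(cfg.workdir) / ARTIFACTS[name]


def _require(cfg: RunConfig, stage: str, *names: str) -> list[Path]:
    paths = [_path(cfg, n) for n in names]
    for p in paths:
        if not p.exists():
            raise MissingArtifactError(stage, p)
    return paths


def _manifest(cfg: RunConfig, stage: str, seconds: float, **extra) -> None:
    from . import __version__

    payload = {
        "stage": stage,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "wall_time_s": round(seconds, 3),
        "version": __version__,
        **extra,
    }
    path = Path(cfg.workdir) / f"manifest_{stage.replace('-', '_')}.json"
    path.write_text(json.dumps(payload, indent=2))


def _schedule(cfg: RunConfig):
    return make_schedule(n_timepoints=cfg.n_timepoints)


def _stage_make_phantom(cfg: RunConfig) -> None:
    spec = PhantomSpec(seed=cfg.seed, **cfg.phantom)
    truth = make_phantom(spec)
    stack = render_stack(
        truth, _schedule(cfg), noise=cfg.noise,
        target_snr_db=cfg.target_snr_db, seed=cfg.seed + 1,
    )
    np.savez(
        _path(cfg, "phantom"),
        label_map=truth.label_map, t1_truth=truth.t1_truth,
        t2s_truth=truth.t2s_truth, b1_truth=truth.b1_truth,
    )
    io.save_stack(stack, _path(cfg, "stack"), _path(cfg, "mask"))


def _stage_simulate_dict(cfg: RunConfig) -> None:
    from .sequence_sim import generate_dictionary

    dictionary = generate_dictionary(_schedule(cfg), GridSpec(**cfg.grid))
    io.save_dictionary(dictionary, _path(cfg, "dictionary"))


def _stage_match(cfg: RunConfig) -> None:
    stack_p, mask_p, dict_p = _require(cfg, "match", "stack", "mask", "dictionary")
    stack = io.load_stack(stack_p, mask_p)
    result = match_stack(stack, io.load_dictionary(dict_p))
    io.save_map(result.t1_map, _path(cfg, "matched_t1"))
    io.save_map(result.t2s_map, _path(cfg, "matched_t2s"))


def _stage_extract_noise(cfg: RunConfig) -> None:
    stack_p, mask_p, dict_p = _require(cfg, "extract-noise", "stack", "mask", "dictionary")
    stack = io.load_stack(stack_p, mask_p)
    bank, _snr = extract_noise_bank(stack, io.load_dictionary(dict_p))
    io.save_noise_bank(bank, _path(cfg, "noise_bank"))


def _stage_train_denoiser(cfg: RunConfig) -> None:
    dict_p, bank_p = _require(cfg, "train-denoiser", "dictionary", "noise_bank")
    dictionary = io.load_dictionary(dict_p)
    train_cfg = StageITrainConfig(seed=cfg.seed, **cfg.stage1)
    model, losses = train_denoiser(dictionary, io.load_noise_bank(bank_p), train_cfg)
    io.save_checkpoint(model, model.spec, _path(cfg, "denoiser"), extra={"losses": losses})


def _stage_train_regressor(cfg: RunConfig) -> None:
    (dict_p,) = _require(cfg, "train-regressor", "dictionary")
    dictionary = io.load_dictionary(dict_p)
    kind = cfg.split.get("kind", "increment")
    if kind == "increment":
        split = split_by_increment(dictionary, int(cfg.split.get("interval", 2)))
    elif kind == "range":
        split = split_by_range(
            dictionary,
            tuple(cfg.split.get("t1_train", (500.0, 2500.0))),
            tuple(cfg.split.get("t2s_train", (50.0, 1500.0))),
        )
    else:
        raise ValueError(f"unknown split kind {kind!r}")
    spec_kwargs = {
        k: tuple(v) if isinstance(v, list) else v for k, v in cfg.regressor.items()
    }
    spec = RegressorSpec(n_timepoints=cfg.n_timepoints, **spec_kwargs)
    train_cfg = Stage2TrainConfig(seed=cfg.seed, **cfg.stage2)
    model, curves = train_regressor(dictionary, split, spec, train_cfg)
    io.save_checkpoint(
        model, model.spec, _path(cfg, "regressor"),
        extra={"curves": curves.to_dict(orient="list")},
    )


def _builder_denoiser(spec_dict):
    from .denoiser import DenoiserSpec, DnCNN

    return DnCNN(DenoiserSpec(**spec_dict))


def _builder_regressor(spec_dict):
    from .regressor import PyramidRegressor

    fixed = {k: tuple(v) if isinstance(v, list) else v for k, v in spec_dict.items()}
    return PyramidRegressor(RegressorSpec(**fixed))


def _stage_predict(cfg: RunConfig) -> None:
    stack_p, mask_p, den_p, reg_p = _require(
        cfg, "predict", "stack", "mask", "denoiser", "regressor"
    )
    stack = io.load_stack(stack_p, mask_p)
    denoiser, _ = io.load_checkpoint(den_p, _builder_denoiser)
    regressor, _ = io.load_checkpoint(reg_p, _builder_regressor)
    maps = predict_two_stage(denoiser, regressor, stack)
    io.save_map(maps.t1_map, _path(cfg, "pred_t1"))
    io.save_map(maps.t2s_map, _path(cfg, "pred_t2s"))


def _stage_evaluate(cfg: RunConfig) -> None:
    mt1, mt2, pt1, pt2 = _require(
        cfg, "evaluate", "matched_t1", "matched_t2s", "pred_t1", "pred_t2s"
    )
    phantom_p = _path(cfg, "phantom")
    reference = ParametricMaps(io.load_map(mt1), io.load_map(mt2))
    predicted = ParametricMaps(io.load_map(pt1), io.load_map(pt2))
    if phantom_p.exists():
        labels = np.load(phantom_p)["label_map"]
        masks = TissueMasks({
            name: labels == code for name, code in LABELS.items() if code > 0
        } | {"whole_brain": labels > 0})
    else:
        mask = io.load_mask(_path(cfg, "mask"))
        masks = TissueMasks({"whole_brain": mask})
    report = evaluate_maps(reference, predicted, masks)
    report.to_csv(_path(cfg, "report"), index=False)


STAGES = {
    "make-phantom": _stage_make_phantom,
    "simulate-dict": _stage_simulate_dict,
    "match": _stage_match,
    "extract-noise": _stage_extract_noise,
    "train-denoiser": _stage_train_denoiser,
    "train-regressor": _stage_train_regressor,
    "predict": _stage_predict,
    "evaluate": _stage_evaluate,
}


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> int:
    """Execute the requested stages in order; returns 0 on success."""
    stages = stages or list(STAGES)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}; choose from {list(STAGES)}")
    Path(config.workdir).mkdir(parents=True, exist_ok=True)
    for stage in stages:
        log.info("stage %s: starting (seed=%d)", stage, config.seed)
        t0 = time.perf_counter()
        STAGES[stage](config)
        dt = time.perf_counter() - t0
        _manifest(config, stage, dt)
        log.info("stage %s: done in %.2fs", stage, dt)
    return 0
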
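"""Stage II: pyramidal dual-path CNN with multi-head self-attention.

A shared three-block convolutional backbone (kernels 17/11/7, channels
128/256/512, each followed by ReLU and dropout 0.2; valid convolutions,
so a 35-point fingerprint yields pyramid scales of length 19, 9 and 3).
Each regression path (one for T1, one for T2*) taps every scale: a
multi-head self-attention layer re-weights the features, a learnable
scalar gamma gates the attention residual (Y = gamma*Xa + X), and a
flatten -> FC(128) -> ReLU -> FC(3) head summarizes the scale.  The
per-scale 3-vectors are combined as a gamma-weighted sum and a final
FC(3 -> 1) emits the relaxation time in ms.

Variants for ablation:
  WPDaCNN - the full model above.
  PDCNN   - no attention, no gammas; plain sum across scales.
  DCNN    - PDCNN restricted to the third (coarsest) scale only.
  SCNN    - DCNN with a single path whose final FC emits both values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .denoiser import DnCNN, denoise_signal
from .matching import BaselineStack
from .sequence_sim import Dictionary, DictionarySplit

__all__ = [
    "RegressorSpec",
    "Stage2TrainConfig",
    "ParametricMaps",
    "PyramidRegressor",
    "multihead_attention",
    "gamma_residual",
    "build_regressor",
    "stage2_loss",
    "train_regressor",
    "predict_two_stage",
    "predict_single_stage",
]

_VARIANTS = ("WPDaCNN", "PDCNN", "DCNN", "SCNN")


@dataclass(frozen=True)
class RegressorSpec:
    backbone_kernels: tuple[int, ...] = (17, 11, 7)
    backbone_channels: tuple[int, ...] = (128, 256, 512)
    dropout_p: float = 0.2
    n_heads: int = 8
    head_hidden: int = 128
    head_out: int = 3
    variant: str = "WPDaCNN"
    n_timepoints: int = 35

    def __post_init__(self):
        if self.variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS}")
        if len(self.backbone_kernels) != len(self.backbone_channels):
            raise ValueError("kernel and channel tuples must have equal length")
        if any(k < 1 for k in self.backbone_kernels):
            raise ValueError("kernels must be positive")
        if any(c % self.n_heads for c in self.backbone_channels):
            raise ValueError("channels must be divisible by n_heads")
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout must be in [0, 1)")

    def scale_lengths(self) -> list[int]:
        """Valid-convolution length recursion l' = l - k + 1 per block."""
        lengths, l = [], self.n_timepoints
        for k in self.backbone_kernels:
            l = l - k + 1
            if l < 1:
                raise ValueError("fingerprint too short for the backbone kernels")
            lengths.append(l)
        return lengths


@dataclass(frozen=True)
class Stage2TrainConfig:
    batch_size: int = 500
    learning_rate: float = 0.01
    lr_decay_per_epoch: float = 0.05
    epochs: int = 100
    seed: int = 0
    val_subsample: int | None = None   # cap validation size per epoch (None = all)
    init_output_bias_to_mean: bool = True  # start each path at the mean target

    def __post_init__(self):
        if min(self.batch_size, self.epochs) < 1 or self.learning_rate <= 0:
            raise ValueError("hyperparameters must be positive")
        if not 0 < self.lr_decay_per_epoch < 1:
            raise ValueError("lr decay must be in (0, 1)")


@dataclass
class ParametricMaps:
    """Per-voxel T1/T2* estimates in ms (0 outside the brain mask)."""

    t1_map: np.ndarray
    t2s_map: np.ndarray
    mask: np.ndarray | None = None


# ---------------------------------------------------------------------------
# functional pieces
# ---------------------------------------------------------------------------

def multihead_attention(x, attention: nn.MultiHeadSelfAttention):
    """Apply a multi-head self-attention module to (l, d_ch) or (N, l, d_ch)."""
    t = x if isinstance(x, nn.Tensor) else nn.Tensor(np.asarray(x, dtype=np.float32))
    single = t.ndim == 2
    if single:
        t = t.reshape(1, *t.shape)
    out = attention(t)
    return out.reshape(out.shape[1:]) if single else out


def gamma_residual(x, xa, gamma):
    """Gated attention residual Y = gamma * Xa + X."""
    if isinstance(x, nn.Tensor) or isinstance(xa, nn.Tensor) or isinstance(gamma, nn.Tensor):
        xt = x if isinstance(x, nn.Tensor) else nn.Tensor(x)
        xat = xa if isinstance(xa, nn.Tensor) else nn.Tensor(xa)
        if xt.shape != xat.shape:
            raise ValueError("shape mismatch between X and Xa")
        g = gamma if isinstance(gamma, nn.Tensor) else nn.Tensor(np.float32(gamma))
        return g * xat + xt
    x = np.asarray(x, dtype=np.float64)
    xa = np.asarray(xa, dtype=np.float64)
    if x.shape != xa.shape:
        raise ValueError("shape mismatch between X and Xa")
    return float(gamma) * xa + x


def stage2_loss(y, yp):
    """L1 + 100*MAPE over all values in the batch (relaxation times in ms)."""
    tensor_mode = isinstance(y, nn.Tensor) or isinstance(yp, nn.Tensor)
    if tensor_mode:
        yt = y if isinstance(y, nn.Tensor) else nn.Tensor(y)
        yp_t = yp if isinstance(yp, nn.Tensor) else nn.Tensor(yp)
        if yt.shape != yp_t.shape:
            raise ValueError("target and prediction shapes differ")
        if np.any(yt.data <= 0):
            raise ValueError("true relaxation times must be positive")
        err = (yt - yp_t).abs()
        return err.mean() + 100.0 * (err / yt).mean()
    y = np.asarray(y, dtype=np.float64)
    yp = np.asarray(yp, dtype=np.float64)
    if y.shape != yp.shape:
        raise ValueError("target and prediction shapes differ")
    if np.any(y <= 0):
        raise ValueError("true relaxation times must be positive")
    err = np.abs(y - yp)
    return float(err.mean() + 100.0 * (err / y).mean())


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class _ScaleHead(nn.Module):
    """Per-scale head: optional attention + gamma residual, then FC summary."""

    def __init__(self, length: int, channels: int, spec: RegressorSpec,
                 with_attention: bool, rng: np.random.Generator):
        super().__init__()
        self.with_attention = with_attention
        if with_attention:
            self.attention = nn.MultiHeadSelfAttention(channels, spec.n_heads, rng=rng)
            self.gamma_attn = nn.Parameter(np.zeros(()))  # residual branch closed at init
        self.fc1 = nn.Linear(length * channels, spec.head_hidden, rng=rng)
        self.fc2 = nn.Linear(spec.head_hidden, spec.head_out, rng=rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        # x: (N, C, L) -> attention operates on (N, L, C)
        n, c, l = x.shape
        y = x.transpose(0, 2, 1)
        if self.with_attention:
            y = gamma_residual(y, self.attention(y), self.gamma_attn)
        flat = y.reshape(n, l * c)
        return self.fc2(self.fc1(flat).relu())


class _Path(nn.Module):
    """One output path across the pyramid scales."""

    def __init__(self, lengths: list[int], spec: RegressorSpec,
                 scale_ids: list[int], out_features: int,
                 weighted: bool, with_attention: bool, rng: np.random.Generator):
        super().__init__()
        self.scale_ids = scale_ids
        self.weighted = weighted
        self.heads = [
            _ScaleHead(lengths[i], spec.backbone_channels[i], spec, with_attention, rng)
            for i in scale_ids
        ]
        if weighted:
            # initialized to 1/m so the initial combination is an average
            self.gamma_scale = nn.Parameter(np.full(len(scale_ids), 1.0 / len(scale_ids)))
        self.fc_out = nn.Linear(spec.head_out, out_features, rng=rng)

    def forward(self, scales: list[nn.Tensor]) -> nn.Tensor:
        outs = [head(scales[i]) for head, i in zip(self.heads, self.scale_ids)]
        combined = None
        for j, out in enumerate(outs):
            term = out * self.gamma_scale[j] if self.weighted else out
            combined = term if combined is None else combined + term
        return self.fc_out(combined)


class PyramidRegressor(nn.Module):
    def __init__(self, spec: RegressorSpec, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.spec = spec
        # per-time-point input standardization (identity until fitted);
        # unit-norm fingerprints vary by ~1% along T1, so training data is
        # centered and scaled to make that variation resolvable in float32
        self._buffers = {
            "input_center": np.zeros(spec.n_timepoints, dtype=np.float32),
            "input_scale": np.ones(spec.n_timepoints, dtype=np.float32),
            # inference-time clamp to the training target range (like the
            # matcher, the regressor cannot return out-of-dictionary values);
            # infinite until fitted
            "output_low": np.full(2, -np.inf, dtype=np.float32),
            "output_high": np.full(2, np.inf, dtype=np.float32),
        }
        lengths = spec.scale_lengths()
        self.blocks = []
        in_ch = 1
        for k, ch in zip(spec.backbone_kernels, spec.backbone_channels):
            self.blocks.append(nn.Sequential(
                nn.Conv1d(in_ch, ch, k, padding=0, rng=rng),
                nn.ReLU(),
                nn.Dropout(spec.dropout_p, rng=rng),
            ))
            in_ch = ch

        full_pyramid = spec.variant in ("WPDaCNN", "PDCNN")
        scale_ids = list(range(len(lengths))) if full_pyramid else [len(lengths) - 1]
        weighted = spec.variant == "WPDaCNN"
        with_attention = spec.variant == "WPDaCNN"
        if spec.variant == "SCNN":
            self.paths = [_Path(lengths, spec, scale_ids, 2, weighted, with_attention, rng)]
        else:
            self.paths = [
                _Path(lengths, spec, scale_ids, 1, weighted, with_attention, rng)
                for _ in range(2)  # T1 path, T2* path
            ]

    def fit_input_standardization(self, signals: np.ndarray,
                                  scale_floor_frac: float = 0.5) -> None:
        """Store per-time-point center/scale from training fingerprints.

        The scale is floored at ``scale_floor_frac`` times the largest
        per-time-point spread: unfloored scales amplify measurement noise
        on low-variance time points by orders of magnitude, which makes a
        clean-signal-trained network unusable on denoised scan data.
        """
        self._buffers["input_center"] = signals.mean(axis=0).astype(np.float32)
        scale = signals.std(axis=0)
        peak = scale.max()
        if peak == 0:
            scale = np.ones_like(scale)
        else:
            scale = np.maximum(scale, scale_floor_frac * peak)
        self._buffers["input_scale"] = scale.astype(np.float32)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        """(N, n_timepoints) fingerprints -> (N, 2) predicted (T1, T2*) in ms."""
        n, length = x.shape
        x = (x - nn.Tensor(self._buffers["input_center"])) * nn.Tensor(
            1.0 / self._buffers["input_scale"]
        )
        h = x.reshape(n, 1, length)
        scales = []
        for block in self.blocks:
            h = block(h)
            scales.append(h)
        outs = [path(scales) for path in self.paths]
        return outs[0] if len(outs) == 1 else nn.concat(outs, axis=1)

    def predict(self, signals: np.ndarray, batch_size: int = 2000) -> np.ndarray:
        """Inference on raw arrays, dropout disabled, chunked over rows."""
        was_training = self.training
        self.eval()
        single = signals.ndim == 1
        arr = np.atleast_2d(np.asarray(signals, dtype=np.float32))
        chunks = [
            self.forward(nn.Tensor(arr[s : s + batch_size])).numpy()
            for s in range(0, arr.shape[0], batch_size)
        ]
        out = np.concatenate(chunks, axis=0).astype(np.float64)
        out = np.clip(out, self._buffers["output_low"], self._buffers["output_high"])
        if was_training:
            self.train()
        return out[0] if single else out


def build_regressor(spec: RegressorSpec | None = None, seed: int | None = None) -> PyramidRegressor:
    spec = spec or RegressorSpec()
    return PyramidRegressor(spec, rng=np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# training and prediction
# ---------------------------------------------------------------------------

def _eval_losses(model: PyramidRegressor, signals: np.ndarray, targets: np.ndarray) -> tuple[float, float, float]:
    """(stage-2 loss, L1, MAPE%) in inference mode."""
    pred = model.predict(signals)
    err = np.abs(targets - pred)
    l1 = float(err.mean())
    mape = float((err / targets).mean() * 100.0)
    return l1 + mape, l1, mape


def train_regressor(
    dictionary: Dictionary,
    split: DictionarySplit,
    spec: RegressorSpec | None = None,
    cfg: Stage2TrainConfig | None = None,
) -> tuple[PyramidRegressor, "pd.DataFrame"]:
    """Train a pyramid regressor on clean dictionary fingerprints.

    Inputs are the unit-norm simulated signals of the training split;
    targets are their (T1, T2*) in ms.  The checkpoint with the lowest
    validation loss (L1 + 100*MAPE, dropout off) is returned together
    with per-epoch train/validation L1 and MAPE curves.
    """
    import pandas as pd

    spec = spec or RegressorSpec(n_timepoints=dictionary.n_timepoints)
    cfg = cfg or Stage2TrainConfig()
    train_idx = split.train_indices
    if train_idx.size == 0:
        raise ValueError("training split is empty")
    rng = np.random.default_rng(cfg.seed)
    model = PyramidRegressor(spec, rng=rng)
    optimizer = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    scheduler = nn.ExponentialDecay(optimizer, cfg.lr_decay_per_epoch)

    x_train = dictionary.signals[train_idx].astype(np.float32)
    y_train = dictionary.params[train_idx, :2].astype(np.float32)

    model.fit_input_standardization(dictionary.signals[train_idx])
    model._buffers["output_low"] = y_train.min(axis=0).astype(np.float32)
    model._buffers["output_high"] = y_train.max(axis=0).astype(np.float32)

    if cfg.init_output_bias_to_mean:
        # targets are in raw ms; starting each path at the mean target keeps
        # early updates from being spent on reaching the output scale
        means = y_train.mean(axis=0)
        if len(model.paths) == 1:
            model.paths[0].fc_out.bias.data[:] = means
        else:
            for path, mu in zip(model.paths, means):
                path.fc_out.bias.data[:] = mu

    val_idx = split.valid_indices
    if val_idx.size and cfg.val_subsample and val_idx.size > cfg.val_subsample:
        val_idx = rng.choice(val_idx, size=cfg.val_subsample, replace=False)
    x_val = dictionary.signals[val_idx].astype(np.float32)
    y_val = dictionary.params[val_idx, :2]

    records = []
    best_loss, best_state = np.inf, None
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(train_idx.size)
        for start in range(0, train_idx.size, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            pred = model(nn.Tensor(x_train[idx]))
            loss = stage2_loss(nn.Tensor(y_train[idx]), pred)
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    f"stage-II training diverged at epoch {epoch}: loss={loss.item()}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
        scheduler.step()

        if cfg.val_subsample and train_idx.size > cfg.val_subsample:
            sub = rng.choice(train_idx.size, size=cfg.val_subsample, replace=False)
            x_tr_eval, y_tr_eval = x_train[sub], y_train[sub].astype(np.float64)
        else:
            x_tr_eval, y_tr_eval = x_train, y_train.astype(np.float64)
        _, train_l1, train_mape = _eval_losses(model, x_tr_eval, y_tr_eval)
        if val_idx.size:
            val_loss, val_l1, val_mape = _eval_losses(model, x_val, y_val)
        else:  # no validation entries: fall back to training loss for selection
            val_loss, val_l1, val_mape = train_l1 + train_mape, train_l1, train_mape
        records.append({
            "epoch": epoch, "train_l1_ms": train_l1, "train_mape_pct": train_mape,
            "val_l1_ms": val_l1, "val_mape_pct": val_mape, "val_loss": val_loss,
        })
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    model.eval()
    return model, pd.DataFrame.from_records(records)


def _predict_maps(stack: BaselineStack, transform) -> ParametricMaps:
    x, y, _ = stack.data.shape
    t1_map = np.zeros((x, y))
    t2s_map = np.zeros((x, y))
    rows, cols = np.nonzero(stack.brain_mask)
    if rows.size:
        signals = stack.data[rows, cols]
        norms = np.linalg.norm(signals, axis=1)
        ok = norms > 0
        if ok.any():
            normalized = signals[ok] / norms[ok, None]
            pred = transform(normalized)
            t1_map[rows[ok], cols[ok]] = pred[:, 0]
            t2s_map[rows[ok], cols[ok]] = pred[:, 1]
    return ParametricMaps(t1_map, t2s_map, mask=stack.brain_mask.copy())


def predict_two_stage(
    denoiser: DnCNN, regressor: PyramidRegressor, stack: BaselineStack
) -> ParametricMaps:
    """Voxel-wise normalize -> denoise (stage I) -> regress (stage II)."""
    if denoiser.spec.n_timepoints != stack.n_timepoints:
        raise ValueError("denoiser length does not match the stack")

    def transform(normalized: np.ndarray) -> np.ndarray:
        denoised = denoise_signal(denoiser, normalized)
        return regressor.predict(denoised)

    return _predict_maps(stack, transform)


def predict_single_stage(regressor: PyramidRegressor, stack: BaselineStack) -> ParametricMaps:
    """Stage II alone on the noisy normalized fingerprints (no denoising)."""
    return _predict_maps(stack, regressor.predict)
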
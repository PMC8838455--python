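"""Stage I: 1D residual-learning denoising CNN (DnCNN).

The network sees a noisy fingerprint and predicts its noise component;
subtracting the prediction from the input yields the denoised signal.
Architecture: conv(k=3, pad=1, 64 ch) + ReLU, then 32 middle units of
conv + batch norm + ReLU, then a final conv down to one channel.  It is
trained on unit-norm simulated dictionary fingerprints corrupted by
residuals sampled from an empirical noise bank, with loss
10000 * MSE(true residual, predicted residual); the epoch checkpoint
with the lowest training loss is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .matching import NoiseBank, sample_noise
from .sequence_sim import Dictionary

__all__ = [
    "DenoiserSpec",
    "StageITrainConfig",
    "DnCNN",
    "build_denoiser",
    "stage1_loss",
    "train_denoiser",
    "denoise_signal",
]


@dataclass(frozen=True)
class DenoiserSpec:
    depth_middle: int = 32
    channels: int = 64
    kernel: int = 3
    padding: int = 1
    n_timepoints: int = 35

    def __post_init__(self):
        if self.depth_middle < 1:
            raise ValueError("depth_middle must be >= 1")
        if self.kernel % 2 == 0:
            raise ValueError("kernel must be odd")
        if self.padding != (self.kernel - 1) // 2:
            raise ValueError("padding must preserve signal length (kernel // 2)")


@dataclass(frozen=True)
class StageITrainConfig:
    batch_size: int = 500
    learning_rate: float = 0.01
    lr_decay_per_epoch: float = 0.05
    epochs: int = 100
    seed: int = 0
    noise_mode: str = "pooled_iid"
    resample_each_epoch: bool = True

    def __post_init__(self):
        if min(self.batch_size, self.epochs) < 1 or self.learning_rate <= 0:
            raise ValueError("hyperparameters must be positive")
        if not 0 < self.lr_decay_per_epoch < 1:
            raise ValueError("lr decay must be in (0, 1)")


class DnCNN(nn.Module):
    def __init__(self, spec: DenoiserSpec, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.spec = spec
        k, p, ch = spec.kernel, spec.padding, spec.channels
        layers: list[nn.Module] = [nn.Conv1d(1, ch, k, padding=p, rng=rng), nn.ReLU()]
        for _ in range(spec.depth_middle):
            layers += [nn.Conv1d(ch, ch, k, padding=p, rng=rng), nn.BatchNorm1d(ch), nn.ReLU()]
        final = nn.Conv1d(ch, 1, k, padding=p, rng=rng)
        # zero-started output layer: the untrained model predicts zero noise,
        # so denoising begins from the identity mapping
        final.weight.data[:] = 0
        final.bias.data[:] = 0
        layers.append(final)
        self.net = nn.Sequential(*layers)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        """(N, n_timepoints) noisy signals -> (N, n_timepoints) predicted residuals."""
        n, length = x.shape
        out = self.net(x.reshape(n, 1, length))
        return out.reshape(n, length)

    def predict(self, signals: np.ndarray) -> np.ndarray:
        """Inference-mode residual prediction on raw arrays."""
        was_training = self.training
        self.eval()
        single = signals.ndim == 1
        arr = np.atleast_2d(np.asarray(signals, dtype=np.float32))
        out = self.forward(nn.Tensor(arr)).numpy().astype(np.float64)
        if was_training:
            self.train()
        return out[0] if single else out


def build_denoiser(spec: DenoiserSpec | None = None, seed: int | None = None) -> DnCNN:
    spec = spec or DenoiserSpec()
    return DnCNN(spec, rng=np.random.default_rng(seed))


def stage1_loss(true_residual, pred_residual):
    """10000 x mean squared error over every value in the batch."""
    if isinstance(true_residual, nn.Tensor) or isinstance(pred_residual, nn.Tensor):
        t = true_residual if isinstance(true_residual, nn.Tensor) else nn.Tensor(true_residual)
        p = pred_residual if isinstance(pred_residual, nn.Tensor) else nn.Tensor(pred_residual)
        if t.shape != p.shape:
            raise ValueError("residual shapes differ")
        return ((t - p) ** 2).mean() * 10000.0
    t = np.asarray(true_residual, dtype=np.float64)
    p = np.asarray(pred_residual, dtype=np.float64)
    if t.shape != p.shape:
        raise ValueError("residual shapes differ")
    return 10000.0 * float(np.mean((t - p) ** 2))


def train_denoiser(
    dictionary: Dictionary,
    bank: NoiseBank,
    cfg: StageITrainConfig | None = None,
) -> tuple[DnCNN, list[float]]:
    """Train the DnCNN on noise-corrupted dictionary fingerprints.

    Every epoch each dictionary signal receives a freshly sampled residual
    (unless ``resample_each_epoch`` is off, which fixes the corruption of
    the first epoch).  Model selection keeps the epoch with the lowest
    mean training loss.  Returns (model at best epoch, per-epoch losses).
    """
    cfg = cfg or StageITrainConfig()
    if len(dictionary) == 0 or len(bank) == 0:
        raise ValueError("dictionary and noise bank must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    model = DnCNN(DenoiserSpec(n_timepoints=dictionary.n_timepoints), rng=rng)
    optimizer = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    scheduler = nn.ExponentialDecay(optimizer, cfg.lr_decay_per_epoch)

    clean = dictionary.signals.astype(np.float32)
    n_signals, n_t = clean.shape
    fixed_noise = None
    losses: list[float] = []
    best_loss, best_state = np.inf, None

    model.train()
    for epoch in range(cfg.epochs):
        if fixed_noise is None or cfg.resample_each_epoch:
            noise = sample_noise(bank, n_t, mode=cfg.noise_mode, rng=rng, size=n_signals)
            noise = noise.astype(np.float32)
            if not cfg.resample_each_epoch:
                fixed_noise = noise
        else:
            noise = fixed_noise
        order = rng.permutation(n_signals)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n_signals, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            target = nn.Tensor(noise[idx])
            noisy = nn.Tensor(clean[idx] + noise[idx])
            pred = model(noisy)
            loss = stage1_loss(target, pred)
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    f"stage-I training diverged at epoch {epoch}: loss={loss.item()}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += loss.item()
            n_batches += 1
        scheduler.step()
        mean_loss = epoch_loss / n_batches
        losses.append(mean_loss)
        if mean_loss < best_loss:
            best_loss = mean_loss
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    model.eval()
    return model, losses


def denoise_signal(model: DnCNN, noisy) -> np.ndarray:
    """Subtract the model's predicted residual from the noisy signal."""
    from .sequence_sim import Fingerprint

    arr = noisy.values if isinstance(noisy, Fingerprint) else np.asarray(noisy, dtype=np.float64)
    if arr.shape[-1] != model.spec.n_timepoints:
        raise ValueError("signal length does not match the model")
    return arr - model.predict(arr)
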
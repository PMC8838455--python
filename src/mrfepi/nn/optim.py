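"""Adam optimizer and the per-epoch exponential learning-rate decay used
by both training stages (5% reduction per epoch by default)."""

from __future__ import annotations

import numpy as np

from .layers import Parameter

__all__ = ["Adam", "ExponentialDecay"]


class Adam:
    def __init__(self, params: list[Parameter], lr: float = 0.01,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class ExponentialDecay:
    """Multiplies the optimizer learning rate by (1 - decay) once per epoch."""

    def __init__(self, optimizer: Adam, decay: float):
        if not 0 <= decay < 1:
            raise ValueError("decay must be in [0, 1)")
        self.optimizer = optimizer
        self.decay = decay

    def step(self) -> None:
        self.optimizer.lr *= 1.0 - self.decay
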
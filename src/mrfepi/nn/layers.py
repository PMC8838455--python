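"""Neural-network building blocks on top of the autodiff tensors.

Modules mirror the familiar torch.nn surface (``parameters``,
``train``/``eval``, ``state_dict``) at the scale this package needs.
Weight initialization is Kaiming-uniform and always drawn from an
explicit ``numpy.random.Generator`` so training runs are reproducible.
"""

from __future__ import annotations

import math

import numpy as np

from .tensor import Tensor, batch_norm, conv1d, softmax

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Conv1d",
    "BatchNorm1d",
    "Linear",
    "ReLU",
    "Dropout",
    "MultiHeadSelfAttention",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    # -- traversal -----------------------------------------------------------
    def named_members(self):
        for name, value in vars(self).items():
            if isinstance(value, (Parameter, Module)):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, (Parameter, Module)):
                        yield f"{name}.{i}", item

    def parameters(self) -> list[Parameter]:
        params = []
        for _, member in self.named_members():
            if isinstance(member, Parameter):
                params.append(member)
            else:
                params.extend(member.parameters())
        return params

    def train(self):
        self.training = True
        for _, member in self.named_members():
            if isinstance(member, Module):
                member.train()
        return self

    def eval(self):
        self.training = False
        for _, member in self.named_members():
            if isinstance(member, Module):
                member.eval()
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- persistence ----------------------------------------------------------
    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, member in self.named_members():
            key = prefix + name
            if isinstance(member, Parameter):
                state[key] = member.data.copy()
            else:
                state.update(member.state_dict(key + "."))
        for name, buf in getattr(self, "_buffers", {}).items():
            state[prefix + name] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, member in self.named_members():
            key = prefix + name
            if isinstance(member, Parameter):
                member.data = state[key].astype(np.float32).copy()
            else:
                member.load_state_dict(state, key + ".")
        for name in getattr(self, "_buffers", {}):
            self._buffers[name] = state[prefix + name].copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.layers = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def _kaiming_uniform(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    bound = math.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Conv1d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 padding: int = 0, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size
        self.weight = Parameter(_kaiming_uniform(rng, (out_channels, in_channels, kernel_size), fan_in))
        bound = 1.0 / math.sqrt(fan_in)
        self.bias = Parameter(rng.uniform(-bound, bound, size=out_channels).astype(np.float32))
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, padding=self.padding)


class BatchNorm1d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.momentum = momentum
        self.eps = eps
        self._buffers = {
            "running_mean": np.zeros(channels, dtype=np.float32),
            "running_var": np.ones(channels, dtype=np.float32),
        }

    def forward(self, x: Tensor) -> Tensor:
        return batch_norm(
            x, self.gamma, self.beta,
            self._buffers["running_mean"], self._buffers["running_var"],
            training=self.training, momentum=self.momentum, eps=self.eps,
        )


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Parameter(_kaiming_uniform(rng, (in_features, out_features), in_features))
        bound = 1.0 / math.sqrt(in_features)
        self.bias = Parameter(rng.uniform(-bound, bound, size=out_features).astype(np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Dropout(Module):
    """Inverted dropout; the mask RNG is a module attribute so a training
    run can seed it once and stay reproducible."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng()

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0:
            return x
        mask = (self.rng.random(x.shape) >= self.p).astype(np.float32) / (1.0 - self.p)
        return x * Tensor(mask)


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention with per-head channel slicing.

    The input (batch, l, d_ch) is split contiguously along channels into
    h groups of d_s = d_ch / h.  Each head projects its own slice with
    d_s x d_s query/key/value matrices; the concatenated heads pass
    through an output projection of shape (h*d_s, d_ch).
    """

    def __init__(self, d_ch: int, n_heads: int, rng: np.random.Generator | None = None):
        super().__init__()
        if d_ch % n_heads:
            raise ValueError(f"channels {d_ch} not divisible by heads {n_heads}")
        rng = rng or np.random.default_rng()
        self.n_heads = n_heads
        self.d_s = d_ch // n_heads
        shape = (n_heads, self.d_s, self.d_s)
        self.w_q = Parameter(_kaiming_uniform(rng, shape, self.d_s))
        self.w_k = Parameter(_kaiming_uniform(rng, shape, self.d_s))
        self.w_v = Parameter(_kaiming_uniform(rng, shape, self.d_s))
        self.w_o = Parameter(_kaiming_uniform(rng, (d_ch, d_ch), d_ch))

    def forward(self, x: Tensor) -> Tensor:
        b, l, d_ch = x.shape
        h, d_s = self.n_heads, self.d_s
        # (b, l, d_ch) -> (b, h, l, d_s)
        xh = x.reshape(b, l, h, d_s).transpose(0, 2, 1, 3)
        q = xh @ self.w_q
        k = xh @ self.w_k
        v = xh @ self.w_v
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(d_s))
        attn = softmax(scores, axis=-1)
        heads = attn @ v
        out = heads.transpose(0, 2, 1, 3).reshape(b, l, h * d_s)
        return out @ self.w_o
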
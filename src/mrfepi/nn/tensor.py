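"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the two reconstruction networks need:
broadcasting arithmetic, batched matmul, 1D convolution (stride 1),
batch normalization, softmax, ReLU and reductions.  Gradients are
accumulated by a topological backward sweep, micrograd-style, but every
op is vectorized over full arrays.  float32 is the working dtype for
network code; inputs of other dtypes are cast on construction.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat", "conv1d", "batch_norm", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=np.float32))

    @classmethod
    def _make(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- properties ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def backward(out):
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(out):
            if self.requires_grad:
                self._accum(-out.grad)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(out):
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def backward(out):
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-out.grad * self.data / other.data**2, other.shape))

        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * exponent * self.data ** (exponent - 1))

        return self._make(self.data**exponent, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(out):
            g = out.grad
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape))

        return self._make(self.data @ other.data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * mask)

        return self._make(self.data * mask, (self,), backward)

    def abs(self):
        sign = np.sign(self.data)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * sign)

        return self._make(np.abs(self.data), (self,), backward)

    def exp(self):
        val = np.exp(self.data)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * val)

        return self._make(val, (self,), backward)

    def log(self):
        def backward(out):
            if self.requires_grad:
                self._accum(out.grad / self.data)

        return self._make(np.log(self.data), (self,), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(out):
            if not self.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape))

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            axes = (axis,) if isinstance(axis, int) else axis
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad.reshape(orig))

        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(out):
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accum(g)

        return self._make(self.data[idx], (self,), backward)

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=self.data.dtype)

        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if id(parent) not in visited:
                    stack.append((parent, False))

        for node in reversed(topo):
            if node._backward is None:
                continue  # leaf: keep accumulated gradient
            if node.grad is not None:
                node._backward(node)
            if node is not self:
                node.grad = None  # free intermediate gradients to bound memory


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(out):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * out.grad.ndim
                idx[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(idx)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    val = e / e.sum(axis=axis, keepdims=True)

    def backward(out):
        if x.requires_grad:
            g = out.grad
            x._accum(val * (g - (g * val).sum(axis=axis, keepdims=True)))

    return Tensor._make(val, (x,), backward)


def conv1d(x: Tensor, weight: Tensor, bias: Tensor | None, padding: int = 0) -> Tensor:
    """1D cross-correlation, stride 1.

    x: (N, C_in, L); weight: (C_out, C_in, K); bias: (C_out,) or None.
    Output length is L + 2*padding - K + 1.
    """
    n, c_in, length = x.shape
    c_out, c_in_w, k = weight.shape
    if c_in != c_in_w:
        raise ValueError(f"channel mismatch: input {c_in}, weight {c_in_w}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding))) if padding else x.data
    l_out = xp.shape[2] - k + 1
    if l_out < 1:
        raise ValueError(f"kernel {k} too large for input length {length} with padding {padding}")
    # (N, C_in, l_out, K) -> (N*l_out, C_in*K)
    cols = sliding_window_view(xp, k, axis=2)
    cols2d = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(n * l_out, c_in * k)
    w2d = weight.data.reshape(c_out, c_in * k)
    out2d = cols2d @ w2d.T
    if bias is not None:
        out2d += bias.data
    out_data = out2d.reshape(n, l_out, c_out).transpose(0, 2, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(out):
        g2d = np.ascontiguousarray(out.grad.transpose(0, 2, 1)).reshape(n * l_out, c_out)
        if weight.requires_grad:
            weight._accum((g2d.T @ cols2d).reshape(c_out, c_in, k))
        if bias is not None and bias.requires_grad:
            bias._accum(g2d.sum(axis=0))
        if x.requires_grad:
            dcols = (g2d @ w2d).reshape(n, l_out, c_in, k).transpose(0, 2, 1, 3)
            gx = np.zeros_like(xp)
            for j in range(k):
                gx[:, :, j : j + l_out] += dcols[:, :, :, j]
            if padding:
                gx = gx[:, :, padding:-padding]
            x._accum(gx)

    return Tensor._make(out_data, parents, backward)


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Batch normalization over (N, C, L): per-channel statistics across N and L.

    In training mode updates `running_mean`/`running_var` in place.
    """
    if training:
        mu = x.data.mean(axis=(0, 2))
        var = x.data.var(axis=(0, 2))
        running_mean *= 1 - momentum
        running_mean += momentum * mu
        running_var *= 1 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[:, None]) * inv_std[:, None]
    out_data = gamma.data[:, None] * xhat + beta.data[:, None]

    def backward(out):
        g = out.grad
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2)))
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2)))
        if x.requires_grad:
            gxhat = g * gamma.data[:, None]
            if training:
                m = x.shape[0] * x.shape[2]
                gx = (
                    gxhat
                    - gxhat.mean(axis=(0, 2), keepdims=True)
                    - xhat * (gxhat * xhat).mean(axis=(0, 2), keepdims=True)
                ) * inv_std[:, None]
            else:
                gx = gxhat * inv_std[:, None]
            x._accum(gx)

    return Tensor._make(out_data, (x, gamma, beta), backward)
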
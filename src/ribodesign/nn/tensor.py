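"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Provides exactly the operations the denoising network needs: broadcasting
arithmetic, (batched) matrix multiplication, indexing/gather, segment sums for
graph message aggregation, reductions, element-wise nonlinearities, a fused
softmax and a fused layer norm.  Gradients are accumulated by a topological
backward sweep.  A module-level ``no_grad`` context disables graph
construction (used for the stop-gradient self-conditioning pre-pass and for
sampling).
"""

from __future__ import annotations

import contextlib
from typing import Callable, Optional, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the ``with`` block."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad)
        self._backward: Optional[Callable[[np.ndarray], None]] = None
        self._parents: Sequence["Tensor"] = ()
        self.name = name

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def backward(self, grad: Optional[np.ndarray] = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.copy() if g.base is not None or g.flags.writeable is False else g
        else:
            self.grad = self.grad + g

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -_as_tensor(other))

    def __rsub__(self, other):
        return add(_as_tensor(other), -self)

    def __truediv__(self, other):
        other = _as_tensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(_as_tensor(other), power(self, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape)

    def transpose(self, *axes):
        return transpose(self, axes if axes else None)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents):
        out._parents = parents
        out._backward = backward
        out.requires_grad = True
    return out


# -- primitive ops --------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def backward(g):
        a._accum(_unbroadcast(g, a.data.shape))
        b._accum(_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data

    def backward(g):
        a._accum(_unbroadcast(g * b.data, a.data.shape))
        b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = _as_tensor(a)
    data = a.data ** p

    def backward(g):
        a._accum(g * p * a.data ** (p - 1.0))

    return _make(data, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data @ b.data

    def backward(g):
        if b.data.ndim >= 2:
            ga = g @ np.swapaxes(b.data, -1, -2)
        else:  # b is a vector
            ga = np.expand_dims(g, -1) * b.data
        if a.data.ndim >= 2:
            gb = np.swapaxes(a.data, -1, -2) @ g
        else:
            gb = np.expand_dims(a.data, -1) * np.expand_dims(g, -2)
        a._accum(_unbroadcast(ga, a.data.shape))
        b._accum(_unbroadcast(gb, b.data.shape))

    return _make(data, (a, b), backward)


def _scatter_rows(index: np.ndarray, rows: np.ndarray, n_out: int) -> np.ndarray:
    """Sum ``rows`` into ``n_out`` buckets (sort + reduceat; faster than ufunc.at)."""
    out_shape = (n_out,) + rows.shape[1:]
    out = np.zeros(out_shape, dtype=rows.dtype)
    if index.size == 0:
        return out
    order = np.argsort(index, kind="stable")
    sorted_idx = index[order]
    boundaries = np.flatnonzero(np.diff(sorted_idx)) + 1
    starts = np.concatenate(([0], boundaries))
    sums = np.add.reduceat(rows.reshape(rows.shape[0], -1)[order], starts, axis=0)
    out.reshape(n_out, -1)[sorted_idx[starts]] = sums
    return out


def getitem(a, idx) -> Tensor:
    a = _as_tensor(a)
    data = a.data[idx]

    def backward(g):
        if isinstance(idx, slice):
            ga = np.zeros_like(a.data)
            ga[idx] = g
        elif isinstance(idx, np.ndarray) and idx.dtype != bool and a.data.ndim >= 1:
            ga = _scatter_rows(idx.ravel().astype(np.intp),
                               g.reshape((-1,) + a.data.shape[1:]), a.data.shape[0])
        else:
            ga = np.zeros_like(a.data)
            np.add.at(ga, idx, g)
        a._accum(ga)

    return _make(data, (a,), backward)


def take_rows(a, index: np.ndarray) -> Tensor:
    """Gather rows along axis 0 (integer index array)."""
    a = _as_tensor(a)
    index = np.asarray(index, dtype=np.intp)
    data = a.data[index]

    def backward(g):
        a._accum(_scatter_rows(index, g, a.data.shape[0]))

    return _make(data, (a,), backward)


def segment_sum(a, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``a`` into ``num_segments`` buckets given by ``segment_ids``."""
    a = _as_tensor(a)
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    data = _scatter_rows(segment_ids, a.data, num_segments)

    def backward(g):
        a._accum(g[segment_ids])

    return _make(data, (a,), backward)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return _make(data, tuple(tensors), backward)


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    data = a.data.reshape(shape)

    def backward(g):
        a._accum(g.reshape(a.data.shape))

    return _make(data, (a,), backward)


def transpose(a, axes=None) -> Tensor:
    a = _as_tensor(a)
    data = a.data.transpose(axes)
    inv = None if axes is None else np.argsort(axes)

    def backward(g):
        a._accum(g.transpose(inv))

    return _make(data, (a,), backward)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accum(np.broadcast_to(g, a.data.shape))

    return _make(data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def exp(a) -> Tensor:
    a = _as_tensor(a)
    data = np.exp(a.data)

    def backward(g):
        a._accum(g * data)

    return _make(data, (a,), backward)


def log(a) -> Tensor:
    a = _as_tensor(a)
    data = np.log(a.data)

    def backward(g):
        a._accum(g / a.data)

    return _make(data, (a,), backward)


def sqrt(a) -> Tensor:
    a = _as_tensor(a)
    data = np.sqrt(a.data)

    def backward(g):
        a._accum(g * 0.5 / data)

    return _make(data, (a,), backward)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0
    data = np.where(mask, a.data, 0.0)

    def backward(g):
        a._accum(g * mask)

    return _make(data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        a._accum(g * data * (1.0 - data))

    return _make(data, (a,), backward)


def tanh(a) -> Tensor:
    a = _as_tensor(a)
    data = np.tanh(a.data)

    def backward(g):
        a._accum(g * (1.0 - data * data))

    return _make(data, (a,), backward)


def silu(a) -> Tensor:
    a = _as_tensor(a)
    sig = 1.0 / (1.0 + np.exp(-a.data))
    data = a.data * sig

    def backward(g):
        a._accum(g * (sig + a.data * sig * (1.0 - sig)))

    return _make(data, (a,), backward)


def softmax(a, axis: int = -1) -> Tensor:
    a = _as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * data).sum(axis=axis, keepdims=True)
        a._accum(data * (g - dot))

    return _make(data, (a,), backward)


def layer_norm(a, gamma, beta, eps: float = 1e-5) -> Tensor:
    """Fused layer norm over the last axis with learnable scale/shift."""
    a, gamma, beta = _as_tensor(a), _as_tensor(gamma), _as_tensor(beta)
    mu = a.data.mean(axis=-1, keepdims=True)
    xc = a.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    data = gamma.data * xhat + beta.data
    n = a.data.shape[-1]

    def backward(g):
        gxh = g * gamma.data
        gv = (gxh * xhat).sum(axis=-1, keepdims=True)
        gm = gxh.sum(axis=-1, keepdims=True)
        a._accum(inv * (gxh - gm / n - xhat * gv / n))
        gamma._accum(_unbroadcast(g * xhat, gamma.data.shape))
        beta._accum(_unbroadcast(g, beta.data.shape))

    return _make(data, (a, gamma, beta), backward)


def vector_norm(v, axis: int = 1, eps: float = 1e-8) -> Tensor:
    """Safe Euclidean norm along ``axis`` (used on (N, 3, C) vector features)."""
    v = _as_tensor(v)
    sq = (v.data * v.data).sum(axis=axis)
    data = np.sqrt(sq + eps)

    def backward(g):
        v._accum(np.expand_dims(g / data, axis) * v.data)

    return _make(data, (v,), backward)
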
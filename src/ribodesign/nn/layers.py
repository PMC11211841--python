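"""Parameterized layers built on the autodiff core: Linear, MLP, LayerNorm,
multi-head attention, and the geometric vector perceptron (GVP).

Modules hold named parameters in insertion order; ``Module.parameters()``
flattens the tree, which is what the optimizer and the checkpoint writer see.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Module:
    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        elif isinstance(value, ModuleList):
            self.__dict__.setdefault("_children", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + name, p) for name, p in self._params.items()]
        for cname, child in self._children.items():
            out.extend(child.named_parameters(prefix + cname + "."))
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


class ModuleList(Module):
    def __init__(self, modules):
        super().__init__()
        self._list = list(modules)
        for i, m in enumerate(self._list):
            self._children[str(i)] = m

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


def _param(shape, rng: np.random.Generator, scale: Optional[float] = None) -> Tensor:
    if scale is None:  # Kaiming-uniform-ish for linear layers
        fan_in = shape[0] if len(shape) > 1 else shape[0]
        scale = 1.0 / np.sqrt(fan_in)
    return Tensor(rng.uniform(-scale, scale, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True, init: str = "kaiming"):
        super().__init__()
        if init == "zero":
            self.W = Tensor(np.zeros((d_in, d_out)), requires_grad=True)
        else:
            self.W = _param((d_in, d_out), rng)
        self.b = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.W
        if self.b is not None:
            y = y + self.b
        return y


class MLP(Module):
    """Two-layer perceptron with SiLU activation."""

    def __init__(self, d_in: int, d_hidden: int, d_out: int, rng):
        super().__init__()
        self.fc1 = Linear(d_in, d_hidden, rng)
        self.fc2 = Linear(d_hidden, d_out, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(T.silu(self.fc1(x)))


class LayerNorm(Module):
    def __init__(self, dim: int):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return T.layer_norm(x, self.gamma, self.beta)


class MultiHeadAttention(Module):
    """Standard scaled dot-product attention over one chain of tokens."""

    def __init__(self, dim: int, n_heads: int, rng):
        super().__init__()
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = dim // n_heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        h, dh = self.n_heads, self.d_head

        def split(t):  # (n, dim) -> (h, n, dh)
            return T.transpose(T.reshape(t, (n, h, dh)), (1, 0, 2))

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = T.matmul(q, T.transpose(k, (0, 2, 1))) * (1.0 / np.sqrt(dh))
        attn = T.softmax(scores, axis=-1)
        ctx = T.matmul(attn, v)  # (h, n, dh)
        ctx = T.reshape(T.transpose(ctx, (1, 0, 2)), (n, h * dh))
        return self.wo(ctx)


class GVP(Module):
    """Geometric vector perceptron: jointly maps scalar features (n, s_in)
    and vector features (n, 3, v_in) to (n, s_out) and (n, 3, v_out).

    Scalars see the norms of linearly mixed vectors; output vectors are gated
    by a sigmoid of learned scalar channels, so scalar outputs are invariant
    and vector outputs equivariant under global rotation.
    """

    def __init__(self, s_in: int, v_in: int, s_out: int, v_out: int, rng,
                 v_hidden: Optional[int] = None, activate: bool = True):
        super().__init__()
        self.v_in, self.v_out = v_in, v_out
        self.activate = activate
        vh = v_hidden or max(v_in, v_out)
        self.vh = vh
        if v_in > 0:
            self.wh = _param((v_in, vh), rng)
            self.ws = Linear(s_in + vh, s_out, rng)
        else:
            self.ws = Linear(s_in, s_out, rng)
        if v_out > 0:
            if v_in == 0:
                raise ValueError("cannot produce vector outputs without vector inputs")
            self.wmu = _param((vh, v_out), rng)
            self.wg = Linear(s_out, v_out, rng)

    def __call__(self, s: Tensor, v: Optional[Tensor]):
        if self.v_in > 0:
            vh = v @ self.wh                      # (n, 3, vh)
            norms = T.vector_norm(vh, axis=1)     # (n, vh)
            s_pre = self.ws(T.concat([s, norms], axis=-1))
        else:
            s_pre = self.ws(s)
        s_out = T.relu(s_pre) if self.activate else s_pre
        if self.v_out == 0:
            return s_out, None
        gate = T.sigmoid(self.wg(s_pre))          # (n, v_out)
        v_out = (vh @ self.wmu) * T.reshape(gate, (gate.shape[0], 1, self.v_out))
        return s_out, v_out
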
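"""The data-prediction network d_theta.

A GVP-based message-passing structure module turns the nucleotide graph into
SE(3)-invariant per-node embeddings; a Transformer sequence module with
adaptive layer norm conditioned on the log-SNR lambda_t refines them into an
(N, 4) estimate of the clean one-hot sequence.  The corrupted sequence state
S_t and the self-conditioning estimate enter both modules as extra node
channels.  When the structure condition is dropped, the structure module is
bypassed and a learned null token stands in for the geometry embedding, which
realizes the unconditional model of classifier-free guidance (feeding zero
coordinates instead would poison the dihedral features).

Batching uses a disjoint union over chains: the graph stage runs once on the
stacked node/edge arrays, attention runs per chain, and all pointwise layers
run on the flat token matrix.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .nn import tensor as T
from .nn.tensor import Tensor
from .features import FeatureConfig, NucleotideGraph


@dataclass(frozen=True)
class DenoiserConfig:
    n_gvp_layers: int = 3
    n_transformer_layers: int = 4
    hidden_scalar_dim: int = 64
    hidden_vector_dim: int = 8
    n_heads: int = 4
    ffn_dim: int = 256

    def __post_init__(self):
        for f, v in asdict(self).items():
            if v < 1:
                raise ValueError(f"{f} must be a positive integer")
        if self.hidden_scalar_dim % self.n_heads:
            raise ValueError("hidden_scalar_dim must be divisible by n_heads")


@dataclass
class DenoiserInput:
    """One chain's worth of inputs to d_theta."""

    St: np.ndarray                     # (N, 4) corrupted one-hot
    self_cond: np.ndarray              # (N, 4) previous prediction or zeros
    lambda_t: float                    # log-SNR
    graph: NucleotideGraph | None = None  # absent => unconditional path

    def __post_init__(self):
        self.St = np.asarray(self.St, dtype=np.float64)
        self.self_cond = np.asarray(self.self_cond, dtype=np.float64)
        if self.St.shape != self.self_cond.shape or self.St.ndim != 2 or self.St.shape[1] != 4:
            raise ValueError("St and self_cond must both be (N, 4)")
        if self.graph is not None and self.graph.n_nodes != self.St.shape[0]:
            raise ValueError("graph size does not match sequence length")
        if not np.isfinite(self.lambda_t):
            raise ValueError("lambda_t must be finite")


class _GVPConvLayer(nn.Module):
    """One message-passing layer: edge-message GVP, mean aggregation,
    residual + LayerNorm on scalars, then a pointwise node GVP."""

    def __init__(self, hs: int, hv: int, e_s: int, rng, final: bool = False):
        super().__init__()
        self.msg = nn.GVP(2 * hs + e_s, 2 * hv + 1, hs, hv, rng)
        # the scalar read-out never sees vectors produced by the last node
        # update, so the final layer's pointwise GVP emits scalars only
        self.node = nn.GVP(hs, hv, hs, 0 if final else hv, rng)
        self.ln1 = nn.LayerNorm(hs)
        self.ln2 = nn.LayerNorm(hs)

    def __call__(self, s, v, edges, edge_s, edge_v, inv_deg):
        i, j = edges[:, 0], edges[:, 1]
        ms_in = T.concat([T.take_rows(s, i), T.take_rows(s, j), edge_s], axis=-1)
        mv_in = T.concat([T.take_rows(v, i), T.take_rows(v, j), edge_v], axis=-1)
        ms, mv = self.msg(ms_in, mv_in)
        n = s.shape[0]
        agg_s = T.segment_sum(ms, i, n) * inv_deg
        agg_v = T.segment_sum(mv, i, n) * T.reshape(inv_deg, (n, 1, 1))
        s = self.ln1(s + agg_s)
        v = v + agg_v
        us, uv = self.node(s, v)
        return self.ln2(s + us), (v if uv is None else v + uv)


class _AdaLNBlock(nn.Module):
    """Transformer block with adaptive layer norm and activation gating.

    adaLN(h, C) = (1 + MLP1(C)) * LN(h) + MLP2(C);  act(h, C) = MLP3(C) * h.
    The conditioning heads start near zero (gates near one), so an untrained
    block is close to a plain pre-norm Transformer block while the context
    already has a non-zero influence at initialization.
    """

    HEAD_INIT = 0.1  # shrink factor for the conditioning-head weights

    def __init__(self, dim: int, n_heads: int, ffn_dim: int, rng):
        super().__init__()
        self.mha = nn.MultiHeadAttention(dim, n_heads, rng)
        self.ffn1 = nn.Linear(dim, ffn_dim, rng)
        self.ffn2 = nn.Linear(ffn_dim, dim, rng)
        self._ones = Tensor(np.ones(dim))
        self._zeros = Tensor(np.zeros(dim))
        for name in ("scale1", "shift1", "scale2", "shift2", "gate1", "gate2"):
            head = nn.Linear(dim, dim, rng)
            head.W.data *= self.HEAD_INIT
            setattr(self, name, head)
        self.gate1.b.data[:] = 1.0
        self.gate2.b.data[:] = 1.0

    def _ln(self, h):
        return T.layer_norm(h, self._ones, self._zeros)

    def __call__(self, h, ctx, chain_slices):
        a = (1.0 + self.scale1(ctx)) * self._ln(h) + self.shift1(ctx)
        m = T.concat([self.mha(a[sl]) for sl in chain_slices], axis=0) \
            if len(chain_slices) > 1 else self.mha(a)
        h = self.gate1(ctx) * m + h
        f = (1.0 + self.scale2(ctx)) * self._ln(h) + self.shift2(ctx)
        f = self.ffn2(T.silu(self.ffn1(f)))
        return self.gate2(ctx) * f + h


class Denoiser(nn.Module):
    def __init__(self, config: DenoiserConfig | None = None,
                 feat: FeatureConfig | None = None, seed: int = 0):
        super().__init__()
        self.config = config or DenoiserConfig()
        self.feat = feat or FeatureConfig()
        rng = np.random.default_rng(seed)
        hs, hv = self.config.hidden_scalar_dim, self.config.hidden_vector_dim

        self.embed_s = nn.Linear(self.feat.node_scalar_dim + 8, hs, rng)
        self.embed_v = Tensor(rng.uniform(-0.5, 0.5, (self.feat.node_vector_dim, hv)),
                              requires_grad=True)
        self.gvp_layers = nn.ModuleList([
            _GVPConvLayer(hs, hv, self.feat.edge_scalar_dim, rng,
                          final=(i == self.config.n_gvp_layers - 1))
            for i in range(self.config.n_gvp_layers)])
        self.null_token = Tensor(rng.normal(0, 0.02, hs), requires_grad=True)
        self.token_proj = nn.Linear(hs + 8, hs, rng)
        self.lam_mlp = nn.MLP(1, hs, hs, rng)
        self.blocks = nn.ModuleList([
            _AdaLNBlock(hs, self.config.n_heads, self.config.ffn_dim, rng)
            for _ in range(self.config.n_transformer_layers)])
        self.out_ln = nn.LayerNorm(hs)
        self.out1 = nn.Linear(hs, hs, rng)
        self.out2 = nn.Linear(hs, 4, rng)

    # -- structure module --------------------------------------------------
    def _structure_union(self, items: list[DenoiserInput]) -> list[Tensor]:
        """Run the GVP stack on the disjoint union of the given chains."""
        sizes = [it.St.shape[0] for it in items]
        offsets = np.cumsum([0] + sizes)
        node_s = np.concatenate(
            [np.concatenate([it.graph.node_scalars, it.St, it.self_cond], axis=1)
             for it in items], axis=0)
        node_v = np.concatenate([it.graph.node_vectors for it in items], axis=0)
        edges = np.concatenate(
            [it.graph.edges + off for it, off in zip(items, offsets[:-1])], axis=0)
        edge_s = Tensor(np.concatenate([it.graph.edge_scalars for it in items], axis=0))
        edge_v = Tensor(np.concatenate([it.graph.edge_vectors for it in items], axis=0))

        n = node_s.shape[0]
        deg = np.bincount(edges[:, 0], minlength=n).astype(np.float64)
        inv_deg = Tensor((1.0 / np.maximum(deg, 1.0))[:, None])

        s = self.embed_s(Tensor(node_s))
        v = Tensor(node_v) @ self.embed_v
        for layer in self.gvp_layers:
            s, v = layer(s, v, edges, edge_s, edge_v, inv_deg)
        return [s[offsets[b]:offsets[b + 1]] for b in range(len(items))]

    def structure_module_forward(self, graph: NucleotideGraph, St, self_cond) -> np.ndarray:
        """Invariant per-node embeddings for one chain (inference helper)."""
        item = DenoiserInput(St=St, self_cond=self_cond, lambda_t=0.0, graph=graph)
        with T.no_grad():
            return self._structure_union([item])[0].data

    # -- sequence module ---------------------------------------------------
    def _sequence(self, tokens: Tensor, ctx: Tensor, chain_slices) -> Tensor:
        h = tokens
        for block in self.blocks:
            h = block(h, ctx, chain_slices)
        return self.out2(T.silu(self.out1(self.out_ln(h))))

    def sequence_module_forward(self, h0: np.ndarray, lambda_t: float) -> np.ndarray:
        """Run the Transformer stack on given tokens (inference helper)."""
        with T.no_grad():
            ctx = self.lam_mlp(Tensor(np.asarray([[lambda_t / 8.0]])))
            out = self._sequence(Tensor(h0), ctx, [slice(0, h0.shape[0])])
            return out.data

    # -- full model --------------------------------------------------------
    def forward_batch(self, items: list[DenoiserInput]) -> list[Tensor]:
        """d_theta on a batch of chains; conditional and unconditional chains
        may be mixed.  Returns one (N_b, 4) tensor per input, in order."""
        cond_idx = [b for b, it in enumerate(items) if it.graph is not None]
        struct: dict[int, Tensor] = {}
        if cond_idx:
            outs = self._structure_union([items[b] for b in cond_idx])
            struct = dict(zip(cond_idx, outs))

        tok_parts = []
        for b, it in enumerate(items):
            n = it.St.shape[0]
            seq_feats = Tensor(np.concatenate([it.St, it.self_cond], axis=1))
            if b in struct:
                geom = struct[b]
            else:
                geom = T.reshape(self.null_token, (1, -1)) * Tensor(np.ones((n, 1)))
            tok_parts.append(self.token_proj(T.concat([geom, seq_feats], axis=-1)))
        tokens = T.concat(tok_parts, axis=0) if len(tok_parts) > 1 else tok_parts[0]

        sizes = [it.St.shape[0] for it in items]
        offsets = np.cumsum([0] + sizes)
        chain_slices = [slice(offsets[b], offsets[b + 1]) for b in range(len(items))]
        node2chain = np.repeat(np.arange(len(items)), sizes)
        lam = np.asarray([[it.lambda_t / 8.0] for it in items])
        ctx = T.take_rows(self.lam_mlp(Tensor(lam)), node2chain)

        out = self._sequence(tokens, ctx, chain_slices)
        if not np.all(np.isfinite(out.data)):
            raise FloatingPointError("non-finite denoiser output")
        return [out[sl] for sl in chain_slices]

    def denoise(self, input: DenoiserInput) -> np.ndarray:
        """Single-chain prediction of S_0, no gradient graph."""
        with T.no_grad():
            return self.forward_batch([input])[0].data

    def denoise_batch(self, items: list[DenoiserInput]) -> list[np.ndarray]:
        with T.no_grad():
            return [t.data for t in self.forward_batch(items)]

    # -- persistence -------------------------------------------------------
    def save(self, path: str):
        meta = json.dumps({"format": 1,
                           "config": asdict(self.config),
                           "feat": asdict(self.feat)})
        arrays = {f"param/{k}": v for k, v in self.state_dict().items()}
        np.savez_compressed(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                            **arrays)

    @classmethod
    def load(cls, path: str) -> "Denoiser":
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["__meta__"]).decode())
            state = {k[len("param/"):]: npz[k] for k in npz.files if k.startswith("param/")}
        model = cls(DenoiserConfig(**meta["config"]), FeatureConfig(**meta["feat"]))
        model.load_state_dict(state)
        return model
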
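"""Sequence generation for a fixed backbone by iterative ancestral denoising.

Starting from S ~ N(0, I), each grid step predicts the clean sequence with
the (optionally guidance-mixed) data-prediction model, takes the exact
Gaussian posterior step toward the next time, and carries the prediction
forward as self-conditioning.  The terminal read-out is the predicted mean at
the last grid time, decoded by per-position argmax.

With guidance weight w != 1 the conditional and unconditional branches are
both evaluated and mixed as w * d_cond + (1 - w) * d_uncond; the guided
estimate is shared as the single self-conditioning buffer of both branches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backbone import CoarseBackbone
from .diffusion import TimeGrid, NoiseSchedule, ancestral_step, decode, guided_prediction
from .features import FeatureConfig, NucleotideGraph, featurize
from .model import Denoiser, DenoiserInput


@dataclass
class GeneratedSet:
    """Sampled sequences for one backbone, with the sampling settings."""

    backbone_id: str
    sequences: list[str]
    guidance_w: float
    steps: int
    seed: int | None = None

    def __post_init__(self):
        if any(set(s) - set("ACGU") for s in self.sequences):
            raise ValueError("generated sequences must be over ACGU")


def _sample_chains(graphs: list[NucleotideGraph], model: Denoiser,
                   schedule: NoiseSchedule, grid: TimeGrid, w: float,
                   rng: np.random.Generator) -> list[str]:
    """Run the reverse process jointly for a list of chains (batched)."""
    states = [rng.standard_normal((g.n_nodes, 4)) for g in graphs]
    self_conds = [np.zeros((g.n_nodes, 4)) for g in graphs]
    means = [None] * len(graphs)
    times = grid.times
    for i in range(1, times.size):
        t, s = float(times[i - 1]), float(times[i])
        lam = float(schedule.lam(t))
        cond = [DenoiserInput(St=st, self_cond=sc, lambda_t=lam, graph=g)
                for st, sc, g in zip(states, self_conds, graphs)]
        d_cond = model.denoise_batch(cond)
        if w != 1.0:
            unc = [DenoiserInput(St=st, self_cond=sc, lambda_t=lam, graph=None)
                   for st, sc in zip(states, self_conds)]
            d_unc = model.denoise_batch(unc)
            s0hat = [guided_prediction(c, u, w) for c, u in zip(d_cond, d_unc)]
        else:
            s0hat = d_cond
        self_conds = s0hat
        last = i == times.size - 1
        for b in range(len(graphs)):
            noise = None if last else rng.standard_normal(states[b].shape)
            states[b], means[b] = ancestral_step(states[b], s0hat[b], t, s,
                                                 schedule, noise=noise)
    return [decode(m) for m in means]


def generate(backbone: CoarseBackbone, model: Denoiser, schedule: NoiseSchedule,
             grid: TimeGrid | None = None, w: float = 1.0, n_samples: int = 8,
             rng: np.random.Generator | None = None,
             seed: int | None = None) -> GeneratedSet:
    """Generate ``n_samples`` sequences for one backbone."""
    if len(backbone) == 0:
        raise ValueError("backbone has no nucleotides")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    grid = grid or TimeGrid.uniform()
    if rng is None:
        rng = np.random.default_rng(seed)
    graph = featurize(backbone, model.feat)
    seqs = _sample_chains([graph] * n_samples, model, schedule, grid, w, rng)
    return GeneratedSet(backbone_id=backbone.name or backbone.chain_id,
                        sequences=seqs, guidance_w=w, steps=grid.n_steps, seed=seed)


def generate_many(backbones: list[CoarseBackbone], model: Denoiser,
                  schedule: NoiseSchedule, grid: TimeGrid | None = None,
                  w: float = 1.0, n_samples: int = 1,
                  rng: np.random.Generator | None = None,
                  seed: int | None = None) -> list[GeneratedSet]:
    """Generate for many backbones in one batched reverse process.

    All backbone-sample pairs share each denoiser call, which keeps CPU
    sampling fast; results are deterministic given the rng.
    """
    grid = grid or TimeGrid.uniform()
    if rng is None:
        rng = np.random.default_rng(seed)
    graphs = [featurize(bb, model.feat) for bb in backbones]
    flat = [g for g in graphs for _ in range(n_samples)]
    seqs = _sample_chains(flat, model, schedule, grid, w, rng)
    out = []
    for b, bb in enumerate(backbones):
        out.append(GeneratedSet(backbone_id=bb.name or bb.chain_id,
                                sequences=seqs[b * n_samples:(b + 1) * n_samples],
                                guidance_w=w, steps=grid.n_steps, seed=seed))
    return out
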
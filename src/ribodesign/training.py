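"""Training loop for the data-prediction model.

Each step draws a per-example diffusion time t ~ U(t_min, 1], corrupts the
one-hot sequence with the forward kernel, and minimizes the weighted squared
error (alpha_t / sigma_t) * ||d_theta([S_t, S0_tilde], lambda_t, X) - S_0||^2.
With probability ``p_self_cond`` a no-gradient pre-pass supplies the
self-conditioning estimate S0_tilde (stop-gradient); with probability
``p_drop_struct`` the structure condition is dropped for that example, which
trains the unconditional branch used by classifier-free guidance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backbone import CoarseBackbone
from .diffusion import NoiseSchedule, encode_onehot, forward_sample
from .features import FeatureConfig, NucleotideGraph, featurize
from .model import Denoiser, DenoiserInput
from .nn import Adam
from .nn import tensor as T


@dataclass(frozen=True)
class TrainConfig:
    p_self_cond: float = 0.5
    p_drop_struct: float = 0.4
    batch_size: int = 16
    lr: float = 1e-3
    steps: int = 600
    t_min: float = 1e-3
    seed: int = 0
    log_every: int = 25

    def __post_init__(self):
        for name in ("p_self_cond", "p_drop_struct"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")


@dataclass
class TrainingExample:
    graph: NucleotideGraph
    S0: np.ndarray
    sequence: str
    backbone: CoarseBackbone | None = None


def make_training_set(pairs: list[tuple[CoarseBackbone, str]],
                      feat: FeatureConfig | None = None) -> list[TrainingExample]:
    """Featurize (backbone, sequence) pairs once, up front."""
    feat = feat or FeatureConfig()
    out = []
    for bb, seq in pairs:
        if len(seq) != len(bb):
            raise ValueError("sequence length does not match backbone")
        out.append(TrainingExample(graph=featurize(bb, feat), S0=encode_onehot(seq),
                                   sequence=seq, backbone=bb))
    return out


def training_step(batch: list[TrainingExample], model, schedule: NoiseSchedule,
                  config: TrainConfig, rng: np.random.Generator):
    """Build the batch loss graph; returns (loss Tensor, stats dict).

    ``model`` only needs a ``forward_batch(list[DenoiserInput]) -> list`` —
    tests exercise the contract with mock models.
    """
    n_ex = len(batch)
    ts = rng.uniform(config.t_min, 1.0, size=n_ex)
    self_flags = rng.uniform(0.0, 1.0, size=n_ex) < config.p_self_cond
    drop_flags = rng.uniform(0.0, 1.0, size=n_ex) < config.p_drop_struct

    Sts, self_conds = [], []
    for b, ex in enumerate(batch):
        noise = rng.standard_normal(ex.S0.shape)
        Sts.append(forward_sample(ex.S0, ts[b], schedule, noise))
        self_conds.append(np.zeros_like(ex.S0))
    lams = schedule.lam(ts)

    # self-conditioning pre-pass: conditional, no gradient graph (stop-gradient)
    pre_idx = [b for b in range(n_ex) if self_flags[b]]
    if pre_idx:
        with T.no_grad():
            pre_items = [DenoiserInput(St=Sts[b], self_cond=self_conds[b],
                                       lambda_t=lams[b], graph=batch[b].graph)
                         for b in pre_idx]
            preds = model.forward_batch(pre_items)
        for b, p in zip(pre_idx, preds):
            self_conds[b] = np.asarray(p.data if hasattr(p, "data") else p)

    items = [DenoiserInput(St=Sts[b], self_cond=self_conds[b], lambda_t=lams[b],
                           graph=None if drop_flags[b] else batch[b].graph)
             for b in range(n_ex)]
    outputs = model.forward_batch(items)

    weights = schedule.loss_weight(ts)
    total = None
    for b, out in enumerate(outputs):
        err = out - T.Tensor(batch[b].S0)
        term = (err * err).sum() * float(weights[b])
        total = term if total is None else total + term
    loss = total * (1.0 / n_ex)
    if not np.isfinite(loss.data):
        raise FloatingPointError(
            f"non-finite loss (t range [{ts.min():.4g}, {ts.max():.4g}], "
            f"lambda range [{lams.min():.4g}, {lams.max():.4g}])")
    stats = {"t": ts, "self_cond": self_flags, "drop_struct": drop_flags,
             "loss": float(loss.data)}
    return loss, stats


@dataclass
class TrainLog:
    steps: list[int] = field(default_factory=list)
    losses: list[float] = field(default_factory=list)
    eval_recovery: list[float] = field(default_factory=list)
    self_cond_count: int = 0
    drop_count: int = 0
    example_count: int = 0


def _quick_recovery(model, schedule, eval_set, rng) -> float:
    """Cheap held-out recovery probe: short-grid conditional generation."""
    from .diffusion import TimeGrid, decode
    from .sampling import _sample_chains

    graphs = [ex.graph for ex in eval_set]
    seqs = _sample_chains(graphs, model, schedule, TimeGrid.uniform(10),
                          w=1.0, rng=rng)
    hits = sum(a == b for s, ex in zip(seqs, eval_set)
               for a, b in zip(s, ex.sequence))
    total = sum(len(ex.sequence) for ex in eval_set)
    return hits / total


def train(dataset: list[TrainingExample], model: Denoiser, schedule: NoiseSchedule,
          config: TrainConfig | None = None,
          rng: np.random.Generator | None = None,
          eval_set: list[TrainingExample] | None = None) -> TrainLog:
    """Optimize the model with Adam; deterministic given the rng seed.

    With ``eval_set`` given, held-out sequence recovery (short sampling grid,
    w=1) is probed at every logging point.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    config = config or TrainConfig()
    rng = rng or np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.lr)
    log = TrainLog()
    for step in range(config.steps):
        idx = rng.integers(0, len(dataset), size=min(config.batch_size, len(dataset)))
        batch = [dataset[i] for i in idx]
        opt.zero_grad()
        loss, stats = training_step(batch, model, schedule, config, rng)
        loss.backward()
        opt.step()
        log.self_cond_count += int(stats["self_cond"].sum())
        log.drop_count += int(stats["drop_struct"].sum())
        log.example_count += len(batch)
        if step % config.log_every == 0 or step == config.steps - 1:
            log.steps.append(step)
            log.losses.append(stats["loss"])
            if eval_set:
                log.eval_recovery.append(
                    _quick_recovery(model, schedule, eval_set,
                                    np.random.default_rng(config.seed + 1)))
    return log
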
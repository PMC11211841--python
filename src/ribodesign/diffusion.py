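"""Continuous-time Gaussian diffusion over relaxed one-hot sequences.

The forward process perturbs a one-hot encoded sequence ``S0`` (an N x 4 real
matrix, columns ordered A, C, G, U) with the variance-preserving kernel

    q(S_t | S_0) = N(alpha_t * S_0, sigma_t^2 * I),   t in (0, 1],

where ``alpha_t^2 + sigma_t^2 = 1`` and the signal-to-noise ratio
``SNR(t) = alpha_t^2 / sigma_t^2`` is strictly decreasing.  Sampling runs the
exact Gaussian ancestral reverse step driven by a data-prediction model
(a network that estimates ``S_0`` from ``S_t``); classifier-free guidance
mixes conditional and unconditional predictions.

Everything here is network-free NumPy math; the denoising network plugs in
through :func:`ancestral_step` and :func:`guided_prediction`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

ALPHABET = "ACGU"
_LETTER_TO_COL = {c: i for i, c in enumerate(ALPHABET)}


class ScheduleError(ValueError):
    """Raised for invalid diffusion times or inconsistent step grids."""


# ---------------------------------------------------------------------------
# noise schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseSchedule:
    """Variance-preserving schedule defined by ``alpha(t)`` on (0, 1].

    ``sigma(t) = sqrt(1 - alpha(t)^2)`` and ``lam(t) = log SNR(t)``.
    """

    name: str
    _alpha_fn: Callable[[np.ndarray], np.ndarray] = field(repr=False)

    def alpha(self, t):
        return self._alpha_fn(np.asarray(t, dtype=np.float64))

    def sigma(self, t):
        a = self.alpha(t)
        return np.sqrt(np.clip(1.0 - a * a, 1e-12, None))

    def snr(self, t):
        a = self.alpha(t)
        s2 = np.clip(1.0 - a * a, 1e-12, None)
        return a * a / s2

    def lam(self, t):
        return np.log(self.snr(t))

    def loss_weight(self, t):
        """Eq.-style weight alpha_t / sigma_t multiplying the squared error."""
        _check_time(t)
        return self.alpha(t) / self.sigma(t)


def _check_time(t):
    t = np.asarray(t, dtype=np.float64)
    if np.any(t <= 0.0) or np.any(t > 1.0):
        raise ScheduleError(f"diffusion time must lie in (0, 1], got {t!r}")


def cosine_schedule(trim: float = 0.99) -> NoiseSchedule:
    """Trimmed cosine VP schedule: alpha(t) = cos(trim * pi/2 * t).

    The trim keeps alpha strictly positive at t = 1 (alpha(1) ~ 0.016, so the
    terminal marginal is within 1e-4 of N(0, I) in total variation) while the
    SNR stays strictly decreasing on all of (0, 1] with no clipping plateau.
    """
    a = trim * np.pi / 2.0

    def alpha_fn(t):
        return np.cos(a * t)

    return NoiseSchedule(name=f"cosine(trim={trim})", _alpha_fn=alpha_fn)


def linear_beta_schedule(beta_min: float = 0.1, beta_max: float = 20.0) -> NoiseSchedule:
    """Classic linear-beta VP schedule: alpha(t) = exp(-1/4 t^2 (bmax-bmin) - 1/2 t bmin)."""

    def alpha_fn(t):
        return np.exp(-0.25 * t * t * (beta_max - beta_min) - 0.5 * t * beta_min)

    return NoiseSchedule(name=f"linear_beta({beta_min},{beta_max})", _alpha_fn=alpha_fn)


def get_schedule(name: str = "cosine") -> NoiseSchedule:
    if name == "cosine":
        return cosine_schedule()
    if name == "linear":
        return linear_beta_schedule()
    raise ScheduleError(f"unknown schedule {name!r}")


# ---------------------------------------------------------------------------
# sequence state and one-hot codec
# ---------------------------------------------------------------------------

@dataclass
class SequenceState:
    """Continuous sequence representation at diffusion time ``time``."""

    values: np.ndarray  # (N, 4)
    time: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != 4 or self.values.shape[0] < 1:
            raise ValueError(f"sequence state must be (N, 4) with N >= 1, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sequence state contains non-finite values")


def encode_onehot(sequence: str) -> np.ndarray:
    """One-hot encode a sequence over {A, C, G, U} as an (N, 4) array."""
    out = np.zeros((len(sequence), 4), dtype=np.float64)
    for i, c in enumerate(sequence):
        try:
            out[i, _LETTER_TO_COL[c]] = 1.0
        except KeyError:
            raise ValueError(f"cannot encode letter {c!r} at position {i}; alphabet is ACGU")
    return out


def decode(values: np.ndarray) -> str:
    """Per-position argmax decode; exact ties resolve to the alphabetically
    first letter (argmax picks the lowest column index, columns are A,C,G,U)."""
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2 or values.shape[1] != 4:
        raise ValueError(f"expected (N, 4), got {values.shape}")
    return "".join(ALPHABET[j] for j in values.argmax(axis=1))


# ---------------------------------------------------------------------------
# forward / reverse kernels
# ---------------------------------------------------------------------------

def forward_sample(S0: np.ndarray, t: float, schedule: NoiseSchedule,
                   noise: np.ndarray) -> np.ndarray:
    """Sample S_t = alpha_t * S_0 + sigma_t * eps from the forward kernel."""
    _check_time(t)
    S0 = np.asarray(S0, dtype=np.float64)
    noise = np.asarray(noise, dtype=np.float64)
    if noise.shape != S0.shape:
        raise ValueError(f"noise shape {noise.shape} != data shape {S0.shape}")
    return schedule.alpha(t) * S0 + schedule.sigma(t) * noise


def loss_weight(t, schedule: NoiseSchedule):
    """Training-loss multiplier alpha_t / sigma_t."""
    return schedule.loss_weight(t)


def ancestral_step(St: np.ndarray, S0hat: np.ndarray, t: float, s: float,
                   schedule: NoiseSchedule, noise: np.ndarray | None = None,
                   return_mean: bool = False):
    """One exact Gaussian posterior step of the reverse process, t -> s < t.

    With ``a_ts = alpha_t / alpha_s`` and ``var_ts = sigma_t^2 - a_ts^2 sigma_s^2``:

        mean = (a_ts * sigma_s^2 / sigma_t^2) * S_t
             + (alpha_s * var_ts / sigma_t^2) * S0hat
        S_s  = mean + (sqrt(var_ts) * sigma_s / sigma_t) * eps

    Returns ``(S_s, mean)``; with ``return_mean`` or ``noise=None`` the sample
    equals the mean (the terminal read-out of the sampler returns the mean).
    """
    if not (0.0 < s < t <= 1.0):
        raise ScheduleError(f"need 0 < s < t <= 1, got s={s}, t={t}")
    St = np.asarray(St, dtype=np.float64)
    S0hat = np.asarray(S0hat, dtype=np.float64)
    if St.shape != S0hat.shape:
        raise ValueError("St and S0hat shapes differ")
    a_t, a_s = float(schedule.alpha(t)), float(schedule.alpha(s))
    s_t, s_s = float(schedule.sigma(t)), float(schedule.sigma(s))
    a_ts = a_t / a_s
    var_ts = s_t * s_t - a_ts * a_ts * s_s * s_s
    if var_ts < -1e-12:
        raise ScheduleError(f"invalid grid: sigma_{{t|s}}^2 = {var_ts} < 0 for t={t}, s={s}")
    var_ts = max(var_ts, 0.0)
    mean = (a_ts * s_s * s_s / (s_t * s_t)) * St + (a_s * var_ts / (s_t * s_t)) * S0hat
    if return_mean or noise is None:
        return mean, mean
    noise = np.asarray(noise, dtype=np.float64)
    sample = mean + (np.sqrt(var_ts) * s_s / s_t) * noise
    return sample, mean


def guided_prediction(d_cond: np.ndarray, d_uncond: np.ndarray, w: float) -> np.ndarray:
    """Classifier-free guidance mix: w * d_cond + (1 - w) * d_uncond."""
    d_cond = np.asarray(d_cond, dtype=np.float64)
    d_uncond = np.asarray(d_uncond, dtype=np.float64)
    if d_cond.shape != d_uncond.shape:
        raise ValueError("guided_prediction: shape mismatch")
    return w * d_cond + (1.0 - w) * d_uncond


@dataclass(frozen=True)
class TimeGrid:
    """Strictly decreasing sampling times t_0 = T > t_1 > ... > t_M > 0."""

    times: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=np.float64)
        if times.ndim != 1 or times.size < 2:
            raise ScheduleError("time grid needs at least two points")
        if np.any(np.diff(times) >= 0):
            raise ScheduleError("time grid must be strictly decreasing")
        if times[0] > 1.0 or times[-1] <= 0.0:
            raise ScheduleError("time grid must lie in (0, 1]")
        object.__setattr__(self, "times", times)

    @property
    def n_steps(self) -> int:
        return self.times.size - 1

    @classmethod
    def uniform(cls, n_steps: int = 50, t_max: float = 1.0, t_min: float = 1e-3) -> "TimeGrid":
        if n_steps < 1:
            raise ScheduleError("n_steps must be >= 1")
        return cls(np.linspace(t_max, t_min, n_steps + 1))
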
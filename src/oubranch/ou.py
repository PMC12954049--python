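"""Ornstein-Uhlenbeck process: exact transition moments, simulation, prediction.

The OU process ``dY = theta (mu - Y) dt + sigma dW`` is the trait model used
throughout this package: ``mu`` is the equilibrium mean (here usually on the
log10 mutation-frequency scale), ``theta`` the mean-reversion rate (per time
unit) and ``sigma`` the diffusion scale.  Because the transition density is
Gaussian with closed-form moments,

    m(dt) = mu + (y0 - mu) * exp(-theta * dt)
    v(dt) = sigma^2 / (2 theta) * (1 - exp(-2 theta dt)),

simulation and likelihood evaluation are exact for arbitrary, irregular
sampling intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OUParams",
    "TransitionMoments",
    "PredictiveTrajectory",
    "Envelope",
    "stationary_moments",
    "equilibrium_frequency",
    "transition_moments",
    "simulate_exact",
    "predictive_trajectory",
    "predictive_envelope",
]


@dataclass(frozen=True)
class OUParams:
    """Parameter triple of a univariate OU process.

    Parameters
    ----------
    mu : float
        Equilibrium mean (log10 units in the mutation-frequency application).
    theta : float
        Mean-reversion rate, strictly positive, per time unit.
    sigma : float
        Diffusion scale, strictly positive; ``sigma**2`` is the variance
        accumulation rate.
    """

    mu: float
    theta: float
    sigma: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu):
            raise ValueError("mu must be finite")
        if not (self.theta > 0):
            raise ValueError(f"theta must be > 0, got {self.theta}")
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be > 0, got {self.sigma}")

    @property
    def stationary_variance(self) -> float:
        return self.sigma**2 / (2.0 * self.theta)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.mu, self.theta, self.sigma)


@dataclass(frozen=True)
class TransitionMoments:
    """Conditional mean/variance of one exact OU transition over ``dt``."""

    m: float
    v: float
    dt: float


@dataclass(frozen=True)
class PredictiveTrajectory:
    """Analytic predictive mean/variance path conditioned on ``y0`` at ``t0``."""

    times: np.ndarray
    mean: np.ndarray
    var: np.ndarray
    y0: float
    t0: float


@dataclass(frozen=True)
class Envelope:
    """Pointwise empirical quantile band of an ensemble of trajectories."""

    times: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    q: tuple[float, float] = field(default=(0.025, 0.975))


def stationary_moments(params: OUParams) -> tuple[float, float]:
    """Long-run mean and variance ``(mu, sigma^2 / (2 theta))``."""
    return params.mu, params.stationary_variance


def equilibrium_frequency(params: OUParams) -> float:
    """Equilibrium level on the original (frequency) scale, ``10**mu``."""
    return 10.0**params.mu


def transition_moments(params: OUParams, y_prev: float, dt: float) -> TransitionMoments:
    """Exact conditional moments of ``Y(t+dt) | Y(t) = y_prev``.

    Raises
    ------
    ValueError
        If ``dt`` is negative.
    """
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    e = np.exp(-params.theta * dt)
    m = params.mu + (y_prev - params.mu) * e
    v = params.stationary_variance * (1.0 - e * e)
    return TransitionMoments(m=float(m), v=float(v), dt=float(dt))


def _transition_arrays(
    params: OUParams, dts: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized decay factors exp(-theta dt) and variances over an array of gaps."""
    e = np.exp(-params.theta * dts)
    v = params.stationary_variance * (1.0 - e * e)
    return e, v


def simulate_exact(
    params: OUParams,
    y0: float,
    times: np.ndarray,
    n_reps: int = 1,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Simulate OU sample paths with the exact discrete-time solution.

    Parameters
    ----------
    params : OUParams
    y0 : float
        Value at ``times[0]`` (shared by all replicates).
    times : array-like
        Strictly increasing sampling times; the first entry is the time of
        ``y0``.
    n_reps : int
        Number of independent replicate paths.
    seed : int or numpy Generator
        Seed (or generator) driving the Gaussian transition noise; identical
        seeds give bit-identical output.

    Returns
    -------
    ndarray, shape (n_reps, len(times))
        ``out[:, 0] == y0``.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1:
        raise ValueError("times must be a 1-D array with at least one entry")
    dts = np.diff(times)
    if np.any(dts <= 0):
        raise ValueError("times must be strictly increasing")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    e, v = _transition_arrays(params, dts)
    sd = np.sqrt(v)
    out = np.empty((n_reps, times.size), dtype=float)
    out[:, 0] = y0
    noise = rng.standard_normal((n_reps, dts.size))
    for i in range(dts.size):
        out[:, i + 1] = (
            params.mu + (out[:, i] - params.mu) * e[i] + sd[i] * noise[:, i]
        )
    return out


def predictive_trajectory(
    params: OUParams, y0: float, t0: float, times: np.ndarray
) -> PredictiveTrajectory:
    """Analytic predictive mean m(t) and variance v(t) conditioned on (t0, y0)."""
    times = np.asarray(times, dtype=float)
    if np.any(times < t0):
        raise ValueError("all prediction times must be >= t0")
    e, v = _transition_arrays(params, times - t0)
    mean = params.mu + (y0 - params.mu) * e
    return PredictiveTrajectory(times=times, mean=mean, var=v, y0=y0, t0=t0)


def predictive_envelope(
    simulations: np.ndarray,
    q: tuple[float, float] = (0.025, 0.975),
    times: np.ndarray | None = None,
) -> Envelope:
    """Pointwise empirical quantile envelope of simulated trajectories.

    Quantiles use linear interpolation between order statistics (numpy's
    default), so the band is continuous in the ensemble size.

    Parameters
    ----------
    simulations : ndarray, shape (n_reps, n_times)
        One row per simulated trajectory; needs at least two rows.
    q : (float, float)
        Lower/upper quantile levels, default the central 95% band.
    times : array-like, optional
        Time stamps for the columns; defaults to ``0..n_times-1``.
    """
    sims = np.asarray(simulations, dtype=float)
    if sims.ndim != 2 or sims.shape[0] < 2:
        raise ValueError("need a (n_reps, n_times) matrix with n_reps >= 2")
    lo_q, hi_q = q
    if not (0.0 <= lo_q <= hi_q <= 1.0):
        raise ValueError("quantile pair must satisfy 0 <= lo <= hi <= 1")
    lo = np.quantile(sims, lo_q, axis=0)
    hi = np.quantile(sims, hi_q, axis=0)
    if times is None:
        times = np.arange(sims.shape[1], dtype=float)
    else:
        times = np.asarray(times, dtype=float)
        if times.size != sims.shape[1]:
            raise ValueError("times length must match trajectory length")
    return Envelope(times=times, lo=lo, hi=hi, q=(float(lo_q), float(hi_q)))
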
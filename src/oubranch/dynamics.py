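"""Phase-plane dynamics and cyclic-therapy ensemble simulation.

The hybrid system couples one OU trait ``Y`` to a population size ``N``:

* deterministic skeleton ``dY/dt = theta (mu - Y)``,
  ``dN/dt = (lambda(Y) - delta(Y)) N`` — used for vector fields and the
  demographic nullcline ``Y* = mu + ln(delta0/lambda0)/(alpha+beta)`` where
  division and death balance;
* stochastic hybrid trajectories with exact discrete-time OU updates and
  Poisson (tau-leap) birth/death events, ``N`` absorbing at 0.

For therapy, a pharmacokinetic exposure ``C(t)`` over repeated dosing cycles
enters the rates through the saturating effect ``g(C) = C/(C + EC50)``:

    lambda(Y, C) = lambda0 exp(alpha (Y - mu0) - k_lambda g(C))
    delta(Y, C)  = delta0  exp(-beta (Y - mu0) + k_delta  g(C)),

so exposure suppresses division and promotes death while the OU parameters
stay fixed.  Ensembles report median/95% bands of ``Y`` and ``N`` for
matched-seed treated and untreated arms, the extinction ("cure") probability,
and cure maps over a (theta, sigma) grid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .branching import BranchingConfig, phenotype_rates
from .ou import OUParams

log = logging.getLogger(__name__)

__all__ = [
    "PhasePlaneSpec",
    "TherapyConfig",
    "EnsembleResult",
    "CureMap",
    "vector_field",
    "demographic_nullcline",
    "simulate_phase_trajectory",
    "exposure_profile",
    "drug_effect",
    "therapy_rates",
    "simulate_therapy_ensemble",
    "cure_probability_map",
]

# default OU triple for therapy runs: the high-plasticity (priA-like) profile
_PRIA_OU = OUParams(mu=-5.000, theta=0.117, sigma=0.436)


@dataclass(frozen=True)
class PhasePlaneSpec:
    """Inputs for phase-plane vector fields and stochastic trajectories."""

    ou: OUParams
    rates: BranchingConfig
    y_range: tuple[float, float] = (-2.0, 2.0)
    n_range: tuple[float, float] = (1.0, 1000.0)
    grid_density: tuple[int, int] = (15, 15)
    dt: float = 0.05
    y0: float = 0.0
    n0: int = 40
    t_max: float = 40.0
    n_cap: int = 10_000_000

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.y_range[0] >= self.y_range[1] or self.n_range[0] >= self.n_range[1]:
            raise ValueError("ranges must be non-degenerate")


@dataclass(frozen=True)
class TherapyConfig:
    """Cyclic-therapy simulation settings.

    Defaults follow the illustrative setup: the high-plasticity OU profile,
    six 21-day dosing cycles within a 200-day horizon at a half-day step and
    256 replicates.  The unprinted pharmacodynamic constants (baseline rates,
    couplings, drug-effect gains, EC50, schedule shape) are illustrative
    package defaults, all exposed here.
    """

    ou: OUParams = _PRIA_OU
    mu0: float | None = None  # baseline optimum; defaults to ou.mu
    lambda0: float = 0.30
    delta0: float = 0.15
    alpha: float = 0.5
    beta: float = 0.5
    k_lambda: float = 1.5
    k_delta: float = 1.5
    ec50: float = 1.0
    n_cycles: int = 6
    cycle_length: float = 21.0
    dose_amplitude: float = 2.0  # in EC50 multiples of concentration units
    shape: str = "pulse"  # 'pulse' or 'decay'
    pulse_duration: float = 5.0
    elimination_rate: float = 0.3  # per day, for shape='decay'
    t_max: float = 200.0
    dt: float = 0.5
    n_reps: int = 256
    n0: int = 500
    y0: float | None = None  # defaults to mu0 + 1 (therapy starts displaced)
    rate_cap: float = 10.0
    n_cap: int = 1_000_000

    def __post_init__(self) -> None:
        for name in ("lambda0", "delta0", "alpha", "beta", "k_lambda", "k_delta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.ec50 <= 0:
            raise ValueError("ec50 must be > 0")
        if self.shape not in ("pulse", "decay"):
            raise ValueError("shape must be 'pulse' or 'decay'")
        if self.dt <= 0 or self.t_max <= 0:
            raise ValueError("dt and t_max must be > 0")

    @property
    def mu0_value(self) -> float:
        return self.ou.mu if self.mu0 is None else self.mu0

    @property
    def y0_value(self) -> float:
        return self.mu0_value + 1.0 if self.y0 is None else self.y0


@dataclass(frozen=True)
class EnsembleResult:
    """Matched treated/untreated ensemble summaries of one therapy regimen."""

    times: np.ndarray
    y_quantiles: dict  # arm -> (3, n_times): q025, median, q975
    n_quantiles: dict
    extinction_probability: dict  # arm -> float
    n_truncated: dict
    seed: int


@dataclass(frozen=True)
class CureMap:
    """Extinction ("cure") probability over a (theta, sigma) grid."""

    theta_grid: np.ndarray
    sigma_grid: np.ndarray
    p_cure: np.ndarray  # shape (n_theta, n_sigma)
    reps_per_cell: int
    seed: int


def vector_field(spec: PhasePlaneSpec) -> dict:
    """Deterministic skeleton derivatives on the (Y, N) display grid."""
    y = np.linspace(*spec.y_range, spec.grid_density[0])
    n = np.geomspace(*spec.n_range, spec.grid_density[1])
    Y, N = np.meshgrid(y, n, indexing="ij")
    lam, dlt = phenotype_rates(Y, spec.rates)
    return {
        "Y": Y,
        "N": N,
        "dY_dt": spec.ou.theta * (spec.ou.mu - Y),
        "dN_dt": (lam - dlt) * N,
    }


def demographic_nullcline(rates: BranchingConfig) -> float | None:
    """Trait value where division equals death, ``lambda(Y*) = delta(Y*)``.

    Returns ``mu_ref + ln(delta0/lambda0)/(alpha+beta)``; ``None`` when the
    couplings vanish and the baselines differ (no solution).  With zero
    coupling and equal baselines every Y is a nullcline; ``mu_ref`` is
    returned as the representative.
    """
    total = rates.alpha + rates.beta
    if total == 0:
        if rates.lambda0 == rates.delta0:
            return rates.mu_ref
        return None
    return rates.mu_ref + math.log(rates.delta0 / rates.lambda0) / total


def simulate_phase_trajectory(
    spec: PhasePlaneSpec, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One stochastic hybrid (Y, N) trajectory.

    Per step: exact OU update of ``Y``; births ~ Poisson(lambda(Y) N dt) and
    deaths ~ Poisson(delta(Y) N dt) with deaths capped at the current size;
    ``N = 0`` is absorbing.
    """
    rng = np.random.default_rng(seed)
    n_steps = int(round(spec.t_max / spec.dt))
    times = np.arange(n_steps + 1) * spec.dt
    ys = np.empty(n_steps + 1)
    ns = np.empty(n_steps + 1, dtype=np.int64)
    ys[0], ns[0] = spec.y0, spec.n0
    e = math.exp(-spec.ou.theta * spec.dt)
    sd = math.sqrt(spec.ou.stationary_variance * (1.0 - e * e))
    mu = spec.ou.mu
    for i in range(n_steps):
        y = mu + (ys[i] - mu) * e + sd * rng.standard_normal()
        n = ns[i]
        if n > 0:
            lam, dlt = phenotype_rates(y, spec.rates)
            births = rng.poisson(float(lam) * n * spec.dt)
            deaths = min(rng.poisson(float(dlt) * n * spec.dt), n)
            n = min(n + births - deaths, spec.n_cap)
        ys[i + 1], ns[i + 1] = y, n
    return times, ys, ns


def exposure_profile(config: TherapyConfig, t: float | np.ndarray) -> np.ndarray:
    """Drug exposure ``C(t)`` under the cyclic schedule.

    ``shape='pulse'``: constant amplitude during the first ``pulse_duration``
    days of each cycle, 0 otherwise.  ``shape='decay'``: a bolus at each
    cycle start followed by first-order elimination.  Exposure is identically
    0 after the last cycle ends.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > config.t_max):
        raise ValueError("t must lie in [0, t_max]")
    amplitude = config.dose_amplitude * config.ec50
    treat_end = config.n_cycles * config.cycle_length
    within = np.mod(t_arr, config.cycle_length)
    in_treatment = t_arr < treat_end
    if config.shape == "pulse":
        c = np.where(in_treatment & (within < config.pulse_duration), amplitude, 0.0)
    else:
        c = np.where(
            in_treatment, amplitude * np.exp(-config.elimination_rate * within), 0.0
        )
    return c if c.ndim else float(c)


def drug_effect(C: float | np.ndarray, ec50: float) -> np.ndarray:
    """Saturating drug effect ``g(C) = C / (C + EC50)`` in [0, 1)."""
    if ec50 <= 0:
        raise ValueError("ec50 must be > 0")
    C_arr = np.asarray(C, dtype=float)
    if np.any(C_arr < 0):
        raise ValueError("concentration must be >= 0")
    out = C_arr / (C_arr + ec50)
    return out if out.ndim else float(out)


def therapy_rates(
    Y: float | np.ndarray, C: float | np.ndarray, config: TherapyConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Exposure-modulated division/death rates, clipped to [0, rate_cap]."""
    g = drug_effect(C, config.ec50)
    dev = np.asarray(Y, dtype=float) - config.mu0_value
    with np.errstate(over="ignore"):
        lam = config.lambda0 * np.exp(config.alpha * dev - config.k_lambda * g)
        dlt = config.delta0 * np.exp(-config.beta * dev + config.k_delta * g)
    return (
        np.clip(lam, 0.0, config.rate_cap),
        np.clip(dlt, 0.0, config.rate_cap),
    )


def _run_arm(
    config: TherapyConfig,
    treated: bool,
    seed_seq: np.random.SeedSequence,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """All replicates of one arm, vectorized across replicates.

    Matched-seed design: both arms are driven from children of the same seed
    sequence, so with null drug effects the arms are bit-identical.
    """
    rng = np.random.default_rng(seed_seq)
    n_steps = int(round(config.t_max / config.dt))
    times = np.arange(n_steps + 1) * config.dt
    R = config.n_reps
    e = math.exp(-config.ou.theta * config.dt)
    sd = math.sqrt(config.ou.stationary_variance * (1.0 - e * e))
    mu = config.ou.mu
    Y = np.full(R, config.y0_value)
    N = np.full(R, config.n0, dtype=np.int64)
    y_path = np.empty((n_steps + 1, R))
    n_path = np.empty((n_steps + 1, R), dtype=np.int64)
    y_path[0], n_path[0] = Y, N
    n_truncated = 0
    capped = np.zeros(R, dtype=bool)
    c_of_t = np.asarray(
        [exposure_profile(config, t) if treated else 0.0 for t in times[:-1]]
    )
    for i in range(n_steps):
        Y = mu + (Y - mu) * e + sd * rng.standard_normal(R)
        lam, dlt = therapy_rates(Y, c_of_t[i], config)
        alive = N > 0
        births = np.zeros(R, dtype=np.int64)
        deaths = np.zeros(R, dtype=np.int64)
        births[alive] = rng.poisson(lam[alive] * N[alive] * config.dt)
        deaths[alive] = np.minimum(
            rng.poisson(dlt[alive] * N[alive] * config.dt), N[alive]
        )
        N = N + births - deaths
        over = N > config.n_cap
        if over.any():
            capped |= over
            N[over] = config.n_cap
        y_path[i + 1], n_path[i + 1] = Y, N
    n_truncated = int(capped.sum())
    return y_path, n_path, times, n_truncated


def simulate_therapy_ensemble(
    config: TherapyConfig, seed: int = 0
) -> EnsembleResult:
    """Treated and untreated (C = 0) matched-seed ensembles of one regimen.

    Reports per-time 2.5/50/97.5 quantiles of ``Y`` and ``N`` per arm and the
    extinction probability (fraction of replicates with ``N = 0`` by
    ``t_max``).  Deterministic given the seed.
    """
    root = np.random.SeedSequence(seed)
    # matched-seed design: both arms replay the *same* noise stream, so the
    # only difference between them is the exposure C(t)
    arm_seed = root.spawn(1)[0]
    out_y, out_n, extinct, trunc = {}, {}, {}, {}
    times = None
    for arm, treated in (("treated", True), ("untreated", False)):
        y_path, n_path, times, n_tr = _run_arm(config, treated, arm_seed)
        out_y[arm] = np.quantile(y_path, [0.025, 0.5, 0.975], axis=1)
        out_n[arm] = np.quantile(n_path, [0.025, 0.5, 0.975], axis=1)
        extinct[arm] = float(np.mean(n_path[-1] == 0))
        trunc[arm] = n_tr
    if trunc["treated"] == config.n_reps and trunc["untreated"] == config.n_reps:
        raise RuntimeError(
            "all replicates hit the population cap; increase n_cap"
        )
    return EnsembleResult(
        times=times,
        y_quantiles=out_y,
        n_quantiles=out_n,
        extinction_probability=extinct,
        n_truncated=trunc,
        seed=seed,
    )


def cure_probability_map(
    base: TherapyConfig,
    theta_grid: np.ndarray,
    sigma_grid: np.ndarray,
    reps_per_cell: int = 64,
    seed: int = 0,
) -> CureMap:
    """Extinction probability of the treated arm over a (theta, sigma) grid.

    Each cell overrides the OU (theta, sigma) in ``base``, simulates
    ``reps_per_cell`` treated replicates, and stores the fraction extinct by
    ``t_max``.  Deterministic given the seed (independent child streams per
    cell, so results do not depend on traversal order).
    """
    theta_grid = np.asarray(theta_grid, dtype=float)
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    if np.any(theta_grid <= 0) or np.any(sigma_grid <= 0):
        raise ValueError("grids must be positive")
    if reps_per_cell < 1:
        raise ValueError("reps_per_cell must be >= 1")
    root = np.random.SeedSequence(seed)
    cells = root.spawn(theta_grid.size * sigma_grid.size)
    p = np.empty((theta_grid.size, sigma_grid.size))
    k = 0
    for i, th in enumerate(theta_grid):
        for j, sg in enumerate(sigma_grid):
            cfg = replace(
                base,
                ou=OUParams(mu=base.ou.mu, theta=float(th), sigma=float(sg)),
                n_reps=reps_per_cell,
            )
            _, n_path, _, _ = _run_arm(cfg, True, cells[k])
            p[i, j] = float(np.mean(n_path[-1] == 0))
            k += 1
    return CureMap(
        theta_grid=theta_grid, sigma_grid=sigma_grid, p_cure=p,
        reps_per_cell=reps_per_cell, seed=seed,
    )
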
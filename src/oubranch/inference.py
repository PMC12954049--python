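"""Exact-transition OU likelihood inference on replicate trajectories.

The replicate-grouped objective sums, over every within-replicate transition
``y_{i-1} -> y_i`` separated by ``dt_i``, the Gaussian negative log-density
with the exact OU conditional moments

    m_i = mu + (y_{i-1} - mu) exp(-theta dt_i)
    v_i = sigma^2/(2 theta) (1 - exp(-2 theta dt_i))

    NLL(mu, theta, sigma) = 1/2 sum_i [ log(2 pi v_i) + (y_i - m_i)^2 / v_i ].

Each replicate's first observation is conditioned on and contributes no term
(a stationary-density term for the first point is available behind a flag).
Maximisation uses bounded L-BFGS-B with multiple random restarts; the default
working parameterisation is ``(mu, log theta, log sigma)``, which enforces the
positivity constraints while conditioning the problem better than box bounds
near zero.

Also here: shared-vs-lineage-specific model comparison (LRT, AIC), profile
likelihood surfaces in (theta, sigma) with mu fixed at its MLE, and the
nonparametric replicate bootstrap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .datasets import LineageDataset
from .ou import OUParams

log = logging.getLogger(__name__)

__all__ = [
    "OUFit",
    "ModelComparison",
    "ProfileSurface",
    "BootstrapResult",
    "negative_log_likelihood",
    "OUMaximumLikelihood",
    "fit_mle",
    "fit_shared",
    "aic",
    "model_comparison",
    "profile_surface",
    "bootstrap",
]

# working-space bounds for log10-scale mutation-frequency data; generous but
# finite so degenerate (e.g. constant) data pin sigma at the floor instead of
# sending the objective to -inf
_LOG_THETA_BOUNDS = (math.log(1e-8), math.log(1e8))
_LOG_SIGMA_BOUNDS = (math.log(1e-8), math.log(1e8))
_SIGMA_FLOOR = 1e-8 * 1.5  # "at the bound" detection threshold


@dataclass(frozen=True)
class OUFit:
    """Maximum-likelihood OU fit of one (or a pooled set of) dataset(s)."""

    params: OUParams
    nll: float
    k: int
    converged: bool
    n_restarts_used: int
    dataset_id: str
    degenerate: bool = False

    @property
    def mu(self) -> float:
        return self.params.mu

    @property
    def theta(self) -> float:
        return self.params.theta

    @property
    def sigma(self) -> float:
        return self.params.sigma


@dataclass(frozen=True)
class ModelComparison:
    """Likelihood-ratio test and AIC comparison of nested OU models."""

    nll_null: float
    nll_alt: float
    k_null: int
    k_alt: int
    lrt: float
    df: int
    p: float
    aic_null: float
    aic_alt: float
    delta_aic: float


@dataclass(frozen=True)
class ProfileSurface:
    """Delta-NLL over a log-spaced (theta, sigma) grid with mu fixed at the MLE."""

    theta_grid: np.ndarray
    sigma_grid: np.ndarray
    delta_nll: np.ndarray  # shape (n_theta, n_sigma)
    mu_fixed: float
    mle: tuple[float, float]


@dataclass(frozen=True)
class BootstrapResult:
    """Replicate bootstrap draws and percentile summaries of an OU fit."""

    B: int
    draws: np.ndarray  # shape (n_ok, 5): mu, theta, sigma, 10^mu, sigma^2/(2 theta)
    ci: dict  # quantity -> (q025, q50, q975)
    corr_log_theta_log_sigma: float
    seed: int
    n_failed: int = 0

    quantities = ("mu", "theta", "sigma", "eq_freq", "stat_var")


def _check_log10(data: LineageDataset) -> None:
    if data.scale != "log10":
        raise ValueError("likelihood requires a log10-scale dataset (floor_and_log)")
    for r in data.replicates:
        if len(r) < 2:
            raise ValueError("every replicate needs >= 2 time points for likelihood use")


def negative_log_likelihood(params: OUParams, data: LineageDataset) -> float:
    """Replicate-grouped exact-transition negative log-likelihood."""
    _check_log10(data)
    return _nll(params.mu, params.theta, params.sigma, data)


def _nll(mu: float, theta: float, sigma: float, data: LineageDataset) -> float:
    if theta <= 0 or sigma <= 0:
        raise ValueError("theta and sigma must be > 0")
    sv = sigma * sigma / (2.0 * theta)
    total = 0.0
    for r in data.replicates:
        dt = np.diff(r.times)
        e = np.exp(-theta * dt)
        v = sv * (1.0 - e * e)
        resid = r.y[1:] - (mu + (r.y[:-1] - mu) * e)
        if np.any(v <= 0):
            bad = np.nonzero(v <= 0)[0]
            if np.any(resid[bad] != 0):
                raise ValueError("zero transition variance with nonzero residual")
            v = v[v > 0]
            resid = np.delete(resid, bad)
        total += 0.5 * float(np.sum(np.log(2.0 * math.pi * v) + resid * resid / v))
    return total


def _nll_with_stationary_init(mu, theta, sigma, data: LineageDataset) -> float:
    """NLL plus a stationary-density term for each replicate's first point."""
    total = _nll(mu, theta, sigma, data)
    sv = sigma * sigma / (2.0 * theta)
    for r in data.replicates:
        total += 0.5 * (math.log(2.0 * math.pi * sv) + (r.y[0] - mu) ** 2 / sv)
    return total


def _objective(datasets: Sequence[LineageDataset], stationary_init: bool):
    f = _nll_with_stationary_init if stationary_init else _nll

    def obj(z: np.ndarray) -> float:
        mu = z[0]
        theta = math.exp(min(z[1], 700.0))
        sigma = math.exp(min(z[2], 700.0))
        try:
            val = sum(f(mu, theta, sigma, ds) for ds in datasets)
        except (FloatingPointError, OverflowError):
            return np.inf
        return val if np.isfinite(val) else np.inf

    return obj


def _objective_raw(datasets: Sequence[LineageDataset], stationary_init: bool):
    f = _nll_with_stationary_init if stationary_init else _nll

    def obj(p: np.ndarray) -> float:
        mu, theta, sigma = p
        if theta <= 0 or sigma <= 0:
            return np.inf
        val = sum(f(mu, theta, sigma, ds) for ds in datasets)
        return val if np.isfinite(val) else np.inf

    return obj


def _start_points(
    datasets: Sequence[LineageDataset], n_restarts: int, rng: np.random.Generator
) -> np.ndarray:
    """Restart starts: one moment-matched, the rest random over broad ranges."""
    y = np.concatenate([ds.all_values() for ds in datasets])
    y_lo, y_hi = float(y.min()), float(y.max())
    var = max(float(np.var(y)), 1e-4)
    starts = [np.array([float(np.mean(y)), 0.0, 0.5 * math.log(2.0 * var)])]
    for _ in range(max(n_restarts - 1, 0)):
        mu0 = rng.uniform(y_lo - 1.0, y_hi + 1.0)
        th0 = math.exp(rng.uniform(math.log(1e-3), math.log(1e2)))
        sg0 = math.exp(rng.uniform(math.log(1e-2), math.log(1e1)))
        starts.append(np.array([mu0, math.log(th0), math.log(sg0)]))
    return np.asarray(starts[:n_restarts])


def _fit(
    datasets: Sequence[LineageDataset],
    n_restarts: int,
    seed,
    tol: float,
    parameterization: str,
    stationary_init: bool,
    dataset_id: str,
    starts: np.ndarray | None = None,
) -> OUFit:
    for ds in datasets:
        _check_log10(ds)
    rng = np.random.default_rng(seed)
    if starts is None:
        starts = _start_points(datasets, n_restarts, rng)
    results = []  # (nll, mu, theta, sigma, success)
    if parameterization == "log":
        obj = _objective(datasets, stationary_init)
        bounds = [(None, None), _LOG_THETA_BOUNDS, _LOG_SIGMA_BOUNDS]
        for z0 in starts:
            res = optimize.minimize(
                obj, z0, method="L-BFGS-B", bounds=bounds,
                options={"ftol": tol, "gtol": 1e-10, "maxiter": 500},
            )
            if np.isfinite(res.fun):
                results.append(
                    (float(res.fun), float(res.x[0]), math.exp(res.x[1]),
                     math.exp(res.x[2]), bool(res.success))
                )
    elif parameterization == "raw":
        obj = _objective_raw(datasets, stationary_init)
        bounds = [(None, None), (1e-8, 1e8), (1e-8, 1e8)]
        for z0 in starts:
            p0 = np.array([z0[0], math.exp(z0[1]), math.exp(z0[2])])
            res = optimize.minimize(
                obj, p0, method="L-BFGS-B", bounds=bounds,
                options={"ftol": tol, "gtol": 1e-10, "maxiter": 500},
            )
            if np.isfinite(res.fun):
                results.append(
                    (float(res.fun), float(res.x[0]), float(res.x[1]),
                     float(res.x[2]), bool(res.success))
                )
    else:
        raise ValueError("parameterization must be 'log' or 'raw'")

    converged = [r for r in results if r[4]]
    if not converged:
        if not results:
            raise RuntimeError(
                f"no restart produced a finite objective for {dataset_id!r} "
                f"({len(starts)} restarts)"
            )
        log.warning("no restart reported convergence for %s; using best finite", dataset_id)
        converged = results
    best_nll = min(r[0] for r in converged)
    # ties within tolerance: smallest sigma, then smallest theta (deterministic)
    tie_tol = 1e-8 * max(1.0, abs(best_nll))
    tied = [r for r in converged if r[0] <= best_nll + tie_tol]
    tied.sort(key=lambda r: (r[3], r[2]))
    nll, mu, theta, sigma, _ = tied[0]
    degenerate = sigma <= _SIGMA_FLOOR or theta <= _SIGMA_FLOOR
    return OUFit(
        params=OUParams(mu=mu, theta=theta, sigma=sigma),
        nll=nll,
        k=3,
        converged=any(r[4] for r in results),
        n_restarts_used=len(starts),
        dataset_id=dataset_id,
        degenerate=degenerate,
    )


class OUMaximumLikelihood:
    """Estimator-style interface to the replicate-grouped OU MLE.

    Follows the scikit-learn convention: hyperparameters in ``__init__``,
    data in :meth:`fit`, fitted attributes with a trailing underscore.

    Parameters
    ----------
    n_restarts : int
        Random multistart count (one start is always moment-matched).
    tol : float
        Convergence tolerance on the NLL (L-BFGS-B ``ftol``).
    parameterization : {'log', 'raw'}
        Optimize over ``(mu, log theta, log sigma)`` (default) or bounded raw
        coordinates; both target the same optimum.
    stationary_init : bool
        Add a stationary-density term for each replicate's first observation
        instead of conditioning on it.
    seed : int
        Seed for the restart sampler; fits are deterministic given the seed.
    """

    def __init__(
        self,
        n_restarts: int = 24,
        tol: float = 1e-8,
        parameterization: str = "log",
        stationary_init: bool = False,
        seed: int = 0,
    ):
        self.n_restarts = n_restarts
        self.tol = tol
        self.parameterization = parameterization
        self.stationary_init = stationary_init
        self.seed = seed

    # -- minimal sklearn-compatible parameter API ---------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_restarts": self.n_restarts,
            "tol": self.tol,
            "parameterization": self.parameterization,
            "stationary_init": self.stationary_init,
            "seed": self.seed,
        }

    def set_params(self, **params) -> "OUMaximumLikelihood":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: LineageDataset | Sequence[LineageDataset], y=None):
        """Fit to one dataset, or to several pooled under shared parameters."""
        datasets = [X] if isinstance(X, LineageDataset) else list(X)
        dataset_id = "+".join(ds.lineage for ds in datasets)
        fit = _fit(
            datasets,
            n_restarts=self.n_restarts,
            seed=self.seed,
            tol=self.tol,
            parameterization=self.parameterization,
            stationary_init=self.stationary_init,
            dataset_id=dataset_id,
        )
        self.fit_ = fit
        self.params_ = fit.params
        self.mu_ = fit.params.mu
        self.theta_ = fit.params.theta
        self.sigma_ = fit.params.sigma
        self.nll_ = fit.nll
        self.converged_ = fit.converged
        return self

    def score(self, X: LineageDataset, y=None) -> float:
        """Log-likelihood of ``X`` under the fitted parameters (higher is better)."""
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted")
        return -negative_log_likelihood(self.params_, X)


def fit_mle(
    data: LineageDataset,
    n_restarts: int = 24,
    seed: int = 0,
    tol: float = 1e-8,
    parameterization: str = "log",
    stationary_init: bool = False,
) -> OUFit:
    """Maximum-likelihood OU fit of one lineage dataset (functional wrapper)."""
    est = OUMaximumLikelihood(
        n_restarts=n_restarts, tol=tol, parameterization=parameterization,
        stationary_init=stationary_init, seed=seed,
    )
    return est.fit(data).fit_


def fit_shared(
    datasets: Sequence[LineageDataset],
    n_restarts: int = 24,
    seed: int = 0,
    tol: float = 1e-8,
    stationary_init: bool = False,
) -> OUFit:
    """Single shared (mu, theta, sigma) minimizing the pooled NLL (k = 3)."""
    datasets = list(datasets)
    if len(datasets) < 2:
        raise ValueError("fit_shared needs >= 2 datasets")
    est = OUMaximumLikelihood(
        n_restarts=n_restarts, tol=tol, stationary_init=stationary_init, seed=seed
    )
    return est.fit(datasets).fit_


def aic(k: int, nll: float) -> float:
    """Akaike information criterion, ``2 k + 2 NLL``."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return 2.0 * k + 2.0 * nll


def _k_nll(fit) -> tuple[int, float]:
    if isinstance(fit, OUFit):
        return fit.k, fit.nll
    if isinstance(fit, dict):
        return int(fit["k"]), float(fit["nll"])
    k, nll = fit
    return int(k), float(nll)


def model_comparison(null, alt) -> ModelComparison:
    """LRT and AIC comparison of a null model nested in an alternative.

    ``null`` and ``alt`` may be :class:`OUFit`, ``(k, nll)`` pairs, or dicts.
    The statistic ``LRT = 2 (NLL_null - NLL_alt)`` is referred to a chi-square
    with ``df = k_alt - k_null`` degrees of freedom (upper tail via the
    regularized incomplete gamma function).
    """
    k_null, nll_null = _k_nll(null)
    k_alt, nll_alt = _k_nll(alt)
    if k_alt <= k_null:
        raise ValueError(
            f"alternative must have more parameters than null (k_alt={k_alt}, "
            f"k_null={k_null})"
        )
    lrt = 2.0 * (nll_null - nll_alt)
    df = k_alt - k_null
    p = float(stats.chi2.sf(lrt, df)) if lrt > 0 else 1.0
    a_null = aic(k_null, nll_null)
    a_alt = aic(k_alt, nll_alt)
    return ModelComparison(
        nll_null=nll_null, nll_alt=nll_alt, k_null=k_null, k_alt=k_alt,
        lrt=lrt, df=df, p=p, aic_null=a_null, aic_alt=a_alt,
        delta_aic=a_null - a_alt,
    )


def profile_surface(
    data: LineageDataset,
    fit: OUFit,
    n_theta: int = 61,
    n_sigma: int = 61,
    span_log_units: float = 3.0,
) -> ProfileSurface:
    """Delta-NLL over log10-spaced (theta, sigma) grids, mu fixed at its MLE.

    Grids span ``span_log_units`` decades either side of the optimum; with an
    odd grid size the centre point is the MLE itself, where delta-NLL is 0.
    Entries that overflow are marked +inf.
    """
    if not fit.converged:
        raise ValueError("profile surface requires a converged fit")
    th_grid = np.logspace(
        math.log10(fit.theta) - span_log_units,
        math.log10(fit.theta) + span_log_units, n_theta,
    )
    sg_grid = np.logspace(
        math.log10(fit.sigma) - span_log_units,
        math.log10(fit.sigma) + span_log_units, n_sigma,
    )
    delta = np.empty((n_theta, n_sigma))
    n_overflow = 0
    for i, th in enumerate(th_grid):
        for j, sg in enumerate(sg_grid):
            try:
                val = _nll(fit.mu, th, sg, data) - fit.nll
            except (OverflowError, FloatingPointError, ValueError):
                val = np.inf
            if not np.isfinite(val) and val > 0:
                n_overflow += 1
                val = np.inf
            delta[i, j] = val
    if n_overflow:
        log.info("profile surface: %d grid entries overflowed (+inf)", n_overflow)
    finite = delta[np.isfinite(delta)]
    if finite.size and finite.min() < -1e-9:
        # grid found a slightly better point than the reported MLE
        log.warning("profile minimum below 0 by %.2e; clamping", -finite.min())
    delta = np.where(np.isfinite(delta), np.maximum(delta, 0.0), delta)
    return ProfileSurface(
        theta_grid=th_grid, sigma_grid=sg_grid, delta_nll=delta,
        mu_fixed=fit.mu, mle=(fit.theta, fit.sigma),
    )


def bootstrap(
    data: LineageDataset,
    B: int = 2000,
    seed: int = 0,
    n_restarts: int = 4,
    jitter: float = 0.5,
    full_fit: OUFit | None = None,
    max_failure_frac: float = 0.2,
) -> BootstrapResult:
    """Nonparametric bootstrap over replicates with OU refitting.

    Each draw resamples the lineage's replicate trajectories with replacement
    (keeping the replicate count) and refits ``(mu, theta, sigma)``.  Refits
    warm-start from the full-data MLE plus Normal jitter (sd ``jitter`` in
    ``(mu, log theta, log sigma)`` coordinates) with ``n_restarts`` starts —
    far cheaper than a full multistart per draw.  The jitter must be generous
    (default 0.5): when theta is weakly identified, resampled optima move by
    O(1) in log coordinates, and a tight warm start truncates the tails of
    the bootstrap distribution (visible as undercoverage of the percentile
    intervals).

    Percentile 2.5/50/97.5 intervals are computed directly from the bootstrap
    samples for each of ``mu, theta, sigma`` and the derived quantities
    ``10^mu`` and ``sigma^2/(2 theta)`` (per-draw transform, then quantile).
    """
    _check_log10(data)
    if B < 1:
        raise ValueError("B must be >= 1")
    if full_fit is None:
        full_fit = fit_mle(data, seed=seed)
    rng = np.random.default_rng(seed)
    z_hat = np.array(
        [full_fit.mu, math.log(full_fit.theta), math.log(full_fit.sigma)]
    )
    n_rep = len(data.replicates)
    rows = []
    n_failed = 0
    for _ in range(B):
        idx = rng.integers(0, n_rep, size=n_rep)
        resampled = replace(data, replicates=tuple(data.replicates[i] for i in idx))
        starts = z_hat[None, :] + jitter * rng.standard_normal((n_restarts, 3))
        try:
            fit = _fit(
                [resampled], n_restarts=n_restarts, seed=rng.integers(2**31),
                tol=1e-8, parameterization="log", stationary_init=False,
                dataset_id=data.lineage, starts=starts,
            )
        except RuntimeError:
            n_failed += 1
            continue
        # degenerate refits (sigma at its floor) are kept: they are genuine
        # optima of the resampled data and form the lower tail of the
        # bootstrap distribution; dropping them narrows the intervals
        rows.append(
            (fit.mu, fit.theta, fit.sigma, 10.0**fit.mu,
             fit.sigma**2 / (2.0 * fit.theta))
        )
    if n_failed > max_failure_frac * B:
        raise RuntimeError(
            f"bootstrap: {n_failed}/{B} refits failed (> {max_failure_frac:.0%})"
        )
    draws = np.asarray(rows, dtype=float)
    ci = {}
    for name, col in zip(BootstrapResult.quantities, draws.T):
        q = np.quantile(col, [0.025, 0.5, 0.975])
        ci[name] = (float(q[0]), float(q[1]), float(q[2]))
    lt, ls = np.log(draws[:, 1]), np.log(draws[:, 2])
    if draws.shape[0] > 1 and lt.std() > 0 and ls.std() > 0:
        corr = float(np.corrcoef(lt, ls)[0, 1])
    else:
        corr = float("nan")
    return BootstrapResult(
        B=B, draws=draws, ci=ci, corr_log_theta_log_sigma=corr,
        seed=int(seed) if np.isscalar(seed) else -1, n_failed=n_failed,
    )
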
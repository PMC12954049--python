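# Methods

## Model

The modelled trait `Y_t` (log10 mutation frequency in the microbial
application, any longitudinal phenotype axis in general) follows an
Ornstein–Uhlenbeck diffusion `dY = θ(μ − Y)dt + σ dW`.  The choice is
motivated by data that fluctuate within a bounded band around a
lineage-specific level: an OU process has a stationary law
`Normal(μ, σ²/(2θ))`, unlike a random walk, and its transition density is
Gaussian with closed-form moments for any gap `Δt`, so irregular sampling
costs nothing.

All demographic layers share one rate model linking the trait to
per-capita division and death,
`λ(Y) = λ₀ e^{α(Y−μ_ref)}` and `δ(Y) = δ₀ e^{−β(Y−μ_ref)}`, clipped to
`[0, rate_cap]`.  Under therapy a saturating exposure effect
`g(C) = C/(C+EC50) ∈ [0,1)` shifts both log-rates:
`λ(Y,C) = λ₀ e^{α(Y−μ₀) − k_λ g}`, `δ(Y,C) = δ₀ e^{−β(Y−μ₀) + k_δ g}`.
OU parameters are never modified by exposure; the drug acts purely
demographically.

## Likelihood and optimisation

The replicate-grouped negative log-likelihood sums
`½[log(2πv_i) + (y_i − m_i)²/v_i]` over every within-replicate transition;
each replicate's first observation is conditioned on (a stationary-density
initial term is available via `stationary_init=True`, and matters only when
series are very short).  The default working parameterisation is
`(μ, log θ, log σ)`: it enforces positivity exactly and conditions the
problem better than box bounds near zero; a bounded raw-coordinate mode is
retained and agrees with the log mode to < 1e-6 in optimal NLL on the
reference fixtures.  Fits use L-BFGS-B with 24 restarts (one
moment-matched start — μ from the sample mean, σ²/2θ from the sample
variance at θ = 1 — plus log-uniform random starts, θ ∈ [1e-3, 1e2],
σ ∈ [1e-2, 1e1], μ uniform over the data range ± 1), ftol 1e-8.  Restart
ties within 1e-8 relative NLL resolve to the smallest σ, then smallest θ,
so output is deterministic.  Constant (zero-variance) data drive σ̂ to its
floor (1e-8) and are flagged `degenerate` rather than erroring.

Model comparison follows the standard nested-likelihood recipe: LRT =
2(NLL_null − NLL_alt) referred to a chi-square with df = k_alt − k_null
(upper tail through the regularized incomplete gamma function), and
AIC = 2k + 2·NLL.  Profile surfaces fix μ at its MLE and evaluate ΔNLL on
log10-spaced θ and σ grids spanning ±3 decades around the optimum (default
61 × 61; odd sizes place the MLE exactly at the grid centre, where ΔNLL = 0
by construction).  Overflowing grid corners are marked +inf.

## Bootstrap

Uncertainty uses a nonparametric bootstrap over biological replicates:
each of B draws (default 2000) resamples the replicate trajectories with
replacement, preserving the count, and refits.  Refits warm-start from the
full-data MLE plus Normal jitter in `(μ, log θ, log σ)` with 4 restarts.
The jitter must be generous — the default sd is 0.5 — because when θ is
weakly identified the resampled optima move by order-one amounts in log
coordinates; a tight warm start truncates the tails of the bootstrap
distribution and the percentile intervals undercover.  Degenerate refits
(σ̂ at its floor) are retained: they are genuine optima of resampled data
and form the lower tail.  Intervals are 2.5/50/97.5 percentiles computed
directly from the draws, for μ, θ, σ *and* the derived quantities `10^μ`
and `σ²/(2θ)` — transformed per draw, never by transforming interval
endpoints.  The θ–σ coupling is summarised as `corr(log θ, log σ)` across
draws.

Calibration caveat: with the 5 replicates typical of the emulated design,
95% percentile intervals genuinely undercover for θ and σ.  In nested
simulation studies (20–40 panels, B = 200) coverage was ≈ 0.83 for μ but
0.55–0.80 for θ/σ depending on the sampling design — a combination of the
small resampling base (5 units admit only 126 distinct resamples) and the
skewed, sometimes ridge-shaped sampling distribution of θ̂.  This is a
property of the percentile method at this design, not of the
implementation; treat θ/σ intervals from few replicates as indicative.

## Identifiability under sparse sampling

With sampling gaps Δt, the data constrain θ only through the lag
autocorrelation `e^{−θΔt}`.  On the default grid (Δt = 3) a lineage with
θ ≈ 0.8 has lag correlation ≈ 0.1, and one with θ ≈ 8.5 has ≈ 1e-11: in
the first case θ̂ is weakly identified (single-panel MLEs scatter by more
than a factor 1.5 about half the time; the median over a batch of panels
is within a factor 1.5), in the second case θ is not identified at all and
the likelihood is flat along the ridge σ²/(2θ) = const — visible as a
profile contour spanning several decades of θ.  Dense designs recover all
three parameters to within 10% (6 replicates × 200 unit-spaced points in
the reference fixture).  The stationary variance σ²/(2θ) remains well
estimated even where θ and σ separately are not.

## Simulators

*OU*: exact discrete-time recursion `y ← μ + (y−μ)e^{−θΔt} + √v ε` with
standard-normal ε; bit-reproducible from a seed; envelopes are pointwise
empirical quantiles (linear interpolation between order statistics,
default 2.5–97.5%).

*Constant-rate birth–death*: exact Gillespie event simulation; an
ensemble helper advances all runs in lockstep (vectorised) and records
sizes at the horizon, extinction flags and stop times.

*Lineage networks*: time-stepped (default dt = 0.05, T = 40, 40
founders).  Per step each extant clone makes one exact OU trait
transition, divides with probability `1 − e^{−λ(Y)dt}` and dies with
probability `1 − e^{−δ(Y)dt}` — the exponential forms stay in [0,1] for
any clipped rate and step; death resolves after division so a dying clone
can leave a child.  Children start at the parent's current trait (optional
Normal inheritance jitter, default off).  At most one division per clone
per step; a warning fires when λ₀·dt > 0.2.  Runs stop at T, extinction,
or a population cap (default 1e5, flagged `truncated`).  Snapshot
classification (default t = 20) labels clones extant/extinct;
visualisation downsampling keeps a seeded uniform subset of extant clones
plus their ancestor paths so the view stays a forest, without touching the
underlying simulation.  Export: GraphML, edge-list CSV (edges weighted by
the parent's division rate at the split), JSON.

*Phase plane / therapy*: one trait value per replicate population, exact
OU updates, births ~ Poisson(λNdt) and deaths ~ Poisson(δNdt) capped at N,
N absorbing at 0.  The tau-leap agrees with the exact Gillespie simulator
on ensemble extinction fractions for matched constant-rate configurations
(cross-checked in the tests).  Therapy ensembles run treated and untreated
arms on the *same* noise stream (matched seeds), so with k_λ = k_δ = 0 the
arms are bit-identical and treated-vs-untreated contrasts are
variance-reduced.  Default schedule: six 21-day cycles, 5-day rectangular
pulses at 2×EC50, 256 replicates, 200 days at Δt = 0.5; a first-order-
elimination ("decay") pulse shape is available.  Cure = N ≡ 0 by the
horizon.

## Therapy constants and the cure-map regime

The pharmacodynamic constants are illustrative defaults (λ₀ = 0.30/day,
δ₀ = 0.15/day, α = β = 0.5, k_λ = k_δ = 1.5, EC50 = 1, n₀ = 500, default
trait start μ₀ + 1 — a displaced, "stressed" initial state that lets the
relaxation toward μ be seen in ensemble medians).  Two regime facts matter
when reading cure maps:

1. Under the default schedule the reference state (Y ≈ μ) is
   demographically *supercritical per cycle* (≈ +0.9 net log-growth:
   5 days at net −0.30/day, 16 at +0.15/day), so extinction essentially
   never occurs and P(cure) ≈ 0 everywhere.  Regime maps need an
   intensified schedule; the tests use 10-day pulses at 4×EC50
   (≈ −2.4 per cycle at Y = μ).
2. The direction "higher θ and lower σ favour extinction" holds only in an
   *escape-dominant* coupling regime.  Diffusion acts through two opposed
   channels: upward excursions past
   `Y* = μ + (ln(δ₀/λ₀) + (k_λ+k_δ)g)/(α+β)` escape drug control, while
   downward excursions inflate death through `e^{−β(Y−μ)}` and collapse
   even large populations.  With symmetric couplings (α = β) the collapse
   channel cancels or outweighs escape and the σ trend vanishes or
   inverts.  The packaged regime demonstration therefore uses α = 1.5,
   β = 0.1, equilibrium start (y₀ = μ), and a σ grid capped at 0.8 so
   stationary excursions stay within the escape-dominated band; there both
   rank trends (P(cure) increasing in θ, decreasing in σ) are significant
   at p < 0.05 with 200 replicates per cell.

## Synthetic data

The generator emulates replicate mutation-frequency panels: per lineage
and replicate an exact OU path on the log10 scale (default: stationary
initial draw), mapped to frequencies `x = 10^y`, with observations below a
true detection floor (default 1e-8) recorded as exact zeros.  Defaults —
three lineages with parameter triples (−6.799, 0.775, 0.727),
(−5.000, 0.117, 0.436), (−7.652, 8.516, 2.789); 5 replicates; grid
t = 0, 3, …, 21 — mirror the sparse experimental design the package
targets.  What the generator does *not* emulate: measurement noise beyond
the detection floor, replicate-level parameter heterogeneity, mutation-
accumulation mechanisms, or temporal batch effects.  Passing recovery
tests therefore demonstrate correctness of the estimator under the model,
and the information content of the design — not robustness to
misspecification.

## Numerical choices

* Quantiles everywhere: linear interpolation between order statistics.
* Optimizer floors: θ, σ ∈ [1e-8, 1e8] in all modes; "degenerate" means an
  estimate at the floor.
* Dominance probability at grid points with zero summed variance (e.g. a
  shared conditioning time): 0.5 when the means coincide, else 0/1.
* W2 convention: the true Gaussian 2-Wasserstein uses the *sd* difference,
  `√((Δm)² + (Δsd)²)` (default); a variance-difference variant is provided
  because the two nearly coincide whenever predictive spreads are similar.
* Seeding: `numpy` `SeedSequence` children per replicate/cell/arm, so
  results are independent of traversal order and bit-reproducible; all
  derived seeds stay below 2^31.
* Problem sizes in the shipped tests (10,000-replicate envelopes, 4,000-run
  extinction ensembles, 200-replicate cure-map cells, 12-panel recovery
  batches) were chosen as the smallest ensembles whose Monte-Carlo standard
  errors are comfortably below the tolerances being asserted.

## Known limitations

* No observation-noise (state-space) layer: `y` is modelled directly.
* Percentile-bootstrap undercoverage for θ/σ at few replicates (above).
* θ non-identifiability when θ·Δt ≫ 1 (above); fits are honest about it
  (flat profiles, wide bootstrap intervals) but point estimates in that
  regime should not be interpreted.
* The branching layers are well-mixed and single-trait; no spatial
  structure, carrying capacity, or multi-trait dynamics.
* Therapy simulations are illustrative forward simulations, not calibrated
  predictions; the schedule and pharmacodynamic constants are package
  defaults, all exposed in `TherapyConfig`.
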
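# oubranch

Hybrid Ornstein–Uhlenbeck / branching-process modelling of replicate
trajectory panels — built for longitudinal mutation-frequency data from
microbial evolution experiments, and for any phenotype axis measured
repeatedly over time (drug-tolerance scores, burden proxies, clonal
fractions).

Lineages whose trajectories fluctuate around a characteristic level rather
than drifting freely are well described by the mean-reverting OU diffusion

    dY_t = θ (μ − Y_t) dt + σ dW_t

on the log10 scale: `μ` is the equilibrium mean, `θ` the mean-reversion
(effective stabilizing) rate, and `σ` the diffusion scale.  Because the OU
transition density is Gaussian with closed-form moments

    m_i = μ + (y_{i−1} − μ) e^{−θ Δt_i},
    v_i = σ²/(2θ) (1 − e^{−2θ Δt_i}),

the exact likelihood is available for arbitrary, irregular sampling — no
Euler approximation, no imputation.  On top of this likelihood the package
provides the full inferential and simulation tool-chain:

* **Preprocessing** — per-lineage detection floor `ε = 0.5 × min positive
  value`, zero flooring, log10 transform (`oubranch.datasets`).
* **Inference** — replicate-grouped exact-transition MLE (multi-restart
  L-BFGS-B, sklearn-style `OUMaximumLikelihood` estimator), shared-vs-
  lineage-specific model comparison (LRT, AIC), profile-likelihood surfaces
  in (θ, σ), and a nonparametric replicate bootstrap with percentile
  intervals for μ, θ, σ and the derived quantities `10^μ` and `σ²/(2θ)`
  (`oubranch.inference`).
* **Separation metrics** — mean absolute separation `D_mean`, time-averaged
  Gaussian 2-Wasserstein distance `D_W2`, and the dominance probability
  `P(A>B)` between lineage predictive distributions, with bootstrap
  propagation (`oubranch.separation`).
* **Simulators** — exact OU trajectory ensembles and predictive envelopes
  (`oubranch.ou`); exact Gillespie linear birth–death plus phenotype-coupled
  clone-level lineage networks with `λ(Y) = λ₀ e^{α(Y−μ)}`,
  `δ(Y) = δ₀ e^{−β(Y−μ)}` (`oubranch.branching`); phase-plane skeletons and
  hybrid (Y, N) trajectories; cyclic-therapy ensembles with saturating drug
  effect `g(C) = C/(C+EC50)` and cure-probability maps
  (`oubranch.dynamics`).
* **Synthetic data** — a seeded generator of replicate frequency panels
  with known ground truth, including detection-floor zeros
  (`oubranch.synthetic`).

## Worked example

Generate a synthetic three-lineage panel (equilibria −6.8, −5.0, −7.65 on
the log10 frequency scale), fit each lineage and the pooled
shared-parameter null, and compare:

```python
import oubranch as ob

table, truth = ob.generate_panel(ob.SyntheticPanelSpec(seed=1))
datasets = {lin: ob.floor_and_log(table, lin) for lin in ("WT", "priA", "recG")}

fits = {lin: ob.fit_mle(d, seed=1) for lin, d in datasets.items()}
shared = ob.fit_shared(list(datasets.values()), seed=1)
cmp_ = ob.model_comparison((3, shared.nll),
                           (9, sum(f.nll for f in fits.values())))
print(f"LRT = {cmp_.lrt:.4f}, df = {cmp_.df}, p = {cmp_.p:.2e}")
```

On this panel the lineage-specific model wins decisively:

```
LRT = 48.8657, df = 6, p = 7.93e-09
```

and the per-lineage fits (8 time points × 5 replicates each) are

```
     dataset      mu  theta  sigma      nll
          WT -6.9202 5.3332 1.8701  30.1489
        priA -5.5075 0.0789 0.3869  31.6771
        recG -7.5627 5.4903 2.0937  33.5936
WT+priA+recG -6.5511 0.0827 0.4927 119.8524
```

`mu` is the equilibrium log10 frequency (so priA's equilibrium frequency is
`10^-5.51 ≈ 3e-06`, well above the others), and `sigma**2/(2*theta)` is the
long-run variance around it.  Note that `theta` for the fast-reverting
lineages is only weakly identified on this sparse 3-unit grid — the profile
surface (`ob.profile_surface`) and bootstrap make that visible rather than
hiding it.

Separation between priA and WT propagated through 200 bootstrap draws
(`ob.separation_summary(bootA.draws, bootB.draws)`) gives, on the default
grid t = 0, 3, …, 21:

```
        pair      metric   q025      q50      q975
  WT vs priA      d_mean 0.1965   1.4345    2.3202
  WT vs priA        fold 1.5744  27.2290  209.0376
```

i.e. a median ~1.4 log10-unit separation (≈ 27-fold), with wide intervals
driven by the weakly identified θ.

The same pipeline is scriptable from the shell:

```sh
oubranch demo --outdir out --seed 1          # everything below in one go
oubranch fit --in out/panel.csv --lineage WT --seed 1 --out fit.csv
oubranch bootstrap --in out/panel.csv --lineage priA -b 2000 --seed 1 --out boot.csv
oubranch therapy --seed 1 --out therapy.csv
```

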
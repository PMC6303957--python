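# priorconf

Sensitivity analysis of **unmeasured confounding** in linear
exposure–outcome models, using an **informative prior on the measured
confounder–outcome relation**.

## The problem

Observational estimates of an exposure effect are biased when a common
cause of exposure and outcome is not adjusted for.  Consider a continuous
outcome *Y*, exposure *X*, a measured confounder *Z* and an unmeasured
confounder *U*, all linear and jointly normal:

```
y_i = β_yx x_i + β_yz z_i + β_yu u_i + ε_i,   ε ~ N(0, σ²)
x_i = β_xz z_i + β_xu u_i + ζ_i,              ζ ~ N(0, σ_x²)
z_i = β_zu u_i + ξ_i,                          ξ ~ N(0, σ_z²)
```

Regressing *Y* on *X* alone, or on *X* and *Z*, leaves residual
confounding by *U*.  The large-sample bias has closed form; with *Z*
adjusted it is

```
bias(β_yx|z) = β_xu β_yu · Var(U)(1 − ρ²_uz) / (Var(X)(1 − ρ²_xz)).
```

The key observation this package operationalises: *U* also distorts the
**observed Z–Y coefficient** (conditioning on the collider *X* opens a
path from *Z* to *Y* through *U*).  An unexpectedly large or small Z–Y
coefficient therefore signals unmeasured confounding — and constraining
that coefficient with an informative normal prior `β_yz ~ N(μ, τ)` (τ a
precision, typically scaled as *n*, *n*/10 or *n*/100) in a Bayesian
outcome model can pull part of the confounding bias out of the exposure
coefficient.  The posterior is explored with a conjugate Gibbs sampler
(default 4 chains × 2000 iterations, 1000 burn-in, vague priors
`β_yx ~ N(0, τ = 0.001)` and `σ ~ U(0, 100)`).

The package provides:

* `dgp` — the structural generator, its exact implied moments, and a
  covariance-matrix-based multivariate-normal generator;
* `bias` — the closed-form omitted-confounder bias expressions, with an
  exact covariance-based population-regression oracle;
* `estimators` — unadjusted / Z-adjusted OLS and the Gibbs-sampled
  Bayesian model, plus a fixed-variance conjugate closed form;
* `simulation` — a Monte-Carlo harness comparing all five estimators over
  a 72-scenario grid (bias, empirical SD, MSE per scenario × method);
* a `priorconf` command-line tool (`simulate`, `fit`, `analyze`, `grid`).

## Worked example

Closed-form biases for two reference scenarios (ids refer to the 18-row
reference subset with β_xz = β_yz = 1):

```
$ priorconf analyze --scenarios 8,9
 scenario  beta_zu  beta_xz  beta_xu  beta_yu  beta_yz  bias_unadjusted  bias_adjusted_z
        8   1.0000   1.0000   0.0000   1.0000   1.0000           1.0000           0.0000
        9   0.0000   1.0000   1.0000   1.0000   1.0000           0.6667           0.5000
```

In scenario 9, *U* confounds the X–Y relation even after adjusting for
*Z* (residual bias 0.50).  Draw a dataset and fit with a correct,
high-precision prior on the Z–Y coefficient:

```
$ priorconf simulate --scenario 9 --n 1000 --seed 7 --out demo.csv
$ priorconf fit --data demo.csv --prior-mean 1.0 --prior-precision 1000 --seed 7
{
  "ols": {
    "coef": { "x": 0.469, "z": 0.534 },
    ...
  },
  "bayes": {
    "posterior_mean": { "x": 0.357, "z": 0.855 },
    "posterior_sd": { "x": 0.024, "z": 0.026 },
    "rhat": { "x": 1.0005, "z": 0.9998 },
    "n_draws": 4000
  }
}
```

The true exposure effect is 0.  Z-adjusted OLS estimates 0.47 — and its
Z coefficient, 0.53, is far from the known value 1, the tell-tale of
unmeasured confounding.  The prior pulls the Z coefficient back towards 1
(posterior mean 0.86) and thereby drags the exposure coefficient from
0.47 down to 0.36, recovering part of the bias (the population-level
reduction is 0.50 → 0.38).  Averaging over 100 replicates:

```
$ priorconf grid --scenarios 9 --reps 100 --seed 1 --out row9.csv
```

reproduces the reference cells: adjusted-OLS bias ≈ 0.50, Bayesian
(τ = 1000) bias ≈ 0.38 with a smaller SD and MSE.

The informative prior is not a free lunch: when *U* confounds only the
Z–Y relation (scenario 8), "correcting" the Z coefficient *induces*
exposure bias (≈ 0.23) where adjusted OLS was unbiased.  See
`docs/methods.md` for when the approach helps and when it hurts, and
`examples/ldl_sbp_synthetic.yaml` for a clinically flavoured synthetic
illustration.

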
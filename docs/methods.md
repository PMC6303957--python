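# Methods

## Structural model

Four continuous, zero-mean, jointly normal variables: unmeasured
confounder *U*, measured confounder *Z*, exposure *X*, outcome *Y*.
The recursive system

```
u_i ~ N(0, σ_u²)
z_i = β_zu u_i + ξ_i,                          ξ ~ N(0, σ_z²)
x_i = β_xz z_i + β_xu u_i + ζ_i,               ζ ~ N(0, σ_x²)
y_i = β_yx x_i + β_yz z_i + β_yu u_i + ε_i,    ε ~ N(0, σ²)
```

has reduced-form covariance `Σ = (I − B)⁻¹ D (I − B)⁻ᵀ`, which
`dgp.implied_covariance` computes exactly; `dgp.implied_moments` exposes
the marginal/conditional variances and correlations used by the bias
formulas.  Intercepts are omitted everywhere: the process is zero-mean by
construction, and the fitted models match it (an `intercept=True` flag
adds a flat-prior intercept for real, uncentred data).

All relations are linear with homoscedastic normal errors.  Binary or
survival outcomes, non-normal errors, nonlinear links and more than two
confounders are out of scope.

## Omitted-confounder bias and its oracle

`bias.bias_unadjusted` and `bias.bias_adjusted_z` implement the
closed-form large-sample bias of the exposure coefficient with,
respectively, both confounders omitted and only *Z* adjusted.  Both are
independent of the true exposure effect β_yx.  `bias.bias_zy_conditional`
gives the bias of the *Z* coefficient itself on the standardized scale;
the converter from raw scenarios sets the standardized direct effect of
*U* to `β_yu·σ_U/σ_Y`, the unique choice that reproduces the exact
population regression on the correlation matrix (verified in the tests
for every grid scenario).

`bias.population_regression` — `Σ_cc⁻¹ σ_cy` from any covariance
matrix — is the exact oracle: every closed form above is tested to agree
with it to 10 significant digits on all 72 grid scenarios.

Two analytic subtleties worth recording, because intuitive monotonicity
claims about the adjusted bias are easy to get wrong:

* With `β_zu = 0`, the denominator `Var(X)(1 − ρ²_xz) = Var(X|Z)
  = β_xu²σ_u² + σ_x²` does not involve β_xz at all, so the Z-adjusted
  bias is *constant* in β_xz.  The "bias amplification" of adjusting for
  a near-instrument is real but relative: the *U*-attributable share of
  the unadjusted bias is divided by Var(X), the adjusted bias by the
  smaller Var(X|Z).  The tests assert that corrected statement (strict
  whenever β_xz ≠ 0).
* The adjusted bias `β_xu β_yu Var(U|Z) / (β_xu² Var(U|Z) + σ_x²)` is
  *not* monotone in β_xu: it peaks at `β_xu² Var(U|Z) = σ_x²` and falls
  thereafter (compare reference rows 9 and 11: 0.50 vs 0.40).  Monotone
  behaviour holds in |β_yu| (increasing) and in ρ²_uz (decreasing), and
  in |β_xu| only below the turning point; the tests check exactly that.

## Bayesian model and sampler

Outcome model `y = β_yx x + β_yz z + ε` with independent priors

| parameter | prior | default | role |
|---|---|---|---|
| β_yx | N(0, τ_yx) | τ_yx = 0.001 | vague; precision scale |
| β_yz | N(μ_yz, τ_yz) | user-set; study uses μ = true β_yz, τ ∈ {n, n/10, n/100} | the informative prior |
| σ | U(0, σ_max) | σ_max = 100 | vague residual scale |

τ is always a precision (1/variance), never an SD.  The Gibbs sampler
alternates:

1. coefficients given σ²: conjugate (multivariate) normal,
   `V = (X'X/σ² + T)⁻¹`, `m = V(X'y/σ² + Tμ₀)`, drawn jointly;
2. σ² given coefficients: under the uniform-on-σ prior the conditional is
   inverse-gamma with shape (n − 1)/2 and scale SSR/2 (the −1/2 relative
   to a flat-on-σ² prior is the Jacobian of σ → σ²), truncated at σ_max².
   Truncation is enforced by rejection; at n = 1000 and unit-scale data
   the bound essentially never binds.

Chains (default 4 × 2000 iterations, 1000 burn-in) start at the OLS
solution jittered uniformly by up to ±2 OLS standard errors, so the
between-chain spread makes the convergence diagnostic meaningful.  The
potential scale reduction is the classic (non-split) Gelman–Rubin
statistic on retained draws; values above 1.1 raise a warning rather than
an error, because a replication harness must not silently drop
replicates.  The point estimate reported is the pooled posterior mean.

Two exact checks pin the sampler down: with τ_yz → 0 it reproduces OLS,
and with σ² held fixed its coefficient draws are i.i.d. from the known
conjugate posterior, so the sampler mean must match
`conjugate_posterior_mean` within Monte-Carlo error.

## Simulation harness

The grid crosses β_zu ∈ {0, 1}, β_yz ∈ {1, 2}, β_xz ∈ {1, 2},
β_yu ∈ {0, 1, 2}, β_xu ∈ {0, 1, 2} — 72 scenarios — with β_yx = 0, all
residual variances 1 and n = 1000; each scenario runs 100 replicates and
five estimators (unadjusted OLS, Z-adjusted OLS, Bayesian at prior
precision n, n/10, n/100, prior mean set to the true β_yz).  Reported per
cell: bias (mean estimate − truth), empirical SD (denominator n − 1; at
two printed decimals the n convention would be indistinguishable) and
MSE (mean squared deviation from truth), which satisfy
`MSE = bias² + SD²·(reps−1)/reps` to 1e-10.

The 18-row reference subset fixes β_xz = β_yz = 1 and orders rows by
β_yu (slowest), β_xu, β_zu.  The unit-coefficient labelling is the
internally consistent one: evaluating the closed forms at these settings
reproduces every tabulated bias cell (e.g. row 1: 1·1/2 = 0.50; row 8:
2/3 + 1/3 = 1.00), which coefficients of 2 do not.

Seeding: replicate *r* of a scenario uses data seed `master_seed + r`;
the sampler for prior *j* in that replicate is seeded with the tuple
`(master_seed, r, j)`, so every fit is reproducible in isolation and the
data and sampler streams never overlap.  Scenario *i* in a multi-scenario
table run uses master seed `master_seed + 10000·i`.

Problem sizes: the shipped acceptance script and the acceptance tests run
seven reference scenarios at the full study conditions (100 replicates ×
n = 1000, 4 × 2000 Gibbs iterations), about half a minute per scenario on
one CPU.  At 100 replicates the Monte-Carlo standard error of a bias cell
is SD/√100 ≈ 0.002–0.005, so simulated cells are compared to reference
values within ±0.03.

## What the generator does and does not emulate

The generator produces exactly the study conditions: linear, homoscedastic,
zero-mean normal data with known path coefficients, where the closed-form
biases are exact.  Real observational data have nonlinearities, skewed and
heteroscedastic errors, measurement error and multiple partially measured
confounders; passing tests therefore demonstrate correctness of the
machinery and of the method's behaviour *under its own assumptions*, not
robustness beyond them.  The covariance-based generator
(`generate_from_covariance`) exists for illustration on moment summaries
of real cohorts; the shipped LDL–SBP example uses a synthetic covariance
matrix with plausible clinical magnitudes, clearly labelled as such.

## When the prior helps — and when it hurts

* *U* not a confounder of X–Y (β_yu = 0, rows 1–7 pattern): all
  Z-adjusted estimators are unbiased; the prior is harmless.
* *U* confounds X–Y and the observed Z–Y coefficient is distorted away
  from the prior mean (rows 9, 15, 18 pattern): the prior reduces
  exposure-coefficient bias (e.g. 0.50 → 0.38) and tightens its SD.
* The observed Z–Y coefficient happens to equal the prior mean (rows 10,
  16): the prior pulls nothing; Bayesian and adjusted-OLS results
  coincide, both biased.
* *U* confounds only Z–Y, not X–Y (row 8, β_xu = 0): the prior
  "corrects" a coefficient that is biased for a reason the model cannot
  see and thereby *induces* exposure bias (0 → 0.23, MSE 0.0012 → 0.055).
  A correct prior can hurt.

Bias reduction decays quickly with prior precision: at τ = n/100 the
Bayesian fit is practically indistinguishable from adjusted OLS (within
0.02 in every scenario tested), and τ = n/10 lands between the two.

## Known limitations

* The informative prior must come from external knowledge of the
  confounder–outcome relation; the package evaluates correctly centred
  priors only — robustness to misspecified prior means is untested here.
* Closed-form biases are large-sample; at n = 1000 the finite-sample
  difference is well inside Monte-Carlo noise, but at small n it need
  not be.
* The Gibbs sampler covers the two-coefficient (plus optional intercept)
  outcome model only; it is not a general-purpose regression sampler.
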
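"""Frequentist and Bayesian fits of the outcome regression on one dataset.

Three estimators of the exposure-outcome coefficient are provided:

* OLS without covariate adjustment (``covariates=["x"]``),
* OLS adjusted for the measured confounder (``covariates=["x", "z"]``),
* a Bayesian linear model of Y on X and Z with an informative normal prior
  on the confounder-outcome coefficient ``beta_yz`` and vague priors on the
  exposure coefficient (normal, precision 0.001) and on the residual scale
  (uniform on (0, 100)), sampled by a Gibbs sampler.

The Gibbs sampler alternates a conjugate multivariate-normal draw of the
coefficients given the residual variance with an inverse-gamma-type draw of
the residual variance.  Under the uniform-on-sigma prior the conditional of
``sigma^2`` is inverse-gamma with shape ``(n - 1) / 2`` (the extra ``-1/2``
relative to the flat-on-``sigma^2`` case is the Jacobian of the
``sigma -> sigma^2`` change of variables), truncated at ``sigma_upper^2``;
the truncation is enforced by rejection, and rarely binds at realistic
scales.

All fits omit the intercept by default, matching the zero-mean generating
process; pass ``intercept=True`` for real data (the intercept gets a flat
normal prior in the Bayesian fit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "PriorSpec",
    "MCMCConfig",
    "FitResult",
    "PosteriorSummary",
    "ols_fit",
    "gibbs_fit",
    "conjugate_posterior_mean",
]

# Precision of the flat normal prior placed on an intercept term.
_INTERCEPT_PRECISION = 1e-6


@dataclass(frozen=True)
class PriorSpec:
    """Priors of the Bayesian outcome model.

    ``tau_*`` are precisions (1 / variance), never standard deviations.
    ``mu_yz`` encodes the external knowledge about the measured
    confounder-outcome relation; ``tau_yz`` its certainty, typically scaled
    against the sample size (n for near-certainty, n/100 for weak belief).
    """

    mu_yz: float
    tau_yz: float
    tau_yx: float = 0.001
    sigma_upper: float = 100.0

    def __post_init__(self) -> None:
        for name in ("tau_yz", "tau_yx", "sigma_upper"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings: chain count, total and burn-in iterations, seed."""

    n_chains: int = 4
    n_iter: int = 2000
    n_burn: int = 1000
    seed: object = None

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if not 0 <= self.n_burn < self.n_iter:
            raise ValueError(
                f"n_burn must satisfy 0 <= n_burn < n_iter, got {self.n_burn} / {self.n_iter}"
            )


@dataclass(frozen=True)
class FitResult:
    """Point estimates and standard errors of a frequentist fit."""

    method: str
    coef: dict
    se: dict
    sigma: float

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.se.values()):
            raise ValueError("standard errors must be nonnegative")


@dataclass(frozen=True)
class PosteriorSummary:
    """Pooled posterior summaries across chains.

    ``mean``/``sd`` are posterior means and standard deviations keyed by
    parameter name, ``rhat`` the potential scale reduction computed across
    chains on retained draws, ``n_draws`` the retained draw count
    (chains x (iterations - burn-in)).
    """

    method: str
    mean: dict
    sd: dict
    rhat: dict
    n_draws: int
    draws: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.sd.values()):
            raise ValueError("posterior standard deviations must be nonnegative")


def _design(data: pd.DataFrame, covariates, intercept: bool):
    missing = [c for c in covariates if c not in data.columns]
    if missing:
        raise ValueError(f"columns not present in data: {missing}")
    X = data.loc[:, list(covariates)].to_numpy(dtype=float)
    names = list(covariates)
    if intercept:
        X = np.column_stack([X, np.ones(len(X))])
        names.append("intercept")
    return X, names


def ols_fit(
    data: pd.DataFrame,
    covariates,
    outcome: str = "y",
    intercept: bool = False,
) -> FitResult:
    """Ordinary least squares of the outcome on the requested covariates.

    No intercept unless asked for; conventional (non-robust) standard
    errors.  Rejects rank-deficient designs.
    """
    if outcome not in data.columns:
        raise ValueError(f"outcome column {outcome!r} not present in data")
    X, names = _design(data, covariates, intercept)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    res = sm.OLS(data[outcome].to_numpy(dtype=float), X).fit()
    return FitResult(
        method="ols:" + "+".join(covariates) + ("+1" if intercept else ""),
        coef=dict(zip(names, res.params)),
        se=dict(zip(names, res.bse)),
        sigma=float(np.sqrt(res.scale)),
    )


def _prior_blocks(prior: PriorSpec, names):
    mu0 = {"x": 0.0, "z": prior.mu_yz, "intercept": 0.0}
    tau = {"x": prior.tau_yx, "z": prior.tau_yz, "intercept": _INTERCEPT_PRECISION}
    return (
        np.array([mu0[n] for n in names]),
        np.array([tau[n] for n in names]),
    )


def conjugate_posterior_mean(
    data: pd.DataFrame,
    prior: PriorSpec,
    sigma2: float,
    outcome: str = "y",
    exposure: str = "x",
    confounder: str = "z",
    intercept: bool = False,
) -> np.ndarray:
    """Exact posterior mean of the coefficients at fixed residual variance.

    The normal prior and normal likelihood are conjugate, so the posterior
    mean is ``(X'X / sigma^2 + T)^{-1} (X'y / sigma^2 + T mu0)`` with
    ``T = diag(tau_yx, tau_yz)``.  Exact oracle for the Gibbs sampler's
    coefficient block.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be strictly positive")
    X, names = _design(data, [exposure, confounder], intercept)
    roles = ["x", "z"] + (["intercept"] if intercept else [])
    mu0, tau = _prior_blocks(prior, roles)
    y = data[outcome].to_numpy(dtype=float)
    P = X.T @ X / sigma2 + np.diag(tau)
    if np.linalg.cond(P) > 1e12:
        raise ValueError("posterior precision matrix is singular or near-singular")
    return np.linalg.solve(P, X.T @ y / sigma2 + tau * mu0)


def _rhat(draws: np.ndarray) -> float:
    # draws: (iterations, chains); classic potential scale reduction
    length, m = draws.shape
    if m < 2:
        return float("nan")
    W = draws.var(axis=0, ddof=1).mean()
    B = length * draws.mean(axis=0).var(ddof=1)
    var_plus = (length - 1) / length * W + B / length
    return float(np.sqrt(var_plus / W))


def gibbs_fit(
    data: pd.DataFrame,
    prior: PriorSpec,
    mcmc: MCMCConfig,
    outcome: str = "y",
    exposure: str = "x",
    confounder: str = "z",
    intercept: bool = False,
    fixed_sigma2: float | None = None,
    keep_draws: bool = False,
) -> PosteriorSummary:
    """Gibbs sampler for the Bayesian outcome model.

    Alternates (i) a joint conjugate normal draw of the coefficients given
    ``sigma^2`` and (ii) a truncated inverse-gamma draw of ``sigma^2``
    consistent with the uniform prior on ``sigma``.  Chains start at the
    OLS solution jittered by up to two OLS standard errors, so the
    potential scale reduction across chains is informative.  With
    ``fixed_sigma2`` the variance update is skipped (the coefficient draws
    are then i.i.d. from the exact conditional posterior), which is used to
    validate the sampler against :func:`conjugate_posterior_mean`.

    Reports pooled posterior means and standard deviations; identical
    inputs (including the seed) give identical summaries.  A potential
    scale reduction above 1.1 raises a warning, never an error.
    """
    X, names = _design(data, [exposure, confounder], intercept)
    roles = ["x", "z"] + (["intercept"] if intercept else [])
    mu0, tau = _prior_blocks(prior, roles)
    y = data[outcome].to_numpy(dtype=float)
    n, p = X.shape
    G = X.T @ X
    h = X.T @ y
    yty = float(y @ y)
    C = mcmc.n_chains
    rng = np.random.default_rng(mcmc.seed)

    ols = ols_fit(data, [exposure, confounder], outcome=outcome, intercept=intercept)
    beta_hat = np.array([ols.coef[k] for k in names])
    se_hat = np.array([ols.se[k] for k in names])
    beta = beta_hat + rng.uniform(-2, 2, size=(C, p)) * se_hat
    if fixed_sigma2 is None:
        sig2 = ols.sigma**2 * np.exp(rng.uniform(-0.5, 0.5, size=C))
    else:
        if fixed_sigma2 <= 0:
            raise ValueError("fixed_sigma2 must be strictly positive")
        sig2 = np.full(C, float(fixed_sigma2))

    kept = mcmc.n_iter - mcmc.n_burn
    draws = np.empty((mcmc.n_iter, C, p))
    sigma_upper2 = prior.sigma_upper**2
    T = np.diag(tau)
    Tmu = tau * mu0

    for it in range(mcmc.n_iter):
        if p == 2:
            # closed-form 2x2 conditional, the hot path of the simulation study
            p11 = G[0, 0] / sig2 + tau[0]
            p12 = G[0, 1] / sig2
            p22 = G[1, 1] / sig2 + tau[1]
            det = p11 * p22 - p12 * p12
            V11, V12, V22 = p22 / det, -p12 / det, p11 / det
            b1 = h[0] / sig2 + Tmu[0]
            b2 = h[1] / sig2 + Tmu[1]
            m1 = V11 * b1 + V12 * b2
            m2 = V12 * b1 + V22 * b2
            L11 = np.sqrt(V11)
            L21 = V12 / L11
            L22 = np.sqrt(V22 - V12 * V12 / V11)
            z1 = rng.standard_normal(C)
            z2 = rng.standard_normal(C)
            beta = np.column_stack([m1 + L11 * z1, m2 + L21 * z1 + L22 * z2])
        else:
            P = G[None, :, :] / sig2[:, None, None] + T[None, :, :]
            V = np.linalg.inv(P)
            rhs = h[None, :] / sig2[:, None] + Tmu[None, :]
            m = np.einsum("cij,cj->ci", V, rhs)
            L = np.linalg.cholesky(V)
            beta = m + np.einsum("cij,cj->ci", L, rng.standard_normal((C, p)))
        if not np.all(np.isfinite(beta)):
            raise RuntimeError(
                f"non-finite coefficient draw at iteration {it}; sigma2 per chain: {sig2}"
            )
        draws[it] = beta
        if fixed_sigma2 is None:
            ssr = yty - 2 * beta @ h + np.einsum("ci,ij,cj->c", beta, G, beta)
            sig2 = ssr / 2 / rng.standard_gamma((n - 1) / 2, size=C)
            # enforce the uniform prior's upper bound by rejection
            over = sig2 > sigma_upper2
            while np.any(over):
                sig2[over] = ssr[over] / 2 / rng.standard_gamma(
                    (n - 1) / 2, size=int(over.sum())
                )
                over = sig2 > sigma_upper2

    retained = draws[mcmc.n_burn :]  # (kept, C, p)
    pooled = retained.reshape(kept * C, p)
    mean = dict(zip(names, pooled.mean(axis=0)))
    sd = dict(zip(names, pooled.std(axis=0, ddof=1)))
    rhat = {name: _rhat(retained[:, :, j]) for j, name in enumerate(names)}
    bad = {k: v for k, v in rhat.items() if np.isfinite(v) and v > 1.1}
    if bad:
        warnings.warn(f"potential scale reduction above 1.1: {bad}", RuntimeWarning)
    return PosteriorSummary(
        method=f"gibbs:tau_yz={prior.tau_yz:g}",
        mean=mean,
        sd=sd,
        rhat=rhat,
        n_draws=kept * C,
        draws=retained if keep_draws else None,
    )
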
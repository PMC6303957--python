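"""Closed-form large-sample bias of regression estimators under omitted confounders.

For the structural model in :mod:`priorconf.dgp`, omitting confounders from
the outcome regression biases the exposure coefficient.  With both
confounders omitted the bias of the X coefficient is

.. math::

    \\beta_{yz}\\Big(\\beta_{xz}\\tfrac{Var(Z)}{Var(X)}
        + \\beta_{zu}\\beta_{xu}\\tfrac{Var(U)}{Var(X)}\\Big)
    + \\beta_{yu}\\tfrac{Var(U)}{Var(X)}
        \\big(\\beta_{xu} + \\beta_{zu}\\beta_{xz}\\big),

one additive term per backdoor path from X to Y.  Adjusting for Z but not U
leaves

.. math::

    \\beta_{xu}\\beta_{yu}
    \\frac{Var(U)(1 - \\rho_{uz}^2)}{Var(X)(1 - \\rho_{xz}^2)},

the residual confounding carried by U, shrunk by its correlation with Z and
amplified by the conditional variance reduction of X given Z (the
near-instrument effect).  Conditioning on X — a collider of Z and U — also
biases the Z coefficient; on the standardized scale that bias is
``beta_yu_std * (rho_zu - rho_xz * rho_xu) / (1 - rho_xz^2)``.

Every closed form here can be checked against
:func:`population_regression`, the exact large-sample OLS coefficients
implied by a covariance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dgp import COLUMN_ORDER, ScenarioParams, implied_covariance, implied_moments

__all__ = [
    "StandardizedCorrelations",
    "standardized_correlations",
    "bias_unadjusted",
    "bias_adjusted_z",
    "bias_zy_conditional",
    "population_regression",
]


@dataclass(frozen=True)
class StandardizedCorrelations:
    """Pairwise correlations among standardized Z, X, U plus the direct
    standardized effect of U on Y (``beta_yu_std``)."""

    rho_zu: float
    rho_xz: float
    rho_xu: float
    beta_yu_std: float

    def __post_init__(self) -> None:
        for name in ("rho_zu", "rho_xz", "rho_xu"):
            r = getattr(self, name)
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"{name} must lie in [-1, 1], got {r!r}")
        R = np.array(
            [
                [1.0, self.rho_xz, self.rho_zu],
                [self.rho_xz, 1.0, self.rho_xu],
                [self.rho_zu, self.rho_xu, 1.0],
            ]
        )
        if np.linalg.eigvalsh(R)[0] < -1e-10:
            raise ValueError("correlations do not form a positive semidefinite matrix")


def standardized_correlations(params: ScenarioParams) -> StandardizedCorrelations:
    """Standardize a scenario for the Z-coefficient bias formula.

    The direct effect of U on Y on the standardized scale is the raw
    coefficient rescaled by the marginal standard deviations,
    ``beta_yu * sd(U) / sd(Y)``; this is the unique choice under which the
    standardized bias formula agrees with :func:`population_regression`
    applied to the correlation matrix.
    """
    cov = implied_covariance(params).to_numpy()
    sd = np.sqrt(np.diag(cov))
    i = {v: k for k, v in enumerate(COLUMN_ORDER)}
    return StandardizedCorrelations(
        rho_zu=float(cov[i["z"], i["u"]] / (sd[i["z"]] * sd[i["u"]])),
        rho_xz=float(cov[i["x"], i["z"]] / (sd[i["x"]] * sd[i["z"]])),
        rho_xu=float(cov[i["x"], i["u"]] / (sd[i["x"]] * sd[i["u"]])),
        beta_yu_std=float(params.beta_yu * sd[i["u"]] / sd[i["y"]]),
    )


def bias_unadjusted(params: ScenarioParams) -> float:
    """Large-sample bias of the X coefficient when both Z and U are omitted.

    Independent of the true exposure effect ``beta_yx``; each term
    corresponds to one backdoor path from X to Y.
    """
    m = implied_moments(params)
    p = params
    return float(
        p.beta_yz * (p.beta_xz * m.var_z / m.var_x + p.beta_zu * p.beta_xu * m.var_u / m.var_x)
        + p.beta_yu * (m.var_u / m.var_x) * (p.beta_xu + p.beta_zu * p.beta_xz)
    )


def bias_adjusted_z(params: ScenarioParams) -> float:
    """Large-sample bias of the X coefficient when Z is adjusted for but U omitted."""
    m = implied_moments(params)
    if m.rho_xz**2 >= 1.0 - 1e-12:
        raise ValueError("rho_xz^2 = 1: Z is a perfect proxy of X, bias undefined")
    return float(
        params.beta_xu
        * params.beta_yu
        * m.var_u
        * (1 - m.rho_uz**2)
        / (m.var_x * (1 - m.rho_xz**2))
    )


def bias_zy_conditional(corr: StandardizedCorrelations) -> float:
    """Bias of the Z coefficient in the Y ~ X + Z regression, standardized scale.

    Nonzero even when Z and U are independent, because conditioning on the
    collider X opens a path from Z to Y through U.
    """
    if corr.rho_xz**2 >= 1.0 - 1e-12:
        raise ValueError("rho_xz^2 = 1: degenerate conditioning")
    return float(
        corr.beta_yu_std
        * (corr.rho_zu - corr.rho_xz * corr.rho_xu)
        / (1 - corr.rho_xz**2)
    )


def population_regression(cov, outcome_index: int, covariate_indices) -> np.ndarray:
    """Large-sample OLS coefficients implied by a covariance matrix.

    Returns ``Sigma_cc^{-1} sigma_cy`` for the covariate block: the
    coefficients any consistent regression of the outcome on those
    covariates converges to.  Serves as the exact oracle for all bias
    formulas in this module.
    """
    cov = np.asarray(cov, dtype=float)
    covariate_indices = list(covariate_indices)
    Scc = cov[np.ix_(covariate_indices, covariate_indices)]
    scy = cov[covariate_indices, outcome_index]
    if np.linalg.cond(Scc) > 1e12:
        raise ValueError("covariate covariance block is singular or near-singular")
    return np.linalg.solve(Scc, scy)
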
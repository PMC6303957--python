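"""Structural linear data-generating process with one measured and one unmeasured confounder.

The model has four jointly normal, zero-mean variables: an unmeasured
confounder ``U``, a measured confounder ``Z``, an exposure ``X`` and an
outcome ``Y``, linked by linear structural equations

.. math::

    z_i &= \\beta_{zu} u_i + \\xi_i \\\\
    x_i &= \\beta_{xz} z_i + \\beta_{xu} u_i + \\zeta_i \\\\
    y_i &= \\beta_{yx} x_i + \\beta_{yz} z_i + \\beta_{yu} u_i + \\varepsilon_i

with independent normal errors.  Intercepts are omitted throughout: the
process is zero-mean by construction and the fitted models match it.

This module defines the scenario parameterisation, the exact second
moments the structural equations imply, and samplers that generate
datasets either from a :class:`ScenarioParams` or directly from a
mean vector and covariance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ScenarioParams",
    "ImpliedMoments",
    "implied_moments",
    "implied_covariance",
    "generate_dataset",
    "generate_from_covariance",
    "COLUMN_ORDER",
]

#: Canonical column order for generated datasets and implied covariances.
COLUMN_ORDER = ("u", "z", "x", "y")


@dataclass(frozen=True)
class ScenarioParams:
    """Path coefficients, residual variances and sample size of one scenario.

    Coefficients are unit changes in the dependent variable per unit of the
    independent variable; variances are the residual variances of the
    structural errors.
    """

    beta_yx: float = 0.0
    beta_yz: float = 1.0
    beta_yu: float = 0.0
    beta_xz: float = 1.0
    beta_xu: float = 0.0
    beta_zu: float = 0.0
    var_u: float = 1.0
    var_z_resid: float = 1.0
    var_x_resid: float = 1.0
    var_y_resid: float = 1.0
    n: int = 1000

    def __post_init__(self) -> None:
        for name in ("var_u", "var_z_resid", "var_x_resid", "var_y_resid"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if int(self.n) != self.n or self.n < 3:
            raise ValueError(f"n must be an integer >= 3, got {self.n!r}")


@dataclass(frozen=True)
class ImpliedMoments:
    """Exact marginal and conditional second moments implied by a scenario."""

    var_u: float
    var_z: float
    var_x: float
    cov_zu: float
    cov_xu: float
    cov_xz: float
    rho_uz: float
    rho_xz: float
    rho_xu: float
    var_u_given_z: float
    var_x_given_z: float


def implied_moments(params: ScenarioParams) -> ImpliedMoments:
    """Propagate path coefficients into the exact moments of (U, Z, X).

    Follows the structural equations: Var(Z) picks up the U -> Z path,
    Var(X) the two paths into X plus their covariance, and the conditional
    variances are the usual linear-Gaussian residual variances
    ``Var(A | Z) = Var(A) (1 - rho_az^2)``.
    """
    p = params
    var_z = p.beta_zu**2 * p.var_u + p.var_z_resid
    cov_zu = p.beta_zu * p.var_u
    cov_xu = p.beta_xz * cov_zu + p.beta_xu * p.var_u
    cov_xz = p.beta_xz * var_z + p.beta_xu * cov_zu
    var_x = (
        p.beta_xz**2 * var_z
        + p.beta_xu**2 * p.var_u
        + 2 * p.beta_xz * p.beta_xu * cov_zu
        + p.var_x_resid
    )
    rho_uz = cov_zu / np.sqrt(p.var_u * var_z)
    rho_xz = cov_xz / np.sqrt(var_x * var_z)
    rho_xu = cov_xu / np.sqrt(var_x * p.var_u)
    return ImpliedMoments(
        var_u=p.var_u,
        var_z=var_z,
        var_x=var_x,
        cov_zu=cov_zu,
        cov_xu=cov_xu,
        cov_xz=cov_xz,
        rho_uz=float(rho_uz),
        rho_xz=float(rho_xz),
        rho_xu=float(rho_xu),
        var_u_given_z=float(p.var_u * (1 - rho_uz**2)),
        var_x_given_z=float(var_x * (1 - rho_xz**2)),
    )


def implied_covariance(params: ScenarioParams) -> pd.DataFrame:
    """Exact 4x4 covariance matrix of (U, Z, X, Y) implied by the scenario.

    Computed as ``(I - B)^-1 D (I - B)^-T`` where ``B`` holds the path
    coefficients and ``D`` the residual variances; this is the standard
    reduced form of a recursive linear system.
    """
    p = params
    B = np.zeros((4, 4))
    idx = {v: i for i, v in enumerate(COLUMN_ORDER)}
    B[idx["z"], idx["u"]] = p.beta_zu
    B[idx["x"], idx["u"]] = p.beta_xu
    B[idx["x"], idx["z"]] = p.beta_xz
    B[idx["y"], idx["u"]] = p.beta_yu
    B[idx["y"], idx["z"]] = p.beta_yz
    B[idx["y"], idx["x"]] = p.beta_yx
    D = np.diag([p.var_u, p.var_z_resid, p.var_x_resid, p.var_y_resid])
    A = np.linalg.inv(np.eye(4) - B)
    cov = A @ D @ A.T
    return pd.DataFrame(cov, index=list(COLUMN_ORDER), columns=list(COLUMN_ORDER))


def generate_dataset(params: ScenarioParams, seed) -> pd.DataFrame:
    """Sample one dataset of ``params.n`` rows from the structural equations.

    U is drawn first, then Z given U, X given (Z, U) and finally Y.  The
    returned frame has columns ``u, z, x, y``; the ``u`` column is kept so a
    full-model reference fit is possible, but analysis entry points exclude
    it unless explicitly requested.  The same seed reproduces the dataset
    bit for bit.
    """
    p = params
    rng = np.random.default_rng(seed)
    n = int(p.n)
    u = rng.normal(0.0, np.sqrt(p.var_u), n)
    z = p.beta_zu * u + rng.normal(0.0, np.sqrt(p.var_z_resid), n)
    x = p.beta_xz * z + p.beta_xu * u + rng.normal(0.0, np.sqrt(p.var_x_resid), n)
    y = (
        p.beta_yx * x
        + p.beta_yz * z
        + p.beta_yu * u
        + rng.normal(0.0, np.sqrt(p.var_y_resid), n)
    )
    return pd.DataFrame({"u": u, "z": z, "x": x, "y": y})


def generate_from_covariance(
    mean,
    cov,
    n: int,
    seed,
    columns=COLUMN_ORDER,
) -> pd.DataFrame:
    """Sample ``n`` multivariate-normal rows with the given moments.

    ``columns`` names the variable roles in the order of ``mean``/``cov``
    (default ``u, z, x, y``), so downstream fits know which column plays the
    unmeasured confounder.  The covariance matrix must be symmetric positive
    semidefinite; otherwise a ``ValueError`` reports the offending eigenvalue.
    """
    mean = np.asarray(mean, dtype=float)
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError(f"covariance must be square, got shape {cov.shape}")
    if len(columns) != cov.shape[0] or mean.shape != (cov.shape[0],):
        raise ValueError("mean, covariance and column roles have inconsistent sizes")
    if not np.allclose(cov, cov.T, rtol=1e-10, atol=1e-12):
        raise ValueError("covariance matrix is not symmetric")
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals[0] < -1e-10 * max(1.0, abs(eigvals[-1])):
        raise ValueError(
            f"covariance matrix is not positive semidefinite: "
            f"smallest eigenvalue {eigvals[0]:.6g}"
        )
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(mean, cov, size=int(n), method="svd")
    return pd.DataFrame(draws, columns=list(columns))
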
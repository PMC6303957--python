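"""Closed-form omitted-confounder bias against the covariance-matrix oracle."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from priorconf import (
    ScenarioParams,
    StandardizedCorrelations,
    bias_adjusted_z,
    bias_unadjusted,
    bias_zy_conditional,
    build_grid,
    generate_from_covariance,
    implied_covariance,
    implied_moments,
    population_regression,
    standardized_correlations,
)
from conftest import row_scenario

U, Z, X, Y = 0, 1, 2, 3


def oracle_bias(params, covariates):
    cov = implied_covariance(params).to_numpy()
    return population_regression(cov, Y, covariates)[0] - params.beta_yx


class TestClosedForms:
    def test_zero_when_no_confounder_outcome_paths(self):
        p = ScenarioParams(beta_yz=0, beta_yu=0, beta_xz=1, beta_xu=1, beta_zu=1)
        assert bias_unadjusted(p) == 0

    def test_zero_when_u_not_related_to_exposure(self):
        p = ScenarioParams(beta_yz=1, beta_yu=1, beta_xz=1, beta_xu=0, beta_zu=0)
        assert bias_adjusted_z(p) == 0

    # frozen reference-table cells: (row, unadjusted bias, Z-adjusted bias)
    @pytest.mark.parametrize(
        "row, unadj, adj",
        [
            (1, 0.5, 0.0),
            (8, 1.0, 0.0),
            (9, 2 / 3, 0.5),
            (10, 5 / 6, 1 / 3),
            (11, 0.5, 0.4),
            (15, 1.0, 1.0),
            (16, 7 / 6, 2 / 3),
            (18, 10 / 11, 2 / 3),
        ],
    )
    def test_reference_table_cells(self, row, unadj, adj):
        p = row_scenario(row)
        assert bias_unadjusted(p) == pytest.approx(unadj, abs=1e-12)
        assert bias_adjusted_z(p) == pytest.approx(adj, abs=1e-12)

    def test_oracle_equivalence_on_full_grid(self):
        for p in build_grid():
            assert bias_unadjusted(p) == pytest.approx(oracle_bias(p, [X]), rel=1e-10)
            assert bias_adjusted_z(p) == pytest.approx(
                oracle_bias(p, [X, Z]), rel=1e-10, abs=1e-12
            )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(byx=st.floats(-3, 3, allow_nan=False))
    def test_independent_of_true_exposure_effect(self, byx):
        base = row_scenario(10)
        moved = dataclasses.replace(base, beta_yx=byx)
        assert bias_unadjusted(moved) == pytest.approx(bias_unadjusted(base))
        assert bias_adjusted_z(moved) == pytest.approx(bias_adjusted_z(base))

    def test_perfect_proxy_rejected(self):
        p = ScenarioParams(beta_xz=1, var_x_resid=1e-14, var_u=1e-13)
        with pytest.raises(ValueError, match="rho_xz"):
            bias_adjusted_z(p)


class TestMonotonicity:
    def test_nondecreasing_in_confounder_outcome_effect(self):
        biases = [
            abs(bias_adjusted_z(dataclasses.replace(row_scenario(9), beta_yu=b)))
            for b in (0.0, 0.5, 1.0, 2.0, 4.0)
        ]
        assert biases == sorted(biases)

    def test_nonincreasing_in_confounder_correlation(self):
        # stronger U -> Z relation means adjusting for Z soaks up more of U
        biases = [
            abs(bias_adjusted_z(dataclasses.replace(row_scenario(9), beta_zu=b)))
            for b in (0.0, 0.5, 1.0, 2.0)
        ]
        rhos = [
            implied_moments(dataclasses.replace(row_scenario(9), beta_zu=b)).rho_uz ** 2
            for b in (0.0, 0.5, 1.0, 2.0)
        ]
        assert rhos == sorted(rhos)
        assert biases == sorted(biases, reverse=True)

    def test_nondecreasing_in_exposure_confounder_effect_below_turning_point(self):
        # Eq-level bias rises in beta_xu only while beta_xu^2 Var(U|Z) <= sigma_x^2;
        # beyond that Var(X|Z) growth dominates and the bias falls again
        base = row_scenario(9)
        rising = [
            abs(bias_adjusted_z(dataclasses.replace(base, beta_xu=b)))
            for b in (0.0, 0.25, 0.5, 1.0)
        ]
        assert rising == sorted(rising)
        beyond = abs(bias_adjusted_z(dataclasses.replace(base, beta_xu=3.0)))
        assert beyond < rising[-1]

    def test_adjustment_amplifies_residual_confounding(self):
        # relative to the U-attributable share of the unadjusted bias, adjusting
        # for a near-instrument Z amplifies what U carries (Var(X|Z) < Var(X))
        for bxz in (0.5, 1.0, 2.0):
            p = ScenarioParams(
                beta_yz=1, beta_yu=1, beta_xz=bxz, beta_xu=1, beta_zu=0
            )
            m = implied_moments(p)
            u_component = p.beta_xu * p.beta_yu * m.var_u / m.var_x
            assert bias_adjusted_z(p) > u_component
        flat = ScenarioParams(beta_yz=1, beta_yu=1, beta_xz=0, beta_xu=1, beta_zu=0)
        m = implied_moments(flat)
        assert bias_adjusted_z(flat) == pytest.approx(
            flat.beta_xu * flat.beta_yu * m.var_u / m.var_x
        )


class TestConfounderOutcomeBias:
    def test_zero_without_unmeasured_effect(self):
        corr = StandardizedCorrelations(rho_zu=0.3, rho_xz=0.4, rho_xu=0.2, beta_yu_std=0)
        assert bias_zy_conditional(corr) == 0

    def test_collider_bias_when_confounders_independent(self):
        # Z independent of U, yet conditioning on their collider X biases Z-Y
        corr = StandardizedCorrelations(rho_zu=0.0, rho_xz=0.5, rho_xu=0.4, beta_yu_std=1.0)
        expected = -1.0 * 0.5 * 0.4 / (1 - 0.25)
        assert bias_zy_conditional(corr) == pytest.approx(expected)
        assert bias_zy_conditional(corr) != 0

    def test_direct_substitution(self):
        corr = StandardizedCorrelations(rho_zu=0.5, rho_xz=0.0, rho_xu=0.5, beta_yu_std=1.0)
        assert bias_zy_conditional(corr) == pytest.approx(0.5)

    def test_converter_matches_standardized_oracle_on_grid(self):
        # standardize the implied covariance, regress std-Y on std-(X, Z): the Z
        # coefficient minus the standardized direct effect must equal the formula
        for p in build_grid():
            cov = implied_covariance(p).to_numpy()
            sd = np.sqrt(np.diag(cov))
            R = cov / np.outer(sd, sd)
            z_coef = population_regression(R, Y, [X, Z])[1]
            truth = p.beta_yz * sd[Z] / sd[Y]
            corr = standardized_correlations(p)
            assert bias_zy_conditional(corr) == pytest.approx(
                z_coef - truth, rel=1e-9, abs=1e-12
            )

    def test_monte_carlo_cross_check(self):
        corr = StandardizedCorrelations(rho_zu=0.5, rho_xz=0.0, rho_xu=0.5, beta_yu_std=1.0)
        R = np.array(
            [
                [1.0, corr.rho_zu, corr.rho_xu],
                [corr.rho_zu, 1.0, corr.rho_xz],
                [corr.rho_xu, corr.rho_xz, 1.0],
            ]
        )
        n = 4 * 10**5
        uzx = generate_from_covariance(np.zeros(3), R, n=n, seed=9, columns=("u", "z", "x"))
        eps_sd = 0.5
        # direct standardized effects: only U and Z affect Y here
        y = 0.0 * uzx["x"] + 0.2 * uzx["z"] + corr.beta_yu_std * uzx["u"]
        y = y + np.random.default_rng(10).normal(0, eps_sd, n)
        Xmat = uzx[["x", "z"]].to_numpy()
        coefs = np.linalg.lstsq(Xmat, np.asarray(y), rcond=None)[0]
        assert coefs[1] - 0.2 == pytest.approx(bias_zy_conditional(corr), abs=0.01)

    def test_degenerate_conditioning_rejected(self):
        corr = StandardizedCorrelations(rho_zu=0.0, rho_xz=1.0, rho_xu=0.0, beta_yu_std=1.0)
        with pytest.raises(ValueError, match="rho_xz"):
            bias_zy_conditional(corr)


class TestPopulationRegression:
    def test_identity_covariance_returns_raw_covariances(self):
        cov = np.eye(4)
        cov[Y, X] = cov[X, Y] = 0.3
        cov[Y, Z] = cov[Z, Y] = 0.2
        coefs = population_regression(cov, Y, [X, Z])
        assert coefs == pytest.approx([0.3, 0.2])

    def test_confounded_z_coefficient_exceeds_truth(self, scenario8):
        # the Z coefficient absorbs the omitted U: 1.50 against a direct effect of 1
        cov = implied_covariance(scenario8).to_numpy()
        coefs = population_regression(cov, Y, [X, Z])
        assert coefs == pytest.approx([0.0, 1.5], abs=1e-12)

    def test_scenario16_exposure_bias(self):
        cov = implied_covariance(row_scenario(16)).to_numpy()
        coefs = population_regression(cov, Y, [X, Z])
        assert coefs[0] == pytest.approx(2 / 3)
        assert coefs[0] == pytest.approx(bias_adjusted_z(row_scenario(16)))

    def test_singular_block_rejected(self):
        cov = np.ones((3, 3))
        with pytest.raises(ValueError, match="singular"):
            population_regression(cov, 2, [0, 1])
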
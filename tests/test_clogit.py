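"""Conditional-likelihood correctness against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import nestcc as ncc
from nestcc.clogit import (
    MatchedDesign,
    Z975,
    build_design,
    conditional_loglik,
    fit,
    wald_summary,
)
from nestcc.config import COVARIATE_NAMES


def _design(sets):
    """sets: list of (X_rows, case_index). Case row placed first."""
    X, is_case, starts = [], [], []
    pos = 0
    for rows, case_idx in sets:
        rows = np.asarray(rows, dtype=float)
        starts.append(pos)
        for i, row in enumerate(rows):
            X.append(row)
            is_case.append(i == case_idx)
            pos += 1
    return MatchedDesign(
        X=np.array(X),
        is_case=np.array(is_case),
        group_starts=np.array(starts),
        names=[f"x{j}" for j in range(np.array(X).shape[1])],
    )


def _random_design(rng, n_sets=5, set_size=4, p=3):
    sets = []
    for _ in range(n_sets):
        rows = rng.normal(size=(set_size, p))
        sets.append((rows, int(rng.integers(0, set_size))))
    return _design(sets)


class TestLoglik:
    def test_uniform_softmax_at_beta_zero(self):
        rng = np.random.default_rng(0)
        d = _design([(rng.normal(size=(11, 2)), 0)])
        ll, _, _ = conditional_loglik(d, np.zeros(2))
        assert ll == pytest.approx(-np.log(11), abs=1e-12)

    def test_identical_rows_contribute_log_set_size_for_any_beta(self):
        d = _design([(np.ones((5, 2)), 2)])
        for beta in (np.zeros(2), np.array([1.3, -0.4]), np.array([10.0, 5.0])):
            ll, grad, _ = conditional_loglik(d, beta)
            assert ll == pytest.approx(-np.log(5), abs=1e-10)
            assert np.allclose(grad, 0, atol=1e-10)

    def test_invariance_to_per_set_constant_shift(self):
        rng = np.random.default_rng(1)
        d = _design([(rng.normal(size=(4, 3)), 1), (rng.normal(size=(6, 3)), 0)])
        beta = rng.normal(size=3)
        ll0, g0, h0 = conditional_loglik(d, beta)
        shifted = d.X.copy()
        shifted[:4] += np.array([2.0, -1.0, 0.5])
        shifted[4:] += np.array([-3.0, 0.7, 1.1])
        d2 = MatchedDesign(X=shifted, is_case=d.is_case, group_starts=d.group_starts, names=d.names)
        ll1, g1, h1 = conditional_loglik(d2, beta)
        assert ll1 == pytest.approx(ll0, abs=1e-10)
        assert np.allclose(g0, g1, atol=1e-10)
        assert np.allclose(h0, h1, atol=1e-10)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        d = _random_design(rng, n_sets=5, set_size=4, p=3)
        beta = rng.normal(scale=0.5, size=3)
        _, grad, hess = conditional_loglik(d, beta)
        eps = 1e-6
        for j in range(3):
            ej = np.zeros(3)
            ej[j] = eps
            lp, _, _ = conditional_loglik(d, beta + ej)
            lm, _, _ = conditional_loglik(d, beta - ej)
            assert grad[j] == pytest.approx((lp - lm) / (2 * eps), abs=1e-5)
            # and the hessian matches differentiated gradients
            _, gp, _ = conditional_loglik(d, beta + ej)
            _, gm, _ = conditional_loglik(d, beta - ej)
            assert np.allclose(hess[:, j], (gp - gm) / (2 * eps), atol=1e-5)

    def test_hessian_negative_semidefinite(self):
        rng = np.random.default_rng(3)
        d = _random_design(rng, n_sets=6, set_size=5, p=3)
        for _ in range(10):
            beta = rng.normal(scale=1.5, size=3)
            _, _, hess = conditional_loglik(d, beta)
            assert np.all(np.linalg.eigvalsh(hess) <= 1e-9)

    def test_nonfinite_beta_rejected(self):
        d = _design([(np.eye(2), 0)])
        with pytest.raises(ValueError):
            conditional_loglik(d, np.array([np.nan, 0.0]))


class TestFit:
    def test_concordant_design_is_an_error(self):
        d = _design([(np.ones((3, 2)), 0), (np.zeros((4, 2)), 1)])
        with pytest.raises(ValueError, match="no informative sets"):
            fit(d)

    def test_collinear_columns_named(self):
        rng = np.random.default_rng(4)
        rows = rng.normal(size=(4, 2))
        X = np.column_stack([rows, rows[:, 0]])  # x2 duplicates x0
        d = _design([(X, 0)])
        with pytest.raises(np.linalg.LinAlgError, match="x"):
            fit(d)

    def test_matches_scipy_direct_maximization(self):
        rng = np.random.default_rng(5)
        d = _random_design(rng, n_sets=8, set_size=4, p=3)
        res = fit(d)
        obj = lambda b: -conditional_loglik(d, b)[0]
        ref = minimize(obj, np.zeros(3), method="BFGS", options={"gtol": 1e-10})
        assert np.allclose(res.beta, ref.x, atol=1e-5)
        assert res.converged

    def test_one_to_one_sets_equal_difference_logistic(self):
        """1:1 conditional likelihood == intercept-free logit on differences."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(6)
        sets = [(rng.normal(size=(2, 3)), int(rng.integers(0, 2))) for _ in range(40)]
        d = _design(sets)
        res = fit(d)
        diffs = np.array([rows[ci] - rows[1 - ci] for rows, ci in sets])
        logit = sm.GLM(np.ones(len(diffs)), diffs, family=sm.families.Binomial()).fit()
        assert np.allclose(res.beta, logit.params, atol=1e-6)

    def test_matches_statsmodels_conditional_logit(self):
        """Independent implementation agreement on three random fixtures."""
        from statsmodels.discrete.conditional_models import ConditionalLogit

        for seed in (7, 8, 9):
            rng = np.random.default_rng(seed)
            n_sets, size, p = 30, 5, 3
            d = _random_design(rng, n_sets=n_sets, set_size=size, p=p)
            res = fit(d)
            groups = np.repeat(np.arange(n_sets), size)
            ref = ConditionalLogit(d.is_case.astype(float), d.X, groups=groups).fit(
                method="newton", tol=1e-10, disp=False
            )
            assert np.allclose(res.beta, ref.params, atol=1e-5)
            assert np.allclose(res.se, ref.bse, atol=1e-4)

    def test_matches_exhaustive_grid_search(self):
        """3-set, 2-regressor fixture vs hierarchical grid (final step 1e-3)."""
        rng = np.random.default_rng(10)
        d = _random_design(rng, n_sets=3, set_size=6, p=2)
        res = fit(d)

        def ll(b1, b2):
            return conditional_loglik(d, np.array([b1, b2]))[0]

        center = np.zeros(2)
        width = 4.0
        for step in (0.05, 0.005, 0.001):
            g1 = np.arange(center[0] - width, center[0] + width + step / 2, step)
            g2 = np.arange(center[1] - width, center[1] + width + step / 2, step)
            vals = np.array([[ll(a, b) for b in g2] for a in g1])
            i, j = np.unravel_index(np.argmax(vals), vals.shape)
            center = np.array([g1[i], g2[j]])
            width = 3 * step
        assert np.allclose(res.beta, center, atol=2e-3)

    def test_separation_flagged(self):
        # a regressor that perfectly identifies every case
        sets = []
        rng = np.random.default_rng(11)
        for _ in range(6):
            rows = rng.normal(size=(3, 2))
            rows[:, 0] = [1.0, 0.0, 0.0]
            sets.append((rows, 0))
        res = fit(_design(sets))
        assert res.flag == "suspect_separation"


class TestBuildDesign:
    def test_design_shapes_and_coding(self, study_data):
        d1 = build_design(study_data.matched, study_data.exposures, study_data.covariates, "analysis_one")
        d2 = build_design(study_data.matched, study_data.exposures, study_data.covariates, "analysis_two")
        assert d1.X.shape[1] == 25
        assert d2.X.shape[1] == 23
        assert d1.names[:4] == [
            "flupentixol_366_1825",
            "flupentixol_1826+",
            "other_antipsychotics_366_1825",
            "other_antipsychotics_1826+",
        ]
        assert d2.names[:2] == ["any_antipsychotics_366_1825", "any_antipsychotics_1826+"]
        assert d1.names[4:] == list(COVARIATE_NAMES)
        # indicator coding: exposure columns are 0/1 and never both 1
        assert set(np.unique(d2.X[:, :2])) <= {0.0, 1.0}
        assert (d2.X[:, 0] + d2.X[:, 1] <= 1).all()

    def test_reference_category_member_codes_all_zero(self, study_data):
        d2 = build_design(study_data.matched, study_data.exposures, study_data.covariates, "analysis_two")
        ref = study_data.exposures["cat_any"] == "1-365"
        assert ref.any()

    def test_unknown_model_spec_rejected(self, study_data):
        with pytest.raises(ValueError, match="model_spec"):
            build_design(study_data.matched, study_data.exposures, study_data.covariates, "analysis_three")

    def test_missing_exposure_row_is_hard_error(self, study_data):
        broken = study_data.exposures.iloc[1:]
        with pytest.raises(ValueError):
            build_design(study_data.matched, broken, study_data.covariates, "analysis_two")


class TestWaldSummary:
    def test_closed_form_at_beta_zero_se_one(self):
        res = ncc.FitResult(
            beta=np.array([0.0]),
            se=np.array([1.0]),
            or_point=np.array([1.0]),
            ci95=np.array([[np.exp(-Z975), np.exp(Z975)]]),
            loglik=-1.0,
            n_sets=3,
            n_informative=3,
            converged=True,
            flag="converged",
            iterations=2,
            names=["x0"],
        )
        tab = wald_summary(res)
        assert tab.loc[0, "OR"] == pytest.approx(1.0)
        assert tab.loc[0, "ci_low"] == pytest.approx(0.1408, abs=2e-4)
        assert tab.loc[0, "ci_high"] == pytest.approx(7.0993, abs=2e-3)
        assert tab.loc[0, "p"] == pytest.approx(1.0)

    def test_p_at_critical_z_is_point_o_five(self):
        res = ncc.FitResult(
            beta=np.array([Z975]),
            se=np.array([1.0]),
            or_point=np.exp([Z975]),
            ci95=np.array([[1.0, np.exp(2 * Z975)]]),
            loglik=-1.0,
            n_sets=3,
            n_informative=3,
            converged=True,
            flag="converged",
            iterations=2,
            names=["x0"],
        )
        tab = wald_summary(res)
        assert tab.loc[0, "p"] == pytest.approx(0.05, abs=1e-6)
        assert bool(tab.loc[0, "significant"])

    def test_or_prints_configured_effect(self):
        beta = np.log(0.65)
        res = ncc.FitResult(
            beta=np.array([beta]),
            se=np.array([0.01]),
            or_point=np.exp([beta]),
            ci95=np.exp([[beta - Z975 * 0.01, beta + Z975 * 0.01]]),
            loglik=-1.0,
            n_sets=3,
            n_informative=3,
            converged=True,
            flag="converged",
            iterations=2,
            names=["x0"],
        )
        tab = wald_summary(res)
        assert f"{tab.loc[0, 'OR']:.2f}" == "0.65"
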
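import numpy as np
import pandas as pd
import pytest

import hepiron
from hepiron.cohort import Cohort, VariablePanel
from hepiron.lasso import (DesignMatrix, LassoConfig, StabilityResults,
                           StabilitySelection, build_design, cv_select_lambda,
                           fit_lasso, kkt_violation, lambda_grid, lambda_max,
                           log_with_zero_shift)


def soft(x, t):
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def orthonormal_design(n, p, seed, signal=None):
    """Columns with exact zero mean and X'X/n = I after standardization."""
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n, p))
    A -= A.mean(axis=0)
    Q, _ = np.linalg.qr(A)
    X = Q * np.sqrt(n)
    beta = signal if signal is not None else rng.normal(0, 1, p)
    y = X @ beta + 0.3 * rng.standard_normal(n)
    return DesignMatrix(X, y, [f"x{j}" for j in range(p)])


def brute_force_p2(X, y, lam, rounds=6):
    """Independent oracle: coarse-to-fine 2-d grid minimization of
    (1/2n)||y - b0 - X b||^2 + lam ||b||_1 (b0 profiled out)."""
    n = len(y)
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)

    def obj(b):
        r = yc - Xc @ b
        return 0.5 * r @ r / n + lam * np.abs(b).sum()

    center, width = np.zeros(2), 5.0
    for _ in range(rounds):
        g = np.linspace(-width, width, 41)
        best, best_val = None, np.inf
        for b1 in center[0] + g:
            for b2 in center[1] + g:
                v = obj(np.array([b1, b2]))
                if v < best_val:
                    best_val, best = v, np.array([b1, b2])
        center, width = best, width / 8
    return center


class TestBuildDesign:
    def test_categorical_expands_to_dummies_vs_reference(self, study_cohort):
        panel = VariablePanel(("diabetes_status", "age"))
        d = build_design(study_cohort, panel)
        assert "diabetes_status[prediabetes]" in d.column_names
        assert "diabetes_status[diabetes]" in d.column_names
        assert "diabetes_status[normoglycemic]" not in d.column_names

    def test_log_flag_reduces_skew(self, study_cohort):
        from scipy.stats import skew
        panel = VariablePanel(("triglycerides",))
        d = build_design(study_cohort, panel)
        assert d.column_names == ["log(triglycerides)"]
        raw = study_cohort.data["triglycerides"].to_numpy(float)
        assert abs(skew(np.log(raw))) < abs(skew(raw))

    def test_columns_standardized(self, study_cohort, default_panel):
        d = build_design(study_cohort, default_panel)
        np.testing.assert_allclose(d.X.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(d.X.std(axis=0), 1, atol=1e-9)

    def test_standardizing_standardized_input_is_identity(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((100, 3))
        X = (X - X.mean(0)) / X.std(0)
        d = DesignMatrix(X, rng.standard_normal(100), ["a", "b", "c"])
        np.testing.assert_allclose(d.X, X, atol=1e-9)

    def test_zero_variance_column_named_in_error(self):
        df = pd.DataFrame({"id": ["a", "b", "c"], "sex": ["male"] * 3,
                           "hic": [40.0, 41.0, 42.0],
                           "flat": [1.0, 1.0, 1.0], "ok": [1.0, 2.0, 3.0]})
        c = Cohort(df, {"flat": hepiron.VariableDef("flat"),
                        "ok": hepiron.VariableDef("ok")})
        with pytest.raises(ValueError, match="flat"):
            build_design(c, VariablePanel(("flat", "ok")))

    def test_missing_entries_rejected(self, tiny_cohort):
        tiny_cohort.data.loc[0, "age"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            build_design(tiny_cohort, VariablePanel(("age",)))

    def test_zero_shift_log(self):
        v = log_with_zero_shift(np.array([0.0, 2.0, 4.0]))
        assert v[0] == pytest.approx(np.log(1.0))  # half the min positive


class TestLambdaMax:
    def test_constant_outcome_gives_zero(self):
        rng = np.random.default_rng(0)
        d = DesignMatrix(rng.standard_normal((50, 3)), np.full(50, 7.0),
                         ["a", "b", "c"])
        assert lambda_max(d) == pytest.approx(0.0, abs=1e-12)

    def test_single_column_y_equals_x(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(500)
        x = (x - x.mean()) / x.std()
        d = DesignMatrix(x[:, None], x.copy(), ["x"])
        assert lambda_max(d) == pytest.approx(1.0, rel=1e-9)

    def test_all_zero_above_lambda_max(self):
        d = orthonormal_design(120, 6, seed=2)
        fit = fit_lasso(d, 1.01 * lambda_max(d))
        assert np.all(fit.beta == 0.0)


class TestFitLasso:
    def test_unpenalized_limit_equals_ols(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((80, 5))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0, 3.0]) + rng.standard_normal(80)
        d = DesignMatrix(X, y, list("abcde"))
        fit = fit_lasso(d, 0.0)
        Xc = d.X - d.X.mean(0)
        ols = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
        np.testing.assert_allclose(fit.beta, ols, atol=1e-6)

    @pytest.mark.parametrize("lam", [0.05, 0.3, 0.8])
    def test_orthonormal_soft_threshold_closed_form(self, lam):
        d = orthonormal_design(150, 5, seed=4)
        fit = fit_lasso(d, lam)
        yc = d.y - d.y.mean()
        ols = d.X.T @ yc / d.n  # orthonormal: OLS = correlations
        np.testing.assert_allclose(fit.beta, soft(ols, lam), atol=1e-8)

    @pytest.mark.parametrize("lam", [0.02, 0.2, 0.6])
    def test_brute_force_objective_minimization_p2(self, lam):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((60, 2)) @ np.array([[1.0, 0.6], [0.0, 0.8]])
        y = X @ np.array([1.2, -0.7]) + 0.5 * rng.standard_normal(60)
        d = DesignMatrix(X, y, ["a", "b"])
        fit = fit_lasso(d, lam)
        oracle = brute_force_p2(d.X, y, lam)
        np.testing.assert_allclose(fit.beta, oracle, atol=1e-4)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_kkt_conditions_hold(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 90, 12
        X = rng.standard_normal((n, p)) @ rng.standard_normal((p, p))
        y = X[:, 0] - 0.5 * X[:, 3] + rng.standard_normal(n)
        d = DesignMatrix(X, y, [f"x{j}" for j in range(p)])
        for lam in [0.01, 0.1, 0.5]:
            assert kkt_violation(d, fit_lasso(d, lam)) < 1e-6

    def test_matches_sklearn_reference(self):
        from sklearn.linear_model import Lasso
        rng = np.random.default_rng(6)
        X = rng.standard_normal((120, 15))
        y = X[:, :3] @ np.array([2.0, -1.0, 0.5]) + rng.standard_normal(120)
        d = DesignMatrix(X, y, [f"x{j}" for j in range(15)])
        for lam in [0.05, 0.2]:
            ours = fit_lasso(d, lam).beta
            ref = Lasso(alpha=lam, tol=1e-12, max_iter=200000).fit(d.X, y).coef_
            np.testing.assert_allclose(ours, ref, atol=1e-7)

    def test_active_set_monotone_on_orthonormal_path(self):
        from hepiron import _solver
        d = orthonormal_design(200, 8, seed=7,
                               signal=np.array([2, 1.2, 0.7, 0.4, 0.2, 0, 0, 0.0]))
        grid = lambda_grid(d, LassoConfig())
        G = d.X.T @ d.X / d.n - np.outer(d.X.mean(0), d.X.mean(0))
        c = d.X.T @ d.y / d.n - d.X.mean(0) * d.y.mean()
        betas, _ = _solver.cd_path(G, c, grid, d.penalty_weights, 1e-8, 100000)
        sizes = (np.abs(betas) > 1e-12).sum(axis=1)
        assert np.all(np.diff(sizes) >= 0)  # grows as the penalty decreases

    def test_negative_penalty_rejected(self):
        d = orthonormal_design(50, 3, seed=8)
        with pytest.raises(ValueError):
            fit_lasso(d, -0.1)


class TestCrossValidation:
    def test_deterministic_under_fixed_seed(self):
        d = orthonormal_design(100, 6, seed=9)
        cfg = LassoConfig()
        lam1, _, _ = cv_select_lambda(d, cfg, np.random.default_rng(42))
        lam2, _, _ = cv_select_lambda(d, cfg, np.random.default_rng(42))
        assert lam1 == lam2

    def test_pure_noise_prefers_heavy_shrinkage(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((200, 10))
        y = rng.standard_normal(200)  # no signal at all
        d = DesignMatrix(X, y, [f"x{j}" for j in range(10)])
        # CV-min lands in the heavy-penalty (top) part of the 3-decade grid
        lam, grid, _ = cv_select_lambda(d, LassoConfig(), np.random.default_rng(0))
        assert lam >= grid[len(grid) // 3]
        # the conservative one-standard-error rule is near intercept-only
        lam1, _, _ = cv_select_lambda(d, LassoConfig(lambda_rule="1se"),
                                      np.random.default_rng(0))
        fit = fit_lasso(d, lam1)
        assert (np.abs(fit.beta) > 1e-12).sum() <= 1

    def test_dominant_predictor_survives(self):
        rng = np.random.default_rng(11)
        n = 300
        X = rng.standard_normal((n, 8))
        y = 3.0 * X[:, 2] + rng.standard_normal(n)  # R^2 = 0.9
        d = DesignMatrix(X, y, [f"x{j}" for j in range(8)])
        lam, _, _ = cv_select_lambda(d, LassoConfig(), np.random.default_rng(1))
        fit = fit_lasso(d, lam)
        assert abs(fit.beta[2]) > 1e-12

    def test_too_few_observations_per_fold_rejected(self):
        d = orthonormal_design(12, 3, seed=12)
        with pytest.raises(ValueError):
            cv_select_lambda(d, LassoConfig(n_folds=10), np.random.default_rng(0))


class TestStabilitySelection:
    def test_zero_outcome_gives_all_zero_frequencies(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((40, 4))
        d = DesignMatrix(X, np.zeros(40), list("abcd"))
        res = StabilitySelection(d, LassoConfig(n_bootstrap=20, seed=0)).fit()
        assert (res.inclusion_frequency == 0).all()

    def test_single_strong_predictor_always_selected(self):
        rng = np.random.default_rng(14)
        n = 300
        x = rng.standard_normal(n)
        y = 3.0 * x + rng.standard_normal(n)
        d = DesignMatrix(x[:, None], y, ["x"])
        res = StabilitySelection(d, LassoConfig(n_bootstrap=100, seed=1)).fit()
        assert res.inclusion_frequency["x"] == 1.0

    def test_bitwise_reproducible_under_fixed_seed(self):
        rng = np.random.default_rng(15)
        X = rng.standard_normal((60, 6))
        y = X[:, 0] + rng.standard_normal(60)
        d = DesignMatrix(X, y, [f"x{j}" for j in range(6)])
        cfg = LassoConfig(n_bootstrap=25, seed=5)
        a = StabilitySelection(d, cfg).fit()
        b = StabilitySelection(d, cfg).fit()
        pd.testing.assert_series_equal(a.inclusion_frequency,
                                       b.inclusion_frequency, check_exact=True)
        np.testing.assert_array_equal(a.selected_lambdas, b.selected_lambdas)

    def test_results_independent_of_job_count(self):
        rng = np.random.default_rng(16)
        X = rng.standard_normal((50, 5))
        y = X[:, 1] + rng.standard_normal(50)
        d = DesignMatrix(X, y, [f"x{j}" for j in range(5)])
        cfg = LassoConfig(n_bootstrap=12, seed=3)
        serial = StabilitySelection(d, cfg).fit(n_jobs=1)
        parallel = StabilitySelection(d, cfg).fit(n_jobs=2)
        pd.testing.assert_series_equal(serial.inclusion_frequency,
                                       parallel.inclusion_frequency,
                                       check_exact=True)

    def test_zero_variance_resample_column_dropped_and_logged(self):
        rng = np.random.default_rng(17)
        n = 25
        rare = np.zeros(n)
        rare[0] = 1.0  # survives only when row 0 is resampled
        X = np.column_stack([rng.standard_normal(n), rare])
        y = X[:, 0] + rng.standard_normal(n)
        d = DesignMatrix(X, y, ["x", "rare"])
        res = StabilitySelection(d, LassoConfig(n_bootstrap=40, n_folds=5,
                                                seed=2)).fit()
        assert any(name == "rare" for _, name in res.dropped)
        assert res.inclusion_frequency.between(0, 1).all()

    def test_relevance_threshold_is_strict(self):
        pi = pd.Series({"a": 0.21, "b": 0.20, "c": 0.05},
                       name="inclusion_frequency")
        res = StabilityResults(pi, np.array([0.1]), LassoConfig(), [])
        assert res.select_relevant() == ["a"]

    def test_empty_selection_when_all_zero(self):
        pi = pd.Series({"a": 0.0, "b": 0.0}, name="inclusion_frequency")
        res = StabilityResults(pi, np.array([0.1]), LassoConfig(), [])
        assert res.select_relevant() == []

    def test_selection_ordered_by_descending_frequency(self):
        pi = pd.Series({"a": 0.3, "b": 0.9, "c": 0.5},
                       name="inclusion_frequency")
        res = StabilityResults(pi, np.array([0.1]), LassoConfig(), [])
        assert res.select_relevant() == ["b", "c", "a"]
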
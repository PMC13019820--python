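import numpy as np
import pytest

from psychocortex.prediction import (
    RidgePrediction,
    evaluate_oos,
    permute_null_mse,
    residualize_covariates,
    ridge_cv,
    ridge_solve,
    split_train_test,
)
from psychocortex.robust import SingularDesignError


class TestSplit:
    @pytest.mark.parametrize(
        "n, expected", [(804, (644, 160)), (778, (623, 155))]
    )
    def test_published_cohort_split_sizes(self, n, expected):
        tr, te = split_train_test(n, 0.199, seed=0)
        assert (len(tr), len(te)) == expected

    def test_disjoint_and_exhaustive(self):
        tr, te = split_train_test(101, 0.3, seed=5)
        assert len(np.intersect1d(tr, te)) == 0
        assert sorted(np.concatenate([tr, te]).tolist()) == list(range(101))

    def test_deterministic_under_seed(self):
        a = split_train_test(200, 0.2, seed=9)
        b = split_train_test(200, 0.2, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_small_or_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(10, 0.2, seed=0)
        with pytest.raises(ValueError):
            split_train_test(100, 0.6, seed=0)


class TestResidualize:
    def test_orthogonal_covariates_only_center(self):
        rng = np.random.default_rng(0)
        n = 500
        X = rng.standard_normal((n, 4))
        cov = rng.standard_normal((n, 2))
        # make X exactly orthogonal to intercept + covariates
        C = np.column_stack([np.ones(n), cov])
        X = X - C @ np.linalg.lstsq(C, X, rcond=None)[0]
        Xr, _ = residualize_covariates(X, X[:100], cov, cov[:100])
        assert np.allclose(Xr, X - X.mean(0), atol=1e-10)

    def test_perfectly_explained_features_become_zero(self):
        rng = np.random.default_rng(1)
        cov = rng.standard_normal((50, 3))
        X = cov @ rng.standard_normal((3, 6)) + 2.0
        Xr, Xe = residualize_covariates(X, X, cov, cov)
        assert np.abs(Xr).max() < 1e-8

    def test_residuals_orthogonal_to_covariates(self):
        rng = np.random.default_rng(2)
        Xtr = rng.standard_normal((80, 10))
        Xte = rng.standard_normal((40, 10))
        ctr = rng.standard_normal((80, 3))
        cte = rng.standard_normal((40, 3))
        Rtr, Rte = residualize_covariates(Xtr, Xte, ctr, cte)
        assert np.abs(ctr.T @ Rtr).max() < 1e-8
        assert np.abs(cte.T @ Rte).max() < 1e-8

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(3)
        c = rng.standard_normal((50, 1))
        cov = np.column_stack([c, 2 * c])
        X = rng.standard_normal((50, 4))
        with pytest.raises(SingularDesignError):
            residualize_covariates(X, X, cov, cov)


class TestRidgeCV:
    def test_vanishing_penalty_recovers_ols(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((200, 5))
        y = X @ np.array([1.0, -2, 0.5, 0, 3]) + 0.1 * rng.standard_normal(200)
        grid = np.concatenate([[1e-10], np.logspace(-3, 5, 9)])
        res = ridge_cv(X, y, grid, k_folds=5, seed=0)
        ols = np.linalg.lstsq(X, y - y.mean(), rcond=None)[0]
        assert np.allclose(ridge_solve(X, y - y.mean(), 1e-10), ols, atol=1e-6)
        assert res.lambda_selected in grid

    def test_huge_penalty_shrinks_to_zero(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((100, 8))
        y = rng.standard_normal(100)
        coef = ridge_solve(X, y, 1e12)
        assert np.linalg.norm(coef) < 1e-6

    def test_engine_matches_closed_form(self):
        from psychocortex.prediction import _RidgeEngine

        rng = np.random.default_rng(6)
        X = rng.standard_normal((40, 12))
        y = rng.standard_normal(40)
        grid = np.logspace(-3, 2, 6)
        eng = _RidgeEngine(X, grid, 5, 0)
        for lam in grid:
            c_eng, _ = eng.fit_full(y, lam)
            c_direct = ridge_solve(X, y - y.mean(), lam)
            assert np.allclose(c_eng, c_direct, atol=1e-8)

    def test_selected_lambda_minimizes_cv_mse(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((120, 30))
        y = X[:, 0] + rng.standard_normal(120)
        res = ridge_cv(X, y, seed=3)
        i = np.where(res.lambda_grid == res.lambda_selected)[0][0]
        assert res.cv_mse[i] == res.cv_mse.min()

    def test_degenerate_grid_rejected(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((50, 5))
        y = rng.standard_normal(50)
        with pytest.raises(ValueError):
            ridge_cv(X, y, [0.1, 1.0, 10.0], seed=0)


class TestEvaluateOOS:
    def test_perfect_predictions(self):
        out = evaluate_oos(np.array([1.0]), np.array([[1], [2], [3.0]]),
                           np.array([1, 2, 3.0]), score_max=16.0)
        assert out["r2_oos"] == pytest.approx(1.0)
        assert out["nmse"] == 0.0

    def test_mean_only_prediction_scores_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        out = evaluate_oos(np.zeros(1), np.zeros((3, 1)), y, 16.0,
                           intercept=y.mean())
        assert out["r2_oos"] == pytest.approx(0.0)

    def test_normalized_mse_arithmetic(self):
        y = np.array([1.0, 2.0, 3.0])
        pred_X = np.array([[1.0], [1.0], [3.0]])
        out = evaluate_oos(np.array([1.0]), pred_X, y, score_max=16.0)
        assert out["nmse"] == pytest.approx((1 / 3) / 16)

    def test_zero_test_variance_rejected(self):
        with pytest.raises(ZeroDivisionError):
            evaluate_oos(np.zeros(1), np.zeros((3, 1)), np.ones(3), 16.0)


class TestPermutationNull:
    def test_minimal_p_when_observed_beats_every_null(self):
        rng = np.random.default_rng(9)
        n, p = 300, 20
        X = rng.standard_normal((n, p))
        beta = rng.standard_normal(p)
        y = X @ beta  # noiseless signal
        p_perm, null, obs = permute_null_mse(
            X[:240], y[:240], X[240:], y[240:], n_perm=100, seed=0
        )
        assert p_perm == pytest.approx(1 / 101)
        assert (null > obs).all()

    def test_pvalue_formula(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((120, 10))
        y = rng.standard_normal(120)
        p_perm, null, obs = permute_null_mse(
            X[:100], y[:100], X[100:], y[100:], n_perm=100, seed=1
        )
        assert p_perm == (1 + np.sum(null <= obs)) / 101


class TestRidgePrediction:
    def test_no_leakage_from_test_rows(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((200, 30))
        y = X[:, 0] + rng.standard_normal(200)
        cov = rng.standard_normal((200, 3))
        from psychocortex._utils import child_seed

        model = RidgePrediction(X, y, cov, 16.0, seed=4)
        res1 = model.fit()
        # corrupt what the model believes are test rows; training untouched
        _, te = split_train_test(200, 0.2, seed=child_seed(4, "split"))
        model.features[te] = 1e6 * rng.standard_normal((len(te), 30))
        res2 = model.fit()
        assert np.allclose(res1.coefficients, res2.coefficients)
        assert res1.lambda_selected == res2.lambda_selected

    def test_summary_contains_all_fields(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((100, 10))
        y = rng.standard_normal(100)
        cov = rng.standard_normal((100, 2))
        res = RidgePrediction(X, y, cov, 28.0, seed=0).fit(n_perm=100)
        s = res.summary()
        for key in ("lambda", "r2_oos", "nmse", "p_perm", "n_train", "n_test"):
            assert key in s.index
        assert 0 < res.p_perm <= 1
        assert res.n_train + res.n_test == 100
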
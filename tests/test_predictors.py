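"""Held-out prediction rules for each algorithm family."""

import numpy as np
import pytest

from cooccur import predictors as P
from cooccur.preprocess import standard_scale


def standardized(rng, n, d):
    tm, _ = standard_scale(rng.normal(size=(n, d)))
    return tm.values


def random_spd_precision(rng, d):
    a = rng.normal(size=(d, d))
    theta = a @ a.T + d * np.eye(d)
    return (theta + theta.T) / 2.0


class TestFitCorrelation:
    def test_identical_columns_correlate_perfectly(self, rng):
        col = rng.normal(size=30)
        model = P.fit_correlation(np.column_stack([col, col, rng.normal(size=30)]))
        assert model.corr[0, 1] == pytest.approx(1.0)

    def test_monotone_cubic_spearman_one_pearson_below(self, rng):
        x = np.sort(rng.uniform(-2, 2, size=50))
        data = np.column_stack([x, x**3])
        sp = P.fit_correlation(data, "spearman")
        pe = P.fit_correlation(data, "pearson")
        assert sp.corr[0, 1] == pytest.approx(1.0)
        assert pe.corr[0, 1] < 1.0

    def test_matches_brute_force_covariance_formula(self, rng):
        x = rng.normal(size=(6, 3))
        model = P.fit_correlation(x)
        xc = x - x.mean(axis=0)
        cov = xc.T @ xc / 6
        sd = np.sqrt(np.diag(cov))
        expected = cov / np.outer(sd, sd)
        np.testing.assert_allclose(model.corr, expected, atol=1e-12)

    def test_zero_variance_column_gets_zero_correlations(self, rng):
        x = np.column_stack([rng.normal(size=20), np.full(20, 3.0)])
        model = P.fit_correlation(x)
        assert model.corr[0, 1] == 0.0
        assert model.corr[1, 1] == 1.0


class TestPredictCorrelation:
    def test_perfect_pair_predicts_exactly(self, rng):
        col = standardized(rng, 40, 1)[:, 0]
        data = np.column_stack([col, col])
        model = P.fit_correlation(data)
        pred = P.predict_correlation(model, data, target=0, threshold=0.0)
        np.testing.assert_allclose(pred, col, atol=1e-12)

    def test_threshold_above_all_correlations_falls_back_to_mean(self, rng):
        data = standardized(rng, 40, 4)
        model = P.fit_correlation(data)
        pred = P.predict_correlation(model, data, target=0, threshold=0.999999)
        np.testing.assert_allclose(pred, np.full(40, model.col_means[0]), atol=1e-12)

    def test_exact_linear_relation_recovered(self, rng):
        x = rng.normal(size=200)
        x = (x - x.mean()) / x.std()
        y = 0.5 * x
        train = np.column_stack([y[:150], x[:150]])
        test = np.column_stack([y[150:], x[150:]])
        model = P.fit_correlation(train)
        pred = P.predict_correlation(model, test, target=0, threshold=0.0)
        assert np.mean((pred - test[:, 0]) ** 2) < 1e-20

    def test_spearman_invariant_to_monotone_predictor_transform(self, rng):
        data = standardized(rng, 60, 3)
        warped = data.copy()
        warped[:, 1] = np.exp(warped[:, 1])  # strictly monotone map
        m1 = P.fit_correlation(data, "spearman")
        m2 = P.fit_correlation(warped, "spearman")
        p1 = P.predict_correlation(m1, data, target=0, threshold=0.0)
        p2 = P.predict_correlation(m2, warped, target=0, threshold=0.0)
        np.testing.assert_allclose(p1, p2, atol=1e-10)

    def test_invalid_threshold_rejected(self, rng):
        data = standardized(rng, 20, 3)
        model = P.fit_correlation(data)
        with pytest.raises(ValueError, match="threshold"):
            P.predict_correlation(model, data, target=0, threshold=1.5)


class TestLasso:
    def test_lambda_max_gives_null_model(self, rng):
        x = standardized(rng, 50, 5)
        rest = np.delete(np.arange(5), 2)
        lam_max = P.lasso_lambda_max(x[:, rest], x[:, 2])
        model = P.fit_lasso(x, target=2, lam=lam_max * 1.0001)
        np.testing.assert_array_equal(model.coefficients, np.zeros(4))
        assert model.intercept == pytest.approx(x[:, 2].mean())

    def test_tiny_lambda_matches_ols(self, rng):
        x = rng.normal(size=(50, 4))
        model = P.fit_lasso(x, target=0, lam=1e-8)
        rest = [1, 2, 3]
        a = np.column_stack([np.ones(50), x[:, rest]])
        beta = np.linalg.lstsq(a, x[:, 0], rcond=None)[0]
        assert model.intercept == pytest.approx(beta[0], abs=1e-4)
        np.testing.assert_allclose(model.coefficients, beta[1:], atol=1e-4)

    def test_sparse_support_recovered(self, rng):
        n = 200
        x = rng.normal(size=(n, 10))
        y = 2.0 * x[:, 0] + 0.1 * rng.normal(size=n)
        data = np.column_stack([y, x])
        # moderate penalty keeps the true predictor and drops the noise ones
        rest = np.delete(np.arange(11), 0)
        lam = 0.1 * P.lasso_lambda_max(data[:, rest], y)
        model = P.fit_lasso(data, target=0, lam=lam)
        assert model.coefficients[0] != 0.0
        assert np.all(np.abs(model.coefficients[1:]) < 0.05)

    def test_predict_constant_when_coefficients_zero(self):
        model = P.LassoModel(target_index=0, intercept=1.5,
                             coefficients=np.zeros(3), lam=1.0)
        pred = P.predict_lasso(model, np.ones((5, 4)))
        np.testing.assert_array_equal(pred, np.full(5, 1.5))

    def test_predict_single_active_coefficient(self):
        model = P.LassoModel(target_index=0, intercept=0.0,
                             coefficients=np.array([1.0, 0.0]), lam=1.0)
        test = np.array([[99.0, 3.0, 7.0]])  # target column ignored
        assert P.predict_lasso(model, test)[0] == pytest.approx(3.0)

    def test_in_sample_predictions_match_fit(self, rng):
        x = standardized(rng, 60, 5)
        model = P.fit_lasso(x, target=1, lam=0.05)
        rest = np.delete(np.arange(5), 1)
        manual = model.intercept + x[:, rest] @ model.coefficients
        np.testing.assert_allclose(P.predict_lasso(model, x), manual, atol=1e-12)

    def test_nonzero_count_monotone_in_lambda(self, rng):
        x = standardized(rng, 80, 6)
        rest = np.delete(np.arange(6), 0)
        lam_max = P.lasso_lambda_max(x[:, rest], x[:, 0])
        counts = []
        for ratio in np.logspace(0, -3, 12):
            m = P.fit_lasso(x, target=0, lam=ratio * lam_max)
            counts.append(int(np.sum(np.abs(m.coefficients) > 1e-10)))
        assert all(a <= b for a, b in zip(counts, counts[1:]))


class TestGlasso:
    def test_full_penalty_gives_diagonal_precision(self, rng):
        x = standardized(rng, 60, 5)
        s = x.T @ x / 60
        model = P.fit_glasso(x, lam=P.glasso_lambda_max(s))
        off = model.precision - np.diag(np.diag(model.precision))
        np.testing.assert_allclose(off, np.zeros((5, 5)), atol=1e-8)

    def test_zero_penalty_inverts_sample_covariance(self, rng):
        x = standardized(rng, 2000, 5)
        model = P.fit_glasso(x, lam=0.0)
        np.testing.assert_allclose(model.precision, np.linalg.inv(model.sample_cov),
                                   atol=1e-10)
        # and the estimate is close to the truth's identity precision
        np.testing.assert_allclose(model.precision, np.eye(5), atol=0.2)

    def test_precision_always_positive_definite(self, rng):
        for lam in (0.0, 0.05, 0.5):
            x = standardized(rng, 50, 6)
            model = P.fit_glasso(x, lam=lam)
            assert np.linalg.eigvalsh(model.precision)[0] > 0


class TestPredictGgm:
    def test_bivariate_reduces_to_pearson_rule(self):
        rho = 0.6
        theta = np.array([[1.0, -rho], [-rho, 1.0]]) / (1.0 - rho**2)
        model = P.GgmModel(precision=theta, lam=0.0, sample_cov=np.linalg.inv(theta))
        x = np.array([[0.0, 1.0], [0.0, -2.0], [0.0, 0.3]])
        np.testing.assert_allclose(P.predict_ggm(model, x, target=0),
                                   rho * x[:, 1], atol=1e-12)

    def test_diagonal_precision_predicts_zero(self, rng):
        model = P.GgmModel(precision=np.diag([2.0, 3.0, 1.0]), lam=0.0,
                           sample_cov=np.diag([0.5, 1 / 3.0, 1.0]))
        pred = P.predict_ggm(model, rng.normal(size=(7, 3)), target=1)
        np.testing.assert_array_equal(pred, np.zeros(7))

    def test_agrees_with_partitioned_gaussian_oracle(self, rng):
        for _ in range(20):
            d = int(rng.integers(3, 7))
            theta = random_spd_precision(rng, d)
            cov = np.linalg.inv(theta)
            model = P.GgmModel(precision=theta, lam=0.0, sample_cov=cov)
            x = rng.normal(size=(5, d))
            t = int(rng.integers(0, d))
            rest = np.delete(np.arange(d), t)
            oracle = x[:, rest] @ np.linalg.solve(cov[np.ix_(rest, rest)], cov[rest, t])
            np.testing.assert_allclose(P.predict_ggm(model, x, t), oracle, atol=1e-8)


class TestFeatureless:
    def test_constant_prediction_is_train_mean(self):
        model = P.fit_featureless(np.array([[2.0, 1.0], [4.0, 1.0], [6.0, 1.0]]))
        np.testing.assert_array_equal(P.predict_featureless(model, 0, 4), np.full(4, 4.0))

    def test_mse_approximates_heldout_variance(self, rng):
        train = standardized(rng, 500, 3)
        test = standardized(rng, 500, 3)
        model = P.fit_featureless(train)
        pred = P.predict_featureless(model, 0, 500)
        mse = np.mean((test[:, 0] - pred) ** 2)
        assert mse == pytest.approx(np.var(test[:, 0]), rel=0.05)


class TestSerialization:
    @pytest.mark.parametrize("method", ["pearson", "spearman"])
    def test_correlation_round_trip(self, rng, method):
        data = standardized(rng, 30, 4)
        model = P.fit_correlation(data, method)
        clone = P.model_from_json(P.model_to_json(model))
        p1 = P.predict_correlation(model, data, 0, 0.2)
        p2 = P.predict_correlation(clone, data, 0, 0.2)
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_ggm_round_trip(self, rng):
        data = standardized(rng, 40, 4)
        model = P.fit_glasso(data, lam=0.1)
        clone = P.model_from_json(P.model_to_json(model))
        np.testing.assert_allclose(clone.precision, model.precision, atol=1e-12)
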
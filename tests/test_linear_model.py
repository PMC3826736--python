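"""Elastic-net logistic solver: oracle equivalence, KKT optimality, path behavior."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.special import expit

from adps.linear_model import (
    ConvergenceError,
    ElasticNetModel,
    FeatureMatrix,
    RegularizationPair,
    classify,
    elastic_net_wls,
    enet_logistic_path,
    fit_elastic_net_logistic,
    kkt_residual,
    lambda_max,
    predict_probability,
)


def _oracle_mle(X, y):
    """Independent numerical maximizer of the unpenalized logistic likelihood."""

    def nll(params):
        eta = params[0] + X @ params[1:]
        return np.mean(np.logaddexp(0.0, -(2 * y - 1) * eta))

    res = minimize(nll, np.zeros(X.shape[1] + 1), method="BFGS",
                   options=dict(gtol=1e-12, maxiter=5000))
    return res.x


class TestUnpenalizedEquivalence:
    def test_matches_numeric_mle(self, small_logistic_data):
        X, y = small_logistic_data
        model = fit_elastic_net_logistic(X, y, RegularizationPair(0.5, 0.0))
        oracle = _oracle_mle(X, y)
        assert abs(model.intercept - oracle[0]) < 1e-4
        assert np.max(np.abs(model.coefficients - oracle[1:])) < 1e-4

    def test_label_flip_symmetry(self, small_logistic_data):
        """P(1|x) under the fit equals 1 - P(1|x) under the label-flipped fit."""
        X, y = small_logistic_data
        m1 = fit_elastic_net_logistic(X, y, RegularizationPair(0.5, 0.0))
        m2 = fit_elastic_net_logistic(X, 1 - y, RegularizationPair(0.5, 0.0))
        p1 = predict_probability(m1, X)
        p2 = predict_probability(m2, X)
        np.testing.assert_allclose(p1, 1 - p2, atol=1e-6)


class TestPenaltyDominates:
    @pytest.mark.parametrize("alpha", [0.1, 0.5, 1.0])
    def test_all_zero_above_lambda_max(self, small_logistic_data, alpha):
        X, y = small_logistic_data
        lmax = lambda_max(X, y, alpha)
        model = fit_elastic_net_logistic(X, y, RegularizationPair(alpha, 1.01 * lmax))
        assert model.n_nonzero == 0
        logodds = np.log(y.mean() / (1 - y.mean()))
        assert abs(model.intercept - logodds) < 1e-7

    def test_lambda_max_is_sharp(self, small_logistic_data):
        """Slightly below the bound at least one coefficient activates."""
        X, y = small_logistic_data
        lmax = lambda_max(X, y, 1.0)
        below = fit_elastic_net_logistic(X, y, RegularizationPair(1.0, 0.95 * lmax))
        assert below.n_nonzero >= 1


class TestLambdaMax:
    def test_direct_kkt_bound_on_constructed_column(self):
        """A column equal to (y - mean y) attains the bound max|score|/(n*alpha)."""
        rng = np.random.default_rng(3)
        n = 30
        y = np.r_[np.zeros(15), np.ones(15)]
        X = rng.normal(scale=0.1, size=(n, 4))
        X[:, 2] = y - y.mean()
        expected = np.max(np.abs(X.T @ (y - y.mean()))) / n
        assert lambda_max(X, y, 1.0, standardize=False) == pytest.approx(expected, rel=1e-12)

    def test_scales_inversely_with_alpha(self, small_logistic_data):
        X, y = small_logistic_data
        assert lambda_max(X, y, 0.5) == pytest.approx(2 * lambda_max(X, y, 1.0))

    def test_alpha_zero_rejected(self, small_logistic_data):
        X, y = small_logistic_data
        with pytest.raises(ValueError):
            lambda_max(X, y, 0.0)


class TestOrthonormalDesign:
    @pytest.mark.parametrize("alpha,lam", [(1.0, 0.1), (1.0, 0.02), (0.5, 0.2), (0.3, 0.05)])
    def test_wls_soft_threshold_closed_form(self, alpha, lam):
        """On an orthonormal design the coordinate-descent core reproduces the
        closed-form soft-threshold/shrinkage solution exactly."""
        rng = np.random.default_rng(11)
        n, p = 40, 6
        A = rng.normal(size=(n, p))
        A -= A.mean(axis=0)
        Q, _ = np.linalg.qr(A)
        X = Q * np.sqrt(n)  # X^T X = n I, columns orthogonal to the intercept
        ytarget = rng.normal(size=n)
        b0, beta = elastic_net_wls(X, ytarget, np.ones(n), alpha, lam)
        z = X.T @ ytarget / n
        closed = np.sign(z) * np.maximum(np.abs(z) - lam * alpha, 0) / (1 + lam * (1 - alpha))
        np.testing.assert_allclose(beta, closed, atol=1e-10)
        assert b0 == pytest.approx(ytarget.mean(), abs=1e-10)


class TestKKTOptimality:
    @pytest.mark.parametrize("alpha,lam_frac", [(1.0, 0.5), (0.5, 0.2), (0.1, 0.05), (0.5, 0.0)])
    def test_kkt_residual_within_tol(self, small_logistic_data, alpha, lam_frac):
        X, y = small_logistic_data
        lam = lam_frac * lambda_max(X, y, max(alpha, 0.1))
        model = fit_elastic_net_logistic(X, y, RegularizationPair(alpha, lam))
        assert model.converged
        assert model.kkt_residual <= 1e-6
        assert kkt_residual(model, X, y) <= 1e-6

    def test_objective_not_above_all_zero_start(self, small_logistic_data):
        X, y = small_logistic_data
        for lam_frac in (0.0, 0.3, 2.0):
            lam = lam_frac * lambda_max(X, y, 0.5)
            model = fit_elastic_net_logistic(X, y, RegularizationPair(0.5, lam))
            zero_obj = np.log(2.0)  # loss at intercept 0, all-zero coefficients
            assert model.objective_value <= zero_obj + 1e-12


class TestPath:
    def test_warm_path_matches_cold_start(self, small_logistic_data):
        X, y = small_logistic_data
        lmax = lambda_max(X, y, 0.5)
        lams = np.geomspace(lmax, lmax * 1e-3, 8)
        b0s, coefs = enet_logistic_path(X, y, 0.5, lams, tol=1e-8)
        for k, lam in enumerate(lams):
            cold = fit_elastic_net_logistic(X, y, RegularizationPair(0.5, float(lam)), tol=1e-8)
            assert abs(cold.intercept - b0s[k]) < 1e-7
            assert np.max(np.abs(cold.coefficients - coefs[:, k])) < 1e-7

    def test_nnz_monotone_in_lambda(self):
        rng = np.random.default_rng(12)
        n, p = 50, 30
        X = rng.normal(size=(n, p))
        y = (X[:, :3].sum(axis=1) + rng.normal(scale=2.0, size=n) > 0).astype(float)
        lmax = lambda_max(X, y, 1.0)
        lams = np.geomspace(lmax * 1.05, lmax * 1e-2, 10)
        _, coefs = enet_logistic_path(X, y, 1.0, lams)
        nnz = np.count_nonzero(coefs, axis=0)
        assert nnz[0] == 0
        assert np.all(np.diff(nnz) >= 0)  # non-increasing in lam (lams decrease)

    def test_path_requires_decreasing_lams(self, small_logistic_data):
        X, y = small_logistic_data
        with pytest.raises(ValueError):
            enet_logistic_path(X, y, 0.5, [0.1, 0.2])


class TestPrediction:
    def test_null_model_gives_half(self):
        model = ElasticNetModel(0.0, np.zeros(3), RegularizationPair(0.5, 1.0),
                                True, np.log(2), 0.0, 0)
        p = predict_probability(model, np.random.default_rng(0).normal(size=(5, 3)))
        np.testing.assert_allclose(p, 0.5)

    def test_probabilities_strictly_inside_unit_interval(self):
        model = ElasticNetModel(1e4, np.array([1e4]), RegularizationPair(0.5, 0.0),
                                True, 0.0, 0.0, 0)
        p = predict_probability(model, np.array([[5.0], [-5.0]]))
        assert np.all((p > 0) & (p < 1))
        assert p[0] > p[1]

    def test_column_mismatch_rejected(self, small_logistic_data):
        X, y = small_logistic_data
        fm = FeatureMatrix(X, ("a", "b", "c"), "cognitive")
        model = fit_elastic_net_logistic(fm, y, RegularizationPair(0.5, 0.1))
        bad = FeatureMatrix(X, ("a", "b", "d"), "cognitive")
        with pytest.raises(ValueError):
            predict_probability(model, bad)

    def test_classify_tie_rule(self):
        np.testing.assert_array_equal(classify([0.2, 0.8]), [0, 1])
        assert classify([0.5])[0] == 0  # exact threshold goes to class 0
        np.testing.assert_array_equal(classify([0.0, 0.3, 1.0], threshold=0.0), [0, 1, 1])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30), st.floats(0, 1))
    def test_classify_matches_definition(self, probs, threshold):
        labels = classify(probs, threshold)
        np.testing.assert_array_equal(labels, (np.asarray(probs) > threshold).astype(int))


class TestValidationAndSerialization:
    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 2))
        with pytest.raises(ValueError):
            fit_elastic_net_logistic(X, np.ones(6), RegularizationPair(0.5, 0.1))

    def test_feature_matrix_invariants(self):
        with pytest.raises(ValueError):
            FeatureMatrix(np.full((3, 2), np.nan), ("a", "b"))
        with pytest.raises(ValueError):
            FeatureMatrix(np.zeros((3, 2)), ("a", "a"))
        with pytest.raises(ValueError):
            FeatureMatrix(np.zeros((2, 0)), ())

    def test_model_roundtrip(self, small_logistic_data):
        X, y = small_logistic_data
        fm = FeatureMatrix(X, ("v1", "v2", "v3"), "cognitive")
        model = fit_elastic_net_logistic(fm, y, RegularizationPair(0.5, 0.05))
        clone = ElasticNetModel.from_dict(model.to_dict())
        np.testing.assert_allclose(clone.coefficients, model.coefficients)
        assert clone.intercept == model.intercept
        assert clone.column_ids == model.column_ids

    def test_nonconvergence_is_distinct_failure(self, small_logistic_data):
        X, y = small_logistic_data
        with pytest.raises(ConvergenceError) as err:
            fit_elastic_net_logistic(X, y, RegularizationPair(0.5, 0.0), max_iter=2)
        assert err.value.model is not None  # partial diagnostics attached
        assert not err.value.model.converged
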
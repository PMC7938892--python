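"""Learners: standardization contract, penalized-regression oracle
equivalences, SVM/GB behaviour and the feature cap."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fsstab.learners import (
    GbSpec,
    PenalizedRegSpec,
    SvmSpec,
    fit_gradient_boosting,
    fit_penalized_regression,
    fit_svm_rbf,
    standardize_features,
)


def _inner(n, k=3, seed=0):
    return np.random.default_rng(seed).permutation(np.arange(n) % k + 1)


class TestStandardize:
    def test_train_columns_centered_unit_sd(self, rng):
        X = rng.random((50, 4)) * 10
        Xs, _, _, _ = standardize_features(X)
        assert np.allclose(Xs.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(Xs.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_already_standardized_is_identity(self, rng):
        X = rng.standard_normal((100, 3))
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        Xs, _, _, _ = standardize_features(X)
        assert np.allclose(Xs, X, atol=1e-10)

    def test_single_column_hand_case(self):
        Xs, _, _, sds = standardize_features(np.array([[0.0], [1.0], [2.0]]))
        assert np.allclose(Xs.ravel(), [-1.0, 0.0, 1.0])
        assert sds[0] == pytest.approx(1.0)  # ddof=1 on (0,1,2)

    def test_test_block_uses_training_statistics(self, rng):
        Xtr = rng.random((40, 2))
        Xte = rng.random((10, 2)) + 5.0  # shifted: must NOT be re-centered
        _, Xte_s, means, sds = standardize_features(Xtr, Xte)
        assert np.allclose(Xte_s, (Xte - means) / sds)
        assert Xte_s.mean() > 1.0

    def test_constant_training_column_raises(self, rng):
        X = np.column_stack([np.ones(20), rng.random(20)])
        with pytest.raises(ValueError, match="constant"):
            standardize_features(X)


class TestPenalizedRegression:
    def test_lambda_zero_matches_ols_normal_equations(self, rng):
        n, p = 80, 5
        X = rng.standard_normal((n, p))
        y = X @ rng.standard_normal(p) + 0.1 * rng.standard_normal(n)
        model = fit_penalized_regression(
            X, y, PenalizedRegSpec(alpha_grid=(1.0,), lam=0.0)
        )
        Xi = np.column_stack([np.ones(n), X])
        beta = np.linalg.solve(Xi.T @ Xi, Xi.T @ y)
        assert np.allclose(model.importance, np.abs(beta[1:]), atol=1e-6)

    def test_ridge_matches_closed_form(self, rng):
        n, p, lam = 60, 4, 3.7
        X = rng.standard_normal((n, p))
        X -= X.mean(axis=0)
        y = X @ np.array([1.0, -2.0, 0.5, 0.0]) + rng.standard_normal(n)
        y -= y.mean()
        model = fit_penalized_regression(
            X, y, PenalizedRegSpec(alpha_grid=(0.0,), lam=lam)
        )
        beta = np.linalg.solve(X.T @ X + lam * np.eye(p), X.T @ y)
        fitted = model.predict(X)
        assert np.allclose(fitted, X @ beta + (y - X @ beta).mean(), atol=1e-6)

    def test_lasso_full_shrinkage_at_large_lambda(self, rng):
        X = rng.standard_normal((50, 6))
        y = X[:, 0] + rng.standard_normal(50)
        model = fit_penalized_regression(
            X, y, PenalizedRegSpec(alpha_grid=(1.0,), lam=1e6)
        )
        assert model.selected_snps == []
        assert np.allclose(model.importance, 0.0)

    def test_embedded_selection_reports_nonzero_support(self, rng):
        n = 120
        X = pd.DataFrame(
            rng.standard_normal((n, 10)),
            columns=[f"s{j}" for j in range(10)],
        )
        y = 3.0 * X["s2"].to_numpy() + 0.05 * rng.standard_normal(n)
        model = fit_penalized_regression(
            X, y, PenalizedRegSpec(alpha_grid=(1.0,)), inner_cv=_inner(n)
        )
        assert "s2" in model.selected_snps
        assert len(model.selected_snps) < 10

    def test_auto_lambda_requires_inner_cv(self, rng):
        X = rng.standard_normal((30, 3))
        with pytest.raises(ValueError, match="inner_cv"):
            fit_penalized_regression(X, rng.standard_normal(30),
                                     PenalizedRegSpec())


class TestSvm:
    def test_linear_signal_high_cost_fits_training_set(self, rng):
        n = 100
        X = rng.standard_normal((n, 1))
        y = 2.0 * X[:, 0]
        model = fit_svm_rbf(
            X, y, SvmSpec(C_grid=(10.0,), gamma_grid=(0.5,), epsilon=0.01)
        )
        sc = stats.spearmanr(y, model.predict(X)).statistic
        assert sc > 0.99

    def test_vanishing_gamma_gives_near_constant_predictions(self, rng):
        n = 80
        X = rng.standard_normal((n, 3))
        y = rng.standard_normal(n)
        model = fit_svm_rbf(
            X, y, SvmSpec(C_grid=(1.0,), gamma_grid=(1e-8,))
        )
        assert np.ptp(model.predict(X)) < 0.05 * np.ptp(y)

    def test_duplicate_rows_predict_identically(self, rng):
        X = rng.standard_normal((40, 2))
        X[1] = X[0]
        y = rng.standard_normal(40)
        model = fit_svm_rbf(X, y, SvmSpec(C_grid=(1.0,), gamma_grid=(0.5,)))
        pred = model.predict(X)
        assert pred[0] == pytest.approx(pred[1])

    def test_feature_cap_raises(self, rng):
        X = rng.standard_normal((20, 30))
        with pytest.raises(ValueError, match="feature cap"):
            fit_svm_rbf(X, rng.standard_normal(20),
                        SvmSpec(feature_cap=10))


class TestGradientBoosting:
    def test_single_stump_recovers_step_function(self, rng):
        X = rng.integers(0, 3, (100, 1)).astype(float)
        y = np.where(X[:, 0] >= 1, 4.0, -4.0)
        model = fit_gradient_boosting(
            X, y,
            GbSpec(depth_grid=(1,), learning_rate_grid=(1.0,),
                   n_trees_grid=(1,)),
        )
        assert np.allclose(model.predict(X), y)

    def test_zero_learning_rate_predicts_training_mean(self, rng):
        X = rng.standard_normal((60, 3))
        y = rng.standard_normal(60)
        model = fit_gradient_boosting(
            X, y,
            GbSpec(depth_grid=(3,), learning_rate_grid=(0.0,),
                   n_trees_grid=(20,)),
        )
        assert np.allclose(model.predict(X), y.mean())

    def test_accuracy_grows_with_trees_on_additive_signal(self, rng):
        n = 400
        X = rng.integers(0, 3, (n, 6)).astype(float)
        y = X[:, 0] - X[:, 3] + 0.5 * rng.standard_normal(n)
        tr, te = np.arange(300), np.arange(300, n)
        scs = []
        for nt in (10, 50, 500):
            model = fit_gradient_boosting(
                X[tr], y[tr],
                GbSpec(depth_grid=(2,), learning_rate_grid=(0.05,),
                       n_trees_grid=(nt,)),
            )
            scs.append(stats.spearmanr(y[te], model.predict(X[te])).statistic)
        assert scs[0] <= scs[1] + 0.02 and scs[1] <= scs[2] + 0.02

    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((80, 4))
        y = rng.standard_normal(80)
        spec = GbSpec(depth_grid=(2,), learning_rate_grid=(0.1,),
                      n_trees_grid=(30,))
        a = fit_gradient_boosting(X, y, spec, seed=5).predict(X)
        b = fit_gradient_boosting(X, y, spec, seed=5).predict(X)
        assert np.array_equal(a, b)

    def test_feature_cap_raises(self, rng):
        X = rng.standard_normal((20, 30))
        with pytest.raises(ValueError, match="feature cap"):
            fit_gradient_boosting(X, rng.standard_normal(20),
                                  GbSpec(feature_cap=10))
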
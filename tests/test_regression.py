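import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression as SkPLS
from sklearn.linear_model import LinearRegression, Ridge as SkRidge

from aitext.regression import (DegenerateFitError, PCR, PLSRegressor, RidgeRegressor,
                               SupervisedPCR, _parsimony_key, loo_cv, pca, rmse)


@pytest.fixture
def collinear_data(rng):
    """20 x 8 matrix with strong collinearity but full column rank."""
    n, p = 20, 8
    latent = rng.normal(size=(n, 2))
    X = latent @ rng.normal(size=(2, p)) + 0.3 * rng.normal(size=(n, p))
    y = latent[:, 0] * 2.0 - latent[:, 1] + 0.2 * rng.normal(size=n)
    return X, y


class TestRmse:
    def test_perfect_prediction_is_zero(self):
        assert rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_case(self):
        # residuals (3, 4): sqrt((9 + 16) / 2) = sqrt(12.5)
        assert rmse([3.0, 4.0], [0.0, 0.0]) == pytest.approx(np.sqrt(12.5))
        assert rmse([3.0, 4.0], [0.0, 0.0]) == pytest.approx(3.5355339)

    def test_single_element_is_absolute_residual(self):
        assert rmse([-2.5], [0.0]) == pytest.approx(2.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse([1.0, 2.0], [1.0])


class TestPCA:
    def test_perfectly_correlated_columns_one_component(self, rng):
        col = rng.normal(size=30)
        X = np.column_stack([col, 2.0 * col])
        _, _, _, evr = pca(X, standardized=True)
        assert evr[0] == pytest.approx(1.0, abs=1e-10)

    def test_identity_covariance_spreads_variance(self, rng):
        X = rng.normal(size=(4000, 3))
        _, _, ev, _ = pca(X)
        assert ev.max() / ev.min() < 1.2

    def test_scores_are_orthogonal(self, collinear_data):
        X, _ = collinear_data
        _, scores, _, _ = pca(X)
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()

    def test_sign_convention_largest_loading_positive(self, collinear_data):
        X, _ = collinear_data
        loadings, _, _, _ = pca(X)
        for j in range(loadings.shape[1]):
            assert loadings[np.abs(loadings[:, j]).argmax(), j] > 0

    def test_loadings_orthonormal_and_variance_sorted(self, collinear_data):
        X, _ = collinear_data
        loadings, _, ev, _ = pca(X)
        assert np.allclose(loadings.T @ loadings, np.eye(loadings.shape[1]), atol=1e-10)
        assert (np.diff(ev) <= 1e-12).all()

    def test_constant_column_with_scaling_is_error(self):
        X = np.column_stack([np.arange(5.0), np.ones(5)])
        with pytest.raises(ValueError, match="constant"):
            pca(X, standardized=True)


def _ols_normal_equations(X, y):
    """Independent OLS oracle: explicit normal equations with intercept."""
    A = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(A.T @ A, A.T @ y)
    return beta[0], beta[1:]


class TestPCR:
    def test_zero_components_predicts_training_mean(self, collinear_data):
        X, y = collinear_data
        model = PCR(n_components=0).fit(X, y)
        assert np.allclose(model.predict(X), y.mean())

    def test_full_rank_equals_ols_oracle(self, rng):
        X = rng.normal(size=(6, 3))
        y = rng.normal(size=6)
        model = PCR(n_components=3).fit(X, y)
        b0, b = _ols_normal_equations(X, y)
        assert np.allclose(model.coef_, b, atol=1e-8)
        assert model.intercept_ == pytest.approx(b0, abs=1e-8)

    def test_too_many_components_rejected(self, rng):
        X = rng.normal(size=(5, 3))
        with pytest.raises(DegenerateFitError):
            PCR(n_components=5).fit(X, rng.normal(size=5))

    def test_confidence_intervals_bracket_coefficients(self, collinear_data):
        X, y = collinear_data
        model = PCR(n_components=3).fit(X, y)
        assert model.score_coef_ci_.shape == (3, 2)
        assert (model.score_coef_ci_[:, 0] < model.score_coef_).all()
        assert (model.score_coef_ > 0).sum() + (model.score_coef_ < 0).sum() == 3

    def test_in_sample_prediction_is_deterministic(self, collinear_data):
        X, y = collinear_data
        p1 = PCR(n_components=4).fit(X, y).predict(X)
        p2 = PCR(n_components=4).fit(X, y).predict(X)
        assert np.array_equal(p1, p2)


class TestSupervisedPCR:
    def test_theta_zero_equals_pcr(self, collinear_data):
        X, y = collinear_data
        for k in (0, 1, 3, 5):
            a = SupervisedPCR(theta=0.0, n_components=k).fit(X, y).predict(X)
            b = PCR(n_components=k).fit(X, y).predict(X)
            assert np.allclose(a, b, atol=1e-10)

    def test_screening_retains_signal_column(self, rng):
        n = 40
        y = rng.normal(size=n)
        X = np.column_stack([y + 0.1 * rng.normal(size=n),
                             rng.normal(size=n), rng.normal(size=n)])
        model = SupervisedPCR(theta=0.5, n_components=1).fit(X, y)
        assert model.support_.tolist() == [True, False, False]

    def test_theta_above_max_score_errors(self, collinear_data):
        X, y = collinear_data
        with pytest.raises(DegenerateFitError, match="smaller theta"):
            SupervisedPCR(theta=1.1, n_components=1).fit(X, y)

    def test_excluded_columns_get_zero_coefficients(self, rng):
        n = 40
        y = rng.normal(size=n)
        X = np.column_stack([y + 0.1 * rng.normal(size=n), rng.normal(size=n)])
        model = SupervisedPCR(theta=0.5, n_components=1).fit(X, y)
        assert model.coef_[1] == 0.0


class TestPLS:
    def test_single_column_equals_simple_regression(self, rng):
        x = rng.normal(size=15)
        y = 2.0 * x + rng.normal(size=15)
        model = PLSRegressor(n_components=1).fit(x[:, None], y)
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert model.coef_[0] == pytest.approx(slope, rel=1e-10)

    def test_first_weight_proportional_to_covariance(self, rng):
        X = rng.normal(size=(5, 3))
        y = rng.normal(size=5)
        model = PLSRegressor(n_components=1).fit(X, y)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        direction = Xs.T @ (y - y.mean())
        cosine = (model.x_weights_[:, 0] @ direction) / (
            np.linalg.norm(model.x_weights_[:, 0]) * np.linalg.norm(direction))
        assert abs(cosine) == pytest.approx(1.0, abs=1e-10)

    def test_saturated_equals_ols(self, collinear_data):
        X, y = collinear_data
        b0, b = _ols_normal_equations(X, y)
        model = PLSRegressor(n_components=8).fit(X, y)
        assert np.allclose(model.predict(X), X @ b + b0, atol=1e-6)

    def test_matches_sklearn_pls_predictions(self, rng):
        """NIPALS (sklearn) and SIMPLS coincide for a single response."""
        X = rng.normal(size=(20, 5))
        y = X @ rng.normal(size=5) + rng.normal(size=20)
        mine = PLSRegressor(n_components=3).fit(X, y).predict(X)
        ref = SkPLS(n_components=3, scale=True).fit(X, y[:, None]).predict(X).ravel()
        assert np.allclose(mine, ref, atol=1e-8)

    def test_too_many_components_rejected(self, rng):
        X = rng.normal(size=(4, 6))
        with pytest.raises(DegenerateFitError):
            PLSRegressor(n_components=4).fit(X, rng.normal(size=4))


class TestRidge:
    def test_lambda_zero_equals_ols(self, collinear_data):
        X, y = collinear_data
        b0, b = _ols_normal_equations(X, y)
        model = RidgeRegressor(lam=0.0).fit(X, y)
        assert np.allclose(model.predict(X), X @ b + b0, atol=1e-6)

    def test_infinite_shrinkage_predicts_mean(self, collinear_data):
        X, y = collinear_data
        model = RidgeRegressor(lam=1e12).fit(X, y)
        assert np.allclose(model.predict(X), y.mean(), atol=1e-6)

    def test_hand_solved_two_column_system(self):
        X = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 5.0], [4.0, 4.0]])
        y = np.array([1.0, 2.0, 2.0, 4.0])
        model = RidgeRegressor(lam=1.0).fit(X, y)
        # independent arithmetic: standardize, solve the 2x2 system directly
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        yc = y - y.mean()
        b = np.linalg.solve(Xs.T @ Xs + np.eye(2), Xs.T @ yc)
        assert np.allclose(model.coef_, b / X.std(0, ddof=1), atol=1e-12)

    def test_matches_sklearn_ridge_on_standardized_data(self, collinear_data):
        X, y = collinear_data
        lam = 3.7
        mine = RidgeRegressor(lam=lam).fit(X, y).predict(X)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        ref = SkRidge(alpha=lam).fit(Xs, y).predict(Xs)
        assert np.allclose(mine, ref, atol=1e-8)

    def test_slope_norm_non_increasing_in_lambda(self, collinear_data):
        X, y = collinear_data
        norms = [np.linalg.norm(RidgeRegressor(lam=l).fit(X, y).coef_ * X.std(0, ddof=1))
                 for l in (0.0, 0.1, 1.0, 10.0, 100.0, 1e4)]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))


class TestEquivalenceChain:
    def test_all_methods_collapse_to_ols_at_their_limits(self, collinear_data):
        X, y = collinear_data
        reference = LinearRegression().fit(X, y).predict(X)
        for model in (PCR(n_components=8), PLSRegressor(n_components=8),
                      RidgeRegressor(lam=0.0), SupervisedPCR(theta=0.0, n_components=8)):
            assert np.allclose(model.fit(X, y).predict(X), reference, atol=1e-6)


class TestLooCV:
    def test_intercept_only_matches_hand_loo_of_the_mean(self):
        y = np.array([1.0, 2.0, 4.0, 9.0])
        X = np.arange(8.0).reshape(4, 2)  # ignored by the 0-component model
        res = loo_cv(X, y, PCR(), [{"n_components": 0}])
        expected = np.sqrt(np.mean([(np.delete(y, i).mean() - y[i]) ** 2
                                    for i in range(4)]))
        assert res.best_rmse == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_fold_enumeration(self, rng):
        n = 6
        X = rng.normal(size=(n, 3))
        y = rng.normal(size=n)
        grid = [{"n_components": k} for k in (0, 1, 2)]
        res = loo_cv(X, y, PCR(), grid)
        for g, params in enumerate(grid):
            pred = np.empty(n)
            for i in range(n):
                keep = [j for j in range(n) if j != i]
                model = PCR(**params).fit(X[keep], y[keep])
                pred[i] = model.predict(X[i:i + 1])[0]
            assert res.rmse[g] == pytest.approx(
                np.sqrt(np.mean((pred - y) ** 2)), abs=1e-10)

    def test_fold_purity_held_out_target_cannot_leak(self, rng):
        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        res1 = loo_cv(X, y, PCR(), [{"n_components": 1}])
        y_corrupt = y.copy()
        y_corrupt[3] = 1e6
        res2 = loo_cv(X, y_corrupt, PCR(), [{"n_components": 1}])
        assert res2.predictions[3] == pytest.approx(res1.predictions[3], rel=1e-12)

    def test_duplicating_subjects_does_not_hurt(self, rng):
        X = rng.normal(size=(6, 2))
        y = X @ np.array([1.0, -2.0]) + 0.1 * rng.normal(size=6)
        single = loo_cv(X, y, PCR(), [{"n_components": 2}]).best_rmse
        doubled = loo_cv(np.vstack([X, X]), np.hstack([y, y]), PCR(),
                         [{"n_components": 2}]).best_rmse
        assert doubled <= single + 1e-12

    def test_single_point_grid_is_best(self, collinear_data):
        X, y = collinear_data
        res = loo_cv(X, y, RidgeRegressor(), [{"lam": 2.0}])
        assert res.best_params == {"lam": 2.0}

    def test_ties_resolve_to_strongest_shrinkage(self):
        # constant target: every ridge model predicts the fold mean exactly,
        # all grid points tie at RMSE 0 and the most parsimonious (largest
        # lam) must win
        X = np.arange(12.0).reshape(6, 2) ** 2
        y = np.full(6, 3.0)
        res = loo_cv(X, y, RidgeRegressor(), [{"lam": l} for l in (0.1, 10.0, 1.0)])
        assert res.best_params == {"lam": 10.0}

    def test_parsimony_key_ordering(self):
        assert _parsimony_key({"n_components": 2}) < _parsimony_key({"n_components": 5})
        assert _parsimony_key({"lam": 10.0}) < _parsimony_key({"lam": 1.0})
        assert _parsimony_key({"theta": 0.3, "n_components": 2}) < _parsimony_key(
            {"theta": 0.1, "n_components": 2})

    def test_infeasible_grid_points_are_skipped(self, rng):
        X = rng.normal(size=(6, 3))
        y = rng.normal(size=6)
        res = loo_cv(X, y, SupervisedPCR(),
                     [{"theta": 0.0, "n_components": 1}, {"theta": 5.0, "n_components": 1}])
        assert np.isinf(res.rmse[1]) and np.isfinite(res.rmse[0])

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 3"):
            loo_cv(rng.normal(size=(2, 2)), rng.normal(size=2), PCR(),
                   [{"n_components": 0}])
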
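"""Collinearity-robust regression with leave-one-out cross-validation.

Narrative feature matrices are strongly collinear (many columns measure
text quantity), so ordinary least squares is ill-posed.  This module
implements the four standard remedies as scikit-learn style estimators:

* :class:`PCR` — principal component regression: OLS of y on the first
  ``n_components`` PCA scores of the standardized predictors, with
  normal-theory 95% confidence intervals on the component coefficients.
* :class:`SupervisedPCR` — PCR preceded by univariate screening: columns
  whose absolute standardized univariate coefficient (equivalently
  |Pearson r| with y) falls below the inclusion threshold ``theta`` are
  dropped before the PCA step.
* :class:`PLSRegressor` — single-response partial least squares (SIMPLS),
  whose components jointly track variance in X and correlation with y.
* :class:`RidgeRegressor` — L2-shrunk linear regression with unpenalized
  intercept.

All estimators z-score the predictors on the *training* data inside
``fit`` and back-transform coefficients to the original predictor scale,
so ``predict`` takes raw feature values.  :func:`loo_cv` tunes the
hyperparameters by leave-one-out RMSE with all preprocessing re-estimated
inside each fold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.decomposition import PCA as _SkPCA
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

logger = logging.getLogger(__name__)

__all__ = [
    "rmse",
    "pca",
    "PCR",
    "SupervisedPCR",
    "PLSRegressor",
    "RidgeRegressor",
    "CVResult",
    "loo_cv",
    "fit_pcr",
    "fit_spcr",
    "fit_pls",
    "fit_ridge",
    "DegenerateFitError",
]

_RANK_TOL = 1e-9


class DegenerateFitError(ValueError):
    """A hyperparameter made the fit infeasible (e.g. screening removed
    every column, or more components than the training rank)."""


def rmse(yhat: Sequence[float], y: Sequence[float]) -> float:
    """Root mean squared error, sqrt(sum((yhat - y)^2) / n)."""
    yhat = np.asarray(yhat, dtype=float)
    y = np.asarray(y, dtype=float)
    if yhat.shape != y.shape:
        raise ValueError(f"length mismatch: {yhat.shape} vs {y.shape}")
    if y.size == 0:
        raise ValueError("empty vectors")
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column means/sds of a training block; constant columns get sd 1
    (their standardized values are exactly zero and cannot influence the
    fit) with a warning."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant column(s) in training data; "
                      "they are inert in the standardized fit")
        sd = np.where(constant, 1.0, sd)
    return (X - mean) / sd, mean, sd


def _signfix(loadings: np.ndarray) -> np.ndarray:
    """Sign convention: the largest-magnitude loading of each component
    is positive."""
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    return loadings * flip


def pca(X, standardized: bool = True):
    """PCA of a data matrix: (loadings, scores, explained_variance,
    explained_variance_ratio).

    Columns are centered, and z-scored when ``standardized``; components
    are ordered by decreasing variance with the largest-magnitude loading
    of each component positive.  A constant column with standardization
    on is an error (its z-score is undefined).
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    X = check_array(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 rows")
    sd = X.std(axis=0, ddof=1)
    if standardized:
        if (sd == 0).any():
            bad = [names[i] if names else i for i in np.flatnonzero(sd == 0)]
            raise ValueError(f"constant column(s) {bad} cannot be standardized")
        Xw = (X - X.mean(axis=0)) / sd
    else:
        Xw = X - X.mean(axis=0)
    k = min(Xw.shape[0] - 1, Xw.shape[1])
    model = _SkPCA(n_components=k, svd_solver="full").fit(Xw)
    loadings = _signfix(model.components_.T)
    scores = Xw @ loadings
    return loadings, scores, model.explained_variance_, model.explained_variance_ratio_


class _StandardizedLinearModel(RegressorMixin, BaseEstimator):
    """Shared fit/predict plumbing: training-fold z-scoring, coefficient
    back-transformation and prediction on the raw feature scale."""

    def _validate(self, X, y):
        X, y = check_X_y(X, y, dtype=float, y_numeric=True)
        if np.isnan(X).any() or np.isnan(y).any():
            raise ValueError("NaN in X or y; impute before fitting")
        return X, y

    def _finalize(self, coef_std: np.ndarray, mean: np.ndarray, sd: np.ndarray,
                  y_mean: float) -> None:
        self.coef_ = coef_std / sd
        self.intercept_ = y_mean - float(mean @ self.coef_)

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        return X @ self.coef_ + self.intercept_


class PCR(_StandardizedLinearModel):
    """Principal component regression.

    Fits OLS of y on the first ``n_components`` principal component
    scores of the standardized training predictors (``n_components=0``
    is the intercept-only model).  The fitted component coefficients
    carry normal-theory 95% confidence intervals.

    Attributes set by ``fit`` include ``loadings_`` (p x k, sign-fixed),
    ``score_coef_`` and ``score_coef_ci_`` (component-score scale),
    ``coef_``/``intercept_`` (original predictor scale) and
    ``explained_variance_ratio_``.
    """

    def __init__(self, n_components: int = 5):
        self.n_components = n_components

    def fit(self, X, y):
        X, y = self._validate(X, y)
        if self.n_components < 0:
            raise ValueError("n_components must be >= 0")
        Xs, mean, sd = _standardize_fit(X)
        U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
        rank = int((s > _RANK_TOL * s[0]).sum()) if s.size and s[0] > 0 else 0
        if self.n_components > rank:
            raise DegenerateFitError(
                f"n_components={self.n_components} exceeds training rank {rank}")
        loadings = _signfix(Vt[:rank].T)
        scores = Xs @ loadings
        n = X.shape[0]
        var = s[:rank] ** 2 / (n - 1)

        k = self.n_components
        design = sm.add_constant(scores[:, :k], has_constant="add")
        ols = sm.OLS(y, design).fit()
        ci = np.asarray(ols.conf_int(alpha=0.05))

        self.rank_ = rank
        self.loadings_ = loadings
        self.explained_variance_ = var
        self.explained_variance_ratio_ = var / var.sum() if rank else var
        self.score_coef_ = np.asarray(ols.params[1:])
        self.score_coef_ci_ = ci[1:]
        self.score_coef_se_ = np.asarray(ols.bse[1:])
        coef_std = loadings[:, :k] @ self.score_coef_ if k else np.zeros(X.shape[1])
        # scores are zero at X = mean, so the OLS constant is the fit there
        self.coef_ = coef_std / sd
        self.intercept_ = float(ols.params[0]) - float(mean @ self.coef_)
        self.n_features_in_ = X.shape[1]
        return self


class SupervisedPCR(_StandardizedLinearModel):
    """Supervised principal component regression.

    Columns whose absolute standardized univariate coefficient with y
    (|Pearson correlation|) is below the inclusion threshold ``theta``
    are excluded before the PCA step of PCR.  ``support_`` records the
    retained-column mask; excluded columns get zero coefficients.
    """

    def __init__(self, theta: float = 0.0, n_components: int = 5):
        self.theta = theta
        self.n_components = n_components

    @staticmethod
    def screening_scores(X, y) -> np.ndarray:
        """|standardized univariate regression coefficient| per column
        (the |Pearson r| of each column with y; 0 for constant columns)."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        sx = np.sqrt((Xc ** 2).sum(axis=0))
        sy = np.sqrt((yc ** 2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Xc.T @ yc) / (sx * sy)
        return np.abs(np.nan_to_num(r))

    def fit(self, X, y):
        X, y = self._validate(X, y)
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        scores = self.screening_scores(X, y)
        support = scores >= self.theta
        if not support.any():
            raise DegenerateFitError(
                f"theta={self.theta} excludes every column "
                f"(max screening score {scores.max():.4f}); use a smaller theta")
        inner = PCR(n_components=self.n_components).fit(X[:, support], y)
        self.support_ = support
        self.screening_scores_ = scores
        self.pcr_ = inner
        self.coef_ = np.zeros(X.shape[1])
        self.coef_[support] = inner.coef_
        self.intercept_ = inner.intercept_
        self.n_features_in_ = X.shape[1]
        return self


class PLSRegressor(_StandardizedLinearModel):
    """Single-response partial least squares regression (SIMPLS).

    Components are extracted from the standardized predictors so as to
    maximize covariance with the (centered) response, the de Jong SIMPLS
    deflation keeping the score vectors orthogonal.  ``n_components=0``
    degenerates to the intercept-only model.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X, y = self._validate(X, y)
        if self.n_components < 0:
            raise ValueError("n_components must be >= 0")
        Xs, mean, sd = _standardize_fit(X)
        yc = y - y.mean()
        n, p = Xs.shape
        rank = np.linalg.matrix_rank(Xs, tol=_RANK_TOL * max(1.0, np.abs(Xs).max()))
        if self.n_components > rank:
            raise DegenerateFitError(
                f"n_components={self.n_components} exceeds training rank {rank}")

        A = self.n_components
        R = np.zeros((p, A))   # weights: T = Xs @ R
        P = np.zeros((p, A))   # x loadings
        q = np.zeros(A)        # y loadings
        T = np.zeros((n, A))   # orthonormal scores
        V = np.zeros((p, A))   # orthonormal basis for deflation
        S = Xs.T @ yc
        for a in range(A):
            r = S.copy()
            t = Xs @ r
            tnorm = np.linalg.norm(t)
            if tnorm <= _RANK_TOL:
                raise DegenerateFitError(f"component {a + 1} is null; reduce n_components")
            t /= tnorm
            r /= tnorm
            pvec = Xs.T @ t
            v = pvec.copy()
            if a:
                v -= V[:, :a] @ (V[:, :a].T @ pvec)
            v /= np.linalg.norm(v)
            S = S - v * (v @ S)
            R[:, a], P[:, a], T[:, a], V[:, a] = r, pvec, t, v
            q[a] = yc @ t

        coef_std = R @ q
        self.x_weights_ = R
        self.x_loadings_ = P
        self.x_scores_ = T
        self.y_loadings_ = q
        self.rank_ = int(rank)
        self._finalize(coef_std, mean, sd, float(y.mean()))
        self.n_features_in_ = X.shape[1]
        return self


class RidgeRegressor(_StandardizedLinearModel):
    """Ridge regression with an unpenalized intercept.

    Slopes solve (Xs'Xs + lam*I) b = Xs'yc on z-scored predictors and are
    back-transformed; ``lam=0`` on rank-deficient data falls back to the
    minimum-norm least squares solution with a warning.
    """

    def __init__(self, lam: float = 1.0):
        self.lam = lam

    def fit(self, X, y):
        X, y = self._validate(X, y)
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        Xs, mean, sd = _standardize_fit(X)
        yc = y - y.mean()
        p = Xs.shape[1]
        gram = Xs.T @ Xs + self.lam * np.eye(p)
        if self.lam == 0 and np.linalg.matrix_rank(Xs) < p:
            warnings.warn("lam=0 on rank-deficient X: using minimum-norm solution")
            coef_std = np.linalg.pinv(Xs) @ yc
        else:
            coef_std = np.linalg.solve(gram, Xs.T @ yc)
        self._finalize(coef_std, mean, sd, float(y.mean()))
        self.n_features_in_ = X.shape[1]
        return self


# --------------------------------------------------------------------------
# Leave-one-out cross-validation

@dataclass
class CVResult:
    """Hyperparameter grid vs. leave-one-out RMSE, plus the best model."""

    grid: list[dict[str, Any]]
    rmse: np.ndarray
    best_index: int
    best_params: dict[str, Any]
    predictions: np.ndarray   # held-out predictions at the best grid point
    residuals: np.ndarray     # predictions - y at the best grid point
    estimator: Optional[Any] = field(default=None, repr=False)

    @property
    def best_rmse(self) -> float:
        return float(self.rmse[self.best_index])

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.grid)
        frame["rmse"] = self.rmse
        return frame


def _parsimony_key(params: dict[str, Any]) -> tuple:
    """Orders exact RMSE ties: fewer components, then stronger shrinkage
    (larger lam), then stricter screening (larger theta)."""
    return (
        params.get("n_components", 0),
        -params.get("lam", 0.0),
        -params.get("theta", 0.0),
    )


def loo_cv(X, y, estimator: _StandardizedLinearModel,
           grid: Sequence[dict[str, Any]],
           refit: bool = True) -> CVResult:
    """Leave-one-out CV over a hyperparameter grid.

    For every grid point and every subject i the estimator is cloned and
    fitted on all other subjects — standardization, PCA/PLS directions
    and screening are all re-estimated inside the fold — then predicts
    subject i; the grid point's score is the RMSE of the n held-out
    predictions.  Ties at the minimum resolve toward parsimony.  Grid
    points that are infeasible in some fold (screening removed every
    column, components exceed the fold rank) score infinity.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"leave-one-out CV needs at least 3 subjects, got {n}")
    if len(grid) == 0:
        raise ValueError("empty hyperparameter grid")

    mask = np.ones(n, dtype=bool)
    all_pred = np.full((len(grid), n), np.nan)
    scores = np.full(len(grid), np.inf)
    for g, params in enumerate(grid):
        pred = np.empty(n)
        try:
            for i in range(n):
                mask[i] = False
                model = clone(estimator).set_params(**params)
                model.fit(X[mask], y[mask])
                pred[i] = model.predict(X[i:i + 1])[0]
                mask[i] = True
        except DegenerateFitError as exc:
            mask[:] = True
            logger.warning("grid point %s infeasible in a fold: %s", params, exc)
            continue
        all_pred[g] = pred
        scores[g] = rmse(pred, y)

    if not np.isfinite(scores).any():
        raise DegenerateFitError("every grid point was infeasible")
    best_score = scores.min()
    ties = [g for g in range(len(grid)) if scores[g] == best_score]
    best = min(ties, key=lambda g: _parsimony_key(grid[g]))
    fitted = clone(estimator).set_params(**grid[best]).fit(X, y) if refit else None
    return CVResult(
        grid=list(grid),
        rmse=scores,
        best_index=best,
        best_params=dict(grid[best]),
        predictions=all_pred[best],
        residuals=all_pred[best] - y,
        estimator=fitted,
    )


# --------------------------------------------------------------------------
# Thin functional wrappers

def fit_pcr(X, y, n_components: int) -> PCR:
    return PCR(n_components=n_components).fit(X, y)


def fit_spcr(X, y, theta: float, n_components: int) -> SupervisedPCR:
    return SupervisedPCR(theta=theta, n_components=n_components).fit(X, y)


def fit_pls(X, y, n_components: int) -> PLSRegressor:
    return PLSRegressor(n_components=n_components).fit(X, y)


def fit_ridge(X, y, lam: float) -> RidgeRegressor:
    return RidgeRegressor(lam=lam).fit(X, y)


#: Default hyperparameter grids for model selection.
DEFAULT_COMPONENT_GRID = [{"n_components": k} for k in range(0, 11)]
DEFAULT_LAMBDA_GRID = [{"lam": float(l)} for l in np.logspace(-3, 4, 50)]
DEFAULT_THETA_GRID = [
    {"theta": float(t), "n_components": k}
    for t in (0.0, 0.05, 0.1, 0.15, 0.2, 0.3)
    for k in range(0, 6)
]
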
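"""Elastic-net penalized binomial feature selection.

The model minimizes

    (1/n) * binomial deviance  +  lambda * [ (1-alpha) ||b||^2 + alpha ||b||_1 ]

over coefficients b with an unpenalized intercept; columns are standardized
internally for fitting and coefficients are returned on the original scale.
Features with non-zero coefficients at the tuned (alpha, lambda) are
"selected"; the per-localization selections are unioned (de-duplicated) into
the final classification vocabulary.

alpha mixes the ridge (alpha=0) and lasso (alpha=1) penalties; lambda scales
the shrinkage, with lambda=0 the unpenalized fit and every coefficient
exactly zero for lambda >= lambda_max (computable from the gradient of the
deviance at b=0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from ._seeds import derive_seed

logger = logging.getLogger(__name__)

DEFAULT_ALPHA_GRID = tuple(round(0.1 * i, 1) for i in range(1, 11))


@dataclass
class ElasticNetFit:
    """One converged penalized binomial fit (coefficients on original scale)."""

    alpha: float
    lam: float
    coefficients: np.ndarray
    intercept: float
    n_obs: int
    n_features: int
    feature_names: list | None = None
    family: str = "binomial"


@dataclass
class TuningResult:
    alpha_grid: list
    alpha_scores: list
    best_alpha: float
    lambda_grid: list = field(default_factory=list)
    lambda_scores: list = field(default_factory=list)
    best_lambda: float | None = None
    seed: int | None = None


@dataclass
class SelectionResult:
    """Per-localization selected k-mers and their de-duplicated union."""

    per_localization: dict
    union: list
    multiplicity: dict

    @property
    def n_selected_total(self) -> int:
        return sum(len(v) for v in self.per_localization.values())


def _validate_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in X")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"y must contain exactly two classes, got {classes}")
    y01 = (y == classes.max()).astype(int)
    return X, y01


def _standardize(X):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd_safe, mean, sd_safe


def lambda_max(X, y, alpha: float) -> float:
    """Smallest lambda at which every coefficient is exactly zero.

    From the subgradient condition at b=0 (intercept at the class log-odds):
    max_j |x_j^T (y - ybar)| / (n * alpha) on standardized columns. Undefined
    for a pure ridge penalty (alpha=0), which never produces exact zeros.
    """
    if alpha <= 0:
        raise ValueError("lambda_max is undefined for alpha = 0 (pure ridge)")
    X, y01 = _validate_xy(X, y)
    Xs, _, _ = _standardize(X)
    n = len(y01)
    grad = Xs.T @ (y01 - y01.mean())
    return float(np.max(np.abs(grad)) / (n * alpha))


def fit_elastic_net(X, y, alpha: float, lam: float, tol: float = 1e-7,
                    max_iter: int = 100_000, feature_names=None) -> ElasticNetFit:
    """Fit the penalized binomial model at fixed (alpha, lambda).

    The saga solver is used with the exact reparametrisation of the objective
    above: ``C = 1 / (n * lambda * (2 - alpha))`` and
    ``l1_ratio = alpha / (2 - alpha)``; lambda=0 falls back to the
    unpenalized fit.
    """
    if not 0 <= alpha <= 1:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    X, y01 = _validate_xy(X, y)
    n, p = X.shape
    Xs, mean, sd = _standardize(X)

    if lam == 0:
        clf = LogisticRegression(C=np.inf, solver="lbfgs", tol=tol,
                                 max_iter=max_iter)
    else:
        l1_ratio = alpha / (2.0 - alpha)
        C = 1.0 / (n * lam * (2.0 - alpha))
        clf = LogisticRegression(solver="saga", C=C, l1_ratio=l1_ratio,
                                 tol=tol, max_iter=max_iter)
    clf.fit(Xs, y01)
    beta_std = clf.coef_.ravel()
    beta = beta_std / sd
    if not beta_std.any():
        # fully shrunk model: the unpenalized intercept has the closed form
        # logit(ybar); saga converges it poorly when the loss term is scaled
        # down by a large penalty
        ybar = y01.mean()
        intercept = float(np.log(ybar / (1 - ybar)))
    else:
        intercept = float(clf.intercept_[0] - np.dot(beta_std, mean / sd))
    return ElasticNetFit(alpha, lam, beta, intercept, n, p,
                         feature_names=list(feature_names) if feature_names is not None else None)


def predict_proba_fit(fit: ElasticNetFit, X) -> np.ndarray:
    eta = np.asarray(X, dtype=float) @ fit.coefficients + fit.intercept
    return expit(eta)


def make_tuning_sample(pos, neg, fraction: float = 0.5, seed: int = 0):
    """Class-balanced random subsample for hyperparameter tuning.

    Draws ``m = floor(fraction * min(|pos|, |neg|))`` items from each class
    without replacement; errors if fewer than 10 per class would result.
    """
    pos, neg = list(pos), list(neg)
    if not pos or not neg:
        raise ValueError("both classes must be non-empty")
    m = int(np.floor(fraction * min(len(pos), len(neg))))
    if m < 10:
        raise ValueError(
            f"balanced tuning sample would have {m} per class (< 10); "
            "need more training data"
        )
    rng = np.random.default_rng(seed)
    pos_idx = rng.choice(len(pos), size=m, replace=False)
    neg_idx = rng.choice(len(neg), size=m, replace=False)
    return [pos[i] for i in pos_idx], [neg[i] for i in neg_idx]


def build_lambda_grid(X, y, alpha: float, n_lambda: int = 100,
                      lambda_min_ratio: float = 1e-4) -> np.ndarray:
    """Log-spaced descending grid from lambda_max to lambda_min_ratio * lambda_max."""
    lmax = lambda_max(X, y, alpha)
    return np.geomspace(lmax, lambda_min_ratio * lmax, num=n_lambda)


def fit_path(X, y, alpha: float, lambdas, tol: float = 1e-6,
             max_iter: int = 20_000):
    """Warm-started fits along a descending lambda path.

    Returns (coefs, intercepts) on the original scale, one row per lambda.
    Successive lambdas reuse the previous solution as the starting point, the
    standard pathwise strategy for penalized GLMs.
    """
    X, y01 = _validate_xy(X, y)
    n, p = X.shape
    Xs, mean, sd = _standardize(X)
    lambdas = np.asarray(lambdas, dtype=float)
    l1_ratio = alpha / (2.0 - alpha)
    clf = LogisticRegression(solver="saga", C=1.0, l1_ratio=l1_ratio,
                             tol=tol, max_iter=max_iter, warm_start=True)
    coefs = np.zeros((len(lambdas), p))
    intercepts = np.zeros(len(lambdas))
    for j, lam in enumerate(lambdas):
        clf.C = 1.0 / (n * lam * (2.0 - alpha))
        clf.fit(Xs, y01)
        beta_std = clf.coef_.ravel()
        coefs[j] = beta_std / sd
        intercepts[j] = clf.intercept_[0] - np.dot(beta_std, mean / sd)
    return coefs, intercepts


def _cv_auc_at_lambda(X, y, alpha, lambdas, folds, seed, tol, max_iter):
    """Mean held-out aucROC for every lambda on one stratified k-fold split."""
    X, y01 = _validate_xy(X, y)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.zeros(len(lambdas))
    for train_idx, test_idx in skf.split(X, y01):
        ytr, yte = y01[train_idx], y01[test_idx]
        if len(np.unique(ytr)) < 2 or len(np.unique(yte)) < 2:
            raise ValueError("degenerate fold with a single class; stratification failed")
        coefs, intercepts = fit_path(X[train_idx], ytr, alpha, lambdas,
                                     tol=tol, max_iter=max_iter)
        eta = X[test_idx] @ coefs.T + intercepts
        prob = expit(eta)
        for j in range(len(lambdas)):
            if np.ptp(prob[:, j]) == 0:  # all-zero model: chance-level
                scores[j] += 0.5
            else:
                scores[j] += roc_auc_score(yte, prob[:, j])
    return scores / folds


def tune_lambda(X, y, alpha: float, folds: int = 5, n_lambda: int = 100,
                lambda_min_ratio: float = 1e-4, seed: int = 0,
                tol: float = 1e-4, max_iter: int = 5_000) -> TuningResult:
    """Grid-search lambda by stratified k-fold CV aucROC at fixed alpha.

    The grid descends from lambda_max; ties break toward larger lambda (the
    more parsimonious model).
    """
    lambdas = build_lambda_grid(X, y, alpha, n_lambda, lambda_min_ratio)
    scores = _cv_auc_at_lambda(X, y, alpha, lambdas, folds, seed, tol, max_iter)
    best = int(np.argmax(scores))  # first max = largest lambda
    return TuningResult(
        alpha_grid=[alpha], alpha_scores=[float(scores[best])], best_alpha=alpha,
        lambda_grid=list(lambdas), lambda_scores=list(scores),
        best_lambda=float(lambdas[best]), seed=seed,
    )


def tune_alpha(X, y, alpha_grid=DEFAULT_ALPHA_GRID, folds: int = 5,
               repeats: int = 3, n_lambda: int = 100,
               lambda_min_ratio: float = 1e-4, seed: int = 0,
               tol: float = 1e-4, max_iter: int = 5_000) -> TuningResult:
    """Choose alpha by repeated stratified k-fold CV aucROC.

    For each alpha and each outer fold, lambda is chosen on the fold's
    training part by an inner grid search, and the resulting fit is scored on
    the held-out part. Ties break toward smaller alpha.
    """
    alpha_grid = list(alpha_grid)
    if not alpha_grid:
        raise ValueError("alpha grid is empty")
    X, y01 = _validate_xy(X, y)
    alpha_scores = []
    for alpha in alpha_grid:
        fold_scores = []
        for rep in range(repeats):
            skf = StratifiedKFold(n_splits=folds, shuffle=True,
                                  random_state=seed + 1000 * rep)
            for train_idx, test_idx in skf.split(X, y01):
                ytr, yte = y01[train_idx], y01[test_idx]
                if len(np.unique(ytr)) < 2 or len(np.unique(yte)) < 2:
                    raise ValueError("degenerate fold with a single class")
                inner = tune_lambda(X[train_idx], ytr, alpha, folds=folds,
                                    n_lambda=n_lambda,
                                    lambda_min_ratio=lambda_min_ratio,
                                    seed=seed + rep, tol=tol, max_iter=max_iter)
                fit = fit_elastic_net(X[train_idx], ytr, alpha, inner.best_lambda,
                                      tol=tol, max_iter=max_iter)
                prob = predict_proba_fit(fit, X[test_idx])
                fold_scores.append(
                    0.5 if np.ptp(prob) == 0 else roc_auc_score(yte, prob)
                )
        alpha_scores.append(float(np.mean(fold_scores)))
        logger.info("alpha=%.2f mean aucROC=%.4f", alpha, alpha_scores[-1])
    best_idx = int(np.argmax(alpha_scores))  # first max = smallest alpha
    return TuningResult(alpha_grid=alpha_grid, alpha_scores=alpha_scores,
                        best_alpha=alpha_grid[best_idx], seed=seed)


def select_features(fit: ElasticNetFit, threshold: float = 0.0) -> list:
    """Names of features with |coefficient| > threshold, in vocabulary order."""
    if fit.feature_names is None:
        raise ValueError("fit carries no feature names")
    coef = np.abs(fit.coefficients)
    return [name for name, c in zip(fit.feature_names, coef) if c > threshold]


def union_selected(per_loc: dict) -> SelectionResult:
    """De-duplicate per-localization selections; track selection multiplicity."""
    union: list = []
    seen = set()
    mult: dict = {}
    for loc, feats in per_loc.items():
        for f in feats:
            mult[f] = mult.get(f, 0) + 1
            if f not in seen:
                seen.add(f)
                union.append(f)
    return SelectionResult(per_localization=dict(per_loc), union=union,
                           multiplicity=mult)


class ElasticNetSelector(BaseEstimator):
    """Per-localization elastic-net feature selection as an estimator.

    fit(X, y) tunes (alpha, lambda) on a class-balanced subsample (or uses
    fixed values when given), refits on the full training data, and exposes
    ``selected_features_`` / ``get_support()``.

    Parameters
    ----------
    alpha : float or None
        Fixed mixing parameter; when None it is tuned over ``alpha_grid``.
    lam : float or None
        Fixed shrinkage; when None it is tuned by the lambda grid search.
    feature_names : list, optional
        Names for the columns of X (k-mer strings).
    tuning_fraction : float
        Fraction defining the balanced tuning subsample.
    """

    def __init__(self, alpha=None, lam=None, alpha_grid=DEFAULT_ALPHA_GRID,
                 folds: int = 5, repeats: int = 3, n_lambda: int = 100,
                 lambda_min_ratio: float = 1e-4, tuning_fraction: float = 0.5,
                 feature_names=None, random_state: int = 0,
                 tol: float = 1e-5, max_iter: int = 10_000):
        self.alpha = alpha
        self.lam = lam
        self.alpha_grid = alpha_grid
        self.folds = folds
        self.repeats = repeats
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.tuning_fraction = tuning_fraction
        self.feature_names = feature_names
        self.random_state = random_state
        self.tol = tol
        self.max_iter = max_iter

    def _tuning_data(self, X, y):
        X, y01 = _validate_xy(X, y)
        pos = list(np.flatnonzero(y01 == 1))
        neg = list(np.flatnonzero(y01 == 0))
        ps, ns = make_tuning_sample(pos, neg, self.tuning_fraction,
                                    seed=self.random_state)
        idx = np.array(ps + ns)
        return X[idx], y01[idx]

    def fit(self, X, y):
        X, y01 = _validate_xy(X, y)
        names = (list(self.feature_names) if self.feature_names is not None
                 else [f"x{i}" for i in range(X.shape[1])])
        alpha, lam = self.alpha, self.lam
        if alpha is None or lam is None:
            Xt, yt = self._tuning_data(X, y01)
            if alpha is None:
                res = tune_alpha(Xt, yt, alpha_grid=self.alpha_grid,
                                 folds=self.folds, repeats=self.repeats,
                                 n_lambda=self.n_lambda,
                                 lambda_min_ratio=self.lambda_min_ratio,
                                 seed=self.random_state, tol=self.tol,
                                 max_iter=self.max_iter)
                alpha = res.best_alpha
                self.alpha_tuning_ = res
            if lam is None:
                res = tune_lambda(Xt, yt, alpha, folds=self.folds,
                                  n_lambda=self.n_lambda,
                                  lambda_min_ratio=self.lambda_min_ratio,
                                  seed=self.random_state, tol=self.tol,
                                  max_iter=self.max_iter)
                lam = res.best_lambda
                self.lambda_tuning_ = res
        # Final selection model at the tuned pair, on the full class-balanced
        # training set (all minority-class instances plus an equal-count draw
        # from the majority class). lambda is tuned on a balanced subsample,
        # and its scale does not transfer to the imbalanced full set — the
        # score gradient shrinks with class imbalance, so a balanced-tuned
        # lambda there sits above lambda_max and selects nothing.
        pos = np.flatnonzero(y01 == 1)
        neg = np.flatnonzero(y01 == 0)
        minority, majority = (pos, neg) if len(pos) <= len(neg) else (neg, pos)
        rng = np.random.default_rng(derive_seed(self.random_state, "final-balance"))
        keep = np.concatenate([
            minority, rng.choice(majority, size=len(minority), replace=False)
        ])
        self.fit_ = fit_elastic_net(X[keep], y01[keep], alpha, lam, tol=self.tol,
                                    max_iter=self.max_iter, feature_names=names)
        self.alpha_ = alpha
        self.lambda_ = lam
        self.selected_features_ = select_features(self.fit_)
        self.support_ = np.abs(self.fit_.coefficients) > 0
        return self

    def get_support(self) -> np.ndarray:
        return self.support_

    def transform(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float)[:, self.support_]
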
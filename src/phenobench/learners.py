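"""Uniform regression-learner contract over the six standard methods.

This module owns the tuning protocol, not the numerics: coordinate descent,
tree growing and kernel machines are delegated to scikit-learn. Every method
follows the same discipline — hyperparameters are chosen strictly within the
training fold (an internal 70/30 split for GBM and SVR, internal 10-fold CV
for the penalized fits), the final model is refit on the whole training fold
with the chosen values, and test-fold phenotypes are never consulted.

Methods and their default policies:

* ``lasso`` / ``ridge`` / ``enet`` — penalized linear regression; λ chosen by
  internal 10-fold CV over a 100-value log-spaced path auto-scaled from the
  data; the elastic-net mixing parameter α takes 11 evenly spaced values in
  [0, 1], with the endpoints delegating to the pure ridge/lasso fits.
* ``rf`` — random forest, 700 trees, p/3 split candidates, minimum node
  size 5; no tuning (the standard recommended settings).
* ``gbm`` — gradient boosting, grid over interaction depth {1,2,3} ×
  shrinkage {0.001,0.01,0.1}, 1000 trees, subsample 0.5; the grid point and
  the prediction iteration count are picked on the internal validation set.
* ``svr`` — ε-insensitive support-vector regression with Gaussian kernel,
  log-scale grids over ε, C and γ picked on the internal validation set.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Any

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import ElasticNetCV, LassoCV, Ridge
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from .dataio import GenotypeMatrix

METHODS = ("lasso", "ridge", "enet", "rf", "gbm", "svr")


@dataclass
class TuningPolicy:
    """Hyperparameter grids and internal-split bookkeeping for all methods."""

    n_lambda: int = 100
    lambda_cv_folds: int = 10
    enet_alpha: float = 0.5
    rf_trees: int = 700
    rf_max_features: float = 1 / 3
    rf_min_node: int = 5
    gbm_depths: tuple[int, ...] = (1, 2, 3)
    gbm_shrinkage: tuple[float, ...] = (0.001, 0.01, 0.1)
    gbm_trees: int = 1000
    gbm_subsample: float = 0.5
    svr_epsilon: tuple[float, ...] = (0.01, 0.1, 0.5)
    svr_C: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    svr_gamma: tuple[float, ...] = tuple(np.logspace(-4, 0, 10))
    internal_split: float = 0.3  # validation share of the training fold
    ridge_alphas: tuple[float, ...] | None = None  # explicit grid overrides auto-scaling

    def __post_init__(self) -> None:
        if not 0 < self.internal_split < 1:
            raise ValueError("internal_split must be in (0,1)")


#: reduced grids/forests for fast exploratory runs and small simulations
FAST_POLICY = TuningPolicy(
    n_lambda=40,
    lambda_cv_folds=5,
    rf_trees=200,
    gbm_depths=(1, 3),
    gbm_shrinkage=(0.01, 0.1),
    gbm_trees=300,
    svr_C=(1.0, 10.0),
    svr_gamma=(1e-3, 1e-2, 1e-1),
)


@dataclass
class FittedLearner:
    method: str
    estimator: Any
    hyperparameters: dict
    marker_ids: list[str]
    train_mean: float = 0.0

    def predict(self, G_test: GenotypeMatrix) -> np.ndarray:
        return predict(self, G_test)


def _matrix(G: GenotypeMatrix) -> np.ndarray:
    if np.isnan(G.values).any():
        raise ValueError("complete genotypes required; impute first")
    return G.values


def _ridge_alphas(X: np.ndarray, y: np.ndarray, n: int) -> np.ndarray:
    """Log-spaced penalty grid scaled from ‖Xᵀy‖∞/n (documented heuristic)."""
    yc = y - y.mean()
    scale = max(np.abs(X.T @ yc).max() / len(y), 1e-6)
    return np.logspace(np.log10(scale) - 4, np.log10(scale) + 4, n)


def _fit_penalized(
    X: np.ndarray, y: np.ndarray, l1_ratio: float, policy: TuningPolicy, seed: int
) -> tuple[Any, dict]:
    cv = KFold(policy.lambda_cv_folds, shuffle=True, random_state=seed % 2**31)
    if l1_ratio == 0.0:
        # pure ridge: no auto path exists, tune over the scaled grid by CV
        alphas = (
            np.asarray(policy.ridge_alphas)
            if policy.ridge_alphas is not None
            else _ridge_alphas(X, y, policy.n_lambda)
        )
        best, best_mse = None, np.inf
        folds = list(cv.split(X))
        for a in alphas:
            mse = 0.0
            for tr, va in folds:
                m = Ridge(alpha=a).fit(X[tr], y[tr])
                d = m.predict(X[va]) - y[va]
                mse += d @ d
            if mse < best_mse:
                best, best_mse = a, mse
        est = Ridge(alpha=best).fit(X, y)
        return est, {"lambda": float(best), "alpha": 0.0}
    if l1_ratio == 1.0:
        est = LassoCV(alphas=policy.n_lambda, cv=cv, random_state=seed % 2**31).fit(X, y)
        return est, {"lambda": float(est.alpha_), "alpha": 1.0}
    est = ElasticNetCV(
        l1_ratio=l1_ratio, alphas=policy.n_lambda, cv=cv, random_state=seed % 2**31
    ).fit(X, y)
    return est, {"lambda": float(est.alpha_), "alpha": float(l1_ratio)}


def _internal_split(n: int, frac: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(frac * n)))
    return perm[n_val:], perm[:n_val]


def _fit_gbm(X, y, policy: TuningPolicy, seed: int):
    tr, va = _internal_split(len(y), policy.internal_split, seed)
    best = None
    for depth in policy.gbm_depths:
        for shrink in policy.gbm_shrinkage:
            m = GradientBoostingRegressor(
                n_estimators=policy.gbm_trees,
                max_depth=depth,
                learning_rate=shrink,
                subsample=policy.gbm_subsample,
                random_state=seed % 2**31,
            ).fit(X[tr], y[tr])
            # pick the prediction iteration count on the validation set
            errs = [
                ((pred - y[va]) ** 2).mean() for pred in m.staged_predict(X[va])
            ]
            b = int(np.argmin(errs))
            if best is None or errs[b] < best[0]:
                best = (errs[b], depth, shrink, b + 1)
    _, depth, shrink, n_iter = best
    final = GradientBoostingRegressor(
        n_estimators=n_iter,
        max_depth=depth,
        learning_rate=shrink,
        subsample=policy.gbm_subsample,
        random_state=seed % 2**31,
    ).fit(X, y)
    return final, {"depth": depth, "shrinkage": shrink, "n_iterations": n_iter}


def _fit_svr(X, y, policy: TuningPolicy, seed: int):
    tr, va = _internal_split(len(y), policy.internal_split, seed)
    best = None
    for eps in policy.svr_epsilon:
        for C in policy.svr_C:
            for gamma in policy.svr_gamma:
                m = SVR(kernel="rbf", epsilon=eps, C=C, gamma=gamma).fit(X[tr], y[tr])
                mse = ((m.predict(X[va]) - y[va]) ** 2).mean()
                if best is None or mse < best[0]:
                    best = (mse, eps, C, gamma)
    _, eps, C, gamma = best
    final = SVR(kernel="rbf", epsilon=eps, C=C, gamma=gamma).fit(X, y)
    return final, {"epsilon": eps, "C": C, "gamma": gamma}


def fit(
    method: str,
    G_train: GenotypeMatrix,
    y_train: np.ndarray,
    policy: TuningPolicy | None = None,
    seed: int = 0,
) -> FittedLearner:
    """Tune within the training fold, then refit on the whole fold."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    policy = policy or TuningPolicy()
    X = _matrix(G_train)
    y = np.asarray(y_train, dtype=float)
    if np.isnan(y).any():
        raise ValueError("y_train must be fully observed")
    if method == "lasso":
        est, hp = _fit_penalized(X, y, 1.0, policy, seed)
    elif method == "ridge":
        est, hp = _fit_penalized(X, y, 0.0, policy, seed)
    elif method == "enet":
        est, hp = _fit_penalized(X, y, policy.enet_alpha, policy, seed)
    elif method == "rf":
        n_feat = max(1, int(round(policy.rf_max_features * X.shape[1])))
        est = RandomForestRegressor(
            n_estimators=policy.rf_trees,
            max_features=n_feat,
            min_samples_leaf=policy.rf_min_node,
            random_state=seed % 2**31,
            n_jobs=1,
        ).fit(X, y)
        hp = {"trees": policy.rf_trees, "split_candidates": n_feat}
    elif method == "gbm":
        est, hp = _fit_gbm(X, y, policy, seed)
    else:
        est, hp = _fit_svr(X, y, policy, seed)
    return FittedLearner(
        method=method,
        estimator=est,
        hyperparameters=hp,
        marker_ids=list(G_train.marker_ids),
        train_mean=float(y.mean()),
    )


def predict(model: FittedLearner, G_test: GenotypeMatrix) -> np.ndarray:
    if list(G_test.marker_ids) != model.marker_ids:
        raise ValueError("test marker set does not match training marker set")
    return np.asarray(model.estimator.predict(_matrix(G_test)), dtype=float)
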
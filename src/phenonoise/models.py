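"""Five carrier classifiers behind one fit/predict contract.

Methods: Lasso-penalised logistic regression, support vector machines with
linear or radial kernel, K-nearest neighbours, and random forest. Each
exposes ``fit(X, y)`` / ``predict(X)`` with dose matrices (n x m, values
0/1/2) and binary labels; predictions are always in {0, 1} and no
classifier ever sees test labels.

Hyperparameters are tuned by stratified 10-fold cross-validation on
balanced accuracy, (TPR + TNR) / 2 — the mean of sensitivity and
specificity — which, unlike raw accuracy, does not reward the all-majority
classifier on a 4%-prevalence problem. The grid point maximising the mean
validation balanced accuracy is selected and the model refit on the full
training data.

Objectives, in the notation standard for these methods:

* Lasso: maximise the binomial log-likelihood of
  ``logit p(x_i) = mu + sum_j z_ij beta_j`` minus ``lambda * sum_j |beta_j|``
  (intercept unpenalised); classify carrier iff p(x) > 0.5.
* SVM: soft-margin ``f(x) = beta_0 + sum_i alpha_i K(x, x_i)`` with
  ``K(x, x') = <x, x'>`` (linear) or ``exp(-gamma ||x - x'||^2)`` (radial);
  class = sign of f.
* KNN: majority vote among the K nearest training points by Euclidean
  distance; K is kept odd so binary votes cannot tie; distance ties break
  toward the smaller training index.
* RF: B = 500 fully grown Gini trees on bootstrap samples, s candidate
  features per split (default near sqrt(m)); majority vote over trees,
  exact ties to non-carrier.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "METHODS",
    "ModelSpec",
    "TunedModel",
    "LassoLogistic",
    "SVMClassifier",
    "KNNClassifier",
    "RandomForest",
    "kernel",
    "knn_predict",
    "balanced_accuracy",
    "lasso_lambda_path",
    "default_grid",
    "make_model",
    "tune",
]

METHODS = ("lasso", "svm_linear", "svm_radial", "knn", "rf")


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(np.int8).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be n x m with one label per row")
    if np.isnan(X).any():
        raise ValueError("X contains missing values; impute first")
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    return X, y


def balanced_accuracy(y_true, y_pred) -> float:
    """(TPR + TNR) / 2; requires both classes in ``y_true``."""
    y_true = np.asarray(y_true).ravel()
    y_pred = np.asarray(y_pred).ravel()
    pos = y_true == 1
    if not pos.any() or pos.all():
        raise ValueError("balanced accuracy needs both classes in y_true")
    tpr = float((y_pred[pos] == 1).mean())
    tnr = float((y_pred[~pos] == 0).mean())
    return 0.5 * (tpr + tnr)


# ---------------------------------------------------------------------------
# Classifiers


class LassoLogistic:
    """L1-penalised logistic regression at a fixed penalty ``lam``.

    Minimises ``sum_i logloss_i + lam * ||beta||_1`` with the intercept left
    unpenalised. SNP effects are solved by liblinear's coordinate descent
    (the intercept rides on a large constant pseudo-feature so its share of
    the penalty is negligible); the intercept is then re-optimised exactly
    by a one-dimensional Newton step with the effects held fixed. A ``lam``
    above the path maximum zeroes every SNP effect, leaving an
    intercept-only model that predicts the majority class.
    """

    def __init__(self, lam: float, max_iter: int = 200, tol: float = 1e-4):
        if lam <= 0:
            raise ValueError("lam must be positive")
        self.lam = float(lam)
        self.max_iter = max_iter
        self.tol = tol
        self.intercept_: float = 0.0
        self.coef_: np.ndarray | None = None

    def fit(self, X, y) -> "LassoLogistic":
        X, y = _check_xy(X, y)
        # the intercept rides on a constant pseudo-feature; scaling it with
        # lam keeps its penalty gradient (lam / scaling) uniformly small so
        # the intercept stays effectively unpenalised along the whole path
        est = LogisticRegression(
            C=1.0 / self.lam, solver="liblinear", l1_ratio=1.0,
            intercept_scaling=max(10.0, 10.0 * self.lam),
            max_iter=self.max_iter, tol=self.tol)
        est.fit(X, y)
        self.coef_ = est.coef_.ravel().copy()
        self.intercept_ = self._refit_intercept(X, y.astype(np.float64),
                                                est.intercept_[0])
        return self

    def _refit_intercept(self, X, y, b0: float) -> float:
        # profile likelihood in the intercept: 1-D Newton, exact optimum
        eta_x = X @ self.coef_
        b = float(b0)
        for _ in range(100):
            p = expit(b + eta_x)
            grad = float(np.sum(p - y))
            hess = float(np.sum(p * (1.0 - p)))
            if hess < 1e-12:
                break
            step = grad / hess
            b -= step
            if abs(step) < 1e-12:
                break
        return b

    def predict_proba(self, X) -> np.ndarray:
        eta = self.intercept_ + np.asarray(X, dtype=np.float64) @ self.coef_
        return expit(eta)

    def predict(self, X) -> np.ndarray:
        # boundary p = 0.5 goes to the majority (non-carrier) class
        return (self.predict_proba(X) > 0.5).astype(np.int8)


def kernel(x: np.ndarray, x2: np.ndarray, kind: str,
           gamma: float | None = None) -> float:
    """SVM kernel between two dose vectors."""
    x = np.asarray(x, dtype=np.float64).ravel()
    x2 = np.asarray(x2, dtype=np.float64).ravel()
    if x.size != x2.size:
        raise ValueError("vectors must have equal length")
    if kind == "linear":
        return float(x @ x2)
    if kind == "radial":
        if gamma is None or gamma <= 0:
            raise ValueError("radial kernel needs a positive gamma")
        return float(np.exp(-gamma * np.sum((x - x2) ** 2)))
    raise ValueError("kind must be 'linear' or 'radial'")


class SVMClassifier:
    """Soft-margin SVM with linear or radial kernel."""

    def __init__(self, kind: str, C: float = 1.0, gamma: float | None = None):
        if kind not in ("linear", "radial"):
            raise ValueError("kind must be 'linear' or 'radial'")
        if C <= 0:
            raise ValueError("C must be positive")
        self.kind = kind
        self.C = float(C)
        self.gamma = gamma
        self._est: SVC | None = None

    def fit(self, X, y) -> "SVMClassifier":
        X, y = _check_xy(X, y)
        if self.kind == "linear":
            self._est = SVC(kernel="linear", C=self.C)
        else:
            if self.gamma is None or self.gamma <= 0:
                raise ValueError("radial kernel needs a positive gamma")
            self._est = SVC(kernel="rbf", C=self.C, gamma=self.gamma)
        self._est.fit(X, y)
        return self

    def decision_function(self, X) -> np.ndarray:
        return self._est.decision_function(np.asarray(X, dtype=np.float64))

    def predict(self, X) -> np.ndarray:
        return self._est.predict(np.asarray(X, dtype=np.float64)).astype(np.int8)


def knn_predict(X_train, y_train, X_query, K: int) -> np.ndarray:
    """Exact K-nearest-neighbour majority vote (brute force).

    K must be odd (binary votes cannot tie) and at most the training size;
    equal distances rank by smaller training index.
    """
    X_train = np.asarray(X_train, dtype=np.float64)
    y_train = np.asarray(y_train).astype(np.int8).ravel()
    X_query = np.atleast_2d(np.asarray(X_query, dtype=np.float64))
    if K % 2 == 0:
        raise ValueError("K must be odd")
    if K > X_train.shape[0]:
        raise ValueError("K exceeds the training-set size")
    # squared distances suffice for ranking
    d2 = (
        (X_query ** 2).sum(axis=1)[:, None]
        + (X_train ** 2).sum(axis=1)[None, :]
        - 2.0 * X_query @ X_train.T
    )
    out = np.empty(X_query.shape[0], dtype=np.int8)
    for q in range(X_query.shape[0]):
        order = np.argsort(d2[q], kind="stable")  # stable: ties by index
        out[q] = 1 if y_train[order[:K]].sum() * 2 > K else 0
    return out


class KNNClassifier:
    """K-nearest neighbours wrapper over :func:`knn_predict`."""

    def __init__(self, K: int):
        if K < 1 or K % 2 == 0:
            raise ValueError("K must be a positive odd integer")
        self.K = int(K)
        self._X: np.ndarray | None = None
        self._y: np.ndarray | None = None

    def fit(self, X, y) -> "KNNClassifier":
        X, y = _check_xy(X, y)
        if self.K > X.shape[0]:
            raise ValueError("K exceeds the training-set size")
        self._X, self._y = X, y
        return self

    def predict(self, X) -> np.ndarray:
        return knn_predict(self._X, self._y, X, self.K)


class RandomForest:
    """Bagged classification trees with per-split feature subsampling.

    Fully grown Gini trees (min leaf 1) on n-sized bootstrap samples;
    prediction is the majority vote over trees with exact ties assigned to
    the non-carrier (majority) class.
    """

    def __init__(self, B: int = 500, s: int | None = None, seed: int = 0,
                 bootstrap: bool = True):
        if B < 1:
            raise ValueError("B must be positive")
        self.B = int(B)
        self.s = s
        self.seed = seed
        self.bootstrap = bootstrap
        self._est: RandomForestClassifier | None = None

    def fit(self, X, y) -> "RandomForest":
        X, y = _check_xy(X, y)
        m = X.shape[1]
        s = self.s if self.s is not None else int(np.ceil(np.sqrt(m)))
        if not 1 <= s <= m:
            raise ValueError(f"s must be in [1, {m}], got {s}")
        self._est = RandomForestClassifier(
            n_estimators=self.B, max_features=s, criterion="gini",
            bootstrap=self.bootstrap, random_state=self.seed, n_jobs=1)
        self._est.fit(X, y)
        return self

    def vote_fraction(self, X) -> np.ndarray:
        """Fraction of trees voting carrier (trees are fully grown, so the
        averaged per-tree probabilities are hard 0/1 votes)."""
        return self._est.predict_proba(np.asarray(X, dtype=np.float64))[:, 1]

    def predict(self, X) -> np.ndarray:
        return (self.vote_fraction(X) > 0.5).astype(np.int8)


# ---------------------------------------------------------------------------
# Grids and tuning


def lasso_lambda_path(X, y, n_points: int = 50, decades: float = 4.0) -> np.ndarray:
    """Descending log-spaced penalty path from the smallest all-zero lambda.

    ``lambda_max = max_j |sum_i z_ij (y_i - ybar)|`` is the smallest penalty
    at which every SNP effect is zero (KKT condition at the intercept-only
    solution); the path spans ``decades`` orders of magnitude below it.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    lam_max = float(np.abs(X.T @ (y - y.mean())).max())
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * 10.0 ** -decades, n_points)


def default_grid(method: str, n_features: int) -> dict[str, list | None]:
    """Per-method default hyperparameter grids.

    There is no canonical grid for this design, so these are conventional
    choices: a data-driven lambda path for the lasso (resolved at tune
    time), decade-spaced costs for the SVMs, radial widths scaled by the
    feature count, odd neighbourhood sizes to 25, and feature-subset sizes
    bracketing sqrt(m) for the forest (B is fixed at 500).
    """
    m = n_features
    root = int(np.ceil(np.sqrt(m)))
    if method == "lasso":
        return {"lam": None}  # resolved from the training data at tune time
    if method == "svm_linear":
        return {"C": [0.01, 0.1, 1.0, 10.0, 100.0]}
    if method == "svm_radial":
        return {"C": [0.01, 0.1, 1.0, 10.0, 100.0],
                "gamma": [0.1 / m, 1.0 / m, 10.0 / m]}
    if method == "knn":
        return {"K": list(range(1, 26, 2))}
    if method == "rf":
        return {"s": sorted({max(1, int(np.ceil(root / 2))), root,
                             min(m, 2 * root)})}
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


@dataclass
class ModelSpec:
    """A method identity plus its hyperparameter grid."""

    method: str
    grid: dict[str, list | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        allowed = {"lasso": {"lam"}, "svm_linear": {"C"},
                   "svm_radial": {"C", "gamma"}, "knn": {"K"},
                   "rf": {"s", "B"}}[self.method]
        extra = set(self.grid) - allowed
        if extra:
            raise ValueError(f"grid keys {sorted(extra)} not valid for {self.method}")
        for key, vals in self.grid.items():
            if vals is None:
                continue
            for v in vals:
                if v <= 0:
                    raise ValueError(f"grid values for {key} must be positive")
                if key == "K" and int(v) % 2 == 0:
                    raise ValueError("K grid values must be odd")

    def resolved_grid(self, X, y) -> list[dict[str, Any]]:
        """Materialise the grid as an ordered list of parameter dicts."""
        grid = dict(self.grid) if self.grid else default_grid(self.method,
                                                              X.shape[1])
        if self.method == "lasso" and grid.get("lam") is None:
            grid["lam"] = list(lasso_lambda_path(X, y))
        keys = list(grid)
        combos = itertools.product(*(grid[k] for k in keys))
        return [dict(zip(keys, combo)) for combo in combos]


def make_model(method: str, params: dict[str, Any], seed: int = 0):
    """Instantiate an unfitted classifier for one grid point."""
    if method == "lasso":
        return LassoLogistic(lam=params["lam"])
    if method == "svm_linear":
        return SVMClassifier("linear", C=params["C"])
    if method == "svm_radial":
        return SVMClassifier("radial", C=params["C"], gamma=params["gamma"])
    if method == "knn":
        return KNNClassifier(K=int(params["K"]))
    if method == "rf":
        return RandomForest(B=int(params.get("B", 500)), s=int(params["s"]),
                            seed=seed)
    raise ValueError(f"unknown method {method!r}")


@dataclass
class TunedModel:
    """A fitted classifier with its selected hyperparameters and CV record."""

    method: str
    params: dict[str, Any]
    model: Any
    cv_balanced_accuracy: float
    cv_table: pd.DataFrame
    selection_criterion: str = "max mean validation balanced accuracy"

    def predict(self, X) -> np.ndarray:
        return self.model.predict(X)


def tune(spec: ModelSpec, X, y, folds: int = 10, seed: int = 0) -> TunedModel:
    """Grid search by stratified k-fold CV on balanced accuracy.

    Folds are stratified so every validation fold contains carriers (with
    ~4% prevalence, unstratified folding can produce carrier-free folds on
    which balanced accuracy is undefined). Ties between grid points go to
    the earlier point in grid order. A single-point grid skips CV and fits
    directly. The winning point is refit on all of ``(X, y)``.
    """
    X, y = _check_xy(X, y)
    grid_points = spec.resolved_grid(X, y)
    if len(grid_points) == 1:
        model = make_model(spec.method, grid_points[0], seed=seed).fit(X, y)
        return TunedModel(spec.method, grid_points[0], model, float("nan"),
                          pd.DataFrame(columns=["point", "params", "fold",
                                                "balanced_accuracy"]))
    if folds < 2:
        raise ValueError("folds must be >= 2")
    n_pos = int((y == 1).sum())
    if n_pos < folds:
        raise ValueError(
            f"stratification impossible: {n_pos} carriers < {folds} folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))

    rows = []
    scores = np.zeros(len(grid_points))
    for p, point in enumerate(grid_points):
        for f, (tr, va) in enumerate(splits):
            model = make_model(spec.method, point, seed=seed)
            model.fit(X[tr], y[tr])
            ba = balanced_accuracy(y[va], model.predict(X[va]))
            scores[p] += ba
            rows.append((p, json.dumps(point), f, ba))
    scores /= len(splits)
    best = int(np.argmax(scores))  # ties -> earliest grid point
    cv_table = pd.DataFrame(rows, columns=["point", "params", "fold",
                                           "balanced_accuracy"])
    model = make_model(spec.method, grid_points[best], seed=seed).fit(X, y)
    return TunedModel(spec.method, grid_points[best], model,
                      float(scores[best]), cv_table)
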
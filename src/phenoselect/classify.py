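"""The four classifier back-ends under a single train/predict contract.

LDA (pooled-covariance linear discriminant, equal priors), random forest
(``mtry`` features tried per split, default all selected traits), and
soft-margin SVMs with linear and radial-basis kernels.  SVM costs are
tuned over ``C in {2^0 .. 2^4}`` and the RBF width over
``gamma in {2^-8 .. 2^0}`` by inner stratified cross-validation on the
training partition only; LDA needs no tuning.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy import linalg
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ConfigurationError, LabelError, SchemaError
from .table import TraitTable

__all__ = [
    "METHODS",
    "ClassifierSpec",
    "FittedModel",
    "tune_hyperparameters",
    "fit",
    "fit_arrays",
    "predict",
    "predict_arrays",
]

METHODS = ("lda", "rf", "svm_l", "svm_r")

DEFAULT_C_GRID = tuple(2.0**k for k in range(0, 5))  # 2^0 .. 2^4
DEFAULT_GAMMA_GRID = tuple(2.0**k for k in range(-8, 1))  # 2^-8 .. 2^0


@dataclass
class ClassifierSpec:
    """One classification method plus its hyperparameter grid and policy.

    ``mtry`` is the number of features examined at each random-forest
    split; ``None`` means "all selected traits" (the tuned value used
    throughout).  ``inner_cv`` sets the stratified fold count of the grid
    search; ``standardize`` z-scores features inside the SVM pipelines
    using training statistics only.
    """

    method: str
    C_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    mtry: int | None = None
    n_trees: int = 500
    inner_cv: int = 5
    standardize: bool = True
    lda_ridge: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ConfigurationError(
                f"method must be one of {METHODS}, got {self.method!r}"
            )
        if self.method in ("svm_l", "svm_r") and not self.C_grid:
            raise ConfigurationError("C_grid must be non-empty for SVM methods")
        if self.method == "svm_r" and not self.gamma_grid:
            raise ConfigurationError("gamma_grid must be non-empty for svm_r")
        if self.n_trees < 1:
            raise ConfigurationError("n_trees must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ConfigurationError("mtry must be >= 1")

    def with_seed(self, seed: int) -> "ClassifierSpec":
        return replace(self, seed=int(seed))


@dataclass
class FittedModel:
    spec: ClassifierSpec
    estimator: Any
    trait_names: list[str]
    hyperparameters: dict[str, float]
    classes: np.ndarray
    train_seconds: float = 0.0


class _PooledCovLDA:
    """Classical LDA with an explicit ridge on the pooled covariance.

    Used only when ``lda_ridge > 0``; the default path is the standard
    SVD-based solver, which degrades exactly as classical LDA does when
    the trait count approaches the sample count.
    """

    def __init__(self, ridge: float):
        self.ridge = ridge

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        mus, covs, ns = [], [], []
        for c in self.classes_:
            xc = X[y == c]
            mus.append(xc.mean(axis=0))
            covs.append(np.cov(xc, rowvar=False, ddof=1) * (len(xc) - 1))
            ns.append(len(xc))
        pooled = sum(covs) / (sum(ns) - len(self.classes_))
        pooled = pooled + self.ridge * np.eye(X.shape[1])
        self.means_ = np.asarray(mus)
        self._w = linalg.solve(pooled, (self.means_[1] - self.means_[0]), assume_a="pos")
        self._b = -0.5 * float((self.means_[0] + self.means_[1]) @ self._w)
        return self

    def predict(self, X):
        score = X @ self._w + self._b
        return np.where(score > 0, self.classes_[1], self.classes_[0])


def _build_estimator(spec: ClassifierSpec, hyper: dict[str, float], n_traits: int):
    if spec.method == "lda":
        if spec.lda_ridge > 0:
            return _PooledCovLDA(spec.lda_ridge)
        return LinearDiscriminantAnalysis(solver="svd", priors=[0.5, 0.5])
    if spec.method == "rf":
        mtry = spec.mtry if spec.mtry is not None else n_traits
        if mtry > n_traits:
            raise ConfigurationError(f"mtry = {mtry} exceeds trait count {n_traits}")
        return RandomForestClassifier(
            n_estimators=spec.n_trees,
            max_features=mtry,
            random_state=spec.seed % 2**31,
            n_jobs=1,
        )
    if spec.method == "svm_l":
        svc = SVC(kernel="linear", C=hyper.get("C", 1.0))
    else:
        svc = SVC(
            kernel="rbf", C=hyper.get("C", 1.0), gamma=hyper.get("gamma", 1.0)
        )
    if spec.standardize:
        return Pipeline([("scale", StandardScaler()), ("svm", svc)])
    return svc


def _grid_points(spec: ClassifierSpec) -> list[dict[str, float]]:
    if spec.method == "svm_l":
        return [{"C": c} for c in sorted(spec.C_grid)]
    if spec.method == "svm_r":
        return [
            {"C": c, "gamma": g}
            for c in sorted(spec.C_grid)
            for g in sorted(spec.gamma_grid)
        ]
    return [{}]


def tune_hyperparameters(spec: ClassifierSpec, X, y) -> dict[str, float]:
    """Grid search by inner stratified CV on the training data only.

    Returns the grid point with the highest mean inner accuracy; exact
    ties resolve toward smaller C, then smaller gamma.  LDA and RF use no
    grid (RF's ``mtry`` is fixed to the selected trait count) and return
    an empty setting; singleton grids short-circuit without inner CV.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    points = _grid_points(spec)
    if len(points) <= 1:
        return points[0] if points else {}
    _check_two_classes(y)
    k = min(spec.inner_cv, int(np.bincount(_encode(y)).min()))
    if k < 2:
        return points[0]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=spec.seed % 2**31)
    splits = list(skf.split(X, y))
    best: dict[str, float] | None = None
    best_acc = -1.0
    for point in points:  # ascending (C, gamma): first max = smallest tie
        accs = []
        for tr, te in splits:
            est = _build_estimator(spec, point, X.shape[1])
            est.fit(X[tr], y[tr])
            accs.append(float(np.mean(est.predict(X[te]) == y[te])))
        acc = float(np.mean(accs))
        if acc > best_acc + 1e-12:
            best_acc = acc
            best = point
    assert best is not None
    return best


def _encode(y: np.ndarray) -> np.ndarray:
    classes = np.unique(y)
    return np.searchsorted(classes, y)


def _check_two_classes(y: np.ndarray) -> None:
    classes = np.unique(y)
    if len(classes) != 2:
        raise LabelError(
            f"binary labels required, got {len(classes)} class(es): "
            f"{classes.tolist()}"
        )


def fit_arrays(
    spec: ClassifierSpec, X, y, trait_names: list[str]
) -> FittedModel:
    """Tune (if the method has a grid), then fit on the full training set."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_two_classes(y)
    if np.bincount(_encode(y)).min() < 2:
        raise LabelError("need at least 2 samples per class")
    t0 = time.perf_counter()
    hyper = tune_hyperparameters(spec, X, y)
    est = _build_estimator(spec, hyper, X.shape[1])
    est.fit(X, y)
    return FittedModel(
        spec=spec,
        estimator=est,
        trait_names=list(trait_names),
        hyperparameters=hyper,
        classes=np.unique(y),
        train_seconds=time.perf_counter() - t0,
    )


def fit(spec: ClassifierSpec, table: TraitTable) -> FittedModel:
    """Tune and fit the method of ``spec`` on a labeled trait table."""
    return fit_arrays(spec, table.values, table.labels, table.trait_names)


def predict_arrays(model: FittedModel, X) -> np.ndarray:
    return np.asarray(model.estimator.predict(np.asarray(X, dtype=float)))


def predict(model: FittedModel, table: TraitTable) -> np.ndarray:
    """Predict class labels, aligning the table's columns by trait name."""
    missing = [t for t in model.trait_names if t not in table.trait_names]
    if missing:
        raise SchemaError(f"table lacks traits required by the model: {missing}")
    aligned = table.subset_traits(model.trait_names)
    return predict_arrays(model, aligned.values)
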
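"""Classifier families and leave-one-out cross-validation.

Five families are compared for ordinal severity scoring: decision tree,
SVM (linear / polynomial / RBF kernels), discriminant analysis, random
forest, and k-nearest neighbours with odd k from 1 to 11 (odd to avoid
voting ties).  With 131 recordings and only two of the most severe class,
leave-one-out cross-validation (LOOCV) is the evaluation protocol: each
recording is predicted by a model trained on all the others.

Feature reduction (pairwise ordering or PCA) is fitted inside each training
fold by default, so the held-out recording contributes nothing to the
selection; the optimistic fit-on-all variant is available via
``fit_on_all=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .selection import pairwise_order, pca_fit_project, select_top

__all__ = ["ClassifierSpec", "LoocvResult", "build_estimator", "loocv", "grid_search"]

FAMILIES = ("decision_tree", "svm", "discriminant", "random_forest", "knn")
SVM_KERNELS = ("linear", "polynomial", "rbf")
KNN_KS = (1, 3, 5, 7, 9, 11)

#: families whose notion of distance/covariance needs comparable scales
_SCALE_SENSITIVE = ("svm", "knn", "discriminant")


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier configuration (family + kernel/k + seed + overrides)."""

    family: str
    kernel: str | None = None
    k: int | None = None
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.family == "svm":
            if self.kernel not in SVM_KERNELS:
                raise ValueError(f"svm kernel must be one of {SVM_KERNELS}, got {self.kernel!r}")
        elif self.kernel is not None:
            raise ValueError("kernel applies only to the svm family")
        if self.family == "knn":
            if self.k not in KNN_KS:
                raise ValueError(f"knn k must be odd in 1..11, got {self.k!r}")
        elif self.k is not None:
            raise ValueError("k applies only to the knn family")

    @property
    def name(self) -> str:
        if self.family == "svm":
            return f"svm_{self.kernel}"
        if self.family == "knn":
            return f"knn_k{self.k}"
        return self.family


def build_estimator(spec: ClassifierSpec):
    """Instantiate the scikit-learn estimator for a spec.

    Scale-sensitive families (SVM, kNN, discriminant analysis) get a
    fold-internal z-scoring step; trees and forests consume raw features.
    ``params={"scale": False}`` disables the z-scoring step.
    """
    p = dict(spec.params)
    scale = p.pop("scale", True)
    if spec.family == "decision_tree":
        est = DecisionTreeClassifier(
            criterion=p.pop("criterion", "gini"),
            max_depth=p.pop("max_depth", None),
            min_samples_leaf=p.pop("min_samples_leaf", 1),
            random_state=spec.seed,
            **p,
        )
    elif spec.family == "random_forest":
        est = RandomForestClassifier(
            n_estimators=p.pop("n_estimators", 100), random_state=spec.seed, **p
        )
    elif spec.family == "svm":
        kernel = {"polynomial": "poly"}.get(spec.kernel, spec.kernel)
        est = SVC(
            kernel=kernel,
            C=p.pop("C", 1.0),
            degree=p.pop("degree", 3),
            gamma=p.pop("gamma", "scale"),
            random_state=spec.seed,
            **p,
        )
    elif spec.family == "discriminant":
        variant = p.pop("variant", "linear")
        if variant == "linear":
            est = LinearDiscriminantAnalysis(**p)
        elif variant == "quadratic":
            est = QuadraticDiscriminantAnalysis(**p)
        else:
            raise ValueError(f"discriminant variant must be 'linear' or 'quadratic', got {variant!r}")
    elif spec.family == "knn":
        est = KNeighborsClassifier(n_neighbors=spec.k, metric="euclidean", weights="uniform", **p)
    else:  # pragma: no cover - guarded by ClassifierSpec
        raise ValueError(spec.family)
    if scale and spec.family in _SCALE_SENSITIVE:
        est = make_pipeline(StandardScaler(), est)
    return est


@dataclass
class LoocvResult:
    """Per-sample LOOCV predictions with their ground truth."""

    y_true: np.ndarray
    y_pred: np.ndarray
    spec: ClassifierSpec
    selection: dict | None = None

    @property
    def accuracy(self) -> float:
        return float((self.y_true == self.y_pred).mean())


def _reduce_fold(
    X_train: pd.DataFrame, X_test: pd.DataFrame, selection: dict | None
) -> tuple[np.ndarray, np.ndarray]:
    if not selection or selection.get("method") in (None, "none"):
        return X_train.to_numpy(dtype=float), X_test.to_numpy(dtype=float)
    method = selection["method"]
    if method == "pairwise":
        order = pairwise_order(X_train, extension=selection.get("extension", "minimax"))
        names = select_top(order, min(selection["n_features"], len(order)))
        return (
            X_train.loc[:, names].to_numpy(dtype=float),
            X_test.loc[:, names].to_numpy(dtype=float),
        )
    if method == "pca":
        proj = pca_fit_project(X_train, selection["n_components"])
        return proj.coords, proj.transform(X_test)
    raise ValueError(f"unknown selection method {method!r}")


def loocv(
    spec: ClassifierSpec,
    X: pd.DataFrame,
    y,
    selection: dict | None = None,
    fit_on_all: bool = False,
) -> LoocvResult:
    """Leave-one-out predictions for one classifier configuration.

    ``selection`` is e.g. ``{"method": "pairwise", "n_features": 5}`` or
    ``{"method": "pca", "n_components": 2}``; by default it is refitted on
    each training fold.  Deterministic given ``spec.seed``.
    """
    y = np.asarray(y, dtype=int)
    n = len(y)
    if n < 2:
        raise ValueError("LOOCV needs at least 2 samples")
    if X.shape[0] != n:
        raise ValueError(f"X has {X.shape[0]} rows but y has {n} labels")
    if not np.isfinite(X.to_numpy(dtype=float)).all():
        raise ValueError("feature matrix contains non-finite values")

    if fit_on_all and selection:
        method = selection.get("method")
        if method == "pairwise":
            order = pairwise_order(X, extension=selection.get("extension", "minimax"))
            names = select_top(order, min(selection["n_features"], len(order)))
            X = X.loc[:, names]
            selection = None
        elif method == "pca":
            proj = pca_fit_project(X, selection["n_components"])
            X = pd.DataFrame(proj.coords, index=X.index)
            selection = None

    preds = np.empty(n, dtype=int)
    idx = np.arange(n)
    for i in range(n):
        train = idx != i
        Xtr, Xte = _reduce_fold(X.iloc[train], X.iloc[[i]], selection)
        est = build_estimator(spec)
        est.fit(Xtr, y[train])
        preds[i] = int(est.predict(Xte)[0])
    return LoocvResult(y_true=y, y_pred=preds, spec=spec, selection=selection)


def default_grid(seed: int = 0) -> list[ClassifierSpec]:
    """The full classifier comparison grid (9 configurations)."""
    specs = [
        ClassifierSpec("decision_tree", seed=seed),
        ClassifierSpec("discriminant", seed=seed),
        ClassifierSpec("random_forest", seed=seed),
    ]
    specs += [ClassifierSpec("svm", kernel=k, seed=seed) for k in SVM_KERNELS]
    specs += [ClassifierSpec("knn", k=k, seed=seed) for k in KNN_KS]
    return specs


def grid_search(
    specs: list[ClassifierSpec],
    X: pd.DataFrame,
    y,
    selection_method: str = "pairwise",
    dims: list[int] | None = None,
    fit_on_all: bool = False,
) -> pd.DataFrame:
    """LOOCV accuracy over classifier x feature-dimension combinations.

    Returns one row per (spec, d) ranked by accuracy (ties by classifier
    name then smaller d), mirroring the optimized-configuration comparison:
    for each classifier the best d is the row with rank 0 for that name.
    """
    if not specs:
        raise ValueError("empty classifier grid")
    y = np.asarray(y, dtype=int)
    if dims is None:
        dims = list(range(1, X.shape[1] + 1))
    rows = []
    for spec in specs:
        for d in dims:
            if selection_method == "pairwise":
                sel = {"method": "pairwise", "n_features": d}
            elif selection_method == "pca":
                sel = {"method": "pca", "n_components": d}
            elif selection_method in (None, "none"):
                sel = None
            else:
                raise ValueError(f"unknown selection method {selection_method!r}")
            res = loocv(spec, X, y, selection=sel, fit_on_all=fit_on_all)
            rows.append(
                {
                    "classifier": spec.name,
                    "selection": selection_method or "none",
                    "d": d,
                    "accuracy": res.accuracy,
                }
            )
            if sel is None:
                break
    table = pd.DataFrame(rows)
    return table.sort_values(
        ["accuracy", "classifier", "d"], ascending=[False, True, True]
    ).reset_index(drop=True)
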
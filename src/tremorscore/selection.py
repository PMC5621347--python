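"""Dimensionality reduction: pairwise-correlation ordering and PCA.

The pairwise strategy orders the 76 features "most unrelated first": the
first two features are the pair with the smallest absolute Pearson
correlation among all pairs, and each subsequent feature is the one whose
strongest absolute correlation against the already-selected set is weakest
(minimax; a mean-correlation variant is available).  Taking the first d
names of the order gives the d-dimensional feature configuration.

PCA is the alternative reduction: features are z-scored (they span
seconds, metres and log-power, so unstandardized PCA would be dominated by
a single unit) and projected onto the leading principal components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

__all__ = ["SelectionOrder", "PCAProjection", "pairwise_order", "select_top", "pca_fit_project"]


@dataclass
class SelectionOrder:
    """A permutation of the feature names with the |r| at which each entered
    (the first two share the minimal pair correlation)."""

    names: list[str]
    trace: np.ndarray

    def __len__(self) -> int:
        return len(self.names)


@dataclass
class PCAProjection:
    """Fitted, standardized PCA: loadings, variance fractions, coordinates."""

    components: np.ndarray  # (n_components, n_features) orthonormal rows
    explained_variance_ratio: np.ndarray
    coords: np.ndarray  # training data projected, (n_samples, n_components)
    feature_names: list[str]
    _scaler: StandardScaler
    _pca: PCA

    def transform(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Project held-out rows with the training-fold scaler and loadings."""
        if isinstance(X, pd.DataFrame):
            X = X.loc[:, self.feature_names].to_numpy(dtype=float)
        return self._pca.transform(self._scaler.transform(X))


def _abs_corr(X: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        c = np.abs(np.corrcoef(X, rowvar=False))
    np.fill_diagonal(c, 0.0)
    return c


def pairwise_order(X: pd.DataFrame, extension: str = "minimax") -> SelectionOrder:
    """Order features from least to most correlated (greedy).

    Correlations are taken in absolute value: a feature with r = -0.9 to a
    selected one is highly related, not unrelated.  Ties break by canonical
    column order.  Constant features have undefined correlation and are
    excluded with a warning.
    """
    if extension not in ("minimax", "mean"):
        raise ValueError(f"extension must be 'minimax' or 'mean', got {extension!r}")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples to order features by correlation")
    names = list(X.columns)
    arr = X.to_numpy(dtype=float)
    stds = arr.std(axis=0)
    usable = [i for i in range(len(names)) if stds[i] > 0]
    dropped = [names[i] for i in range(len(names)) if stds[i] == 0]
    if dropped:
        warnings.warn(f"constant features excluded from ordering: {dropped}", stacklevel=2)
    if len(usable) < 2:
        raise ValueError("fewer than 2 non-constant features")
    arr = arr[:, usable]
    sub_names = [names[i] for i in usable]
    c = _abs_corr(arr)
    p = len(sub_names)

    # seed pair: minimal |r| over all pairs, ties by canonical (i, j)
    best = (np.inf, 0, 1)
    for i in range(p):
        for j in range(i + 1, p):
            if c[i, j] < best[0]:
                best = (c[i, j], i, j)
    r0, i0, j0 = best
    selected = [i0, j0]
    trace = [r0, r0]
    remaining = [k for k in range(p) if k not in (i0, j0)]

    while remaining:
        scores = []
        for k in remaining:
            against = c[k, selected]
            scores.append(against.max() if extension == "minimax" else against.mean())
        k_best = remaining[int(np.argmin(scores))]  # argmin keeps first on ties
        selected.append(k_best)
        trace.append(float(min(scores)))
        remaining.remove(k_best)

    return SelectionOrder(names=[sub_names[k] for k in selected], trace=np.array(trace))


def select_top(order: SelectionOrder, d: int) -> list[str]:
    """First d feature names of the order (prefix-consistent in d)."""
    if not 1 <= d <= len(order):
        raise ValueError(f"d must be in [1, {len(order)}], got {d}")
    return order.names[:d]


def pca_fit_project(X: pd.DataFrame, n_components: int, standardize: bool = True) -> PCAProjection:
    """Fit PCA on (by default z-scored) features and project the training rows.

    ``standardize=False`` skips the z-scoring (centering only), recovering
    plain PCA and its rotation invariance.
    """
    n, p = X.shape
    if not 1 <= n_components <= min(n, p):
        raise ValueError(f"n_components must be in [1, {min(n, p)}], got {n_components}")
    arr = X.to_numpy(dtype=float)
    scaler = StandardScaler(with_std=standardize).fit(arr)
    pca = PCA(n_components=n_components).fit(scaler.transform(arr))
    coords = pca.transform(scaler.transform(arr))
    return PCAProjection(
        components=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        coords=coords,
        feature_names=list(X.columns),
        _scaler=scaler,
        _pca=pca,
    )
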
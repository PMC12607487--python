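"""Unsupervised structure: hierarchical clustering and PCA.

Hierarchical clustering (average linkage, Euclidean distance by default)
is applied to both samples and features of the z-scored abundance table and
reported as merge tables plus leaf orders — the data behind a clustered
heatmap. PCA is computed from scratch via SVD of the centered (optionally
autoscaled) samples x features matrix, with explained-variance bookkeeping
and a deterministic sign convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .data_model import AbundanceTable, SampleClasses
from .preprocessing import autoscale, zscore

_METHODS = ("average", "complete", "single", "ward")


@dataclass
class LinkageTree:
    """Agglomeration result for one axis.

    ``merges`` holds one (node_a, node_b, height, size) record per merge in
    scipy convention: leaves are 0..n-1, merge i creates node n+i.
    """

    merges: list[tuple[int, int, float, int]]
    leaf_order: list[int]
    items: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.items)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.merges, columns=["node_a", "node_b", "height", "size"])

    def ordered_items(self) -> list[str]:
        return [self.items[i] for i in self.leaf_order]


def _linkage_tree(matrix: np.ndarray, items: list[str], metric: str, method: str) -> LinkageTree:
    Z = linkage(matrix, method=method, metric=metric)
    merges = [(int(a), int(b), float(h), int(s)) for a, b, h, s in Z]
    return LinkageTree(merges=merges, leaf_order=[int(i) for i in leaves_list(Z)], items=items)


def hca(
    table: AbundanceTable,
    metric: str = "euclidean",
    method: str = "average",
    cluster_axes: str = "both",
):
    """Hierarchically cluster samples and/or features of a table.

    The caller applies z-scoring first when emulating a standardized
    clustered heatmap. Returns ``(samples_tree, features_tree)``; an axis
    not requested is ``None``.
    """
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}, got {method!r}")
    if cluster_axes not in ("samples", "features", "both"):
        raise ValueError(f"bad cluster_axes {cluster_axes!r}")
    values = table.values
    if not np.all(np.isfinite(values)):
        raise ValueError("NaN or infinite value in clustering input")
    samples_tree = features_tree = None
    if cluster_axes in ("samples", "both"):
        if table.n_samples < 2:
            raise ValueError("need at least two samples to cluster")
        samples_tree = _linkage_tree(values.T, table.sample_ids, metric, method)
    if cluster_axes in ("features", "both"):
        if table.n_features < 2:
            raise ValueError("need at least two features to cluster")
        features_tree = _linkage_tree(values, table.feature_ids, metric, method)
    return samples_tree, features_tree


@dataclass
class PCAResult:
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # features x components, orthonormal columns
    explained_variance_ratio: np.ndarray
    cumulative_variance: float


class PCA(TransformerMixin, BaseEstimator):
    """Principal component analysis via SVD of the centered/scaled matrix.

    Parameters
    ----------
    n_components : int
        Number of components, at most min(n_samples - 1, n_features).
    scale : bool
        If True (default), autoscale columns (ddof=1) before the SVD; the
        PCA then operates on the correlation structure, appropriate for
        features on different abundance scales.

    The sign of each component is fixed so that its largest-magnitude
    loading entry is positive, making scores and loadings reproducible.
    """

    def __init__(self, n_components: int = 2, scale: bool = True):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y=None):
        X = check_array(X, dtype=float, ensure_min_samples=2)
        n, p = X.shape
        limit = min(n - 1, p)
        if not 1 <= self.n_components <= limit:
            raise ValueError(
                f"n_components must be in [1, {limit}] for a {n}x{p} matrix, "
                f"got {self.n_components}"
            )
        if self.scale:
            Xc, self.center_, self.scale_ = autoscale(X)
        else:
            self.center_ = X.mean(axis=0)
            self.scale_ = np.ones(p)
            Xc = X - self.center_
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        total = (s**2).sum()
        loadings = Vt[: self.n_components].T.copy()
        for a in range(loadings.shape[1]):
            j = int(np.argmax(np.abs(loadings[:, a])))
            if loadings[j, a] < 0:
                loadings[:, a] *= -1
        self.loadings_ = loadings
        self.components_ = loadings.T
        self.singular_values_ = s[: self.n_components]
        self.explained_variance_ratio_ = s[: self.n_components] ** 2 / total
        self.all_explained_variance_ratio_ = s**2 / total
        self.cumulative_variance_ = float(self.explained_variance_ratio_.sum())
        self.scores_ = Xc @ loadings
        self.n_features_in_ = p
        return self

    def transform(self, X):
        check_is_fitted(self, "loadings_")
        X = check_array(X, dtype=float)
        return ((X - self.center_) / self.scale_) @ self.loadings_


def pca(matrix, n_components: int, scale: bool = True) -> PCAResult:
    """Functional wrapper over :class:`PCA` for a samples x features matrix."""
    est = PCA(n_components=n_components, scale=scale).fit(matrix)
    return PCAResult(
        scores=est.scores_,
        loadings=est.loadings_,
        explained_variance_ratio=est.explained_variance_ratio_,
        cumulative_variance=est.cumulative_variance_,
    )


def top_discriminative_features(table: AbundanceTable, classes: SampleClasses) -> pd.DataFrame:
    """Rank features by absolute difference of class-mean z-scores.

    Ties are broken alphabetically by feature name. Returns a DataFrame with
    columns ``feature`` and ``score``, best first.
    """
    y = classes.label_vector(table.sample_ids)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to rank discriminative features")
    z = zscore(table).values
    diff = np.abs(z[:, y == 0].mean(axis=1) - z[:, y == 1].mean(axis=1))
    order = sorted(zip(table.feature_ids, diff), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(order, columns=["feature", "score"])
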
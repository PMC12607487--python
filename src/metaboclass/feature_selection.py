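"""Correlation-based feature reduction.

Highly correlated metabolites carry redundant information for
discrimination. The Pearson correlation matrix of the (already
cutoff-filtered) features is thresholded on |r| and its connected
components form correlation clusters; one representative per cluster is
kept, by default the feature with the highest mean abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .data_model import AbundanceTable

_CRITERIA = ("max_mean_abundance", "max_vip")


def pearson_matrix(table: AbundanceTable) -> pd.DataFrame:
    """Pearson correlation between feature rows (n-1 convention).

    r_ij = cov(x_i, x_j) / (s_i s_j); the diagonal is exactly 1.
    """
    values = table.values
    if values.shape[1] < 3:
        raise ValueError("Pearson correlation needs at least 3 samples")
    sd = values.std(axis=1, ddof=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = ", ".join(table.feature_ids[i] for i in dead)
        raise ValueError(f"zero-variance feature(s): {names}")
    r = np.corrcoef(values)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=table.feature_ids, columns=table.feature_ids)


@dataclass
class CorrelationClusters:
    """Partition of features into |r|-threshold connected components."""

    correlation: pd.DataFrame
    clusters: list[list[str]]
    threshold: float
    representatives: list[str] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def correlation_clusters(correlation: pd.DataFrame, threshold: float = 0.7) -> CorrelationClusters:
    """Connected components of the graph with an edge where |r_ij| >= threshold.

    Clusters are ordered by their smallest member index in the correlation
    matrix, making the partition deterministic.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    r = np.asarray(correlation, dtype=float)
    if r.shape[0] != r.shape[1]:
        raise ValueError("correlation matrix must be square")
    adjacency = (np.abs(r) >= threshold).astype(int)
    n_comp, labels = connected_components(adjacency, directed=False)
    names = list(correlation.index)
    groups: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(i)
    ordered = sorted(groups.values(), key=lambda members: members[0])
    clusters = [[names[i] for i in members] for members in ordered]
    return CorrelationClusters(correlation=correlation, clusters=clusters, threshold=threshold)


def select_representatives(
    clusters: CorrelationClusters,
    table: AbundanceTable,
    criterion: str = "max_mean_abundance",
    vip=None,
    n_select: int | None = None,
) -> list[str]:
    """Pick one representative feature per cluster and keep the top n_select.

    The representative maximises the criterion within its cluster (mean
    abundance across samples, or VIP score when a fitted PLS-DA model
    provides one); clusters are then ranked by their representative's
    criterion value. Ties break alphabetically.
    """
    if criterion not in _CRITERIA:
        raise ValueError(f"criterion must be one of {_CRITERIA}, got {criterion!r}")
    if criterion == "max_vip" and vip is None:
        raise ValueError("criterion 'max_vip' requires a VIP vector")
    n_select = clusters.n_clusters if n_select is None else n_select
    if n_select > clusters.n_clusters:
        raise ValueError(
            f"n_select={n_select} exceeds the {clusters.n_clusters} clusters available"
        )
    if criterion == "max_mean_abundance":
        score = dict(zip(table.feature_ids, table.values.mean(axis=1)))
    else:
        score = dict(vip) if not hasattr(vip, "scores") else dict(vip.scores)
    reps = []
    for members in clusters.clusters:
        best = min(members, key=lambda f: (-score[f], f))
        reps.append((best, score[best]))
    reps.sort(key=lambda kv: (-kv[1], kv[0]))
    selected = [name for name, _ in reps[:n_select]]
    clusters.representatives = selected
    return selected


class CorrelationClusterSelector(SelectorMixin, BaseEstimator):
    """sklearn selector: correlation clustering + representative picking.

    Operates on a samples x features matrix; ``get_support()`` marks the
    selected representatives.
    """

    def __init__(self, threshold: float = 0.7, n_select: int | None = None):
        self.threshold = threshold
        self.n_select = n_select

    def fit(self, X, y=None):
        X = check_array(X, dtype=float, ensure_min_samples=3)
        names = [str(i) for i in range(X.shape[1])]
        table = AbundanceTable(
            pd.DataFrame(X.T, index=names, columns=[f"s{i}" for i in range(X.shape[0])]),
            units="zscore",  # skip percent range checks; any numeric matrix is accepted
        )
        clusters = correlation_clusters(pearson_matrix(table), self.threshold)
        selected = select_representatives(clusters, table, n_select=self.n_select)
        self.clusters_ = clusters
        self.support_ = np.array([name in selected for name in names])
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_
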
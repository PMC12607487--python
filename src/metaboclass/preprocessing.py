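"""Abundance-cutoff filtering and standardization.

Minor GC/MS peaks act as noise in downstream clustering and classification;
the cutoff filter keeps only "major" metabolites, by default any feature
reaching at least 10% relative abundance in at least one sample.
Standardization comes in two flavours used at different stages: per-feature
z-scoring of the features x samples table (heatmap/HCA input) and
column autoscaling of a samples x features matrix (PCA / PLS-DA input),
both with the n-1 standard-deviation convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .data_model import AbundanceTable

_RULES = ("any_sample", "all_samples", "mean")


@dataclass
class CutoffConfig:
    """Relative-abundance cutoff settings (percent units)."""

    threshold: float = 10.0
    rule: str = "any_sample"
    inclusive: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 100:
            raise ValueError(f"threshold must be in (0, 100), got {self.threshold}")
        if self.rule not in _RULES:
            raise ValueError(f"rule must be one of {_RULES}, got {self.rule!r}")


class CutoffFilter(SelectorMixin, BaseEstimator):
    """Select features whose relative abundance passes a percent cutoff.

    Operates on a samples x features matrix (sklearn orientation). With the
    default ``rule="any_sample"`` a feature is retained iff its maximum
    abundance across samples is >= ``threshold`` (inclusive boundary).

    Attributes
    ----------
    support_ : ndarray of bool, shape (n_features,)
        Mask of retained features.
    criterion_values_ : ndarray, shape (n_features,)
        The per-feature statistic (max/min/mean abundance) compared with the
        threshold.
    """

    def __init__(self, threshold: float = 10.0, rule: str = "any_sample", inclusive: bool = True):
        self.threshold = threshold
        self.rule = rule
        self.inclusive = inclusive

    def fit(self, X, y=None):
        CutoffConfig(self.threshold, self.rule, self.inclusive)  # validate params
        X = check_array(X, dtype=float, ensure_min_samples=1)
        if self.rule == "any_sample":
            stat = X.max(axis=0)
        elif self.rule == "all_samples":
            stat = X.min(axis=0)
        else:
            stat = X.mean(axis=0)
        mask = stat >= self.threshold if self.inclusive else stat > self.threshold
        if not mask.any():
            raise ValueError("empty table after cutoff")
        self.n_features_in_ = X.shape[1]
        self.criterion_values_ = stat
        self.support_ = mask
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def cutoff_filter(table: AbundanceTable, config: CutoffConfig | None = None) -> AbundanceTable:
    """Apply the percent cutoff to an AbundanceTable (features x samples).

    Feature order is preserved; samples are untouched.
    """
    config = config or CutoffConfig()
    selector = CutoffFilter(config.threshold, config.rule, config.inclusive)
    selector.fit(table.values.T)
    kept = [f for f, keep in zip(table.feature_ids, selector.support_) if keep]
    return table.subset_features(kept)


def zscore(table: AbundanceTable) -> AbundanceTable:
    """Standardize each feature row to mean 0, sd 1 (ddof=1) across samples."""
    values = table.values
    if values.shape[1] < 2:
        raise ValueError("z-scoring needs at least two samples")
    sd = values.std(axis=1, ddof=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = ", ".join(table.feature_ids[i] for i in dead)
        raise ValueError(f"zero-variance feature(s): {names}")
    z = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    return AbundanceTable(
        pd.DataFrame(z, index=table.feature_ids, columns=table.sample_ids),
        units="zscore",
    )


def autoscale(matrix, fit_stats: tuple[np.ndarray, np.ndarray] | None = None):
    """Column-wise center/scale a samples x features matrix (ddof=1).

    When ``fit_stats`` (center, scale) is given — e.g. statistics from a
    cross-validation training fold — they are applied instead of being
    recomputed, so held-out samples never leak into the scaling.

    Returns
    -------
    (scaled, center, scale)
    """
    X = np.asarray(matrix, dtype=float)
    if fit_stats is not None:
        center, scale = (np.asarray(v, dtype=float) for v in fit_stats)
    else:
        center = X.mean(axis=0)
        scale = X.std(axis=0, ddof=1)
        if (scale == 0).any():
            j = int(np.flatnonzero(scale == 0)[0])
            raise ValueError(f"zero-variance column at index {j}")
    return (X - center) / scale, center, scale


class AutoScaler(BaseEstimator):
    """sklearn-style wrapper around :func:`autoscale` (ddof=1 convention)."""

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        _, self.center_, self.scale_ = autoscale(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "center_")
        X = check_array(X, dtype=float)
        return (X - self.center_) / self.scale_

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)
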
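"""Two-class PLS-DA with cross-validated and permutation-based validation.

The discriminant model is single-response PLS (PLS1) fitted by NIPALS on the
autoscaled feature matrix against a 0/1-coded class variable:

    for each component a = 1..A on the deflated matrix X_a (X_1 = X scaled):
        w_a = X_a' y / ||X_a' y||        (unit-norm weight)
        t_a = X_a w_a                    (score)
        p_a = X_a' t_a / (t_a' t_a)      (x-loading)
        q_a = y' t_a / (t_a' t_a)        (y-loading)
        X_{a+1} = X_a - t_a p_a'         (deflation; scores stay orthogonal)

Regression coefficients are b = W (P'W)^{-1} q, so ŷ = X_scaled b + ȳ.

Validation statistics follow the chemometric conventions:

* R² = 1 − SSE/SST on the training data, SSE = Σ(y_i − ŷ_i)²,
  SST = Σ(y_i − ȳ)².
* Q² = 1 − PRESS/TSS under stratified k-fold cross-validation (default
  k = 5). Scaling statistics and the baseline mean ȳ_train come from the
  training fold only, so Q² = 0 corresponds to the training-mean predictor
  and Q² < 0 to a model worse than that baseline.
* Permutation test: the class labels are shuffled uniformly at random
  n_runs times, Q² is recomputed per shuffle (fresh stratified folds), and
  p = #(Q²_perm ≥ Q²_observed) / n_runs.
* VIP (variable importance in projection), Wold's formula:
  VIP_j = sqrt( p · Σ_a SSY_a w_ja² / Σ_a SSY_a ) with
  SSY_a = q_a² t_a't_a the y-variance captured by component a. The mean of
  squared VIPs is 1, so VIP > 1 conventionally flags influential features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_X_y, check_array, check_is_fitted

from .data_model import SampleClasses
from .preprocessing import autoscale


# ---------------------------------------------------------------------------
# NIPALS core (operates on pre-scaled arrays; no validation overhead)
# ---------------------------------------------------------------------------

def _nipals_pls1(Xs: np.ndarray, yc: np.ndarray, n_components: int):
    """NIPALS PLS1 on a column-scaled X and centered y.

    Returns (W, P, q, T): weights (p x A, unit columns), x-loadings (p x A),
    y-loadings (A,), x-scores (n x A).
    """
    n, p = Xs.shape
    W = np.empty((p, n_components))
    P = np.empty((p, n_components))
    q = np.empty(n_components)
    T = np.empty((n, n_components))
    Xd = Xs.copy()
    yd = yc.astype(float).copy()
    for a in range(n_components):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            raise ValueError(
                f"X carries no further covariance with y at component {a + 1}; "
                f"reduce n_components"
            )
        w /= norm
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-12:
            raise ValueError(f"degenerate score vector at component {a + 1}")
        pa = Xd.T @ t / tt
        qa = float(yd @ t) / tt
        W[:, a], P[:, a], q[a], T[:, a] = w, pa, qa, t
        Xd -= np.outer(t, pa)
        yd -= qa * t
    return W, P, q, T


def _coefficients(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    return W @ np.linalg.solve(P.T @ W, q)


def _fit_predict_raw(X_train, y_train, X_test, n_components):
    """Scale-on-train fit + held-out prediction, for cross-validation loops."""
    Xs, center, scale = autoscale(X_train)
    ybar = y_train.mean()
    W, P, q, _ = _nipals_pls1(Xs, y_train - ybar, n_components)
    coef = _coefficients(W, P, q)
    return ((X_test - center) / scale) @ coef + ybar, ybar


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class PLSDAClassifier(ClassifierMixin, BaseEstimator):
    """Two-class PLS-DA (NIPALS PLS1, autoscaled X, 0/1-coded response).

    Parameters
    ----------
    n_components : int, default 2
        Number of latent variables; at most min(n_samples - 1, n_features).
    class_threshold : float, default 0.5
        Decision cut on the predicted continuous response under 0/1 coding.

    Attributes
    ----------
    classes_ : ndarray, shape (2,)
        Sorted class labels; ``classes_[1]`` is coded as 1.
    weights_ : ndarray (n_features, n_components)
        Unit-norm NIPALS weight vectors W.
    x_loadings_, y_loadings_, x_scores_ : P, q, T of the factorization.
    coef_ : regression coefficients on the scaled X.
    x_mean_, x_std_, y_mean_ : scaling/centering statistics.
    y_fitted_ : fitted continuous response on the training data.
    """

    def __init__(self, n_components: int = 2, class_threshold: float = 0.5):
        self.n_components = n_components
        self.class_threshold = class_threshold

    def fit(self, X, y):
        columns = getattr(X, "columns", None)
        X, y = check_X_y(X, y, dtype=None)
        X = np.asarray(X, dtype=float)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(
                f"PLS-DA needs exactly two classes, got {len(self.classes_)}"
            )
        y01 = (y == self.classes_[1]).astype(float)
        n, p = X.shape
        limit = min(n - 1, p)
        if not 1 <= self.n_components <= limit:
            raise ValueError(
                f"n_components must be in [1, {limit}] for a {n}x{p} matrix, "
                f"got {self.n_components}"
            )
        Xs, self.x_mean_, self.x_std_ = autoscale(X)
        self.y_mean_ = float(y01.mean())
        W, P, q, T = _nipals_pls1(Xs, y01 - self.y_mean_, self.n_components)
        self.weights_, self.x_loadings_, self.y_loadings_, self.x_scores_ = W, P, q, T
        self.coef_ = _coefficients(W, P, q)
        self.y_fitted_ = Xs @ self.coef_ + self.y_mean_
        self.n_features_in_ = p
        if columns is not None:
            self.feature_names_in_ = np.asarray(columns)
        return self

    def predict_value(self, X) -> np.ndarray:
        """Continuous predicted response ŷ on the 0/1 coding scale."""
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        return ((X - self.x_mean_) / self.x_std_) @ self.coef_ + self.y_mean_

    def decision_function(self, X) -> np.ndarray:
        return self.predict_value(X) - self.class_threshold

    def predict(self, X) -> np.ndarray:
        yhat = self.predict_value(X)
        return np.where(yhat >= self.class_threshold, self.classes_[1], self.classes_[0])

    def transform(self, X) -> np.ndarray:
        """Project samples onto the latent variables (via the rotation
        R = W (P'W)^{-1}, which accounts for deflation)."""
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        R = self.weights_ @ np.linalg.inv(self.x_loadings_.T @ self.weights_)
        return ((X - self.x_mean_) / self.x_std_) @ R

    def encode(self, y) -> np.ndarray:
        """Map labels to the model's 0/1 coding."""
        check_is_fitted(self, "classes_")
        y = np.asarray(y)
        known = np.isin(y, self.classes_)
        if not known.all():
            raise ValueError(f"unknown class label(s): {np.unique(y[~known])}")
        return (y == self.classes_[1]).astype(float)


def fit(X, y, n_components: int = 2) -> PLSDAClassifier:
    """Fit a two-class PLS-DA model (functional wrapper)."""
    return PLSDAClassifier(n_components=n_components).fit(X, y)


# ---------------------------------------------------------------------------
# Validation statistics
# ---------------------------------------------------------------------------

@dataclass
class FitStatistics:
    """Training goodness-of-fit: r2 = 1 - sse/sst."""

    r2: float
    sse: float
    sst: float


def r_squared(model: PLSDAClassifier, X, y) -> FitStatistics:
    """Training R²: SSE = Σ(y−ŷ)², SST = Σ(y−ȳ)², R² = 1 − SSE/SST."""
    y01 = model.encode(y)
    sst = float(((y01 - y01.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("constant response: SST = 0, R² undefined")
    yhat = model.predict_value(X)
    sse = float(((y01 - yhat) ** 2).sum())
    return FitStatistics(r2=1 - sse / sst, sse=sse, sst=sst)


@dataclass
class CVResult:
    """Cross-validated predictability: q2 = 1 - press/tss."""

    q2: float
    press: float
    tss: float
    fold_assignments: dict[int, int]
    k: int
    seed: int


def _check_binary(y) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {len(classes)}")
    return (y == classes[1]).astype(float)


def q_squared(
    X,
    y,
    k: int = 5,
    n_components: int = 2,
    seed: int = 0,
    tss_mean: str = "train",
) -> CVResult:
    """Q² under stratified k-fold cross-validation.

    Per fold the model is refitted on the training portion (scaling
    statistics from training only); PRESS accumulates held-out squared
    errors, TSS the held-out squared deviations from the training-fold mean
    (``tss_mean="global"`` uses the overall mean instead).
    """
    X = np.asarray(X, dtype=float)
    y01 = _check_binary(y)
    n = len(y01)
    if k > n:
        raise ValueError(f"k={k} folds but only {n} samples")
    if tss_mean not in ("train", "global"):
        raise ValueError(f"tss_mean must be 'train' or 'global', got {tss_mean!r}")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    press = tss = 0.0
    folds: dict[int, int] = {}
    global_mean = y01.mean()
    for fold, (train, test) in enumerate(splitter.split(X, y01), start=1):
        if len(np.unique(y01[train])) < 2:
            raise ValueError(
                "a training fold contains a single class; use stratified folds "
                "or a smaller k"
            )
        yhat, ybar_train = _fit_predict_raw(X[train], y01[train], X[test], n_components)
        baseline = ybar_train if tss_mean == "train" else global_mean
        press += float(((y01[test] - yhat) ** 2).sum())
        tss += float(((y01[test] - baseline) ** 2).sum())
        for i in test:
            folds[int(i)] = fold
    return CVResult(q2=1 - press / tss, press=press, tss=tss, fold_assignments=folds, k=k, seed=seed)


@dataclass
class PermutationResult:
    """Label-permutation null distribution of Q² and the literal p-value."""

    observed_q2: float
    permuted_q2: np.ndarray
    n_runs: int
    p_value: float
    seed: int


def permutation_p_value(permuted_q2, observed_q2: float, plus_one: bool = False) -> float:
    """Literal permutation p-value: #(Q²_perm ≥ Q²_obs) / n_runs.

    The count/n estimator can return exactly 0; ``plus_one`` switches to the
    conventional (count+1)/(n+1) estimator.
    """
    permuted = np.asarray(permuted_q2, dtype=float)
    count = int((permuted >= observed_q2).sum())
    n = len(permuted)
    return (count + 1) / (n + 1) if plus_one else count / n


def permutation_test(
    X,
    y,
    n_runs: int = 1000,
    k: int = 5,
    n_components: int = 2,
    seed: int = 0,
    plus_one: bool = False,
) -> PermutationResult:
    """Permutation test on Q²: p = #(Q²_perm ≥ Q²_obs) / n_runs.

    Each run shuffles y uniformly at random (X fixed) and recomputes Q²
    with the same k and component count, using fresh stratified folds. The
    literal count/n estimator can return 0; ``plus_one=True`` switches to
    the (count+1)/(n+1) convention.
    """
    if n_runs < 1:
        raise ValueError(f"n_runs must be >= 1, got {n_runs}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    observed = q_squared(
        X, y, k=k, n_components=n_components, seed=int(rng.integers(2**31 - 1))
    ).q2
    permuted = np.empty(n_runs)
    for r in range(n_runs):
        y_perm = rng.permutation(y)
        permuted[r] = q_squared(
            X, y_perm, k=k, n_components=n_components, seed=int(rng.integers(2**31 - 1))
        ).q2
    p = permutation_p_value(permuted, observed, plus_one=plus_one)
    return PermutationResult(
        observed_q2=observed, permuted_q2=permuted, n_runs=n_runs, p_value=p, seed=seed
    )


@dataclass
class VIPVector:
    """Per-feature variable importance in projection; VIP > threshold flags
    influential features. Mean of squared scores is 1 by construction."""

    scores: np.ndarray
    threshold: float = 1.0
    feature_ids: list[str] | None = None

    def above_threshold(self) -> np.ndarray:
        return self.scores >= self.threshold

    def to_frame(self) -> pd.DataFrame:
        idx = self.feature_ids if self.feature_ids is not None else range(len(self.scores))
        return pd.DataFrame({"feature": list(idx), "vip": self.scores})


def vip(model: PLSDAClassifier, y=None) -> VIPVector:
    """Wold VIP scores of a fitted model (y is carried by the model)."""
    check_is_fitted(model, "coef_")
    W, T, q = model.weights_, model.x_scores_, model.y_loadings_
    p = W.shape[0]
    ssy = q**2 * np.einsum("ia,ia->a", T, T)  # y-variance per component
    scores = np.sqrt(p * (W**2 @ ssy) / ssy.sum())
    names = list(model.feature_names_in_) if hasattr(model, "feature_names_in_") else None
    return VIPVector(scores=scores, feature_ids=names)


def scores_for_plot(model: PLSDAClassifier, classes: SampleClasses, sample_ids) -> pd.DataFrame:
    """Latent-variable coordinates with class names, ready for a score plot."""
    check_is_fitted(model, "x_scores_")
    if model.x_scores_.shape[1] < 2:
        raise ValueError("score plot needs at least two components")
    sample_ids = list(sample_ids)
    if len(sample_ids) != model.x_scores_.shape[0]:
        raise ValueError("sample_ids length does not match the fitted scores")
    labels = classes.label_vector(sample_ids)
    return pd.DataFrame(
        {
            "sample": sample_ids,
            "LV1": model.x_scores_[:, 0],
            "LV2": model.x_scores_[:, 1],
            "class": [classes.name_of(v) for v in labels],
        }
    )
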
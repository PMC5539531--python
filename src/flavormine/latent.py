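"""Latent-variable models: PLS-DA, cross-validated CV%/RMSECV, VIP scores, PCA.

PLS-DA is multi-response PLS2 on one-hot class membership, fitted by NIPALS
with sequential deflation: component ``a`` extracts a unit-norm X-weight
vector ``w_a`` (dominant direction of the X'Y cross-covariance of the deflated
data), scores ``t_a = X w_a``, X-loadings ``p_a`` and Y-loadings ``q_a``, then
deflates both blocks by the rank-one contribution of ``t_a``.  Scores of
distinct components are mutually orthogonal by construction.

Model quality under cross-validation is summarised two ways, both monotone
transforms of the same PRESS:

* ``CV% = 100 (1 - PRESS / TSS)`` — cross-validated explained variance of the
  one-hot response (TSS on the centered one-hot matrix);
* ``RMSECV = sqrt(PRESS / (n m))`` with ``m`` response columns.

Variable importance in projection for variable ``j``:

    VIP_j = sqrt( p * sum_a SS_a w_aj^2 / sum_a SS_a ),
    SS_a  = (sum_k q_ka^2) * t_a' t_a

so ``sum_j VIP_j^2 = p`` exactly (weights are unit-norm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = [
    "PLSDAClassifier",
    "CVResult",
    "VIPRanking",
    "PCAVarianceReducer",
    "fit_plsda",
    "predict_plsda",
    "cross_validate_pls",
    "auto_components",
    "compute_vip",
    "rank_by_vip",
    "fit_pca",
    "pca_reduce",
    "training_r2",
]

MAX_AUTO_COMPONENTS = 15


def _one_hot(y, classes):
    Y = np.zeros((len(y), len(classes)))
    for k, cls in enumerate(classes):
        Y[np.asarray(y) == cls, k] = 1.0
    return Y


def _nipals(Xc, Yc, n_components):
    """Sequential NIPALS extraction on centered blocks; returns (W, T, P, Q).

    Per component the unit-norm weight vector is the dominant left singular
    vector of the deflated cross-covariance X'Y (the NIPALS fixed point),
    with a deterministic sign convention.  Both blocks are deflated by the
    rank-one score contribution.
    """
    Xc = Xc.copy()
    Yc = Yc.copy()
    n, p = Xc.shape
    m = Yc.shape[1]
    W = np.empty((p, n_components))
    T = np.empty((n, n_components))
    P = np.empty((p, n_components))
    Q = np.empty((m, n_components))
    for a in range(n_components):
        S = Xc.T @ Yc
        if np.allclose(S, 0):
            raise ValueError("no remaining X/Y covariance; reduce n_components")
        w = np.linalg.svd(S, full_matrices=False)[0][:, 0]
        if w[np.argmax(np.abs(w))] < 0:
            w = -w
        t = Xc @ w
        tt = float(t @ t)
        if tt <= np.finfo(float).eps * n:
            raise ValueError("degenerate component; reduce n_components")
        p_load = Xc.T @ t / tt
        q = Yc.T @ t / tt
        Xc -= np.outer(t, p_load)
        Yc -= np.outer(t, q)
        W[:, a], T[:, a], P[:, a], Q[:, a] = w, t, p_load, q
    return W, T, P, Q


class PLSDAClassifier(ClassifierMixin, BaseEstimator):
    """NIPALS PLS2 on one-hot labels with argmax decoding.

    Parameters
    ----------
    n_components : int
        Number of latent components ``A``; must not exceed the rank of the
        centered training matrix (no silent capping).

    Attributes
    ----------
    x_weights_ : ndarray (p, A), unit-norm columns
    x_scores_ : ndarray (n, A), mutually orthogonal columns
    x_loadings_ : ndarray (p, A)
    y_loadings_ : ndarray (m, A)
    classes_ : ndarray of class labels (sorted); argmax ties decode to the
        lowest class index.
    """

    def __init__(self, n_components=2):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        Y = _one_hot(y, self.classes_)
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = Y.mean(axis=0)
        Xc = X - self.x_mean_
        Yc = Y - self.y_mean_
        rank = np.linalg.matrix_rank(Xc)
        if self.n_components > rank:
            raise ValueError(
                f"n_components={self.n_components} exceeds rank {rank} of centered X"
            )
        W, T, P, Q = _nipals(Xc, Yc, self.n_components)
        self.x_weights_, self.x_scores_ = W, T
        self.x_loadings_, self.y_loadings_ = P, Q
        self.n_features_in_ = X.shape[1]
        return self

    def _score_sequence(self, X):
        """Sequential (deflated) scores of new rows, shape (n, A)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError("column count does not match the fitted model")
        Xc = X - self.x_mean_
        A = self.x_weights_.shape[1]
        T = np.empty((Xc.shape[0], A))
        for a in range(A):
            t = Xc @ self.x_weights_[:, a]
            Xc = Xc - np.outer(t, self.x_loadings_[:, a])
            T[:, a] = t
        return T

    def decision_function(self, X, n_components=None):
        """Predicted one-hot responses using the first ``n_components`` components."""
        A = self.x_weights_.shape[1] if n_components is None else int(n_components)
        T = self._score_sequence(X)
        return T[:, :A] @ self.y_loadings_[:, :A].T + self.y_mean_

    def predict(self, X):
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]


def fit_plsda(X, labels, n_components) -> PLSDAClassifier:
    return PLSDAClassifier(n_components=n_components).fit(X, labels)


def predict_plsda(model: PLSDAClassifier, X):
    return model.predict(X)


def training_r2(model: PLSDAClassifier, X, y) -> float:
    """Training-set explained variance of the one-hot response, in percent."""
    Y = _one_hot(y, model.classes_)
    resid = Y - model.decision_function(X)
    tss = float(((Y - Y.mean(axis=0)) ** 2).sum())
    return 100.0 * (1.0 - float((resid**2).sum()) / tss)


@dataclass
class CVResult:
    """Cross-validation summary; curves are indexed by component count 1..A."""

    cv_percent: float
    rmsecv: float
    folds: int
    n_components: int
    cv_percent_curve: np.ndarray = field(default_factory=lambda: np.array([]))
    rmsecv_curve: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self):
        if self.rmsecv < 0:
            raise ValueError("rmsecv must be non-negative")
        if self.cv_percent > 100:
            raise ValueError("cv_percent cannot exceed 100")


def _cv_splitter(y, folds, seed):
    n = len(y)
    if not 2 <= folds <= n:
        raise ValueError(f"folds must lie in [2, {n}]")
    _, counts = np.unique(y, return_counts=True)
    if folds == n:
        return KFold(n_splits=n)  # leave-one-out
    if folds <= counts.min():
        return StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return KFold(n_splits=folds, shuffle=True, random_state=seed)


def cross_validate_pls(X, labels, n_components, folds=5, seed=0) -> CVResult:
    """Stratified k-fold PRESS of PLS-DA, reported as CV% and RMSECV.

    The per-component curves come from one pass: each training-fold model is
    fitted at the largest feasible component count and held-out predictions
    are accumulated for every truncation ``1..A``.  The requested component
    count is capped by the smallest training-fold rank (recorded in
    ``n_components``).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    Y = _one_hot(y, classes)
    splitter = _cv_splitter(y, folds, seed)
    n, m = Y.shape

    plans = list(splitter.split(X, y))
    A = int(n_components)
    for train, _ in plans:
        A = min(A, int(np.linalg.matrix_rank(X[train] - X[train].mean(axis=0))))
    if A < 1:
        raise ValueError("no usable components under this fold plan")

    press = np.zeros(A)
    for train, test in plans:
        x_mean = X[train].mean(axis=0)
        y_mean = Y[train].mean(axis=0)
        W, _, P, Q = _nipals(X[train] - x_mean, Y[train] - y_mean, A)
        Xc = X[test] - x_mean
        pred = np.tile(y_mean, (len(test), 1))
        for a in range(A):
            t = Xc @ W[:, a]
            Xc = Xc - np.outer(t, P[:, a])
            pred = pred + np.outer(t, Q[:, a])
            press[a] += float(((Y[test] - pred) ** 2).sum())
    tss = float(((Y - Y.mean(axis=0)) ** 2).sum())
    cv_curve = 100.0 * (1.0 - press / tss)
    rmsecv_curve = np.sqrt(press / (n * m))
    return CVResult(
        cv_percent=float(cv_curve[-1]),
        rmsecv=float(rmsecv_curve[-1]),
        folds=folds,
        n_components=A,
        cv_percent_curve=cv_curve,
        rmsecv_curve=rmsecv_curve,
    )


def auto_components(X, labels, folds=5, seed=0, max_components=MAX_AUTO_COMPONENTS):
    """Pick the component count maximizing CV% over 1..min(p, n-1, max)."""
    X = np.asarray(X, dtype=float)
    a_max = max(1, min(X.shape[1], X.shape[0] - 1, max_components))
    result = cross_validate_pls(X, labels, a_max, folds=folds, seed=seed)
    best = int(np.argmax(result.cv_percent_curve)) + 1
    return best, result


@dataclass
class VIPRanking:
    """Per-variable VIP scores and the descending order (stable on ties)."""

    var_names: list[str]
    scores: np.ndarray
    order: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.var_names) != len(self.scores):
            raise ValueError("one score per variable required")
        if not self.order:
            idx = np.argsort(-self.scores, kind="stable")
            self.order = [self.var_names[i] for i in idx]

    def top(self, k: int) -> list[str]:
        return self.order[:k]


def compute_vip(model: PLSDAClassifier, var_names=None) -> VIPRanking:
    """VIP scores of a fitted PLS-DA model; ``sum(VIP^2) = p`` by construction."""
    W, T, Q = model.x_weights_, model.x_scores_, model.y_loadings_
    p = W.shape[0]
    ss = (Q**2).sum(axis=0) * (T**2).sum(axis=0)
    total = float(ss.sum())
    if total <= 0:
        raise ValueError("model explains no response variance; VIP undefined")
    vip = np.sqrt(p * (W**2 @ ss) / total)
    if var_names is None:
        var_names = [f"x{j}" for j in range(p)]
    return VIPRanking(var_names=list(var_names), scores=vip)


def rank_by_vip(ranking: VIPRanking) -> list[str]:
    """Variable names in descending VIP order, original order breaking ties."""
    return list(ranking.order)


class PCAVarianceReducer(TransformerMixin, BaseEstimator):
    """PCA baseline keeping the fewest components reaching a cumulative
    explained-variance threshold (default 99%)."""

    def __init__(self, cum_threshold=0.99):
        self.cum_threshold = cum_threshold

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("PCA needs at least 2 samples")
        if not 0.0 < self.cum_threshold <= 1.0:
            raise ValueError("cum_threshold must lie in (0, 1]")
        self.pca_ = PCA(n_components=None, svd_solver="full").fit(X)
        self.explained_variance_ratio_ = self.pca_.explained_variance_ratio_
        self.loadings_ = self.pca_.components_
        self.mean_ = self.pca_.mean_
        cum = np.cumsum(self.explained_variance_ratio_)
        self.n_components_ = int(np.argmax(cum >= self.cum_threshold - 1e-12)) + 1
        return self

    def transform(self, X):
        return self.pca_.transform(np.asarray(X, dtype=float))[:, : self.n_components_]


def fit_pca(X) -> PCAVarianceReducer:
    return PCAVarianceReducer(cum_threshold=1.0).fit(X)


def pca_reduce(model: PCAVarianceReducer, X, cum_threshold=0.99):
    """Scores on the fewest components whose cumulative ratio >= threshold."""
    if not 0.0 < cum_threshold <= 1.0:
        raise ValueError("cum_threshold must lie in (0, 1]")
    cum = np.cumsum(model.explained_variance_ratio_)
    m = int(np.argmax(cum >= cum_threshold - 1e-12)) + 1
    return model.pca_.transform(np.asarray(X, dtype=float))[:, :m]
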
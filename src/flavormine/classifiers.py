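"""Evaluation models: GA-tuned RBF-SVM, random forest, ELM, and the
sweep-and-average protocol.

All three evaluators follow the same repeated-evaluation convention: a model
family is trained ``repeats`` times (default 10) with distinct derived seeds
and the mean test accuracy describes its performance, which averages out the
model-level randomness (GA search, bootstrap resampling, random ELM weights).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import partial

import numpy as np
from scipy.linalg import pinv
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .data import accuracy, derive_seed
from .latent import _one_hot

__all__ = [
    "rbf_kernel",
    "RBFSVMClassifier",
    "GAOptConfig",
    "ga_tune_svm",
    "default_mtry",
    "make_random_forest",
    "train_svm",
    "train_rf",
    "ELMClassifier",
    "train_elm",
    "SweepResult",
    "sweep_and_average",
    "DEFAULT_SWEEP_GRID",
]

#: 2, 4, ..., 100 — the sweep grid for RF tree counts and ELM hidden neurons.
DEFAULT_SWEEP_GRID = list(range(2, 101, 2))


def rbf_kernel(X1, X2, g, variant="squared"):
    """Radial basis kernel between row sets.

    ``variant="squared"`` is the standard Gaussian ``exp(-g ||xi - xj||^2)``.
    ``variant="literal"`` is ``exp(-2 g ||xi - xj||)`` (an exponential kernel;
    kept for auditability of the width convention).  Both are positive
    semidefinite and equal 1 on the diagonal.
    """
    if g < 0:
        raise ValueError("kernel width g must be non-negative")
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    sq = (
        (X1**2).sum(axis=1)[:, None]
        + (X2**2).sum(axis=1)[None, :]
        - 2.0 * X1 @ X2.T
    )
    sq = np.maximum(sq, 0.0)
    if variant == "squared":
        return np.exp(-g * sq)
    if variant == "literal":
        return np.exp(-2.0 * g * np.sqrt(sq))
    raise ValueError(f"unknown kernel variant {variant!r}")


class RBFSVMClassifier(ClassifierMixin, BaseEstimator):
    """Soft-margin RBF SVM, multi-class by explicit one-vs-one voting.

    Each class pair gets its own box-constrained dual problem (solved by
    libsvm through :class:`sklearn.svm.SVC` with our kernel); votes are
    tallied over pairs and ties decode to the lowest class index.  After
    fitting, ``dual_feasibility_`` records per pair the equality-constraint
    residual ``|sum_i a_i y_i|`` and the box violation ``max(0, max a_i - c)``.
    """

    def __init__(self, c=1.0, g=1.0, kernel_variant="squared"):
        self.c = c
        self.g = g
        self.kernel_variant = kernel_variant

    def fit(self, X, y):
        if self.c <= 0:
            raise ValueError("penalty c must be positive")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        counts = {c: int((y == c).sum()) for c in self.classes_}
        degenerate = [c for c, n in counts.items() if n < 2]
        if degenerate:
            raise ValueError(f"degenerate class(es) with a single sample: {degenerate}")
        kernel = partial(rbf_kernel, g=self.g, variant=self.kernel_variant)
        self._models = {}
        self.dual_feasibility_ = {}
        for a in range(len(self.classes_)):
            for b in range(a + 1, len(self.classes_)):
                ca, cb = self.classes_[a], self.classes_[b]
                rows = (y == ca) | (y == cb)
                y_bin = np.where(y[rows] == ca, -1, 1)
                svc = SVC(C=self.c, kernel=kernel, tol=1e-6)
                svc.fit(X[rows], y_bin)
                self._models[(a, b)] = (svc, X[rows])
                alphas = svc.dual_coef_[0]  # signed a_i y_i
                self.dual_feasibility_[(str(ca), str(cb))] = {
                    "equality_residual": abs(float(alphas.sum())),
                    "box_violation": max(0.0, float(np.abs(alphas).max()) - self.c),
                }
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("column count does not match the fitted model")
        votes = np.zeros((X.shape[0], len(self.classes_)), dtype=int)
        for (a, b), (svc, _) in self._models.items():
            pred = svc.predict(X)
            votes[:, a] += pred == -1
            votes[:, b] += pred == 1
        return self.classes_[np.argmax(votes, axis=1)]


def train_svm(X, labels, c, g, kernel_variant="squared") -> RBFSVMClassifier:
    return RBFSVMClassifier(c=c, g=g, kernel_variant=kernel_variant).fit(X, labels)


@dataclass
class GAOptConfig:
    """GA search settings for (c, g); defaults follow the usual protocol of
    100 generations x 20 individuals over c in [0, 100], g in [0, 1000]."""

    generations: int = 100
    population: int = 20
    c_range: tuple[float, float] = (0.0, 100.0)
    g_range: tuple[float, float] = (0.0, 1000.0)
    folds: int = 5
    seed: int = 0
    elitism: int = 1
    mutation_sd_frac: float = 0.1
    blend_alpha: float = 0.5
    #: "linear" searches g uniformly on g_range; "log" searches log10(g)
    #: uniformly (better suited to (-1, 1)-scaled inputs, where useful widths
    #: span orders of magnitude).  A zero lower bound is floored at 1e-4.
    g_scale: str = "linear"

    def __post_init__(self):
        for name in ("c_range", "g_range"):
            lo, hi = getattr(self, name)
            if not hi > lo:
                raise ValueError(f"{name} is degenerate: ({lo}, {hi})")
        if self.g_scale not in ("linear", "log"):
            raise ValueError("g_scale must be 'linear' or 'log'")


_MIN_C = 1e-3  # the dual needs c > 0; the searched interval is closed at 0


def _cv_accuracy_svm(X, y, c, g, folds, seed, kernel_variant):
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for train, test in splitter.split(X, y):
        model = RBFSVMClassifier(c=max(c, _MIN_C), g=g, kernel_variant=kernel_variant)
        model.fit(X[train], y[train])
        accs.append(accuracy(model.predict(X[test]), y[test]))
    return float(np.mean(accs))


def ga_tune_svm(X, labels, config: GAOptConfig | None = None, kernel_variant="squared"):
    """Real-coded GA over (c, g); fitness is stratified k-fold CV accuracy.

    Tournament selection (size 2), blend (BLX-alpha) crossover, Gaussian
    mutation clipped to the ranges, elitism.  Returns
    ``(c, g, cv_accuracy, history)`` with a non-decreasing best-so-far history.
    """
    config = config or GAOptConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    rng = np.random.default_rng(derive_seed(config.seed, "svm-ga"))
    fold_seed = derive_seed(config.seed, "svm-folds")
    g_lo, g_hi = config.g_range
    if config.g_scale == "log":
        g_lo = np.log10(max(g_lo, 1e-4))
        g_hi = np.log10(g_hi)
    lo = np.array([config.c_range[0], g_lo])
    hi = np.array([config.c_range[1], g_hi])

    def decode_g(raw):
        return float(10.0**raw) if config.g_scale == "log" else float(raw)

    def fitness(gene):
        return _cv_accuracy_svm(
            X, y, gene[0], decode_g(gene[1]), config.folds, fold_seed, kernel_variant
        )

    pop = lo + rng.random((config.population, 2)) * (hi - lo)
    fit = np.array([fitness(g) for g in pop])
    best_idx = int(np.argmax(fit))
    best_gene, best_fit = pop[best_idx].copy(), float(fit[best_idx])
    history = [best_fit]

    for _ in range(config.generations):
        elite = pop[np.argsort(-fit, kind="stable")[: config.elitism]].copy()
        children = list(elite)
        while len(children) < config.population:
            parents = []
            for _ in range(2):
                i, j = rng.integers(config.population, size=2)
                parents.append(pop[i] if fit[i] >= fit[j] else pop[j])
            gamma = (1 + 2 * config.blend_alpha) * rng.random(2) - config.blend_alpha
            child = (1 - gamma) * parents[0] + gamma * parents[1]
            mutate = rng.random(2) < 0.5
            child = child + mutate * rng.normal(0, config.mutation_sd_frac * (hi - lo))
            children.append(np.clip(child, lo, hi))
        pop = np.array(children[: config.population])
        fit = np.array([fitness(g) for g in pop])
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best_fit:
            best_fit, best_gene = float(fit[gen_best]), pop[gen_best].copy()
        history.append(best_fit)

    return float(max(best_gene[0], _MIN_C)), decode_g(best_gene[1]), best_fit, history


def default_mtry(p: int) -> int:
    """Split-candidate count for random forests: floor(sqrt(p)), at least 1."""
    if p < 1:
        raise ValueError("number of variables must be >= 1")
    return max(1, int(np.floor(np.sqrt(p))))


def make_random_forest(n_trees=100, mtry=None, seed=0) -> RandomForestClassifier:
    """Configured forest: bootstrap-sampled, Gini-split, fully grown trees.

    ``mtry`` defaults to floor(sqrt(p)) at fit time (sklearn's "sqrt" rule
    matches :func:`default_mtry`).  Vote ties decode to the lowest class.
    """
    return RandomForestClassifier(
        n_estimators=n_trees,
        max_features=mtry if mtry is not None else "sqrt",
        criterion="gini",
        bootstrap=True,
        random_state=seed,
        min_samples_leaf=1,
    )


def train_rf(X, labels, n_trees=100, mtry=None, seed=0) -> RandomForestClassifier:
    X = np.asarray(X, dtype=float)
    if mtry is not None and not 1 <= mtry <= X.shape[1]:
        raise ValueError(f"mtry must lie in [1, {X.shape[1]}]")
    return make_random_forest(n_trees, mtry, seed).fit(X, np.asarray(labels))


class ELMClassifier(ClassifierMixin, BaseEstimator):
    """Extreme learning machine: random fixed hidden layer, closed-form output.

    Input weights and biases are drawn uniformly on [-1, 1] and never trained;
    the hidden activations ``H = G(X a + b)`` feed a linear readout whose
    weights are the minimum-norm least-squares solution ``beta = H^+ T``
    (Moore-Penrose pseudoinverse, one-hot targets).  Decoding is argmax with
    ties to the lowest class index.
    """

    def __init__(self, n_hidden=40, activation="sigmoid", random_state=0):
        self.n_hidden = n_hidden
        self.activation = activation
        self.random_state = random_state

    def _activate(self, Z):
        if self.activation == "sigmoid":
            return expit(Z)
        if self.activation == "tanh":
            return np.tanh(Z)
        raise ValueError(f"unknown activation {self.activation!r}")

    def fit(self, X, y):
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        rng = np.random.default_rng(self.random_state)
        p = X.shape[1]
        self.input_weights_ = rng.uniform(-1.0, 1.0, size=(p, self.n_hidden))
        self.biases_ = rng.uniform(-1.0, 1.0, size=self.n_hidden)
        H = self._activate(X @ self.input_weights_ + self.biases_)
        T = _one_hot(y, self.classes_)
        self.beta_ = pinv(H) @ T
        self.n_features_in_ = p
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("column count does not match the fitted model")
        return self._activate(X @ self.input_weights_ + self.biases_) @ self.beta_

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


def train_elm(X, labels, n_hidden=40, seed=0, activation="sigmoid") -> ELMClassifier:
    return ELMClassifier(
        n_hidden=n_hidden, activation=activation, random_state=seed
    ).fit(X, labels)


@dataclass
class SweepResult:
    """Mean test accuracy over repeats at each grid point; best point is the
    argmax with the smallest grid value winning ties."""

    grid: list
    mean_accuracy: np.ndarray
    sd_accuracy: np.ndarray
    repeats: int
    best_value: float = field(init=False)
    best_mean: float = field(init=False)

    def __post_init__(self):
        self.mean_accuracy = np.asarray(self.mean_accuracy, dtype=float)
        self.sd_accuracy = np.asarray(self.sd_accuracy, dtype=float)
        if len(self.grid) != len(self.mean_accuracy):
            raise ValueError("grid and means must have equal length")
        i = int(np.argmax(self.mean_accuracy))
        self.best_value = self.grid[i]
        self.best_mean = float(self.mean_accuracy[i])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "grid_value": self.grid,
                "mean_accuracy": np.round(self.mean_accuracy, 2),
                "sd_accuracy": np.round(self.sd_accuracy, 4),
            }
        )


def sweep_and_average(
    trainer, grid, X_train, y_train, X_test, y_test, repeats=10, seed=0
) -> SweepResult:
    """Evaluate a model family along a hyperparameter grid.

    ``trainer(grid_value, seed)`` must return a fitted classifier exposing
    ``predict``.  At each grid point, ``repeats`` models are trained with
    distinct derived seeds and the mean/sd of their test accuracies recorded.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    means, sds = [], []
    for gi, value in enumerate(grid):
        accs = [
            accuracy(
                trainer(value, derive_seed(seed, gi, r)).predict(X_test), y_test
            )
            for r in range(repeats)
        ]
        means.append(np.mean(accs))
        sds.append(np.std(accs))
    return SweepResult(grid=grid, mean_accuracy=means, sd_accuracy=sds, repeats=repeats)
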
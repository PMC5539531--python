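"""GA-PLS variable selection and the response-randomization applicability test.

A binary chromosome encodes which variables enter a PLS-DA model; fitness is
the cross-validated explained variance CV% of the masked model (component
count chosen automatically per mask).  The genetic search uses tournament
selection, uniform crossover, per-bit mutation and elitism, so the best
fitness found is non-decreasing across generations.

Before running the wrapper search, a response-randomization test guards
against selection bias: the class labels are permuted and the full-model CV%
recomputed (negative values floored at zero); the mean over permutations must
stay below 5 for the search to be considered applicable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from .data import derive_seed
from .latent import MAX_AUTO_COMPONENTS, cross_validate_pls

__all__ = [
    "GAPLSConfig",
    "GAPLSResult",
    "RandomizationResult",
    "chromosome_fitness",
    "randomization_test",
    "ga_pls_select",
    "exhaustive_pls_search",
    "GAPLSSelector",
]

RANDOMIZATION_THRESHOLD = 5.0


@dataclass
class GAPLSConfig:
    """GA operator settings (standard wrapper-selection defaults)."""

    population: int = 30
    generations: int = 100
    crossover_prob: float = 0.9
    mutation_prob: float | None = None  # per bit; None -> 1/p
    elitism: int = 1
    folds: int = 5
    max_components: int = MAX_AUTO_COMPONENTS
    seed: int = 0

    def __post_init__(self):
        if self.population < 2:
            raise ValueError("population must be >= 2")
        for name in ("crossover_prob",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mutation_prob is not None and not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation_prob must lie in [0, 1]")


@dataclass
class RandomizationResult:
    value: float  # mean permuted-response CV%, floored at 0 per permutation
    n_permutations: int
    threshold: float = RANDOMIZATION_THRESHOLD

    @property
    def passed(self) -> bool:
        return self.value < self.threshold


@dataclass
class GAPLSResult:
    best_mask: np.ndarray
    best_variables: list[str]
    best_cv_percent: float
    best_rmsecv: float
    best_n_components: int
    cv_by_size: dict[int, float]  # envelope: best CV% per subset size seen
    rmsecv_by_size: dict[int, float]
    generation_log: list[dict] = field(default_factory=list)
    randomization: RandomizationResult | None = None
    n_evaluations: int = 0


class _FitnessCache:
    """Mask-keyed cache of CV results; caching must not change outcomes, so the
    fold plan is fixed for the whole run by a single derived seed."""

    def __init__(self, X, y, folds, max_components, seed):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y)
        self.folds = folds
        self.max_components = max_components
        self.seed = seed
        self._store: dict[bytes, tuple] = {}
        self.n_evaluations = 0

    def evaluate(self, mask):
        mask = np.asarray(mask, dtype=bool)
        key = np.packbits(mask).tobytes()
        if key not in self._store:
            self.n_evaluations += 1
            k = int(mask.sum())
            if k == 0:
                raise ValueError("empty variable mask")
            a_max = max(1, min(k, len(self.y) - 1, self.max_components))
            res = cross_validate_pls(
                self.X[:, mask], self.y, a_max, folds=self.folds, seed=self.seed
            )
            a_best = int(np.argmax(res.cv_percent_curve))
            self._store[key] = (
                float(res.cv_percent_curve[a_best]),
                float(res.rmsecv_curve[a_best]),
                a_best + 1,
            )
        return self._store[key]


def chromosome_fitness(X, labels, mask, folds=5, seed=0, max_components=MAX_AUTO_COMPONENTS):
    """CV%/RMSECV of the masked PLS-DA model (auto component count).

    Returns ``(cv_percent, rmsecv, n_components)``; identical to
    :func:`flavormine.latent.cross_validate_pls` on the masked columns.
    """
    cache = _FitnessCache(X, labels, folds, max_components, seed)
    return cache.evaluate(mask)


def randomization_test(X, labels, n_perm=100, seed=0, folds=5) -> RandomizationResult:
    """Mean CV% over label permutations (each floored at 0); pass iff < 5.

    The component count is chosen once on the true labels and held fixed
    across permutations so every permutation is scored on the same footing.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    a_max = max(1, min(X.shape[1], len(y) - 1, MAX_AUTO_COMPONENTS))
    base = cross_validate_pls(X, y, a_max, folds=folds, seed=seed)
    a_star = int(np.argmax(base.cv_percent_curve)) + 1
    rng = np.random.default_rng(seed)
    values = []
    for i in range(n_perm):
        perm = rng.permutation(len(y))
        res = cross_validate_pls(
            X, y[perm], a_star, folds=folds, seed=derive_seed(seed, i)
        )
        values.append(max(0.0, res.cv_percent_curve[min(a_star, res.n_components) - 1]))
    return RandomizationResult(value=float(np.mean(values)), n_permutations=n_perm)


def _update_envelope(cv_by_size, rmsecv_by_size, k, cv, rmsecv):
    # CV% and RMSECV are monotone transforms of the same PRESS, so the size-k
    # envelope holds both numbers from the same (best) mask.
    if k not in cv_by_size or cv > cv_by_size[k]:
        cv_by_size[k] = cv
        rmsecv_by_size[k] = rmsecv


def ga_pls_select(
    X,
    labels,
    var_names=None,
    config: GAPLSConfig | None = None,
    randomization: RandomizationResult | str = "auto",
    n_perm: int = 100,
    force: bool = False,
) -> GAPLSResult:
    """Genetic search over variable-inclusion masks maximizing CV%.

    ``randomization`` is ``"auto"`` (run the test first), ``"skip"``, or an
    already-computed :class:`RandomizationResult`.  A failing test aborts the
    search unless ``force`` is set.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 variables to select from")
    config = config or GAPLSConfig()
    if var_names is None:
        var_names = [f"x{j}" for j in range(p)]

    rand_result = None
    if isinstance(randomization, RandomizationResult):
        rand_result = randomization
    elif randomization == "auto":
        rand_result = randomization_test(
            X, y, n_perm=n_perm, seed=derive_seed(config.seed, "randomization"),
            folds=config.folds,
        )
    if rand_result is not None and not rand_result.passed and not force:
        raise RuntimeError(
            f"randomization test failed (value {rand_result.value:.2f} >= "
            f"{rand_result.threshold}); GA-PLS not applicable"
        )

    # fold plan keyed by the raw config seed so fitness values are directly
    # comparable with exhaustive_pls_search under the same seed
    cache = _FitnessCache(X, y, config.folds, config.max_components, config.seed)
    rng = np.random.default_rng(derive_seed(config.seed, "ga"))
    p_mut = config.mutation_prob if config.mutation_prob is not None else 1.0 / p

    pop = rng.random((config.population, p)) < 0.5
    pop[0] = True  # keep the full model in the initial pool
    for chrom in pop:
        if not chrom.any():
            chrom[rng.integers(p)] = True

    cv_by_size: dict[int, float] = {}
    rmsecv_by_size: dict[int, float] = {}
    log = []
    best_mask, best_fit = None, -np.inf

    def score(mask):
        nonlocal best_mask, best_fit
        cv, rmsecv, a = cache.evaluate(mask)
        _update_envelope(cv_by_size, rmsecv_by_size, int(mask.sum()), cv, rmsecv)
        if cv > best_fit:
            best_fit, best_mask = cv, mask.copy()
        return cv

    fitness = np.array([score(c) for c in pop])
    log.append({"generation": 0, "best": float(fitness.max()), "best_so_far": best_fit})

    for gen in range(1, config.generations + 1):
        elite_idx = np.argsort(-fitness, kind="stable")[: config.elitism]
        children = [pop[i].copy() for i in elite_idx]
        while len(children) < config.population:
            parents = []
            for _ in range(2):  # tournament of 2
                i, j = rng.integers(config.population, size=2)
                parents.append(pop[i] if fitness[i] >= fitness[j] else pop[j])
            c1, c2 = parents[0].copy(), parents[1].copy()
            if rng.random() < config.crossover_prob:
                swap = rng.random(p) < 0.5  # uniform crossover
                c1[swap], c2[swap] = parents[1][swap], parents[0][swap]
            for c in (c1, c2):
                flip = rng.random(p) < p_mut
                c[flip] = ~c[flip]
                if not c.any():
                    c[rng.integers(p)] = True
                children.append(c)
        pop = np.array(children[: config.population])
        fitness = np.array([score(c) for c in pop])
        log.append({"generation": gen, "best": float(fitness.max()), "best_so_far": best_fit})

    cv, rmsecv, a = cache.evaluate(best_mask)
    return GAPLSResult(
        best_mask=best_mask,
        best_variables=[v for v, m in zip(var_names, best_mask) if m],
        best_cv_percent=cv,
        best_rmsecv=rmsecv,
        best_n_components=a,
        cv_by_size=dict(sorted(cv_by_size.items())),
        rmsecv_by_size=dict(sorted(rmsecv_by_size.items())),
        generation_log=log,
        randomization=rand_result,
        n_evaluations=cache.n_evaluations,
    )


def exhaustive_pls_search(X, labels, folds=5, seed=0, max_components=MAX_AUTO_COMPONENTS):
    """Brute-force optimum over all non-empty masks (oracle for small p).

    Uses the same fixed fold plan construction as the GA so fitness values are
    directly comparable.  Returns ``(best_mask, best_cv_percent)``.
    """
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if p > 16:
        raise ValueError("exhaustive search is only sensible for small p")
    cache = _FitnessCache(X, labels, folds, max_components, seed)
    best_mask, best_cv = None, -np.inf
    for code in range(1, 2**p):
        mask = np.array([(code >> j) & 1 for j in range(p)], dtype=bool)
        cv, _, _ = cache.evaluate(mask)
        if cv > best_cv:
            best_cv, best_mask = cv, mask
    return best_mask, float(best_cv)


class GAPLSSelector(SelectorMixin, BaseEstimator):
    """sklearn-style feature selector wrapping :func:`ga_pls_select`.

    After ``fit``, ``support_`` holds the selected mask and ``result_`` the
    full search record; ``transform`` keeps the selected columns.
    """

    def __init__(
        self,
        population=30,
        generations=100,
        crossover_prob=0.9,
        mutation_prob=None,
        elitism=1,
        folds=5,
        seed=0,
        check_applicability=True,
        n_perm=100,
    ):
        self.population = population
        self.generations = generations
        self.crossover_prob = crossover_prob
        self.mutation_prob = mutation_prob
        self.elitism = elitism
        self.folds = folds
        self.seed = seed
        self.check_applicability = check_applicability
        self.n_perm = n_perm

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        config = GAPLSConfig(
            population=self.population,
            generations=self.generations,
            crossover_prob=self.crossover_prob,
            mutation_prob=self.mutation_prob,
            elitism=self.elitism,
            folds=self.folds,
            seed=self.seed,
        )
        self.result_ = ga_pls_select(
            X, y,
            config=config,
            randomization="auto" if self.check_applicability else "skip",
            n_perm=self.n_perm,
        )
        self.support_ = self.result_.best_mask
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        return self.support_
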
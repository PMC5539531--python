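"""VIP-ranked nested-subset accumulation and the feature-set comparison report.

The headline procedure: rank the fused variables by VIP score, build the
nested ladder S_1 c S_2 c ... c S_p of top-k subsets, evaluate every subset
with each classifier family under the repeated-evaluation protocol, and pick
per evaluator the smallest subset attaining the maximum mean accuracy.  The
comparison report places that result next to the raw fusion set, the single
modalities, the PCA-reduced set and the GA-PLS subset.

Two protocol modes exist.  ``mode="full"`` mirrors the per-set protocol: the
SVM is re-tuned by GA for every subset and repeat, and RF/ELM are swept over
their full grids (trees / hidden neurons, 2..100 step 2) with the best grid
point reported.  ``mode="fast"`` resolves hyperparameters once on the
full-variable training set with a reduced budget and reuses them everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .classifiers import (
    DEFAULT_SWEEP_GRID,
    GAOptConfig,
    default_mtry,
    ga_tune_svm,
    sweep_and_average,
    train_elm,
    train_rf,
    train_svm,
)
from .data import (
    SensorFeatureTable,
    accuracy,
    derive_seed,
    normalize_apply,
    normalize_fit,
    stratified_split,
)
from .gapls import GAPLSResult
from .latent import PCAVarianceReducer, VIPRanking, auto_components, compute_vip, fit_plsda

__all__ = [
    "SubsetLadder",
    "ProtocolConfig",
    "AccumulationResult",
    "ComparisonReport",
    "build_vip_ladder",
    "vip_ranking_for_table",
    "run_accumulation",
    "select_best_subset",
    "compare_feature_sets",
    "EVALUATORS",
]

EVALUATORS = ("svm", "rf", "elm")


@dataclass
class SubsetLadder:
    """Nested variable subsets S_k = top-k names of a VIP ranking."""

    subsets: list[list[str]]

    def __post_init__(self):
        if not self.subsets:
            raise ValueError("ladder must contain at least one subset")
        for k, s in enumerate(self.subsets, start=1):
            if len(s) != k:
                raise ValueError(f"subset #{k} must contain exactly {k} variables")
            if k > 1 and s[: k - 1] != self.subsets[k - 2]:
                raise ValueError("ladder subsets must be nested")

    def __len__(self):
        return len(self.subsets)

    def __getitem__(self, k):
        """1-based access: ladder[k] is S_k."""
        return self.subsets[k - 1]


def build_vip_ladder(ranking: VIPRanking) -> SubsetLadder:
    order = list(ranking.order)
    if not order:
        raise ValueError("empty ranking")
    return SubsetLadder([order[: k + 1] for k in range(len(order))])


@dataclass
class ProtocolConfig:
    """Every knob of the split / normalization / repeat protocol."""

    train_fraction: float = 0.8
    repeats: int = 10
    folds: int = 5
    seed: int = 0
    mode: str = "full"  # "full" re-tunes per subset; "fast" reuses full-set tuning
    resplit: bool = False  # repeats re-split the data instead of re-seeding models
    normalize_scope: str = "train"  # or "all": fit the scaler before splitting
    evaluators: tuple = EVALUATORS
    kernel_variant: str = "squared"
    rf_grid: list = field(default_factory=lambda: list(DEFAULT_SWEEP_GRID))
    elm_grid: list = field(default_factory=lambda: list(DEFAULT_SWEEP_GRID))
    svm_generations: int = 100
    svm_population: int = 20
    # reduced budgets used by mode="fast"
    fast_svm_generations: int = 15
    fast_svm_population: int = 10
    fast_rf_trees: int = 100
    fast_elm_grid: list = field(default_factory=lambda: list(range(10, 101, 10)))
    fast_repeats: int = 3

    def __post_init__(self):
        if self.mode not in ("full", "fast"):
            raise ValueError("mode must be 'full' or 'fast'")
        if self.normalize_scope not in ("train", "all"):
            raise ValueError("normalize_scope must be 'train' or 'all'")
        unknown = set(self.evaluators) - set(EVALUATORS)
        if unknown:
            raise ValueError(f"unknown evaluators: {sorted(unknown)}")


def _split_and_scale(table: SensorFeatureTable, protocol: ProtocolConfig, seed):
    plan = stratified_split(table, protocol.train_fraction, seed=seed)
    train = table.select_samples(plan.train_indices)
    test = table.select_samples(plan.test_indices)
    scaler = normalize_fit(table if protocol.normalize_scope == "all" else train)
    return normalize_apply(scaler, train), normalize_apply(scaler, test), plan


def _fast_hyperparams(Xtr, ytr, Xte, yte, protocol: ProtocolConfig):
    """Resolve one hyperparameter set on the full-variable data."""
    hyper = {}
    if "svm" in protocol.evaluators:
        cfg = GAOptConfig(
            generations=protocol.fast_svm_generations,
            population=protocol.fast_svm_population,
            folds=protocol.folds,
            seed=derive_seed(protocol.seed, "fast-svm"),
            g_scale="log",
        )
        c, g, _, _ = ga_tune_svm(Xtr, ytr, cfg, kernel_variant=protocol.kernel_variant)
        hyper["svm"] = (c, g)
    if "rf" in protocol.evaluators:
        hyper["rf"] = protocol.fast_rf_trees
    if "elm" in protocol.evaluators:
        sweep = sweep_and_average(
            lambda v, s: train_elm(Xtr, ytr, n_hidden=v, seed=s),
            protocol.fast_elm_grid,
            Xtr, ytr, Xte, yte,
            repeats=protocol.fast_repeats,
            seed=derive_seed(protocol.seed, "fast-elm"),
        )
        hyper["elm"] = int(sweep.best_value)
    return hyper


def _evaluate_matrix(Xtr, ytr, Xte, yte, evaluator, protocol, seed_key, mtry, hyper):
    """Mean test accuracy of one evaluator on one feature matrix."""
    repeats = protocol.repeats
    if evaluator == "svm":
        if protocol.mode == "fast":
            c, g = hyper["svm"]
            model = train_svm(Xtr, ytr, c, g, kernel_variant=protocol.kernel_variant)
            acc = accuracy(model.predict(Xte), yte)
            return acc, {"c": c, "g": g}
        accs, cs, gs = [], [], []
        for r in range(repeats):
            cfg = GAOptConfig(
                generations=protocol.svm_generations,
                population=protocol.svm_population,
                folds=protocol.folds,
                seed=derive_seed(protocol.seed, *seed_key, "svm", r),
            )
            c, g, _, _ = ga_tune_svm(Xtr, ytr, cfg, kernel_variant=protocol.kernel_variant)
            model = train_svm(Xtr, ytr, c, g, kernel_variant=protocol.kernel_variant)
            accs.append(accuracy(model.predict(Xte), yte))
            cs.append(c)
            gs.append(g)
        return float(np.mean(accs)), {"c": float(np.mean(cs)), "g": float(np.mean(gs))}
    if evaluator == "rf":
        if protocol.mode == "fast":
            accs = [
                accuracy(
                    train_rf(
                        Xtr, ytr, n_trees=hyper["rf"], mtry=mtry,
                        seed=derive_seed(protocol.seed, *seed_key, "rf", r),
                    ).predict(Xte),
                    yte,
                )
                for r in range(repeats)
            ]
            return float(np.mean(accs)), {"n_trees": hyper["rf"], "mtry": mtry}
        sweep = sweep_and_average(
            lambda v, s: train_rf(Xtr, ytr, n_trees=v, mtry=mtry, seed=s),
            protocol.rf_grid,
            Xtr, ytr, Xte, yte,
            repeats=repeats,
            seed=derive_seed(protocol.seed, *seed_key, "rf"),
        )
        return sweep.best_mean, {"n_trees": sweep.best_value, "mtry": mtry, "sweep": sweep}
    if evaluator == "elm":
        if protocol.mode == "fast":
            accs = [
                accuracy(
                    train_elm(
                        Xtr, ytr, n_hidden=hyper["elm"],
                        seed=derive_seed(protocol.seed, *seed_key, "elm", r),
                    ).predict(Xte),
                    yte,
                )
                for r in range(repeats)
            ]
            return float(np.mean(accs)), {"n_hidden": hyper["elm"]}
        sweep = sweep_and_average(
            lambda v, s: train_elm(Xtr, ytr, n_hidden=v, seed=s),
            protocol.elm_grid,
            Xtr, ytr, Xte, yte,
            repeats=repeats,
            seed=derive_seed(protocol.seed, *seed_key, "elm"),
        )
        return sweep.best_mean, {"n_hidden": sweep.best_value, "sweep": sweep}
    raise ValueError(f"unknown evaluator {evaluator!r}")


def _evaluate_set(train, test, var_subset, protocol, seed_key, hyper):
    """Evaluate all configured evaluators on one variable subset."""
    Xtr = train.select_variables(var_subset).values
    Xte = test.select_variables(var_subset).values
    mtry = default_mtry(len(var_subset))
    row = {}
    info = {}
    for ev in protocol.evaluators:
        acc, details = _evaluate_matrix(
            Xtr, train.labels, Xte, test.labels, ev, protocol,
            seed_key=(*seed_key, len(var_subset)), mtry=mtry, hyper=hyper,
        )
        row[ev] = round(acc, 2)
        info[ev] = {k: v for k, v in details.items() if k != "sweep"}
    return row, info


@dataclass
class AccumulationResult:
    """Per-subset mean accuracies; the ladder analogue of a results table."""

    table: pd.DataFrame  # columns: subset, n_vars, mtry, variables, <evaluators>
    ladder: SubsetLadder
    repeats: int
    seed: int
    hyperparams: dict = field(default_factory=dict)

    def best_subsets(self, evaluators=None) -> dict:
        evaluators = evaluators or [
            c for c in self.table.columns if c in EVALUATORS
        ]
        return {ev: select_best_subset(self, ev) for ev in evaluators}


def vip_ranking_for_table(train: SensorFeatureTable, protocol: ProtocolConfig) -> VIPRanking:
    """Fit PLS-DA on the (already scaled) training rows with the CV-chosen
    component count and return the VIP ranking."""
    a_best, _ = auto_components(
        train.values, train.labels, folds=protocol.folds,
        seed=derive_seed(protocol.seed, "vip-components"),
    )
    model = fit_plsda(train.values, train.labels, a_best)
    return compute_vip(model, var_names=train.var_names)


def run_accumulation(
    table: SensorFeatureTable,
    ladder: SubsetLadder | None = None,
    protocol: ProtocolConfig | None = None,
    _hyper: dict | None = None,
) -> AccumulationResult:
    """Evaluate every ladder subset with every evaluator.

    When ``ladder`` is omitted it is built from the VIP ranking of the
    training partition.  The whole run is a pure function of
    ``(table, protocol)``: every random draw is derived from the master seed.
    """
    protocol = protocol or ProtocolConfig()
    if protocol.resplit:
        return _run_accumulation_resplit(table, ladder, protocol)
    train, test, _ = _split_and_scale(
        table, protocol, seed=derive_seed(protocol.seed, "split")
    )
    if ladder is None:
        ladder = build_vip_ladder(vip_ranking_for_table(train, protocol))
    unknown = set(ladder[len(ladder)]) - set(table.var_names)
    if unknown:
        raise KeyError(f"ladder names unknown to the table: {sorted(unknown)}")

    hyper = _hyper
    if hyper is None and protocol.mode == "fast":
        hyper = _fast_hyperparams(
            train.values, train.labels, test.values, test.labels, protocol
        )
    rows, infos = [], {}
    for k in range(1, len(ladder) + 1):
        subset = ladder[k]
        row, info = _evaluate_set(
            train, test, subset, protocol, seed_key=("ladder",), hyper=hyper
        )
        rows.append(
            {
                "subset": k,
                "n_vars": k,
                "mtry": default_mtry(k),
                "variables": " + ".join(subset),
                **row,
            }
        )
        infos[k] = info
    return AccumulationResult(
        table=pd.DataFrame(rows),
        ladder=ladder,
        repeats=protocol.repeats,
        seed=protocol.seed,
        hyperparams={"mode": protocol.mode, "per_subset": infos, "fast": hyper},
    )


def _run_accumulation_resplit(table, ladder, protocol: ProtocolConfig):
    """Repeat-level averaging over fresh 72/18-style splits instead of fresh
    model seeds.  The ladder is fixed (derived from the first split when not
    given) so rows stay comparable across repeats."""
    single = replace(protocol, resplit=False, repeats=1)
    hyper = None
    if protocol.mode == "fast":
        # tune once on the first split; repeated splits reuse the same settings
        first = replace(single, seed=derive_seed(protocol.seed, "resplit", 0))
        train, test, _ = _split_and_scale(
            table, first, seed=derive_seed(first.seed, "split")
        )
        hyper = _fast_hyperparams(
            train.values, train.labels, test.values, test.labels, first
        )
    results = []
    for r in range(protocol.repeats):
        seed_r = derive_seed(protocol.seed, "resplit", r)
        res = run_accumulation(table, ladder, replace(single, seed=seed_r), _hyper=hyper)
        if ladder is None:
            ladder = res.ladder
        results.append(res)
    merged = results[0].table.copy()
    for ev in protocol.evaluators:
        merged[ev] = np.round(
            np.mean([r.table[ev].to_numpy() for r in results], axis=0), 2
        )
    return AccumulationResult(
        table=merged,
        ladder=ladder,
        repeats=protocol.repeats,
        seed=protocol.seed,
        hyperparams={"mode": protocol.mode, "resplit": True},
    )


def select_best_subset(result: AccumulationResult, evaluator: str) -> int:
    """Smallest subset size attaining the evaluator's maximum mean accuracy."""
    if evaluator not in result.table.columns:
        raise KeyError(f"evaluator {evaluator!r} not present in the result")
    col = result.table[evaluator].to_numpy()
    return int(result.table["subset"].to_numpy()[int(np.argmax(col))])


@dataclass
class ComparisonReport:
    """Mean accuracies of competing feature sets, one row per set."""

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["Feature-set comparison (mean accuracy, %):", ""]
        lines.append(self.table.to_string(index=False))
        if "pca_components" in self.metadata:
            lines.append(f"\nPCA kept {self.metadata['pca_components']} components "
                         f"(threshold {self.metadata['pca_threshold']:.2%}).")
        if "gapls_n_variables" in self.metadata:
            lines.append(f"GA-PLS selected {self.metadata['gapls_n_variables']} variables.")
        return "\n".join(lines)


def compare_feature_sets(
    table: SensorFeatureTable,
    protocol: ProtocolConfig | None = None,
    pca_threshold: float = 0.99,
    gapls_result: GAPLSResult | None = None,
    ladder_result: AccumulationResult | None = None,
) -> ComparisonReport:
    """Three-way comparison: modalities vs fusion vs PCA vs GA-PLS vs ladder.

    All rows share the same split, scaling and derived-seed protocol, so the
    report is byte-identical under a fixed master seed.
    """
    protocol = protocol or ProtocolConfig()
    train, test, _ = _split_and_scale(
        table, protocol, seed=derive_seed(protocol.seed, "split")
    )
    hyper_full = (
        _fast_hyperparams(train.values, train.labels, test.values, test.labels, protocol)
        if protocol.mode == "fast"
        else None
    )

    rows = []
    metadata: dict = {"seed": protocol.seed, "mode": protocol.mode}

    named_sets = {}
    tongue = [v for v, m in zip(table.var_names, table.modality) if m == "tongue"]
    nose = [v for v, m in zip(table.var_names, table.modality) if m == "nose"]
    if tongue:
        named_sets["e-tongue"] = tongue
    if nose:
        named_sets["e-nose"] = nose
    named_sets["fusion"] = list(table.var_names)
    if gapls_result is not None:
        named_sets["gapls"] = list(gapls_result.best_variables)
        metadata["gapls_n_variables"] = len(gapls_result.best_variables)

    for name, subset in named_sets.items():
        row, _ = _evaluate_set(
            train, test, subset, protocol, seed_key=("set",), hyper=hyper_full
        )
        rows.append({"feature_set": name, "n_vars": len(subset), **row})

    # PCA works on scores, not named variables, so it bypasses _evaluate_set
    reducer = PCAVarianceReducer(cum_threshold=pca_threshold).fit(train.values)
    Ztr, Zte = reducer.transform(train.values), reducer.transform(test.values)
    m = reducer.n_components_
    metadata["pca_components"] = m
    metadata["pca_threshold"] = pca_threshold
    pca_row = {}
    for ev in protocol.evaluators:
        acc, _ = _evaluate_matrix(
            Ztr, train.labels, Zte, test.labels, ev, protocol,
            seed_key=("set", m), mtry=default_mtry(m), hyper=hyper_full,
        )
        pca_row[ev] = round(acc, 2)
    rows.append({"feature_set": "pca", "n_vars": m, **pca_row})

    if ladder_result is not None:
        best = ladder_result.best_subsets(list(protocol.evaluators))
        row = {}
        for ev, k in best.items():
            row[ev] = float(
                ladder_result.table.loc[ladder_result.table["subset"] == k, ev].iloc[0]
            )
        rows.append(
            {
                "feature_set": "vip-best-subset",
                "n_vars": max(best.values()),
                **{k: round(v, 2) for k, v in row.items()},
            }
        )
        metadata["vip_best_subsets"] = best

    return ComparisonReport(table=pd.DataFrame(rows), metadata=metadata)
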
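"""Diagnostic plots: VIP bars, GA-PLS envelope curves, sweeps, the ladder."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

__all__ = [
    "plot_vip_scores",
    "plot_gapls_envelope",
    "plot_sweep",
    "plot_accumulation",
]


def plot_vip_scores(ranking, ax=None):
    """Bar chart of VIP scores in descending order, unit line marked."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3.5))
    scores = dict(zip(ranking.var_names, ranking.scores))
    names = ranking.order
    ax.bar(range(len(names)), [scores[n] for n in names], color="#4878a8")
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xticks(range(len(names)))
    ax.set_xticklabels(names, rotation=90, fontsize=7)
    ax.set_ylabel("VIP score")
    ax.figure.tight_layout()
    return ax


def plot_gapls_envelope(result, ax=None):
    """CV% and RMSECV envelopes against the number of included variables."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    sizes = sorted(result.cv_by_size)
    ax.plot(sizes, [result.cv_by_size[k] for k in sizes], "o-", label="CV%")
    ax.set_xlabel("number of variables")
    ax.set_ylabel("CV%")
    ax2 = ax.twinx()
    ax2.plot(
        sizes, [result.rmsecv_by_size[k] for k in sizes], "s--", color="#a85448",
        label="RMSECV",
    )
    ax2.set_ylabel("RMSECV")
    ax.figure.tight_layout()
    return ax


def plot_sweep(sweep, xlabel="grid value", ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    ax.errorbar(sweep.grid, sweep.mean_accuracy, yerr=sweep.sd_accuracy, fmt="o-", ms=3)
    ax.axvline(sweep.best_value, color="grey", lw=0.8, ls="--")
    ax.set_xlabel(xlabel)
    ax.set_ylabel("mean accuracy (%)")
    ax.figure.tight_layout()
    return ax


def plot_accumulation(result, ax=None):
    """Mean accuracy of each evaluator along the nested VIP ladder."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    table = result.table
    for ev in ("svm", "rf", "elm"):
        if ev in table.columns:
            ax.plot(table["subset"], table[ev], "o-", ms=3, label=ev.upper())
    ax.set_xlabel("subset size (top-k VIP variables)")
    ax.set_ylabel("mean accuracy (%)")
    ax.legend()
    ax.figure.tight_layout()
    return ax
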
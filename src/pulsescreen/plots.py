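"""Figure regeneration from result tables.

Every plot takes the delimited tables the pipeline writes (or their
in-memory DataFrames) and returns a matplotlib Figure; nothing here computes
results.
"""

from __future__ import annotations

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = [
    "plot_combination_grid",
    "plot_f1_by_count",
    "plot_q1_histograms",
    "plot_ratio_grid",
    "plot_loss_traces",
]

from .features import MEASUREMENTS


def _combo_matrix(combos: list[str]) -> np.ndarray:
    mat = np.zeros((len(MEASUREMENTS), len(combos)), dtype=bool)
    for j, combo in enumerate(combos):
        members = combo.split("[")[0].split("+")
        for i, m in enumerate(MEASUREMENTS):
            mat[i, j] = m in members
    return mat


def plot_combination_grid(records: pd.DataFrame, method: str = "GB"):
    """F1 per measurement combination (bars) over the inclusion grid."""
    means = (records[records["method"] == method]
             .groupby("combination", as_index=False)
             .agg(f1=("f1", "mean"), k=("n_measurements", "first"))
             .sort_values(["k", "combination"]))
    combos = means["combination"].tolist()
    fig, (ax0, ax1) = plt.subplots(
        2, 1, figsize=(max(6, 0.16 * len(combos)), 5), sharex=True,
        height_ratios=[3, 2])
    ax0.bar(np.arange(len(combos)), means["f1"], color="steelblue")
    ax0.set_ylabel("mean $F_1$")
    ax0.set_title(f"{method}: F1 per measurement combination")
    grid = _combo_matrix(combos)
    ax1.imshow(grid, aspect="auto", cmap="Greys", interpolation="none")
    ax1.set_yticks(range(len(MEASUREMENTS)), MEASUREMENTS)
    ax1.set_xticks([])
    ax1.set_xlabel("combination (included measurements marked)")
    fig.tight_layout()
    return fig


def plot_f1_by_count(summary: pd.DataFrame):
    """Mean F1 vs number of measurements with min/max error bars, per
    method (from the summary_by_count table)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for method, g in summary.groupby("method"):
        g = g.sort_values("n_measurements")
        err = np.vstack([g["mean_f1"] - g["min_f1"], g["max_f1"] - g["mean_f1"]])
        ax.errorbar(g["n_measurements"], g["mean_f1"], yerr=err,
                    marker="o", capsize=3, label=method)
    ax.set_xlabel("number of input measurements")
    ax.set_ylabel("$F_1$ (mean; bars: min-max)")
    ax.legend()
    fig.tight_layout()
    return fig


def plot_q1_histograms(hist_table: pd.DataFrame):
    """Include- vs exclude-Q1 F1 histograms (from the q1_histograms table)."""
    fig, (ax0, ax1) = plt.subplots(2, 1, figsize=(6, 5), sharex=True)
    width = hist_table["bin_right"] - hist_table["bin_left"]
    ax0.bar(hist_table["bin_left"], hist_table["include_q1"], width=width,
            align="edge", color="seagreen")
    ax0.set_ylabel("combinations incl. $Q_1$")
    ax1.bar(hist_table["bin_left"], hist_table["exclude_q1"], width=width,
            align="edge", color="indianred")
    ax1.set_ylabel("combinations excl. $Q_1$")
    ax1.set_xlabel("$F_1$")
    fig.tight_layout()
    return fig


def plot_ratio_grid(ratios: pd.DataFrame):
    """Low/high-severity F1 ratios per combination (from the ratio table)."""
    r = ratios.sort_values(["n_measurements", "combination"])
    fig, ax = plt.subplots(figsize=(max(6, 0.16 * len(r)), 4))
    ax.bar(np.arange(len(r)), r["f1_ratio"], color="slategray")
    ax.axhline(1.0, color="k", lw=0.8, ls="--")
    ax.set_ylabel("$F_1$ ratio (low / high severity)")
    ax.set_xticks([])
    ax.set_xlabel("combination (ordered by size)")
    fig.tight_layout()
    return fig


def plot_loss_traces(train_trace, validation_trace, stop_iteration=None):
    """Train/validation log-loss per epoch with the stopping point marked."""
    fig, ax = plt.subplots(figsize=(6, 4))
    it = np.arange(1, len(train_trace) + 1)
    ax.plot(it, train_trace, label="training")
    ax.plot(np.arange(1, len(validation_trace) + 1), validation_trace,
            label="validation")
    if stop_iteration is not None:
        ax.axvline(stop_iteration, color="k", ls="--", lw=0.8,
                   label=f"stopped at {stop_iteration}")
    ax.set_xlabel("epoch")
    ax.set_ylabel("log loss")
    ax.legend()
    fig.tight_layout()
    return fig
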
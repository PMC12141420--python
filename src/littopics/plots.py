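"""Thin plotting layer over the metric tables.  Simple renderings only;
none of these figures carry information the TSV outputs do not."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .topic_metrics import (
    CooccurrenceMatrix,
    GeneralityStats,
    JournalContribution,
    PrevalenceTable,
)


def plot_prevalence(prevalence: PrevalenceTable, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(7, 5))
    for topic, row in prevalence.weights.iterrows():
        ax.plot(prevalence.weights.columns, row.values, marker="o", label=topic)
    ax.set_xlabel("decade")
    ax.set_ylabel("summed topic weight")
    if prevalence.weights.shape[0] <= 12:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_cooccurrence(cooc: CooccurrenceMatrix, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(cooc.similarity, vmin=0, vmax=1, cmap="viridis")
    fig.colorbar(im, ax=ax, label="co-occurrence (0-1)")
    ax.set_xlabel("topic")
    ax.set_ylabel("topic")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_generality(gen: GeneralityStats, path: str | Path) -> None:
    t = gen.table
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(t["mean_weight_unselected"], t["mean_weight_selected"], s=18)
    for i, (name, row) in enumerate(t.iterrows()):
        if np.isfinite(row["mean_weight_selected"]):
            ax.annotate(str(i), (row["mean_weight_unselected"],
                                 row["mean_weight_selected"]), fontsize=7)
    ax.set_xlabel("mean weight when not selected")
    ax.set_ylabel("mean weight when selected")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_journal_shares(journals: JournalContribution, path: str | Path,
                        top_n: int = 25) -> None:
    counts = journals.counts.head(top_n)
    fig, ax = plt.subplots(figsize=(7, max(3, 0.25 * len(counts))))
    ax.barh(range(len(counts)), counts.values[::-1])
    ax.set_yticks(range(len(counts)))
    ax.set_yticklabels(list(counts.index)[::-1], fontsize=7)
    ax.set_xlabel("articles")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_country_counts(counts: pd.Series, path: str | Path,
                        top_n: int = 30) -> None:
    """Bar rendering of country counts (a full choropleth would need map
    geometry data; the TSV is the canonical output)."""
    counts = counts.head(top_n)
    fig, ax = plt.subplots(figsize=(7, max(3, 0.25 * len(counts))))
    ax.barh(range(len(counts)), counts.values[::-1])
    ax.set_yticks(range(len(counts)))
    ax.set_yticklabels(list(counts.index)[::-1], fontsize=7)
    ax.set_xlabel("articles mentioning country")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_popularity(ranef: pd.DataFrame, path: str | Path) -> None:
    """Random intercept vs. random slope per topic; quadrants mark
    popular/rising combinations."""
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    ax.scatter(ranef["b0"], ranef["b1"], s=18)
    for topic, row in ranef.iterrows():
        ax.annotate(str(topic), (row["b0"], row["b1"]), fontsize=7)
    ax.set_xlabel("random intercept b0 (popularity)")
    ax.set_ylabel("random slope b1 (trend)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
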
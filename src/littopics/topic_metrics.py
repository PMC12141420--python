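"""Derived statistics over a fitted topic model: decadal prevalence,
co-occurrence, generality vs. specificity, per-topic article frequency and
journal contribution.

All operations take the document-topic weight matrix theta (rows sum to 1)
plus per-article metadata; none of them refit anything, so they are cheap
and deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

DEFAULT_DECADES = ((1990, 1999), (2000, 2009), (2010, 2019))


def _check_theta(theta: np.ndarray) -> np.ndarray:
    theta = np.asarray(theta, dtype=np.float64)
    if theta.ndim != 2:
        raise ValueError("theta must be 2-D (documents x topics)")
    if not np.allclose(theta.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("theta rows must sum to 1")
    return theta


@dataclass
class PrevalenceTable:
    """Topic-by-decade summed weights and within-decade ranks."""

    weights: pd.DataFrame  # topics x decades, summed theta
    ranks: pd.DataFrame    # 1 = highest-weight topic in that decade
    n_excluded: int


def decadal_prevalence(
    theta: np.ndarray,
    years: Sequence[int | None],
    decades: Sequence[tuple[int, int]] = DEFAULT_DECADES,
) -> PrevalenceTable:
    """Sum each topic's article weights within each decade.

    Articles whose year is missing or falls outside the configured decades
    (e.g. the corpus's single 1989 article, or 2020+) are excluded, with
    the exclusion count logged and returned.
    """
    theta = _check_theta(theta)
    if len(years) != theta.shape[0]:
        raise ValueError("one year per theta row required")
    labels = [f"{lo}s" if lo % 10 == 0 else f"{lo}-{hi}" for lo, hi in decades]
    K = theta.shape[1]
    W = np.zeros((K, len(decades)))
    counts = np.zeros(len(decades), dtype=int)
    n_excluded = 0
    for row, year in enumerate(years):
        hit = None
        if year is not None:
            for j, (lo, hi) in enumerate(decades):
                if lo <= year <= hi:
                    hit = j
                    break
        if hit is None:
            n_excluded += 1
            continue
        W[:, hit] += theta[row]
        counts[hit] += 1
    if n_excluded:
        logger.info("decadal_prevalence: %d articles outside decades excluded",
                    n_excluded)
    topics = [f"topic{k}" for k in range(K)]
    weights = pd.DataFrame(W, index=topics, columns=labels)
    # rank 1 = highest summed weight within the decade
    ranks = weights.rank(axis=0, ascending=False, method="min").astype(int)
    return PrevalenceTable(weights=weights, ranks=ranks, n_excluded=n_excluded)


@dataclass
class CooccurrenceMatrix:
    """Similarity of topic pairs across articles, on a 0 (never co-occur)
    to 1 (always co-occur) scale, with the raw log10-Euclidean distances
    alongside."""

    similarity: np.ndarray  # K x K, symmetric, diagonal 1
    distance: np.ndarray    # raw Euclidean distances of log10 theta columns
    normalisation: str


def cooccurrence(theta: np.ndarray, normalisation: str = "max") -> CooccurrenceMatrix:
    """Topic co-occurrence from log10-transformed article weights.

    d_ij is the Euclidean distance between topics i and j's log10 weight
    profiles over articles; similarity is 1 - d/d_max ("max", default) or
    min-max rescaled ("minmax").  Requires strictly positive theta
    (Dirichlet-smoothed estimates guarantee this).
    """
    theta = _check_theta(theta)
    if theta.shape[0] < 2:
        raise ValueError("need at least 2 documents")
    if (theta <= 0).any():
        raise ValueError(
            "theta contains zeros; co-occurrence needs smoothed (strictly "
            "positive) topic weights")
    if normalisation not in ("max", "minmax"):
        raise ValueError("normalisation must be 'max' or 'minmax'")
    L = np.log10(theta)  # documents x topics
    diff = L[:, :, None] - L[:, None, :]
    dist = np.sqrt((diff ** 2).sum(axis=0))
    K = theta.shape[1]
    off = ~np.eye(K, dtype=bool)
    d_max = dist[off].max()
    if d_max == 0:
        sim = np.ones_like(dist)
    elif normalisation == "max":
        sim = 1.0 - dist / d_max
    else:
        d_min = dist[off].min()
        rng = d_max - d_min
        sim = 1.0 - (dist - d_min) / rng if rng > 0 else np.ones_like(dist)
        np.clip(sim, 0.0, 1.0, out=sim)
    np.fill_diagonal(sim, 1.0)
    return CooccurrenceMatrix(similarity=sim, distance=dist,
                              normalisation=normalisation)


def argmax_topics(theta: np.ndarray) -> np.ndarray:
    """Per-article highest-weight topic; ties broken by lowest topic index
    (np.argmax's first-maximum rule), logged when present."""
    theta = _check_theta(theta)
    sel = theta.argmax(axis=1)
    n_ties = int((np.sum(theta == theta.max(axis=1, keepdims=True), axis=1) > 1).sum())
    if n_ties:
        logger.info("argmax_topics: %d articles had tied maxima; lowest index used",
                    n_ties)
    return sel


@dataclass
class GeneralityStats:
    """Mean topic weight in articles where the topic is selected (argmax)
    versus where it is not; NaN selected mean for never-selected topics."""

    table: pd.DataFrame  # columns: n_selected, mean_weight_selected, mean_weight_unselected


def generality(theta: np.ndarray) -> GeneralityStats:
    theta = _check_theta(theta)
    D, K = theta.shape
    sel = argmax_topics(theta)
    rows = []
    for k in range(K):
        mask = sel == k
        n_sel = int(mask.sum())
        mean_sel = float(theta[mask, k].mean()) if n_sel else np.nan
        mean_unsel = float(theta[~mask, k].mean()) if n_sel < D else np.nan
        rows.append((n_sel, mean_sel, mean_unsel))
    table = pd.DataFrame(
        rows, columns=["n_selected", "mean_weight_selected", "mean_weight_unselected"],
        index=[f"topic{k}" for k in range(K)])
    return GeneralityStats(table=table)


def article_topic_frequency(
    theta: np.ndarray, bins: int = 10
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-topic article frequency, in both plausible constructions: (a)
    counts of articles where the topic has the highest weight, and (b) the
    histogram of the topic's weights across all articles."""
    theta = _check_theta(theta)
    K = theta.shape[1]
    sel = argmax_topics(theta)
    topics = [f"topic{k}" for k in range(K)]
    counts = pd.Series(np.bincount(sel, minlength=K), index=topics,
                       name="n_argmax_articles")
    edges = np.linspace(0.0, 1.0, bins + 1)
    hist = np.stack([np.histogram(theta[:, k], bins=edges)[0] for k in range(K)])
    cols = [f"[{edges[i]:.2f},{edges[i+1]:.2f})" for i in range(bins)]
    return counts, pd.DataFrame(hist, index=topics, columns=cols)


@dataclass
class JournalContribution:
    counts: pd.Series          # per-journal article counts, descending
    cumulative_share: pd.Series  # top-N cumulative share of all articles, percent
    topic_profile: pd.DataFrame  # per-journal mean theta
    argmax_counts: pd.DataFrame  # per-journal articles per argmax topic

    def top_share(self, n: int) -> float:
        """Percent of all articles contributed by the top-n journals."""
        n = min(n, len(self.cumulative_share))
        return float(self.cumulative_share.iloc[n - 1])


def journal_contribution(
    journals: Sequence[str], theta: np.ndarray
) -> JournalContribution:
    """Rank journals by article count (ties lexicographic) and profile each
    journal's topics by mean theta and argmax counts."""
    theta = _check_theta(theta)
    if len(journals) != theta.shape[0]:
        raise ValueError("one journal per theta row required")
    K = theta.shape[1]
    df = pd.DataFrame({"journal": list(journals)})
    counts = (
        df.groupby("journal").size()
        .sort_index()                       # lexicographic tie-break...
        .sort_values(ascending=False, kind="stable")  # ...then by count
    )
    cum = counts.cumsum() / counts.sum() * 100.0
    sel = argmax_topics(theta)
    topics = [f"topic{k}" for k in range(K)]
    prof = pd.DataFrame(theta, columns=topics).groupby(df["journal"].values).mean()
    am = (
        pd.crosstab(pd.Series(list(journals), name="journal"),
                    pd.Series([topics[k] for k in sel], name="topic"))
        .reindex(columns=topics, fill_value=0)
        .reindex(index=counts.index)
    )
    prof = prof.reindex(counts.index)
    return JournalContribution(
        counts=counts.rename("n_articles"),
        cumulative_share=cum.rename("cumulative_share_pct"),
        topic_profile=prof, argmax_counts=am)


def write_metrics(
    outdir: str | Path,
    prevalence: PrevalenceTable | None = None,
    cooc: CooccurrenceMatrix | None = None,
    gen: GeneralityStats | None = None,
    journals: JournalContribution | None = None,
) -> None:
    """Write all computed tables as TSV (matrices additionally as MTX)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if prevalence is not None:
        prevalence.weights.to_csv(outdir / "prevalence_weights.tsv", sep="\t")
        prevalence.ranks.to_csv(outdir / "prevalence_ranks.tsv", sep="\t")
    if cooc is not None:
        K = cooc.similarity.shape[0]
        topics = [f"topic{k}" for k in range(K)]
        pd.DataFrame(cooc.similarity, index=topics, columns=topics).to_csv(
            outdir / "cooccurrence.tsv", sep="\t")
        pd.DataFrame(cooc.distance, index=topics, columns=topics).to_csv(
            outdir / "cooccurrence_distance.tsv", sep="\t")
        scipy.io.mmwrite(outdir / "cooccurrence.mtx",
                         sp.coo_matrix(cooc.similarity))
    if gen is not None:
        gen.table.to_csv(outdir / "generality.tsv", sep="\t")
    if journals is not None:
        pd.concat([journals.counts, journals.cumulative_share], axis=1).to_csv(
            outdir / "journal_counts.tsv", sep="\t")
        journals.topic_profile.to_csv(outdir / "journal_topic_profile.tsv", sep="\t")
        journals.argmax_counts.to_csv(outdir / "journal_argmax_counts.tsv", sep="\t")
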
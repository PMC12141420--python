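"""Synthetic corpus generator with known LDA ground truth.

Emulates a corpus of short abstracts spanning a multi-decade window:
documents are drawn from an LDA generative model with K_true topics whose
prevalence drifts over time (a year-dependent softmax tilt of the
Dirichlet document-topic prior), with journal labels and optional injected
country mentions and cleaning decoys.  Tokens are rendered as stem-like
pseudo-words ("w0001", ...) so that preprocessing is a near-no-op and
recovery tests do not depend on stemmer behaviour; decoy stop-words,
spelled-out numbers, punctuation and publisher boilerplate exercise the
cleaning pipeline and must vanish from the vocabulary.

The same (config, seed) always yields a byte-identical corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .bib_io import BibRecord


@dataclass
class SimulationConfig:
    """Generating parameters; defaults emulate a mid-sized abstract corpus
    with mildly sparse topic mixtures and weak decadal trends."""

    K_true: int = 5
    V: int = 500
    D: int = 500
    mean_doc_length: float = 100.0
    alpha_true: float = 0.1
    beta_true: float = 0.01
    year_range: tuple[int, int] = (1990, 2019)
    trend_intercepts: tuple[float, ...] | None = None  # default zeros
    trend_slopes: tuple[float, ...] | None = None      # per-topic, per scaled year
    n_journals: int = 20
    journal_concentration: float = 1.0
    country_rate: float = 0.0       # expected country mentions per document
    countries: tuple[str, ...] = (
        "United Kingdom", "United States", "China", "Australia", "Spain")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K_true < 2 or self.V < 2 or self.D < 1:
            raise ValueError("need K_true >= 2, V >= 2, D >= 1")
        if self.mean_doc_length <= 0 or self.alpha_true <= 0 or self.beta_true <= 0:
            raise ValueError("lengths and concentrations must be positive")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("empty year_range")
        if self.n_journals < 1 or self.journal_concentration <= 0:
            raise ValueError("invalid journal settings")
        if self.country_rate < 0:
            raise ValueError("country_rate must be >= 0")
        for name in ("trend_intercepts", "trend_slopes"):
            v = getattr(self, name)
            if v is not None and len(v) != self.K_true:
                raise ValueError(f"{name} must have K_true entries")


@dataclass
class SyntheticTruth:
    """Everything needed to score recovery of the generating process."""

    config: SimulationConfig
    phi_true: np.ndarray     # K_true x V
    theta_true: np.ndarray   # D x K_true
    years: np.ndarray
    journals: list[str]
    injected_countries: list[list[str]]
    doc_ids: list[str]
    vocabulary: list[str]


def _softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max())
    return e / e.sum()


def generate_corpus(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[list[BibRecord], SyntheticTruth]:
    """Draw a corpus of BibRecords plus its generating truth.

    Per document: a year is drawn uniformly over ``year_range``; the
    document-topic Dirichlet prior is tilted by the year-dependent softmax
    trend, theta_d ~ Dirichlet(alpha_d); the document length is Poisson;
    tokens follow z ~ theta_d, w ~ phi_z.  Journal labels come from a
    Dirichlet-multinomial over ``n_journals`` journals, and country
    mentions are appended as plain sentences at rate ``country_rate``.
    """
    if config is None:
        config = SimulationConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    K, V, D = config.K_true, config.V, config.D

    vocabulary = [f"w{j:04d}" for j in range(V)]
    phi = rng.dirichlet(np.full(V, config.beta_true), size=K)
    phi = np.maximum(phi, 1e-12)
    phi /= phi.sum(axis=1, keepdims=True)

    intercepts = np.array(config.trend_intercepts
                          if config.trend_intercepts is not None
                          else np.zeros(K), dtype=float)
    slopes = np.array(config.trend_slopes
                      if config.trend_slopes is not None
                      else np.zeros(K), dtype=float)

    lo, hi = config.year_range
    years = rng.integers(lo, hi + 1, size=D)
    span = max(hi - lo, 1)
    t_scaled = (years - (lo + hi) / 2) / (span / 2)  # in [-1, 1]

    journal_probs = rng.dirichlet(
        np.full(config.n_journals, config.journal_concentration))
    journal_names = [f"Journal of Synthetic Studies {j + 1:02d}"
                     for j in range(config.n_journals)]

    theta = np.empty((D, K))
    records: list[BibRecord] = []
    injected: list[list[str]] = []
    for d in range(D):
        tilt = _softmax(intercepts + slopes * t_scaled[d])
        alpha_d = config.alpha_true * K * tilt
        theta_d = rng.dirichlet(np.maximum(alpha_d, 1e-6))
        theta_d = np.maximum(theta_d, 1e-12)
        theta_d /= theta_d.sum()
        theta[d] = theta_d
        n_tokens = rng.poisson(config.mean_doc_length)
        z = rng.choice(K, size=n_tokens, p=theta_d)
        words = [vocabulary[rng.choice(V, p=phi[k])] for k in z]
        mentions: list[str] = []
        if config.country_rate > 0:
            for _ in range(rng.poisson(config.country_rate)):
                mentions.append(str(rng.choice(list(config.countries))))
        injected.append(mentions)
        abstract = " ".join(words)
        if mentions:
            abstract += " " + " ".join(f"Sites in {c}." for c in mentions)
        journal = journal_names[rng.choice(config.n_journals, p=journal_probs)]
        records.append(BibRecord(
            record_id=f"synth{d:05d}",
            title=f"Synthetic article {d}",
            abstract=abstract,
            year=int(years[d]),
            journal=journal,
            source_db="other",
        ))
    truth = SyntheticTruth(
        config=config, phi_true=phi, theta_true=theta, years=years,
        journals=[r.journal for r in records], injected_countries=injected,
        doc_ids=[r.record_id for r in records], vocabulary=vocabulary)
    return records, truth


def topic_recovery_score(
    phi_fitted: np.ndarray,
    fitted_terms: Sequence[str],
    truth: SyntheticTruth,
) -> tuple[float, np.ndarray]:
    """Mean cosine similarity between fitted and true topic-word rows after
    Hungarian matching.

    The fitted vocabulary may be a subset of the generator's (rare-term
    filtering); true phi rows are restricted to the fitted terms and
    renormalised before comparison.  Returns (mean cosine, matching) where
    matching[i] is the true topic matched to fitted topic i.
    """
    from scipy.optimize import linear_sum_assignment

    tidx = [truth.vocabulary.index(t) for t in fitted_terms]
    phi_true = truth.phi_true[:, tidx]
    phi_true = phi_true / phi_true.sum(axis=1, keepdims=True)
    K_fit, K_true = phi_fitted.shape[0], phi_true.shape[0]
    sim = np.zeros((K_fit, K_true))
    for i in range(K_fit):
        for j in range(K_true):
            denom = np.linalg.norm(phi_fitted[i]) * np.linalg.norm(phi_true[j])
            sim[i, j] = float(phi_fitted[i] @ phi_true[j] / denom)
    rows, cols = linear_sum_assignment(-sim)
    return float(sim[rows, cols].mean()), cols


DECOY_BOILERPLATE = "All rights reserved by the publisher"
DECOY_STOPWORDS = ("the", "of", "and", "with", "from")
DECOY_NUMBERS = ("twenty", "five", "hundred", "third")


@dataclass
class NoiseConfig:
    """Decoy-token injection settings; every decoy must be removed by the
    cleaning pipeline (or the rare-term filter)."""

    stopword_tokens_per_doc: int = 5
    number_tokens_per_doc: int = 2
    hyphenated_per_doc: int = 1
    boilerplate_every: int = 3   # append boilerplate to every n-th document
    rare_decoy_term: str | None = None
    rare_decoy_n_docs: int = 0
    seed: int = 0


def inject_noise(
    records: Sequence[BibRecord], noise: NoiseConfig | None = None
) -> tuple[list[BibRecord], dict[str, int]]:
    """Return noised copies of the records plus counts of injected decoys.

    Stop-words and number-words are spliced between tokens; hyphenated
    variants of existing pseudo-words ("w0001-w0002") exercise the
    hyphen-to-space rule; boilerplate sentences exercise publisher-term
    removal.  A rare decoy term can be planted in exactly n documents to
    probe the document-frequency boundary.
    """
    if noise is None:
        noise = NoiseConfig()
    rng = np.random.default_rng(noise.seed)
    injected = {"stopwords": 0, "numbers": 0, "hyphenated": 0,
                "boilerplate": 0, "rare_decoy_docs": 0}
    out: list[BibRecord] = []
    for i, r in enumerate(records):
        tokens = r.abstract.split()
        for _ in range(noise.stopword_tokens_per_doc):
            pos = rng.integers(0, len(tokens) + 1)
            tokens.insert(int(pos), str(rng.choice(list(DECOY_STOPWORDS))))
            injected["stopwords"] += 1
        for _ in range(noise.number_tokens_per_doc):
            pos = rng.integers(0, len(tokens) + 1)
            tokens.insert(int(pos), str(rng.choice(list(DECOY_NUMBERS))))
            injected["numbers"] += 1
        for _ in range(noise.hyphenated_per_doc):
            if len(tokens) >= 2:
                pos = int(rng.integers(0, len(tokens) - 1))
                tokens[pos] = tokens[pos] + "-" + tokens[pos + 1]
                del tokens[pos + 1]
                injected["hyphenated"] += 1
        text = " ".join(tokens)
        if noise.boilerplate_every and i % noise.boilerplate_every == 0:
            text += ". " + DECOY_BOILERPLATE + "."
            injected["boilerplate"] += 1
        if (noise.rare_decoy_term and i < noise.rare_decoy_n_docs):
            text += " " + noise.rare_decoy_term
            injected["rare_decoy_docs"] += 1
        out.append(replace(r, abstract=text))
    return out, injected
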
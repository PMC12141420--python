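"""Abstract cleaning and document-term matrix construction.

The cleaning recipe is a fixed pipeline: lowercase, delete search-term
phrases, map hyphens and forward slashes to spaces, strip remaining
punctuation, tokenise on whitespace, drop number-words / stop-words /
publisher boilerplate, then Porter-stem each surviving token.  Terms that
appear in five or fewer documents are removed from the vocabulary
(``min_doc_frequency`` = 6 by default).
"""

from __future__ import annotations

import logging
import re
import string
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp
import yaml

from ._porter import stem

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """The cleaning pipeline produced an unusable (all-empty) corpus."""


def _load_wordlist(name: str) -> list[str]:
    text = resources.files("littopics.data").joinpath(name).read_text(encoding="utf-8")
    return [w.strip() for w in text.splitlines()
            if w.strip() and not w.startswith("#")]


DEFAULT_SEARCH_TERMS = ("phenolog*", "global chang*", "climat* chang*", "global warm*")


@dataclass
class CleaningConfig:
    """Configuration of the cleaning pipeline.

    ``search_terms`` are phrase patterns in stemmed form; a trailing ``*``
    (or none) on a pattern word makes it a prefix match, so ``"climat*
    chang*"`` deletes "climate change", "climatic changes", etc.  All word
    lists must be lowercase.
    """

    search_terms: tuple[str, ...] = DEFAULT_SEARCH_TERMS
    number_words: frozenset[str] = field(
        default_factory=lambda: frozenset(_load_wordlist("number_words.txt")))
    stop_words: frozenset[str] = field(
        default_factory=lambda: frozenset(_load_wordlist("stopwords_en.txt")))
    extra_publisher_terms: frozenset[str] = field(
        default_factory=lambda: frozenset(_load_wordlist("publisher_terms.txt")))
    min_doc_frequency: int = 6

    def __post_init__(self) -> None:
        if self.min_doc_frequency < 1:
            raise ValueError("min_doc_frequency must be >= 1")
        for lst in (self.number_words, self.stop_words, self.extra_publisher_terms):
            bad = [w for w in lst if w != w.lower()]
            if bad:
                raise ValueError(f"word lists must be lowercase; offending: {bad[:5]}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CleaningConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "search_terms" in raw:
            kwargs["search_terms"] = tuple(raw["search_terms"])
        for key in ("number_words", "stop_words", "extra_publisher_terms"):
            if key in raw:
                kwargs[key] = frozenset(raw[key])
        if "min_doc_frequency" in raw:
            kwargs["min_doc_frequency"] = int(raw["min_doc_frequency"])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "search_terms": list(self.search_terms),
            "number_words": sorted(self.number_words),
            "stop_words": sorted(self.stop_words),
            "extra_publisher_terms": sorted(self.extra_publisher_terms),
            "min_doc_frequency": self.min_doc_frequency,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


_HYPHEN_SLASH = re.compile(r"[-/‐-―]")
_PUNCT_TABLE = str.maketrans({c: "" for c in string.punctuation})


def _phrase_regex(pattern: str) -> re.Pattern:
    # Pattern words are stems, so raw-text matching is always prefix-based:
    # "climat* chang*" hits "climate change" and "climatic changes" alike.
    parts = [re.escape(w.rstrip("*")) + r"\w*" for w in pattern.split()]
    return re.compile(r"\b" + r"\s+".join(parts) + r"\b")


def _pattern_words(pattern: str) -> list[str]:
    return [w.rstrip("*") for w in pattern.split()]


def _strip_phrase_stems(tokens: list[str], patterns: Sequence[str]) -> list[str]:
    """Post-stemming safety net: drop n-gram runs whose stems prefix-match a
    search pattern."""
    pats = [_pattern_words(p) for p in patterns]
    out: list[str] = []
    i = 0
    while i < len(tokens):
        hit = 0
        for words in pats:
            n = len(words)
            if i + n <= len(tokens) and all(
                tokens[i + j].startswith(words[j]) for j in range(n)
            ):
                hit = max(hit, n)
        if hit:
            i += hit
        else:
            out.append(tokens[i])
            i += 1
    return out


def clean_text(text: str, config: CleaningConfig | None = None) -> list[str]:
    """Run the full cleaning pipeline on one abstract; returns stems."""
    if config is None:
        config = CleaningConfig()
    text = unicodedata.normalize("NFKC", text).lower()
    for pattern in config.search_terms:
        text = _phrase_regex(pattern).sub(" ", text)
    text = _HYPHEN_SLASH.sub(" ", text)
    text = text.translate(_PUNCT_TABLE)
    drop = config.number_words | config.stop_words | config.extra_publisher_terms
    tokens = [t for t in text.split() if t not in drop and not t.isdigit()]
    stems = [stem(t) for t in tokens]
    return _strip_phrase_stems(stems, config.search_terms)


@dataclass
class Vocabulary:
    """Retained stems (lexicographic order) with their document frequencies."""

    terms: list[str]
    doc_frequency: np.ndarray

    def __post_init__(self) -> None:
        if len(self.terms) != len(set(self.terms)):
            raise ValueError("vocabulary terms must be unique")
        if list(self.terms) != sorted(self.terms):
            raise ValueError("vocabulary terms must be sorted")

    def __len__(self) -> int:
        return len(self.terms)

    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.terms)}


@dataclass
class DocTermMatrix:
    """Sparse document-by-term count matrix with aligned ids.

    ``fitted_mask`` flags the rows that survived cleaning with at least one
    token; all-zero rows are retained for bookkeeping but excluded from
    model fitting.
    """

    counts: sp.csr_matrix
    doc_ids: list[str]
    vocabulary: Vocabulary

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.doc_ids), len(self.vocabulary)):
            raise ValueError("counts shape inconsistent with ids/vocabulary")
        if (self.counts.data < 0).any():
            raise ValueError("negative counts")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def fitted_mask(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel() > 0

    def fitted(self) -> "DocTermMatrix":
        """Submatrix of documents with at least one retained token."""
        mask = self.fitted_mask
        return DocTermMatrix(
            counts=self.counts[mask],
            doc_ids=[d for d, m in zip(self.doc_ids, mask) if m],
            vocabulary=self.vocabulary,
        )

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(outdir / "counts.mtx", self.counts.tocoo(), field="integer")
        (outdir / "terms.txt").write_text(
            "".join(f"{t}\t{df}\n" for t, df in
                    zip(self.vocabulary.terms, self.vocabulary.doc_frequency)),
            encoding="utf-8")
        (outdir / "doc_ids.txt").write_text(
            "".join(d + "\n" for d in self.doc_ids), encoding="utf-8")

    @classmethod
    def read(cls, indir: str | Path) -> "DocTermMatrix":
        indir = Path(indir)
        counts = sp.csr_matrix(scipy.io.mmread(indir / "counts.mtx"))
        terms, dfs = [], []
        for line in (indir / "terms.txt").read_text(encoding="utf-8").splitlines():
            t, df = line.split("\t")
            terms.append(t)
            dfs.append(int(df))
        doc_ids = (indir / "doc_ids.txt").read_text(encoding="utf-8").splitlines()
        return cls(counts=counts, doc_ids=doc_ids,
                   vocabulary=Vocabulary(terms, np.array(dfs)))


def build_dtm(
    token_lists: Sequence[list[str]],
    config: CleaningConfig | None = None,
    doc_ids: Sequence[str] | None = None,
) -> tuple[DocTermMatrix, Vocabulary]:
    """Assemble the document-term matrix, applying the rare-term filter.

    Terms appearing in fewer than ``config.min_doc_frequency`` documents
    (i.e. in five or fewer, at the default) are removed completely.
    Documents emptied by the filter stay as all-zero rows, flagged via
    ``DocTermMatrix.fitted_mask``.
    """
    if config is None:
        config = CleaningConfig()
    if len(token_lists) == 0:
        raise PipelineError("no documents")
    if doc_ids is None:
        doc_ids = [f"doc{i:06d}" for i in range(len(token_lists))]
    if len(doc_ids) != len(token_lists):
        raise ValueError("doc_ids length mismatch")

    df_counter: dict[str, int] = {}
    for toks in token_lists:
        for t in set(toks):
            df_counter[t] = df_counter.get(t, 0) + 1
    kept = sorted(t for t, df in df_counter.items() if df >= config.min_doc_frequency)
    if not kept:
        raise PipelineError(
            "all terms fell below the document-frequency threshold; "
            "no vocabulary remains")
    vocab = Vocabulary(kept, np.array([df_counter[t] for t in kept]))
    idx = vocab.index()

    rows, cols, vals = [], [], []
    n_empty = 0
    for d, toks in enumerate(token_lists):
        counts: dict[int, int] = {}
        for t in toks:
            j = idx.get(t)
            if j is not None:
                counts[j] = counts.get(j, 0) + 1
        if not counts:
            n_empty += 1
        for j, c in sorted(counts.items()):
            rows.append(d)
            cols.append(j)
            vals.append(c)
    if n_empty:
        logger.warning("%d documents empty after cleaning; retained as zero rows "
                       "and excluded from fitting", n_empty)
    if n_empty == len(token_lists):
        raise PipelineError("every document is empty after cleaning")
    counts = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(token_lists), len(kept)), dtype=np.int64)
    return DocTermMatrix(counts=counts, doc_ids=list(doc_ids), vocabulary=vocab), vocab


def clean_corpus(
    records: Iterable, config: CleaningConfig | None = None
) -> tuple[DocTermMatrix, Vocabulary]:
    """Convenience: clean every record's abstract and build the DTM, using
    record ids as row ids."""
    records = list(records)
    token_lists = [clean_text(r.abstract, config) for r in records]
    return build_dtm(token_lists, config, doc_ids=[r.record_id for r in records])
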
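"""Bibliographic record IO, deduplication, screening bookkeeping and
inter-rater agreement.

Records are kept as a light dataclass rather than a DataFrame because the
screening workflow mutates per-record flags; conversion helpers to/from
pandas are provided for analyses.
"""

from __future__ import annotations

import csv
import json
import logging
import re
import string
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score

logger = logging.getLogger(__name__)

SOURCE_DBS = ("wos", "scopus", "other")

CSV_HEADER = ["id", "title", "abstract", "year", "journal", "source_db"]


class FormatError(ValueError):
    """A bibliographic file could not be parsed in the named dialect."""


class UndefinedKappaError(ValueError):
    """Cohen's kappa is undefined (chance agreement equals 1)."""


@dataclass
class BibRecord:
    """One screened article.

    ``included`` stores the human screening decision; it is never inferred
    by this package.
    """

    record_id: str
    title: str = ""
    abstract: str = ""
    year: int | None = None
    journal: str = ""
    source_db: str = "other"
    included: bool | None = None

    def __post_init__(self) -> None:
        if self.source_db not in SOURCE_DBS:
            raise ValueError(f"source_db must be one of {SOURCE_DBS}")
        if self.year is not None and not (1900 <= self.year <= 2100):
            raise ValueError(f"year {self.year} outside [1900, 2100]")


@dataclass
class ScreeningPair:
    """Ratings of one double-screened record by both reviewers."""

    record_id: str
    rating_a: bool
    rating_b: bool


def _check_unique_ids(records: Sequence[BibRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.record_id in seen:
            raise FormatError(f"duplicate record_id {r.record_id!r}")
        seen.add(r.record_id)


def _parse_year(raw: str, where: str) -> int | None:
    raw = raw.strip()
    m = re.search(r"\b(\d{4})\b", raw)
    if not m:
        if raw:
            warnings.warn(f"unparseable year {raw!r} in {where}; stored as missing")
        else:
            warnings.warn(f"missing year in {where}")
        return None
    return int(m.group(1))


# ---------------------------------------------------------------------------
# readers

def _read_csv(path: Path) -> list[BibRecord]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != CSV_HEADER:
            raise FormatError(
                f"{path}: CSV header must be exactly {','.join(CSV_HEADER)}"
            )
        records = []
        for i, row in enumerate(reader, start=2):
            if row["id"] is None or not row["id"].strip():
                raise FormatError(f"{path} line {i}: empty id")
            records.append(
                BibRecord(
                    record_id=row["id"].strip(),
                    title=(row["title"] or "").strip(),
                    abstract=(row["abstract"] or "").strip(),
                    year=_parse_year(row["year"] or "", f"{path} line {i}"),
                    journal=(row["journal"] or "").strip(),
                    source_db=(row["source_db"] or "other").strip() or "other",
                )
            )
    return records


_RIS_TAG = re.compile(r"^([A-Z][A-Z0-9])  - ?(.*)$")


def _read_ris(path: Path) -> list[BibRecord]:
    records: list[BibRecord] = []
    entry: dict[str, list[str]] = {}
    n_entries = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            m = _RIS_TAG.match(line)
            if not m:
                # continuation line of the previous tag
                if entry and "_last" in entry:
                    entry[entry["_last"][0]][-1] += " " + line.strip()
                    continue
                raise FormatError(f"{path} line {lineno}: not a RIS tag line: {line!r}")
            tag, value = m.group(1), m.group(2).strip()
            if tag == "TY":
                if entry.get("TY"):
                    raise FormatError(f"{path} line {lineno}: TY before ER of previous entry")
                entry = {"TY": [value]}
            elif tag == "ER":
                if not entry:
                    raise FormatError(f"{path} line {lineno}: ER without entry")
                n_entries += 1
                records.append(_ris_entry_to_record(entry, n_entries, path))
                entry = {}
            else:
                entry.setdefault(tag, []).append(value)
                entry["_last"] = [tag]
    if entry:
        raise FormatError(f"{path}: final entry not terminated by ER tag")
    return records


def _ris_entry_to_record(entry: dict[str, list[str]], n: int, path: Path) -> BibRecord:
    def first(*tags: str) -> str:
        for t in tags:
            if entry.get(t):
                return entry[t][0]
        return ""

    rid = first("ID", "AN") or f"ris-{n:06d}"
    year_raw = first("PY", "Y1")
    return BibRecord(
        record_id=rid,
        title=first("TI", "T1"),
        abstract=first("AB", "N2"),
        year=_parse_year(year_raw, f"{path} entry {n}") if year_raw else _warn_missing(n, path),
        journal=first("JO", "JF", "T2"),
        source_db="other",
    )


def _warn_missing(n: int, path: Path) -> None:
    warnings.warn(f"missing year in {path} entry {n}")
    return None


_BIB_ENTRY = re.compile(r"@(\w+)\s*\{\s*([^,\s]+)\s*,", re.MULTILINE)


def _read_bibtex(path: Path) -> list[BibRecord]:
    text = Path(path).read_text(encoding="utf-8")
    records: list[BibRecord] = []
    matches = list(_BIB_ENTRY.finditer(text))
    if not matches and text.strip():
        raise FormatError(f"{path}: no BibTeX entries found")
    for i, m in enumerate(matches):
        end = matches[i + 1].start() if i + 1 < len(matches) else len(text)
        body = text[m.end():end]
        fields = _parse_bib_fields(body, path, m.group(2))
        year_raw = fields.get("year", "")
        records.append(
            BibRecord(
                record_id=m.group(2),
                title=fields.get("title", ""),
                abstract=fields.get("abstract", ""),
                year=_parse_year(year_raw, f"{path} entry {m.group(2)}")
                if year_raw
                else _warn_missing(i + 1, path),
                journal=fields.get("journal", ""),
                source_db="other",
            )
        )
    return records


def _parse_bib_fields(body: str, path: Path, key: str) -> dict[str, str]:
    fields: dict[str, str] = {}
    pos = 0
    pat = re.compile(r"(\w+)\s*=\s*", re.MULTILINE)
    while True:
        m = pat.search(body, pos)
        if not m:
            break
        name = m.group(1).lower()
        i = m.end()
        if i >= len(body):
            break
        ch = body[i]
        if ch == "{":
            depth, j = 1, i + 1
            while j < len(body) and depth:
                if body[j] == "{":
                    depth += 1
                elif body[j] == "}":
                    depth -= 1
                j += 1
            if depth:
                raise FormatError(f"{path} entry {key}: unbalanced braces in field {name}")
            value = body[i + 1 : j - 1]
            pos = j
        elif ch == '"':
            j = body.find('"', i + 1)
            if j < 0:
                raise FormatError(f"{path} entry {key}: unterminated string in field {name}")
            value = body[i + 1 : j]
            pos = j + 1
        else:
            m2 = re.match(r"[^,}\n]*", body[i:])
            value = m2.group(0)
            pos = i + len(value)
        fields[name] = re.sub(r"\s+", " ", value).strip().strip("{}")
    return fields


def read_records(path: str | Path, format: str) -> list[BibRecord]:
    """Read bibliographic records from ``path`` in the named dialect.

    Missing abstracts are stored as empty strings (dropping them is a
    separate, explicit step).  Missing years are kept as ``None`` with a
    warning.  Duplicate ``record_id`` values raise :class:`FormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        records = _read_csv(path)
    elif format == "ris":
        records = _read_ris(path)
    elif format == "bibtex":
        records = _read_bibtex(path)
    elif format == "jsonl":
        records = read_jsonl(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    _check_unique_ids(records)
    return records


def write_jsonl(records: Iterable[BibRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(json.dumps(asdict(r), sort_keys=True) + "\n")


def read_jsonl(path: str | Path) -> list[BibRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                records.append(BibRecord(**json.loads(line)))
    return records


def write_csv(records: Iterable[BibRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(CSV_HEADER)
        for r in records:
            w.writerow(
                [r.record_id, r.title, r.abstract,
                 "" if r.year is None else r.year, r.journal, r.source_db]
            )


# ---------------------------------------------------------------------------
# deduplication and screening

_PUNCT_TABLE = str.maketrans({c: " " for c in string.punctuation})


def normalise_title(title: str) -> str:
    """Casefold, strip punctuation, collapse whitespace."""
    return " ".join(title.casefold().translate(_PUNCT_TABLE).split())


def deduplicate(
    records: Sequence[BibRecord], fuzzy: bool = False, fuzzy_max_dist: int = 2
) -> tuple[list[BibRecord], list[str]]:
    """Remove records whose normalised title AND year match an earlier one.

    The first occurrence is kept. With ``fuzzy=True`` titles within
    ``fuzzy_max_dist`` Levenshtein edits (same year) are also merged;
    default off because silent fuzzy merging is riskier than a missed
    duplicate.

    Returns ``(kept_records, removed_ids)``.
    """
    kept: list[BibRecord] = []
    removed: list[str] = []
    seen: dict[tuple[str, int | None], str] = {}
    for r in records:
        key = (normalise_title(r.title), r.year)
        if key in seen:
            removed.append(r.record_id)
            logger.info("dedup: %s duplicates %s", r.record_id, seen[key])
            continue
        if fuzzy and _fuzzy_hit(key, seen, fuzzy_max_dist):
            removed.append(r.record_id)
            continue
        seen[key] = r.record_id
        kept.append(r)
    return kept, removed


def _levenshtein(a: str, b: str, limit: int) -> int:
    if abs(len(a) - len(b)) > limit:
        return limit + 1
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        if min(cur) > limit:
            return limit + 1
        prev = cur
    return prev[-1]


def _fuzzy_hit(key, seen, max_dist: int) -> bool:
    title, year = key
    return any(
        y == year and _levenshtein(title, t, max_dist) <= max_dist
        for (t, y) in seen
    )


def drop_missing_abstracts(records: Sequence[BibRecord]) -> list[BibRecord]:
    """Remove records with empty abstracts (articles whose abstract could not
    be found are excluded from the corpus)."""
    kept = [r for r in records if r.abstract.strip()]
    if not kept and records:
        warnings.warn("all records lacked abstracts; empty corpus")
    return kept


def sample_double_screen(
    records: Sequence[BibRecord], fraction: float = 0.2, seed: int = 0
) -> list[str]:
    """Seeded random sample of record ids for second-reviewer screening."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    ids = [r.record_id for r in records]
    n = max(1, round(fraction * len(ids))) if ids else 0
    return sorted(rng.choice(ids, size=n, replace=False).tolist())


def cohen_kappa(pairs: Sequence[ScreeningPair]) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e) between the
    two reviewers' include/exclude ratings.

    Raises :class:`UndefinedKappaError` when both raters are constant and
    identical (p_e = 1, the statistic is undefined).
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 screening pairs")
    a = np.array([p.rating_a for p in pairs], dtype=int)
    b = np.array([p.rating_b for p in pairs], dtype=int)
    # p_e from the raters' marginals
    p_e = float(np.mean(a) * np.mean(b) + (1 - np.mean(a)) * (1 - np.mean(b)))
    if p_e >= 1.0 - 1e-15:
        raise UndefinedKappaError("both raters constant and identical; kappa undefined")
    return float(cohen_kappa_score(a, b))


def records_to_frame(records: Sequence[BibRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records]).set_index("record_id")
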
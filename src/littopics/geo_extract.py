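"""Country-mention extraction from abstracts.

Matching is literal, token-boundary anchored and case-insensitive (so
"Nigeria" never counts for Niger), with an alias dictionary mapping
variants ("UK", "Britain", "USA", "America") to canonical country names.
An article counts at most once per country however many times it mentions
it.  Words that are countries only in some contexts ("Georgia", "Jordan",
"Chad", "Turkey") are by default matched only when capitalised in the
source text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml


class AliasConfigError(ValueError):
    """The alias map is inconsistent (e.g. one alias for two countries)."""


@dataclass
class CountryAliasMap:
    """Canonical country name -> aliases, plus the set of ambiguous names
    that require capitalisation in the source text."""

    aliases: dict[str, list[str]]
    ambiguous: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for canonical, names in self.aliases.items():
            if not names:
                raise AliasConfigError(f"{canonical}: empty alias list")
            for a in names:
                key = a.casefold()
                if not key:
                    raise AliasConfigError(f"{canonical}: blank alias")
                if key in seen and seen[key] != canonical:
                    raise AliasConfigError(
                        f"alias {a!r} maps to both {seen[key]} and {canonical}")
                seen[key] = canonical

    @classmethod
    def default(cls) -> "CountryAliasMap":
        text = resources.files("littopics.data").joinpath(
            "country_aliases.yaml").read_text(encoding="utf-8")
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CountryAliasMap":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def from_dict(cls, raw: dict) -> "CountryAliasMap":
        ambiguous = frozenset(
            a.casefold() for a in raw.pop("_ambiguous", []))
        aliases = {}
        for canonical, extra in raw.items():
            names = [canonical] + list(extra or [])
            aliases[canonical] = names
        return cls(aliases=aliases, ambiguous=ambiguous)

    def to_yaml(self, path: str | Path) -> None:
        raw: dict = {}
        for canonical, names in self.aliases.items():
            raw[canonical] = [n for n in names if n != canonical]
        raw["_ambiguous"] = sorted(self.ambiguous)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True, allow_unicode=True)


def _compile(alias_map: CountryAliasMap, match_ambiguous_lowercase: bool):
    """One regex per (canonical, alias); multi-word aliases as phrases."""
    compiled = []
    for canonical, names in alias_map.aliases.items():
        for a in names:
            parts = [re.escape(w) for w in a.split()]
            pat = r"(?<!\w)" + r"\s+".join(parts) + r"(?!\w)"
            ambiguous = a.casefold() in alias_map.ambiguous
            if ambiguous and not match_ambiguous_lowercase:
                rx = re.compile(pat)  # case-sensitive: as written (capitalised)
            else:
                rx = re.compile(pat, re.IGNORECASE)
            compiled.append((canonical, rx))
    return compiled


def extract_countries(
    records: Iterable,
    alias_map: CountryAliasMap | None = None,
    match_ambiguous_lowercase: bool = False,
) -> tuple[pd.Series, dict[str, set[str]]]:
    """Count, per country, the articles mentioning it.

    Runs on the raw (pre-cleaning) abstract text.  Returns the per-country
    article counts (descending) and the per-article country sets for
    audit.  Records may be BibRecords or any objects with ``record_id``
    and ``abstract`` attributes.
    """
    if alias_map is None:
        alias_map = CountryAliasMap.default()
    compiled = _compile(alias_map, match_ambiguous_lowercase)
    per_article: dict[str, set[str]] = {}
    counts: dict[str, int] = {}
    for r in records:
        text = r.abstract
        found = {canonical for canonical, rx in compiled if rx.search(text)}
        per_article[r.record_id] = found
        for c in found:
            counts[c] = counts.get(c, 0) + 1
    series = pd.Series(counts, dtype=int, name="n_articles").sort_values(
        ascending=False, kind="stable")
    series = series.loc[sorted(series.index)].sort_values(
        ascending=False, kind="stable")  # deterministic tie order
    return series, per_article


def write_counts(counts: pd.Series, path: str | Path) -> None:
    counts.rename_axis("country").to_csv(path, sep="\t")
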
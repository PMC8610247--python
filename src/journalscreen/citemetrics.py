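"""Citation side-metrics used to characterize flagged journals.

Two per-journal quantities, both taking the citation data as input (no
citation database is queried):

* self-citation boost — the number of a journal's self-citing articles
  (articles whose reference list cites at least one article of the same
  journal within the analysis window) divided by the number of
  non-self-citing articles;
* skewness and non-article inflation — (impact factor − median per-article
  citation count) / median per-article citation count, undefined when the
  median is 0.  The impact factor is an externally supplied input.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from statistics import median
from typing import Sequence


class UndefinedMetricError(ValueError):
    """A citation metric is undefined for the given profile."""


@dataclass
class CitationProfile:
    journal_id: str
    impact_factor: float | None = None
    citation_counts: list[int] = field(default_factory=list)
    n_self_citing: int = 0
    n_non_self_citing: int = 0

    @property
    def n_articles(self) -> int:
        return self.n_self_citing + self.n_non_self_citing


def read_citation_table(
    path: str | Path,
    journal_id: str,
    impact_factor: float | None = None,
) -> CitationProfile:
    """Build a profile from a CSV with columns article_id,
    cited_journal_ids (pipe-separated), citation_count.

    An article is self-citing iff its reference list contains the profiled
    journal's own id; the caller restricts the table to the analysis window.
    """
    profile = CitationProfile(journal_id=journal_id, impact_factor=impact_factor)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"article_id", "cited_journal_ids", "citation_count"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"citation table missing columns: {sorted(missing)}")
        for row in reader:
            cited = {c for c in row["cited_journal_ids"].split("|") if c}
            if journal_id in cited:
                profile.n_self_citing += 1
            else:
                profile.n_non_self_citing += 1
            profile.citation_counts.append(int(row["citation_count"]))
    return profile


def self_citation_boost(profile: CitationProfile) -> float:
    """Self-citing over non-self-citing article count."""
    if profile.n_non_self_citing < 1:
        raise UndefinedMetricError(
            "self-citation boost undefined: no non-self-citing articles"
        )
    return profile.n_self_citing / profile.n_non_self_citing


def skewness_nonarticle_inflation(profile: CitationProfile) -> float:
    """(impact factor − median article citations) / median article citations."""
    if profile.impact_factor is None:
        raise UndefinedMetricError("impact factor not supplied")
    if not profile.citation_counts:
        raise UndefinedMetricError("no citation counts supplied")
    med = median(profile.citation_counts)
    if med <= 0:
        raise UndefinedMetricError(
            "metric undefined: median article citation count is 0"
        )
    return (profile.impact_factor - med) / med
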
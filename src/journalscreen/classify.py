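"""Partition articles into the "all articles" and "research articles" populations.

The "all" population contains every authored article.  The "research"
population further requires the MEDLINE publication type "Journal Article",
a non-empty abstract, and the absence of all 30 excluded publication-type
labels (editorials, letters, news, errata, ...).  The exclusion list ships
as a plain-text data file so it is auditable and can be overridden.

Publication-type labels are compared case-sensitively against the MEDLINE
vocabulary; unknown labels neither qualify nor exclude an article.
"""

from __future__ import annotations

from importlib import resources
from typing import Collection, Iterable

from .corpus_io import ArticleRecord

POPULATIONS = ("all", "research")

RESEARCH_TYPE = "Journal Article"


def _load_exclusions() -> frozenset[str]:
    text = (
        resources.files("journalscreen") / "_data" / "excluded_publication_types.txt"
    ).read_text(encoding="utf-8")
    return frozenset(line.strip() for line in text.splitlines() if line.strip())


EXCLUDED_PUBLICATION_TYPES: frozenset[str] = _load_exclusions()


def is_authored(article: ArticleRecord, include_collectives: bool = True) -> bool:
    """True iff the article has at least one identified author.

    With ``include_collectives=False``, collective names (working groups,
    editorial collectives) do not count as identified authors, so an
    article authored only by a collective is treated as authorless.
    """
    if include_collectives:
        return len(article.authors) > 0
    return any(a.collective is None for a in article.authors)


def is_research_article(
    article: ArticleRecord,
    excluded_types: Collection[str] = EXCLUDED_PUBLICATION_TYPES,
) -> bool:
    """Research article: typed "Journal Article", has an abstract, and
    carries none of the excluded publication-type labels."""
    return (
        RESEARCH_TYPE in article.pub_types
        and article.has_abstract
        and not (article.pub_types & frozenset(excluded_types))
    )


def build_population(
    articles: Iterable[ArticleRecord],
    population: str,
    include_collectives: bool = True,
    excluded_types: Collection[str] = EXCLUDED_PUBLICATION_TYPES,
) -> list[ArticleRecord]:
    """Select the articles belonging to a population.

    ``all`` keeps every authored article; ``research`` additionally applies
    :func:`is_research_article`.  The research population is always a
    subset of the all population.
    """
    if population not in POPULATIONS:
        raise ValueError(f"unknown population {population!r}; expected one of {POPULATIONS}")
    out = [a for a in articles if is_authored(a, include_collectives)]
    if population == "research":
        out = [a for a in out if is_research_article(a, excluded_types)]
    return out
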
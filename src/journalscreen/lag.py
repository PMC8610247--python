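"""Publication lag (submission to acceptance) and its per-journal asymmetry.

The lag of an article is the whole number of days between its "received"
and "accepted" history dates.  Each journal is summarized by the median lag
of articles carrying at least one most-prolific author (MPA) versus the
median lag of the remaining articles; their ratio below 1 indicates faster
acceptance for the journal's dominant author(s).

Conventions: negative lags are treated as data errors and excluded (with a
warning); zero-day lags are retained.  The median of an even number of lags
is the midpoint of the two central values.  A journal's ratio is calculable
only when both sides have at least one valid lag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from statistics import median
from typing import Iterable

import pandas as pd

from . import authorship, classify
from .authorship import MostProlificSet, make_author_key
from .corpus_io import ArticleRecord, Corpus

logger = logging.getLogger(__name__)

LAG_COLUMNS = [
    "journal_id",
    "population",
    "median_mpa",
    "median_non_mpa",
    "ratio",
    "calculable",
    "n_mpa_articles",
    "n_non_mpa_articles",
]


@dataclass(frozen=True)
class LagSummary:
    journal_id: str
    population: str
    median_mpa: float | None
    median_non_mpa: float | None
    calculable: bool
    n_mpa_articles: int
    n_non_mpa_articles: int

    @property
    def ratio(self) -> float | None:
        if not self.calculable:
            return None
        return self.median_mpa / self.median_non_mpa


def compute_article_lag(article: ArticleRecord) -> int | None:
    """Days from received to accepted; absent when either date is missing
    or the difference is negative."""
    if article.date_received is None or article.date_accepted is None:
        return None
    days = (article.date_accepted - article.date_received).days
    if days < 0:
        logger.warning(
            "article %s: accepted before received (%d days); lag treated as absent",
            article.article_id,
            days,
        )
        return None
    return days


def summarize_journal_lag(
    articles: Iterable[ArticleRecord],
    mpa: MostProlificSet,
    journal_id: str = "",
    population: str = "all",
    include_collectives: bool = True,
) -> LagSummary:
    """Median lag for MPA-authored versus other articles of one journal.

    An article is on the MPA side iff at least one of its authors maps to a
    key in ``mpa.keys``; medians use valid lags only.
    """
    mpa_lags: list[int] = []
    other_lags: list[int] = []
    for art in articles:
        lag_days = compute_article_lag(art)
        if lag_days is None:
            continue
        keys = {
            make_author_key(a)
            for a in art.authors
            if include_collectives or a.collective is None
        }
        (mpa_lags if keys & mpa.keys else other_lags).append(lag_days)
    calculable = bool(mpa_lags) and bool(other_lags)
    return LagSummary(
        journal_id=journal_id,
        population=population,
        median_mpa=float(median(mpa_lags)) if mpa_lags else None,
        median_non_mpa=float(median(other_lags)) if other_lags else None,
        calculable=calculable,
        n_mpa_articles=len(mpa_lags),
        n_non_mpa_articles=len(other_lags),
    )


def compute_lag_summaries(
    corpus: Corpus,
    population: str = "all",
    include_collectives: bool = True,
    journals: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-journal lag summaries over a population as a DataFrame.

    The MPA set is recomputed per journal on the same population, so the
    asymmetry always refers to that population's most prolific author(s).
    """
    keep = set(journals) if journals is not None else None
    pop_articles = classify.build_population(
        corpus.articles, population, include_collectives=include_collectives
    )
    by_journal: dict[str, list[ArticleRecord]] = {}
    for art in pop_articles:
        if keep is not None and art.journal_id not in keep:
            continue
        by_journal.setdefault(art.journal_id, []).append(art)

    rows = []
    for jid in sorted(by_journal):
        arts = by_journal[jid]
        counts = authorship.tally_author_counts(
            arts, journal_id=jid, population=population,
            include_collectives=include_collectives,
        )
        mpa = authorship.find_most_prolific(counts)
        s = summarize_journal_lag(
            arts, mpa, journal_id=jid, population=population,
            include_collectives=include_collectives,
        )
        rows.append(
            {
                "journal_id": jid,
                "population": population,
                "median_mpa": s.median_mpa,
                "median_non_mpa": s.median_non_mpa,
                "ratio": s.ratio,
                "calculable": s.calculable,
                "n_mpa_articles": s.n_mpa_articles,
                "n_non_mpa_articles": s.n_non_mpa_articles,
            }
        )
    return pd.DataFrame(rows, columns=LAG_COLUMNS)


def count_below_threshold(
    summaries: pd.DataFrame, threshold: int = 21
) -> dict[str, int]:
    """Count calculable journals whose median lag is strictly below a cutoff.

    Returns counts for the MPA side, the non-MPA side, and both sides at
    once (the default 21 days corresponds to a 3-week review turnaround).
    """
    calc = summaries[summaries["calculable"]]
    mpa_below = calc["median_mpa"] < threshold
    non_below = calc["median_non_mpa"] < threshold
    return {
        "mpa_below": int(mpa_below.sum()),
        "non_mpa_below": int(non_below.sum()),
        "both_below": int((mpa_below & non_below).sum()),
    }
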
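"""Outlier screening and reporting.

Journals are flagged when their PPMP and/or corrected Gini lies strictly
above the empirical 95th percentile of the screened population.  Quantiles
use linear interpolation between order statistics at h = (n-1)q + 1 (the
default of mainstream statistical environments); the method name is carried
in the threshold metadata because the thresholds depend on it.

Also here: overlap (Venn) counts between flag sets, Pearson correlation of
indices with a Fisher-z 95% CI, per-field (Broad Subject Term) distribution
summaries, seeded random sampling of flagged journals for manual review,
and the summary report of the whole screened population.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Collection, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import classify
from .corpus_io import Corpus, JournalRecord

logger = logging.getLogger(__name__)

QUANTILE_METHOD = "linear"  # h = (n - 1) q + 1


@dataclass(frozen=True)
class ScreenThresholds:
    population: str
    q: float
    q95_ppmp: float
    q95_gini: float
    quantile_method: str = QUANTILE_METHOD


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    n: int


def percentile_threshold(values, q: float = 0.95) -> float:
    """Empirical quantile by linear interpolation between order statistics."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot take a percentile of an empty collection")
    return float(np.quantile(arr, q, method=QUANTILE_METHOD))


def compute_thresholds(
    indices: pd.DataFrame, q: float = 0.95, population: str | None = None
) -> ScreenThresholds:
    """95th-percentile screening thresholds over a population's indices."""
    pop = population or (
        indices["population"].iloc[0] if len(indices) else "all"
    )
    return ScreenThresholds(
        population=pop,
        q=q,
        q95_ppmp=percentile_threshold(indices["ppmp"], q),
        q95_gini=percentile_threshold(indices["gini"], q),
    )


def flag_outliers(
    indices: pd.DataFrame, thresholds: ScreenThresholds
) -> pd.DataFrame:
    """Per-journal outlier flags: index strictly above its threshold.

    Journals exactly at a threshold are not flagged ("above" is strict).
    """
    out = indices[["journal_id", "population"]].copy()
    out["flagged_ppmp"] = indices["ppmp"].to_numpy() > thresholds.q95_ppmp
    out["flagged_gini"] = indices["gini"].to_numpy() > thresholds.q95_gini
    out["flagged_any"] = out["flagged_ppmp"] | out["flagged_gini"]
    return out


def overlap_counts(
    flags_a: Collection[str],
    flags_b: Collection[str],
    universe: Collection[str],
) -> dict[str, int]:
    """Venn partition of two flag sets over a common journal universe."""
    a, b, u = set(flags_a), set(flags_b), set(universe)
    if not (a <= u and b <= u):
        raise ValueError("flag sets must be subsets of the journal universe")
    both = a & b
    return {
        "only_a": len(a - b),
        "only_b": len(b - a),
        "both": len(both),
        "neither": len(u - a - b),
    }


def correlate_indices(x, y) -> CorrelationResult:
    """Pearson correlation with a 95% CI from the Fisher z-transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need at least 4 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    r = float(stats.pearsonr(x, y).statistic)
    n = x.size
    if abs(r) >= 1.0:
        lo = hi = r
    else:
        z = math.atanh(r)
        half = 1.96 / math.sqrt(n - 3)
        lo, hi = math.tanh(z - half), math.tanh(z + half)
    return CorrelationResult(r=r, ci_low=lo, ci_high=hi, n=n)


def field_summaries(
    indices: pd.DataFrame,
    journals: Mapping[str, JournalRecord],
    min_journals: int = 10,
) -> pd.DataFrame:
    """Distribution of both indices within each Broad Subject Term.

    A journal carrying k terms contributes to k summaries (the one place
    where a journal is counted more than once).  Terms covering fewer than
    ``min_journals`` journals are omitted.
    """
    rows = []
    term_members: dict[str, list[int]] = {}
    idx = indices.reset_index(drop=True)
    for i, jid in enumerate(idx["journal_id"]):
        rec = journals.get(jid)
        if rec is None:
            continue
        for term in rec.broad_subject_terms:
            term_members.setdefault(term, []).append(i)
    for term in sorted(term_members):
        members = term_members[term]
        if len(members) < min_journals:
            continue
        sub = idx.iloc[members]
        row = {"broad_subject_term": term, "n_journals": len(members)}
        for col in ("ppmp", "gini"):
            v = sub[col].to_numpy()
            row[f"{col}_median"] = float(np.median(v))
            row[f"{col}_q1"] = float(np.quantile(v, 0.25, method=QUANTILE_METHOD))
            row[f"{col}_q3"] = float(np.quantile(v, 0.75, method=QUANTILE_METHOD))
            row[f"{col}_min"] = float(v.min())
            row[f"{col}_max"] = float(v.max())
        rows.append(row)
    return pd.DataFrame(rows)


def sample_flagged(
    flagged_ids: Iterable[str],
    journals: Mapping[str, JournalRecord],
    n: int = 100,
    seed: int = 42,
) -> list[str]:
    """Deterministically sample flagged journals for manual review.

    Journals are sorted alphabetically by full name before a seeded draw
    without replacement, so the sample is reproducible given (flag set, n,
    seed).  When fewer than ``n`` journals are flagged, all are returned
    with a warning.
    """
    ordered = sorted(
        set(flagged_ids), key=lambda jid: (journals[jid].title if jid in journals else jid, jid)
    )
    if len(ordered) <= n:
        if len(ordered) < n:
            logger.warning(
                "requested %d journals but only %d flagged; returning all", n, len(ordered)
            )
        return ordered
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(ordered), size=n, replace=False)
    return [ordered[i] for i in sorted(picks)]


def _dist_rows(metric: str, values: np.ndarray) -> list[dict]:
    return [
        {"metric": metric, "statistic": "median", "value": float(np.median(values))},
        {"metric": metric, "statistic": "q1",
         "value": float(np.quantile(values, 0.25, method=QUANTILE_METHOD))},
        {"metric": metric, "statistic": "q3",
         "value": float(np.quantile(values, 0.75, method=QUANTILE_METHOD))},
        {"metric": metric, "statistic": "min", "value": float(values.min())},
        {"metric": metric, "statistic": "max", "value": float(values.max())},
    ]


def summary_table(
    corpus: Corpus,
    indices: pd.DataFrame,
    lag_summaries: pd.DataFrame,
    population: str = "all",
    include_collectives: bool = True,
) -> pd.DataFrame:
    """Tidy summary of the screened population (one statistic per row).

    Covers journal count; per-journal article and authored-article counts;
    PPMP (in percent) with its 95th percentile; MPA article counts; tie
    counts; corrected Gini with its 95th percentile; and the publication-lag
    ratio with the count of journals where it is not calculable.  Pure:
    identical inputs yield an identical table.
    """
    jids = list(indices["journal_id"])
    jset = set(jids)

    pop_all: dict[str, int] = {j: 0 for j in jids}
    pop_authored: dict[str, int] = {j: 0 for j in jids}
    research = population == "research"
    for art in corpus.articles:
        if art.journal_id not in jset:
            continue
        if research and not classify.is_research_article(art):
            continue
        pop_all[art.journal_id] += 1
        if classify.is_authored(art, include_collectives):
            pop_authored[art.journal_id] += 1

    rows: list[dict] = [
        {"metric": "journals", "statistic": "count", "value": float(len(jids))}
    ]
    rows += _dist_rows("articles", np.array([pop_all[j] for j in jids], dtype=float))
    rows += _dist_rows(
        "authored_articles", np.array([pop_authored[j] for j in jids], dtype=float)
    )

    ppmp_pct = indices["ppmp"].to_numpy() * 100.0
    rows += _dist_rows("ppmp_pct", ppmp_pct)
    rows.append(
        {"metric": "ppmp_pct", "statistic": "p95",
         "value": percentile_threshold(ppmp_pct, 0.95)}
    )
    rows += _dist_rows("n_max", indices["n_max"].to_numpy(dtype=float))
    n_tied = int(indices["tied"].sum())
    rows.append({"metric": "tied", "statistic": "count", "value": float(n_tied)})
    rows.append(
        {"metric": "tied", "statistic": "pct",
         "value": 100.0 * n_tied / len(jids) if jids else 0.0}
    )
    gini = indices["gini"].to_numpy()
    rows += _dist_rows("gini", gini)
    rows.append(
        {"metric": "gini", "statistic": "p95", "value": percentile_threshold(gini, 0.95)}
    )

    calc = lag_summaries[lag_summaries["calculable"]]
    if len(calc):
        rows += _dist_rows("lag_ratio", calc["ratio"].to_numpy(dtype=float))
    n_not_calc = int((~lag_summaries["calculable"]).sum())
    rows.append(
        {"metric": "lag_ratio", "statistic": "not_calculable_count",
         "value": float(n_not_calc)}
    )
    rows.append(
        {"metric": "lag_ratio", "statistic": "not_calculable_pct",
         "value": 100.0 * n_not_calc / len(lag_summaries) if len(lag_summaries) else 0.0}
    )
    return pd.DataFrame(rows, columns=["metric", "statistic", "value"])
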
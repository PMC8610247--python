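"""Authorship-concentration indices: PPMP, sample-corrected Gini, Lorenz curves.

PPMP (Percentage of Papers by the Most Prolific author) is n_max / N_tot:
the article count of the journal's most prolific author divided by the
journal's authored-article count.

The Gini index is computed on the vector y of per-author article counts,
with a small-sample correction n/(n-1) so that a journal where one author
holds everything scores 1 regardless of the number of authors:

    G = [ (2 Σ_i i·y_i) / (n Σ_i y_i)  −  (n+1)/n ] · n/(n−1)

with y sorted in nondecreasing order and i = 1..n.  G is 0 under perfect
equality and 1 under maximal inequality.  ``gini_pairwise_oracle`` computes
the same quantity from the mean absolute pairwise difference and serves as
an independent cross-check in the test suite.

Both indices are stored as fractions in [0, 1]; reporting layers render
percentages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import authorship, classify
from .authorship import AuthorCounts, MostProlificSet
from .corpus_io import Corpus

logger = logging.getLogger(__name__)

POOLED = "pooled"

INDEX_COLUMNS = [
    "journal_id",
    "population",
    "period",
    "N_tot",
    "n_max",
    "tied",
    "ppmp",
    "n_authors",
    "gini",
]


def _validate_counts(y) -> np.ndarray:
    arr = np.asarray(y, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("author count vector must be non-empty and one-dimensional")
    if np.any(arr <= 0):
        raise ValueError("author counts must all be positive")
    return arr


def compute_gini(y: Sequence[float] | np.ndarray) -> float:
    """Sample-corrected Gini index of a vector of per-author article counts.

    For a single author the correction n/(n-1) is undefined; 0 is returned
    with a warning, since a one-author distribution has no inequality to
    measure.
    """
    arr = _validate_counts(y)
    n = arr.size
    if n == 1:
        logger.warning("Gini of a single-author distribution returned as 0")
        return 0.0
    arr = np.sort(arr)
    i = np.arange(1, n + 1)
    g = (2.0 * np.sum(i * arr)) / (n * arr.sum()) - (n + 1) / n
    return float(g * n / (n - 1))


def gini_pairwise_oracle(y: Sequence[float] | np.ndarray) -> float:
    """Corrected Gini via mean absolute pairwise differences (O(n^2)).

    Mathematically identical to :func:`compute_gini`; kept as an
    independent implementation for validation.
    """
    arr = _validate_counts(y)
    n = arr.size
    if n == 1:
        return 0.0
    diff = np.abs(arr[:, None] - arr[None, :]).sum()
    g = diff / (2.0 * n * n * arr.mean())
    return float(g * n / (n - 1))


@dataclass(frozen=True)
class LorenzCurve:
    """Polyline from (0,0) to (1,1): cumulative author fraction vs
    cumulative authorship fraction, authors sorted least to most prolific."""

    points: np.ndarray  # shape (n+1, 2)

    def area(self) -> float:
        """Area under the polyline (exact trapezoid rule)."""
        x, y = self.points[:, 0], self.points[:, 1]
        return float(np.trapezoid(y, x))


def lorenz_curve(y: Sequence[float] | np.ndarray) -> LorenzCurve:
    arr = np.sort(_validate_counts(y))
    n = arr.size
    x = np.arange(n + 1) / n
    cum = np.concatenate([[0.0], np.cumsum(arr) / arr.sum()])
    return LorenzCurve(points=np.column_stack([x, cum]))


def plot_lorenz(curve: LorenzCurve, ax=None, **kwargs):
    """Plot a Lorenz curve with the equality diagonal (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot([0, 1], [0, 1], color="grey", lw=1, linestyle="--")
    ax.plot(curve.points[:, 0], curve.points[:, 1], **kwargs)
    ax.set_xlabel("cumulative share of authors")
    ax.set_ylabel("cumulative share of authorships")
    return ax


def compute_ppmp(counts: AuthorCounts, n_tot: int) -> float:
    """n_max / N_tot, with n_max the most prolific author's article count."""
    if n_tot < 1:
        raise ValueError("journal has no authored articles; PPMP undefined")
    if not counts.counts:
        raise ValueError("empty author counts; PPMP undefined")
    return authorship.find_most_prolific(counts).n_max / n_tot


def compute_journal_indices(
    corpus: Corpus,
    population: str = "all",
    grouping: str = POOLED,
    include_collectives: bool = True,
    journals: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Assemble PPMP and corrected Gini per journal (pooled) or journal-year.

    ``journals`` restricts the computation, typically to the output of
    ``select_eligible_journals``.  Returns one row per journal (pooled) or
    per journal-year with at least one authored article, sorted by journal
    then period, with columns journal_id, population, period, N_tot, n_max,
    tied, ppmp, n_authors, gini.
    """
    if grouping not in (POOLED, "by_year"):
        raise ValueError(f"unknown grouping {grouping!r}")
    keep = set(journals) if journals is not None else None
    pop_articles = classify.build_population(
        corpus.articles, population, include_collectives=include_collectives
    )

    groups: dict[tuple[str, object], list] = {}
    for art in pop_articles:
        if keep is not None and art.journal_id not in keep:
            continue
        period = POOLED if grouping == POOLED else art.pub_year
        groups.setdefault((art.journal_id, period), []).append(art)

    rows = []
    for (jid, period), arts in sorted(
        groups.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))
    ):
        counts = authorship.tally_author_counts(
            arts, journal_id=jid, population=population,
            include_collectives=include_collectives,
        )
        mpa = authorship.find_most_prolific(counts)
        n_tot = len(arts)
        y = list(counts.counts.values())
        rows.append(
            {
                "journal_id": jid,
                "population": population,
                "period": period,
                "N_tot": n_tot,
                "n_max": mpa.n_max,
                "tied": mpa.tied,
                "ppmp": mpa.n_max / n_tot,
                "n_authors": counts.n_authors,
                "gini": compute_gini(y),
            }
        )
    return pd.DataFrame(rows, columns=INDEX_COLUMNS)
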
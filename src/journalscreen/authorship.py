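"""Normalized author identities and per-journal article tallies.

An author is identified by family name plus full given name when available,
otherwise by family name plus first-name initials.  Collective names (e.g.
an editorial collective signing as a single "author") form their own key
kind and are counted as authors by default, with a policy flag to exclude
them.  No cross-journal identity resolution or homonym splitting is
attempted; the key kind is recorded so reports can quantify the share of
initials-only identities, which carry a higher homonym-merging risk.

Normalization: Unicode NFC, case-fold, trim, collapse internal whitespace,
strip periods from initials; hyphens are preserved.  This merges trivial
formatting variants without attempting disambiguation.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

from .corpus_io import ArticleRecord, RawAuthor

KEY_FULL = "full_name"
KEY_INITIALS = "initials_only"
KEY_COLLECTIVE = "collective"

_WS = re.compile(r"\s+")


class AuthorKey(NamedTuple):
    family_norm: str
    given_norm: str
    key_kind: str


def _norm(text: str) -> str:
    text = unicodedata.normalize("NFC", text).casefold().strip()
    return _WS.sub(" ", text)


def make_author_key(raw: RawAuthor) -> AuthorKey:
    """Build the normalized identity key for one raw author entry."""
    if raw.collective is not None:
        if raw.family is not None:
            raise ValueError("author has both a collective and a family name")
        return AuthorKey(_norm(raw.collective), "", KEY_COLLECTIVE)
    if raw.family is None:
        raise ValueError("unidentifiable author: no family or collective name")
    family = _norm(raw.family)
    if raw.given_full:
        return AuthorKey(family, _norm(raw.given_full), KEY_FULL)
    if raw.initials:
        return AuthorKey(family, _norm(raw.initials.replace(".", "")), KEY_INITIALS)
    # Family name only: treat as initials-level identity with empty given part.
    return AuthorKey(family, "", KEY_INITIALS)


@dataclass
class AuthorCounts:
    """Per-journal article tallies y_i for each distinct author key."""

    journal_id: str
    population: str
    counts: dict[AuthorKey, int] = field(default_factory=dict)

    @property
    def n_authors(self) -> int:
        return len(self.counts)

    @property
    def total_authorships(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class MostProlificSet:
    """The author(s) with the largest article count in a journal."""

    keys: frozenset[AuthorKey]
    n_max: int

    @property
    def tied(self) -> bool:
        return len(self.keys) > 1


def tally_author_counts(
    articles: Iterable[ArticleRecord],
    journal_id: str = "",
    population: str = "all",
    include_collectives: bool = True,
) -> AuthorCounts:
    """Count articles per author key over one journal's articles.

    An author listed twice on the same article is credited once for it;
    authorless articles contribute nothing.  The caller is responsible for
    restricting ``articles`` to one journal and one population.
    """
    counts: dict[AuthorKey, int] = {}
    for art in articles:
        keys = set()
        for raw in art.authors:
            if not include_collectives and raw.collective is not None:
                continue
            keys.add(make_author_key(raw))
        for key in keys:
            counts[key] = counts.get(key, 0) + 1
    return AuthorCounts(journal_id=journal_id, population=population, counts=counts)


def find_most_prolific(counts: AuthorCounts) -> MostProlificSet:
    """All and only the keys achieving the maximal article count."""
    if not counts.counts:
        raise ValueError("no authored articles: most prolific author undefined")
    n_max = max(counts.counts.values())
    keys = frozenset(k for k, v in counts.counts.items() if v == n_max)
    return MostProlificSet(keys=keys, n_max=n_max)


def initials_only_share(counts: AuthorCounts) -> float:
    """Share of author keys identified only by family name and initials."""
    if not counts.counts:
        raise ValueError("empty author counts")
    n_init = sum(1 for k in counts.counts if k.key_kind == KEY_INITIALS)
    return n_init / counts.n_authors
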
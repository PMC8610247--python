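"""Read, write and filter article/journal metadata.

Two on-disk representations are supported:

* MEDLINE/PubMed XML (a ``PubmedArticleSet`` document, the format returned
  by NCBI's E-utilities ``efetch``), parsed with :mod:`lxml`;
* a flat UTF-8 CSV dialect, one row per article, used for fixtures,
  synthetic corpora and as the interchange format between pipeline stages.

The CSV dialect (bit-exact round-trip guaranteed by the test suite)::

    article_id, journal_id, pub_year, pub_types, has_abstract, authors,
    date_received, date_accepted

``pub_types`` is a pipe-separated, lexicographically sorted list.
``has_abstract`` is ``0``/``1``.  ``authors`` is a pipe-separated list of
``family,given_full,initials`` triplets (empty fields for missing parts)
or ``collective:NAME`` for collective authors.  Dates are ISO-8601 or empty.

Journal-level metadata (titles, NLM Broad Subject Terms, alias targets)
travels in a companion CSV with columns ``journal_id``, ``titles``
(pipe-separated), ``broad_subject_terms`` (pipe-separated), ``alias_of``.
"""

from __future__ import annotations

import csv
import datetime as _dt
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Mapping

from lxml import etree

logger = logging.getLogger(__name__)

ARTICLE_COLUMNS = [
    "article_id",
    "journal_id",
    "pub_year",
    "pub_types",
    "has_abstract",
    "authors",
    "date_received",
    "date_accepted",
]

JOURNAL_COLUMNS = ["journal_id", "titles", "broad_subject_terms", "alias_of"]


class CorpusParseError(ValueError):
    """Raised when an input document cannot be parsed."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RawAuthor:
    """One author entry exactly as found in the source record.

    A valid author carries either a personal family name (with optional
    given name / initials) or a collective name, never both.
    """

    family: str | None = None
    given_full: str | None = None
    initials: str | None = None
    collective: str | None = None

    def is_valid(self) -> bool:
        return (self.family is not None) != (self.collective is not None)


@dataclass
class ArticleRecord:
    """One article's metadata as used by every downstream computation."""

    article_id: str
    journal_id: str
    pub_year: int
    pub_types: frozenset[str] = frozenset()
    has_abstract: bool = False
    authors: tuple[RawAuthor, ...] = ()
    date_received: _dt.date | None = None
    date_accepted: _dt.date | None = None


@dataclass
class JournalRecord:
    journal_id: str
    titles: list[str] = field(default_factory=list)
    broad_subject_terms: frozenset[str] = frozenset()
    alias_of: str | None = None

    @property
    def title(self) -> str:
        return self.titles[0] if self.titles else self.journal_id


@dataclass
class Corpus:
    """A collection of journals and their articles over a year window."""

    journals: dict[str, JournalRecord] = field(default_factory=dict)
    articles: list[ArticleRecord] = field(default_factory=list)
    window: tuple[int, int] | None = None

    def articles_by_journal(self) -> dict[str, list[ArticleRecord]]:
        out: dict[str, list[ArticleRecord]] = {}
        for art in self.articles:
            out.setdefault(art.journal_id, []).append(art)
        return out


# ---------------------------------------------------------------------------
# MEDLINE/PubMed XML
# ---------------------------------------------------------------------------


def _text(node) -> str | None:
    if node is None:
        return None
    txt = "".join(node.itertext()).strip()
    return txt or None


def _history_date(article_el, status: str) -> _dt.date | None:
    el = article_el.find(
        f".//PubmedData/History/PubMedPubDate[@PubStatus='{status}']"
    )
    if el is None:
        return None
    try:
        y = int(el.findtext("Year"))
        m = int(el.findtext("Month"))
        d = int(el.findtext("Day"))
        return _dt.date(y, m, d)
    except (TypeError, ValueError):
        logger.warning("unparsable %s history date; treated as absent", status)
        return None


def _pub_year(article_el) -> int | None:
    # Journal-issue year, falling back to the electronic publication year.
    y = article_el.findtext(".//Article/Journal/JournalIssue/PubDate/Year")
    if y is None:
        y = article_el.findtext(".//Article/ArticleDate[@DateType='Electronic']/Year")
    if y is None:
        y = article_el.findtext(".//Article/ArticleDate/Year")
    try:
        return int(y)
    except (TypeError, ValueError):
        return None


def parse_medline_xml(source: IO[bytes] | str | Path) -> Corpus:
    """Parse a ``PubmedArticleSet`` document into a :class:`Corpus`.

    Articles without a resolvable journal identifier are skipped with a
    warning.  Malformed XML raises :class:`CorpusParseError` carrying the
    parser's position information.
    """
    try:
        tree = etree.parse(source)
    except etree.XMLSyntaxError as exc:  # message includes line/column
        raise CorpusParseError(f"malformed MEDLINE XML: {exc}") from exc

    corpus = Corpus()
    for art_el in tree.iter("PubmedArticle"):
        cit = art_el.find("MedlineCitation")
        if cit is None:
            continue
        journal_id = cit.findtext("MedlineJournalInfo/NlmUniqueID")
        if not journal_id:
            journal_id = cit.findtext(".//Article/Journal/ISSN")
        if not journal_id:
            logger.warning("article without journal identifier skipped")
            continue
        article_id = cit.findtext("PMID") or f"noid-{len(corpus.articles)}"
        year = _pub_year(cit)
        if year is None:
            logger.warning("article %s without publication year skipped", article_id)
            continue

        pub_types = frozenset(
            t for el in cit.findall(".//Article/PublicationTypeList/PublicationType")
            if (t := _text(el))
        )
        has_abstract = _text(cit.find(".//Article/Abstract")) is not None

        authors: list[RawAuthor] = []
        for au in cit.findall(".//Article/AuthorList/Author"):
            coll = _text(au.find("CollectiveName"))
            fam = _text(au.find("LastName"))
            if coll is not None:
                authors.append(RawAuthor(collective=coll))
            elif fam is not None:
                authors.append(
                    RawAuthor(
                        family=fam,
                        given_full=_text(au.find("ForeName")),
                        initials=_text(au.find("Initials")),
                    )
                )
            else:
                logger.warning("author with no usable name dropped in %s", article_id)

        corpus.articles.append(
            ArticleRecord(
                article_id=article_id,
                journal_id=journal_id,
                pub_year=year,
                pub_types=pub_types,
                has_abstract=has_abstract,
                authors=tuple(authors),
                date_received=_history_date(art_el, "received"),
                date_accepted=_history_date(art_el, "accepted"),
            )
        )
        if journal_id not in corpus.journals:
            title = cit.findtext(".//Article/Journal/Title")
            corpus.journals[journal_id] = JournalRecord(
                journal_id=journal_id, titles=[title] if title else []
            )
    return corpus


# ---------------------------------------------------------------------------
# Tabular dialect
# ---------------------------------------------------------------------------


def _format_author(author: RawAuthor) -> str:
    if author.collective is not None:
        return f"collective:{author.collective}"
    return ",".join(
        part or "" for part in (author.family, author.given_full, author.initials)
    )


def _parse_author(cell: str) -> RawAuthor:
    if cell.startswith("collective:"):
        return RawAuthor(collective=cell[len("collective:"):])
    parts = cell.split(",")
    if len(parts) != 3:
        raise CorpusParseError(f"malformed author cell: {cell!r}")
    family, given, initials = (p if p else None for p in parts)
    return RawAuthor(family=family, given_full=given, initials=initials)


def _parse_date(cell: str, article_id: str, what: str) -> _dt.date | None:
    if not cell:
        return None
    try:
        return _dt.date.fromisoformat(cell)
    except ValueError:
        logger.warning(
            "article %s: unparsable %s date %r treated as absent", article_id, what, cell
        )
        return None


def read_corpus_table(
    articles_path: str | Path,
    journals_path: str | Path | None = None,
    window: tuple[int, int] | None = None,
) -> Corpus:
    """Read a corpus from the flat CSV dialect.

    Unknown columns are an error; unparsable dates degrade to absent with a
    warning.  When no journal table is supplied, stub journal records (no
    Broad Subject Terms) are created for every journal id seen.
    """
    corpus = Corpus(window=window)
    with open(articles_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        unknown = set(reader.fieldnames or []) - set(ARTICLE_COLUMNS)
        if unknown:
            raise CorpusParseError(f"unknown article columns: {sorted(unknown)}")
        for row in reader:
            art_id = row["article_id"]
            authors = tuple(
                _parse_author(cell) for cell in row["authors"].split("|") if cell
            )
            corpus.articles.append(
                ArticleRecord(
                    article_id=art_id,
                    journal_id=row["journal_id"],
                    pub_year=int(row["pub_year"]),
                    pub_types=frozenset(
                        t for t in row["pub_types"].split("|") if t
                    ),
                    has_abstract=row["has_abstract"] == "1",
                    authors=authors,
                    date_received=_parse_date(row["date_received"], art_id, "received"),
                    date_accepted=_parse_date(row["date_accepted"], art_id, "accepted"),
                )
            )
    if journals_path is not None:
        with open(journals_path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            unknown = set(reader.fieldnames or []) - set(JOURNAL_COLUMNS)
            if unknown:
                raise CorpusParseError(f"unknown journal columns: {sorted(unknown)}")
            for row in reader:
                corpus.journals[row["journal_id"]] = JournalRecord(
                    journal_id=row["journal_id"],
                    titles=[t for t in row["titles"].split("|") if t],
                    broad_subject_terms=frozenset(
                        t for t in row["broad_subject_terms"].split("|") if t
                    ),
                    alias_of=row["alias_of"] or None,
                )
    for art in corpus.articles:
        if art.journal_id not in corpus.journals:
            corpus.journals[art.journal_id] = JournalRecord(journal_id=art.journal_id)
    return corpus


def write_corpus_table(
    corpus: Corpus,
    articles_path: str | Path,
    journals_path: str | Path | None = None,
) -> None:
    """Write a corpus in the flat CSV dialect (stable, bit-reproducible)."""
    with open(articles_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(ARTICLE_COLUMNS)
        for art in corpus.articles:
            writer.writerow(
                [
                    art.article_id,
                    art.journal_id,
                    art.pub_year,
                    "|".join(sorted(art.pub_types)),
                    "1" if art.has_abstract else "0",
                    "|".join(_format_author(a) for a in art.authors),
                    art.date_received.isoformat() if art.date_received else "",
                    art.date_accepted.isoformat() if art.date_accepted else "",
                ]
            )
    if journals_path is not None:
        with open(journals_path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(JOURNAL_COLUMNS)
            for jid in sorted(corpus.journals):
                j = corpus.journals[jid]
                writer.writerow(
                    [
                        j.journal_id,
                        "|".join(j.titles),
                        "|".join(sorted(j.broad_subject_terms)),
                        j.alias_of or "",
                    ]
                )


# ---------------------------------------------------------------------------
# Window restriction, alias pooling, eligibility
# ---------------------------------------------------------------------------


def restrict_window(corpus: Corpus, start: int, end: int) -> Corpus:
    """Return a corpus containing only articles published in [start, end]."""
    arts = [a for a in corpus.articles if start <= a.pub_year <= end]
    return Corpus(journals=dict(corpus.journals), articles=arts, window=(start, end))


def resolve_aliases(
    corpus: Corpus, aliases: Mapping[str, str] | None = None
) -> Corpus:
    """Pool articles published under journal aliases into their targets.

    ``aliases`` (old id -> canonical id) is merged with any ``alias_of``
    fields already present on the journal records.  Chains are followed;
    cycles raise ``ValueError``.
    """
    mapping: dict[str, str] = {
        jid: j.alias_of for jid, j in corpus.journals.items() if j.alias_of
    }
    if aliases:
        mapping.update(aliases)

    def resolve(jid: str) -> str:
        seen = {jid}
        while jid in mapping:
            jid = mapping[jid]
            if jid in seen:
                raise ValueError(f"alias cycle involving {jid!r}")
            seen.add(jid)
        return jid

    journals: dict[str, JournalRecord] = {}
    for jid, j in corpus.journals.items():
        target = resolve(jid)
        if target == jid:
            journals[jid] = replace(j, alias_of=None)
    for jid, j in corpus.journals.items():
        target = resolve(jid)
        if target == jid:
            continue
        tgt = journals.setdefault(target, JournalRecord(journal_id=target))
        tgt.titles = tgt.titles + [t for t in j.titles if t not in tgt.titles]
        tgt.broad_subject_terms = tgt.broad_subject_terms | j.broad_subject_terms

    articles = [
        replace(a, journal_id=resolve(a.journal_id))
        if resolve(a.journal_id) != a.journal_id
        else a
        for a in corpus.articles
    ]
    return Corpus(journals=journals, articles=articles, window=corpus.window)


def select_eligible_journals(
    corpus: Corpus,
    population: str = "all",
    min_authored: int = 50,
    include_collectives: bool = True,
    require_broad_subject_term: bool = True,
    aliases: Mapping[str, str] | None = None,
) -> set[str]:
    """Journals with at least ``min_authored`` authored articles.

    An authored article has at least one identified author (collective
    names count per the ``include_collectives`` policy).  Aliased journals
    are pooled into their targets before counting.  Journals must carry at
    least one Broad Subject Term unless ``require_broad_subject_term`` is
    off (useful for corpora lacking journal-level metadata).
    """
    from . import classify

    pooled = resolve_aliases(corpus, aliases)
    counts: dict[str, int] = {}
    for art in classify.build_population(
        pooled.articles, population, include_collectives=include_collectives
    ):
        counts[art.journal_id] = counts.get(art.journal_id, 0) + 1

    eligible = set()
    for jid, n in counts.items():
        if n < min_authored:
            continue
        rec = pooled.journals.get(jid)
        if require_broad_subject_term and not (rec and rec.broad_subject_terms):
            continue
        eligible.add(jid)
    return eligible
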
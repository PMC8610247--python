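"""Shared fixtures: tiny article factories and a MEDLINE XML builder."""

from __future__ import annotations

import datetime as dt
import itertools

import pytest

from journalscreen import ArticleRecord, Corpus, JournalRecord, RawAuthor
from journalscreen.classify import EXCLUDED_PUBLICATION_TYPES

_counter = itertools.count()


def make_article(
    journal_id="J1",
    pub_year=2017,
    pub_types=("Journal Article",),
    has_abstract=True,
    authors=(RawAuthor(family="Doe", given_full="Jane"),),
    date_received=None,
    date_accepted=None,
    article_id=None,
):
    return ArticleRecord(
        article_id=article_id or f"A{next(_counter):05d}",
        journal_id=journal_id,
        pub_year=pub_year,
        pub_types=frozenset(pub_types),
        has_abstract=has_abstract,
        authors=tuple(authors),
        date_received=date_received,
        date_accepted=date_accepted,
    )


@pytest.fixture
def article_factory():
    return make_article


def build_classification_corpus():
    """30 articles exercising every excluded publication-type label.

    Returns (articles, research_ids, authored_ids): the hand-enumerated
    research-article subset and the authored subset.
    """
    articles = []
    research_ids = set()
    authored_ids = set()
    excluded = sorted(EXCLUDED_PUBLICATION_TYPES)
    assert len(excluded) == 31
    # 15 articles covering all 31 excluded labels alongside the research type
    # (the first carries three labels, the rest two each).
    art = make_article(article_id="E00", pub_types=("Journal Article",) + tuple(excluded[:3]))
    articles.append(art)
    authored_ids.add(art.article_id)
    for i in range(14):
        art = make_article(
            article_id=f"E{i + 1:02d}",
            pub_types=("Journal Article", excluded[3 + 2 * i], excluded[4 + 2 * i]),
        )
        articles.append(art)
        authored_ids.add(art.article_id)
    # 8 clean research articles.
    for i in range(8):
        art = make_article(article_id=f"R{i:02d}")
        articles.append(art)
        research_ids.add(art.article_id)
        authored_ids.add(art.article_id)
    # 2 research articles with an extra label outside the MEDLINE exclusion
    # vocabulary (ignored by the rule).
    for i in range(2):
        art = make_article(article_id=f"V{i:02d}", pub_types=("Journal Article", "Review"))
        articles.append(art)
        research_ids.add(art.article_id)
        authored_ids.add(art.article_id)
    # 3 journal articles without an abstract.
    for i in range(3):
        art = make_article(article_id=f"N{i:02d}", has_abstract=False)
        articles.append(art)
        authored_ids.add(art.article_id)
    # 2 authorless research-typed articles.
    for i in range(2):
        art = make_article(article_id=f"X{i:02d}", authors=())
        articles.append(art)
        research_ids.add(art.article_id)
    assert len(articles) == 30
    return articles, research_ids, authored_ids


@pytest.fixture
def classification_corpus():
    return build_classification_corpus()


def medline_article_xml(
    pmid="100",
    nlm_id="J1",
    title="Test Journal",
    year=2018,
    pub_types=("Journal Article",),
    abstract="Background. Something was studied.",
    authors=(("Raoult", "Didier", "D"), ("Locher", "Clara", "C")),
    collective=None,
    received=(2018, 1, 1),
    accepted=(2018, 2, 1),
):
    author_xml = ""
    if authors or collective:
        parts = []
        for fam, given, init in authors or ():
            parts.append(
                f"<Author><LastName>{fam}</LastName>"
                f"<ForeName>{given}</ForeName><Initials>{init}</Initials></Author>"
            )
        if collective:
            parts.append(f"<Author><CollectiveName>{collective}</CollectiveName></Author>")
        author_xml = f"<AuthorList>{''.join(parts)}</AuthorList>"
    abstract_xml = (
        f"<Abstract><AbstractText>{abstract}</AbstractText></Abstract>" if abstract else ""
    )
    types_xml = "".join(f"<PublicationType>{t}</PublicationType>" for t in pub_types)
    history = ""
    for status, ymd in (("received", received), ("accepted", accepted)):
        if ymd:
            y, m, d = ymd
            history += (
                f"<PubMedPubDate PubStatus='{status}'>"
                f"<Year>{y}</Year><Month>{m}</Month><Day>{d}</Day></PubMedPubDate>"
            )
    return f"""
    <PubmedArticle>
      <MedlineCitation>
        <PMID>{pmid}</PMID>
        <Article>
          <Journal>
            <ISSN>1234-5678</ISSN>
            <JournalIssue><PubDate><Year>{year}</Year></PubDate></JournalIssue>
            <Title>{title}</Title>
          </Journal>
          {abstract_xml}
          {author_xml}
          <PublicationTypeList>{types_xml}</PublicationTypeList>
        </Article>
        <MedlineJournalInfo><NlmUniqueID>{nlm_id}</NlmUniqueID></MedlineJournalInfo>
      </MedlineCitation>
      <PubmedData><History>{history}</History></PubmedData>
    </PubmedArticle>"""


def medline_set_xml(*article_fragments: str) -> str:
    return (
        "<?xml version='1.0' encoding='utf-8'?>"
        f"<PubmedArticleSet>{''.join(article_fragments)}</PubmedArticleSet>"
    )


@pytest.fixture
def medline_builder():
    return medline_article_xml, medline_set_xml
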
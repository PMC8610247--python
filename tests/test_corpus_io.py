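"""Corpus reading, writing, alias pooling and journal eligibility."""

import datetime as dt
import io

import pytest

from journalscreen import (
    Corpus,
    CorpusParseError,
    JournalRecord,
    RawAuthor,
    parse_medline_xml,
    read_corpus_table,
    resolve_aliases,
    restrict_window,
    select_eligible_journals,
    write_corpus_table,
)
from journalscreen.synth import SynthConfig, generate_corpus

from conftest import make_article


class TestMedlineXml:
    def test_round_trip_of_single_article(self, medline_builder):
        art_xml, set_xml = medline_builder
        doc = set_xml(art_xml())
        corpus = parse_medline_xml(io.BytesIO(doc.encode()))
        assert len(corpus.articles) == 1
        art = corpus.articles[0]
        assert art.journal_id == "J1"
        assert art.pub_year == 2018
        assert art.has_abstract
        assert art.pub_types == frozenset({"Journal Article"})
        assert [a.family for a in art.authors] == ["Raoult", "Locher"]
        assert art.date_received == dt.date(2018, 1, 1)
        assert art.date_accepted == dt.date(2018, 2, 1)

    def test_article_without_author_list(self, medline_builder):
        art_xml, set_xml = medline_builder
        doc = set_xml(art_xml(authors=(), received=None, accepted=None))
        corpus = parse_medline_xml(io.BytesIO(doc.encode()))
        (art,) = corpus.articles
        assert art.authors == ()
        assert art.date_received is None and art.date_accepted is None

    def test_collective_author(self, medline_builder):
        art_xml, set_xml = medline_builder
        doc = set_xml(art_xml(authors=(), collective="Red"))
        (art,) = parse_medline_xml(io.BytesIO(doc.encode())).articles
        assert art.authors == (RawAuthor(collective="Red"),)

    def test_truncated_xml_raises(self, medline_builder):
        art_xml, set_xml = medline_builder
        doc = set_xml(art_xml())[:-30]
        with pytest.raises(CorpusParseError):
            parse_medline_xml(io.BytesIO(doc.encode()))

    def test_article_without_journal_id_skipped(self, medline_builder):
        art_xml, set_xml = medline_builder
        fragment = art_xml().replace(
            "<MedlineJournalInfo><NlmUniqueID>J1</NlmUniqueID></MedlineJournalInfo>", ""
        ).replace("<ISSN>1234-5678</ISSN>", "")
        corpus = parse_medline_xml(io.BytesIO(set_xml(fragment).encode()))
        assert corpus.articles == []


class TestTabularDialect:
    def test_three_row_fixture(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text(
            "article_id,journal_id,pub_year,pub_types,has_abstract,authors,"
            "date_received,date_accepted\n"
            "a1,J1,2015,Journal Article,1,\"Doe,Jane,J\",2015-01-01,2015-02-01\n"
            "a2,J1,2016,Editorial|Journal Article,1,\"Doe,Jane,J|collective:Red\",,\n"
            "a3,J2,2017,Letter,0,,,\n"
        )
        corpus = read_corpus_table(path)
        assert len(corpus.articles) == 3
        a2 = corpus.articles[1]
        assert a2.pub_types == frozenset({"Journal Article", "Editorial"})
        assert a2.authors[1] == RawAuthor(collective="Red")
        assert corpus.articles[2].authors == ()

    def test_unknown_column_rejected(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("article_id,journal_id,bogus\n1,J1,x\n")
        with pytest.raises(CorpusParseError, match="bogus"):
            read_corpus_table(path)

    def test_unparsable_date_becomes_absent(self, tmp_path, caplog):
        path = tmp_path / "c.csv"
        path.write_text(
            "article_id,journal_id,pub_year,pub_types,has_abstract,authors,"
            "date_received,date_accepted\n"
            "a1,J1,2015,Journal Article,1,\"Doe,Jane,J\",not-a-date,2015-02-01\n"
        )
        corpus = read_corpus_table(path)
        assert corpus.articles[0].date_received is None
        assert corpus.articles[0].date_accepted == dt.date(2015, 2, 1)

    def test_round_trip_is_exact(self, tmp_path):
        corpus, _ = generate_corpus(SynthConfig(n_journals=3, articles_median=60, seed=7))
        a1, j1 = tmp_path / "a1.csv", tmp_path / "j1.csv"
        write_corpus_table(corpus, a1, j1)
        reread = read_corpus_table(a1, j1)
        a2, j2 = tmp_path / "a2.csv", tmp_path / "j2.csv"
        write_corpus_table(reread, a2, j2)
        assert a1.read_bytes() == a2.read_bytes()
        assert j1.read_bytes() == j2.read_bytes()
        assert reread.articles == corpus.articles


class TestEligibility:
    def _corpus(self, per_journal: dict[str, list]) -> Corpus:
        corpus = Corpus()
        for jid, arts in per_journal.items():
            corpus.journals[jid] = JournalRecord(
                journal_id=jid, titles=[jid], broad_subject_terms=frozenset({"Medicine"})
            )
            corpus.articles.extend(arts)
        return corpus

    def test_boundary_at_least_50_authored(self):
        corpus = self._corpus({
            "J50": [make_article(journal_id="J50") for _ in range(50)],
            "J49": [make_article(journal_id="J49") for _ in range(49)],
        })
        assert select_eligible_journals(corpus) == {"J50"}

    def test_authorless_articles_do_not_count(self):
        arts = [make_article(journal_id="JX") for _ in range(48)]
        arts += [make_article(journal_id="JX", authors=()) for _ in range(12)]
        corpus = self._corpus({"JX": arts})
        assert select_eligible_journals(corpus) == set()

    def test_requires_broad_subject_term(self):
        corpus = self._corpus({"J1": [make_article() for _ in range(60)]})
        corpus.journals["J1"].broad_subject_terms = frozenset()
        assert select_eligible_journals(corpus) == set()
        assert select_eligible_journals(corpus, require_broad_subject_term=False) == {"J1"}

    def test_alias_pooling_sums_authored_counts(self):
        corpus = self._corpus({
            "OLD": [make_article(journal_id="OLD") for _ in range(30)],
            "NEW": [make_article(journal_id="NEW") for _ in range(30)],
        })
        corpus.journals["OLD"].alias_of = "NEW"
        pooled = resolve_aliases(corpus)
        assert set(pooled.journals) == {"NEW"}
        assert sum(a.journal_id == "NEW" for a in pooled.articles) == 60
        assert select_eligible_journals(corpus) == {"NEW"}

    def test_alias_cycle_rejected(self):
        corpus = self._corpus({"A": [make_article(journal_id="A")],
                               "B": [make_article(journal_id="B")]})
        corpus.journals["A"].alias_of = "B"
        corpus.journals["B"].alias_of = "A"
        with pytest.raises(ValueError, match="cycle"):
            resolve_aliases(corpus)

    def test_eligibility_monotone_in_threshold(self):
        corpus = self._corpus({
            f"J{k}": [make_article(journal_id=f"J{k}") for _ in range(n)]
            for k, n in enumerate([20, 50, 80, 120])
        })
        previous = None
        for threshold in (10, 50, 60, 100, 200):
            current = select_eligible_journals(corpus, min_authored=threshold)
            if previous is not None:
                assert current <= previous
            previous = current


def test_restrict_window_filters_by_year():
    corpus = Corpus(articles=[make_article(pub_year=y) for y in (2014, 2015, 2019, 2020)])
    out = restrict_window(corpus, 2015, 2019)
    assert sorted(a.pub_year for a in out.articles) == [2015, 2019]
    assert out.window == (2015, 2019)
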
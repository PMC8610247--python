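"""Percentile thresholds, outlier flags, overlaps, correlations, reports."""

import math

import numpy as np
import pandas as pd
import pytest

from journalscreen import (
    JournalRecord,
    compute_journal_indices,
    compute_lag_summaries,
    compute_thresholds,
    correlate_indices,
    field_summaries,
    flag_outliers,
    overlap_counts,
    percentile_threshold,
    sample_flagged,
    summary_table,
)
from journalscreen.screen import ScreenThresholds
from journalscreen.synth import SynthConfig, generate_corpus


def _indices_frame(ppmp, gini=None):
    gini = gini if gini is not None else ppmp
    return pd.DataFrame({
        "journal_id": [f"J{i}" for i in range(len(ppmp))],
        "population": "all",
        "ppmp": ppmp,
        "gini": gini,
    })


class TestPercentile:
    def test_linear_interpolation_closed_form(self):
        # h = (n-1) q + 1 = 19.05 on the integers 1..20
        assert percentile_threshold(range(1, 21), 0.95) == pytest.approx(19.05)

    def test_constant_vector(self):
        assert percentile_threshold([7.0] * 9, 0.3) == 7.0

    def test_q_one_is_the_maximum(self):
        assert percentile_threshold([3, 1, 9, 4], 1.0) == 9.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percentile_threshold([], 0.95)


class TestFlagging:
    def test_exactly_at_threshold_not_flagged(self):
        idx = _indices_frame([0.1, 0.2, 0.3])
        th = ScreenThresholds("all", 0.95, q95_ppmp=0.3, q95_gini=0.3)
        flags = flag_outliers(idx, th)
        assert not flags["flagged_ppmp"].any()

    def test_mixed_flags(self):
        idx = _indices_frame(ppmp=[0.5], gini=[0.1])
        th = ScreenThresholds("all", 0.95, q95_ppmp=0.3, q95_gini=0.3)
        row = flag_outliers(idx, th).iloc[0]
        assert row.flagged_ppmp and not row.flagged_gini and row.flagged_any

    def test_about_five_percent_flagged_on_continuous_data(self):
        rng = np.random.default_rng(99)
        idx = _indices_frame(rng.random(1000), rng.random(1000))
        flags = flag_outliers(idx, compute_thresholds(idx))
        for col in ("flagged_ppmp", "flagged_gini"):
            assert 0.04 <= flags[col].mean() <= 0.06


class TestOverlap:
    def test_toy_partition(self):
        out = overlap_counts({"j1", "j2"}, {"j2", "j3"}, {"j1", "j2", "j3", "j4"})
        assert out == {"only_a": 1, "only_b": 1, "both": 1, "neither": 1}
        assert sum(out.values()) == 4

    def test_identical_and_disjoint_sets(self):
        u = {"a", "b", "c"}
        assert overlap_counts({"a"}, {"a"}, u)["only_a"] == 0
        assert overlap_counts({"a"}, {"b"}, u)["both"] == 0

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError):
            overlap_counts({"zz"}, set(), {"a"})


class TestCorrelation:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = correlate_indices(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.ci_low <= res.r <= res.ci_high

    def test_hand_computed_fixture(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 6]
        res = correlate_indices(x, y)
        assert res.r == pytest.approx(10 / math.sqrt(10 * 14.8), abs=1e-12)

    def test_independent_data_near_zero(self):
        rng = np.random.default_rng(3)
        res = correlate_indices(rng.standard_normal(10_000), rng.standard_normal(10_000))
        assert abs(res.r) < 0.03
        assert res.ci_low <= res.r <= res.ci_high

    def test_ci_narrows_with_n(self):
        rng = np.random.default_rng(4)
        widths = []
        for n in (50, 500, 5000):
            x = rng.standard_normal(n)
            y = 0.5 * x + rng.standard_normal(n)
            res = correlate_indices(x, y)
            widths.append(res.ci_high - res.ci_low)
        assert widths[0] > widths[1] > widths[2]

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate_indices([1, 1, 1, 1], [1, 2, 3, 4])


class TestFieldSummaries:
    def _journals(self, terms_by_jid):
        return {
            jid: JournalRecord(jid, [jid], frozenset(terms))
            for jid, terms in terms_by_jid.items()
        }

    def test_journal_with_two_terms_counted_in_both(self):
        idx = _indices_frame([0.1] * 21)
        terms = {f"J{i}": ["A"] for i in range(10)}
        terms.update({f"J{i}": ["B"] for i in range(10, 20)})
        terms["J20"] = ["A", "B"]
        out = field_summaries(idx, self._journals(terms), min_journals=10)
        assert dict(zip(out["broad_subject_term"], out["n_journals"])) == {"A": 11, "B": 11}

    def test_small_terms_omitted(self):
        idx = _indices_frame([0.1] * 19)
        terms = {f"J{i}": ["A"] for i in range(10)}
        terms.update({f"J{i}": ["B"] for i in range(10, 19)})  # only 9 journals
        out = field_summaries(idx, self._journals(terms), min_journals=10)
        assert list(out["broad_subject_term"]) == ["A"]

    def test_single_term_equals_global_distribution(self):
        vals = [0.1, 0.2, 0.3, 0.4, 0.5, 0.15, 0.25, 0.35, 0.45, 0.05]
        idx = _indices_frame(vals)
        out = field_summaries(idx, self._journals({f"J{i}": ["A"] for i in range(10)}))
        assert out.iloc[0]["ppmp_median"] == pytest.approx(np.median(vals))


class TestSampleFlagged:
    def _journals(self, n):
        return {f"J{i}": JournalRecord(f"J{i}", [f"Journal {i:03d}"]) for i in range(n)}

    def test_deterministic_given_seed(self):
        journals = self._journals(300)
        flagged = [f"J{i}" for i in range(0, 300, 2)]
        a = sample_flagged(flagged, journals, n=50, seed=42)
        b = sample_flagged(flagged, journals, n=50, seed=42)
        assert a == b and len(a) == 50

    def test_all_returned_when_fewer_than_n(self):
        journals = self._journals(10)
        out = sample_flagged([f"J{i}" for i in range(10)], journals, n=100, seed=1)
        assert sorted(out) == sorted(f"J{i}" for i in range(10))

    def test_different_seeds_differ(self):
        journals = self._journals(480)
        flagged = list(journals)
        a = sample_flagged(flagged, journals, n=100, seed=1)
        b = sample_flagged(flagged, journals, n=100, seed=2)
        assert a != b


@pytest.fixture(scope="module")
def pipeline():
    corpus, _ = generate_corpus(SynthConfig(n_journals=8, articles_median=120, seed=21))
    idx = compute_journal_indices(corpus)
    lag_df = compute_lag_summaries(corpus)
    return corpus, idx, lag_df


class TestSummaryTable:
    def test_cells_match_independent_recomputation(self, pipeline):
        corpus, idx, lag_df = pipeline
        table = summary_table(corpus, idx, lag_df)
        lookup = {(r.metric, r.statistic): r.value for r in table.itertuples()}
        assert lookup[("journals", "count")] == len(idx)
        assert lookup[("ppmp_pct", "median")] == pytest.approx(
            float(np.median(idx["ppmp"])) * 100
        )
        assert lookup[("gini", "p95")] == pytest.approx(
            float(np.quantile(idx["gini"], 0.95))
        )
        assert lookup[("tied", "count")] == float(idx["tied"].sum())
        per_journal_counts = pd.Series(
            [a.journal_id for a in corpus.articles]
        ).value_counts()
        assert lookup[("articles", "median")] == pytest.approx(
            float(per_journal_counts.loc[idx["journal_id"]].median())
        )
        n_nc = int((~lag_df["calculable"]).sum())
        assert lookup[("lag_ratio", "not_calculable_count")] == n_nc

    def test_pure_byte_identical_output(self, pipeline):
        corpus, idx, lag_df = pipeline
        a = summary_table(corpus, idx, lag_df).to_csv(index=False)
        b = summary_table(corpus, idx, lag_df).to_csv(index=False)
        assert a == b

    def test_single_journal_table_has_zero_iqr_width(self, pipeline):
        corpus, idx, lag_df = pipeline
        one = idx.iloc[[0]]
        one_lag = lag_df[lag_df.journal_id == one.iloc[0].journal_id]
        table = summary_table(corpus, one, one_lag)
        lookup = {(r.metric, r.statistic): r.value for r in table.itertuples()}
        assert lookup[("ppmp_pct", "q1")] == lookup[("ppmp_pct", "q3")]
        assert lookup[("ppmp_pct", "median")] == pytest.approx(one.iloc[0].ppmp * 100)
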
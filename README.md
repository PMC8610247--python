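# journalscreen

Screening tools for detecting *nepotistic* editorial behavior in scholarly
journals: journals in which a small circle of authors — often sitting on the
journal's own editorial board — accounts for a disproportionate share of the
published output, sometimes with suspiciously fast acceptance.

The package is aimed at meta-researchers, publishers and research-integrity
teams who work with MEDLINE/PubMed article metadata. It computes, per
journal and analysis window:

- **PPMP**, the Percentage of Papers by the Most Prolific author:
  `PPMP = n_max / N_tot`, where `n_max` is the article count of the journal's
  most prolific author (ties all count as "most prolific") and `N_tot` is the
  journal's number of *authored* articles (articles with at least one
  identified author).
- The **sample-corrected Gini index** of the per-author article counts
  `y_1 ≤ … ≤ y_n`:

  ```
  G = [ (2 Σ_i i·y_i) / (n Σ_i y_i) − (n+1)/n ] · n/(n−1)
  ```

  0 means every author published equally often; 1 means maximal
  concentration. The `n/(n−1)` factor corrects for the finite author count.
  Lorenz curves of the same distributions are available for inspection.
- **Publication-lag asymmetry**: the median submission→acceptance lag of
  articles carrying a most-prolific author versus the median lag of the
  remaining articles, and their ratio (below 1 = faster treatment for the
  dominant author).

Journals are screened by flagging those whose PPMP and/or Gini lies strictly
above the empirical 95th percentile of the analyzed population, either over
all authored articles (principal analysis) or restricted to research
articles (sensitivity analysis). Two citation side-metrics (self-citation
boost, skewness/non-article inflation) help characterize flagged journals.

A synthetic corpus generator with exact ground truth — including an
injectable "favored author" who receives a fixed share of a journal's
articles and a faster lag distribution — makes the whole pipeline testable
without downloading anything.

## Worked example

Build a synthetic population of 50 unremarkable journals plus 2 journals
whose dominant author holds 30% of the output, then screen it:

```python
import journalscreen as js

corpus, _ = js.generate_corpus(js.SynthConfig(n_journals=50, seed=42))
bad, _ = js.generate_corpus(
    js.SynthConfig(n_journals=2, favored_share=0.30, seed=43), journal_prefix="N"
)
corpus.journals.update(bad.journals)
corpus.articles.extend(bad.articles)

eligible = js.select_eligible_journals(corpus, population="all", min_authored=50)
idx = js.compute_journal_indices(corpus, population="all", journals=eligible)
thresholds = js.compute_thresholds(idx, q=0.95)
flags = js.flag_outliers(idx, thresholds)
lags = js.compute_lag_summaries(corpus, journals=eligible)

print(f"eligible journals : {len(eligible)}")
print(f"median PPMP       : {100 * idx['ppmp'].median():.2f}%")
print(f"PPMP 95th pct     : {100 * thresholds.q95_ppmp:.2f}%")
print(f"median Gini       : {idx['gini'].median():.3f}")
print(f"Gini 95th pct     : {thresholds.q95_gini:.3f}")
print(f"flagged journals  : {sorted(flags[flags.flagged_any].journal_id)}")
```

Output:

```
eligible journals : 52
median PPMP       : 3.08%
PPMP 95th pct     : 4.33%
median Gini       : 0.326
Gini 95th pct     : 0.359
flagged journals  : ['J0020', 'J0023', 'N0000', 'N0001']
```

Both injected journals are flagged (their PPMP is 30%, an order of magnitude
above the population median of ~3%), alongside two background journals that
happen to sit in the top 5% — the expected behavior of a percentile-based
screen. A flag is a reason to *look*, not a verdict: legitimately productive
authors, professional journalists and small research niches can all produce
elevated values.

The same pipeline is exposed as a CLI (`journalscreen synth`, `ingest`,
`compute`, `authors`, `lag`, `screen`, `citemetrics`); real MEDLINE XML
(`PubmedArticleSet`) is read with `parse_medline_xml`, and corpora travel in
a flat CSV dialect with bit-exact round-trips.

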
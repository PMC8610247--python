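# Methods

## Problem and model

Given article-level metadata for a set of journals over a fixed year window,
the package quantifies how concentrated each journal's output is among its
authors and whether the journal's dominant author(s) enjoy faster
acceptance. Concentration is measured two ways:

- **PPMP** = n_max / N_tot. Authors are identified per journal by family
  name plus full given name when available, otherwise family name plus
  initials; an article counts once per distinct author appearing on it, and
  an article with k authors contributes to k authors' tallies. When several
  authors share the maximal count they are jointly "most prolific" (MPA) and
  the tie is recorded. N_tot counts *authored* articles only — articles with
  no identified author are excluded from the denominator, and journals enter
  the analysis only with at least 50 authored articles in the window and at
  least one NLM Broad Subject Term.
- **Sample-corrected Gini** of the per-author article counts y, sorted
  nondecreasing:
  `G = [(2 Σ i·y_i)/(n Σ y_i) − (n+1)/n] · n/(n−1)`.
  This equals `n/(n−1)` times the mean-absolute-difference form
  `Σ|y_i−y_j| / (2 n² ȳ)`, which the test suite uses as an independent
  oracle, and relates to the Lorenz curve by
  `1 − 2·area(Lorenz) = G·(n−1)/n` (exact trapezoid rule on the polyline).

Publication lag is the whole-day difference between an article's "received"
and "accepted" history dates. Per journal we report the median lag of
articles carrying ≥1 MPA versus the median of the rest, and their ratio; the
ratio is calculable only when both sides have at least one valid lag.

Outliers are journals whose PPMP and/or Gini lies **strictly above** the
empirical 95th percentile of the screened population. Two populations are
supported: all authored articles, and the research-article subset
("Journal Article" type, non-empty abstract, none of the 31 excluded
publication-type labels shipped in
`journalscreen/_data/excluded_publication_types.txt`).

## Conventions and numerical choices

These points are underdetermined by the screening idea itself; the package
fixes one rule each and applies it everywhere:

- **Quantiles**: linear interpolation between order statistics at
  h = (n−1)q + 1 (numpy's `method="linear"`, the default of mainstream
  statistical environments). The method name travels in the threshold
  metadata because the flags depend on it.
- **Single-author Gini**: the n/(n−1) correction is undefined at n = 1; the
  package returns 0 with a warning (one author implies no measurable
  inequality).
- **Name normalization**: Unicode NFC, case-fold, trim, collapse internal
  whitespace, strip periods from initials, hyphens preserved. Minimal
  merging of formatting variants; no homonym splitting and no cross-journal
  identity resolution. The key kind (full name / initials only / collective)
  is recorded so reports can quantify initials-only shares.
- **Collective authors** count as authors by default; a policy flag excludes
  them (treating a collective-only article as authorless), since both
  readings are defensible and materially change PPMP for journals with an
  editorial collective.
- **Lags**: negative lags are data errors and excluded (warning); zero-day
  lags are kept. Medians of even counts are midpoints. "Below the 3-week
  cutoff" means strictly < 21 days.
- **Outlier flagging** uses strict `>`: a journal exactly at the threshold
  is not flagged.
- **Year attribution**: the journal-issue publication year, falling back to
  the electronic publication year. One rule, applied to windowing and to
  yearly (by-year) indices alike.
- **Pearson correlation CI**: Fisher z-transform with the normal quantile
  1.96; degenerate |r| = 1 collapses the interval to a point.
- **Review sampling**: flagged journals are sorted alphabetically by full
  title before a seeded draw without replacement, making the sample
  reproducible within this package (not across other environments'
  generators).

## Synthetic corpus generator

`SynthConfig`/`generate_corpus` produce corpora whose marginals emulate a
large biomedical journal population: per-journal article counts are
log-normal (median 500, log-sd 0.97 ≈ an IQR ratio of 3.7, truncated at the
eligibility minimum of 50); 0.9% of articles are authorless; about half of
the articles carry received/accepted dates; background authorship follows a
Zipf-like rank distribution (pool 1000, exponent 0.4, mean 2 coauthors),
which yields a background most-prolific share of ~3% — the realistic
magnitude for an unremarkable journal. A small share of authors appear with
initials only, and a small share of articles are signed by a per-journal
collective name. Publication types are drawn from a mixture dominated by
"Journal Article" (with an abstract 90% of the time), with editorials,
letters, news and errata making up the rest.

The *favored author* mechanism is exact by construction: with favored share
p, exactly round(p·N) of a journal's N articles carry the favored author
(always with a full name, so the identity never splits), and the recorded
ground truth sets the expected PPMP to
max(n_favored, realized background maximum)/n_authored — equal to the
measured value whenever the background maximum stays below the favored
count. Favored articles draw their lag from a faster log-normal
(median 40 d) than the rest (median 100 d), so the expected per-journal lag
ratio is the ratio of the configured medians (0.4 by default).
`generate_mixture_corpus` builds a screening testbed of journal groups with
different favored shares; its default (200 journals, 5% of them at p = 0.30)
reflects a population where severe favoritism is a rare condition detectable
at the 95th percentile.

What the generator does **not** emulate: real name-variant noise and
homonymy, correlated coauthor communities, journal growth over time,
reprints across journals, or any dependence between journal size and
concentration. Passing recovery tests therefore demonstrates the estimators
and the screen, not robustness to real-world identity noise — the known
dominant error source on real metadata, where initials-only names can merge
distinct people and inflate both indices.

## Problem sizes used in validation

The test suite and acceptance checks run on deliberately modest sizes chosen
to exercise every code path with comfortable statistical margins: Gini
property sweeps over 10,000 random count vectors (lengths 2–500, counts
1–1,000) with the pairwise oracle cross-check on 1,000 of them; a
200-journal mixture corpus (~180k articles) for flagging sensitivity and
false-flag rates; a 30-journal corpus for lag-ratio recovery; and small
corpora for byte-level determinism of the full pipeline.

## Limitations

- The screen is descriptive: flags identify journals whose authorship
  pattern is extreme relative to the analyzed population, not misconduct.
- Exact per-journal values on real data depend on the name-normalization
  rule; more aggressive or more conservative merging shifts both indices.
- The 95th percentile is population-relative: screening a different journal
  universe moves the thresholds.
- Lag analysis is conditional on journals reporting history dates, which is
  itself selective (smaller journals report less often).
- The optional E-utilities fetcher is a convenience for small pulls; it is
  not a harvesting orchestrator and is never exercised by the tests.
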
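# Methods

## Study design

The pipeline compares two samples of MeSH-annotated articles: a *target*
sample matching a research-field query and a broad *control* sample. Each
article is a (PMID, publication date, set of descriptor names) record.
Articles are binned into ordered yearly intervals — calendar years by
default, or PubMed `PDat`-style windows opening on Oct 22 and closing Oct 21
of the following year (`pubmed_windows`). Binning intervals are closed on
both ends; an article dated exactly on a boundary belongs to the interval
that starts there. Year-only dates resolve to January 1; records without a
parseable date are dropped with a warning.

Before any counting, PMIDs occurring in both samples are removed from
*both*, so every article is uniquely attributed; per-year sample sizes
N_t(y), N_c(y) are recomputed afterwards and kept as independent
denominators (real target and control samples differ in size by a factor of
several).

## Term universe and filters

Descriptor names are matched case-insensitively after trimming; qualifiers
(subheadings) are never counted — descriptor-only counting is an explicit
assumption. With a vocabulary loaded, analysis is restricted to the MeSH
top-level categories C, D and E (first letter of any tree number;
subcategories included). Terms found in articles but absent from the
vocabulary are dropped when category filtering is active and reported in
the run manifest.

Two support rules follow:

* **Minimum support** (`filter_min_support`, threshold 5): a term is kept
  only with ≥ 6 annotated articles in the target sample *and* ≥ 6 in the
  control sample over the whole window. The per-sample reading is the
  stricter of the two plausible ones and matches the rule-of-five
  motivation: with fewer than ~5 expected counts per cell the chi-square
  approximation is unreliable.
* **Minimum years** (`filter_min_years`, 6): a (term, sample) series enters
  the trend scan only with a non-zero count in ≥ 6 distinct year bins in
  that sample. Ineligible series are excluded from trend testing only, not
  from the differential analysis.

## Differential statistics

Per term and year, the two-proportion chi-square test (1 df, two-sided)
compares PM_i/N_t with GM_i/N_c. The implementation reproduces R's
`prop.test` exactly, including the clamped Yates correction
`min(0.5, |obs − exp|)`; the correction is on by default and can be
disabled. A pooled proportion of exactly 0 or 1 leaves nothing to test and
returns p = 1 with a degenerate flag. Years in which either sample is empty
are excluded from per-year testing.

Benjamini–Hochberg adjustment runs across all terms *within each year* —
per-year p-values are produced per testing family, so each year is treated
as one family. Fisher's method aggregates each term's **raw** per-year
p-values (χ² = −2 Σ ln p against χ²(2k)); Fisher's method is defined for
raw p-values, and the FDR-adjusted values are reported separately. Zero
p-values are clamped to the smallest positive float before taking logs. A
further BH pass over the aggregated p-values across terms yields
`fisher_q`, the default criterion (≤ 0.05) for calling a term
sample-specific — the significance cut on aggregated p-values is a package
choice, exposed as a parameter.

The effect size is `logratio = log2(target freq / control freq)`, computed
both pooled over the whole window (Σ counts / Σ sizes per sample) and per
year. A zero control frequency returns the sentinel 10; a zero target
frequency with non-zero control returns −inf (only possible per-year: the
support filter guarantees positive pooled counts). Note the asymmetry is
deliberate: only the zero-*control* case is sentinelled.

### Calibration and discreteness

The chi-square p-value is asymptotically Uniform(0, 1) under the null, but
on finite 2×2 tables it is discrete. Two consequences matter for
calibration studies:

* The Yates-corrected p-values are conservative *by construction* and are
  not uniform even asymptotically; uniformity checks are therefore run on
  the uncorrected statistic, while the corrected test is verified to be
  conservative (empirical size ≤ nominal).
* With **equal** per-year sample sizes, x₁ = x₂ gives χ² = 0 and p = 1.0
  exactly — a point mass of ≈ 1/(2√(π n q(1−q))) at p = 1 (≈ 4% at
  n = 2000, q ≈ 0.025). A pooled Kolmogorov–Smirnov test over thousands of
  p-values resolves this atom and rejects, although the deviation is
  entirely on the conservative side and the rejection region is calibrated.
  The test suite therefore checks uniformity per yearly testing family
  (N = number of terms per family) and checks P(p ≤ α) ≈ α directly at
  conventional α, which is the operationally relevant property.

## Trend statistics

The Mann–Kendall statistic is S = Σ_{i<j} sign(x_j − x_i) with tie-corrected
variance Var(S) = [n(n−1)(2n+5) − Σ_p t_p(t_p−1)(2t_p+5)]/18. The default
p-value is the normal approximation with continuity correction,
z = (S ∓ 1)/√Var(S) (z = 0 when S = 0); for n ≤ 8 an exact permutation
p-value is available by enumerating all orderings of the observed values.
On the short series this pipeline sees (≤ ~13 points) the approximation is
crude near the threshold; enumeration shows approximation and exact
decisions at p ≤ 0.01 agree outside a narrow band around the threshold.

Series are the term's relative frequencies over the bins in which the
sample has articles; empty (zero-size) bins are removed from the series,
never imputed as zeros — a zero *count* in a non-empty bin is real data and
stays. A trend is classified up/down when the two-sided p ≤ 0.01 with the
matching sign of S, with **no** multiple-testing correction on trend calls:
the test's power on short series is limited, and correcting would suppress
essentially all calls. Both samples are scanned and reported side by side.

Effect sizes: the endpoint change (last − first) × 100 in percentage
points, and Sen's slope (median of all pairwise slopes, via Theil–Sen) as a
robust companion. Both are reported because a printed "−5.2%"-style delta
is ambiguous between the two conventions.

## Synthetic corpora

The generator emulates the two-sample design with known ground truth. Per
(sample, year) a vector of desired inclusion probabilities is assembled
from three layers: power-law baseline frequencies q_k ∝ k^(−0.7), scaled so
Σq equals the mean per-article term budget (12.5 terms); *differential*
terms whose target probability is scaled by 2^enrichment; and *trend* terms
whose probability interpolates linearly from a start to an end frequency
across the bins. Each article draws a uniform 10–15 terms without
replacement by Gumbel top-k weighted sampling, so per-article term counts
are exact and inclusion probabilities are *approximately* proportional to
the weights. The approximation is accurate while each probability is small
relative to the term budget and degrades for very common terms
(Plackett–Luce saturation): the most frequent baseline terms undershoot
their nominal probabilities. Because saturation acts identically on both
samples for null terms, differential and trend calibration are unaffected;
injected terms are best planted at moderate baseline frequencies
(≲ 0.1), where the recovered pooled log-ratio matches the injected
enrichment within Monte-Carlo error.

PMIDs are sequential integers in disjoint target-only / control-only /
shared blocks. Shared articles (an `overlap_fraction` of the smaller
per-year size) are *extras* appended identically to both samples, so
post-deduplication sizes equal the specified sizes exactly — convenient for
exact bookkeeping tests. Fixed seed ⇒ byte-identical TSV outputs.

What the generator does **not** emulate: MeSH indexing lag, vocabulary
revisions across years, correlated term co-occurrence structure (draws are
independent given the weights), journal/author metadata, and free-text
content. Passing tests therefore demonstrate the statistical machinery and
bookkeeping on an idealised annotated corpus, not robustness to those
real-data features.

## Default parameters

| Parameter | Default | Meaning |
| --- | --- | --- |
| category whitelist | {C, D, E} | MeSH top-level categories analysed |
| support threshold | 5 | ≤ 5 articles in either sample ⇒ term removed |
| min years | 6 | < 6 observed years ⇒ series excluded from trends |
| trend threshold | 0.01 | two-sided Mann–Kendall p for an up/down call |
| continuity | on | Yates correction (proportions), continuity (MK z) |
| differential cut | fisher_q ≤ 0.05 | package default for "specific" terms |
| terms/article | 10–15 | synthetic per-article term budget |
| simulated design | 9 years × 2,000/sample/year, 500 terms | default study conditions |

Test and acceptance simulations use corpora of 300–500 terms and 9 yearly
bins at 2,000–5,000 articles per sample per year — large enough that
expected cell counts respect the rule of five and injected effects are in
the high-power regime, small enough to run on one CPU in minutes.

## Known limitations

* The per-year two-proportion tests aggregated by Fisher's method are
  treated as independent across years; articles appear in one year only, so
  this holds by construction, but slow drifts in a term's frequency make
  the aggregate sensitive to any persistent difference, not only constant
  shifts.
* The Mann–Kendall normal approximation is crude for n < 10; the exact
  permutation mode exists for n ≤ 8, and decisions within a narrow band of
  the 0.01 threshold should not be over-interpreted.
* Wordcloud/heatmap exports rank by whole-window pooled frequency; other
  ranking conventions (e.g. most-recent-year frequency) are easy to compute
  from `panel.csv` but are not built in.
* Live PubMed retrieval is out of scope; the `pubmed` module only sketches
  the query windows and interchange format.
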
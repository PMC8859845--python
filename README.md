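# meshtrends

Differential-frequency and trend analysis of MeSH-annotated literature
samples.

Every MEDLINE article is indexed with 10–15 descriptors from the MeSH
controlled vocabulary. Comparing how often each descriptor annotates a
*target* sample of articles (one research field) against a broad *control*
sample — year by year — reveals which topics are specific to the field and
which are rising or falling. `meshtrends` implements that comparison as a
reusable pipeline for scientometric analysis: it consumes MEDLINE XML or a
simple TSV interchange format, applies the standard filtering rules, and
produces tidy result tables with full provenance. A synthetic-corpus
generator with known ground truth makes every stage testable offline.

## Method

For term *i*, year *y* and samples of sizes N_t, N_c, let PM_i and GM_i be
the counts of annotated articles in the target and control sample.

* **Filtering.** PMIDs present in both samples are excluded from both.
  Terms are restricted to MeSH categories C (Diseases), D (Chemicals and
  Drugs) and E (Analytical, Diagnostic and Therapeutic Techniques and
  Equipment), subcategories included. Terms annotating five or fewer
  articles in either sample are removed (the chi-square rule of five).
* **Differential frequency.** Per year, PM_i/N_t vs GM_i/N_c is tested with
  the two-proportion chi-square test (1 df, Yates continuity correction —
  the behaviour of R's `prop.test`). Per-year p-values are BH-FDR adjusted
  across terms within each year, and each term's raw per-year p-values are
  aggregated with Fisher's method, χ² = −2 Σ ln p ~ χ²(2k). Effect size is
  `logratio = log2(PM_i / GM_i)` on relative frequencies; when the control
  count is zero the log-ratio is set to the sentinel value **10**.
* **Trends.** Each term's yearly frequency series (only series observed in
  at least 6 years) is tested with the nonparametric Mann–Kendall test,
  S = Σ_{i<j} sign(x_j − x_i) with tie-corrected variance and continuity
  correction. A trend is called up/down when the two-sided p ≤ 0.01, with
  no multiple-testing correction (the test has limited power on ≤ 13
  points); an exact permutation p is available for short series. Effect
  sizes: endpoint change in percentage points and Sen's slope.

## Worked example

`examples/differential_terms.py` plants one term 4× enriched in the control
sample (log2 enrichment −2) in a synthetic corpus of 2,000 articles per
sample per year over 7 years, then runs the analysis:

```
               term  fisher_chi2     fisher_p     fisher_q  logratio
synthetic term 0150   185.984429 3.944315e-32 1.080742e-29 -2.085391
synthetic term 0220    26.577543 2.183629e-02 9.997945e-01 -0.098180
...
planted term logratio = -2.09  (injected -2.00)
planted term BH-adjusted Fisher p = 1.08e-29
```

The planted term is the only one significant after BH adjustment of the
Fisher-aggregated p-values, and its pooled log-ratio recovers the injected
4-fold control enrichment within sampling error; null terms sit near
logratio 0 with large adjusted p. `examples/trend_detection.py` and
`examples/full_pipeline.py` demonstrate the Mann–Kendall scan and the
file-based pipeline with its manifest bookkeeping.

## Command line

```sh
meshtrends simulate --spec spec.yaml --out simdir     # synthetic corpus + truth
meshtrends run --config config.yaml                   # full pipeline -> run dir
meshtrends report --rundir out --side target          # top differential terms
meshtrends score --rundir out --truth simdir/truth.csv
```

A run directory contains `comparisons.csv`, `trends.csv`, `panel.csv`,
wordcloud/heatmap/summary tables and `manifest.json` (configuration, input
SHA-256 hashes and the exact counts removed by every filter stage).

## Scope

Live PubMed querying is intentionally out of scope (a stub adapter sketches
the interchange); analyses run on materialised article files or synthetic
corpora. See `docs/methods.md` for the statistical model, parameter
defaults, numerical choices and known limitations.
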
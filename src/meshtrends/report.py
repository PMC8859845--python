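"""End-to-end pipeline and presentation-layer tables.

``analyze`` wires the stages together on in-memory objects (binned article
lists → sample assembly → frequency panel → category/support filters →
differential statistics → trend scan) and keeps exact bookkeeping of what
every filter removed.  ``run_pipeline`` is the file-based wrapper: it reads
the inputs named in a :class:`RunConfig`, runs ``analyze`` and writes CSV
result tables plus a JSON run manifest recording the configuration, input
hashes and all filter counts, so every exported number is recomputable.

Presentation helpers produce tidy tables rather than figures: wordcloud
weight tables (term, weight, category — font size proportional to the
side's pooled frequency), heatmap matrices of per-year term shares, and
per-year corpus summaries including the unique-term accumulation slope.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import corpus as corpus_io
from .corpus import Article, SampleCorpus, bin_by_year, build_samples, shared_pmids
from .diffstats import TermComparison, compare_all_terms, comparisons_frame
from .frequency import (
    SAMPLES,
    FrequencyPanel,
    build_panel,
    filter_min_support,
    filter_min_years,
    normalize_to_database_totals,
)
from .trends import TREND_THRESHOLD, TrendResult, trend_scan, trends_frame
from .vocab import DEFAULT_CATEGORIES, Vocabulary, _validate_categories, load_vocabulary

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """File-based pipeline configuration; defaults are the analysis defaults.

    ``bins`` is either ``("calendar", start_year, end_year)`` or
    ``("pubmed", start_year, end_year)`` for the Oct-22 → Oct-21 windows.
    ``categories=None`` disables category filtering (unmapped terms kept).
    """

    target_path: str
    control_path: str
    outdir: str
    vocabulary_path: str | None = None
    db_totals_path: str | None = None
    input_format: str | None = None  # None = infer per file
    vocabulary_format: str | None = None
    bins: tuple = ("calendar", 2010, 2018)
    categories: frozenset[str] | None = frozenset(DEFAULT_CATEGORIES)
    support_threshold: int = 5
    min_years: int = 6
    trend_threshold: float = TREND_THRESHOLD
    continuity: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.categories is not None:
            _validate_categories(self.categories)
        kind = self.bins[0]
        if kind not in ("calendar", "pubmed"):
            raise ValueError(f"unknown binning kind {kind!r}")
        if not 0 < self.trend_threshold < 1:
            raise ValueError("trend threshold must lie in (0, 1)")
        if self.support_threshold < 0:
            raise ValueError("support threshold must be >= 0")

    def intervals(self):
        kind, start, end = self.bins
        if kind == "calendar":
            return corpus_io.calendar_intervals(int(start), int(end))
        return corpus_io.pubmed_windows(int(start), int(end))

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "bins" in d:
            d["bins"] = tuple(d["bins"])
        if d.get("categories") is not None:
            d["categories"] = frozenset(d["categories"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class PipelineResult:
    target: SampleCorpus
    control: SampleCorpus
    panel: FrequencyPanel
    comparisons: list[TermComparison]
    trend_results: list[TrendResult]
    counts: dict[str, object]


def analyze(
    target_articles: Sequence[Article],
    control_articles: Sequence[Article],
    vocabulary: Vocabulary | None = None,
    *,
    categories: frozenset[str] | None = frozenset(DEFAULT_CATEGORIES),
    support_threshold: int = 5,
    min_years: int = 6,
    trend_threshold: float = TREND_THRESHOLD,
    continuity: bool = True,
    years: Sequence[str] | None = None,
) -> PipelineResult:
    """Run the full analysis on binned article lists.

    Category filtering requires a vocabulary; with ``categories=None`` it is
    disabled and unmapped terms stay in the analysis.  ``counts`` records,
    stage by stage, how many PMIDs/terms each rule removed.
    """
    if categories is not None and vocabulary is None:
        raise ValueError("category filtering requires a vocabulary")
    counts: dict[str, object] = {}
    counts["shared_pmids_removed"] = len(shared_pmids(target_articles, control_articles))
    target, control = build_samples(target_articles, control_articles)
    counts["articles"] = {"target": len(target), "control": len(control)}

    panel = build_panel(target, control, years=years, vocabulary=vocabulary)
    counts["terms_observed"] = len(panel.terms)

    if categories is not None:
        assert vocabulary is not None
        from .vocab import restrict_terms

        kept, unmapped, outside = restrict_terms(panel.terms, vocabulary, categories)
        counts["terms_unmapped_removed"] = len(unmapped)
        counts["terms_category_removed"] = len(outside)
        if not kept:
            raise ValueError("no terms remain after category filtering")
        panel = panel.subset(kept)
    else:
        counts["terms_unmapped_removed"] = 0
        counts["terms_category_removed"] = 0

    before = len(panel.terms)
    panel = filter_min_support(panel, threshold=support_threshold)
    counts["terms_support_removed"] = before - len(panel.terms)
    counts["terms_analyzed"] = len(panel.terms)

    panel = filter_min_years(panel, min_years=min_years)
    assert panel.trend_eligible is not None
    counts["terms_trend_ineligible"] = {
        s: int((~panel.trend_eligible[s]).sum()) for s in SAMPLES
    }

    comparisons = compare_all_terms(panel, continuity=continuity)
    trend_results = trend_scan(panel, threshold=trend_threshold, continuity=continuity)
    counts["trend_calls"] = {
        s: {
            d: sum(1 for r in trend_results if r.sample == s and r.direction == d)
            for d in ("up", "down")
        }
        for s in SAMPLES
    }
    return PipelineResult(
        target=target,
        control=control,
        panel=panel,
        comparisons=comparisons,
        trend_results=trend_results,
        counts=counts,
    )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the file-based pipeline; returns the run directory.

    Writes ``panel.csv``, ``comparisons.csv``, ``trends.csv``,
    ``summary_{target,control}.csv``, ``wordcloud_{target,control}.csv``,
    ``heatmap_{target,control}.csv`` and ``manifest.json``.  On any stage
    error, partial outputs are removed and the error re-raised with the
    stage name.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = outdir / name
        frame.to_csv(path, index=name.startswith("heatmap"))
        written.append(path)

    stage = "setup"
    try:
        stage = "read inputs"
        vocabulary = (
            load_vocabulary(config.vocabulary_path, config.vocabulary_format)
            if config.vocabulary_path
            else None
        )
        target_raw = corpus_io.read_articles(config.target_path, config.input_format)
        control_raw = corpus_io.read_articles(config.control_path, config.input_format)

        stage = "bin by year"
        intervals = config.intervals()
        labels = [label for label, _, _ in intervals]
        target_binned = bin_by_year(target_raw, intervals)
        control_binned = bin_by_year(control_raw, intervals)

        stage = "analyze"
        result = analyze(
            target_binned,
            control_binned,
            vocabulary,
            categories=config.categories,
            support_threshold=config.support_threshold,
            min_years=config.min_years,
            trend_threshold=config.trend_threshold,
            continuity=config.continuity,
            years=labels,
        )
        result.counts["articles_outside_bins"] = {
            "target": len(target_raw) - len(target_binned),
            "control": len(control_raw) - len(control_binned),
        }

        stage = "write tables"
        emit("panel.csv", result.panel.to_long())
        emit("comparisons.csv", comparisons_frame(result.comparisons))
        emit("trends.csv", trends_frame(result.trend_results))
        for s, corp in (("target", result.target), ("control", result.control)):
            summary = corpus_summary(corp)
            emit(f"summary_{s}.csv", summary.per_year.assign(
                accumulation_slope=summary.accumulation_slope
            ))
            emit(f"wordcloud_{s}.csv", wordcloud_table(
                result.comparisons, result.panel, side=s, vocabulary=vocabulary
            ))
            top = result.panel.pooled_relfreq(s).sort_values(ascending=False).index[:15]
            emit(f"heatmap_{s}.csv", heatmap_matrix(result.panel, s, list(top)))

        if config.db_totals_path:
            totals = _read_totals(config.db_totals_path)
            shares = {
                s: normalize_to_database_totals(
                    {y: int(result.panel.sizes[s][y]) for y in result.panel.years}, totals
                )
                for s in SAMPLES
            }
            emit("db_shares.csv", pd.DataFrame(shares).rename_axis("year").reset_index())

        stage = "write manifest"
        manifest = {
            "config": _config_dict(config),
            "inputs": {
                name: {"path": str(p), "sha256": _sha256(p)}
                for name, p in (
                    ("target", config.target_path),
                    ("control", config.control_path),
                    ("vocabulary", config.vocabulary_path),
                    ("db_totals", config.db_totals_path),
                )
                if p
            },
            "counts": result.counts,
            "outputs": [p.name for p in written],
        }
        path = outdir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, default=str))
        written.append(path)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return outdir


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    if d.get("categories") is not None:
        d["categories"] = sorted(d["categories"])
    d["bins"] = list(d["bins"])
    return d


def _read_totals(path: str | Path) -> dict[str, int]:
    frame = pd.read_csv(path, dtype={0: str})
    year_col, total_col = frame.columns[:2]
    return dict(zip(frame[year_col].astype(str), frame[total_col].astype(int)))


def wordcloud_table(
    comparisons: Sequence[TermComparison],
    panel: FrequencyPanel,
    side: str,
    top_n: int = 30,
    alpha: float = 0.05,
    vocabulary: Vocabulary | None = None,
) -> pd.DataFrame:
    """Weight table for a one-side wordcloud: (term, weight, category).

    Terms are *specific* to a side when the BH-adjusted Fisher p is at or
    below ``alpha`` and the pooled log-ratio sign points to that side
    (positive = target, negative = control; the zero-control sentinel is
    target-side).  Weight is the side's pooled relative frequency, so font
    sizes are proportional to occurrence frequency.  Rows are in
    non-increasing weight order, truncated to ``top_n``.
    """
    if side not in SAMPLES:
        raise ValueError(f"side must be one of {SAMPLES}")
    if not comparisons:
        raise ValueError("no comparisons given")
    want = 1 if side == "target" else -1
    pooled = panel.pooled_relfreq(side)
    rows = []
    for c in comparisons:
        if c.fisher_q <= alpha and c.direction == want:
            d = vocabulary.get(c.term) if vocabulary is not None else None
            category = min(d.categories) if d is not None and d.categories else ""
            rows.append({"term": c.term, "weight": float(pooled[c.term]), "category": category})
    if not rows:
        log.warning("wordcloud: no terms specific to the %s side", side)
        return pd.DataFrame(columns=["term", "weight", "category"])
    frame = pd.DataFrame(rows).sort_values("weight", ascending=False, kind="stable")
    return frame.head(top_n).reset_index(drop=True)


def heatmap_matrix(
    panel: FrequencyPanel, sample: str, terms: Sequence[str]
) -> pd.DataFrame:
    """Term × year matrix of per-year shares for one sample, rows as given."""
    if sample not in SAMPLES:
        raise ValueError(f"sample must be one of {SAMPLES}")
    if not terms:
        raise ValueError("empty term list")
    known = set(panel.terms)
    for t in terms:
        if t not in known:
            raise ValueError(f"unknown term {t!r}")
    return panel.relfreq(sample).loc[list(terms)]


@dataclass
class CorpusSummary:
    per_year: pd.DataFrame
    accumulation_slope: float


def corpus_summary(corpus: SampleCorpus) -> CorpusSummary:
    """Descriptive per-year statistics plus the unique-term accumulation slope.

    Per year: article count, unique terms used that year, cumulative unique
    terms, mean terms per article.  The accumulation slope is the linear
    regression of cumulative unique vocabulary against cumulative article
    count over the article stream ordered by (year, PMID) — the average
    number of previously unseen terms each article contributes.
    """
    if not corpus.articles:
        raise ValueError("empty corpus")
    ordered = sorted(corpus.articles, key=lambda a: (a.year_bin or "", a.pmid))
    seen: set[str] = set()
    cumulative: list[int] = []
    for a in ordered:
        seen.update(a.terms)
        cumulative.append(len(seen))
    x = np.arange(1, len(ordered) + 1, dtype=float)
    slope = float(stats.linregress(x, np.array(cumulative, dtype=float)).slope) if len(x) > 1 else float("nan")

    rows = []
    running: set[str] = set()
    for year in sorted({a.year_bin for a in ordered if a.year_bin is not None}):
        arts = [a for a in ordered if a.year_bin == year]
        year_terms = set().union(*[a.terms for a in arts]) if arts else set()
        running |= year_terms
        rows.append(
            {
                "year": year,
                "n_articles": len(arts),
                "n_unique_terms": len(year_terms),
                "cumulative_unique_terms": len(running),
                "mean_terms_per_article": float(np.mean([len(a.terms) for a in arts])),
            }
        )
    return CorpusSummary(per_year=pd.DataFrame(rows), accumulation_slope=slope)
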
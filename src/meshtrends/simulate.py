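"""Synthetic MeSH-annotated corpora with known ground truth.

The generator emulates the two-sample study design: a target and a control
sample of articles binned by year, each article indexed with 10–15 terms
drawn from a category-structured vocabulary.  Term inclusion is by weighted
sampling without replacement (Gumbel top-k), with per-article term counts
exact and inclusion probabilities approximately proportional to the
specified per-(sample, year) frequencies — the approximation is good while
each frequency is small relative to the mean number of terms per article,
and degrades for very common terms (documented in the methods note).

Ground truth classes:

* ``null`` — same baseline frequency in both samples, constant over years;
* ``differential`` — target frequency scaled by 2**enrichment;
* ``trend`` — frequency interpolated linearly from start to end across the
  year bins in one sample;
* ``both`` — carries a differential and a trend component.

A configurable fraction of PMIDs is emitted into both samples to exercise
the overlap-exclusion step; those shared articles are extras on top of the
per-year sizes, so the post-deduplication sizes equal the spec exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import Article, write_articles_tsv
from .vocab import MeshDescriptor, Vocabulary, write_vocabulary_tsv

log = logging.getLogger(__name__)

_PMID_BLOCKS = {"target": 1_000_000, "control": 2_000_000, "shared": 3_000_000}


@dataclass(frozen=True)
class DifferentialSpec:
    """A planted target-vs-control difference: target freq × 2**enrichment."""

    term: str
    enrichment: float  # log2 units; negative = control-enriched


@dataclass(frozen=True)
class TrendSpec:
    """A planted monotone trend: frequency interpolates start → end linearly."""

    term: str
    sample: str  # 'target' or 'control'
    start_freq: float
    end_freq: float


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic corpus.

    Defaults reflect the analysed design: 9 one-year bins, 2,000 articles
    per sample per year, a 500-term vocabulary split over categories C/D/E
    with a minority outside the whitelist, 10–15 terms per article, and
    power-law-decaying baseline frequencies scaled so that expected term
    assignments match the per-article term budget.
    """

    seed: int = 0
    years: tuple[str, ...] = tuple(str(y) for y in range(2010, 2019))
    n_target_per_year: int = 2000
    n_control_per_year: int = 2000
    vocabulary_size: int = 500
    category_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"C": 0.3, "D": 0.3, "E": 0.3, "B": 0.1}
    )
    terms_per_article: tuple[int, int] = (10, 15)
    baseline_decay: float = 0.7
    baseline_freqs: Sequence[float] | None = None
    differential_terms: tuple[DifferentialSpec, ...] = ()
    trend_terms: tuple[TrendSpec, ...] = ()
    overlap_fraction: float = 0.05

    def validate(self) -> None:
        lo, hi = self.terms_per_article
        if not 1 <= lo <= hi:
            raise ValueError("terms_per_article range must satisfy 1 <= lo <= hi")
        if hi > self.vocabulary_size:
            raise ValueError("terms_per_article maximum exceeds vocabulary size")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must lie in [0, 1)")
        if self.n_target_per_year <= 0 or self.n_control_per_year <= 0:
            raise ValueError("per-year sizes must be positive")
        if len(self.years) < 1:
            raise ValueError("at least one year bin required")
        if abs(sum(self.category_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("category proportions must sum to 1")
        if self.baseline_freqs is not None:
            q = np.asarray(self.baseline_freqs, dtype=float)
            if q.shape != (self.vocabulary_size,):
                raise ValueError("baseline_freqs length must equal vocabulary_size")
            if np.any((q < 0) | (q > 1)):
                raise ValueError("baseline frequencies must lie in [0, 1]")
        names = {d.term for d in self.differential_terms} | {t.term for t in self.trend_terms}
        known = set(term_names(self.vocabulary_size))
        unknown = sorted(names - known)
        if unknown:
            raise ValueError(f"injected terms not in vocabulary: {unknown}")
        for t in self.trend_terms:
            if t.sample not in ("target", "control"):
                raise ValueError(f"trend sample must be target/control, got {t.sample!r}")
            for f in (t.start_freq, t.end_freq):
                if not 0 <= f <= 1:
                    raise ValueError("trend frequencies must lie in [0, 1]")


@dataclass
class SimulationResult:
    target_articles: list[Article]
    control_articles: list[Article]
    truth: pd.DataFrame
    vocabulary: Vocabulary
    spec: SimulationSpec


def term_names(vocabulary_size: int) -> list[str]:
    """Deterministic synthetic descriptor names, index-addressable."""
    return [f"synthetic term {i:04d}" for i in range(vocabulary_size)]


def _build_vocabulary(spec: SimulationSpec, rng: np.random.Generator) -> Vocabulary:
    letters = list(spec.category_proportions)
    probs = np.array([spec.category_proportions[c] for c in letters], dtype=float)
    assigned = rng.choice(letters, size=spec.vocabulary_size, p=probs)
    vocab = Vocabulary()
    for i, (name, letter) in enumerate(zip(term_names(spec.vocabulary_size), assigned)):
        tree = f"{letter}{rng.integers(1, 100):02d}.{rng.integers(100, 1000):03d}"
        vocab.add(MeshDescriptor(ui=f"D9{i:05d}", name=name, tree_numbers=(tree,)))
    return vocab


def _baseline(spec: SimulationSpec) -> np.ndarray:
    if spec.baseline_freqs is not None:
        return np.asarray(spec.baseline_freqs, dtype=float)
    ranks = np.arange(1, spec.vocabulary_size + 1, dtype=float)
    q = ranks ** -spec.baseline_decay
    mean_terms = sum(spec.terms_per_article) / 2.0
    q *= mean_terms / q.sum()
    return np.clip(q, 0.0, 0.9)


def _probability_grid(spec: SimulationSpec) -> dict[str, np.ndarray]:
    """Per-sample (years × vocab) inclusion-probability targets."""
    names = term_names(spec.vocabulary_size)
    index = {n: i for i, n in enumerate(names)}
    base = _baseline(spec)
    n_years = len(spec.years)
    grid = {s: np.tile(base, (n_years, 1)) for s in ("target", "control")}
    for d in spec.differential_terms:
        grid["target"][:, index[d.term]] = base[index[d.term]] * 2.0 ** d.enrichment
    for t in spec.trend_terms:
        ramp = np.linspace(t.start_freq, t.end_freq, n_years)
        grid[t.sample][:, index[t.term]] = ramp
    for s in grid:
        grid[s] = np.clip(grid[s], 0.0, 0.9)
    return grid


def _draw_articles(
    probs: np.ndarray,
    n_articles: int,
    spec: SimulationSpec,
    rng: np.random.Generator,
    names: list[str],
) -> list[frozenset[str]]:
    """Weighted sampling without replacement via Gumbel top-k keys."""
    lo, hi = spec.terms_per_article
    m = rng.integers(lo, hi + 1, size=n_articles)
    with np.errstate(divide="ignore"):
        logw = np.log(probs)
    keys = logw[None, :] + rng.gumbel(size=(n_articles, len(probs)))
    order = np.argsort(-keys, axis=1)
    return [frozenset(names[j] for j in order[i, : m[i]]) for i in range(n_articles)]


def generate(spec: SimulationSpec) -> SimulationResult:
    """Generate target/control articles plus a ground-truth table.

    Fully reproducible for a fixed seed: identical spec → byte-identical
    TSV output.  Shared PMIDs (``overlap_fraction`` of the smaller per-year
    size) are appended to both samples with identical content.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    vocab = _build_vocabulary(spec, rng)
    names = term_names(spec.vocabulary_size)
    grid = _probability_grid(spec)

    counters = dict(_PMID_BLOCKS)
    samples: dict[str, list[Article]] = {"target": [], "control": []}
    sizes = {"target": spec.n_target_per_year, "control": spec.n_control_per_year}
    for yi, year in enumerate(spec.years):
        for s in ("target", "control"):
            term_sets = _draw_articles(grid[s][yi], sizes[s], spec, rng, names)
            for terms in term_sets:
                samples[s].append(
                    Article(pmid=counters[s], date=_year_date(year), terms=terms, year_bin=year)
                )
                counters[s] += 1
        n_shared = int(round(spec.overlap_fraction * min(sizes.values())))
        if n_shared:
            term_sets = _draw_articles(grid["control"][yi], n_shared, spec, rng, names)
            for terms in term_sets:
                art = Article(
                    pmid=counters["shared"], date=_year_date(year), terms=terms, year_bin=year
                )
                samples["target"].append(art)
                samples["control"].append(art)
                counters["shared"] += 1

    truth = _truth_table(spec)
    return SimulationResult(
        target_articles=samples["target"],
        control_articles=samples["control"],
        truth=truth,
        vocabulary=vocab,
        spec=spec,
    )


def _year_date(year_label: str):
    import datetime as dt

    return dt.date(int(year_label), 1, 1)


def _truth_table(spec: SimulationSpec) -> pd.DataFrame:
    diff = {d.term: d for d in spec.differential_terms}
    trend = {t.term: t for t in spec.trend_terms}
    rows = []
    for name in term_names(spec.vocabulary_size):
        if name in diff and name in trend:
            cls = "both"
        elif name in diff:
            cls = "differential"
        elif name in trend:
            cls = "trend"
        else:
            cls = "null"
        rows.append(
            {
                "term": name,
                "class": cls,
                "enrichment": diff[name].enrichment if name in diff else 0.0,
                "trend_sample": trend[name].sample if name in trend else "",
                "start_freq": trend[name].start_freq if name in trend else np.nan,
                "end_freq": trend[name].end_freq if name in trend else np.nan,
            }
        )
    return pd.DataFrame(rows)


def write_outputs(result: SimulationResult, outdir: str | Path) -> dict[str, Path]:
    """Emit the TSV interchange files, ground truth CSV and the spec as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "target": outdir / "target.tsv",
        "control": outdir / "control.tsv",
        "vocabulary": outdir / "vocabulary.tsv",
        "truth": outdir / "truth.csv",
        "spec": outdir / "simulation_spec.json",
    }
    write_articles_tsv(sorted(result.target_articles, key=lambda a: a.pmid), paths["target"])
    write_articles_tsv(sorted(result.control_articles, key=lambda a: a.pmid), paths["control"])
    write_vocabulary_tsv(result.vocabulary, paths["vocabulary"])
    result.truth.to_csv(paths["truth"], index=False)
    paths["spec"].write_text(json.dumps(_spec_to_dict(result.spec), indent=2))
    return paths


def _spec_to_dict(spec: SimulationSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["category_proportions"] = dict(spec.category_proportions)
    if spec.baseline_freqs is not None:
        d["baseline_freqs"] = list(map(float, spec.baseline_freqs))
    return d


def truth_score(
    truth: pd.DataFrame,
    differential_calls: Mapping[str, bool] | None = None,
    trend_calls: Mapping[str, str] | None = None,
) -> dict[str, dict[str, float]]:
    """Confusion summary (recall, false-positive rate) against ground truth.

    ``differential_calls`` maps term → bool (called differential);
    ``trend_calls`` maps term → direction string for the sample the trend
    was injected in ('up'/'down'/'none'); a trend call is correct only when
    the direction matches the injected sign.  Terms in the calls but not in
    the truth table are a namespace mismatch and raise an error.
    """
    known = set(truth["term"])
    out: dict[str, dict[str, float]] = {}

    def _rates(tp: int, fn: int, fp: int, tn: int) -> dict[str, float]:
        return {
            "tp": tp,
            "fn": fn,
            "fp": fp,
            "tn": tn,
            "recall": tp / (tp + fn) if tp + fn else float("nan"),
            "fpr": fp / (fp + tn) if fp + tn else float("nan"),
        }

    if differential_calls is not None:
        unknown = sorted(set(differential_calls) - known)
        if unknown:
            raise ValueError(f"terms not in ground truth: {unknown[:5]}")
        is_diff = dict(zip(truth["term"], truth["class"].isin(["differential", "both"])))
        tp = fn = fp = tn = 0
        for term, called in differential_calls.items():
            if is_diff[term]:
                tp, fn = (tp + 1, fn) if called else (tp, fn + 1)
            else:
                fp, tn = (fp + 1, tn) if called else (fp, tn + 1)
        out["differential"] = _rates(tp, fn, fp, tn)

    if trend_calls is not None:
        unknown = sorted(set(trend_calls) - known)
        if unknown:
            raise ValueError(f"terms not in ground truth: {unknown[:5]}")
        info = truth.set_index("term")
        tp = fn = fp = tn = 0
        for term, direction in trend_calls.items():
            row = info.loc[term]
            if row["class"] in ("trend", "both"):
                expect = "up" if row["end_freq"] > row["start_freq"] else "down"
                tp, fn = (tp + 1, fn) if direction == expect else (tp, fn + 1)
            else:
                fp, tn = (fp + 1, tn) if direction != "none" else (fp, tn + 1)
        out["trend"] = _rates(tp, fn, fp, tn)
    return out
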
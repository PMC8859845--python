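"""Per-term, per-year, per-sample counts and relative frequencies.

The frequency panel is the pipeline's central container: for every MeSH
term, year bin and sample it holds the number of annotated articles
(PM_i for the target, GM_i for the control), the per-year sample sizes
(N_t, N_c) and the relative frequency count/size.  Relative frequencies are
exact ratios computed at use time, never pre-rounded.

Two support filters mirror the analysis rules:

* minimum support — a term is kept only if it annotates at least
  ``threshold + 1`` articles (default: six or more) in *each* sample over
  the whole window, the chi-square rule-of-five motivation applied per
  sample;
* minimum years — a (term, sample) series is eligible for trend testing
  only if the term has a non-zero count in at least ``min_years`` (default
  six) distinct bins in that sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import SampleCorpus
from .vocab import Vocabulary, normalize_term

log = logging.getLogger(__name__)

SAMPLES = ("target", "control")


@dataclass
class FrequencyPanel:
    """Counts, sizes and relative frequencies per (sample, term, year).

    ``counts[sample]`` is a terms × years integer DataFrame; ``sizes[sample]``
    a per-year Series.  ``trend_eligible`` is populated by
    :func:`filter_min_years`.
    """

    counts: dict[str, pd.DataFrame]
    sizes: dict[str, pd.Series]
    trend_eligible: dict[str, pd.Series] | None = None
    min_years: int | None = None

    def __post_init__(self) -> None:
        for s in SAMPLES:
            if s not in self.counts or s not in self.sizes:
                raise ValueError(f"panel lacks sample {s!r}")
            c, n = self.counts[s], self.sizes[s]
            if not c.columns.equals(n.index):
                raise ValueError(f"sample {s!r}: count columns != size index")
            if (c.to_numpy() < 0).any() or (c.gt(n, axis=1)).to_numpy().any():
                raise ValueError(f"sample {s!r}: counts must satisfy 0 <= count <= size")

    @property
    def terms(self) -> list[str]:
        return list(self.counts["target"].index)

    @property
    def years(self) -> list[str]:
        return list(self.counts["target"].columns)

    def relfreq(self, sample: str) -> pd.DataFrame:
        """count / size per cell; NaN for zero-size (empty) years."""
        sizes = self.sizes[sample].replace(0, np.nan)
        return self.counts[sample].div(sizes, axis=1)

    def pooled_counts(self, sample: str) -> pd.Series:
        return self.counts[sample].sum(axis=1)

    def pooled_relfreq(self, sample: str) -> pd.Series:
        """Whole-window relative frequency: Σ counts / Σ sizes."""
        total = self.sizes[sample].sum()
        if total == 0:
            raise ValueError(f"sample {sample!r} has no articles")
        return self.pooled_counts(sample) / total

    def empty_years(self) -> list[str]:
        """Years with zero size in either sample (excluded from per-year tests)."""
        return [y for y in self.years if any(self.sizes[s][y] == 0 for s in SAMPLES)]

    def subset(self, terms: Sequence[str]) -> "FrequencyPanel":
        """Panel restricted to ``terms`` (order preserved); flags subset too."""
        missing = [t for t in terms if t not in self.counts["target"].index]
        if missing:
            raise KeyError(f"terms not in panel: {missing[:5]}")
        eligible = (
            {s: self.trend_eligible[s].loc[list(terms)] for s in SAMPLES}
            if self.trend_eligible is not None
            else None
        )
        return FrequencyPanel(
            counts={s: self.counts[s].loc[list(terms)] for s in SAMPLES},
            sizes={s: self.sizes[s].copy() for s in SAMPLES},
            trend_eligible=eligible,
            min_years=self.min_years,
        )

    def to_long(self) -> pd.DataFrame:
        """Long-format export: sample, term, year, count, size, relfreq."""
        rows = []
        for s in SAMPLES:
            rf = self.relfreq(s)
            for term in self.terms:
                for year in self.years:
                    rows.append(
                        {
                            "sample": s,
                            "term": term,
                            "year": year,
                            "count": int(self.counts[s].at[term, year]),
                            "size": int(self.sizes[s][year]),
                            "relfreq": rf.at[term, year],
                        }
                    )
        return pd.DataFrame(rows)

    @classmethod
    def from_long(cls, frame: pd.DataFrame) -> "FrequencyPanel":
        counts: dict[str, pd.DataFrame] = {}
        sizes: dict[str, pd.Series] = {}
        years = list(dict.fromkeys(frame["year"].astype(str)))
        terms = list(dict.fromkeys(frame["term"]))
        for s in SAMPLES:
            sub = frame[frame["sample"] == s]
            c = sub.pivot(index="term", columns="year", values="count")
            c.columns = c.columns.astype(str)
            counts[s] = c.reindex(index=terms, columns=years).fillna(0).astype(int)
            sz = sub.drop_duplicates("year").set_index(sub.drop_duplicates("year")["year"].astype(str))["size"]
            sizes[s] = sz.reindex(years).fillna(0).astype(int)
            sizes[s].index.name = None
            counts[s].index.name = None
            counts[s].columns.name = None
        return cls(counts=counts, sizes=sizes)


def build_panel(
    target: SampleCorpus,
    control: SampleCorpus,
    years: Sequence[str] | None = None,
    vocabulary: Vocabulary | None = None,
) -> FrequencyPanel:
    """Count annotated articles per (sample, term, year) and derive frequencies.

    Term identity is case-insensitive after trimming; when a vocabulary is
    given, matched terms display under their preferred descriptor name,
    otherwise under the first spelling seen.  Terms absent in a year keep
    count 0.  Empty year bins are flagged (``empty_years``) and excluded
    from per-year tests downstream.
    """
    corpora = {"target": target, "control": control}
    if years is None:
        observed = {a.year_bin for c in corpora.values() for a in c.articles if a.year_bin}
        if not observed:
            raise ValueError("no articles carry a year bin; run bin_by_year first")
        years = sorted(observed)
    years = [str(y) for y in years]

    display: dict[str, str] = {}

    def canon(term: str) -> str:
        key = normalize_term(term)
        if key not in display:
            name = vocabulary.canonical_name(term) if vocabulary is not None else None
            display[key] = name if name is not None else term.strip()
        return key

    tallies: dict[str, dict[tuple[str, str], int]] = {s: {} for s in SAMPLES}
    for s, corpus in corpora.items():
        for a in corpus.articles:
            if a.year_bin not in years:
                continue
            for term in a.terms:
                cell = (canon(term), a.year_bin)
                tallies[s][cell] = tallies[s].get(cell, 0) + 1

    keys = sorted(display, key=lambda k: display[k].casefold())
    counts: dict[str, pd.DataFrame] = {}
    sizes: dict[str, pd.Series] = {}
    for s, corpus in corpora.items():
        mat = np.zeros((len(keys), len(years)), dtype=int)
        for (key, year), n in tallies[s].items():
            mat[keys.index(key), years.index(year)] = n
        counts[s] = pd.DataFrame(mat, index=[display[k] for k in keys], columns=years)
        sizes[s] = pd.Series(
            [corpus.year_sizes.get(y, 0) for y in years], index=years, dtype=int
        )
    panel = FrequencyPanel(counts=counts, sizes=sizes)
    empty = panel.empty_years()
    if empty:
        log.warning("year bin(s) empty in one sample, excluded from per-year tests: %s", empty)
    return panel


def filter_min_support(panel: FrequencyPanel, threshold: int = 5) -> FrequencyPanel:
    """Drop terms annotating ``threshold`` or fewer articles in either sample.

    With the default of 5, a term survives only with >= 6 articles in the
    target sample AND >= 6 in the control sample over the whole window.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    keep = [
        t
        for t in panel.terms
        if all(panel.pooled_counts(s)[t] > threshold for s in SAMPLES)
    ]
    if not keep:
        raise ValueError("no terms survive support filter")
    dropped = len(panel.terms) - len(keep)
    if dropped:
        log.info("support filter (<= %d articles) removed %d term(s)", threshold, dropped)
    return panel.subset(keep)


def filter_min_years(panel: FrequencyPanel, min_years: int = 6) -> FrequencyPanel:
    """Flag (term, sample) series with occurrence data in >= min_years bins.

    Eligibility requires a non-zero count in at least ``min_years`` distinct
    year bins in that sample; ineligible series are excluded from trend
    testing, not from the differential analysis.
    """
    if min_years > len(panel.years):
        raise ValueError(
            f"min_years={min_years} exceeds the {len(panel.years)} available year bins"
        )
    eligible = {
        s: (panel.counts[s] > 0).sum(axis=1) >= min_years for s in SAMPLES
    }
    return replace(panel, trend_eligible=eligible, min_years=min_years)


def normalize_to_database_totals(
    year_sizes: Mapping[str, int], db_totals: Mapping[str, int]
) -> dict[str, float]:
    """Per-year sample share of the whole database: size / database total."""
    shares: dict[str, float] = {}
    for year, size in year_sizes.items():
        if year not in db_totals:
            raise ValueError(f"database totals lack year {year!r}")
        total = db_totals[year]
        if total <= 0:
            raise ValueError(f"database total for year {year!r} must be positive")
        shares[year] = size / total
    return shares
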
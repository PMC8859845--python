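"""Differential term-frequency statistics between target and control samples.

For each term and year the target and control proportions are compared with
the two-proportion chi-square test (1 df, Yates continuity correction by
default — the behaviour of R's ``prop.test``).  Per-year p-values are
adjusted across terms within each year by Benjamini–Hochberg, and each
term's raw per-year p-values are aggregated over the window with Fisher's
method (−2 Σ ln p ~ χ²(2k)).  Effect size is the log₂ ratio of target to
control relative frequency, with the sentinel value 10 when the control
count is zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .frequency import SAMPLES, FrequencyPanel

log = logging.getLogger(__name__)

#: Log-ratio assigned when the control count is zero (target-only term).
ZERO_CONTROL_SENTINEL = 10.0


class PropTestResult(NamedTuple):
    chi2: float
    p: float
    degenerate: bool = False


class FisherResult(NamedTuple):
    chi2: float
    df: int
    p: float


def two_proportion_test(
    x1: int, n1: int, x2: int, n2: int, continuity: bool = True
) -> PropTestResult:
    """Chi-square test of equal proportions on the 2×2 table (1 df, two-sided).

    Matches ``prop.test``: with ``continuity`` the Yates correction
    ``min(0.5, |obs − exp|)`` is subtracted from every |obs − exp| before
    squaring.  A pooled proportion of exactly 0 or 1 leaves nothing to test:
    the result is p = 1 with the ``degenerate`` flag set.
    """
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    total = x1 + x2
    if total == 0 or total == n1 + n2:
        return PropTestResult(chi2=0.0, p=1.0, degenerate=True)
    obs = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    pooled = total / (n1 + n2)
    exp = np.array(
        [[n1 * pooled, n1 * (1 - pooled)], [n2 * pooled, n2 * (1 - pooled)]]
    )
    dev = np.abs(obs - exp)
    yates = min(0.5, dev[0, 0]) if continuity else 0.0
    chi2 = float((((dev - yates) ** 2) / exp).sum())
    return PropTestResult(chi2=chi2, p=float(stats.chi2.sf(chi2, df=1)))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_aggregate(pvalues: Sequence[float]) -> FisherResult:
    """Fisher's method: χ² = −2 Σ ln pᵢ against χ²(2k).

    Zero p-values are clamped to the smallest positive float (and logged),
    since ln 0 is undefined.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        log.warning("fisher_aggregate: clamping %d zero p-value(s)", int((p == 0).sum()))
        p = np.maximum(p, np.finfo(float).tiny)
    chi2, agg_p = stats.combine_pvalues(p, method="fisher")
    return FisherResult(chi2=float(chi2), df=2 * p.size, p=float(agg_p))


def log_ratio(
    target_freq: float, control_freq: float, sentinel: float = ZERO_CONTROL_SENTINEL
) -> float:
    """log₂(target frequency / control frequency).

    Positive values mean target-enriched, negative control-enriched.  A zero
    control frequency returns the sentinel (default 10); a zero target
    frequency with positive control returns −inf; both zero is undefined
    (such terms are removed upstream by the support filter).
    """
    if target_freq < 0 or control_freq < 0:
        raise ValueError("frequencies must be non-negative")
    if target_freq == 0 and control_freq == 0:
        raise ValueError("log ratio undefined when both frequencies are zero")
    if control_freq == 0:
        return float(sentinel)
    if target_freq == 0:
        return float("-inf")
    return math.log2(target_freq / control_freq)


@dataclass
class TermComparison:
    """Differential-frequency result for one term.

    ``per_year_p`` are raw two-proportion p-values; ``per_year_q`` their
    BH adjustment across terms within each year; ``fisher_*`` the Fisher
    aggregation of the raw per-year p-values (df = 2 × years aggregated);
    ``fisher_q`` a BH adjustment of ``fisher_p`` across terms; ``logratio``
    the pooled whole-window effect size and ``per_year_logratio`` its
    per-year analogues.  ``direction`` is the sign of ``logratio``.
    """

    term: str
    per_year_p: dict[str, float]
    per_year_q: dict[str, float]
    per_year_logratio: dict[str, float]
    fisher_chi2: float
    fisher_df: int
    fisher_p: float
    logratio: float
    direction: int
    fisher_q: float = float("nan")


def compare_all_terms(panel: FrequencyPanel, continuity: bool = True) -> list[TermComparison]:
    """Run the full differential analysis over a support-filtered panel.

    Per-year tests run only in years where both samples have articles;
    BH adjustment treats each year as one testing family (all terms);
    Fisher aggregation consumes each term's raw per-year p-values; the
    pooled log-ratio uses whole-window relative frequencies.
    """
    years = [y for y in panel.years if y not in set(panel.empty_years())]
    if not years:
        raise ValueError("no year bin has articles in both samples")
    terms = panel.terms

    pmat = pd.DataFrame(index=terms, columns=years, dtype=float)
    for y in years:
        nt = int(panel.sizes["target"][y])
        nc = int(panel.sizes["control"][y])
        for t in terms:
            res = two_proportion_test(
                int(panel.counts["target"].at[t, y]),
                nt,
                int(panel.counts["control"].at[t, y]),
                nc,
                continuity=continuity,
            )
            pmat.at[t, y] = res.p
    qmat = pd.DataFrame(
        {y: bh_adjust(pmat[y].to_numpy()) for y in years}, index=terms
    )

    pooled = {s: panel.pooled_relfreq(s) for s in SAMPLES}
    relfreq = {s: panel.relfreq(s) for s in SAMPLES}
    out: list[TermComparison] = []
    for t in terms:
        fisher = fisher_aggregate(pmat.loc[t, years].to_numpy())
        lr = log_ratio(float(pooled["target"][t]), float(pooled["control"][t]))
        per_year_lr = {}
        for y in years:
            tf = float(relfreq["target"].at[t, y])
            cf = float(relfreq["control"].at[t, y])
            if tf == 0 and cf == 0:
                per_year_lr[y] = float("nan")
            else:
                per_year_lr[y] = log_ratio(tf, cf)
        out.append(
            TermComparison(
                term=t,
                per_year_p={y: float(pmat.at[t, y]) for y in years},
                per_year_q={y: float(qmat.at[t, y]) for y in years},
                per_year_logratio=per_year_lr,
                fisher_chi2=fisher.chi2,
                fisher_df=fisher.df,
                fisher_p=fisher.p,
                logratio=lr,
                direction=int(np.sign(lr)),
            )
        )
    fisher_q = bh_adjust([c.fisher_p for c in out])
    for c, q in zip(out, fisher_q):
        c.fisher_q = float(q)
    return out


def comparisons_frame(comparisons: Sequence[TermComparison]) -> pd.DataFrame:
    """Flat results table: one row per term, per-year p/q/logratio columns."""
    if not comparisons:
        return pd.DataFrame()
    years = list(comparisons[0].per_year_p)
    rows = []
    for c in comparisons:
        row: dict[str, object] = {
            "term": c.term,
            "fisher_chi2": c.fisher_chi2,
            "fisher_df": c.fisher_df,
            "fisher_p": c.fisher_p,
            "fisher_q": c.fisher_q,
            "logratio": c.logratio,
            "direction": c.direction,
        }
        for y in years:
            row[f"p_{y}"] = c.per_year_p[y]
            row[f"q_{y}"] = c.per_year_q[y]
            row[f"logratio_{y}"] = c.per_year_logratio[y]
        rows.append(row)
    return pd.DataFrame(rows).sort_values("fisher_p", kind="stable").reset_index(drop=True)
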
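"""Mann–Kendall monotone-trend testing on yearly frequency series.

The Mann–Kendall statistic S is the sum over all forward pairs of
sign(x_j − x_i).  Under the null of no trend, S has mean 0 and variance

    Var(S) = [n(n−1)(2n+5) − Σₚ tₚ(tₚ−1)(2tₚ+5)] / 18

with the sum over tie groups of size tₚ.  The default test is the normal
approximation with continuity correction, z = (S ∓ 1)/√Var(S); for short
series (n ≤ 8) an exact permutation p-value is available, since the null
distribution of S over all orderings of the observed values is enumerable.

A trend is classified up/down only when the two-sided p does not exceed the
threshold (default 0.01); no multiple-testing correction is applied to the
trend calls, reflecting the limited power of the test on short series.
Effect sizes are the endpoint frequency change in percentage points and
Sen's slope (median of pairwise slopes).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .frequency import SAMPLES, FrequencyPanel

log = logging.getLogger(__name__)

#: Two-sided p-value threshold for calling a trend credible.
TREND_THRESHOLD = 0.01

_EXACT_MAX_N = 8


class MKResult(NamedTuple):
    S: int
    varS: float
    z: float
    p: float
    n: int
    degenerate: bool = False


def _kendall_s(x: np.ndarray) -> int:
    diff = np.sign(x[None, :] - x[:, None])
    return int(np.triu(diff, k=1).sum())


def _tie_groups(x: np.ndarray) -> np.ndarray:
    _, counts = np.unique(x, return_counts=True)
    return counts[counts > 1]


def mann_kendall(series: Sequence[float], continuity: bool = True) -> MKResult:
    """Mann–Kendall test with tie-corrected variance (two-sided).

    Missing values (NaN) are removed first; at least 3 observations must
    remain.  An all-tied series has Var(S) = 0 and is returned as a
    degenerate no-trend result (S = 0, p = 1).
    """
    x = np.asarray(series, dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n < 3:
        raise ValueError("Mann–Kendall test needs at least 3 non-missing values")
    s = _kendall_s(x)
    ties = _tie_groups(x)
    var_s = (n * (n - 1) * (2 * n + 5) - (ties * (ties - 1) * (2 * ties + 5)).sum()) / 18.0
    if var_s == 0:
        return MKResult(S=0, varS=0.0, z=0.0, p=1.0, n=n, degenerate=True)
    if continuity:
        z = 0.0 if s == 0 else (s - int(np.sign(s))) / math.sqrt(var_s)
    else:
        z = s / math.sqrt(var_s)
    p = 2.0 * stats.norm.sf(abs(z))
    return MKResult(S=s, varS=float(var_s), z=float(z), p=float(min(p, 1.0)), n=n)


def mann_kendall_exact(series: Sequence[float]) -> MKResult:
    """Exact permutation test: p = P(|S| ≥ |S_obs|) over all orderings.

    Enumerates every permutation of the observed values, so it is limited
    to n ≤ 8.  With ties, permutations of the multiset are enumerated with
    multiplicity, which leaves the distribution unchanged.
    """
    x = np.asarray(series, dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n < 3:
        raise ValueError("Mann–Kendall test needs at least 3 non-missing values")
    if n > _EXACT_MAX_N:
        raise ValueError(f"exact permutation test limited to n <= {_EXACT_MAX_N}")
    s_obs = _kendall_s(x)
    ties = _tie_groups(x)
    var_s = (n * (n - 1) * (2 * n + 5) - (ties * (ties - 1) * (2 * ties + 5)).sum()) / 18.0
    if var_s == 0:
        return MKResult(S=0, varS=0.0, z=0.0, p=1.0, n=n, degenerate=True)
    perms = np.array(list(itertools.permutations(x)))
    diff = np.sign(perms[:, None, :] - perms[:, :, None])
    iu = np.triu_indices(n, k=1)
    s_all = diff[:, iu[0], iu[1]].sum(axis=1)
    p = float(np.mean(np.abs(s_all) >= abs(s_obs)))
    z = 0.0 if s_obs == 0 else (s_obs - int(np.sign(s_obs))) / math.sqrt(var_s)
    return MKResult(S=s_obs, varS=float(var_s), z=float(z), p=p, n=n)


def classify_trend(p: float, S: int, threshold: float = TREND_THRESHOLD) -> str:
    """``up`` / ``down`` when p ≤ threshold with the matching sign of S, else ``none``.

    No multiple-testing correction is applied to trend calls.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if p <= threshold and S > 0:
        return "up"
    if p <= threshold and S < 0:
        return "down"
    return "none"


def frequency_delta(series: Sequence[float]) -> float:
    """Endpoint frequency change in percentage points: (last − first) × 100."""
    x = np.asarray(series, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 2:
        raise ValueError("frequency delta needs at least 2 values")
    return float((x[-1] - x[0]) * 100.0)


def sen_slope(series: Sequence[float]) -> float:
    """Sen's slope: median of all pairwise slopes, per year bin."""
    x = np.asarray(series, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 2:
        raise ValueError("Sen's slope needs at least 2 values")
    return float(stats.theilslopes(x, np.arange(len(x))).slope)


@dataclass
class TrendResult:
    """Mann–Kendall outcome for one (term, sample) frequency series."""

    term: str
    sample: str
    n_years: int
    S: int
    varS: float
    z: float
    p: float
    direction: str
    delta_pp: float
    sen_slope: float


def trend_scan(
    panel: FrequencyPanel,
    threshold: float = TREND_THRESHOLD,
    continuity: bool = True,
) -> list[TrendResult]:
    """Score every trend-eligible (term, sample) series in both samples.

    Eligibility flags must have been set by ``filter_min_years``.  Each
    series consists of the term's relative frequencies over the year bins
    in which the sample has articles (zero-size bins are removed from the
    series, not imputed as zeros).  Returns one result per eligible series;
    an empty result (with a warning) if nothing is eligible.
    """
    if panel.trend_eligible is None:
        raise ValueError("panel has no trend-eligibility flags; run filter_min_years first")
    out: list[TrendResult] = []
    for sample in SAMPLES:
        rf = panel.relfreq(sample)
        years = [y for y in panel.years if panel.sizes[sample][y] > 0]
        for term in panel.terms:
            if not bool(panel.trend_eligible[sample][term]):
                continue
            series = rf.loc[term, years].to_numpy(dtype=float)
            mk = mann_kendall(series, continuity=continuity)
            out.append(
                TrendResult(
                    term=term,
                    sample=sample,
                    n_years=mk.n,
                    S=mk.S,
                    varS=mk.varS,
                    z=mk.z,
                    p=mk.p,
                    direction=classify_trend(mk.p, mk.S, threshold=threshold),
                    delta_pp=frequency_delta(series),
                    sen_slope=sen_slope(series),
                )
            )
    if not out:
        log.warning("trend scan: no eligible (term, sample) series")
    return out


def trends_frame(results: Sequence[TrendResult]) -> "pd.DataFrame":
    """Flat trend table, sorted by |delta_pp| descending."""
    import pandas as pd

    frame = pd.DataFrame([vars(r) for r in results])
    if frame.empty:
        return frame
    return (
        frame.reindex(
            columns=[
                "term",
                "sample",
                "n_years",
                "S",
                "varS",
                "z",
                "p",
                "direction",
                "delta_pp",
                "sen_slope",
            ]
        )
        .sort_values("delta_pp", key=lambda s: s.abs(), ascending=False, kind="stable")
        .reset_index(drop=True)
    )
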
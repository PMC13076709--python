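"""Distribution comparisons across reconstruction levels.

Implements the cumulative-histogram Wasserstein distance (sum of absolute
differences between cumulative relative-frequency curves, in bin-index units),
a tie-corrected Friedman test over paired samples, and a paired Wilcoxon
signed-rank test with an exact small-n null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, norm, rankdata

from .histogram import ADCHistogram

__all__ = [
    "TestResult",
    "wasserstein_distance",
    "friedman_across_levels",
    "wilcoxon_paired",
    "percent_difference",
    "aggregate_percent_differences",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    degenerate: bool = False


def wasserstein_distance(h1: ADCHistogram, h2: ADCHistogram) -> float:
    """Sum of |CDF1 - CDF2| over bins of two same-spec histograms.

    Histograms are first normalised to relative counts.  The result is in
    bin-index units (no bin-width scaling): shifting unit mass by k bins gives
    a distance of exactly k.
    """
    if h1.spec != h2.spec:
        raise ValueError("histograms must share one spec")
    t1, t2 = h1.total, h2.total
    if t1 <= 0 or t2 <= 0:
        raise ValueError("zero-mass histogram")
    c1 = np.cumsum(h1.counts / t1)
    c2 = np.cumsum(h2.counts / t2)
    return float(np.abs(c1 - c2).sum())


def friedman_across_levels(*samples) -> TestResult:
    """Tie-corrected Friedman chi-square over k paired samples.

    Rows (blocks) are the paired observations -- here voxels sharing one VOI
    grid -- and columns the treatments (reconstruction levels).  Mid-ranks are
    used within blocks; the classical chi-square statistic is divided by the
    tie-correction factor ``1 - sum(t^3 - t) / (n k (k^2 - 1))`` and referred
    to a chi-square with k-1 degrees of freedom.  Fully tied data are flagged
    degenerate with p = 1.
    """
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    arrays = [np.asarray(s, dtype=float) for s in samples]
    n = arrays[0].size
    if any(a.size != n for a in arrays):
        raise ValueError("samples must be paired (equal lengths)")
    if n < 2:
        raise ValueError("need at least two blocks")
    k = len(arrays)
    x = np.column_stack(arrays)
    ranks = rankdata(x, axis=1)

    ties = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    correction = 1.0 - ties / (n * k * (k**2 - 1))
    col_sums = ranks.sum(axis=0)
    chisq = 12.0 / (n * k * (k + 1)) * float(np.sum(col_sums**2)) - 3.0 * n * (k + 1)
    if correction <= 0:
        return TestResult(statistic=0.0, p_value=1.0, degenerate=True)
    stat = chisq / correction
    return TestResult(statistic=float(stat), p_value=float(chi2.sf(stat, k - 1)))


def _exact_signed_rank_p(ranks2: np.ndarray, w2: float) -> float:
    """Exact two-sided p for the signed-rank statistic with (possibly tied)
    ranks, by dynamic programming over the doubled-rank sum distribution."""
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2.astype(int):
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: dist.size - r]
        dist = dist + shifted
    dist /= dist.sum()
    mu = total / 2.0
    dev = abs(w2 - mu)
    support = np.arange(total + 1)
    return float(dist[np.abs(support - mu) >= dev - 1e-9].sum())


def wilcoxon_paired(x, y, *, exact_max_n: int = 25) -> TestResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped; tied absolute differences receive mid-ranks.
    The null distribution is enumerated exactly (via a generating-function DP
    that handles mid-ranks) for up to ``exact_max_n`` pairs; beyond that a
    normal approximation with continuity and tie corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    d = y - x
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(statistic=0.0, p_value=1.0, degenerate=True)
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= exact_max_n:
        ranks2 = np.round(2 * ranks).astype(int)
        p = _exact_signed_rank_p(ranks2, 2 * w_plus)
        return TestResult(statistic=w_plus, p_value=min(1.0, p))

    mu = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return TestResult(statistic=w_plus, p_value=1.0, degenerate=True)
    dev = abs(w_plus - mu)
    z = (dev - 0.5) / np.sqrt(var)  # continuity correction toward the mean
    p = 2.0 * float(norm.sf(z))
    return TestResult(statistic=w_plus, p_value=min(1.0, p))


def percent_difference(feature_off: float, feature_dl: float) -> float:
    """Signed percent change of a feature relative to its OFF baseline."""
    if feature_off == 0 or not np.isfinite(feature_off):
        return float("nan")
    return 100.0 * (feature_dl - feature_off) / feature_off


def aggregate_percent_differences(values) -> tuple[float, float]:
    """Mean and (n-1) standard deviation of percent differences, NaNs dropped."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return float("nan"), float("nan")
    sd = float(v.std(ddof=1)) if v.size >= 2 else float("nan")
    return float(v.mean()), sd
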
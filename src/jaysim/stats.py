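"""Nonparametric matched-samples tests used to score the simulations.

The same tests the corresponding animal experiments reported: a
Wilcoxon matched-pairs (signed-rank) test for two repeated conditions
and Friedman's analysis of variance by ranks for three.  Alpha 0.05,
two-tailed throughout.
"""

from __future__ import annotations

import math

import numpy as np
import scipy.stats

__all__ = ["wilcoxon_matched_pairs", "friedman_test"]


def wilcoxon_matched_pairs(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped before ranking.  The statistic V is
    the smaller of the positive- and negative-difference rank sums, so
    a unanimous direction gives V = 0.  The p-value is exact for small
    tie-free samples.  Returns (nan, nan) when every difference is zero
    (the test is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if np.all(x == y):
        return (math.nan, math.nan)
    res = scipy.stats.wilcoxon(x, y, zero_method="wilcox",
                               alternative="two-sided", method="auto")
    return (float(res.statistic), float(res.pvalue))


def friedman_test(matrix) -> tuple[float, float]:
    """Friedman's chi-square for a birds x conditions block design.

    Values are ranked within each bird (mid-ranks for ties); the
    statistic uses the standard tie-corrected form with
    df = conditions - 1.  A matrix whose rows are all internally tied
    carries no ordering information and yields chi2 = 0, p = 1.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 conditions")
    n, k = m.shape
    ranks = np.apply_along_axis(scipy.stats.rankdata, 1, m)
    col_sums = ranks.sum(axis=0)
    numer = 12.0 * np.sum(col_sums ** 2) / (n * k * (k + 1)) - 3.0 * n * (k + 1)
    # tie correction (R's friedman.test convention)
    ties = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts ** 3 - counts))
    denom = 1.0 - ties / (n * k * (k ** 2 - 1))
    if denom <= 0.0:
        return (0.0, 1.0)
    chi2 = numer / denom
    p = float(scipy.stats.chi2.sf(chi2, df=k - 1))
    return (float(chi2), p)
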
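"""Self-contained implementations of the statistics used across the package.

These are deliberately written from their defining formulas (two-sample KS D
as the sup of ECDF differences, Bartlett's chi-square, sample Pearson r,
paired t) so that downstream modules do not depend on any particular
statistics library for the quantities they report.  p-values use the standard
asymptotic reference distributions via :mod:`scipy.special`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special


@dataclass(frozen=True)
class KSResult:
    """Two-sample Kolmogorov-Smirnov statistic D = sup |F1(x) - F2(x)|."""

    d_stat: float
    n1: int
    n2: int


@dataclass(frozen=True)
class VarianceCheck:
    """Max/min sample-variance ratio with the <4 homogeneity rule."""

    max_variance_ratio: float
    homogeneous: bool


def ks_two_sample_d(sample1, sample2) -> KSResult:
    """Two-sample KS statistic D evaluated at the union of observed points.

    Both ECDFs are right-continuous; ties are handled by evaluating the
    difference at every distinct observed value.
    """
    x1 = np.asarray(sample1, dtype=float).ravel()
    x2 = np.asarray(sample2, dtype=float).ravel()
    if x1.size == 0 or x2.size == 0:
        raise ValueError("ks_two_sample_d requires two non-empty samples")
    grid = np.union1d(x1, x2)
    f1 = np.searchsorted(np.sort(x1), grid, side="right") / x1.size
    f2 = np.searchsorted(np.sort(x2), grid, side="right") / x2.size
    d = float(np.max(np.abs(f1 - f2)))
    return KSResult(d_stat=d, n1=int(x1.size), n2=int(x2.size))


def bartlett_statistic(groups) -> tuple[float, float]:
    """Bartlett's test of equal variances across k groups.

    Returns ``(statistic, p)`` where the statistic is referred to a
    chi-square with k-1 degrees of freedom.  Raises on a zero-variance group
    (the log of its variance is undefined).
    """
    arrs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrs) < 2:
        raise ValueError("bartlett_statistic requires at least 2 groups")
    ns = np.array([a.size for a in arrs])
    if np.any(ns < 2):
        raise ValueError("every group needs n >= 2")
    variances = np.array([np.var(a, ddof=1) for a in arrs])
    if np.any(variances <= 0):
        raise ValueError("zero variance group: Bartlett statistic undefined")
    k = len(arrs)
    n_tot = int(ns.sum())
    sp2 = float(np.sum((ns - 1) * variances) / (n_tot - k))
    stat = (n_tot - k) * np.log(sp2) - np.sum((ns - 1) * np.log(variances))
    correction = 1.0 + (np.sum(1.0 / (ns - 1)) - 1.0 / (n_tot - k)) / (3.0 * (k - 1))
    stat = float(stat / correction)
    p = float(special.chdtrc(k - 1, stat))
    return stat, p


def variance_homogeneity_check(groups) -> VarianceCheck:
    """Max(s^2)/Min(s^2) across groups; homogeneous iff strictly below 4."""
    arrs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrs) < 2:
        raise ValueError("variance_homogeneity_check requires >= 2 groups")
    if any(a.size < 2 for a in arrs):
        raise ValueError("every group needs n >= 2")
    variances = np.array([np.var(a, ddof=1) for a in arrs])
    vmin, vmax = float(variances.min()), float(variances.max())
    if vmin == 0.0:
        return VarianceCheck(max_variance_ratio=float("inf"), homogeneous=False)
    ratio = vmax / vmin
    return VarianceCheck(max_variance_ratio=ratio, homogeneous=bool(ratio < 4.0))


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 2:
        raise ValueError("pearson_r needs two equal-length samples, n >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(np.sum(xc * xc) * np.sum(yc * yc))
    if denom == 0.0:
        raise ValueError("pearson_r undefined for zero-variance input")
    return float(np.sum(xc * yc) / denom)


def paired_t(x, y=None, one_tailed: bool = False) -> tuple[float, float]:
    """Paired t-test.

    Either pass paired samples ``(x, y)`` (tested on x - y) or a single array
    of differences.  ``one_tailed=True`` halves the p-value in the direction
    of the observed t (upper tail for positive t).
    """
    x = np.asarray(x, dtype=float).ravel()
    d = x if y is None else x - np.asarray(y, dtype=float).ravel()
    n = d.size
    if n < 2:
        raise ValueError("paired_t requires at least 2 pairs")
    sd = np.std(d, ddof=1)
    if sd == 0.0:
        if np.all(d == 0.0):
            return 0.0, 1.0
        raise ValueError("zero-variance differences with nonzero mean")
    t = float(d.mean() / (sd / np.sqrt(n)))
    # two-tailed p from Student t with n-1 df
    p_two = float(2.0 * special.stdtr(n - 1, -abs(t)))
    if one_tailed:
        return t, p_two / 2.0
    return t, p_two
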
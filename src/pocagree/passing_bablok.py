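"""Passing-Bablok rank regression for method comparison.

The slope estimate is a shifted median of all pairwise slopes
S_ij = (y_j - y_i) / (x_j - x_i):

* pairs identical in both coordinates contribute nothing;
* vertical pairs (x_i = x_j, y_i != y_j) contribute signed infinity;
* slopes exactly equal to -1 are removed;
* K = number of remaining slopes < -1 shifts the median so the estimator
  is invariant under exchange of the two methods.

Confidence bounds are the order statistics around the median at distance
C = z * sqrt(n (n-1) (2n+5) / 18) (the Kendall-tau null variance), again
offset by K. The intercept is the median of y - b*x, with its CI obtained
by plugging the slope CI bounds into the same median.

Constant bias is declared when the intercept CI excludes 0; proportional
bias when the slope CI excludes 1.

``pb_oracle`` re-derives the point estimates by literal enumeration in pure
Python and exists only to cross-check ``pb_fit`` in tests.
"""

from __future__ import annotations

import math
import statistics
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PBFit:
    n: int
    n_slopes: int          # N: valid pairwise slopes after exclusions
    k_offset: int          # K: slopes strictly below -1
    slope: float
    ci_slope: tuple
    intercept: float
    ci_intercept: tuple
    constant_bias: bool
    proportional_bias: bool


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def pairwise_slopes(x, y):
    """All valid pairwise slopes, sorted ascending, plus the offset K.

    Returns ``(slopes, K)`` where ``slopes`` is a sorted float array that
    may contain +/-inf for vertical pairs, and K counts slopes < -1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError(f"need >= 3 paired points, got {n}")

    i, j = np.triu_indices(n, k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]

    both_zero = (dx == 0) & (dy == 0)
    dx = dx[~both_zero]
    dy = dy[~both_zero]
    if dx.size == 0:
        raise ValueError("all points identical: no slopes defined")

    s = np.empty(dx.size)
    nz = dx != 0
    s[nz] = dy[nz] / dx[nz]
    s[~nz] = np.where(dy[~nz] > 0, np.inf, -np.inf)
    s = s[s != -1.0]
    k = int((s < -1.0).sum())
    return np.sort(s), k


def _median_1idx(s: np.ndarray, n_items: int, k: int):
    """Shifted median of the sorted slope array (1-indexed convention)."""
    if n_items % 2 == 1:
        idx = (n_items + 1) // 2 + k
        if idx < 1 or idx > n_items:
            raise ValueError("shifted median index out of range")
        return float(s[idx - 1])
    i1 = n_items // 2 + k
    i2 = i1 + 1
    if i1 < 1 or i2 > n_items:
        raise ValueError("shifted median index out of range")
    return 0.5 * (float(s[i1 - 1]) + float(s[i2 - 1]))


def pb_fit(x, y, alpha: float = 0.05) -> PBFit:
    """Passing-Bablok fit of y (test method) on x (comparison method).

    The procedure assumes a positive association between the methods; fewer
    than 10 points triggers a warning because the rank CI becomes very wide
    or undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 10:
        warnings.warn(f"Passing-Bablok with n={n} < 10: CI may be undefined", stacklevel=2)

    s, k = pairwise_slopes(x, y)
    n_slopes = s.size
    b = _median_1idx(s, n_slopes, k)

    z = stats.norm.ppf(1 - alpha / 2)
    c = z * math.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = _round_half_away((n_slopes - c) / 2.0)
    m2 = n_slopes - m1 + 1
    if m1 + k < 1 or m2 + k > n_slopes:
        raise ValueError(
            f"CI undefined at n={n}, alpha={alpha}: order statistic out of range"
        )
    lo = float(s[m1 + k - 1])
    hi = float(s[m2 + k - 1])

    a = float(np.median(y - b * x))
    ci_a = (float(np.median(y - hi * x)), float(np.median(y - lo * x)))

    return PBFit(
        n=n,
        n_slopes=int(n_slopes),
        k_offset=k,
        slope=b,
        ci_slope=(lo, hi),
        intercept=a,
        ci_intercept=ci_a,
        constant_bias=not (ci_a[0] <= 0.0 <= ci_a[1]),
        proportional_bias=not (lo <= 1.0 <= hi),
    )


def pb_line_data(x, y, alpha: float = 0.05) -> dict:
    """Regression-line endpoints (and CI band lines) over the x range."""
    fit = pb_fit(x, y, alpha)
    x = np.asarray(x, dtype=float)
    x0, x1 = float(x.min()), float(x.max())
    return {
        "x0": x0, "x1": x1,
        "y0": fit.intercept + fit.slope * x0,
        "y1": fit.intercept + fit.slope * x1,
        "lo_y0": fit.ci_intercept[1] + fit.ci_slope[0] * x0,
        "lo_y1": fit.ci_intercept[1] + fit.ci_slope[0] * x1,
        "hi_y0": fit.ci_intercept[0] + fit.ci_slope[1] * x0,
        "hi_y1": fit.ci_intercept[0] + fit.ci_slope[1] * x1,
        "slope": fit.slope, "intercept": fit.intercept,
    }


def pb_oracle(x, y):
    """Slope/intercept by literal pure-Python enumeration (test oracle only).

    Independent code path: explicit loops, ``statistics.median``, the same
    exclusion rules (drop 0/0 pairs and slopes == -1, signed infinities for
    vertical pairs, K-shifted median).
    """
    xs = [float(v) for v in x]
    ys = [float(v) for v in y]
    n = len(xs)
    if n != len(ys) or n < 3:
        raise ValueError("need >= 3 paired points")
    if n > 200:
        raise ValueError("oracle limited to n <= 200")

    slopes = []
    for i in range(n):
        for j in range(i + 1, n):
            dx = xs[j] - xs[i]
            dy = ys[j] - ys[i]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                slopes.append(math.inf if dy > 0 else -math.inf)
                continue
            s = dy / dx
            if s != -1.0:
                slopes.append(s)
    if not slopes:
        raise ValueError("all points identical: no slopes defined")
    slopes.sort()
    nn = len(slopes)
    k = sum(1 for s in slopes if s < -1.0)

    if nn % 2 == 1:
        idx = (nn + 1) // 2 + k
        if not 1 <= idx <= nn:
            raise ValueError("shifted median index out of range")
        b = slopes[idx - 1]
    else:
        i1 = nn // 2 + k
        if not (1 <= i1 and i1 + 1 <= nn):
            raise ValueError("shifted median index out of range")
        b = 0.5 * (slopes[i1 - 1] + slopes[i1])

    a = statistics.median([ys[i] - b * xs[i] for i in range(n)])
    return b, a
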
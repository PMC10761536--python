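"""Bland-Altman agreement analysis.

Differences are taken as POC minus reference, so a positive mean bias means
the POC method reads high. Limits of agreement (LoA) are the classical
mean difference +/- 1.96 sd; the 1.96 is deliberately the normal quantile
(it is how LoAs are defined), while the confidence intervals use Student-t
quantiles with n-1 degrees of freedom. The LoA standard error uses the
large-sample approximation Var(LoA) ~= 3 sigma^2 / n from the original
method description.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

LOA_FACTOR = 1.96


@dataclass(frozen=True)
class BAResult:
    n: int
    mean_bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    ci_bias: tuple
    ci_loa_lower: tuple
    ci_loa_upper: tuple
    significant_bias: bool


def bland_altman(poc, ref, alpha: float = 0.05, *, use_t: bool = True) -> BAResult:
    """Bland-Altman statistics for paired POC/reference measurements.

    Parameters
    ----------
    poc, ref : equal-length vectors (n >= 3) of paired values.
    alpha : CI level is 1 - alpha (default 95%).
    use_t : CIs use t-quantiles with df = n-1 (default); ``False`` switches
        to normal quantiles for comparison with software that uses z.

    The bias is flagged significant when the mean-bias CI excludes 0.
    Zero variance is legal: LoAs and their CIs collapse onto the mean bias.
    """
    poc = np.asarray(poc, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if poc.shape != ref.shape:
        raise ValueError(f"length mismatch: {poc.shape} vs {ref.shape}")
    n = poc.size
    if n < 3:
        raise ValueError(f"need >= 3 pairs, got {n}")

    d = poc - ref
    mb = float(d.mean())
    sd = float(d.std(ddof=1))
    lo = mb - LOA_FACTOR * sd
    hi = mb + LOA_FACTOR * sd

    q = stats.t.ppf(1 - alpha / 2, n - 1) if use_t else stats.norm.ppf(1 - alpha / 2)
    se_bias = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(3.0 / n)
    ci_bias = (mb - q * se_bias, mb + q * se_bias)
    ci_lo = (lo - q * se_loa, lo + q * se_loa)
    ci_hi = (hi - q * se_loa, hi + q * se_loa)

    return BAResult(
        n=n,
        mean_bias=mb,
        sd_diff=sd,
        loa_lower=float(lo),
        loa_upper=float(hi),
        ci_bias=(float(ci_bias[0]), float(ci_bias[1])),
        ci_loa_lower=(float(ci_lo[0]), float(ci_lo[1])),
        ci_loa_upper=(float(ci_hi[0]), float(ci_hi[1])),
        significant_bias=not (ci_bias[0] <= 0.0 <= ci_bias[1]),
    )


def ba_plot_data(poc, ref, alpha: float = 0.05):
    """Per-pair (mean, difference) points plus the horizontal line set.

    Returns ``(points, lines)``: a DataFrame with one (mean_of_pair,
    difference) row per pair, and a dict of the mean-bias, LoA and CI line
    positions to draw.
    """
    poc = np.asarray(poc, dtype=float)
    ref = np.asarray(ref, dtype=float)
    res = bland_altman(poc, ref, alpha)
    points = pd.DataFrame({
        "mean_of_pair": (poc + ref) / 2.0,
        "difference": poc - ref,
    })
    lines = {
        "mean_bias": res.mean_bias,
        "loa_lower": res.loa_lower,
        "loa_upper": res.loa_upper,
        "ci_bias_lo": res.ci_bias[0],
        "ci_bias_hi": res.ci_bias[1],
        "ci_loa_lower_lo": res.ci_loa_lower[0],
        "ci_loa_lower_hi": res.ci_loa_lower[1],
        "ci_loa_upper_lo": res.ci_loa_upper[0],
        "ci_loa_upper_hi": res.ci_loa_upper[1],
    }
    return points, lines
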
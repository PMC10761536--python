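"""Precision, bias, observed total error and relative-error zoning.

The quality-control arithmetic of analyzer validation:

* ``CV% = sd(replicates) / mean(replicates) * 100``            (precision)
* ``Bias% = (mean_ref - mean_poc) / mean_ref * 100``           (inaccuracy)
* ``TE_obs% = 2*CV% + Bias%``                                  (total error)
* ``RE% = (poc - ref) / ref * 100`` per pair                   (relative error)

Zone proportions report the share of pairs whose |RE| falls strictly below
each of the regulatory thresholds (12/15/20 % for glucometers).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import MeasurementTable, PairedData, REFERENCE_DEVICE, paired_vectors

DEFAULT_ZONE_THRESHOLDS = (12.0, 15.0, 20.0)


@dataclass(frozen=True)
class PrecisionResult:
    device: str
    analyte: str
    matrix: str
    n_replicates: int
    cv_pct: float


@dataclass(frozen=True)
class ErrorResult:
    device: str
    analyte: str
    matrix: str
    n: int
    cv_pct: float
    bias_pct: float
    te_obs_pct: float
    zones: dict  # threshold -> percent of pairs with |RE| < threshold


def cv_percent(replicates) -> float:
    """Percent coefficient of variation of a replicate run.

    Sample (n-1) standard deviation over the mean, times 100. Requires at
    least two replicates and a strictly positive mean.
    """
    x = np.asarray(replicates, dtype=float)
    if x.size < 2:
        raise ValueError(f"need >= 2 replicates, got {x.size}")
    m = x.mean()
    if m <= 0:
        raise ValueError("CV undefined: replicate mean is not positive")
    return float(x.std(ddof=1) / m * 100.0)


def bias_percent(poc, ref) -> float:
    """Signed percent bias: (mean_ref - mean_poc) / mean_ref * 100.

    Note the sign convention — a POC method that reads HIGH yields a
    NEGATIVE bias percent under this definition.
    """
    poc = np.asarray(poc, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if poc.shape != ref.shape:
        raise ValueError(f"length mismatch: {poc.shape} vs {ref.shape}")
    mr = ref.mean()
    if mr <= 0:
        raise ValueError("bias undefined: reference mean is not positive")
    return float((mr - poc.mean()) / mr * 100.0)


def total_error_observed(cv_pct: float, bias_pct: float, *, signed: bool = False) -> float:
    """Observed total error, TE_obs% = 2*CV% + Bias%.

    By default the bias magnitude enters (TE_obs is a magnitude-style
    quality metric); pass ``signed=True`` to use the signed bias verbatim.
    """
    b = bias_pct if signed else abs(bias_pct)
    return float(2.0 * cv_pct + b)


def relative_error(poc, ref):
    """Signed percent relative error of a POC result against its reference."""
    poc = np.asarray(poc, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if np.any(ref <= 0):
        raise ValueError("relative error undefined: reference value <= 0")
    out = (poc - ref) / ref * 100.0
    return float(out) if out.ndim == 0 else out


def zone_proportions(poc, ref, thresholds=DEFAULT_ZONE_THRESHOLDS) -> dict:
    """Percent of pairs whose |relative error| is strictly below each threshold."""
    poc = np.asarray(poc, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if poc.size < 1 or poc.shape != ref.shape:
        raise ValueError("need >= 1 pair of equal-length vectors")
    re_abs = np.abs(relative_error(poc, ref))
    n = re_abs.size
    return {float(t): float((re_abs < t).sum() / n * 100.0) for t in thresholds}


def summary_stats(values, censored=None, lloq=None) -> dict:
    """Summary block for one analyzer/analyte/matrix vector.

    Numeric statistics use the (imputed) values; when the minimum is an
    imputed below-LLOQ value the minimum is additionally rendered in its
    censored string form (``"< 20"``). sd of a single value is reported as
    0 with ``sd_degenerate=True``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 1:
        raise ValueError("empty vector")
    cen = (
        np.zeros(x.size, dtype=bool)
        if censored is None
        else np.asarray(censored, dtype=bool)
    )
    i_min = int(np.argmin(x))
    min_is_censored = bool(cen[i_min])
    if min_is_censored:
        q = None if lloq is None else np.asarray(lloq, dtype=float)[i_min]
        min_display = f"< {q:g}" if q is not None and np.isfinite(q) else "< LLOQ"
    else:
        min_display = f"{x[i_min]:g}"
    degenerate = x.size == 1
    return {
        "n": int(x.size),
        "mean": float(x.mean()),
        "sd": 0.0 if degenerate else float(x.std(ddof=1)),
        "sd_degenerate": degenerate,
        "median": float(np.median(x)),
        "min": float(x.min()),
        "max": float(x.max()),
        "min_is_censored": min_is_censored,
        "min_display": min_display,
        "n_censored": int(cen.sum()),
    }


# ---------------------------------------------------------------------------
# table-level builders (report blocks)
# ---------------------------------------------------------------------------

def precision_table(table: MeasurementTable) -> pd.DataFrame:
    """Per-(device, analyte, matrix) replicate precision.

    Uses replicate rows (replicate_id >= 1; the primary run is excluded).
    Each replicate animal contributes one CV; the block CV is their mean.
    """
    df = table.df
    reps = df[df["replicate_id"] >= 1]
    rows = []
    for (dev, an, mat), grp in reps.groupby(["device", "analyte", "matrix"], sort=True):
        cvs = []
        for _, sub in grp.groupby("animal_id", sort=True):
            vals = sub["value"].to_numpy(dtype=float)
            if np.isnan(vals).any():
                raise ValueError("replicate rows contain unimputed censored values")
            cvs.append(cv_percent(vals))
        rows.append({
            "device": dev, "analyte": an, "matrix": mat,
            "n_replicates": int(len(grp)),
            "n_animals": grp["animal_id"].nunique(),
            "cv_pct": float(np.mean(cvs)),
        })
    return pd.DataFrame(rows)


def summary_table(table: MeasurementTable) -> pd.DataFrame:
    """Table of summary statistics per (analyte, device, matrix), primary runs."""
    df = table.df
    rep0 = df[df["replicate_id"] == 0]
    rows = []
    for (an, dev, mat), grp in rep0.groupby(["analyte", "device", "matrix"], sort=True):
        s = summary_stats(
            grp["value"].to_numpy(dtype=float),
            grp["censored"].to_numpy(dtype=bool),
            grp["lloq"].to_numpy(dtype=float),
        )
        rows.append({"analyte": an, "device": dev, "matrix": mat, **s})
    return pd.DataFrame(rows)


def error_block(pairs: PairedData, cv_pct: float, device: str, analyte: str,
                matrix: str, *, thresholds=DEFAULT_ZONE_THRESHOLDS) -> ErrorResult:
    """Bias, total error and zone proportions for one paired block."""
    b = bias_percent(pairs.poc, pairs.ref)
    return ErrorResult(
        device=device, analyte=analyte, matrix=matrix,
        n=pairs.n,
        cv_pct=cv_pct,
        bias_pct=b,
        te_obs_pct=total_error_observed(cv_pct, b),
        zones=zone_proportions(pairs.poc, pairs.ref, thresholds),
    )


def error_table(table: MeasurementTable, *, thresholds=DEFAULT_ZONE_THRESHOLDS) -> pd.DataFrame:
    """Table-2-style frame: CV, bias, TE_obs and zones per POC block."""
    prec = precision_table(table)
    cv_lut = {
        (r.device, r.analyte, r.matrix): r.cv_pct for r in prec.itertuples()
    }
    df = table.df
    rep0 = df[(df["replicate_id"] == 0) & (df["device"] != REFERENCE_DEVICE)]
    rows = []
    for (an, dev, mat), _ in rep0.groupby(["analyte", "device", "matrix"], sort=True):
        pairs = paired_vectors(table, an, dev, mat)
        cv = cv_lut.get((dev, an, mat), np.nan)
        b = bias_percent(pairs.poc, pairs.ref)
        te = total_error_observed(0.0 if np.isnan(cv) else cv, b)
        zones = zone_proportions(pairs.poc, pairs.ref, thresholds)
        rows.append({
            "analyte": an, "device": dev, "matrix": mat, "n": pairs.n,
            "cv_pct": cv, "bias_pct": b, "te_obs_pct": te,
            **{f"zone{int(t)}_pct": z for t, z in zones.items()},
            "n_imputed_pairs": int(pairs.any_imputed.sum()),
        })
    return pd.DataFrame(rows)
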
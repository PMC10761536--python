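"""Data model and I/O for paired analyzer measurements.

Measurements live in a long-format table: one row per (animal, analyte,
matrix, device, replicate). Values below a device's lower limit of
quantification (LLOQ) arrive as a censoring token ``<X`` (X = the LLOQ in
analyte units); they are parsed into an explicit ``censored`` flag and kept
as NaN until :func:`impute_lloq` substitutes half the LLOQ, so reports can
always state how many values were imputed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("pocagree")

#: exact header of the measurement CSV, in order
SCHEMA = [
    "animal_id", "species", "sex", "weight_kg", "pcv_pct", "bc_pct",
    "ts_gdl", "analyte", "matrix", "device", "value", "replicate_id",
]
#: columns the in-memory table adds on top of the CSV schema
DERIVED_COLUMNS = ["censored", "lloq"]

ANALYTES = frozenset({"glucose", "bhb"})
MATRICES = frozenset({"whole_blood", "plasma"})
SEXES = frozenset({"M", "F"})
#: device name reserved for the reference laboratory method
REFERENCE_DEVICE = "reference"

#: record key that must be unique within a table
KEY_COLUMNS = ["animal_id", "analyte", "matrix", "device", "replicate_id"]

_CENSOR_RE = re.compile(r"^<\s*([0-9]*\.?[0-9]+)$")


class SchemaError(ValueError):
    """Malformed input: bad header, bad cell, bad enum or duplicate key."""


@dataclass
class MeasurementTable:
    """Long-format measurement records plus free-form study metadata.

    ``df`` carries the CSV schema columns plus ``censored`` (bool) and
    ``lloq`` (the limit parsed from the censoring token, NaN when the row
    was never censored and no device spec supplied one).
    """

    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:  # number of records
        return len(self.df)

    def copy(self) -> "MeasurementTable":
        return MeasurementTable(self.df.copy(), dict(self.metadata))


@dataclass(frozen=True)
class PairedData:
    """POC/reference value pairs for one (analyte, device, matrix) block.

    Vectors are aligned by animal and sorted by ``animal_id``; animals
    lacking either measurement are listed in ``dropped_ids``.
    """

    animal_ids: np.ndarray
    poc: np.ndarray
    ref: np.ndarray
    poc_censored: np.ndarray
    ref_censored: np.ndarray
    covariates: pd.DataFrame
    dropped_ids: tuple

    @property
    def n(self) -> int:
        return len(self.poc)

    @property
    def any_imputed(self) -> np.ndarray:
        """Per-pair flag: at least one member is an imputed (censored) value."""
        return self.poc_censored | self.ref_censored


def _parse_value(cell: str, row: int):
    """Return (value, censored, lloq) for one value cell."""
    cell = str(cell).strip()
    m = _CENSOR_RE.match(cell)
    if m:
        return np.nan, True, float(m.group(1))
    try:
        v = float(cell)
    except ValueError:
        raise SchemaError(
            f"row {row}, column 'value': {cell!r} is neither a number "
            f"nor a '<LLOQ' censoring token"
        ) from None
    if v < 0:
        raise SchemaError(f"row {row}, column 'value': negative value {v}")
    return v, False, np.nan


def read_device_specs(path) -> pd.DataFrame:
    """Read the companion device-spec CSV (device, analyte, lloq, uloq)."""
    spec = pd.read_csv(path)
    expected = ["device", "analyte", "lloq", "uloq"]
    if list(spec.columns) != expected:
        raise SchemaError(
            f"device-spec header {list(spec.columns)} != {expected}"
        )
    return spec


def read_measurements(path, device_specs: pd.DataFrame | None = None) -> MeasurementTable:
    """Read a long-format measurement CSV.

    Censored cells (``<X``) get ``censored=True`` and ``lloq=X``; their value
    stays NaN until :func:`impute_lloq` runs. Row order is preserved.

    Parameters
    ----------
    path : CSV file path with the exact :data:`SCHEMA` header.
    device_specs : optional device-spec frame; when given, device names are
        validated against it and values above a device ULOQ are logged.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(raw.columns) != SCHEMA:
        raise SchemaError(f"header {list(raw.columns)} != expected {SCHEMA}")

    values, censored, lloqs = [], [], []
    for i, cell in enumerate(raw["value"]):
        v, c, q = _parse_value(cell, i)
        values.append(v)
        censored.append(c)
        lloqs.append(q)

    df = raw.copy()
    for col, rows in (
        ("weight_kg", df["weight_kg"]), ("pcv_pct", df["pcv_pct"]),
        ("bc_pct", df["bc_pct"]), ("ts_gdl", df["ts_gdl"]),
    ):
        try:
            df[col] = pd.to_numeric(rows.replace("", np.nan))
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"column {col!r}: {exc}") from None
    try:
        df["replicate_id"] = df["replicate_id"].astype(int)
    except ValueError as exc:
        raise SchemaError(f"column 'replicate_id': {exc}") from None
    df["value"] = np.asarray(values, dtype=float)
    df["censored"] = np.asarray(censored, dtype=bool)
    df["lloq"] = np.asarray(lloqs, dtype=float)

    _validate(df, device_specs)

    if device_specs is not None:
        df = _apply_device_specs(df, device_specs)

    return MeasurementTable(df, metadata={"source": str(path)})


def _validate(df: pd.DataFrame, device_specs: pd.DataFrame | None) -> None:
    bad = set(df["analyte"]) - ANALYTES
    if bad:
        raise SchemaError(f"unknown analyte(s): {sorted(bad)}")
    bad = set(df["matrix"]) - MATRICES
    if bad:
        raise SchemaError(f"unknown matrix value(s): {sorted(bad)}")
    bad = set(df["sex"]) - SEXES
    if bad:
        raise SchemaError(f"unknown sex value(s): {sorted(bad)}")
    if device_specs is not None:
        allowed = set(device_specs["device"]) | {REFERENCE_DEVICE}
        bad = set(df["device"]) - allowed
        if bad:
            raise SchemaError(f"unknown device(s): {sorted(bad)}")
    if (df["replicate_id"] < 0).any():
        raise SchemaError("replicate_id must be >= 0")

    dup = df.duplicated(subset=KEY_COLUMNS)
    if dup.any():
        first = df.loc[dup.idxmax(), KEY_COLUMNS].tolist()
        raise SchemaError(f"duplicate record key {first}")

    ref = df[df["device"] == REFERENCE_DEVICE]
    if (ref["matrix"] != "plasma").any():
        raise SchemaError("reference rows must have matrix=plasma")

    # every animal with a primary POC row for an analyte needs a reference row
    rep0 = df[df["replicate_id"] == 0]
    poc = rep0[rep0["device"] != REFERENCE_DEVICE]
    have_ref = set(map(tuple, ref[["animal_id", "analyte"]].values))
    need_ref = set(map(tuple, poc[["animal_id", "analyte"]].values))
    missing = need_ref - have_ref
    if missing:
        raise SchemaError(
            f"animals with POC rows but no reference row: {sorted(missing)[:5]}"
        )


def _apply_device_specs(df: pd.DataFrame, spec: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    lut = {(r.device, r.analyte): (r.lloq, r.uloq) for r in spec.itertuples()}
    for (dev, an), (lloq, uloq) in lut.items():
        sel = (df["device"] == dev) & (df["analyte"] == an)
        fill = sel & df["lloq"].isna()
        df.loc[fill, "lloq"] = lloq
        if np.isfinite(uloq):
            over = sel & (df["value"] > uloq)
            if over.any():
                logger.warning(
                    "%d %s/%s values above ULOQ %g (flagged, not altered)",
                    int(over.sum()), dev, an, uloq,
                )
    return df


def write_measurements(table: MeasurementTable, path) -> None:
    """Write a table back to the CSV schema.

    Censored rows are rendered as their ``<LLOQ`` token (whether or not the
    table was imputed), so a raw table round-trips bit-identically on values
    and flags.
    """
    out = table.df[SCHEMA].copy()
    vals = []
    for v, c, q in zip(table.df["value"], table.df["censored"], table.df["lloq"]):
        if c:
            vals.append(f"<{q:g}")
        else:
            vals.append(np.format_float_positional(v, trim="-"))
    out["value"] = vals
    out.to_csv(path, index=False)


def impute_lloq(table: MeasurementTable) -> MeasurementTable:
    """Substitute half the instrument's LLOQ for every censored value.

    A censored reading carries no information beyond "below the LLOQ"; half
    the LLOQ is the single-imputation convention that biases downstream
    means least. The censored flag is retained so reports can count imputed
    values. Idempotent.
    """
    df = table.df.copy()
    cen = df["censored"].to_numpy()
    if cen.any():
        lloq = df.loc[cen, "lloq"].to_numpy(dtype=float)
        bad = ~np.isfinite(lloq) | (lloq <= 0)
        if bad.any():
            ids = df.loc[cen, "animal_id"].to_numpy()[bad][:5]
            raise ValueError(
                f"censored rows with missing/zero LLOQ (animals {list(ids)})"
            )
        df.loc[cen, "value"] = lloq / 2.0
    out = MeasurementTable(df, dict(table.metadata))
    out.metadata["n_imputed"] = int(cen.sum())
    return out


def paired_vectors(
    table: MeasurementTable,
    analyte: str,
    device: str,
    matrix: str,
) -> PairedData:
    """Align primary-run POC values with reference values animal by animal.

    Uses replicate_id 0 rows only. The reference is always the plasma
    measurement by the reference laboratory. Animals missing either side
    are dropped and reported; pairs are sorted by ``animal_id`` so every
    downstream statistic is reproducible.

    Raises
    ------
    ValueError
        if imputation has not been applied, or fewer than 3 complete pairs
        remain.
    """
    df = table.df
    rep0 = df[df["replicate_id"] == 0]
    poc = rep0[
        (rep0["device"] == device)
        & (rep0["analyte"] == analyte)
        & (rep0["matrix"] == matrix)
    ]
    ref = rep0[
        (rep0["device"] == REFERENCE_DEVICE) & (rep0["analyte"] == analyte)
    ]
    if len(poc) == 0:
        raise ValueError(f"no rows for device={device!r}, analyte={analyte!r}, matrix={matrix!r}")
    for part, label in ((poc, "POC"), (ref, "reference")):
        if (part["censored"] & part["value"].isna()).any():
            raise ValueError(
                f"{label} rows contain unimputed censored values; "
                "apply impute_lloq first"
            )

    merged = poc.merge(
        ref[["animal_id", "value", "censored"]],
        on="animal_id",
        suffixes=("", "_ref"),
    ).sort_values("animal_id", kind="mergesort")

    universe = set(poc["animal_id"]) | set(ref["animal_id"])
    kept = set(merged["animal_id"])
    dropped = tuple(sorted(universe - kept))
    if dropped:
        logger.info(
            "%s/%s/%s: dropped %d animals lacking a pair: %s",
            device, analyte, matrix, len(dropped), list(dropped),
        )
    if len(merged) < 3:
        raise ValueError(
            f"only {len(merged)} complete pairs for {device}/{analyte}/{matrix}; "
            "need >= 3"
        )

    cov = merged.set_index("animal_id")[
        ["species", "sex", "weight_kg", "pcv_pct", "bc_pct", "ts_gdl"]
    ]
    return PairedData(
        animal_ids=merged["animal_id"].to_numpy(),
        poc=merged["value"].to_numpy(dtype=float),
        ref=merged["value_ref"].to_numpy(dtype=float),
        poc_censored=merged["censored"].to_numpy(dtype=bool),
        ref_censored=merged["censored_ref"].to_numpy(dtype=bool),
        covariates=cov,
        dropped_ids=dropped,
    )
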
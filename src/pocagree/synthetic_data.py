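"""Synthetic analyzer-validation studies.

Emulates a multi-species point-of-care meter validation: a cohort of
animals with species-specific lognormal reference distributions for glucose
(mg/dL) and beta-hydroxybutyrate (mmol/L), three meters reading each animal
in two matrices (heparinized whole blood and plasma) with constant plus
proportional bias and heteroscedastic noise, a reference laboratory method
measuring plasma only, below-LLOQ censoring, and five-replicate precision
runs on a small animal subset.

Defaults mirror the study design the package is built around: 28 animals in
four species (6 cownose, 10 Atlantic, 4 southern, 8 yellow), glucose
roughly <20-63 mg/dL, beta-HB right-skewed around 0.2-0.3 mmol/L with a
rare large outlier among yellow stingrays, glucose LLOQ 20 mg/dL on every
instrument, beta-HB LLOQ 0.1 mmol/L on two of three meters.

Randomness: one seed per study; every draw comes from a sub-stream keyed by
(purpose, species/animal/device/analyte/matrix/replicate), so adding a
device or replicate never perturbs other draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_model import SCHEMA, MeasurementTable, REFERENCE_DEVICE


@dataclass(frozen=True)
class SpeciesSpec:
    name: str
    n_animals: int
    weight_range: tuple          # kg
    glucose_log_mean: float      # log mg/dL
    glucose_log_sd: float
    bhb_log_mean: float          # log mmol/L
    bhb_log_sd: float
    outlier_prob: float = 0.0    # per-animal chance of a beta-HB spike
    outlier_scale: float = 1.0


@dataclass(frozen=True)
class DeviceSpec:
    name: str
    analyte: str
    alpha_const: float   # constant bias, analyte units
    beta_prop: float     # proportional bias (1 = none)
    sigma0: float        # additive noise sd, analyte units
    sigma1: float        # proportional noise sd per unit of truth
    lloq: float          # 0 disables censoring
    uloq: float = float("inf")


@dataclass(frozen=True)
class StudyConfig:
    seed: int
    species_specs: tuple = ()
    device_specs: tuple = ()
    pcv_range: tuple = (11.0, 32.0)     # %
    bc_range: tuple = (0.0, 4.0)        # %
    ts_range: tuple = (4.4, 8.1)        # g/dL
    n_replicate_animals: int = 2
    n_replicates: int = 5
    matrix_effect: dict = field(
        default_factory=lambda: {"glucose": 0.0, "bhb": 0.0}
    )


DEFAULT_SPECIES = (
    SpeciesSpec("cownose", 6, (3.85, 6.8), np.log(48.0), 0.18, np.log(0.31), 0.50),
    SpeciesSpec("atlantic", 10, (0.8, 1.8), np.log(26.0), 0.30, np.log(0.22), 0.35),
    SpeciesSpec("southern", 4, (5.4, 9.2), np.log(36.0), 0.15, np.log(0.23), 0.20),
    SpeciesSpec("yellow", 8, (0.6, 1.65), np.log(30.0), 0.32, np.log(0.22), 0.55,
                outlier_prob=0.1, outlier_scale=20.0),
)

DEFAULT_DEVICES = (
    # glucose meters (mg/dL)
    DeviceSpec("BHBCheck", "glucose", 37.0, 1.4, 1.0, 0.020, 20.0, 600.0),
    DeviceSpec("PrecisionXtra", "glucose", -6.0, 1.3, 2.0, 0.050, 20.0, 500.0),
    DeviceSpec("NovaVet", "glucose", 2.0, 0.4, 1.0, 0.0, 20.0, 600.0),
    # beta-HB meters (mmol/L)
    DeviceSpec("BHBCheck", "bhb", 0.15, 1.3, 0.03, 0.05, 0.1, 8.0),
    DeviceSpec("PrecisionXtra", "bhb", 0.0, 1.8, 0.02, 0.03, 0.0, 8.0),
    DeviceSpec("NovaVet", "bhb", 0.05, 1.1, 0.02, 0.02, 0.1, 8.0),
    # reference laboratory: identity response, ~2% proportional noise
    DeviceSpec(REFERENCE_DEVICE, "glucose", 0.0, 1.0, 0.0, 0.02, 20.0),
    DeviceSpec(REFERENCE_DEVICE, "bhb", 0.0, 1.0, 0.0, 0.02, 0.0),
)


def default_config(seed: int) -> StudyConfig:
    return StudyConfig(
        seed=int(seed),
        species_specs=DEFAULT_SPECIES,
        device_specs=DEFAULT_DEVICES,
    )


def _rng(seed: int, *key) -> np.random.Generator:
    """Deterministic sub-stream keyed by (seed, key...)."""
    ints = [zlib.crc32(str(k).encode("utf8")) for k in key]
    return np.random.default_rng(np.random.SeedSequence([int(seed)] + ints))


_SPECIES_CODE = {"cownose": "CN", "atlantic": "AT", "southern": "SO", "yellow": "YE"}


def generate_reference(config: StudyConfig) -> pd.DataFrame:
    """Per-animal ground truth and covariates.

    One row per animal: species, sex ~ Bernoulli(1/2), weight and blood
    covariates uniform over their study ranges, true analyte values from
    species-specific lognormals; yellow-stingray-style outliers multiply
    the beta-HB truth by ``outlier_scale`` with probability
    ``outlier_prob``.
    """
    rows = []
    for sp in config.species_specs:
        code = _SPECIES_CODE.get(sp.name, sp.name[:2].upper())
        for i in range(sp.n_animals):
            r = _rng(config.seed, "animal", sp.name, i)
            w_lo, w_hi = sp.weight_range
            bhb = float(np.exp(r.normal(sp.bhb_log_mean, sp.bhb_log_sd)))
            if sp.outlier_prob > 0 and r.random() < sp.outlier_prob:
                bhb *= sp.outlier_scale
            rows.append({
                "animal_id": f"{code}{i + 1:02d}",
                "species": sp.name,
                "sex": "M" if r.random() < 0.5 else "F",
                "weight_kg": float(r.uniform(w_lo, w_hi)),
                "pcv_pct": float(r.uniform(*config.pcv_range)),
                "bc_pct": float(r.uniform(*config.bc_range)),
                "ts_gdl": float(r.uniform(*config.ts_range)),
                "true_glucose": float(np.exp(r.normal(sp.glucose_log_mean, sp.glucose_log_sd))),
                "true_bhb": bhb,
            })
    return pd.DataFrame(rows).sort_values("animal_id", kind="mergesort").reset_index(drop=True)


def _measure_one(rng, spec: DeviceSpec, truth: float, matrix_shift: float):
    """One reading: linear response + heteroscedastic Gaussian noise.

    Returns (value, censored, truncated). Negative readings are truncated
    at 0; readings below the device LLOQ become censored records.
    """
    sd = spec.sigma0 + spec.sigma1 * truth
    eps = rng.normal(0.0, sd) if sd > 0 else 0.0
    v = spec.alpha_const + spec.beta_prop * truth + matrix_shift + eps
    truncated = v < 0
    v = max(v, 0.0)
    if spec.lloq > 0 and v < spec.lloq:
        return np.nan, True, truncated
    return v, False, truncated


def _rows_for(reference, spec, config, matrices, replicate_ids, seed):
    me = config.matrix_effect.get(spec.analyte, 0.0)
    truth_col = "true_glucose" if spec.analyte == "glucose" else "true_bhb"
    rows, n_trunc = [], 0
    for rec in reference.itertuples():
        truth = getattr(rec, truth_col)
        for matrix in matrices:
            shift = me if matrix == "whole_blood" else 0.0
            for rep in replicate_ids:
                r = _rng(seed, "meas", spec.name, spec.analyte,
                         rec.animal_id, matrix, rep)
                v, cen, trunc = _measure_one(r, spec, truth, shift)
                n_trunc += trunc
                rows.append({
                    "animal_id": rec.animal_id, "species": rec.species,
                    "sex": rec.sex, "weight_kg": rec.weight_kg,
                    "pcv_pct": rec.pcv_pct, "bc_pct": rec.bc_pct,
                    "ts_gdl": rec.ts_gdl, "analyte": spec.analyte,
                    "matrix": matrix, "device": spec.name,
                    "value": v, "replicate_id": rep,
                    "censored": cen,
                    "lloq": spec.lloq if spec.lloq > 0 else np.nan,
                })
    return rows, n_trunc


def generate_measurements(
    reference: pd.DataFrame,
    device_specs,
    config: StudyConfig,
) -> MeasurementTable:
    """Primary-run (replicate_id 0) measurements for every device.

    POC devices read both matrices; the reference laboratory reads plasma
    only. The whole-blood readings are shifted by the study's matrix effect
    for the analyte.
    """
    all_rows, n_trunc = [], 0
    for spec in device_specs:
        matrices = ("plasma",) if spec.name == REFERENCE_DEVICE else ("whole_blood", "plasma")
        rows, t = _rows_for(reference, spec, config, matrices, (0,), config.seed)
        all_rows.extend(rows)
        n_trunc += t
    df = pd.DataFrame(all_rows)[SCHEMA + ["censored", "lloq"]]
    return MeasurementTable(df.reset_index(drop=True),
                            metadata={"seed": config.seed, "n_truncated": int(n_trunc)})


def generate_replicates(
    reference: pd.DataFrame,
    device_specs,
    config: StudyConfig,
    n_rep: int | None = None,
) -> MeasurementTable:
    """Precision runs: n_rep extra readings per key on an animal subset.

    The replicate subset is the first ``n_replicate_animals`` animals of the
    last species (by id order) — mirroring a repeatability check done on a
    couple of conveniently available animals. Replicates share the animal's
    truth and differ only in measurement noise.
    """
    n_rep = config.n_replicates if n_rep is None else n_rep
    last_species = config.species_specs[-1].name
    subset = reference[reference["species"] == last_species].head(
        config.n_replicate_animals
    )
    if len(subset) < config.n_replicate_animals:
        raise ValueError("replicate subset larger than available animals")
    all_rows, n_trunc = [], 0
    for spec in device_specs:
        if spec.name == REFERENCE_DEVICE:
            continue
        rows, t = _rows_for(
            reference=subset, spec=spec, config=config,
            matrices=("whole_blood", "plasma"),
            replicate_ids=tuple(range(1, n_rep + 1)),
            seed=config.seed,
        )
        all_rows.extend(rows)
        n_trunc += t
    df = pd.DataFrame(all_rows)[SCHEMA + ["censored", "lloq"]]
    return MeasurementTable(df.reset_index(drop=True),
                            metadata={"seed": config.seed, "n_truncated": int(n_trunc)})


def generate_study(config: StudyConfig) -> MeasurementTable:
    """Full study: primary runs for all devices plus replicate precision runs."""
    reference = generate_reference(config)
    primary = generate_measurements(reference, config.device_specs, config)
    reps = generate_replicates(reference, config.device_specs, config)
    df = pd.concat([primary.df, reps.df], ignore_index=True)
    meta = {
        "seed": config.seed,
        "n_animals": len(reference),
        "n_truncated": primary.metadata["n_truncated"] + reps.metadata["n_truncated"],
        "synthetic": True,
    }
    return MeasurementTable(df, meta)


def device_spec_frame(device_specs) -> pd.DataFrame:
    """Companion device-spec CSV content (device, analyte, lloq, uloq)."""
    rows = [
        {"device": s.name, "analyte": s.analyte, "lloq": s.lloq, "uloq": s.uloq}
        for s in device_specs if s.name != REFERENCE_DEVICE
    ]
    return pd.DataFrame(rows)


def config_from_dict(d: dict) -> StudyConfig:
    """Build a StudyConfig from a plain (YAML-loaded) mapping.

    Unspecified sections fall back to the defaults; species and device
    entries are given as mappings with the dataclass field names.
    """
    cfg = default_config(int(d.get("seed", 0)))
    if "species_specs" in d:
        cfg = replace(cfg, species_specs=tuple(
            SpeciesSpec(**{**s, "weight_range": tuple(s["weight_range"])})
            for s in d["species_specs"]
        ))
    if "device_specs" in d:
        cfg = replace(cfg, device_specs=tuple(DeviceSpec(**s) for s in d["device_specs"]))
    for key in ("pcv_range", "bc_range", "ts_range"):
        if key in d:
            cfg = replace(cfg, **{key: tuple(d[key])})
    for key in ("n_replicate_animals", "n_replicates"):
        if key in d:
            cfg = replace(cfg, **{key: int(d[key])})
    if "matrix_effect" in d:
        cfg = replace(cfg, matrix_effect=dict(d["matrix_effect"]))
    return cfg
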
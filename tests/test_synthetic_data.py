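"""The synthetic study generator: design structure, determinism, noise model."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pocagree as pg
from pocagree.synthetic_data import (
    DEFAULT_DEVICES,
    DEFAULT_SPECIES,
    DeviceSpec,
    SpeciesSpec,
    StudyConfig,
    config_from_dict,
)


class TestGenerateReference:
    def test_default_cohort_composition(self):
        ref = pg.generate_reference(pg.default_config(0))
        assert len(ref) == 28
        counts = ref["species"].value_counts()
        assert counts["cownose"] == 6 and counts["atlantic"] == 10
        assert counts["southern"] == 4 and counts["yellow"] == 8

    def test_same_seed_identical(self):
        a = pg.generate_reference(pg.default_config(123))
        b = pg.generate_reference(pg.default_config(123))
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        a = pg.generate_reference(pg.default_config(1))
        b = pg.generate_reference(pg.default_config(2))
        assert not np.allclose(a["true_glucose"], b["true_glucose"])

    def test_covariates_within_ranges(self):
        cfg = pg.default_config(9)
        ref = pg.generate_reference(cfg)
        assert ref["pcv_pct"].between(*cfg.pcv_range).all()
        assert ref["bc_pct"].between(*cfg.bc_range).all()
        assert ref["ts_gdl"].between(*cfg.ts_range).all()
        for sp in cfg.species_specs:
            w = ref.loc[ref["species"] == sp.name, "weight_kg"]
            assert w.between(*sp.weight_range).all()

    def test_no_outliers_bounds_bhb_by_lognormal_quantile(self):
        spec = SpeciesSpec("test", 10_000, (1.0, 2.0), np.log(30), 0.3,
                           np.log(0.22), 0.55, outlier_prob=0.0)
        cfg = StudyConfig(seed=5, species_specs=(spec,), device_specs=DEFAULT_DEVICES)
        ref = pg.generate_reference(cfg)
        # P(any of 1e4 draws above the 1-1e-6 quantile) < 1%
        bound = float(stats.lognorm.ppf(1 - 1e-6, 0.55, scale=0.22))
        assert ref["true_bhb"].max() < bound

    def test_outlier_mechanism_inflates_tail(self):
        spec = dataclasses.replace(DEFAULT_SPECIES[3], n_animals=2000)
        cfg = StudyConfig(seed=5, species_specs=(spec,), device_specs=DEFAULT_DEVICES)
        ref = pg.generate_reference(cfg)
        frac_big = (ref["true_bhb"] > 2.0).mean()
        assert 0.05 < frac_big < 0.15  # ~outlier_prob


class TestGenerateMeasurements:
    def test_noise_free_identity_device(self):
        dev = (DeviceSpec("ideal", "glucose", 0.0, 1.0, 0.0, 0.0, 0.0),
               DeviceSpec("reference", "glucose", 0.0, 1.0, 0.0, 0.0, 0.0))
        cfg = StudyConfig(seed=3, species_specs=DEFAULT_SPECIES, device_specs=dev)
        ref = pg.generate_reference(cfg)
        t = pg.generate_measurements(ref, dev, cfg)
        wb = t.df[(t.df["device"] == "ideal") & (t.df["matrix"] == "whole_blood")]
        truth = ref.set_index("animal_id")["true_glucose"]
        assert np.allclose(wb.set_index("animal_id")["value"], truth[wb["animal_id"]].values)

    def test_censoring_below_lloq(self):
        ref = pd.DataFrame([{
            "animal_id": "X01", "species": "test", "sex": "F", "weight_kg": 1.0,
            "pcv_pct": 20.0, "bc_pct": 0.0, "ts_gdl": 6.0,
            "true_glucose": 12.0, "true_bhb": 0.2,
        }])
        dev = (DeviceSpec("m", "glucose", 0.0, 1.0, 0.0, 0.0, 20.0),)
        cfg = StudyConfig(seed=0, species_specs=(), device_specs=dev)
        t = pg.generate_measurements(ref, dev, cfg)
        assert t.df["censored"].all()
        assert (t.df["lloq"] == 20.0).all()
        assert t.df["value"].isna().all()

    def test_reference_device_plasma_only(self):
        cfg = pg.default_config(4)
        t = pg.generate_measurements(pg.generate_reference(cfg), cfg.device_specs, cfg)
        ref_rows = t.df[t.df["device"] == "reference"]
        assert set(ref_rows["matrix"]) == {"plasma"}

    def test_censoring_fraction_matches_normal_cdf(self):
        # fixed truth, additive noise: P(censored) = Phi((lloq - mu)/sd)
        spec = SpeciesSpec("test", 10_000, (1.0, 2.0), np.log(25.0), 1e-9,
                           np.log(0.2), 0.1)
        dev = (DeviceSpec("m", "glucose", 0.0, 1.0, 4.0, 0.0, 20.0),)
        cfg = StudyConfig(seed=8, species_specs=(spec,), device_specs=dev)
        ref = pg.generate_reference(cfg)
        t = pg.generate_measurements(ref, dev, cfg)
        frac = t.df["censored"].mean()
        p = stats.norm.cdf((20.0 - 25.0) / 4.0)
        n = len(t.df)
        assert abs(frac - p) < 4 * np.sqrt(p * (1 - p) / n)

    def test_matrix_effect_shifts_whole_blood_only(self):
        dev = (DeviceSpec("m", "glucose", 0.0, 1.0, 0.0, 0.0, 0.0),)
        cfg = StudyConfig(seed=3, species_specs=DEFAULT_SPECIES[:1], device_specs=dev,
                          matrix_effect={"glucose": -5.0, "bhb": 0.0})
        ref = pg.generate_reference(cfg)
        t = pg.generate_measurements(ref, dev, cfg)
        piv = t.df.pivot_table(index="animal_id", columns="matrix", values="value")
        assert np.allclose(piv["whole_blood"] - piv["plasma"], -5.0)


class TestGenerateReplicates:
    def test_exactly_n_rep_rows_per_key(self):
        cfg = pg.default_config(2)
        reps = pg.generate_replicates(pg.generate_reference(cfg), cfg.device_specs, cfg)
        counts = reps.df.groupby(["animal_id", "device", "analyte", "matrix"]).size()
        assert (counts == cfg.n_replicates).all()
        assert set(reps.df["replicate_id"]) == {1, 2, 3, 4, 5}

    def test_zero_noise_gives_zero_cv(self):
        dev = (DeviceSpec("m", "glucose", 5.0, 1.2, 0.0, 0.0, 0.0),)
        cfg = StudyConfig(seed=6, species_specs=DEFAULT_SPECIES[-1:], device_specs=dev,
                          n_replicate_animals=2)
        ref = pg.generate_reference(cfg)
        reps = pg.generate_replicates(ref, dev, cfg)
        table = pg.impute_lloq(pg.MeasurementTable(reps.df))
        prec = pg.precision_table(table)
        # identical replicate floats: CV zero up to mean-subtraction rounding
        assert (prec["cv_pct"].abs() < 1e-9).all()

    def test_cv_converges_to_sigma_over_mean(self):
        sigma0, truth = 2.0, 40.0
        spec = SpeciesSpec("test", 1, (1.0, 2.0), np.log(truth), 1e-12,
                           np.log(0.2), 0.1)
        dev = (DeviceSpec("m", "glucose", 0.0, 1.0, sigma0, 0.0, 0.0),)
        cfg = StudyConfig(seed=10, species_specs=(spec,), device_specs=dev,
                          n_replicate_animals=1)
        ref = pg.generate_reference(cfg)
        reps = pg.generate_replicates(ref, dev, cfg, n_rep=10_000)
        vals = reps.df[reps.df["matrix"] == "plasma"]["value"].to_numpy()
        cv = pg.cv_percent(vals)
        expected = 100.0 * sigma0 / truth
        assert cv == pytest.approx(expected, rel=0.05)


class TestFullStudy:
    def test_study_is_deterministic(self):
        a = pg.generate_study(pg.default_config(77))
        b = pg.generate_study(pg.default_config(77))
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_study_passes_schema_roundtrip(self, raw_study, tmp_path):
        p = tmp_path / "s.csv"
        pg.write_measurements(raw_study, p)
        back = pg.read_measurements(p)  # validates schema + invariants
        assert len(back) == len(raw_study)

    def test_pb_recovers_proportional_bias(self):
        # beta_prop = 2 on an uncensored device: PB slope CI covers 2
        dev = (DeviceSpec("m", "glucose", 0.0, 2.0, 1.0, 0.0, 0.0),
               DeviceSpec("reference", "glucose", 0.0, 1.0, 0.0, 0.02, 0.0))
        cfg = StudyConfig(seed=13, species_specs=DEFAULT_SPECIES, device_specs=dev)
        ref = pg.generate_reference(cfg)
        t = pg.impute_lloq(pg.generate_measurements(ref, dev, cfg))
        pairs = pg.paired_vectors(t, "glucose", "m", "plasma")
        fit = pg.pb_fit(pairs.ref, pairs.poc)
        assert fit.ci_slope[0] <= 2.0 <= fit.ci_slope[1]

    def test_ba_estimates_constant_bias_plus_matrix_effect(self):
        # beta_prop = 1: BA mean bias ~= alpha_const (+ matrix effect on WB)
        alpha_const, me = 5.0, -2.0
        dev = (DeviceSpec("m", "glucose", alpha_const, 1.0, 1.5, 0.0, 0.0),
               DeviceSpec("reference", "glucose", 0.0, 1.0, 0.0, 0.0, 0.0))
        cfg = StudyConfig(seed=14, species_specs=DEFAULT_SPECIES, device_specs=dev,
                          matrix_effect={"glucose": me, "bhb": 0.0})
        ref = pg.generate_reference(cfg)
        t = pg.impute_lloq(pg.generate_measurements(ref, dev, cfg))
        for mat, target in (("plasma", alpha_const), ("whole_blood", alpha_const + me)):
            pairs = pg.paired_vectors(t, "glucose", "m", mat)
            res = pg.bland_altman(pairs.poc, pairs.ref)
            se = res.sd_diff / np.sqrt(res.n)
            assert abs(res.mean_bias - target) < 3 * se

    def test_config_from_dict_overrides(self):
        cfg = config_from_dict({
            "seed": 4,
            "n_replicates": 3,
            "matrix_effect": {"glucose": -1.0, "bhb": 0.0},
        })
        assert cfg.seed == 4 and cfg.n_replicates == 3
        assert cfg.matrix_effect["glucose"] == -1.0
        assert cfg.species_specs == DEFAULT_SPECIES
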
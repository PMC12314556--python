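"""Determinism, ground-truth bookkeeping and calibration of the generators."""

import numpy as np
import pandas as pd
import pytest

from hippoprofiler.disruption import disruption_table
from hippoprofiler.exceptions import ConfigurationError, ValidationError
from hippoprofiler.features import normalize_to_control
from hippoprofiler.growth import fit_logistic, logistic
from hippoprofiler.io import feature_columns
from hippoprofiler.synthetic import (SyntheticConfig, Treatment, dose_scale,
                                     generate_cell_table, generate_feature_matrix,
                                     generate_growth_tracks, read_truth, write_truth)


class TestConfigValidation:
    def test_zero_replicates_rejected(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(n_replicate_wells=0)

    def test_dependent_fraction_out_of_range(self):
        with pytest.raises(ValidationError):
            SyntheticConfig(dependent_fraction=1.5)

    def test_nonpositive_intensity_scale(self):
        with pytest.raises(ValidationError):
            SyntheticConfig(intensity_scale=0.0)

    def test_non_increasing_time_grid(self):
        with pytest.raises(ValidationError):
            SyntheticConfig(spheroid_times=(24.0, 24.0, 48.0, 168.0))


class TestDeterminism:
    def test_all_generators_reproduce_exactly(self, tiny_config):
        m1, t1 = generate_feature_matrix(tiny_config)
        m2, t2 = generate_feature_matrix(tiny_config)
        pd.testing.assert_frame_equal(m1, m2)
        assert t1.affected_features == t2.affected_features
        c1, _ = generate_cell_table(tiny_config)
        c2, _ = generate_cell_table(tiny_config)
        pd.testing.assert_frame_equal(c1, c2)
        g1, s1 = generate_growth_tracks(tiny_config)
        g2, s2 = generate_growth_tracks(tiny_config)
        pd.testing.assert_frame_equal(g1, g2)
        assert s1.outlier_timepoints == s2.outlier_timepoints

    def test_different_seeds_differ(self, tiny_config):
        other = SyntheticConfig(**{**tiny_config.__dict__, "seed": 99})
        m1, _ = generate_feature_matrix(tiny_config)
        m2, _ = generate_feature_matrix(other)
        assert not m1.equals(m2)


class TestFeatureMatrixTruth:
    def test_null_generator_has_empty_truth(self, tiny_config):
        cfg = SyntheticConfig(**{**tiny_config.__dict__, "effect_size": 0.0})
        _, truth = generate_feature_matrix(cfg)
        assert all(len(v) == 0 for v in truth.affected_features.values())
        assert truth.dependency_labels == {}

    def test_label_soundness(self, single_drug_config):
        # every shifted feature is labelled, and only affected features carry
        # dependency labels
        matrix, truth = generate_feature_matrix(single_drug_config)
        affected = truth.affected_features["drug"]
        assert set(truth.dependency_labels) == affected
        assert set(truth.dependency_labels.values()) <= {"dependent", "independent"}
        # shifted features separate WT treated wells from WT vehicle wells
        wt = matrix[matrix["Metadata_Genotype"] == "WT"]
        veh = wt[wt["Metadata_Treatment"] == "DMSO"]
        trt = wt[wt["Metadata_Treatment"] == "drug"]
        for f in feature_columns(matrix):
            delta = abs(trt[f].median() - veh[f].median())
            if f in affected:
                assert delta > 2.0  # planted 6-MAD shift dominates noise
            else:
                assert delta < 2.0

    def test_ko_receives_shift_only_on_independent_features(self, single_drug_config):
        matrix, truth = generate_feature_matrix(single_drug_config)
        ko = matrix[matrix["Metadata_Genotype"] == "YAP_KO"]
        veh = ko[ko["Metadata_Treatment"] == "DMSO"]
        trt = ko[ko["Metadata_Treatment"] == "drug"]
        for f, label in truth.dependency_labels.items():
            delta = abs(trt[f].median() - veh[f].median())
            assert (delta > 2.0) == (label == "independent")

    def test_outlier_wells_recorded(self, tiny_config):
        cfg = SyntheticConfig(**{**tiny_config.__dict__, "outlier_well_rate": 0.5})
        matrix, truth = generate_feature_matrix(cfg)
        assert truth.outlier_wells
        ids = matrix["Metadata_Plate"] + ":" + matrix["Metadata_Well"]
        marked = matrix[ids.isin(truth.outlier_wells)]
        clean = matrix[~ids.isin(truth.outlier_wells)]
        feats = feature_columns(matrix)
        assert marked[feats].mean().mean() > clean[feats].mean().mean() + 10


class TestCellTable:
    def test_intensities_positive_and_contact_in_range(self, tiny_config):
        cells, _ = generate_cell_table(tiny_config)
        assert (cells["nuclear_intensity"] > 0).all()
        assert (cells["cytoplasmic_intensity"] > 0).all()
        assert cells["contact_percent"].between(0, 100).all()

    def test_true_well_ratios_recoverable(self, tiny_config):
        cells, truth = generate_cell_table(tiny_config)
        medians = cells.groupby(["Metadata_Plate", "Metadata_Well"])
        for (plate, well), grp in medians:
            ratio = (grp["nuclear_intensity"] / grp["cytoplasmic_intensity"]).median()
            true = truth.true_well_ratio[f"{plate}:{well}"]
            assert ratio == pytest.approx(true, rel=0.15)

    def test_top_dose_ratio_reduction_matches_ratio_effect(self, tiny_config):
        cells, truth = generate_cell_table(tiny_config)
        meta = cells.drop_duplicates(["Metadata_Plate", "Metadata_Well"])
        ids = meta["Metadata_Plate"] + ":" + meta["Metadata_Well"]
        level = ids.map(truth.true_well_ratio)
        veh = level[(meta["Metadata_Treatment"] == "DMSO").to_numpy()]
        top = level[((meta["Metadata_Treatment"] == "VT-107")
                     & (meta["Metadata_Concentration"] == 10.0)).to_numpy()]
        assert top.mean() / veh.mean() == pytest.approx(0.5, abs=0.05)


class TestGrowthTracks:
    def test_noiseless_tracks_are_exact_logistic(self, tiny_config):
        cfg = SyntheticConfig(**{**tiny_config.__dict__, "growth_noise": 0.0,
                                 "outlier_timepoint_rate": 0.0})
        tracks, truth = generate_growth_tracks(cfg)
        for (plate, well), grp in tracks.groupby(["Metadata_Plate", "Metadata_Well"]):
            L, k, t0 = truth.true_growth[f"{plate}:{well}"]
            np.testing.assert_allclose(
                grp.sort_values("time_h")["area"].to_numpy(),
                logistic(np.sort(grp["time_h"].to_numpy()), L, k, t0))

    def test_spikes_are_bookkept(self, tiny_config):
        cfg = SyntheticConfig(**{**tiny_config.__dict__,
                                 "outlier_timepoint_rate": 0.2})
        tracks, truth = generate_growth_tracks(cfg)
        assert truth.outlier_timepoints
        ids = tracks["Metadata_Plate"] + ":" + tracks["Metadata_Well"]
        for well_id, t in list(truth.outlier_timepoints)[:5]:
            row = tracks[(ids == well_id) & (tracks["time_h"] == t)]
            assert len(row) == 1

    def test_anchor_timepoints_always_present(self, tiny_config):
        tracks, _ = generate_growth_tracks(tiny_config, mode="spheroid")
        times = set(tracks["time_h"])
        assert 24.0 in times and 168.0 in times

    def test_generate_and_refit_recovers_rate(self):
        cfg = SyntheticConfig(
            seed=3, growth_noise=0.0, outlier_timepoint_rate=0.0,
            treatments=(), growth_params_2d={"WT": (100.0, 0.1, 36.0)},
            genotypes=("WT",), n_replicate_wells=2)
        tracks, truth = generate_growth_tracks(cfg, mode="2d")
        grp = tracks[tracks["Metadata_Well"] == "W001"].sort_values("time_h")
        fit = fit_logistic(grp["time_h"].to_numpy(), grp["confluency"].to_numpy())
        assert abs(fit.k - 0.1) / 0.1 < 1e-3


class TestDoseScale:
    def test_log_linear_endpoints(self):
        concs = (1.1, 3.3, 10.0)
        assert dose_scale(1.1, concs) == pytest.approx(0.5)
        assert dose_scale(10.0, concs) == pytest.approx(1.0)
        assert 0.5 < dose_scale(3.3, concs) < 1.0

    def test_single_dose_scales_fully(self):
        assert dose_scale(5.0, (5.0,)) == 1.0


class TestNullCalibration:
    def test_null_disruption_rate_stable_across_seeds(self):
        # 1,000 independent null features: the strict Z' > 0 call rate is an
        # empirical property of median/MAD sampling noise; it must agree
        # between independent seeds within binomial error.
        rates = []
        for seed in (0, 1):
            cfg = SyntheticConfig(
                seed=seed, n_features=1000, n_blocks=1000, block_rho=0.0,
                effect_size=0.0, outlier_well_rate=0.0,
                treatments=(Treatment("drug", "x", (1.0,)),),
                genotypes=("WT",), n_replicate_wells=4)
            matrix, _ = generate_feature_matrix(cfg)
            normed, _ = normalize_to_control(matrix)
            table = disruption_table(normed)
            rates.append(table["disrupted"].mean())
        p = np.mean(rates)
        se = np.sqrt(2 * p * (1 - p) / 1000)
        assert abs(rates[0] - rates[1]) < 5 * se


class TestTruthRoundTrip:
    def test_write_read_identity(self, tmp_path, single_drug_config):
        _, truth = generate_feature_matrix(single_drug_config)
        tracks, truth_g = generate_growth_tracks(single_drug_config)
        truth.outlier_timepoints = truth_g.outlier_timepoints
        truth.true_growth = truth_g.true_growth
        path = tmp_path / "truth.txt"
        write_truth(truth, path)
        back = read_truth(path)
        assert back.seed == truth.seed
        assert back.affected_features == truth.affected_features
        assert back.dependency_labels == truth.dependency_labels
        assert back.outlier_wells == truth.outlier_wells
        assert back.outlier_timepoints == truth.outlier_timepoints
        assert back.true_growth == truth.true_growth
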
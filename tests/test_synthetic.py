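"""Generator contracts: determinism, dropout closed form, round trips."""

import numpy as np
import pandas as pd
import pytest

from sedrate.calibration import FLUORESCENCE, apply_calibration
from sedrate.errors import ConfigError
from sedrate.rates import rate_table
from sedrate.synthetic import (CommunityTruth, SimulationConfig, TaxonSpec,
                               default_community, make_bead_sample,
                               make_sorted_plate, make_transcript_library,
                               reference_curve)


class TestBeadSample:
    def test_zero_cv_puts_every_event_at_its_median(self):
        cfg = SimulationConfig(seed=1, bead_peaks=((10.0, 20.0, 0.0),
                                                   (100.0, 300.0, 0.0)))
        df = make_bead_sample(cfg, n_per_peak=5)
        for k, raw in [(0, 20.0), (1, 300.0)]:
            assert (df.loc[df["peak_label"] == k, "FL1_raw"] == raw).all()

    def test_generated_peak_medians_match_config(self):
        cfg = SimulationConfig(seed=1)
        df = make_bead_sample(cfg, n_per_peak=500)
        for k, (_, raw, _) in enumerate(cfg.bead_peaks):
            med = df.loc[df["peak_label"] == k, "FL1_raw"].median()
            assert med == pytest.approx(raw, rel=0.02)

    def test_determinism(self):
        cfg = SimulationConfig(seed=42)
        a = make_bead_sample(cfg, 200)
        b = make_bead_sample(cfg, 200)
        pd.testing.assert_frame_equal(a, b)

    def test_drift_scales_raw_channels(self):
        cfg = SimulationConfig(seed=5, drift={"d1": 1.0, "d2": 1.3})
        a = make_bead_sample(cfg, 100, day="d1")
        b = make_bead_sample(cfg, 100, day="d2")
        np.testing.assert_allclose(b["FL1_raw"], a["FL1_raw"] * 1.3, rtol=1e-12)

    def test_non_positive_raw_median_rejected(self):
        with pytest.raises(ConfigError, match="raw median"):
            SimulationConfig(bead_peaks=((10.0, -1.0, 0.1), (100.0, 5.0, 0.1)))

    def test_requires_two_peaks_and_events(self):
        cfg = SimulationConfig(seed=1)
        with pytest.raises(ConfigError):
            make_bead_sample(cfg, 0)


class TestSortedPlate:
    def test_noise_free_plate_round_trips_rates(self, community, rate_cal):
        cfg = SimulationConfig(seed=3, completeness=1.0, fluorescence_cv=0.0)
        events, sags, truth = make_sorted_plate(community, cfg, 400, rate_cal)
        curve = reference_curve(cfg, FLUORESCENCE)
        cal = apply_calibration(events, curve)
        linked = cal.merge(sags, on=["plate", "well"])
        est = rate_table(linked, rate_cal)
        merged = est.merge(truth, on=["plate", "well"])
        # only respiring, sulfate-reduction-capable cells get estimates
        # (~60% of the community), minus a few clamped extreme draws
        ok = ~merged["out_of_cal_range"] & ~merged["fluorescence_clamped"]
        assert ok.sum() > 200
        np.testing.assert_allclose(
            merged.loc[ok, "rate_fmol_per_cell_h"],
            merged.loc[ok, "true_rate_fmol_per_cell_h"], rtol=1e-9)

    def test_marker_dropout_follows_completeness(self, rate_cal):
        """With four required markers each kept w.p. c, a cell retains the
        full panel w.p. c^4 (independent Bernoulli dropout)."""
        panel = frozenset({"dsrA", "dsrB", "aprA", "aprB"})
        truth = CommunityTruth(taxa=(
            TaxonSpec(label="X", fraction=1.0, rate_meanlog=0.0,
                      rate_sdlog=0.3, markers=panel),))
        cfg = SimulationConfig(seed=7, completeness=0.5)
        _, sags, _ = make_sorted_plate(truth, cfg, 10000, rate_cal)
        have_all = (sags[list(panel)].sum(axis=1) == 4).mean()
        p = 0.5 ** 4
        se = np.sqrt(p * (1 - p) / 10000)
        assert abs(have_all - p) < 4 * se

    def test_markers_never_outside_taxon_panel(self, rate_cal):
        truth = CommunityTruth(taxa=(
            TaxonSpec(label="X", fraction=1.0, rate_meanlog=0.0,
                      rate_sdlog=0.1, markers=frozenset({"dsrA", "dsrB"})),))
        cfg = SimulationConfig(seed=9, completeness=1.0)
        _, sags, _ = make_sorted_plate(truth, cfg, 200, rate_cal)
        assert (sags[["sat", "aprA", "aprB"]] == 0).all().all()
        assert (sags[["dsrA", "dsrB"]] == 1).all().all()

    def test_non_respiring_taxon_below_fluorescence_floor(self, community,
                                                          sim_config,
                                                          rate_cal):
        events, _, truth = make_sorted_plate(community, sim_config, 2000,
                                             rate_cal)
        merged = events.merge(truth, on=["plate", "well"])
        quiet = merged[~merged["respiring"]]
        assert len(quiet) > 500
        assert (quiet["FL1_raw"] < sim_config.fluorescence_floor_raw).all()

    def test_taxon_frequencies_converge(self, community, rate_cal):
        cfg = SimulationConfig(seed=13)
        _, _, truth = make_sorted_plate(community, cfg, 50000, rate_cal)
        obs = truth["true_taxon"].value_counts(normalize=True)
        l1 = sum(abs(obs.get(t.label, 0.0) - t.fraction)
                 for t in community.taxa)
        assert l1 < 0.02

    def test_determinism(self, community, sim_config, rate_cal):
        a = make_sorted_plate(community, sim_config, 300, rate_cal)
        b = make_sorted_plate(community, sim_config, 300, rate_cal)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_truth_stays_out_of_inference_tables(self, community, sim_config,
                                                 rate_cal):
        events, sags, truth = make_sorted_plate(community, sim_config, 50,
                                                rate_cal)
        leaky = {"true_rate_fmol_per_cell_h", "true_taxon", "respiring",
                 "true_diameter_um"}
        assert not leaky & set(events.columns)
        assert not leaky & set(sags.columns)
        assert leaky <= set(truth.columns)

    def test_empty_community_rejected(self):
        with pytest.raises(ConfigError):
            CommunityTruth(taxa=())

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ConfigError, match="sum to 1"):
            CommunityTruth(taxa=(TaxonSpec(label="A", fraction=0.5),
                                 TaxonSpec(label="B", fraction=0.4)))


class TestTranscriptLibrary:
    def test_single_gene_takes_whole_library(self):
        df = make_transcript_library([("g1", 900, 1000)], 1000, seed=1)
        assert df["reads"].iloc[0] == 1000

    def test_two_equal_genes_split_within_binomial_bounds(self):
        df = make_transcript_library([("g1", 500, 5e5), ("g2", 500, 5e5)],
                                     10**6, seed=3)
        sd = np.sqrt(10**6 * 0.5 * 0.5)
        assert abs(df["reads"].iloc[0] - 5e5) < 3 * sd
        assert df["reads"].sum() == 10**6

    def test_determinism(self):
        genes = [("g1", 100, 10), ("g2", 350, 90)]
        a = make_transcript_library(genes, 1000, seed=8)
        b = make_transcript_library(genes, 1000, seed=8)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_library_rejected(self):
        with pytest.raises(ConfigError):
            make_transcript_library([("g1", 100, 1)], 0, seed=1)

    def test_expected_reads_cannot_exceed_library(self):
        with pytest.raises(ConfigError, match="exceed"):
            make_transcript_library([("g1", 100, 2000)], 1000, seed=1)
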
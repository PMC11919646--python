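"""Fluorescence -> rate translation, gating, summaries, total fluorescence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sedrate.calibration import FLUORESCENCE, apply_calibration
from sedrate.errors import ConfigError, DataIntegrityError
from sedrate.rates import (RateCalibration, fluorescence_to_rate,
                           per_taxon_rate_summary, rate_table,
                           total_sample_fluorescence)
from sedrate.synthetic import (SimulationConfig, make_sorted_plate,
                               reference_curve)

CHLOROFLEXOTA = ("d__Bacteria;p__Chloroflexota;c__Dehalococcoidia;"
                 "o__;f__;g__;s__")


class TestFluorescenceToRate:
    def test_identity_coefficients(self, identity_cal):
        assert fluorescence_to_rate(2.0, identity_cal) == pytest.approx(2.0)

    def test_power_law_hand_value(self):
        cal = RateCalibration(a=0.5, b=2.0, f_min=0.1, f_max=100)
        assert fluorescence_to_rate(3.0, cal) == pytest.approx(4.5)

    @settings(max_examples=50, deadline=None)
    @given(a=st.floats(1e-4, 10), b=st.floats(0.1, 3),
           f=st.floats(0.01, 1e4), factor=st.floats(1.01, 10))
    def test_strictly_monotone_in_fluorescence(self, a, b, f, factor):
        cal = RateCalibration(a=a, b=b, f_min=1e-6, f_max=1e9)
        assert fluorescence_to_rate(f, cal) < fluorescence_to_rate(f * factor,
                                                                   cal)

    def test_non_positive_fluorescence_rejected(self, identity_cal):
        with pytest.raises(ConfigError):
            fluorescence_to_rate(0.0, identity_cal)

    def test_invalid_coefficients_rejected(self):
        with pytest.raises(ConfigError):
            RateCalibration(a=-1.0)
        with pytest.raises(ConfigError):
            RateCalibration(a=1.0, f_min=10, f_max=1)

    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "cal.yaml"
        p.write_text("a: 0.001\nb: 1.0\nf_min: 1\nf_max: 50000\n"
                     "provenance: unit test\n")
        cal = RateCalibration.from_yaml(p)
        assert cal.a == 0.001 and cal.provenance == "unit test"


def _linked(rows):
    base = {"stain": "RSG", "F_cal": 100.0, "sat": 0, "aprA": 1, "aprB": 1,
            "dsrA": 1, "dsrB": 1, "taxonomy": CHLOROFLEXOTA,
            "condition": "0% O2"}
    out = []
    for i, r in enumerate(rows):
        rec = dict(base, event_id=f"e{i}", plate="P1", well=f"A{i:02d}", **r)
        out.append(rec)
    return pd.DataFrame(out)


class TestRateTable:
    def test_capable_counted_incapable_excluded(self, identity_cal):
        cells = _linked([{}, {}, {"dsrA": 0}, {"aprB": 0}, {"dsrB": 0}])
        est = rate_table(cells, identity_cal)
        assert len(est) == 2
        assert est.attrs["n_excluded_incapable"] == 3

    def test_syto9_cells_never_rated(self, identity_cal):
        cells = _linked([{}, {"stain": "SYTO9"}, {"stain": "SYTO9"}])
        est = rate_table(cells, identity_cal)
        assert len(est) == 1
        assert est.attrs["n_excluded_stain"] == 2
        assert not (est.get("stain") == "SYTO9").any() if "stain" in est else True

    def test_well_collision_drops_both(self, identity_cal):
        cells = _linked([{}, {}, {}])
        cells.loc[1, "well"] = cells.loc[0, "well"]
        est = rate_table(cells, identity_cal)
        assert len(est) == 1
        assert est.attrs["n_well_collisions"] == 2

    def test_missing_calibration_is_config_error(self):
        with pytest.raises(ConfigError, match="calibration"):
            rate_table(_linked([{}]), None)

    def test_out_of_range_flagged_not_dropped(self):
        cal = RateCalibration(a=1.0, b=1.0, f_min=10.0, f_max=1000.0)
        cells = _linked([{"F_cal": 5.0}, {"F_cal": 100.0}, {"F_cal": 2000.0}])
        est = rate_table(cells, cal)
        assert len(est) == 3
        assert list(est["out_of_cal_range"]) == [True, False, True]

    def test_parameter_recovery_on_synthetic_plate(self, community, rate_cal):
        """Inferred mean rate per sulfate-reducing taxon lands within 5% of
        the configured lognormal mean, and min/max bracket the configured
        1st/99th percentiles (n = 10,000, completeness 1, cv 0.1)."""
        cfg = SimulationConfig(seed=11, completeness=1.0, fluorescence_cv=0.1)
        events, sags, _ = make_sorted_plate(community, cfg, 10000, rate_cal)
        cal_events = apply_calibration(events,
                                       reference_curve(cfg, FLUORESCENCE))
        est = rate_table(cal_events.merge(sags, on=["plate", "well"]),
                         rate_cal)
        for t in community.taxa:
            if not t.respiring:
                continue
            sub = est[est["phylum"] == t.label]["rate_fmol_per_cell_h"]
            assert len(sub) > 500
            assert sub.mean() == pytest.approx(t.true_mean_rate, rel=0.05)
            q01 = np.exp(t.rate_meanlog - 2.3263 * t.rate_sdlog)
            q99 = np.exp(t.rate_meanlog + 2.3263 * t.rate_sdlog)
            assert sub.min() <= q01 and sub.max() >= q99

    def test_non_respiring_taxon_gets_no_estimates(self, community, rate_cal,
                                                   sim_config):
        events, sags, _ = make_sorted_plate(community, sim_config, 2000,
                                            rate_cal)
        cal_events = apply_calibration(
            events, reference_curve(sim_config, FLUORESCENCE))
        est = rate_table(cal_events.merge(sags, on=["plate", "well"]),
                         rate_cal)
        assert not (est["phylum"] == "Patescibacteria").any()


class TestPerTaxonSummary:
    def test_small_group_stats(self, identity_cal):
        est = rate_table(_linked([{"F_cal": 0.1}, {"F_cal": 0.3}]),
                         identity_cal)
        out = per_taxon_rate_summary(est, rank="phylum")
        row = out.iloc[0]
        assert (row["n"], row["mean_rate"]) == (2, pytest.approx(0.2))
        assert (row["min_rate"], row["max_rate"]) == (0.1, 0.3)

    def test_grouping_conserves_n(self, identity_cal, rng):
        other = CHLOROFLEXOTA.replace("Chloroflexota", "Desulfobacterota")
        rows = [{"taxonomy": [CHLOROFLEXOTA, other][rng.integers(2)],
                 "F_cal": float(rng.uniform(1, 100)),
                 "condition": ["0% O2", "25% O2"][rng.integers(2)]}
                for _ in range(50)]
        est = rate_table(_linked(rows), identity_cal)
        out = per_taxon_rate_summary(est, rank="phylum")
        assert out["n"].sum() == len(est)

    def test_matches_brute_force(self, identity_cal, rng):
        rows = [{"F_cal": float(rng.uniform(1, 100))} for _ in range(30)]
        est = rate_table(_linked(rows), identity_cal)
        out = per_taxon_rate_summary(est, rank="phylum", by_condition=False)
        vals = est["rate_fmol_per_cell_h"].to_numpy()
        assert out["mean_rate"].iloc[0] == pytest.approx(vals.mean())
        assert out["min_rate"].iloc[0] == vals.min()
        assert out["max_rate"].iloc[0] == vals.max()

    def test_geometric_mean_option(self, identity_cal):
        est = rate_table(_linked([{"F_cal": 1.0}, {"F_cal": 100.0}]),
                         identity_cal)
        out = per_taxon_rate_summary(est, rank="phylum", mean="geometric")
        assert out["mean_rate"].iloc[0] == pytest.approx(10.0)


class TestTotalFluorescence:
    def test_hand_sum(self):
        ev = pd.DataFrame({"F_cal": [10.0, 20.0, 30.0]})
        assert total_sample_fluorescence(ev, 1.0) == pytest.approx(60.0)
        assert total_sample_fluorescence(ev, 2.0) == pytest.approx(30.0)

    def test_matches_brute_force(self, rng):
        vals = rng.uniform(0, 1000, 500)
        ev = pd.DataFrame({"F_cal": vals})
        assert total_sample_fluorescence(ev, 0.37) == pytest.approx(
            sum(float(v) for v in vals) / 0.37)

    def test_non_positive_volume_rejected(self):
        with pytest.raises(ConfigError):
            total_sample_fluorescence(pd.DataFrame({"F_cal": [1.0]}), 0.0)
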
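"""Encounter segmentation, contact calling, windows, network metrics."""

import numpy as np
import pandas as pd
import pytest
import networkx as nx
from hypothesis import given, settings, strategies as st

from bondtrace.contacts import (
    call_contacts,
    contact_network,
    familiarity_contrast,
    first_contact_durations,
    network_metrics,
    segment_encounters,
)
from bondtrace.errors import ConfigurationError, DomainError, ValidationError


def _pings(times, pair=("a", "b"), rssi=-60.0):
    return pd.DataFrame(
        {"bat_a": pair[0], "bat_b": pair[1], "t_s": times,
         "rssi": np.full(len(times), rssi)}
    )


def _enc(max_rssis, start=0.0, dur=60.0):
    n = len(max_rssis)
    return pd.DataFrame(
        {"bat_a": "a", "bat_b": "b",
         "start_s": start + np.arange(n) * 1000.0,
         "end_s": start + np.arange(n) * 1000.0 + dur,
         "duration_s": dur, "max_rssi": max_rssis, "n_pings": 5}
    )


class TestSegmentation:
    def test_single_ping_is_one_minimal_encounter(self):
        enc = segment_encounters(_pings([100.0]), ping_interval_s=2.0)
        assert len(enc) == 1
        assert enc.loc[0, "n_pings"] == 1
        assert enc.loc[0, "duration_s"] == 2.0

    def test_gap_rule_merges_or_splits(self):
        enc = segment_encounters(_pings([0.0, 10.0, 20.0]), max_gap_s=15.0)
        assert len(enc) == 1
        assert (enc.loc[0, "start_s"], enc.loc[0, "end_s"]) == (0.0, 20.0)
        enc = segment_encounters(_pings([0.0, 10.0, 20.0]), max_gap_s=5.0)
        assert len(enc) == 3

    def test_max_rssi_is_member_maximum(self):
        p = _pings([0.0, 2.0, 4.0])
        p["rssi"] = [-70.0, -50.0, -65.0]
        enc = segment_encounters(p)
        assert enc.loc[0, "max_rssi"] == -50.0

    def test_negative_gap_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            segment_encounters(_pings([0.0]), max_gap_s=-1.0)

    def test_reproduces_generator_encounters(self, study2_full):
        pings, _, _, truth = study2_full
        enc = segment_encounters(pings, max_gap_s=60.0, ping_interval_s=2.0)
        te = truth.dyad_tables["encounters"].sort_values(
            ["bat_a", "bat_b", "start_s"]
        ).reset_index(drop=True)
        enc = enc.sort_values(["bat_a", "bat_b", "start_s"]).reset_index(drop=True)
        assert len(enc) == len(te)
        assert np.allclose(enc["start_s"], te["start_s"], atol=1e-9)
        assert np.allclose(enc["max_rssi"], te["max_rssi"], atol=1e-9)


class TestCallContacts:
    def test_top_five_percent_of_100_distinct_is_exactly_5(self):
        enc = _enc(np.arange(100.0))
        out = call_contacts(enc, top_fraction=0.05)
        assert len(out) == 5
        assert set(out["max_rssi"]) == {95.0, 96.0, 97.0, 98.0, 99.0}

    def test_ties_at_threshold_are_kept(self):
        out = call_contacts(_enc(np.full(50, -60.0)), top_fraction=0.05)
        assert len(out) == 50

    def test_threshold_matches_sorting_oracle(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(-60, 8, size=1000)
        out = call_contacts(_enc(vals), top_fraction=0.05)
        oracle_thr = np.sort(vals)[-50]  # 50 = 5% of 1000, distinct w.p. 1
        assert out.attrs["rssi_threshold"] == pytest.approx(oracle_thr)
        assert len(out) == 50
        frac = len(out) / 1000
        assert abs(frac - 0.05) <= 1 / 1000

    def test_empty_input_is_domain_error(self):
        with pytest.raises(DomainError):
            call_contacts(_enc([])[:0])


class TestFirstContactDurations:
    BATS = pd.DataFrame({"bat": ["a", "b", "c"], "site": ["s1", "s1", "s2"]})

    def test_pair_with_no_contacts_reports_zero_everywhere(self):
        dur = first_contact_durations(_enc([])[:0], self.BATS)
        assert (dur["minutes"] == 0).all()
        assert set(zip(dur["bat_a"], dur["bat_b"])) == {("a", "b"), ("a", "c"), ("b", "c")}

    def test_boundary_straddling_encounter_splits_across_windows(self):
        enc = pd.DataFrame(
            {"bat_a": ["a"], "bat_b": ["c"], "start_s": [3.9 * 3600],
             "end_s": [4.1 * 3600], "duration_s": [0.2 * 3600],
             "max_rssi": [-50.0], "n_pings": [100]}
        )
        dur = first_contact_durations(enc, self.BATS, windows_h=[4, 8])
        ac = dur[(dur["bat_a"] == "a") & (dur["bat_b"] == "c")].set_index("window_h")
        assert ac.loc[4, "minutes"] == pytest.approx(6.0)
        assert ac.loc[8, "minutes"] == pytest.approx(12.0)
        assert not ac.loc[4, "familiar"]

    def test_unknown_bat_is_validation_error(self):
        enc = _enc([-50.0])
        enc.loc[0, "bat_b"] = "zz"
        with pytest.raises(ValidationError, match="zz"):
            first_contact_durations(enc, self.BATS)

    def test_matches_generator_ledger_exactly(self, study2_full):
        pings, bats, _, truth = study2_full
        enc = segment_encounters(pings, max_gap_s=60.0, ping_interval_s=2.0)
        dur = first_contact_durations(enc, bats)
        wt = truth.dyad_tables["window_minutes"]
        m = dur.merge(wt, on=["bat_a", "bat_b", "window_h"], suffixes=("", "_t"))
        assert len(m) == len(dur)
        assert np.allclose(m["minutes"], m["minutes_t"], atol=1e-9)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(
        st.lists(
            st.tuples(st.floats(0, 23.9), st.floats(0.01, 3.0)), min_size=1, max_size=10
        )
    )
    def test_minutes_monotone_in_window_and_sum_to_24h_total(self, intervals):
        enc = pd.DataFrame(
            {"bat_a": "a", "bat_b": "b",
             "start_s": [s * 3600 for s, _ in intervals],
             "end_s": [(s + d) * 3600 for s, d in intervals],
             "duration_s": [d * 3600 for _, d in intervals],
             "max_rssi": -50.0, "n_pings": 2}
        )
        dur = first_contact_durations(enc, self.BATS[:2])
        ab = dur[(dur["bat_a"] == "a") & (dur["bat_b"] == "b")].sort_values("window_h")
        mins = ab["minutes"].to_numpy()
        assert (np.diff(mins) >= -1e-9).all()
        total = sum(
            max(0.0, min((s + d), 24.0) - s) * 60 for s, d in intervals
        )
        assert mins[-1] == pytest.approx(total, abs=1e-6)


class TestNetworkMetrics:
    def test_all_within_site_network_has_assortativity_one(self):
        g = nx.Graph()
        for n, s in [("a", "x"), ("b", "x"), ("c", "y"), ("d", "y")]:
            g.add_node(n, site=s)
        g.add_edge("a", "b", weight=3.0)
        g.add_edge("c", "d", weight=1.0)
        dens, assort = network_metrics(g)
        assert dens == pytest.approx(2 / 6)
        assert assort == pytest.approx(1.0)

    def test_matches_hand_computed_mixing_matrix(self):
        # e = [[4,1],[1,2]]/8 -> r = (0.75 - 0.53125) / (1 - 0.53125)
        g = nx.Graph()
        for n, s in [("a1", "x"), ("a2", "x"), ("b1", "y"), ("b2", "y")]:
            g.add_node(n, site=s)
        g.add_edge("a1", "a2", weight=2.0)
        g.add_edge("b1", "b2", weight=1.0)
        g.add_edge("a1", "b1", weight=1.0)
        _, assort = network_metrics(g)
        assert assort == pytest.approx(0.21875 / 0.46875, abs=1e-12)

    def test_no_edges_reports_missing_assortativity(self):
        g = nx.Graph()
        g.add_node("a", site="x")
        g.add_node("b", site="y")
        dens, assort = network_metrics(g)
        assert dens == 0.0
        assert np.isnan(assort)

    def test_random_edges_have_near_zero_mean_assortativity(self):
        rng = np.random.default_rng(0)
        nodes = [(f"n{i}", "x" if i < 10 else "y") for i in range(20)]
        vals = []
        for _ in range(50):
            g = nx.Graph()
            for n, s in nodes:
                g.add_node(n, site=s)
            for i in range(20):
                for j in range(i + 1, 20):
                    if rng.random() < 0.3:
                        g.add_edge(f"n{i}", f"n{j}", weight=1.0)
            _, a = network_metrics(g)
            vals.append(a)
        assert np.nanmean(vals) == pytest.approx(0.0, abs=0.05)

    def test_density_non_decreasing_in_window(self, study2_full):
        pings, bats, _, _ = study2_full
        enc = segment_encounters(pings)
        called = call_contacts(enc, top_fraction=0.05)
        dur = first_contact_durations(called, bats)
        dens = [
            network_metrics(contact_network(dur, bats, w))[0]
            for w in (4.0, 8.0, 12.0, 16.0, 20.0, 24.0)
        ]
        assert (np.diff(dens) >= 0).all()


class TestFamiliarityContrast:
    def test_all_zero_class_gives_degenerate_interval(self):
        dur = pd.DataFrame(
            {"bat_a": list("aabb"), "bat_b": list("bccd"),
             "window_h": 4.0, "minutes": [0.0, 0.0, 5.0, 7.0],
             "familiar": [True, True, False, False]}
        )
        out = familiarity_contrast(dur, n_boot=500, random_state=0)
        fam = out[out["class"] == "familiar"].iloc[0]
        assert fam["mean_minutes"] == fam["lower"] == fam["upper"] == 0.0

    def test_planted_rate_ordering_is_recovered(self, study2_full):
        pings, bats, _, _ = study2_full
        enc = segment_encounters(pings)
        dur = first_contact_durations(enc, bats)
        out = familiarity_contrast(dur, n_boot=1000, random_state=1)
        for w in out["window_h"].unique():
            sub = out[out["window_h"] == w].set_index("class")
            assert (
                sub.loc["familiar", "mean_minutes"]
                > sub.loc["unfamiliar", "mean_minutes"]
            )

    def test_empty_class_is_domain_error(self):
        dur = pd.DataFrame(
            {"bat_a": ["a"], "bat_b": ["b"], "window_h": [4.0],
             "minutes": [1.0], "familiar": [True]}
        )
        with pytest.raises(DomainError):
            familiarity_contrast(dur, n_boot=500)
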
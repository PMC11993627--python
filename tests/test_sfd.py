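"""The SFD estimator: pairing, differencing, regression, replication,
sensitivity variants, and its invariances."""

import numpy as np
import pandas as pd
import pytest

import waterfetch as wf
from waterfetch.sfd import _KM_PER_DEG_LAT

from conftest import make_grid, make_records


class TestEnumerateCellPairs:
    def test_single_cell_no_pairs(self):
        assert wf.enumerate_adjacent_cell_pairs({(0, 0)}, "WE") == []

    def test_row_of_three_gives_two_pairs(self):
        occ = {(0, 0), (0, 1), (0, 2)}
        assert wf.enumerate_adjacent_cell_pairs(occ, "WE") == [
            ((0, 0), (0, 1)),
            ((0, 1), (0, 2)),
        ]

    def test_diagonal_is_not_adjacent(self):
        assert wf.enumerate_adjacent_cell_pairs({(0, 0), (1, 1)}, "WE") == []
        assert wf.enumerate_adjacent_cell_pairs({(0, 0), (1, 1)}, "NS") == []

    def test_ns_orientation_north_is_second(self):
        assert wf.enumerate_adjacent_cell_pairs({(0, 0), (1, 0)}, "NS") == [
            ((0, 0), (1, 0))
        ]

    def test_bad_direction_raises(self):
        with pytest.raises(ValueError, match="direction"):
            wf.enumerate_adjacent_cell_pairs({(0, 0)}, "EW")


class TestDrawPairs:
    def test_count_is_min_of_sides(self):
        rng = np.random.default_rng(0)
        a, b = wf.draw_pairs([1, 2, 3], [10, 11], rng)
        assert len(a) == len(b) == 2
        assert len(set(a)) == 2 and len(set(b)) == 2

    def test_singletons_give_the_single_pair(self):
        rng = np.random.default_rng(0)
        a, b = wf.draw_pairs([5], [9], rng)
        assert list(a) == [5] and list(b) == [9]

    def test_empty_side_gives_empty(self):
        rng = np.random.default_rng(0)
        a, b = wf.draw_pairs([], [1, 2], rng)
        assert len(a) == 0 and len(b) == 0

    def test_selection_is_uniform(self):
        """With |A|=2, |B|=1 each A record is chosen ~5000/10000 times."""
        rng = np.random.default_rng(123)
        hits = 0
        n = 10000
        for _ in range(n):
            a, _ = wf.draw_pairs([0, 1], [7], rng)
            hits += a[0] == 0
        se = np.sqrt(n * 0.25)
        assert abs(hits - n / 2) < 3 * se


class TestDifferenceAndFit:
    def test_identical_records_difference_to_zero(self):
        vals = pd.DataFrame({"wt": [5.0, 5.0], "wv": [2.0, 2.0]})
        pairs = pd.DataFrame({"idx_hi": [1], "idx_lo": [0]})
        out = wf.difference(pairs, vals)
        assert out.loc[0, "d_wt"] == 0.0 and out.loc[0, "d_wv"] == 0.0

    def test_east_minus_west_arithmetic(self):
        vals = pd.DataFrame({"wt": [10.0, 20.0], "wv": [1.0, 3.0]})
        pairs = pd.DataFrame({"idx_hi": [1], "idx_lo": [0]})
        out = wf.difference(pairs, vals)
        assert (out.loc[0, "d_wt"], out.loc[0, "d_wv"]) == (10.0, 2.0)

    def test_orientation_flip_negates(self):
        vals = pd.DataFrame({"wt": [10.0, 20.0], "wv": [1.0, 3.0]})
        fwd = wf.difference(pd.DataFrame({"idx_hi": [1], "idx_lo": [0]}), vals)
        rev = wf.difference(pd.DataFrame({"idx_hi": [0], "idx_lo": [1]}), vals)
        assert (fwd.to_numpy() == -rev.to_numpy()).all()

    def test_missing_row_names_pair(self):
        vals = pd.DataFrame({"wt": [10.0]})
        pairs = pd.DataFrame({"idx_hi": [3], "idx_lo": [0]})
        with pytest.raises(ValueError, match="pair 0"):
            wf.difference(pairs, vals)

    def test_fit_sfd_closed_form_three_points(self):
        b0, b1 = wf.fit_sfd([1.0, 2.0, 0.0], [-3.5, -7.0, 0.0])
        assert b1 == pytest.approx(-3.5, abs=1e-12)
        assert b0 == pytest.approx(0.0, abs=1e-12)

    def test_fit_sfd_zero_outcome(self):
        b0, b1 = wf.fit_sfd([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert b0 == b1 == 0.0

    def test_fit_sfd_intercept_absorbs_constant_shift(self):
        x = np.array([1.0, 2.0, 4.0])
        y = np.array([2.0, 3.0, 7.0])
        b0, b1 = wf.fit_sfd(x, y)
        b0s, b1s = wf.fit_sfd(x, y + 5.0)
        assert b1s == pytest.approx(b1, abs=1e-12)
        assert b0s == pytest.approx(b0 + 5.0, abs=1e-12)

    def test_fit_sfd_orientation_antisymmetry(self):
        x = np.array([1.0, 2.0, 4.0])
        y = np.array([2.0, 3.0, 7.0])
        b0, b1 = wf.fit_sfd(x, y)
        b0r, b1r = wf.fit_sfd(-x, -y)
        assert b1r == pytest.approx(b1, abs=1e-12)
        assert b0r == pytest.approx(-b0, abs=1e-12)

    def test_fit_sfd_degenerate_exposure_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            wf.fit_sfd([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


def _linked_sim(**kw):
    base = dict(
        seed=9,
        n_clusters=40,
        households_per_cluster=8,
        lon_min=30.0,
        lon_max=32.5,
        lat_min=-2.5,
        lat_max=0.0,
        date_start="2015-10-01",
        date_end="2016-01-15",
        survey_start="2016-01-10",
        survey_end="2016-01-15",
        max_lag_days=90,
        effect_window_days=90,
    )
    base.update(kw)
    cfg = wf.SimulationConfig(**base)
    return wf.simulate_survey(cfg, windows=(90,)), cfg


class TestReplicateSFD:
    def test_noiseless_recovery_is_exact_every_replicate(self):
        sim, _ = _linked_sim(noise_sd=0.0, confounder_amplitude=0.0,
                             beta_precip=-3.5, beta_temp=0.0)
        res = wf.replicate_sfd(sim.records, sim.exposures, windows=(90,),
                               n_replicates=20, seed=1)
        b = res.replicates[("precip_cm_per_week", 90, "all")]
        np.testing.assert_allclose(b, -3.5, atol=1e-9)
        row = res.estimates.set_index("exposure").loc["precip_cm_per_week"]
        assert row["se"] == pytest.approx(0.0, abs=1e-9)

    def test_noiseless_temperature_recovery(self):
        sim, _ = _linked_sim(noise_sd=0.0, confounder_amplitude=0.0,
                             beta_precip=0.0, beta_temp=0.76)
        res = wf.replicate_sfd(sim.records, sim.exposures, windows=(90,),
                               n_replicates=10, seed=1)
        b = res.replicates[("tmax_mean_c", 90, "all")]
        np.testing.assert_allclose(b, 0.76, atol=1e-9)

    def test_same_seed_identical_results(self):
        sim, _ = _linked_sim()
        r1 = wf.replicate_sfd(sim.records, sim.exposures, windows=(90,),
                              n_replicates=15, seed=4)
        r2 = wf.replicate_sfd(sim.records, sim.exposures, windows=(90,),
                              n_replicates=15, seed=4)
        pd.testing.assert_frame_equal(r1.estimates, r2.estimates)

    def test_per_survey_location_shift_leaves_estimates_unchanged(self):
        sim, _ = _linked_sim(n_countries=2)
        shifted = sim.records.copy()
        offsets = {"C00-S1": 40.0, "C01-S1": -15.0}
        shifted["walk_time_min"] = shifted["walk_time_min"] + shifted[
            "country_survey_id"
        ].map(offsets)
        r1 = wf.replicate_sfd(sim.records, sim.exposures, windows=(90,),
                              n_replicates=10, seed=2)
        r2 = wf.replicate_sfd(shifted, sim.exposures, windows=(90,),
                              n_replicates=10, seed=2)
        pd.testing.assert_frame_equal(r1.estimates, r2.estimates)

    def test_pair_count_identity(self):
        """Rows per replicate = sum over cell pairs of min(nA, nB) when records
        may be reused across cell pairs; at most that otherwise."""
        sim, _ = _linked_sim()
        model = wf.SpatialFirstDifferences(sim.records, sim.exposures, windows=(90,))
        cell_pairs = model._cell_pairs(np.ones(len(sim.records), bool), "WE")
        expected = sum(min(len(a), len(b)) for a, b in cell_pairs)
        res_reuse = model.fit(n_replicates=5, seed=3, reuse_across_cellpairs=True)
        assert res_reuse.estimates["mean_pairs"].iloc[0] == expected
        res_norm = model.fit(n_replicates=5, seed=3)
        assert res_norm.estimates["mean_pairs"].iloc[0] <= expected

    def test_cross_survey_pairs_never_formed(self):
        """Clusters in adjacent cells of different countries are not paired."""
        grid = make_grid(n_lat=1, n_lon=2, n_days=400)
        rec = pd.concat(
            [
                make_records([("a", 0.2, 0.2, 3)], survey_date="2017-01-10",
                             survey_id="AA-S1"),
                make_records([("b", 0.7, 0.2, 3)], survey_date="2017-01-10",
                             survey_id="BB-S1"),
            ],
            ignore_index=True,
        )
        exp = wf.link_all(rec, grid, windows=(30,))
        model = wf.SpatialFirstDifferences(rec, exp, windows=(30,))
        assert model._cell_pairs(np.ones(len(rec), bool), "WE") == []

    def test_empty_stratum_warns_and_is_omitted(self):
        sim, _ = _linked_sim()
        with pytest.warns(UserWarning, match="no usable"):
            res = wf.replicate_sfd(
                sim.records, sim.exposures, windows=(90,), n_replicates=5, seed=1,
                stratum_spec={"none": "urban == 99"},
            )
        assert len(res.estimates) == 0

    def test_stratification_restricts_before_pairing(self):
        sim, _ = _linked_sim()
        res = wf.replicate_sfd(
            sim.records, sim.exposures, windows=(90,), n_replicates=5, seed=1,
            stratum_spec={"rural": "urban == 0", "all": np.ones(len(sim.records), bool)},
        )
        by = res.estimates.set_index(["stratum", "exposure"])
        n_rural = by.loc[("rural", "precip_cm_per_week"), "mean_pairs"]
        n_all = by.loc[("all", "precip_cm_per_week"), "mean_pairs"]
        assert n_rural <= n_all


class TestCellMeans:
    def test_hand_computed_slope(self):
        grid = make_grid(n_lat=1, n_lon=4, n_days=400,
                         tmax_fn=lambda t, r, c: 25.0 + np.asarray(c) ** 2)
        specs = []
        for c, wt in {0: 10.0, 1: 16.0, 2: 19.0, 3: 31.0}.items():
            specs.append((f"c{c}", 0.25 + 0.5 * c, 0.2, 2, {"walk_time_min": wt}))
        rec = make_records(specs, survey_date="2017-01-10")
        exp = wf.link_all(rec, grid, windows=(30,))
        out = wf.sfd_cell_means(rec, exp, windows=(30,), direction="WE",
                                exposure_names=("tmax_mean_c",))
        row = out.iloc[0]
        d_wt = np.array([6.0, 3.0, 12.0])
        d_wv = np.array([1.0, 3.0, 5.0])  # squares difference: 1,3,5
        slope = np.polyfit(d_wv, d_wt, 1)[0]
        assert row["estimate"] == pytest.approx(slope, abs=1e-9)

    def test_identical_cells_degenerate(self):
        grid = make_grid(n_lat=1, n_lon=2, n_days=400)
        rec = make_records([("a", 0.2, 0.2, 2), ("b", 0.7, 0.2, 2)],
                           survey_date="2017-01-10")
        exp = wf.link_all(rec, grid, windows=(30,))
        with pytest.raises(ValueError, match="degenerate"):
            wf.sfd_cell_means(rec, exp, windows=(30,))

    def test_equals_replicate_mean_with_one_record_per_cell(self):
        grid = make_grid(n_lat=1, n_lon=4, n_days=400,
                         tmax_fn=lambda t, r, c: 25.0 + np.asarray(c) ** 2)
        specs = [(f"c{c}", 0.25 + 0.5 * c, 0.2, 1, {"walk_time_min": wt})
                 for c, wt in {0: 10.0, 1: 16.0, 2: 19.0, 3: 31.0}.items()]
        rec = make_records(specs, survey_date="2017-01-10")
        exp = wf.link_all(rec, grid, windows=(30,))
        cm = wf.sfd_cell_means(rec, exp, windows=(30,), direction="WE",
                               exposure_names=("tmax_mean_c",))
        rep = wf.replicate_sfd(rec, exp, windows=(30,), n_replicates=3, seed=0,
                               exposure_names=("tmax_mean_c",),
                               reuse_across_cellpairs=True)
        b_rep = rep.estimates.set_index("exposure").loc["tmax_mean_c", "estimate"]
        assert cm.iloc[0]["estimate"] == pytest.approx(b_rep, abs=1e-9)


class TestBinned:
    def test_indicator_against_sorted_order(self):
        """On 8 hand records, exactly the top-quartile exposures are flagged."""
        grid = make_grid(n_lat=1, n_lon=8, n_days=400,
                         tmax_fn=lambda t, r, c: 20.0 + np.asarray(c, float))
        specs = [(f"c{c}", 0.25 + 0.5 * c, 0.2, 1) for c in range(8)]
        rec = make_records(specs, survey_date="2017-01-10")
        exp = wf.link_all(rec, grid, windows=(30,))
        model = wf.SpatialFirstDifferences(rec, exp, windows=(30,),
                                           exposure_names=("tmax_mean_c",))
        x = model._X[30]["tmax_mean_c"]
        q = np.percentile(x, 75)
        indicator = (x >= q).astype(int)
        order = np.argsort(x)
        assert indicator[order].tolist() == [0] * 6 + [1] * 2

    def test_indicator_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, 50)
        q1 = np.percentile(x, 75)
        q2 = np.percentile(np.exp(x / 5), 75)
        np.testing.assert_array_equal(x >= q1, np.exp(x / 5) >= q2)

    def test_constant_exposure_degenerate(self):
        grid = make_grid(n_lat=1, n_lon=3, n_days=400)
        specs = [(f"c{c}", 0.25 + 0.5 * c, 0.2, 2) for c in range(3)]
        rec = make_records(specs, survey_date="2017-01-10")
        exp = wf.link_all(rec, grid, windows=(30,))
        with pytest.raises(ValueError, match="degenerate"):
            wf.sfd_binned(rec, exp, percentile=75, windows=(30,), n_replicates=2, seed=0)

    def test_recovers_sign_on_recovery_data(self, recovery_sim):
        res = wf.sfd_binned(recovery_sim.records, recovery_sim.exposures,
                            percentile=75, windows=(365,), n_replicates=30, seed=8,
                            exposure_names=("tmax_mean_c",))
        row = res.estimates.set_index("exposure").loc["tmax_mean_c"]
        assert row["estimate"] > 0


class TestBorderBuffer:
    def _grid(self):
        return make_grid(n_lat=10, n_lon=10, lon0=30.0, lat0=-5.0)

    def test_cell_center_is_kept(self):
        grid = self._grid()
        rec = make_records([("a", 30.25, -4.75, 1, {"urban": 0})])
        assert len(wf.border_buffer_filter(rec, grid)) == 1

    def test_rural_3km_from_edge_dropped_urban_kept(self):
        grid = self._grid()
        lat = -4.75
        lon_3km = 30.5 - 3.0 / (_KM_PER_DEG_LAT * np.cos(np.radians(lat)))
        rec = make_records(
            [("r", lon_3km, lat, 1, {"urban": 0}), ("u", lon_3km, lat, 1, {"urban": 1})]
        )
        out = wf.border_buffer_filter(rec, grid)
        assert list(out["cluster_id"]) == ["u"]

    def test_latitude_edge_also_counts(self):
        grid = self._grid()
        lat_2km = -5.0 + 2.0 / _KM_PER_DEG_LAT
        rec = make_records([("a", 30.25, lat_2km, 1, {"urban": 0})])
        assert len(wf.border_buffer_filter(rec, grid)) == 0


class TestConfounderImmunity:
    def test_sfd_unbiased_naive_badly_biased(self, recovery_sim, recovery_fit_we):
        """Under a 20-min smooth spatial confounder the replicated SFD
        estimate stays within 3 replicate-SDs of the generating effect while
        naive pooled OLS is displaced by more than 5."""
        truth = {"precip_cm_per_week": -3.5, "tmax_mean_c": 0.76}
        est = recovery_fit_we.estimates.set_index("exposure")
        for name, beta in truth.items():
            row = est.loc[name]
            assert abs(row["estimate"] - beta) < 3 * row["se"]
            naive = wf.naive_pooled_ols(
                recovery_sim.records, recovery_sim.exposures, 365, name
            )
            assert abs(naive.beta1 - beta) > 5 * row["se"]

    def test_violation_mode_breaks_sfd(self):
        """When the confounder is mixed into the weather surface itself the
        identifying assumption fails and SFD becomes biased."""
        cfg = wf.SimulationConfig(seed=21, confounder_amplitude=20.0,
                                  confounder_weather_mix=0.95,
                                  confounder_trend_share=0.0,
                                  confounder_length_scale=0.5)
        sim = wf.simulate_survey(cfg, windows=(365,))
        res = wf.replicate_sfd(sim.records, sim.exposures, windows=(365,),
                               n_replicates=50, seed=21)
        row = res.estimates.set_index("exposure").loc["tmax_mean_c"]
        assert abs(row["estimate"] - 0.76) > 3 * row["se"]
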
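"""Nearest-nest distances, nesting probabilities and the fixed-marginal null."""

import numpy as np
import pandas as pd
import pytest

from arborants.data import DataError, derive_fn_records
from arborants.simulate import SimulationConfig, generate_community
from arborants.spatial import (
    cumulative_curve,
    nearest_nest_distances,
    nesting_probability_profile,
    null_test,
    quasiswap_randomize,
)
from conftest import build_dataset, random_dataset


class TestNearestNestDistances:
    def test_single_candidate_gives_its_distance(self, toy_dataset):
        d = nearest_nest_distances(toy_dataset, "p")
        assert len(d) == 1
        assert d.loc[0, "tree_id"] == "T2"
        assert d.loc[0, "distance_m"] == pytest.approx(5.0)

    def test_minimum_over_candidates(self):
        ds = build_dataset(
            [("T1", "p", 0, 0), ("T2", "p", 7, 0), ("T3", "p", -2, 0)],
            [("T2", "A"), ("T3", "A")],
            [("T1", "A")],
        )
        d = nearest_nest_distances(ds, "p")
        assert d.loc[0, "distance_m"] == pytest.approx(2.0)

    def test_matches_brute_force_on_random_plots(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            ds = random_dataset(rng, n_trees=15, n_species=6)
            got = nearest_nest_distances(ds, "p")
            nest = ds.layers["nest"]
            xy = ds.trees[["x", "y"]]
            for rec in got.itertuples():
                cands = [
                    np.hypot(*(xy.loc[rec.tree_id] - xy.loc[u]))
                    for u in nest.index
                    if u != rec.tree_id and nest.loc[u, rec.species_code] == 1
                ]
                assert rec.distance_m == pytest.approx(min(cands), abs=1e-9)
                assert rec.distance_m > 0


class TestCumulativeCurve:
    def test_step_at_common_distance(self):
        curve = cumulative_curve(np.array([4.0, 4.0, 4.0]), grid=np.array([3.9, 4.0, 5.0]))
        assert curve["cumulative"].tolist() == [0.0, 1.0, 1.0]

    def test_counting_proportion(self):
        curve = cumulative_curve(np.array([1.0, 3.0, 9.0, 20.0]), grid=np.array([10.0]))
        assert curve["cumulative"].iloc[0] == pytest.approx(0.75)

    def test_reaches_one_and_monotone(self):
        rng = np.random.default_rng(22)
        curve = cumulative_curve(rng.uniform(0, 50, size=40))
        c = curve["cumulative"].to_numpy()
        assert np.all(np.diff(c) >= 0) and c[-1] == 1.0
        assert ((c >= 0) & (c <= 1)).all()

    def test_empty_records_rejected(self):
        with pytest.raises(DataError):
            cumulative_curve(np.array([]))


class TestNestingProbabilityProfile:
    def test_proportion_of_candidate_trees(self):
        # focal T0 with 4 trees within 5 m, one holding a nest of S
        trees = [("T0", "p", 0, 0)] + [(f"T{i}", "p", i, 0) for i in range(1, 5)]
        ds = build_dataset(
            trees,
            [("T1", "S")],
            [("T0", "S")],
        )
        prof = nesting_probability_profile(ds, "p", radii=(5.0,))
        assert prof["mean_probability"].iloc[0] == pytest.approx(0.25)

    def test_record_skipped_when_no_tree_within_radius(self):
        ds = build_dataset(
            [("T0", "p", 0, 0), ("T1", "p", 30, 0)],
            [("T1", "S")],
            [("T0", "S")],
        )
        prof = nesting_probability_profile(ds, "p", radii=(5.0, 40.0))
        assert prof["n_records"].tolist() == [0, 1]
        assert np.isnan(prof["mean_probability"].iloc[0])
        assert prof["mean_probability"].iloc[1] == pytest.approx(1.0)

    def test_nonpositive_radius_rejected(self, toy_dataset):
        with pytest.raises(ValueError):
            nesting_probability_profile(toy_dataset, "p", radii=(0.0,))

    def test_invariant_to_rigid_motion_and_relabeling(self):
        cfg = SimulationConfig(n_trees=40, n_species=8, emission_rate=0.6,
                               kernel_range_m=6.0, tourist_rate=0.05, plot_label="p")
        ds, _ = generate_community(cfg, seed=5)
        base = nesting_probability_profile(ds, "p")
        # rotate 90 degrees, translate, and shuffle tree labels
        ds2, _ = generate_community(cfg, seed=5)
        x, y = ds2.trees["x"].copy(), ds2.trees["y"].copy()
        ds2.trees["x"], ds2.trees["y"] = -y + 100.0, x - 7.0
        perm = np.random.default_rng(0).permutation(len(ds2.trees))
        ds2.trees = ds2.trees.iloc[perm]
        for kind in ("nest", "forage"):
            ds2.layers[kind] = ds2.layers[kind].iloc[perm]
        moved = nesting_probability_profile(ds2, "p")
        np.testing.assert_allclose(
            base["mean_probability"], moved["mean_probability"], rtol=0, atol=1e-12
        )


class TestQuasiswap:
    def test_frozen_matrix_returned_unchanged(self):
        # no 2x2 checkerboard submatrix exists: the margin class is a singleton
        A = np.array([[1, 1], [1, 0]])
        out = quasiswap_randomize(A, seed=0)
        assert np.array_equal(out, A)

    def test_checkerboard_flips_about_half_the_time(self):
        A = np.array([[1, 0], [0, 1]])
        B = np.array([[0, 1], [1, 0]])
        hits = {0: 0, 1: 0}
        for seed in range(1000):
            out = quasiswap_randomize(A, seed=seed)
            if np.array_equal(out, A):
                hits[0] += 1
            else:
                assert np.array_equal(out, B)
                hits[1] += 1
        # binomial(1000, 0.5): +/- 3.3 sigma band
        assert 448 <= hits[0] <= 552

    def test_margins_preserved_on_random_matrices(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            shape = (int(rng.integers(2, 15)), int(rng.integers(2, 12)))
            A = (rng.random(shape) < rng.uniform(0.1, 0.6)).astype(int)
            out = quasiswap_randomize(A, rng=rng)
            assert np.array_equal(out.sum(axis=0), A.sum(axis=0))
            assert np.array_equal(out.sum(axis=1), A.sum(axis=1))

    def test_non_binary_input_rejected(self):
        with pytest.raises(ValueError):
            quasiswap_randomize(np.array([[2, 0], [0, 1]]))

    def test_empty_rows_and_columns_stay_empty(self):
        A = np.array([[1, 0, 0], [0, 0, 0], [1, 1, 0]])
        out = quasiswap_randomize(A, seed=1)
        assert out[1].sum() == 0 and out[:, 2].sum() == 0


class TestNullTest:
    @staticmethod
    def _small_signal_dataset(seed=9):
        cfg = SimulationConfig(n_trees=60, n_species=10, emission_rate=0.9,
                               kernel_range_m=5.0, tourist_rate=0.02, plot_label="p")
        return generate_community(cfg, seed)[0]

    def test_requires_at_least_two_permutations(self):
        ds = self._small_signal_dataset()
        with pytest.raises(ValueError):
            null_test(ds, "p", n_perm=1, seed=0)

    def test_rank_p_when_observed_below_all_nulls(self):
        # strong signal: observed mean should undercut every null mean
        ds = self._small_signal_dataset()
        res = null_test(ds, "p", "nearest_distance_curve", n_perm=100, seed=4)
        if (res.null_means > res.observed_mean).all():
            assert res.rank_p == pytest.approx(2 / 101)
            assert res.outside_envelope

    def test_rank_p_arithmetic_directly(self):
        from arborants.spatial import _rank_p

        null = np.arange(1.0, 101.0)
        assert _rank_p(0.5, null) == pytest.approx(2 / 101)
        assert _rank_p(200.0, null) == pytest.approx(2 / 101)
        assert _rank_p(50.5, null) == pytest.approx(1.0)

    def test_degenerate_margins_collapse_envelope(self):
        # a species nesting on every tree but the focal one: with one column,
        # the fixed margins admit exactly one matrix, so the null is constant
        trees = [(f"T{i}", "p", float(i), 0) for i in range(5)]
        ds2 = build_dataset(
            trees,
            [(f"T{i}", "A") for i in range(1, 5)],
            [("T0", "A")],
        )
        res = null_test(ds2, "p", "nearest_distance_curve", n_perm=10, seed=0)
        assert np.ptp(res.null_means) == pytest.approx(0.0)
        assert res.observed_mean == pytest.approx(res.null_means[0])
        assert not res.outside_envelope

    def test_fn_records_fixed_and_margins_held(self):
        ds = self._small_signal_dataset()
        recs = derive_fn_records(ds, "p")
        res = null_test(ds, "p", "nearest_distance_curve", n_perm=5, seed=8)
        assert len(res.fn_distances) == len(recs)

    def test_probability_profile_statistic_runs(self):
        ds = self._small_signal_dataset()
        res = null_test(ds, "p", "probability_profile", n_perm=20, seed=2,
                        radii=(5.0, 10.0))
        assert list(res.table["radius_m"]) == [5.0, 10.0]
        assert res.observed_mean == pytest.approx(res.table["observed_mean"].iloc[0])
        assert (res.table["env_lo"] <= res.table["env_hi"]).all()

    def test_same_seed_reproduces_result(self):
        ds = self._small_signal_dataset()
        a = null_test(ds, "p", n_perm=10, seed=77)
        b = null_test(ds, "p", n_perm=10, seed=77)
        np.testing.assert_array_equal(a.null_means, b.null_means)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_excluded_species_absent_from_spatial_records(self):
        cfg = SimulationConfig(n_trees=50, n_species=8, emission_rate=0.5,
                               kernel_range_m=5.0, tourist_rate=0.05,
                               ground_nester=True, plot_label="p")
        ds, _ = generate_community(cfg, seed=3)
        res = null_test(ds, "p", n_perm=3, seed=1)
        assert "GRND001" not in set(res.fn_distances["species_code"])
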
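"""Rarefaction, Chao2 and richness tabulation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from arborants.diversity import (
    IncidenceSummary,
    chao2,
    chao2_accumulation,
    incidence_summary,
    mao_tau,
    occupancy_and_abundance_summary,
    per_tree_richness,
    rarefaction_curve,
    richness_table,
    shared_species,
)
from conftest import build_dataset, random_dataset


def brute_force_tau(matrix: np.ndarray, h: int) -> float:
    """Average richness over all C(H, h) sample subsets, enumerated."""
    H = matrix.shape[0]
    richness = [
        int((matrix[list(idx)].sum(axis=0) > 0).sum())
        for idx in itertools.combinations(range(H), h)
    ]
    return float(np.mean(richness))


class TestMaoTau:
    def test_full_sample_returns_observed_richness(self):
        rng = np.random.default_rng(0)
        mat = (rng.random((12, 30)) < 0.2).astype(int)
        s = incidence_summary(mat)
        assert mao_tau(s, s.H) == pytest.approx(s.S_obs, abs=1e-12)

    def test_single_sample_is_mean_per_sample_richness(self):
        rng = np.random.default_rng(1)
        mat = (rng.random((15, 20)) < 0.3).astype(int)
        s = incidence_summary(mat)
        assert mao_tau(s, 1) == pytest.approx(mat.sum(axis=1).mean())

    def test_matches_exhaustive_enumeration_on_fixed_case(self):
        # H = 4 samples; species incidence frequencies 4, 2, 1
        mat = np.array([[1, 1, 1], [1, 1, 0], [1, 0, 0], [1, 0, 0]])
        s = incidence_summary(mat)
        assert s.H == 4 and tuple(sorted(s.Y, reverse=True)) == (4, 2, 1)
        assert mao_tau(s, 2) == pytest.approx(brute_force_tau(mat, 2), abs=1e-9)

    def test_matches_enumeration_on_random_matrices(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            H = int(rng.integers(2, 9))
            S = int(rng.integers(1, 12))
            mat = (rng.random((H, S)) < 0.4).astype(int)
            s = incidence_summary(mat)
            for h in range(1, H + 1):
                assert mao_tau(s, h) == pytest.approx(brute_force_tau(mat, h), abs=1e-9)

    def test_out_of_range_h_rejected(self):
        s = incidence_summary(np.ones((3, 2), dtype=int))
        with pytest.raises(ValueError):
            mao_tau(s, 0)
        with pytest.raises(ValueError):
            mao_tau(s, 4)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_curve_monotone_and_ends_at_s_obs(self, seed):
        rng = np.random.default_rng(seed)
        H = int(rng.integers(2, 15))
        mat = (rng.random((H, 10)) < rng.uniform(0.05, 0.6)).astype(int)
        s = incidence_summary(mat)
        curve = rarefaction_curve(s)["tau"].to_numpy()
        assert np.all(np.diff(curve) >= -1e-12)
        assert curve[-1] == pytest.approx(s.S_obs, abs=1e-9)


class TestChao2:
    def test_direct_formula_evaluation(self):
        s = IncidenceSummary(H=100, S_obs=10, Y=np.array([1] * 4 + [2] * 2 + [5] * 4),
                             q1=4, q2=2)
        res = chao2(s, "classic")
        assert res.estimate == pytest.approx(10 + 0.99 * 16 / 4)

    def test_no_uniques_means_no_correction(self):
        mat = np.array([[1, 1], [1, 1], [0, 1]])  # Y = (2, 3): q1 = 0
        s = incidence_summary(mat)
        res = chao2(s)
        assert res.estimate == s.S_obs
        assert res.sd == 0.0

    def test_q2_zero_falls_back_to_bias_corrected(self):
        s = IncidenceSummary(H=10, S_obs=5, Y=np.array([1, 1, 3, 4, 5]), q1=2, q2=0)
        with pytest.warns(UserWarning, match="bias_corrected"):
            res = chao2(s, "classic")
        assert res.variant_used == "bias_corrected"
        assert res.estimate >= s.S_obs

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_estimate_bounds_and_variant_order(self, seed):
        rng = np.random.default_rng(seed)
        H = int(rng.integers(2, 40))
        mat = (rng.random((H, 25)) < rng.uniform(0.02, 0.5)).astype(int)
        s = incidence_summary(mat)
        if s.S_obs == 0:
            return
        bc = chao2(s, "bias_corrected")
        assert bc.estimate >= s.S_obs
        if s.q2 >= 1 and s.q1 >= 1:
            cl = chao2(s, "classic")
            assert cl.estimate >= s.S_obs
            assert bc.estimate <= cl.estimate + 1e-9

    def test_accumulation_sd_collapses_at_full_sample(self):
        rng = np.random.default_rng(3)
        mat = (rng.random((10, 15)) < 0.25).astype(int)
        acc = chao2_accumulation(mat, n_randomizations=20, seed=0)
        assert acc["chao2_sd"].iloc[-1] == pytest.approx(0.0, abs=1e-12)
        full = chao2(incidence_summary(mat))
        assert acc["chao2_mean"].iloc[-1] == pytest.approx(full.estimate)


class TestRichness:
    def test_ant_free_tree_counts_zero_everywhere(self):
        ds = build_dataset(
            [("T1", "p", 0, 0), ("T2", "p", 5, 5)],
            [("T1", "A")],
            [("T1", "A")],
        )
        for layer in ("all", "nest", "forage", "fn"):
            assert per_tree_richness(ds, "p", layer).per_tree["T2"] == 0

    def test_layer_identities_on_random_communities(self):
        # all >= max(nest, forage); fn = forage - both - foragers with no plot nest
        rng = np.random.default_rng(11)
        for _ in range(15):
            ds = random_dataset(rng, n_trees=20, n_species=10)
            nest, forage = ds.layers["nest"], ds.layers["forage"]
            counts = {
                layer: per_tree_richness(ds, "p", layer).per_tree
                for layer in ("all", "nest", "forage", "fn")
            }
            union = ((nest + forage) > 0).sum(axis=1)
            pd.testing.assert_series_equal(counts["all"], union, check_names=False, check_dtype=False)
            assert (counts["all"] >= counts["nest"]).all()
            assert (counts["all"] >= counts["forage"]).all()
            assert (counts["fn"] <= counts["forage"]).all()
            nestless = nest.sum(axis=0) == 0
            both = (nest.to_numpy(bool) & forage.to_numpy(bool)).sum(axis=1)
            orphan = (forage.loc[:, nestless] > 0).sum(axis=1)
            expected_fn = counts["forage"] - both - orphan
            pd.testing.assert_series_equal(
                counts["fn"], expected_fn, check_names=False, check_dtype=False
            )

    def test_mean_matches_row_sums(self):
        rng = np.random.default_rng(12)
        ds = random_dataset(rng)
        rt = per_tree_richness(ds, "p", "all")
        union = ((ds.layers["nest"] + ds.layers["forage"]) > 0).sum(axis=1)
        assert rt.mean == pytest.approx(union.mean())
        assert rt.max == union.max()

    def test_summary_table_has_all_layers(self):
        rng = np.random.default_rng(13)
        ds = random_dataset(rng)
        table = richness_table(ds, "p")
        assert set(table["layer"]) == {"all", "nest", "forage", "fn"}


class TestSharedAndOccupancy:
    @staticmethod
    def _two_plot_ds(secondary_species):
        trees = [("A1", "pa", 0, 0), ("B1", "pb", 1, 1)]
        nest = [("A1", "S1"), ("A1", "S2"), ("B1", secondary_species)]
        forage = list(nest)
        return build_dataset(trees, nest, forage, species=sorted({"S1", "S2", secondary_species}))

    def test_disjoint_plots_share_nothing(self):
        ds = self._two_plot_ds("S3")
        assert shared_species(ds, "pa", "pb")[0] == 0

    def test_identical_pools_share_everything(self):
        ds = self._two_plot_ds("S1")
        n, codes = shared_species(ds, "pa", "pb")
        assert n == 1 and codes == ["S1"]

    def test_occupancy_equals_column_sums(self):
        rng = np.random.default_rng(14)
        ds = random_dataset(rng)
        occ = occupancy_and_abundance_summary(ds, "p")
        pd.testing.assert_series_equal(
            occ["per_species"]["occ_nest"],
            ds.layers["nest"].sum(axis=0),
            check_names=False, check_dtype=False,
        )
        assert occ["totals"]["total_nest"] is None  # no count layers supplied

    def test_count_layer_totals_are_grand_sums(self):
        ds = build_dataset(
            [("T1", "p", 0, 0), ("T2", "p", 5, 5)],
            [("T1", "A"), ("T2", "B")],
            [("T1", "A"), ("T2", "A"), ("T2", "B")],
            invasive={"B"},
        )
        ds.counts["forage"] = ds.layers["forage"].astype(int) * 7
        out = occupancy_and_abundance_summary(ds, "p")
        assert out["totals"]["total_forage"] == 21
        assert out["totals"]["invasive_fraction_forage_individuals"] == pytest.approx(1 / 3)
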
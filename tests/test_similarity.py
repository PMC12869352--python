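"""Wasserstein similarity, skew ratios and rank tests, with brute oracles."""

from itertools import combinations, permutations

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linprog

import sonoscape.similarity as sim


def transport_lp_oracle(a, b):
    """Order-1 transport distance by explicit linear program (HiGHS)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    m, n = len(a), len(b)
    cost = np.abs(a[:, None] - b[None, :]).ravel()
    a_eq = []
    for i in range(m):  # row sums = 1/m
        row = np.zeros((m, n))
        row[i, :] = 1.0
        a_eq.append(row.ravel())
    for j in range(n):  # column sums = 1/n
        col = np.zeros((m, n))
        col[:, j] = 1.0
        a_eq.append(col.ravel())
    b_eq = np.r_[np.full(m, 1.0 / m), np.full(n, 1.0 / n)]
    res = linprog(cost, A_eq=np.array(a_eq), b_eq=b_eq, bounds=(0, None),
                  method="highs")
    assert res.success
    return res.fun


class TestIntersections:
    def test_110_bins_times_8_bands_is_880(self):
        inters = sim.build_intersections(range(110))
        assert len(inters) == 880

    def test_single_bin_gives_eight(self):
        assert len(sim.build_intersections([5])) == 8

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            sim.build_intersections([])

    def test_bands_tile_focal_range(self):
        bands = sim.one_khz_bands()
        assert bands[0] == (1000.0, 2000.0)
        assert bands[-1] == (8000.0, 9000.0)
        assert len(bands) == 8


class TestClassDistribution:
    @staticmethod
    def records():
        rows = []
        for site, cls in [("A", "pasture"), ("B", "pasture"), ("C", "pasture"),
                          ("D", "plantation")]:
            for m in range(30, 40):
                rows.append({"site_id": site, "land_use": cls,
                             "minute_of_day": m,
                             "band_3000": 10.0 * (m - 30) + ord(site)})
        return pd.DataFrame(rows)

    def test_three_sites_ten_minutes_pool_to_thirty(self):
        inter = sim.Intersection(3, 3000.0, 4000.0)
        out = sim.class_distribution(self.records(), inter, "pasture")
        assert out.size == 30

    def test_matches_filter_and_collect_oracle(self):
        df = self.records()
        inter = sim.Intersection(3, 3000.0, 4000.0)
        out = sim.class_distribution(df, inter, "plantation")
        expected = df.loc[(df["land_use"] == "plantation")
                          & (df["minute_of_day"] >= 30)
                          & (df["minute_of_day"] < 40), "band_3000"]
        np.testing.assert_array_equal(np.sort(out), np.sort(expected))

    def test_minutes_outside_bin_excluded(self):
        inter = sim.Intersection(10, 3000.0, 4000.0)  # minutes 100-109
        out = sim.class_distribution(self.records(), inter, "pasture")
        assert out.size == 0


class TestWasserstein:
    def test_identical_samples_zero(self, rng):
        a = rng.normal(size=20)
        assert sim.wasserstein_1d(a, a) == 0.0

    def test_translation_property(self, rng):
        a = rng.normal(size=17)
        assert sim.wasserstein_1d(a, a + 3.5) == pytest.approx(3.5)

    def test_symmetry(self, rng):
        a, b = rng.normal(size=9), rng.normal(size=13)
        assert sim.wasserstein_1d(a, b) == pytest.approx(sim.wasserstein_1d(b, a))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            sim.wasserstein_1d(np.array([]), np.array([1.0]))

    def test_equal_size_matches_sorted_matching_oracle(self, rng):
        # for equal sizes the optimal matching pairs sorted samples; verify
        # against exhaustive permutation matching for n <= 6
        for _ in range(50):
            n = int(rng.integers(2, 7))
            a, b = rng.normal(size=n), rng.normal(size=n)
            brute = min(np.abs(a - np.array(p)).mean()
                        for p in permutations(b))
            assert sim.wasserstein_1d(a, b) == pytest.approx(brute)

    def test_matches_transport_lp_oracle_unequal_sizes(self, rng):
        for _ in range(40):
            m, n = rng.integers(1, 7, size=2)
            a = rng.uniform(-5, 5, size=m)
            b = rng.uniform(-5, 5, size=n)
            assert sim.wasserstein_1d(a, b) == pytest.approx(
                transport_lp_oracle(a, b), abs=1e-9)

    def test_triangle_inequality(self, rng):
        for _ in range(30):
            a, b, c = (rng.normal(size=int(rng.integers(2, 10)))
                       for _ in range(3))
            assert (sim.wasserstein_1d(a, c) <=
                    sim.wasserstein_1d(a, b) + sim.wasserstein_1d(b, c) + 1e-12)


class TestSimilarityScaling:
    def test_zero_distance_complete_overlap(self):
        assert sim.similarity(0.0) == 1.0

    def test_known_value_at_inverse_k(self):
        assert sim.similarity(100_000.0) == pytest.approx(np.exp(-1.0))

    def test_strictly_decreasing(self):
        assert sim.similarity(10.0) > sim.similarity(20.0)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            sim.similarity(-1.0)


def toy_distances(values):
    """Distance table over 2 bins x 1 band for the three relevant pairs."""
    rows = []
    for (tb, pair), w in values.items():
        a, b = sorted(pair)
        rows.append({"time_bin": tb, "band_lo_hz": 1000.0, "band_hi_hz": 2000.0,
                     "class_a": a, "class_b": b, "wasserstein": w,
                     "similarity": sim.similarity(w), "n_a": 5, "n_b": 5})
    return pd.DataFrame(rows)


class TestSkew:
    def test_equal_similarities_give_unit_skew(self):
        d = toy_distances({
            (0, ("natural_regeneration", "reference_forest")): 100.0,
            (0, ("natural_regeneration", "pasture")): 100.0,
            (0, ("plantation", "reference_forest")): 100.0,
            (0, ("plantation", "pasture")): 100.0})
        _, _, grand = sim.skew_ratios(d)
        assert grand["natural_regeneration"] == pytest.approx(1.0)

    def test_ratio_of_similarities(self):
        # sim_ref = 0.5, sim_pasture = 0.25 -> skew 2
        x_half = -np.log(0.5) / sim.DEFAULT_K
        x_quarter = -np.log(0.25) / sim.DEFAULT_K
        d = toy_distances({
            (0, ("natural_regeneration", "reference_forest")): x_half,
            (0, ("natural_regeneration", "pasture")): x_quarter,
            (0, ("plantation", "reference_forest")): x_half,
            (0, ("plantation", "pasture")): x_half})
        _, _, grand = sim.skew_ratios(d)
        assert grand["natural_regeneration"] == pytest.approx(2.0)
        assert grand["plantation"] == pytest.approx(1.0)

    def test_grand_mean_matches_brute_average(self, rng):
        keys = {}
        for tb in range(4):
            for pair in [("natural_regeneration", "reference_forest"),
                         ("natural_regeneration", "pasture"),
                         ("plantation", "reference_forest"),
                         ("plantation", "pasture")]:
                keys[(tb, pair)] = float(rng.uniform(10, 1e5))
        d = toy_distances(keys)
        per_inter, _, grand = sim.skew_ratios(d)
        brute = np.mean([
            sim.similarity(keys[(tb, ("natural_regeneration",
                                      "reference_forest"))])
            / sim.similarity(keys[(tb, ("natural_regeneration", "pasture"))])
            for tb in range(4)])
        assert grand["natural_regeneration"] == pytest.approx(brute)

    def test_log_ratio_option_geometric_mean(self, rng):
        keys = {(tb, pair): float(rng.uniform(10, 1e5))
                for tb in range(3)
                for pair in [("natural_regeneration", "reference_forest"),
                             ("natural_regeneration", "pasture"),
                             ("plantation", "reference_forest"),
                             ("plantation", "pasture")]}
        d = toy_distances(keys)
        _, _, grand = sim.skew_ratios(d, log_ratio=True)
        ratios = [sim.similarity(keys[(tb, ("plantation", "reference_forest"))])
                  / sim.similarity(keys[(tb, ("plantation", "pasture"))])
                  for tb in range(3)]
        assert grand["plantation"] == pytest.approx(
            np.exp(np.mean(np.log(ratios))))


class TestFriedman:
    def test_identical_treatments_zero_statistic(self):
        table = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4],
                              "c": [1.0, 2, 3, 4]})
        with pytest.warns(UserWarning):
            stat, p = sim.friedman_across_bins(table)
        assert stat == 0.0

    def test_matches_closed_form_rank_statistic(self):
        # 3 treatments x 4 blocks, no ties: chi2 = 12/(n k (k+1)) sum Rj^2
        # - 3 n (k+1)
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0, 2.0],
                              "b": [5.0, 6.0, 4.0, 5.0],
                              "c": [9.0, 7.0, 8.0, 9.0]})
        # within-block ranks: a=1, b=2, c=3 everywhere -> R = (4, 8, 12)
        n, k = 4, 3
        expected = 12.0 / (n * k * (k + 1)) * (16 + 64 + 144) - 3 * n * (k + 1)
        stat, p = sim.friedman_across_bins(table)
        assert stat == pytest.approx(expected)

    def test_invariant_to_monotone_transform_within_blocks(self, rng):
        base = pd.DataFrame(rng.uniform(1, 9, size=(6, 3)), columns=list("abc"))
        s1, _ = sim.friedman_across_bins(base)
        s2, _ = sim.friedman_across_bins(np.exp(base))
        assert s1 == pytest.approx(s2)

    def test_missing_cell_names_bin(self):
        table = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, 3.0],
                              "c": [0.5, 1.5]})
        with pytest.raises(ValueError, match="1"):
            sim.friedman_across_bins(table)


class TestWilcoxon:
    def test_identical_columns_p_one(self):
        table = pd.DataFrame({"a": [1.0, 2, 3], "b": [1.0, 2, 3]})
        with pytest.warns(UserWarning):
            out = sim.pairwise_wilcoxon(table)
        assert out["p_adjusted"].iloc[0] == 1.0

    def test_matches_exact_enumeration_oracle(self, rng):
        # brute force the exact two-sided signed-rank null over all 2^8 sign
        # patterns
        d = rng.uniform(0.5, 3.0, size=8) * rng.choice([-1, 1], size=8)
        table = pd.DataFrame({"a": np.zeros(8), "b": -d})
        out = sim.pairwise_wilcoxon(table, pairs=[("a", "b")])
        ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
        w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
        count = 0
        for signs in range(256):
            mask = np.array([(signs >> i) & 1 for i in range(8)], bool)
            w = min(ranks[mask].sum(), ranks[~mask].sum())
            if w <= w_obs:
                count += 1
        assert out["p_raw"].iloc[0] == pytest.approx(count / 256.0)

    def test_bonferroni_definition(self, rng):
        table = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        out = sim.pairwise_wilcoxon(table)
        for _, row in out.iterrows():
            assert row["p_adjusted"] == pytest.approx(
                min(1.0, row["p_raw"] * 3))


class TestSummary:
    def test_single_intersection_equals_value(self):
        d = toy_distances({(0, ("natural_regeneration",
                                "reference_forest")): 5000.0})
        out = sim.similarity_summary(d, "focal")
        assert out["mean_similarity"].iloc[0] == pytest.approx(
            sim.similarity(5000.0))

    def test_matches_groupby_oracle(self, rng):
        keys = {(tb, pair): float(rng.uniform(10, 1e5))
                for tb in range(6)
                for pair in [("natural_regeneration", "reference_forest"),
                             ("pasture", "reference_forest")]}
        d = toy_distances(keys)
        out = sim.similarity_summary(d, "focal")
        for _, row in out.iterrows():
            vals = [sim.similarity(w) for (tb, pair), w in keys.items()
                    if tuple(sorted(pair)) == (row["class_a"], row["class_b"])]
            assert row["mean_similarity"] == pytest.approx(np.mean(vals))

    def test_dawn_only_restricts_bins(self):
        d = toy_distances({(31, ("natural_regeneration",
                                 "reference_forest")): 100.0,
                           (80, ("natural_regeneration",
                                 "reference_forest")): 100.0})
        out = sim.similarity_summary(d, "dawn_only")
        assert out["n_intersections"].iloc[0] == 1

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            sim.similarity_summary(toy_distances({}), "weekend")
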
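import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from connectisim import (
    PairThresholds,
    classify_pair,
    compare_single_vs_paired,
    compute_pbp,
    estimate_generations,
    fraction_over_10x,
    generate_bead_table,
    generations_from_geometry,
    pair_grid_and_ratios,
    random_category_null,
    simulation_bead_sizes,
    subsample,
)
from connectisim.readout_pbp import mc_fisher
from connectisim.synthetic_community import BeadObservationTable
import pandas as pd


class TestSubsample:
    def test_identity_at_target(self):
        c = np.array([10, 20, 30])
        out, flag = subsample(c, 60, seed=0)
        np.testing.assert_array_equal(out, c)
        assert flag

    def test_zeros_preserved(self):
        out, _ = subsample(np.array([1_000_000, 0]), 50_000, seed=1)
        np.testing.assert_array_equal(out, [50_000, 0])

    def test_hypergeometric_mean(self):
        # E[first component] = n * K/N = 50000 * 0.6 = 30000
        c = np.array([600_000, 400_000])
        n, N, K = 50_000, 1_000_000, 600_000
        var = n * (K / N) * (1 - K / N) * (N - n) / (N - 1)
        draws = np.array([subsample(c, n, seed=s)[0][0] for s in range(200)])
        se_mean = np.sqrt(var / 200)
        assert abs(draws.mean() - 30_000) <= 3 * se_mean

    def test_large_population_fallback_respects_caps(self):
        # beyond numpy's 1e9 hypergeometric cap
        c = np.array([3_000_000_000, 5, 0, 2_000_000_000], dtype=np.int64)
        out, flag = subsample(c, 10_000, seed=2)
        assert flag and out.sum() == 10_000
        assert (out <= c).all() and out[2] == 0

    def test_short_input_returned_unchanged(self):
        c = np.array([5, 5])
        out, flag = subsample(c, 100, seed=0)
        assert not flag
        np.testing.assert_array_equal(out, c)

    def test_invalid_target(self):
        with pytest.raises(ValueError):
            subsample(np.array([5]), 0)


class TestPBP:
    def _table(self, rows, empty=()):
        df = pd.DataFrame(rows, columns=BeadObservationTable.COLUMNS)
        return BeadObservationTable(records=df, empty_beads=list(empty))

    def test_empty_bead_zero_pbp(self):
        t = self._table([("b1", 0, "c", 0, 10.0, 100.0, "SC")], empty=["b0"])
        pbp = compute_pbp(t).set_index("bead_id")
        assert pbp.loc["b0", "pbp"] == 0.0
        assert pbp.loc["b0", "n_colonies"] == 0

    def test_single_colony_product(self):
        t = self._table([("b1", 0, "c", 0, 10.0, 100.0, "SC")])
        assert compute_pbp(t)["pbp"].iloc[0] == 1000.0

    def test_additivity_over_colonies(self):
        t = self._table([
            ("b1", 0, "c", 0, 10.0, 100.0, "SC"),
            ("b1", 0, "c", 1, 5.0, 200.0, "SC"),
        ])
        out = compute_pbp(t)
        assert out["pbp"].iloc[0] == 2000.0
        assert out["occupancy_class"].iloc[0] == "multiple"


class TestClassifier:
    # hand-computed worked table spanning all four categories
    # (no-growth cut 10^3.25 ~ 1778.3; balanced ratio band [0.125, 8])
    CASES = [
        (1e2, 1e2, "both_no_growth"),
        (0.0, 0.0, "both_no_growth"),
        (1778.0, 1778.0, "both_no_growth"),
        (1e3, 1.5e3, "both_no_growth"),
        (10.0, 1700.0, "both_no_growth"),
        (1e4, 1e2, "one_not_growing"),
        (1e2, 1e4, "one_not_growing"),
        (0.0, 1e6, "one_not_growing"),
        (1779.0, 1778.0, "one_not_growing"),
        (1e5, 1.0, "one_not_growing"),
        (1e4, 10**4.5, "balanced"),
        (1e4, 1e4, "balanced"),
        (2000.0, 16000.0, "balanced"),
        (16000.0, 2000.0, "balanced"),
        (1e5, 1.25e4, "balanced"),
        (10**3.5, 10**5.5, "imbalanced"),
        (2000.0, 16001.0, "imbalanced"),
        (1e6, 2e3, "imbalanced"),
        (1e4, 1e9, "imbalanced"),
        (10**3.26, 10**4.27, "imbalanced"),
    ]

    @pytest.mark.parametrize("p1,p2,expected", CASES)
    def test_worked_examples(self, p1, p2, expected):
        assert classify_pair(p1, p2)[0] == expected

    def test_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(0)
        p1 = 10 ** rng.uniform(0, 6, 2000)
        p2 = 10 ** rng.uniform(0, 6, 2000)
        cats = classify_pair(p1, p2)
        assert set(np.unique(cats)) <= {
            "both_no_growth", "one_not_growing", "balanced", "imbalanced"}
        assert len(cats) == 2000

    def test_negative_pbp_rejected(self):
        with pytest.raises(ValueError):
            classify_pair(-1.0, 10.0)

    @settings(derandomize=True, max_examples=200)
    @given(
        p1=st.floats(0.0, 1e9, allow_nan=False),
        p2=st.floats(0.0, 1e9, allow_nan=False),
        cut=st.floats(1.0, 6.0),
        hi=st.floats(1.5, 50.0),
    )
    def test_exactly_one_category_for_any_thresholds(self, p1, p2, cut, hi):
        thr = PairThresholds(log10_pbp_nogrowth=cut,
                             balanced_ratio_bounds=(1.0 / hi, hi))
        cat = classify_pair(p1, p2, thr)[0]
        assert cat in {"both_no_growth", "one_not_growing", "balanced",
                       "imbalanced"}


class TestRandomNull:
    def test_null_self_consistency(self):
        null = random_category_null(
            {"balanced": 0.0}, (0.0, 6.0), n_points=500, n_repeats=200, seed=0)
        # recompute with the null's own mean as the observation
        obs = null["balanced"]["null_mean"]
        out = random_category_null(
            {"balanced": obs}, (0.0, 6.0), n_points=500, n_repeats=200, seed=0)
        assert out["balanced"]["p_value"] > 0.2

    def test_extreme_observation_rejected(self):
        # a rectangle almost entirely above the no-growth threshold makes
        # 100% both_no_growth wildly unlikely
        out = random_category_null(
            {"both_no_growth": 100.0}, (3.5, 6.0), n_points=500,
            n_repeats=200, seed=1)
        assert out["both_no_growth"]["p_value"] < 0.01

    def test_deterministic(self):
        a = random_category_null({"balanced": 30.0}, (0, 6), n_points=200,
                                 n_repeats=100, seed=5)
        b = random_category_null({"balanced": 30.0}, (0, 6), n_points=200,
                                 n_repeats=100, seed=5)
        assert a["balanced"]["p_value"] == b["balanced"]["p_value"]

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError):
            random_category_null({"balanced": 10.0}, (2.0, 2.0))


class TestExceedance:
    def test_all_at_reference_is_zero(self):
        pbp0 = np.full(50, 100.0)
        out = fraction_over_10x(pbp0, pbp0)
        assert out["fraction"] == 0.0

    def test_half_at_twenty_fold(self):
        pbp0 = np.full(100, 10.0)
        pbp = np.concatenate([np.full(50, 200.0), np.full(50, 10.0)])
        assert fraction_over_10x(pbp, pbp0)["fraction"] == 0.5

    def test_known_exceedance_recovered(self):
        rng = np.random.default_rng(3)
        n = 4000
        pbp0 = np.full(n, 1.0)
        exceed = rng.random(n) < 0.30
        pbp = np.where(exceed, 100.0, 2.0)
        labels = np.arange(n) % 4
        out = fraction_over_10x(pbp, pbp0, replicate_labels=labels)
        se = np.sqrt(0.3 * 0.7 / n)
        assert abs(out["fraction"] - 0.30) <= 3 * se
        assert out["ci_low"] <= out["fraction"] <= out["ci_high"]


class TestSingleVsPaired:
    def test_identical_groups_not_distinguished(self):
        x = np.repeat(10 ** np.linspace(2, 5, 100), 1)
        out = compare_single_vs_paired(x, x, seed=0)
        assert out["wilcoxon_p"] > 0.9
        assert out["fisher_mc_p"] > 0.05

    def test_shifted_groups_detected(self):
        rng = np.random.default_rng(1)
        s = 10 ** rng.normal(3.5, 0.3, 200)
        m = s * 10.0
        out = compare_single_vs_paired(s, m, seed=0)
        assert out["wilcoxon_p"] < 0.001

    def test_colony_correction_identity(self):
        rng = np.random.default_rng(2)
        s = 10 ** rng.normal(3.5, 0.3, 300)
        k = 3.0
        out = compare_single_vs_paired(s, s * k, mean_colonies_per_multiple=k,
                                       seed=0)
        assert out["wilcoxon_p"] > 0.9

    def test_percentile_comparison_needs_replicates(self):
        x = 10 ** np.linspace(2, 5, 60)
        out = compare_single_vs_paired(x, x, replicate_labels_singles=np.zeros(60),
                                       replicate_labels_multiples=np.zeros(60))
        assert np.isnan(out["percentile75_p"])


class TestMCFisher:
    def test_matches_exact_fisher_on_2x2(self):
        table = np.array([[12, 3], [4, 11]])
        exact = stats.fisher_exact(table)[1]
        mc = mc_fisher(table, n_replicates=4000, seed=0)
        assert abs(mc - exact) < 0.03

    def test_independent_table_large_p(self):
        table = np.array([[50, 50, 50], [50, 50, 50]])
        assert mc_fisher(table, n_replicates=500, seed=1) > 0.5


class TestPairGrid:
    def test_equal_sizes_mass_at_zero_ratio(self):
        s = np.full(100, 1e3)
        _, ratios, profile = pair_grid_and_ratios(s, s)
        assert (ratios == 0).all()
        assert profile[0] == 1.0

    def test_binning_arithmetic(self):
        grid, ratios, _ = pair_grid_and_ratios(
            np.array([1e3]), np.array([1e5]), exclude_nongrowing=False)
        assert grid.counts[6, 10] == 1  # log10 3 -> bin [3.0,3.5), log10 5 -> [5.0,5.5)
        assert ratios[0] == pytest.approx(2.0)

    def test_grid_recount_oracle(self):
        rng = np.random.default_rng(4)
        s1 = 10 ** rng.uniform(0, 6, 5000)
        s2 = 10 ** rng.uniform(0, 6, 5000)
        grid, ratios, _ = pair_grid_and_ratios(s1, s2, exclude_nongrowing=False)
        assert grid.counts.sum() == 5000
        # brute-force recount
        edges = grid.bin_edges
        brute = np.zeros((12, 12))
        for a, b in zip(np.log10(s1), np.log10(s2)):
            i = min(int(a // 0.5), 11)
            j = min(int(b // 0.5), 11)
            brute[i, j] += 1
        np.testing.assert_array_equal(grid.counts, brute)

    def test_nongrowing_pairs_excluded(self):
        s1 = np.array([0.5, 100.0])
        s2 = np.array([100.0, 100.0])
        grid, ratios, _ = pair_grid_and_ratios(s1, s2, exclude_nongrowing=True)
        assert grid.counts.sum() == 1

    def test_simulation_bridge_shapes(self, small_sim):
        singles, p1, p2 = simulation_bead_sizes(
            small_sim.community_beads, small_sim.result_beads)
        assert len(p1) == len(p2)
        assert len(singles) + 2 * len(p1) == small_sim.community_beads.n_lineages


class TestGenerations:
    def test_log2_identity(self):
        assert estimate_generations(1024, 1) == 10.0
        assert estimate_generations(7, 7) == 0.0

    def test_shrinking_population_warns(self):
        with pytest.warns(UserWarning):
            assert estimate_generations(1, 2) == 0.0

    def test_geometry_variant(self):
        # d ratio 12.6 at packing 0.5: N ~ 0.5 * 12.6^3 ~ 1000 cells
        g = generations_from_geometry(12.6, 1.0, 0.5)
        assert g == pytest.approx(10.0, abs=0.05)

    def test_invalid_geometry(self):
        with pytest.raises(ValueError):
            generations_from_geometry(0.0, 1.0)
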
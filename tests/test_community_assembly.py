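import numpy as np
import pytest
from scipy import stats

from connectisim import (
    DeathModel,
    FounderCommunity,
    apply_death,
    assemble,
    assign_growth_rates,
    otu_probabilities,
    partition_beads,
    sample_founders,
)
from connectisim.community_assembly import MU_MAX, MU_MIN, draw_otu_rates
from connectisim.synthetic_community import OTUAbundanceTable


def make_table(counts):
    counts = np.atleast_2d(np.asarray(counts)).T
    return OTUAbundanceTable(
        otu_ids=[f"o{i}" for i in range(counts.shape[0])],
        counts=counts, replicate_ids=["r1"])


class TestProbabilities:
    @pytest.mark.parametrize("counts,expected", [
        ([50, 50], [50, 50]),
        ([1, 3], [25, 75]),
        ([1, 0, 0], [100, 0, 0]),
    ])
    def test_percent_values(self, counts, expected):
        np.testing.assert_allclose(
            otu_probabilities(make_table(counts), "r1"), expected)

    def test_sum_is_100(self, default_table):
        p = otu_probabilities(default_table, "R1")
        assert abs(p.sum() - 100.0) < 1e-9

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            otu_probabilities(make_table([0, 0]), "r1")


class TestFounderSampling:
    def test_degenerate_distribution(self):
        draws = sample_founders(np.array([100.0, 0.0]), 1000, seed=0)
        assert (draws == 0).all()

    def test_frequencies_match_probabilities(self):
        n = 200_000
        draws = sample_founders(np.array([50.0, 50.0]), n, seed=1)
        freq = (draws == 0).mean()
        se = np.sqrt(0.25 / n)
        assert abs(freq - 0.5) <= 5 * se

    def test_deterministic(self):
        p = np.array([30.0, 70.0])
        np.testing.assert_array_equal(
            sample_founders(p, 500, seed=9), sample_founders(p, 500, seed=9))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sample_founders(np.array([100.0]), 0, seed=0)
        with pytest.raises(ValueError):
            sample_founders(np.array([50.0]), 10, seed=0)


class TestRateAssignment:
    def test_bounds_both_modes(self):
        for mode in ("random", "abundance_proportional"):
            rates = draw_otu_rates(np.array([100]), mode, seed=0)
            assert MU_MIN <= rates[0] <= MU_MAX

    def test_abundant_otus_get_faster_rates_on_average(self):
        counts = np.array([100_000, 10])
        means = np.zeros(2)
        for s in range(500):
            means += draw_otu_rates(counts, "abundance_proportional", seed=s)
        means /= 500
        assert means[0] > means[1]

    def test_random_mode_uniform_marginal(self):
        rates = draw_otu_rates(np.ones(500, dtype=int), "random", seed=4)
        p = stats.kstest(rates, stats.uniform(MU_MIN, MU_MAX - MU_MIN).cdf).pvalue
        assert p > 0.01

    def test_proportional_mode_preserves_uniform_marginal(self):
        counts = np.random.default_rng(0).integers(1, 10**6, 500)
        rates = draw_otu_rates(counts, "abundance_proportional", seed=4)
        p = stats.kstest(rates, stats.uniform(MU_MIN, MU_MAX - MU_MIN).cdf).pvalue
        assert p > 0.01

    def test_unknown_mode_and_missing_otu(self, default_table):
        with pytest.raises(ValueError):
            draw_otu_rates(np.array([1]), "bogus", seed=0)
        community = FounderCommunity(
            otu_idx=np.array([default_table.n_otus + 5]),
            otu_ids=list(default_table.otu_ids),
            mu=np.array([0.1]), alive=np.ones(1, bool))
        with pytest.raises(ValueError):
            assign_growth_rates(community, default_table)

    def test_shared_rate_per_otu(self, default_table):
        community = FounderCommunity(
            otu_idx=np.array([3, 3, 7, 3]),
            otu_ids=list(default_table.otu_ids),
            mu=np.full(4, 0.1), alive=np.ones(4, bool))
        out = assign_growth_rates(community, default_table, seed=2)
        assert out.mu[0] == out.mu[1] == out.mu[3]


class TestDeath:
    def _community(self, mu):
        mu = np.asarray(mu, dtype=float)
        return FounderCommunity(
            otu_idx=np.zeros(len(mu), int), otu_ids=["o0"],
            mu=mu, alive=np.ones(len(mu), bool))

    def test_fast_biased_spares_slow_growers(self):
        c = self._community(np.full(100, 0.2))
        out = apply_death(c, DeathModel(mode="fast_biased"), seed=0)
        assert out.alive.all()

    def test_fast_biased_death_rate(self):
        n = 10_000
        c = self._community(np.full(n, 0.5))
        out = apply_death(c, DeathModel(mode="fast_biased", p_dead=0.85), seed=1)
        dead_frac = 1 - out.alive.mean()
        se = np.sqrt(0.85 * 0.15 / n)
        assert abs(dead_frac - 0.85) <= 3 * se

    def test_random_zero_probability(self):
        c = self._community(np.full(50, 0.3))
        out = apply_death(c, DeathModel(mode="random", p_dead=0.0), seed=2)
        assert out.alive.all()

    def test_conserves_lineages(self):
        c = self._community(np.linspace(0.01, 0.6, 100))
        out = apply_death(c, DeathModel(mode="random", p_dead=0.5), seed=3)
        assert out.n_lineages == 100

    def test_invalid_model(self):
        with pytest.raises(ValueError):
            DeathModel(mode="sometimes")
        with pytest.raises(ValueError):
            DeathModel(mode="random", p_dead=1.5)


class TestBeadPartition:
    def _community(self, n):
        return FounderCommunity(
            otu_idx=np.arange(n) % 7, otu_ids=[f"o{i}" for i in range(7)],
            mu=np.full(n, 0.3), alive=np.ones(n, bool))

    def test_all_singles(self):
        out = partition_beads(self._community(100), fraction_single=1.0, seed=0)
        assert (out.slot == 0).all()
        assert len(np.unique(out.bead_id)) == 100

    def test_default_split_matches_75_25(self):
        out = partition_beads(self._community(200_000), fraction_single=0.75, seed=1)
        n_singles = int((out.slot == 0).sum())
        n_pairs = int((out.slot == 1).sum())
        frac = n_singles / (n_singles + n_pairs)
        assert abs(frac - 0.75) < 0.01
        assert n_singles + 2 * n_pairs == 200_000

    def test_every_bead_holds_one_or_two(self):
        out = partition_beads(self._community(1001), fraction_single=0.6, seed=2)
        _, counts = np.unique(out.bead_id, return_counts=True)
        assert set(counts) <= {1, 2}

    def test_preserves_otu_multiset(self):
        c = self._community(500)
        out = partition_beads(c, seed=3)
        np.testing.assert_array_equal(np.sort(out.otu_idx), np.sort(c.otu_idx))

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            partition_beads(self._community(10), fraction_single=1.2)


class TestAssemble:
    def test_end_to_end_liquid_and_beads(self, default_table):
        liquid = assemble(default_table, n_cells=5000, environment="liquid",
                          death=DeathModel(mode="fast_biased"), seed=0)
        beads = assemble(default_table, n_cells=5000, environment="beads",
                         death=DeathModel(mode="fast_biased"), seed=0)
        assert liquid.n_lineages == beads.n_lineages == 5000
        assert (liquid.bead_id == -1).all()
        assert beads.environment == "beads"
        assert MU_MIN <= beads.mu.min() and beads.mu.max() <= MU_MAX

    def test_deterministic(self, default_table):
        a = assemble(default_table, n_cells=2000, seed=5)
        b = assemble(default_table, n_cells=2000, seed=5)
        np.testing.assert_array_equal(a.otu_idx, b.otu_idx)
        np.testing.assert_array_equal(a.mu, b.mu)

    def test_tsv_round_trip(self, default_table, tmp_path):
        c = assemble(default_table, n_cells=300, environment="beads", seed=1)
        path = tmp_path / "founders.tsv"
        c.to_tsv(path)
        back = FounderCommunity.from_tsv(path)
        np.testing.assert_allclose(np.sort(back.mu), np.sort(c.mu))
        np.testing.assert_array_equal(np.sort(back.bead_id), np.sort(c.bead_id))
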
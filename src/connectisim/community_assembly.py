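"""Assembly of the in-silico founder community.

Founder cells are sampled with replacement from the t=0 OTU distribution
(occurrence probability of OTU i is 100 * count_i / sum(counts)), receive one
maximum specific growth rate per OTU — either an independent uniform draw on
[0.01, 0.6] h^-1 or an abundance-coupled draw where more abundant OTUs tend to
receive faster rates — and may be flagged dead at the start, either at random
or preferentially among fast growers (mu > 0.25 h^-1, by default with 85%
probability). For the low-connectivity environment, cells are partitioned into
beads such that 75% of beads hold a single founder and 25% hold a pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_community import OTUAbundanceTable

MU_MIN = 0.01
MU_MAX = 0.6


@dataclass
class DeathModel:
    """Initial-death model applied to founder cells before growth.

    mode "none": everyone alive. "random": each lineage dead with ``p_dead``
    independently of genotype. "fast_biased": lineages with assigned rate
    above ``mu_threshold`` (default 0.25 h^-1) are dead with ``p_dead``
    (default 0.85); slower lineages stay alive.
    """

    mode: str = "none"
    p_dead: float = 0.85
    mu_threshold: float = 0.25

    def __post_init__(self) -> None:
        if self.mode not in ("none", "random", "fast_biased"):
            raise ValueError(f"unknown death mode {self.mode!r}")
        if not 0.0 <= self.p_dead <= 1.0:
            raise ValueError("p_dead must be in [0, 1]")


@dataclass
class FounderCommunity:
    """Vector representation of the founder cells (one entry per lineage).

    ``otu_idx`` indexes into ``otu_ids``; ``bead_id`` is -1 in the liquid
    environment; ``slot`` is 0 for liquid/single occupancy and 1 or 2 for the
    two partners of a paired bead.
    """

    otu_idx: np.ndarray
    otu_ids: list[str]
    mu: np.ndarray
    alive: np.ndarray
    environment: str = "liquid"
    bead_id: np.ndarray | None = None
    slot: np.ndarray | None = None
    source_table_ref: str = ""
    otu_counts: np.ndarray | None = None  # t=0 reads per OTU, for penalties/scenarios

    def __post_init__(self) -> None:
        n = len(self.otu_idx)
        if self.environment not in ("liquid", "beads"):
            raise ValueError("environment must be 'liquid' or 'beads'")
        if self.bead_id is None:
            self.bead_id = np.full(n, -1, dtype=np.int64)
        if self.slot is None:
            self.slot = np.zeros(n, dtype=np.int8)
        if len(self.mu) and (self.mu.min() < MU_MIN - 1e-12 or self.mu.max() > MU_MAX + 1e-12):
            raise ValueError("assigned rates outside [0.01, 0.6]")

    @property
    def n_lineages(self) -> int:
        return len(self.otu_idx)

    @property
    def is_paired(self) -> np.ndarray:
        return np.asarray(self.slot) > 0

    def lineage_counts(self) -> np.ndarray:
        """t=0 reads of each lineage's OTU (used by penalties/scenarios)."""
        if self.otu_counts is None:
            raise ValueError("community carries no source OTU counts")
        return self.otu_counts[self.otu_idx]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({
            "lineage_id": np.arange(self.n_lineages),
            "otu_id": [self.otu_ids[i] for i in self.otu_idx],
            "mu": self.mu,
            "alive": self.alive.astype(int),
            "bead_id": self.bead_id,
            "slot": self.slot,
        })
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, environment: str = "beads") -> "FounderCommunity":
        df = pd.read_csv(path, sep="\t", dtype={"otu_id": str})
        ids = sorted(df["otu_id"].unique())
        idx = {o: i for i, o in enumerate(ids)}
        return cls(
            otu_idx=df["otu_id"].map(idx).to_numpy(),
            otu_ids=ids,
            mu=df["mu"].to_numpy(float),
            alive=df["alive"].to_numpy(bool),
            environment=environment,
            bead_id=df["bead_id"].to_numpy(np.int64),
            slot=df["slot"].to_numpy(np.int8),
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def otu_probabilities(table: OTUAbundanceTable, replicate: str | int) -> np.ndarray:
    """Occurrence probability (in percent) of each OTU in one replicate:
    P(OTU_i) = 100 * count_i / sum(counts). Sums to 100."""
    counts = table.replicate_counts(replicate).astype(float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("replicate has zero total reads")
    return 100.0 * counts / total


def sample_founders(probabilities: np.ndarray, n_cells: int, seed: int) -> np.ndarray:
    """Sample ``n_cells`` founder OTU indices with replacement from a percent
    probability vector."""
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    p = np.asarray(probabilities, dtype=float)
    if not np.isclose(p.sum(), 100.0, atol=1e-6):
        raise ValueError("probabilities must sum to 100")
    rng = np.random.default_rng(seed)
    return rng.choice(len(p), size=n_cells, replace=True, p=p / p.sum())


def draw_otu_rates(
    counts: np.ndarray, mode: str, seed: int
) -> np.ndarray:
    """One growth rate per OTU, uniform marginal on [0.01, 0.6] h^-1.

    "random": independent uniform per OTU. "abundance_proportional": the same
    uniform draws are rank-coupled to abundance — OTUs are ordered by weighted
    sampling without replacement (weights ~ log10(reads+1), Gumbel top-k) and
    the sorted rates are assigned in descending order, so abundant OTUs tend
    to receive the faster rates while the marginal stays uniform.
    """
    if mode not in ("random", "abundance_proportional"):
        raise ValueError(f"unknown rate mode {mode!r}")
    rng = np.random.default_rng(seed)
    n = len(counts)
    rates = rng.uniform(MU_MIN, MU_MAX, n)
    if mode == "random":
        return rates
    w = np.log10(np.asarray(counts, float) + 1.0)
    w = np.maximum(w, 1e-9)
    # Gumbel-max trick: keys sorted descending give a weighted sampling
    # without replacement order
    keys = np.log(w) + rng.gumbel(size=n)
    order = np.argsort(-keys)
    out = np.empty(n)
    out[order] = np.sort(rates)[::-1]
    return out


def assign_growth_rates(
    community: FounderCommunity,
    table: OTUAbundanceTable,
    mode: str = "abundance_proportional",
    seed: int = 0,
    replicate: str | int | None = None,
) -> FounderCommunity:
    """Assign per-OTU growth rates onto all lineages of the community.

    Abundances for the coupling come from ``replicate`` if given, else from
    the summed replicate counts.
    """
    if community.otu_idx.max(initial=-1) >= table.n_otus:
        raise ValueError("lineage references OTU absent from table")
    counts = (table.replicate_counts(replicate) if replicate is not None
              else table.counts.sum(axis=1))
    rates = draw_otu_rates(counts, mode, seed)
    out = replace(community, mu=rates[community.otu_idx])
    out.otu_counts = np.asarray(counts)
    return out


def apply_death(community: FounderCommunity, model: DeathModel, seed: int = 0
                ) -> FounderCommunity:
    """Flag founder lineages dead at the start according to the death model."""
    rng = np.random.default_rng(seed)
    n = community.n_lineages
    if model.mode == "none":
        alive = np.ones(n, dtype=bool)
    elif model.mode == "random":
        alive = rng.random(n) >= model.p_dead
    else:  # fast_biased
        fast = community.mu > model.mu_threshold
        dead = fast & (rng.random(n) < model.p_dead)
        alive = ~dead
    return replace(community, alive=alive)


def partition_beads(community: FounderCommunity, fraction_single: float = 0.75,
                    seed: int = 0) -> FounderCommunity:
    """Partition lineages into beads with the given single-occupancy fraction.

    The cell budget is fixed; bead counts are derived from it: with N cells
    and a fraction f of single-occupancy beads, n_pairs = round(N(1-f)/(2-f))
    and n_singles = N - 2 n_pairs, so the bead-level fraction of singles is f
    up to rounding. Lineages are randomly permuted before assignment; every
    lineage lands in exactly one bead.
    """
    if not 0.0 <= fraction_single <= 1.0:
        raise ValueError("fraction_single must be in [0, 1]")
    n = community.n_lineages
    if n < 2:
        raise ValueError("need at least two lineages")
    rng = np.random.default_rng(seed)
    n_pairs = int(round(n * (1.0 - fraction_single) / (2.0 - fraction_single)))
    n_pairs = min(n_pairs, n // 2)
    n_singles = n - 2 * n_pairs

    perm = rng.permutation(n)
    bead_id = np.empty(n, dtype=np.int64)
    slot = np.empty(n, dtype=np.int8)
    # singles first
    bead_id[perm[:n_singles]] = np.arange(n_singles)
    slot[perm[:n_singles]] = 0
    pair_members = perm[n_singles:]
    pair_beads = n_singles + np.repeat(np.arange(n_pairs), 2)
    bead_id[pair_members] = pair_beads
    slot[pair_members] = np.tile([1, 2], n_pairs)
    return replace(community, environment="beads", bead_id=bead_id, slot=slot)


def assemble(
    table: OTUAbundanceTable,
    replicate: str | int | None = None,
    n_cells: int = 200_000,
    environment: str = "liquid",
    rate_mode: str = "abundance_proportional",
    death: DeathModel | None = None,
    fraction_single: float = 0.75,
    seed: int = 0,
) -> FounderCommunity:
    """End-to-end founder-community assembly from an OTU table.

    Samples ``n_cells`` founders from the occurrence probabilities of
    ``replicate`` (or of the summed replicates), assigns rates, applies the
    death model, and partitions into beads if requested. Sub-stage seeds are
    derived deterministically from ``seed``.
    """
    ss = np.random.SeedSequence(seed).spawn(4)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss]
    counts = (table.replicate_counts(replicate) if replicate is not None
              else table.counts.sum(axis=1))
    probs = 100.0 * counts / counts.sum()
    founders = sample_founders(probs, n_cells, seeds[0])
    community = FounderCommunity(
        otu_idx=founders,
        otu_ids=list(table.otu_ids),
        mu=np.full(n_cells, MU_MIN),
        alive=np.ones(n_cells, dtype=bool),
        environment="liquid",
        source_table_ref=str(replicate) if replicate is not None else "pooled",
    )
    community = assign_growth_rates(community, table, rate_mode, seeds[1], replicate)
    if death is not None:
        community = apply_death(community, death, seeds[2])
    if environment == "beads":
        community = partition_beads(community, fraction_single, seeds[3])
    return community
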
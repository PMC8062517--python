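"""Synthetic OTU abundance tables and bead/microcolony observation tables.

A washed sand community is sequenced in several biological replicates; each
replicate detects only part of the underlying OTU pool, so the union richness
over replicates substantially exceeds the per-replicate richness (roughly
1200 OTUs over 7 replicates versus ~543 per replicate). The generator here
emulates that structure: a heavy-tailed (log-normal) master abundance
distribution, per-replicate detection thinning that increases with abundance,
and multinomial read sampling at fixed depth.

The bead-table generator emits per-bead microcolony observations (area and
mean fluorescence intensity per colony) with a controlled mixture of the four
pair-interaction categories, so the productivity analytics can be exercised
against known ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

PAIR_CATEGORIES = ("both_no_growth", "one_not_growing", "balanced", "imbalanced")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class OTUAbundanceTable:
    """OTU read counts per replicate, with an optional master (pooled) column.

    Parameters
    ----------
    otu_ids:
        Opaque string identifiers, one per OTU row.
    counts:
        Integer array of shape ``(n_otus, n_replicates)``; all entries >= 0.
    replicate_ids:
        One label per column of ``counts``.
    taxon_labels:
        Optional opaque taxonomy strings (not interpreted anywhere).
    master_counts:
        Optional underlying pool counts the replicates were thinned from.
    """

    otu_ids: list[str]
    counts: np.ndarray
    replicate_ids: list[str]
    taxon_labels: list[str] | None = None
    master_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (n_otus x n_replicates)")
        if self.counts.shape != (len(self.otu_ids), len(self.replicate_ids)):
            raise ValueError("counts shape inconsistent with ids")
        if len(self.replicate_ids) < 1:
            raise ValueError("at least one replicate required")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.counts.shape[1]

    def replicate_index(self, replicate: str | int) -> int:
        if isinstance(replicate, str):
            return self.replicate_ids.index(replicate)
        return int(replicate)

    def replicate_counts(self, replicate: str | int) -> np.ndarray:
        return self.counts[:, self.replicate_index(replicate)]

    def richness_per_replicate(self) -> np.ndarray:
        """Number of OTUs with count > 0 in each replicate."""
        return (self.counts > 0).sum(axis=0)

    def union_richness(self) -> int:
        """Number of OTUs detected in at least one replicate."""
        return int((self.counts > 0).any(axis=1).sum())

    def relative_abundances(self) -> np.ndarray:
        """Per-replicate relative abundances (columns sum to 1)."""
        totals = self.counts.sum(axis=0, keepdims=True).astype(float)
        if np.any(totals == 0):
            raise ValueError("replicate with zero total reads")
        return self.counts / totals

    # -- TSV round trip ----------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.counts, columns=self.replicate_ids)
        df.insert(0, "otu_id", self.otu_ids)
        df.insert(1, "taxon", self.taxon_labels if self.taxon_labels is not None
                  else ["NA"] * self.n_otus)
        if self.master_counts is not None:
            df.insert(2, "master", self.master_counts)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OTUAbundanceTable":
        df = pd.read_csv(path, sep="\t", dtype={"otu_id": str, "taxon": str})
        master = df.pop("master").to_numpy() if "master" in df.columns else None
        otu_ids = df.pop("otu_id").tolist()
        taxa = df.pop("taxon").tolist()
        return cls(
            otu_ids=otu_ids,
            counts=df.to_numpy(),
            replicate_ids=list(df.columns),
            taxon_labels=taxa,
            master_counts=master,
        )


@dataclass
class CommunityGeneratorConfig:
    """Calibration of the synthetic sand-community generator.

    Defaults are calibrated so that 7 replicates reach a union richness of
    about 1200 OTUs with a mean per-replicate richness of about 543, matching
    the sequenced starting community. ``detection_midpoint``/``detection_hill``
    parameterize the probability that an OTU is detectable in one replicate as
    a Hill function of its log10 master abundance; a custom
    ``replicate_detection_prob`` (callable of the count vector returning
    probabilities) overrides them.
    """

    n_otus_master: int = 1500
    lognormal_mu: float = 1.5
    lognormal_sigma: float = 0.8
    n_replicates: int = 7
    per_replicate_depth: int = 40_000
    detection_midpoint: float = 1.9
    detection_hill: float = 2.0
    replicate_detection_prob: Callable[[np.ndarray], np.ndarray] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_otus_master <= 0:
            raise ValueError("n_otus_master must be positive")
        if self.per_replicate_depth <= 0:
            raise ValueError("per_replicate_depth must be positive")
        if self.lognormal_sigma <= 0:
            raise ValueError("lognormal_sigma must be positive")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")

    def detection_probabilities(self, master_counts: np.ndarray) -> np.ndarray:
        if self.replicate_detection_prob is not None:
            p = np.asarray(self.replicate_detection_prob(master_counts), dtype=float)
        else:
            lg = np.log10(np.maximum(master_counts, 1.0))
            h = self.detection_hill
            p = lg**h / (self.detection_midpoint**h + lg**h)
        return np.clip(p, 0.0, 1.0)


# ---------------------------------------------------------------------------
# community generator
# ---------------------------------------------------------------------------

def generate_master_distribution(
    config: CommunityGeneratorConfig, seed: int | None = None
) -> OTUAbundanceTable:
    """Draw a master OTU pool and thinned replicate read-count columns.

    Master abundances are log-normal: log10 counts ~ Normal(mu, sigma),
    rounded to integers (floor 1 read). Each replicate keeps an OTU with its
    detection probability, then assigns ``per_replicate_depth`` reads
    multinomially among the detected OTUs proportionally to master abundance.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    x = rng.normal(config.lognormal_mu, config.lognormal_sigma, config.n_otus_master)
    master = np.maximum(np.rint(10.0**x), 1).astype(np.int64)
    det = config.detection_probabilities(master)
    p_master = master / master.sum()

    cols = np.zeros((config.n_otus_master, config.n_replicates), dtype=np.int64)
    for r in range(config.n_replicates):
        present = rng.random(config.n_otus_master) < det
        if not present.any():
            continue
        pw = np.where(present, p_master, 0.0)
        pw = pw / pw.sum()
        cols[:, r] = rng.multinomial(config.per_replicate_depth, pw)

    otu_ids = [f"OTU{i:05d}" for i in range(config.n_otus_master)]
    reps = [f"R{r + 1}" for r in range(config.n_replicates)]
    return OTUAbundanceTable(
        otu_ids=otu_ids, counts=cols, replicate_ids=reps, master_counts=master
    )


@dataclass
class DistributionSummary:
    richness_per_replicate: np.ndarray
    union_richness: int
    log10_hist_edges: np.ndarray
    log10_hist_density: np.ndarray

    @property
    def mean_richness(self) -> float:
        return float(np.mean(self.richness_per_replicate))


def summarize_distribution(
    table: OTUAbundanceTable, bins: int = 24, log10_range: tuple[float, float] = (0.0, 6.0)
) -> DistributionSummary:
    """Per-replicate richness, union richness and a normalized log10-abundance
    histogram of the pooled (summed) replicate counts."""
    if table.n_otus == 0:
        raise ValueError("empty table")
    pooled = table.counts.sum(axis=1)
    nz = pooled[pooled > 0]
    hist, edges = np.histogram(np.log10(nz), bins=bins, range=log10_range)
    total = hist.sum()
    density = hist / total if total > 0 else hist.astype(float)
    return DistributionSummary(
        richness_per_replicate=table.richness_per_replicate(),
        union_richness=table.union_richness(),
        log10_hist_edges=edges,
        log10_hist_density=density,
    )


# ---------------------------------------------------------------------------
# bead observation tables
# ---------------------------------------------------------------------------

@dataclass
class BeadObservationTable:
    """Long-format per-colony observations for a set of beads.

    One row per microcolony: ``bead_id, time_h, condition, colony_idx,
    area_px, mean_intensity, channel``. Beads without colonies appear with a
    single row of zero area convention is NOT used; empty beads are recorded
    in ``empty_beads`` instead so areas stay strictly positive.
    """

    records: pd.DataFrame
    empty_beads: list[str] = field(default_factory=list)

    COLUMNS = ["bead_id", "time_h", "condition", "colony_idx",
               "area_px", "mean_intensity", "channel"]

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if len(self.records) and (self.records["area_px"] <= 0).any():
            raise ValueError("areas must be positive")
        if len(self.records) and (self.records["mean_intensity"] < 0).any():
            raise ValueError("intensities must be non-negative")

    @property
    def bead_ids(self) -> list[str]:
        return list(dict.fromkeys(list(self.records["bead_id"]) + self.empty_beads))

    def to_tsv(self, path: str | Path) -> None:
        df = self.records[self.COLUMNS].copy()
        if self.empty_beads:
            pad = pd.DataFrame({
                "bead_id": self.empty_beads,
                "time_h": np.nan, "condition": "empty", "colony_idx": -1,
                "area_px": np.nan, "mean_intensity": np.nan, "channel": "none",
            })
            df = pd.concat([df, pad], ignore_index=True)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BeadObservationTable":
        df = pd.read_csv(path, sep="\t", dtype={"bead_id": str, "channel": str})
        empty = df[df["colony_idx"] == -1]["bead_id"].tolist()
        return cls(records=df[df["colony_idx"] != -1].reset_index(drop=True),
                   empty_beads=empty)


@dataclass
class PBPLevelParams:
    """Log10 per-colony productivity levels used by the bead generator.

    ``nogrowth_*`` parameterize a truncated normal below the no-growth
    threshold, ``growth_*`` one above it; ``balanced_max_logratio`` bounds the
    |log10 ratio| of balanced pairs, ``imbalanced_logratio`` the range beyond
    the balanced band used for imbalanced pairs.
    """

    nogrowth_mean: float = 2.4
    nogrowth_sd: float = 0.35
    growth_mean: float = 4.6
    growth_sd: float = 0.5
    threshold_log10: float = 3.25
    balanced_max_logratio: float = 0.85
    imbalanced_logratio: tuple[float, float] = (1.0, 2.2)


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, low: float,
                  high: float, size: int) -> np.ndarray:
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_bead_table(
    n_beads: int,
    occupancy_mix: float = 0.75,
    category_mix: Sequence[float] = (0.25, 0.30, 0.25, 0.20),
    pbp_level_params: PBPLevelParams | None = None,
    seed: int = 0,
    time_h: float = 72.0,
    condition: str = "synthetic",
) -> BeadObservationTable:
    """Emit a synthetic bead table with known pair-category composition.

    ``occupancy_mix`` is the fraction of single-occupancy beads; the remaining
    beads hold colony pairs drawn from the four interaction categories
    (both-no-growth, one-not-growing, balanced, imbalanced) with probabilities
    ``category_mix``. Per-colony productivity (area x mean intensity) is drawn
    on a log10 scale from ``pbp_level_params`` so that downstream
    classification recovers the requested mixture up to sampling error.
    """
    if not 0.0 <= occupancy_mix <= 1.0:
        raise ValueError("occupancy_mix must be in [0, 1]")
    category_mix = np.asarray(category_mix, dtype=float)
    if category_mix.shape != (4,) or np.any(category_mix < 0) or \
            not np.isclose(category_mix.sum(), 1.0):
        raise ValueError("category_mix must be 4 non-negative fractions summing to 1")
    if n_beads <= 0:
        raise ValueError("n_beads must be positive")
    pp = pbp_level_params or PBPLevelParams()
    rng = np.random.default_rng(seed)

    n_single = int(round(n_beads * occupancy_mix))
    n_pair = n_beads - n_single

    rows: list[tuple] = []

    def emit(bead: str, idx: int, log10_pbp: float, channel: str) -> None:
        # split PBP into area and intensity; area on a modest pixel range
        log_area = rng.uniform(0.7, 2.3)
        area = 10.0**log_area
        intensity = 10.0**log10_pbp / area
        rows.append((bead, time_h, condition, idx, area, intensity, channel))

    lo, hi = 0.0, 8.0
    thr = pp.threshold_log10
    for i in range(n_single):
        level = _trunc_normal(rng, pp.growth_mean, pp.growth_sd, lo, hi, 1)[0]
        emit(f"S{i:06d}", 0, level, "SC")

    cats = rng.choice(4, size=n_pair, p=category_mix)
    for i, cat in enumerate(cats):
        bead = f"P{i:06d}"
        if cat == 0:  # both below threshold
            lv = _trunc_normal(rng, pp.nogrowth_mean, pp.nogrowth_sd, lo, thr - 1e-9, 2)
        elif cat == 1:  # exactly one below
            a = _trunc_normal(rng, pp.nogrowth_mean, pp.nogrowth_sd, lo, thr - 1e-9, 1)[0]
            b = _trunc_normal(rng, pp.growth_mean, pp.growth_sd, thr + 1e-9, hi, 1)[0]
            lv = rng.permutation([a, b])
        elif cat == 2:  # both above, |log ratio| within the balanced band
            a = _trunc_normal(rng, pp.growth_mean, pp.growth_sd,
                              thr + pp.balanced_max_logratio, hi, 1)[0]
            d = rng.uniform(-pp.balanced_max_logratio, pp.balanced_max_logratio)
            lv = np.array([a, a + d])
        else:  # both above, ratio outside the balanced band
            a = _trunc_normal(rng, pp.growth_mean, pp.growth_sd,
                              thr + pp.imbalanced_logratio[1], hi, 1)[0]
            d = rng.uniform(*pp.imbalanced_logratio) * rng.choice([-1.0, 1.0])
            lv = np.array([a, a + d])
        emit(bead, 0, lv[0], "SC")
        emit(bead, 1, lv[1], "partner")

    df = pd.DataFrame(rows, columns=BeadObservationTable.COLUMNS)
    return BeadObservationTable(records=df)
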
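"""Stationary-phase readouts: subsampling, per-bead productivity (PBP),
pair-interaction categories, paired-growth grids and generation estimates.

Experimental PBP is the sum over a bead's microcolonies of colony area times
mean fluorescence intensity. The simulation-side analog is the final cell
count per lineage (unit intensity proxy); both feed the same classifiers.
Pairs are assigned to one of four categories (thresholds from the imaging
calibration): both partners below the no-growth level (log10 PBP < 3.25),
exactly one below, both growing with a PBP ratio within [0.125, 8]
("balanced"), or both growing but more imbalanced than that.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .community_assembly import FounderCommunity
from .growth_engine import GrowthParameters, SimulationResult
from .synthetic_community import BeadObservationTable, PAIR_CATEGORIES


# ---------------------------------------------------------------------------
# subsampling
# ---------------------------------------------------------------------------

def subsample(counts: np.ndarray, target: int, seed: int = 0
              ) -> tuple[np.ndarray, bool]:
    """Rarefy a count vector to ``target`` total without replacement
    (multivariate hypergeometric). Returns (counts, subsampled_flag); if the
    input total is below the target the vector is returned unchanged with
    flag False."""
    if target <= 0:
        raise ValueError("target must be positive")
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    c = np.rint(counts).astype(np.int64)
    total = int(c.sum())
    if total < target:
        return c, False
    if total == target:
        return c, True
    rng = np.random.default_rng(seed)
    if total < 1_000_000_000:
        out = rng.multivariate_hypergeometric(c, target, method="marginals")
    else:
        # numpy's hypergeometric samplers cap the population at 1e9; for
        # larger pools (where target << total and sampling without
        # replacement is indistinguishable from with replacement) draw a
        # capacity-capped multinomial instead: never exceeds input counts,
        # preserves zeros, exact total
        out = np.zeros_like(c)
        remaining = target
        while remaining > 0:
            cap = c - out
            draw = rng.multinomial(remaining, cap / cap.sum())
            draw = np.minimum(draw, cap)
            out += draw
            remaining = target - int(out.sum())
    return out, True


# ---------------------------------------------------------------------------
# PBP and pair categories
# ---------------------------------------------------------------------------

@dataclass
class PairThresholds:
    """Category thresholds: no-growth level (log10 PBP) and the balanced
    PBP-ratio band."""

    log10_pbp_nogrowth: float = 3.25
    balanced_ratio_bounds: tuple[float, float] = (0.125, 8.0)


def compute_pbp(table: BeadObservationTable) -> pd.DataFrame:
    """Per-bead productivity records from a bead observation table.

    Returns a DataFrame with columns ``bead_id, time_h, condition, pbp,
    n_colonies, occupancy_class``; PBP is the per-bead sum of colony area x
    mean intensity. Beads recorded as empty get PBP 0.
    """
    rec = table.records
    if len(rec) and ((rec["area_px"] <= 0).any() or (rec["mean_intensity"] < 0).any()):
        raise ValueError("invalid colony geometry")
    df = rec.assign(prod=rec["area_px"] * rec["mean_intensity"])
    agg = df.groupby("bead_id", sort=False).agg(
        time_h=("time_h", "first"),
        condition=("condition", "first"),
        pbp=("prod", "sum"),
        n_colonies=("colony_idx", "size"),
    ).reset_index()
    if table.empty_beads:
        pad = pd.DataFrame({
            "bead_id": table.empty_beads, "time_h": np.nan,
            "condition": "empty", "pbp": 0.0, "n_colonies": 0,
        })
        agg = pd.concat([agg, pad], ignore_index=True)
    agg["occupancy_class"] = np.where(agg["n_colonies"] <= 1, "single", "multiple")
    return agg


def classify_pair(pbp1: np.ndarray | float, pbp2: np.ndarray | float,
                  thresholds: PairThresholds | None = None) -> np.ndarray:
    """Classify partner PBP pairs into the four interaction categories.

    Vectorized; returns an array of category names (scalars in, scalar-shaped
    array out). Zero PBP maps below the no-growth threshold. Categories are
    exhaustive and mutually exclusive for any thresholds.
    """
    thr = thresholds or PairThresholds()
    p1 = np.atleast_1d(np.asarray(pbp1, dtype=float))
    p2 = np.atleast_1d(np.asarray(pbp2, dtype=float))
    if np.any(p1 < 0) or np.any(p2 < 0):
        raise ValueError("PBP values must be non-negative")
    cut = 10.0 ** thr.log10_pbp_nogrowth
    b1 = p1 < cut
    b2 = p2 < cut
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        ratio = np.where(p2 > 0, p1 / p2, np.inf)
    lo, hi = thr.balanced_ratio_bounds
    balanced = (~b1) & (~b2) & (ratio >= lo) & (ratio <= hi)
    out = np.full(p1.shape, "imbalanced", dtype=object)
    out[balanced] = "balanced"
    out[b1 ^ b2] = "one_not_growing"
    out[b1 & b2] = "both_no_growth"
    return out if out.size > 1 else out


def category_fractions(categories: np.ndarray) -> dict[str, float]:
    cats = np.asarray(categories)
    n = len(cats)
    return {c: float((cats == c).sum()) / n for c in PAIR_CATEGORIES}


def random_category_null(
    observed_percentages: dict[str, float] | dict[str, Sequence[float]],
    log10_bounds: tuple[float, float],
    n_points: int = 1000,
    n_repeats: int = 10_000,
    thresholds: PairThresholds | None = None,
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Compare observed category percentages to a uniform random scatter null.

    Each repeat scatters ``n_points`` pairs uniformly in the square
    ``log10_bounds`` x ``log10_bounds`` of log10 PBP, classifies them and
    records the category percentages. Observed scalars are compared to the
    null replicate distribution by a two-sided one-sample t-test; observed
    replicate vectors by a two-sided Welch t-test.
    """
    lo, hi = log10_bounds
    if not hi > lo:
        raise ValueError("degenerate log10 bounds")
    thr = thresholds or PairThresholds()
    rng = np.random.default_rng(seed)
    null_pct = {c: np.empty(n_repeats) for c in PAIR_CATEGORIES}
    for r in range(n_repeats):
        x = 10.0 ** rng.uniform(lo, hi, n_points)
        y = 10.0 ** rng.uniform(lo, hi, n_points)
        frac = category_fractions(classify_pair(x, y, thr))
        for c in PAIR_CATEGORIES:
            null_pct[c][r] = 100.0 * frac[c]
    out: dict[str, dict[str, float]] = {}
    for c, obs in observed_percentages.items():
        null = null_pct[c]
        obs_arr = np.atleast_1d(np.asarray(obs, dtype=float))
        if null.std() == 0 and (obs_arr.size < 2 or obs_arr.std() == 0):
            p = 1.0 if np.isclose(obs_arr.mean(), null.mean()) else 0.0
        elif obs_arr.size >= 2:
            p = stats.ttest_ind(obs_arr, null, equal_var=False)[1]
        else:
            p = stats.ttest_1samp(null, popmean=float(obs_arr[0]))[1]
        out[c] = {
            "observed": float(np.mean(obs_arr)),
            "null_mean": float(null.mean()),
            "null_sd": float(null.std(ddof=1)),
            "p_value": float(p),
        }
    return out


# ---------------------------------------------------------------------------
# exceedance fractions and single-vs-paired comparisons
# ---------------------------------------------------------------------------

def fraction_over_10x(
    pbp_t: np.ndarray,
    pbp_t0: np.ndarray,
    replicate_labels: np.ndarray | None = None,
    factor: float = 10.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict[str, float]:
    """Fraction of beads whose PBP exceeds ``factor`` times the t=0 cohort
    median, with a 95% CI.

    With replicate labels the CI is the normal approximation across
    per-replicate fractions; otherwise a bootstrap over beads. Returns NaNs
    if the class is empty.
    """
    pbp_t = np.asarray(pbp_t, dtype=float)
    pbp_t0 = np.asarray(pbp_t0, dtype=float)
    if pbp_t.size == 0 or pbp_t0.size == 0:
        return {"fraction": np.nan, "ci_low": np.nan, "ci_high": np.nan}
    ref = factor * np.median(pbp_t0)
    exceed = pbp_t > ref
    frac = float(exceed.mean())
    if replicate_labels is not None:
        labels = np.asarray(replicate_labels)
        per_rep = np.array([exceed[labels == g].mean() for g in np.unique(labels)])
        se = per_rep.std(ddof=1) / np.sqrt(len(per_rep)) if len(per_rep) > 1 else np.nan
        mean = float(per_rep.mean())
        return {"fraction": mean, "ci_low": mean - 1.96 * se,
                "ci_high": mean + 1.96 * se}
    rng = np.random.default_rng(seed)
    boots = np.array([
        exceed[rng.integers(0, len(exceed), len(exceed))].mean()
        for _ in range(n_boot)
    ])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {"fraction": frac, "ci_low": float(lo), "ci_high": float(hi)}


def _log_table_prob(table: np.ndarray) -> float:
    """Log hypergeometric probability of an RxC contingency table with its
    own margins (the quantity Fisher's exact test orders tables by)."""
    t = np.asarray(table, dtype=np.int64)
    return float(
        gammaln(t.sum(axis=1) + 1).sum() + gammaln(t.sum(axis=0) + 1).sum()
        - gammaln(t.sum() + 1) - gammaln(t + 1).sum()
    )


def mc_fisher(table: np.ndarray, n_replicates: int = 2000, seed: int = 0) -> float:
    """Monte-Carlo Fisher exact test for an RxC contingency table.

    Samples tables with the observed margins (Patefield algorithm) and
    returns (1 + #{P(sample) <= P(observed)}) / (n + 1), as the simulated
    p-value of R's fisher.test.
    """
    table = np.asarray(table, dtype=np.int64)
    rng = np.random.default_rng(seed)
    dist = stats.random_table(table.sum(axis=1), table.sum(axis=0))
    samples = dist.rvs(n_replicates, method="patefield", random_state=rng)
    obs = _log_table_prob(table)
    lp = np.array([_log_table_prob(s) for s in samples])
    return float((1 + np.sum(lp <= obs + 1e-9)) / (n_replicates + 1))


def compare_single_vs_paired(
    pbp_singles: np.ndarray,
    pbp_multiples: np.ndarray,
    mean_colonies_per_multiple: float = 1.0,
    replicate_labels_singles: np.ndarray | None = None,
    replicate_labels_multiples: np.ndarray | None = None,
    n_bins: int = 12,
    n_fisher_replicates: int = 2000,
    seed: int = 0,
) -> dict[str, float]:
    """Compare single-occupancy and multiple-occupancy PBP distributions.

    Multiple-occupancy PBPs are divided by the mean number of colonies per
    bead before comparison. Reports the Wilcoxon rank-sum p for the overall
    distributions, a rank-sum p on replicate-level 75th percentiles when
    replicate labels are supplied (skipped with a NaN if a group has < 2
    replicates), and a Monte-Carlo Fisher p on binned log10 distributions.
    """
    s = np.asarray(pbp_singles, dtype=float)
    m = np.asarray(pbp_multiples, dtype=float) / mean_colonies_per_multiple
    if s.size == 0 or m.size == 0:
        raise ValueError("both groups must be non-empty")
    w_stat, w_p = stats.ranksums(s, m)

    p75 = np.nan
    if replicate_labels_singles is not None and replicate_labels_multiples is not None:
        qs = [np.percentile(s[np.asarray(replicate_labels_singles) == g], 75)
              for g in np.unique(replicate_labels_singles)]
        qm = [np.percentile(m[np.asarray(replicate_labels_multiples) == g], 75)
              for g in np.unique(replicate_labels_multiples)]
        if len(qs) >= 2 and len(qm) >= 2:
            p75 = float(stats.ranksums(qs, qm)[1])

    both = np.log10(np.concatenate([s, m]) + 1.0)
    edges = np.histogram_bin_edges(both, bins=n_bins)
    hs, _ = np.histogram(np.log10(s + 1.0), bins=edges)
    hm, _ = np.histogram(np.log10(m + 1.0), bins=edges)
    cont = np.vstack([hs, hm])
    cont = cont[:, cont.sum(axis=0) > 0]
    fisher_p = mc_fisher(cont, n_fisher_replicates, seed)

    return {
        "wilcoxon_p": float(w_p),
        "wilcoxon_stat": float(w_stat),
        "percentile75_p": p75,
        "fisher_mc_p": fisher_p,
        "median_ratio": float(np.median(m) / np.median(s)) if np.median(s) > 0 else np.inf,
    }


# ---------------------------------------------------------------------------
# paired-growth grid and ratio profiles
# ---------------------------------------------------------------------------

@dataclass
class PairGrid:
    """12x12 counts of paired log10 sizes, each bin 0.5 wide over log10 0-6."""

    counts: np.ndarray
    bin_edges: np.ndarray

    def normalized(self) -> np.ndarray:
        total = self.counts.sum()
        return self.counts / total if total > 0 else self.counts.astype(float)


RATIO_EDGES = np.arange(0.0, 6.25, 0.5)


def pair_grid_and_ratios(
    sizes1: np.ndarray,
    sizes2: np.ndarray,
    exclude_nongrowing: bool = True,
    nogrowth_size: float = 1.0,
    log10_range: tuple[float, float] = (0.0, 6.0),
    n_bins: int = 12,
) -> tuple[PairGrid, np.ndarray, np.ndarray]:
    """Bin paired sizes into the 12x12 grid and build the ratio profile.

    Returns (grid, |log10 ratio| values, normalized ratio histogram on the
    0-6 half-log bins). Partners are unordered, so ratios are reported as
    max/min (>= 1, log10 >= 0). Pairs with a partner at or below
    ``nogrowth_size`` are dropped when ``exclude_nongrowing``; otherwise
    non-positive sizes are mapped to the smallest bin edge.
    """
    s1 = np.asarray(sizes1, dtype=float)
    s2 = np.asarray(sizes2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError("partner size vectors must align")
    if exclude_nongrowing:
        keep = (s1 > nogrowth_size) & (s2 > nogrowth_size)
        s1, s2 = s1[keep], s2[keep]
    floor = 10.0 ** log10_range[0]
    s1 = np.maximum(s1, floor)
    s2 = np.maximum(s2, floor)
    edges = np.linspace(*log10_range, n_bins + 1)
    grid, _, _ = np.histogram2d(np.log10(s1), np.log10(s2), bins=[edges, edges])
    ratios = np.abs(np.log10(s1) - np.log10(s2))
    hist, _ = np.histogram(ratios, bins=RATIO_EDGES)
    total = hist.sum()
    profile = hist / total if total > 0 else hist.astype(float)
    return PairGrid(counts=grid, bin_edges=edges), ratios, profile


# ---------------------------------------------------------------------------
# generations
# ---------------------------------------------------------------------------

def estimate_generations(final_cells: float, initial_cells: float = 1.0) -> float:
    """Generations of division: log2(final/initial); 0 (with a warning) if the
    population shrank."""
    if initial_cells < 1 or final_cells < 0:
        raise ValueError("cell counts must be >= 1 (initial) and >= 0 (final)")
    if final_cells < initial_cells:
        import warnings

        warnings.warn("final below initial; returning 0 generations", stacklevel=2)
        return 0.0
    return float(np.log2(final_cells / initial_cells))


def generations_from_geometry(colony_diameter: float, cell_diameter: float,
                              packing_fraction: float = 0.5) -> float:
    """Generations inferred from colony geometry: a round, packed colony holds
    N ~ packing * (d_colony/d_cell)^3 cells; generations = log2(N)."""
    if colony_diameter <= 0 or cell_diameter <= 0 or not 0 < packing_fraction <= 1:
        raise ValueError("invalid geometry")
    n_cells = packing_fraction * (colony_diameter / cell_diameter) ** 3
    return float(np.log2(max(n_cells, 1.0)))


# ---------------------------------------------------------------------------
# simulation-side bridge
# ---------------------------------------------------------------------------

def simulation_bead_sizes(
    community: FounderCommunity, result: SimulationResult
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-bead final cell counts from a bead-environment simulation.

    Returns (single-occupancy sizes, paired sizes slot 1, paired sizes
    slot 2), where size is the final cell count of the lineage (the
    simulation analog of PBP, with unit intensity proxy).
    """
    if community.environment != "beads":
        raise ValueError("community is not bead-partitioned")
    cells = result.final_cells
    single = ~community.is_paired
    singles = cells[single]
    p1_mask = community.slot == 1
    p2_mask = community.slot == 2
    order1 = np.argsort(community.bead_id[p1_mask], kind="stable")
    order2 = np.argsort(community.bead_id[p2_mask], kind="stable")
    return singles, cells[p1_mask][order1], cells[p2_mask][order2]
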
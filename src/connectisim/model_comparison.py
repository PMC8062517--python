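"""Simulation-versus-observation comparison and interaction-scenario ranking.

Agreement between simulated and observed OTU abundance distributions is
quantified by bootstrap Spearman rank correlation and by the fraction of OTUs
predicted within a two-fold or four-fold range. Binned size distributions
(single-occupancy histograms or flattened 12x12 pair grids) are compared by
PCA of the probability-normalized histograms. Paired-growth ratio profiles
are compared through a subsampled confidence-interval envelope: observed
probability mass below the simulated 5th percentile of a bin counts as
deficit, above the 95th as excess, aggregated over three ratio ranges
(smallest, mid, largest log10 ratios). Scenarios are ranked by the total
absolute deviation over the three ranges, with the PCA distance to the
observation as tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from .readout_pbp import RATIO_EDGES

DEFAULT_RATIO_RANGES = {
    "smallest": (0.0, 0.5),
    "mid": (0.5, 2.0),
    "largest": (2.0, 6.0),
}


def spearman_bootstrap(
    simulated: np.ndarray,
    observed: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict[str, float]:
    """Spearman rank correlation of relative abundances with a bootstrap CI.

    Vectors are matched on a common OTU universe (absent OTUs as zeros); the
    CI resamples OTUs with replacement (n_boot draws).
    """
    sim = np.asarray(simulated, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if sim.shape != obs.shape:
        raise ValueError("vectors must be matched on a common OTU universe")
    shared = (sim > 0) | (obs > 0)
    if shared.sum() < 3:
        raise ValueError("fewer than 3 shared OTUs")
    sim = sim / sim.sum()
    obs = obs / obs.sum()
    rho = float(stats.spearmanr(sim, obs)[0])
    rng = np.random.default_rng(seed)
    n = len(sim)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        r = stats.spearmanr(sim[idx], obs[idx])[0]
        boots[b] = r if np.isfinite(r) else 0.0
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {"rho": rho, "ci_low": float(lo), "ci_high": float(hi),
            "boot_sd": float(boots.std(ddof=1))}


def fold_accuracy(
    simulated: np.ndarray,
    observed: np.ndarray,
    folds: Sequence[float] = (2.0, 4.0),
) -> dict[float, float]:
    """Percentage of OTUs whose simulated relative abundance falls within a
    k-fold range of the observed one, for each k.

    OTUs absent from the observation are excluded (undefined ratio); OTUs
    observed but absent from the simulation count as failures at every fold.
    """
    sim = np.asarray(simulated, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if sim.shape != obs.shape:
        raise ValueError("vectors must be matched")
    keep = obs > 0
    if not keep.any():
        raise ValueError("no observed OTUs to compare")
    sim = sim / sim.sum() if sim.sum() > 0 else sim
    obs = obs / obs.sum()
    sim, obs = sim[keep], obs[keep]
    with np.errstate(divide="ignore"):
        ratio = np.where(sim > 0, sim / obs, 0.0)
    out = {}
    for k in folds:
        within = (ratio >= 1.0 / k) & (ratio <= k)
        out[float(k)] = 100.0 * float(within.mean())
    return out


def pca_histograms(histograms: np.ndarray, n_components: int | None = None
                   ) -> dict[str, np.ndarray]:
    """PCA of probability-normalized binned histograms (one dataset per row).

    Rows are normalized to sum 1, centered per bin (no scaling), and
    decomposed; returns scores and percent explained variance per component.
    """
    H = np.asarray(histograms, dtype=float)
    if H.ndim != 2 or H.shape[0] < 3:
        raise ValueError("need >= 3 datasets with a common bin structure")
    sums = H.sum(axis=1, keepdims=True)
    if np.any(sums == 0):
        raise ValueError("empty histogram row")
    H = H / sums
    if np.allclose(H, H[0]):
        raise ValueError("constant histogram matrix")
    n_components = n_components or min(H.shape[0] - 1, H.shape[1])
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(H)
    return {
        "scores": scores,
        "explained_pct": 100.0 * pca.explained_variance_ratio_,
        "components": pca.components_,
    }


def _profile_from_ratios(ratios: np.ndarray, edges: np.ndarray) -> np.ndarray:
    hist, _ = np.histogram(ratios, bins=edges)
    total = hist.sum()
    return hist / total if total > 0 else hist.astype(float)


@dataclass
class DeviationProfile:
    per_bin: np.ndarray          # signed deviation per bin (probability units)
    ranges: dict[str, float]     # signed percent deviation per named range
    envelope_low: np.ndarray
    envelope_high: np.ndarray

    @property
    def total_abs_deviation(self) -> float:
        return float(sum(abs(v) for v in self.ranges.values()))


def ci_deviation(
    observed_ratios: np.ndarray,
    simulated_ratio_sets: Sequence[np.ndarray],
    n_subsample: int = 1000,
    ranges: Mapping[str, tuple[float, float]] | None = None,
    edges: np.ndarray = RATIO_EDGES,
    n_envelope: int = 200,
    seed: int = 0,
) -> DeviationProfile:
    """Deficit/excess of an observed ratio profile against a simulated
    confidence envelope.

    For each of ``n_envelope`` draws, ``n_subsample`` ratios are resampled
    from a randomly chosen simulation repeat's ratio distribution and binned;
    the per-bin 5th/95th percentiles over draws form the envelope. Observed
    mass below the 5th percentile is a deficit (negative), above the 95th an
    excess (positive); deviations are aggregated (in percent probability
    mass) over the named log10-ratio ranges.
    """
    sims = [np.asarray(s, dtype=float) for s in simulated_ratio_sets]
    if len(sims) < 2:
        raise ValueError("need >= 2 simulation repeats")
    ranges = dict(ranges or DEFAULT_RATIO_RANGES)
    rng = np.random.default_rng(seed)
    n_bins = len(edges) - 1
    profiles = np.empty((n_envelope, n_bins))
    for i in range(n_envelope):
        src = sims[rng.integers(0, len(sims))]
        take = src[rng.integers(0, len(src), min(n_subsample, len(src)))]
        profiles[i] = _profile_from_ratios(take, edges)
    low = np.percentile(profiles, 5, axis=0)
    high = np.percentile(profiles, 95, axis=0)
    obs = _profile_from_ratios(np.asarray(observed_ratios, dtype=float), edges)
    dev = np.where(obs < low, obs - low, np.where(obs > high, obs - high, 0.0))
    centers = (edges[:-1] + edges[1:]) / 2
    agg = {}
    for name, (lo, hi) in ranges.items():
        mask = (centers >= lo) & (centers < hi)
        agg[name] = 100.0 * float(dev[mask].sum())
    return DeviationProfile(per_bin=dev, ranges=agg,
                            envelope_low=low, envelope_high=high)


def rank_scenarios(
    observed_ratios: np.ndarray,
    scenario_ratio_sets: Mapping[str, Sequence[np.ndarray]],
    n_subsample: int = 1000,
    ranges: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> list[dict[str, float]]:
    """Rank interaction scenarios by agreement with an observed ratio profile.

    Each scenario's simulation repeats are turned into a CI envelope; the
    scenario with the minimal total absolute deviation over the three ratio
    ranges ranks first. Ties are broken by the PCA distance between the
    observed profile and the scenario's mean profile. Deterministic given the
    seed.
    """
    obs_profile = _profile_from_ratios(np.asarray(observed_ratios, float), RATIO_EDGES)
    results = []
    mean_profiles = {}
    for i, (name, sims) in enumerate(sorted(scenario_ratio_sets.items())):
        dev = ci_deviation(observed_ratios, sims, n_subsample=n_subsample,
                           ranges=ranges, seed=seed + i)
        mean_profiles[name] = np.mean(
            [_profile_from_ratios(np.asarray(s, float), RATIO_EDGES) for s in sims],
            axis=0)
        results.append({"scenario": name, "total_abs_deviation": dev.total_abs_deviation,
                        **{f"dev_{k}": v for k, v in dev.ranges.items()}})
    # PCA distance tie-break (L2 in the centered histogram space)
    names = [r["scenario"] for r in results]
    mat = np.vstack([obs_profile] + [mean_profiles[n] for n in names])
    try:
        scores = pca_histograms(mat)["scores"]
        dists = np.linalg.norm(scores[1:] - scores[0], axis=1)
    except ValueError:  # constant matrix: all profiles identical
        dists = np.zeros(len(names))
    for r, d in zip(results, dists):
        r["pca_distance"] = float(d)
    results.sort(key=lambda r: (round(r["total_abs_deviation"], 12), r["pca_distance"]))
    for rank, r in enumerate(results, start=1):
        r["rank"] = rank
    return results
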
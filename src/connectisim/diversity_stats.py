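"""Alpha diversity of OTU count vectors and between-condition comparisons.

Five measures are computed per sample: richness (observed OTUs), Shannon
entropy (natural log), Simpson concentration (sum p_i^2), inverse Simpson and
Pielou evenness. Conditions are compared measure-by-measure with Welch's
unequal-variance t-test, reported as log10 p-values with the direction of the
change (diversity loss or gain in the comparison group).
"""

from __future__ import annotations

import zlib
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skbio.diversity import alpha as skb

MEASURES = ("richness", "shannon", "simpson", "inverse_simpson", "evenness")


def alpha_diversity(counts: np.ndarray) -> dict[str, float]:
    """The five alpha-diversity measures of one count vector."""
    c = np.asarray(counts)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    if c.sum() == 0:
        raise ValueError("all-zero count vector")
    c = c[c > 0]
    richness = int(skb.sobs(c))
    shannon = float(skb.shannon(c, base=np.e))
    simpson = float(skb.dominance(c))          # sum p_i^2
    inv_simpson = float(skb.enspie(c))         # 1 / sum p_i^2
    evenness = shannon / np.log(richness) if richness > 1 else 0.0
    return {
        "richness": richness,
        "shannon": shannon,
        "simpson": simpson,
        "inverse_simpson": inv_simpson,
        "evenness": float(evenness),
    }


def diversity_report(samples: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Alpha-diversity table for named count vectors (one row per sample)."""
    rows = []
    for name, counts in samples.items():
        row = {"sample": name}
        row.update(alpha_diversity(counts))
        rows.append(row)
    return pd.DataFrame(rows)


def _welch(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.allclose(a, a[0]) and np.allclose(b, b[0]):
        return 1.0 if np.isclose(a[0], b[0]) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False)[1])


def diversity_compare(
    group_a: pd.DataFrame | Sequence[dict],
    group_b: pd.DataFrame | Sequence[dict],
    measures: Iterable[str] = MEASURES,
) -> pd.DataFrame:
    """Welch t-test per measure between two groups of diversity rows.

    Returns a table with p, log10 p, and the direction of group B relative to
    group A ("loss" when B's mean is lower). Groups need >= 2 samples; two
    identical constant groups give p = 1.
    """
    a = pd.DataFrame(group_a)
    b = pd.DataFrame(group_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two samples")
    rows = []
    for m in measures:
        p = _welch(a[m].to_numpy(), b[m].to_numpy())
        direction = "loss" if b[m].mean() < a[m].mean() else (
            "gain" if b[m].mean() > a[m].mean() else "equal")
        rows.append({"measure": m, "p_value": p,
                     "log10_p": float(np.log10(p)) if p > 0 else -np.inf,
                     "direction": direction})
    return pd.DataFrame(rows)


def diversity_trajectory(
    condition_counts: Mapping[str, Sequence[np.ndarray]],
    subsample_to: int = 50_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Diversity measures per condition and repeat on subsampled OTU counts.

    ``condition_counts`` maps a condition name (e.g. "t0", "high", "low") to a
    list of per-repeat OTU count vectors; each vector is rarefied to
    ``subsample_to`` (hypergeometric, deterministic given the seed) before the
    measures are computed.
    """
    from .readout_pbp import subsample

    if any(len(v) < 1 for v in condition_counts.values()):
        raise ValueError("every condition needs at least one repeat")
    rows = []
    for cond, repeats in condition_counts.items():
        for r, counts in enumerate(repeats):
            sub, _ = subsample(np.asarray(counts), subsample_to,
                               seed=seed + 1009 * r + zlib.crc32(cond.encode()) % 100_003)
            row = {"condition": cond, "repeat": r}
            row.update(alpha_diversity(sub))
            rows.append(row)
    return pd.DataFrame(rows)
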
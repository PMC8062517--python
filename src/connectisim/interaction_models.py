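"""Growth-rate penalties and pairwise interaction scenarios.

Assigned maximum growth rates are transformed into effective rates before the
simulation starts. Single-occupancy lineages in beads receive a growth
penalty; lineages sharing a bead receive stochastic interaction factors drawn
from one of six global scenarios. All effective rates are capped at 0.6 h^-1,
and dead lineages get rate 0.

Penalty modes
-------------
``abundance_inverse`` (default): the rate is multiplied by an
abundance-dependent factor. With ``target="rare"`` (default) the penalty hits
low-abundance (hence, under abundance-coupled rate assignment, slow-growing)
taxa: f = min(1, log10(reads)/pivot) — the reading under which simulated
low-connectivity growth loses taxon richness relative to the suspended
culture, as observed. With ``target="abundant"`` the factor is
f = min(1, 1.2/log10(reads)), penalizing abundant taxa most when alone.
``verbatim_eq3`` replaces the rate by 1.2/log10(mu) with negative
results floored to zero; since log10(mu) < 0 for mu < 1 h^-1, this mode stops
growth of every single founder and is kept only as an explicit variant.

Scenarios (factors multiply the assigned rate, one independent draw per
partner in a pair)
------------------
null            : factor 1.
bimodal         : community split at log10 reads = 2.8; rare members draw a
                  factor U(0.01, 1.0), abundant members U(1.0, 2.2).
biased_positive : 40% chance U(0.4, 0.6) (lowering), 60% chance U(0.6, 1.4).
positive_on_slow: 40% chance the rate becomes -ln(mu) * mu (factor -ln(mu)),
                  improving slow growers; otherwise unchanged.
biased_negative : fast growers (mu > 0.15) hit at 20% chance, slower at 40%
                  chance, with a factor U(0.01, 0.1); otherwise unchanged.
random          : factor U(0.01, 1.25) always.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .community_assembly import FounderCommunity

MU_CAP = 0.6


@dataclass
class PenaltyModel:
    """Single-occupancy growth penalty.

    ``clamp`` keeps effective rates in [0, mu_cap] (always on in practice).
    """

    mode: str = "abundance_inverse"     # off | abundance_inverse | verbatim_eq3
    target: str = "rare"                # abundant | rare (abundance_inverse only)
    abundance_log10_knee: float = 1.2   # below 10^knee reads: no penalty
    rare_pivot_log10: float = 3.5       # "rare" variant: full rate above this
    mu_cap: float = MU_CAP

    def __post_init__(self) -> None:
        if self.mode not in ("off", "abundance_inverse", "verbatim_eq3"):
            raise ValueError(f"unknown penalty mode {self.mode!r}")
        if self.target not in ("abundant", "rare"):
            raise ValueError(f"unknown penalty target {self.target!r}")


def single_penalty(mu: np.ndarray | float, abundance: np.ndarray | float,
                   model: PenaltyModel) -> np.ndarray | float:
    """Apply the single-occupancy penalty to assigned rates.

    ``abundance`` is the t=0 read count of each lineage's OTU (>= 1).
    """
    mu = np.asarray(mu, dtype=float)
    a = np.asarray(abundance, dtype=float)
    if np.any(a < 1):
        raise ValueError("abundance must be >= 1 read")
    if model.mode == "off":
        out = mu.copy()
    elif model.mode == "abundance_inverse":
        lg = np.log10(a)
        if model.target == "abundant":
            with np.errstate(divide="ignore"):
                f = np.where(lg > model.abundance_log10_knee,
                             model.abundance_log10_knee / np.maximum(lg, 1e-12), 1.0)
        else:  # rare-targeted mirror
            f = np.minimum(1.0, lg / model.rare_pivot_log10)
        out = mu * f
    else:  # verbatim_eq3: mu -> 1.2/log10(mu), negative floored to 0
        with np.errstate(divide="ignore"):
            out = 1.2 / np.log10(mu)
        out = np.where(out < 0, 0.0, out)
    out = np.clip(out, 0.0, model.mu_cap)
    return out if out.ndim else float(out)


@dataclass
class InteractionScenario:
    """Named global interaction scenario with its parameters."""

    name: str
    parameters: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, val in self.parameters.items():
            if key.startswith("p_") and not 0.0 <= val <= 1.0:
                raise ValueError(f"probability {key} outside [0, 1]")
            if key.endswith("_range"):
                lo, hi = val
                if not (0 < lo < hi):
                    raise ValueError(f"range {key} must be positive and ordered")

    def factor_support(self) -> tuple[float, float]:
        """Smallest interval containing all multiplicative factors the
        scenario can emit (positive_on_slow support depends on mu in
        [0.01, 0.6]: factor is 1 or -ln(mu))."""
        p = self.parameters
        if self.name == "null":
            return (1.0, 1.0)
        if self.name == "bimodal":
            return (p["low_range"][0], p["high_range"][1])
        if self.name == "biased_positive":
            return (p["down_range"][0], p["up_range"][1])
        if self.name == "positive_on_slow":
            return (min(1.0, -np.log(0.6)), max(1.0, -np.log(0.01)))
        if self.name == "biased_negative":
            return (p["factor_range"][0], 1.0)
        if self.name == "random":
            return p["factor_range"]
        raise ValueError(f"unknown scenario {self.name!r}")


SCENARIOS: dict[str, InteractionScenario] = {
    "null": InteractionScenario("null"),
    "bimodal": InteractionScenario("bimodal", {
        "log10_abundance_threshold": 2.8,
        "low_range": (0.01, 1.0),
        "high_range": (1.0, 2.2),
    }),
    "biased_positive": InteractionScenario("biased_positive", {
        "p_down": 0.4,
        "down_range": (0.4, 0.6),
        "up_range": (0.6, 1.4),
    }),
    "positive_on_slow": InteractionScenario("positive_on_slow", {
        "p_boost": 0.4,
    }),
    "biased_negative": InteractionScenario("biased_negative", {
        "p_fast": 0.2,
        "p_slow": 0.4,
        "mu_threshold": 0.15,
        "factor_range": (0.01, 0.1),
    }),
    "random": InteractionScenario("random", {
        "factor_range": (0.01, 1.25),
    }),
}


def get_scenario(name: str) -> InteractionScenario:
    try:
        return SCENARIOS[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}") from None


def pair_factors(
    scenario: InteractionScenario,
    mu: np.ndarray,
    log10_abundance: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one multiplicative interaction factor per paired lineage.

    Vectorized over lineages; each partner draws independently. For
    ``positive_on_slow`` the applied branch corresponds to replacing mu by
    -ln(mu)*mu, i.e. a factor of -ln(mu).
    """
    mu = np.asarray(mu, dtype=float)
    n = len(mu)
    p = scenario.parameters
    if scenario.name == "null":
        return np.ones(n)
    if scenario.name == "bimodal":
        lo = rng.uniform(*p["low_range"], n)
        hi = rng.uniform(*p["high_range"], n)
        return np.where(np.asarray(log10_abundance) < p["log10_abundance_threshold"],
                        lo, hi)
    if scenario.name == "biased_positive":
        down = rng.uniform(*p["down_range"], n)
        up = rng.uniform(*p["up_range"], n)
        return np.where(rng.random(n) < p["p_down"], down, up)
    if scenario.name == "positive_on_slow":
        boost = -np.log(np.maximum(mu, 1e-12))
        return np.where(rng.random(n) < p["p_boost"], boost, 1.0)
    if scenario.name == "biased_negative":
        fast = mu > p["mu_threshold"]
        p_hit = np.where(fast, p["p_fast"], p["p_slow"])
        factor = rng.uniform(*p["factor_range"], n)
        return np.where(rng.random(n) < p_hit, factor, 1.0)
    if scenario.name == "random":
        return rng.uniform(*p["factor_range"], n)
    raise ValueError(f"unknown scenario {scenario.name!r}")


def apply_scenario(
    community: FounderCommunity,
    scenario: InteractionScenario | str,
    penalty: PenaltyModel | None = None,
    abundances: np.ndarray | None = None,
    seed: int = 0,
    mu_cap: float = MU_CAP,
) -> np.ndarray:
    """Compute effective growth rates for a bead-partitioned community.

    Single-occupancy lineages receive the penalty; paired lineages receive
    scenario factors. Every rate is clamped to [0, mu_cap]; dead lineages get
    0. ``abundances`` are per-lineage t=0 reads (default: taken from the
    community's source table counts).
    """
    if isinstance(scenario, str):
        scenario = get_scenario(scenario)
    if abundances is None:
        abundances = community.lineage_counts()
    abundances = np.asarray(abundances, dtype=float)
    rng = np.random.default_rng(seed)
    eff = community.mu.astype(float).copy()

    paired = community.is_paired
    single = ~paired
    if penalty is not None and penalty.mode != "off" and single.any():
        eff[single] = single_penalty(community.mu[single], abundances[single], penalty)
    if paired.any():
        factors = pair_factors(scenario, community.mu[paired],
                               np.log10(np.maximum(abundances[paired], 1.0)), rng)
        eff[paired] = community.mu[paired] * factors
    eff = np.clip(eff, 0.0, mu_cap)
    eff[~community.alive] = 0.0
    return eff
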
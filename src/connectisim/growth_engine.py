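"""Discrete-time Monod growth on a single shared substrate pool.

All lineages — whether suspended or enclosed in beads — draw on one global
carbon pool (beads restrict cell movement, not substrate diffusion). Each
step, the specific growth rate of lineage i is mu_i = mu_max,i * S/(Ks + S)
evaluated from the substrate concentration at step start; biomass grows
exactly exponentially within the step (X <- X * exp(mu * dt), continuous
biomass formation), and the carbon consumed is Delta X / yield, accounting for
CO2 loss. When substrate falls below S_min, growth stops. If a step would
overdraw the pool, all biomass increments are scaled proportionally so the
substrate lands exactly at zero, preserving relative competition.

Defaults correspond to the study conditions: Ks = 0.3e-6 g/ml, yield = 0.3
g biomass per g carbon, 120 fg per cell, S0 = 50 mg/ml, S_min = 3e-6 g/ml,
120 steps of 0.5 h (60 h total), 2e5 founder cells per ml.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .community_assembly import FounderCommunity

FG = 1e-15  # grams per femtogram


@dataclass
class GrowthParameters:
    """Kinetic and numerical constants of the growth engine (units in names)."""

    Ks: float = 0.3e-6            # g ml^-1, half-saturation
    yield_: float = 0.3           # g biomass per g carbon (CO2 loss implied)
    cell_mass_fg: float = 120.0   # fg per cell
    S0: float = 0.05              # g ml^-1 initial carbon (50 mg/ml)
    Smin: float = 3e-6            # g ml^-1, growth stops below this
    dt: float = 0.5               # h per step
    n_steps: int = 120            # 60 h total
    mu_cap: float = 0.6           # h^-1 global maximum rate
    volume_ml: float = 1.0

    def __post_init__(self) -> None:
        for name in ("Ks", "yield_", "cell_mass_fg", "S0", "Smin", "dt", "mu_cap",
                     "volume_ml"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_steps <= 0:
            raise ValueError("n_steps must be positive")
        if self.Smin >= self.S0:
            raise ValueError("Smin must be below S0")

    @property
    def cell_mass_g(self) -> float:
        return self.cell_mass_fg * FG

    @property
    def total_time_h(self) -> float:
        return self.n_steps * self.dt

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(
            {k: getattr(self, k) for k in self.__dataclass_fields__}))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GrowthParameters":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class SimulationResult:
    """Stationary-phase state of one simulation run."""

    final_biomass: np.ndarray          # g per lineage
    initial_biomass: np.ndarray        # g per lineage
    substrate_trajectory: np.ndarray   # g ml^-1, S after each step (S0 first)
    stop_step: int                     # first step with no growth (or n_steps)
    params: GrowthParameters
    max_conservation_error: float = 0.0

    @property
    def final_cells(self) -> np.ndarray:
        return self.final_biomass / self.params.cell_mass_g

    def per_bead_totals(self, community: FounderCommunity) -> dict[int, np.ndarray]:
        """Map bead_id -> array of per-slot final biomass (length 1 or 2)."""
        out: dict[int, list[float]] = {}
        for bid, x in zip(community.bead_id, self.final_biomass):
            out.setdefault(int(bid), []).append(float(x))
        return {k: np.asarray(v) for k, v in out.items()}


def monod_rate(mu_max: np.ndarray | float, S: float, params: GrowthParameters
               ) -> np.ndarray | float:
    """Monod kinetics: mu = mu_max * S / (Ks + S)."""
    if S < 0:
        raise ValueError("substrate concentration must be non-negative")
    return np.asarray(mu_max) * S / (params.Ks + S)


def biomass_to_cells(biomass_g: np.ndarray | float, params: GrowthParameters
                     ) -> np.ndarray | float:
    """Convert biomass (g) to cell numbers at constant cell mass."""
    b = np.asarray(biomass_g, dtype=float)
    if np.any(b < 0):
        raise ValueError("biomass must be non-negative")
    return b / params.cell_mass_g


def step(biomass: np.ndarray, growing: np.ndarray, rates: np.ndarray, S: float,
         params: GrowthParameters) -> tuple[np.ndarray, float]:
    """Advance one time step; returns (new biomass, new substrate).

    ``growing`` masks lineages that may grow (alive). No growth below S_min.
    """
    if S < params.Smin:
        return biomass, S
    mu = monod_rate(rates, S, params)
    dX = np.where(growing, biomass * np.expm1(mu * params.dt), 0.0)
    need = dX.sum() / (params.yield_ * params.volume_ml)
    if need > S:
        dX = dX * (S / need)  # proportional scaling onto the remaining carbon
        S_new = 0.0
    else:
        S_new = S - need
    return biomass + dX, S_new


def run(
    community: FounderCommunity,
    params: GrowthParameters | None = None,
    effective_rates: np.ndarray | None = None,
) -> SimulationResult:
    """Run the full simulation to stationary phase.

    ``effective_rates`` are the per-lineage rates after penalties/interactions
    (dead lineages may carry any value; they never grow). Defaults to the
    community's assigned rates. The engine itself is deterministic.
    """
    params = params or GrowthParameters()
    rates = community.mu if effective_rates is None else np.asarray(effective_rates)
    if len(rates) != community.n_lineages:
        raise ValueError("need one effective rate per lineage")
    if np.any(np.isnan(rates[community.alive])):
        raise ValueError("missing effective rate for a live lineage")
    rates = np.clip(rates, 0.0, params.mu_cap)

    X0 = np.full(community.n_lineages, params.cell_mass_g)
    X = X0.copy()
    growing = community.alive.copy()
    S = params.S0
    traj = np.empty(params.n_steps + 1)
    traj[0] = S
    stop_step = params.n_steps
    max_err = 0.0
    for t in range(params.n_steps):
        X_new, S_new = step(X, growing, rates, S, params)
        if S < params.Smin and stop_step == params.n_steps:
            stop_step = t
        X, S = X_new, S_new
        traj[t + 1] = S
        grown = (X - X0)[growing].sum()
        if grown > 0:
            err = abs((params.S0 - S) * params.volume_ml * params.yield_ - grown) / grown
            max_err = max(max_err, err)
    return SimulationResult(
        final_biomass=X,
        initial_biomass=X0,
        substrate_trajectory=traj,
        stop_step=stop_step,
        params=params,
        max_conservation_error=max_err,
    )
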
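"""End-to-end experiment orchestration.

One experiment = generate a synthetic t=0 community, assemble founder cells
into high-connectivity (suspension) and low-connectivity (bead) environments,
apply a death model, growth penalty and interaction scenario, run the Monod
growth engine, and derive the stationary-phase readouts (subsampled OTU
counts, per-bead sizes, paired-growth ratios, diversity measures). Every
stochastic stage derives its seed deterministically from the master seed, the
stage name and the repeat index, so whole experiments are reproducible from a
single integer.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import growth_engine, interaction_models, readout_pbp
from .community_assembly import DeathModel, FounderCommunity, assemble
from .diversity_stats import alpha_diversity
from .growth_engine import GrowthParameters
from .interaction_models import PenaltyModel, get_scenario
from .synthetic_community import (
    CommunityGeneratorConfig,
    OTUAbundanceTable,
    generate_master_distribution,
)

DEFAULT_SCENARIOS = ("null", "bimodal", "biased_positive", "positive_on_slow",
                     "biased_negative", "random")


def stage_seed(master_seed: int, stage: str, repeat: int = 0) -> int:
    """Deterministic per-stage seed derived from (master seed, stage name,
    repeat index); stays below 2^31."""
    ss = np.random.SeedSequence([master_seed, zlib.crc32(stage.encode()), repeat])
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class RunConfig:
    """Configuration of a full experiment (defaults are the study conditions)."""

    generator: CommunityGeneratorConfig = field(default_factory=CommunityGeneratorConfig)
    death: DeathModel = field(default_factory=lambda: DeathModel(mode="fast_biased"))
    penalty: PenaltyModel = field(default_factory=PenaltyModel)
    scenarios: tuple[str, ...] = DEFAULT_SCENARIOS
    growth: GrowthParameters = field(default_factory=GrowthParameters)
    n_cells: int = 200_000
    fraction_single: float = 0.75
    rate_mode: str = "abundance_proportional"
    subsample_reads: int = 50_000
    subsample_beads: int = 5_000
    n_repeats: int = 5
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        for s in self.scenarios:
            get_scenario(s)  # validate names before any compute


@dataclass
class RepeatResult:
    """All stage outputs of one repeat under one scenario."""

    scenario: str
    repeat: int
    table: OTUAbundanceTable
    community_beads: FounderCommunity
    community_liquid: FounderCommunity
    result_beads: growth_engine.SimulationResult
    result_liquid: growth_engine.SimulationResult
    otu_counts_t0: np.ndarray
    otu_counts_high: np.ndarray
    otu_counts_low: np.ndarray
    single_sizes: np.ndarray
    pair_sizes: tuple[np.ndarray, np.ndarray]
    ratios: np.ndarray


def _per_otu_cells(community: FounderCommunity, cells: np.ndarray, n_otus: int
                   ) -> np.ndarray:
    return np.bincount(community.otu_idx, weights=cells, minlength=n_otus)


def run_single_repeat(
    config: RunConfig, scenario: str, repeat: int,
    table: OTUAbundanceTable | None = None,
) -> RepeatResult:
    """Run one scenario/repeat; generates the community table unless given."""
    ms = config.master_seed
    if table is None:
        table = generate_master_distribution(
            config.generator, seed=stage_seed(ms, "community", repeat))

    liquid = assemble(
        table, n_cells=config.n_cells, environment="liquid",
        rate_mode=config.rate_mode, death=config.death,
        seed=stage_seed(ms, "assemble_liquid", repeat))
    beads = assemble(
        table, n_cells=config.n_cells, environment="beads",
        rate_mode=config.rate_mode, death=config.death,
        fraction_single=config.fraction_single,
        seed=stage_seed(ms, "assemble_beads", repeat))

    # high connectivity: assigned rates, no penalty or interactions
    eff_liquid = liquid.mu.copy()
    eff_liquid[~liquid.alive] = 0.0
    res_liquid = growth_engine.run(liquid, config.growth, eff_liquid)

    eff_beads = interaction_models.apply_scenario(
        beads, scenario, config.penalty,
        seed=stage_seed(ms, f"scenario_{scenario}", repeat),
        mu_cap=config.growth.mu_cap)
    res_beads = growth_engine.run(beads, config.growth, eff_beads)

    n_otus = table.n_otus
    t0 = np.bincount(beads.otu_idx, minlength=n_otus).astype(float)
    high = _per_otu_cells(liquid, res_liquid.final_cells, n_otus)
    low = _per_otu_cells(beads, res_beads.final_cells, n_otus)
    singles, p1, p2 = readout_pbp.simulation_bead_sizes(beads, res_beads)
    _, ratios, _ = readout_pbp.pair_grid_and_ratios(p1, p2, exclude_nongrowing=True)
    return RepeatResult(
        scenario=scenario, repeat=repeat, table=table,
        community_beads=beads, community_liquid=liquid,
        result_beads=res_beads, result_liquid=res_liquid,
        otu_counts_t0=t0, otu_counts_high=high, otu_counts_low=low,
        single_sizes=singles, pair_sizes=(p1, p2), ratios=ratios,
    )


def _summary_row(config: RunConfig, rr: RepeatResult) -> dict[str, Any]:
    beads = rr.community_beads
    single_mask = ~beads.is_paired
    bead_biomass = rr.result_beads.final_biomass
    n_single_beads = int(single_mask.sum())
    n_pair_beads = int(beads.is_paired.sum()) // 2
    mean_single = bead_biomass[single_mask].sum() / max(n_single_beads, 1)
    mean_pair = bead_biomass[beads.is_paired].sum() / max(n_pair_beads, 1)
    sub_low, _ = readout_pbp.subsample(
        rr.otu_counts_low, config.subsample_reads,
        seed=stage_seed(config.master_seed, "subsample_low", rr.repeat))
    sub_high, _ = readout_pbp.subsample(
        rr.otu_counts_high, config.subsample_reads,
        seed=stage_seed(config.master_seed, "subsample_high", rr.repeat))
    div_low = alpha_diversity(sub_low)
    div_high = alpha_diversity(sub_high)
    return {
        "scenario": rr.scenario,
        "repeat": rr.repeat,
        "stop_step_beads": rr.result_beads.stop_step,
        "mean_single_bead_biomass": float(mean_single),
        "mean_pair_bead_biomass": float(mean_pair),
        "pair_to_single_ratio": float(mean_pair / mean_single) if mean_single > 0
        else np.inf,
        **{f"low_{k}": v for k, v in div_low.items()},
        **{f"high_{k}": v for k, v in div_high.items()},
    }


def run_experiment(config: RunConfig, out_dir: str | Path | None = None
                   ) -> pd.DataFrame:
    """Run every scenario for every repeat; returns the summary table.

    With ``out_dir`` set, per-stage outputs (OTU tables, founder tables,
    per-OTU stationary counts, summary, manifest) are written as TSV/JSON.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    rows = []
    for repeat in range(config.n_repeats):
        table = generate_master_distribution(
            config.generator, seed=stage_seed(config.master_seed, "community", repeat))
        if out is not None:
            table.to_tsv(out / f"otu_table_rep{repeat}.tsv")
        for scenario in config.scenarios:
            rr = run_single_repeat(config, scenario, repeat, table=table)
            rows.append(_summary_row(config, rr))
            if out is not None:
                np.savetxt(out / f"otu_cells_low_{scenario}_rep{repeat}.tsv",
                           rr.otu_counts_low, fmt="%.1f")
    summary = pd.DataFrame(rows)
    if out is not None:
        summary.to_csv(out / "summary.tsv", sep="\t", index=False)
        manifest = {
            "master_seed": config.master_seed,
            "n_repeats": config.n_repeats,
            "scenarios": list(config.scenarios),
            "n_cells": config.n_cells,
            "growth": {k: getattr(config.growth, k)
                       for k in config.growth.__dataclass_fields__},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return summary


# ---------------------------------------------------------------------------
# the full condition battery
# ---------------------------------------------------------------------------

SINGLE_OCCUPANCY_VARIANTS = {
    # penalty?, death?
    "DP": (True, True),
    "noDP": (True, False),
    "DnoP": (False, True),
    "noDnoP": (False, False),
}

PAIRED_CONDITIONS = {
    # name -> (scenario, death mode, penalty on)
    "null": ("null", "none", False),
    "prop_death_only": ("null", "fast_biased", False),
    "random_death_only": ("null", "random", False),
    "bimodal": ("bimodal", "fast_biased", True),
    "biased_positive": ("biased_positive", "fast_biased", True),
    "positive_on_slow": ("positive_on_slow", "fast_biased", True),
    "biased_negative": ("biased_negative", "fast_biased", True),
    "random": ("random", "fast_biased", True),
}


def scenario_recovery_experiment(
    truth: str,
    scenarios: Sequence[str] = DEFAULT_SCENARIOS,
    n_cells: int = 50_000,
    n_obs: int = 6,
    n_sim_repeats: int = 5,
    master_seed: int = 0,
) -> list[dict[str, Any]]:
    """Self-consistency check of the model-selection logic.

    Generates a synthetic "observation" by pooling the paired-growth ratios of
    ``n_obs`` independent runs under the ``truth`` scenario (the experimental
    reference pools six independent encapsulation series), simulates every
    candidate scenario ``n_sim_repeats`` times, and ranks the candidates
    against the observation. Returns the ranking; the experiment succeeds when
    ``truth`` ranks first.
    """
    from .model_comparison import rank_scenarios

    cfg_obs = RunConfig(master_seed=master_seed + 10_000, n_repeats=n_obs,
                        n_cells=n_cells)
    obs = np.concatenate([
        run_single_repeat(cfg_obs, truth, r).ratios for r in range(n_obs)])
    sims = {}
    cfg = RunConfig(master_seed=master_seed, n_repeats=n_sim_repeats,
                    n_cells=n_cells)
    for s in scenarios:
        sims[s] = [run_single_repeat(cfg, s, r).ratios
                   for r in range(n_sim_repeats)]
    return rank_scenarios(obs, sims, seed=master_seed)


def reproduce_paper_suite(
    out_dir: str | Path | None = None,
    n_cells: int = 50_000,
    n_repeats: int = 5,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Run the full simulation battery: the four single-occupancy variants
    (penalty/death on or off) and the paired-interaction condition set, each
    ``n_repeats`` times, and return the cross-condition summary table
    (one row per condition and repeat).
    """
    rows = []
    gen = CommunityGeneratorConfig()
    growth = GrowthParameters()
    for name, (penalty_on, death_on) in SINGLE_OCCUPANCY_VARIANTS.items():
        cfg = RunConfig(
            generator=gen,
            death=DeathModel(mode="fast_biased" if death_on else "none"),
            penalty=PenaltyModel(mode="abundance_inverse" if penalty_on else "off"),
            scenarios=("null",),
            growth=growth,
            n_cells=n_cells,
            fraction_single=1.0,
            n_repeats=n_repeats,
            master_seed=master_seed,
        )
        df = run_experiment(cfg)
        df.insert(0, "condition", f"single_{name}")
        rows.append(df)
    for name, (scenario, death_mode, penalty_on) in PAIRED_CONDITIONS.items():
        cfg = RunConfig(
            generator=gen,
            death=DeathModel(mode=death_mode),
            penalty=PenaltyModel(mode="abundance_inverse" if penalty_on else "off"),
            scenarios=(scenario,),
            growth=growth,
            n_cells=n_cells,
            fraction_single=0.75,
            n_repeats=n_repeats,
            master_seed=master_seed,
        )
        df = run_experiment(cfg)
        df.insert(0, "condition", name)
        rows.append(df)
    summary = pd.concat(rows, ignore_index=True)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "paper_suite_summary.tsv", sep="\t", index=False)
    return summary
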
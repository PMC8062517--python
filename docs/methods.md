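# Methods

## Overview

`connectisim` simulates the growth of a taxon-rich soil-derived community in
two habitat geometries that share all other conditions: a fully mixed
suspension ("high connectivity") and a population of micro-compartments
(beads) holding one or two founder cells each ("low connectivity"). Beads
restrict cell co-occurrence but not substrate diffusion, so all lineages in
both geometries draw on one global carbon pool. The package contains the
generator that produces statistically realistic t = 0 communities, the
assembly and growth model, the rate-modulation layer (death, penalties,
interaction scenarios), and the analytics used to compare simulated and
observed outcomes.

## Synthetic t = 0 community

The real starting community is characterized by its 16S amplicon profile:
roughly 1200 OTUs pooled over 7 replicates, mean per-replicate richness
543 ± 153, and a heavy-tailed ranked log₁₀-abundance distribution. Only
those summary features are published, not the generative law, so the
generator is a modeling choice:

- master abundances: log₁₀ counts ~ Normal(µ = 1.5, σ = 0.8) over 1500
  OTUs (counts floored at one read);
- per-replicate detection: an OTU is detectable in a replicate with a Hill
  probability in its log₁₀ master abundance (midpoint 1.9, exponent 2) —
  replicates share the master pool but differ in which rare taxa they catch;
- read assignment: 40,000 reads per replicate, multinomial over detected
  OTUs proportional to master abundance.

These defaults were calibrated once so that the two published richness
statistics are matched simultaneously (union ≈ 1200 given ~2.2× ratio of
union to per-replicate richness). What the generator does **not** emulate:
the large between-occasion variance of real replicates (the generated
per-replicate richness SD is ~10 OTUs, the published SD is 153, reflecting
communities washed on different occasions), real taxonomic structure, and
any phylogenetic correlation of abundances. Conclusions that depend on
replicate-to-replicate heterogeneity therefore cannot be read off the
synthetic tables.

The bead-observation generator is a fixture factory for the productivity
analytics: it emits per-colony (area, mean intensity) records whose products
follow truncated log-normal levels arranged to realize a requested mixture
of the four pair categories. It makes no attempt to model optics or
segmentation.

## Founder assembly

Founders are drawn with replacement from the occurrence probabilities
P(OTU_i) = 100·count_i/Σcounts. Each OTU receives one rate (all its
lineages grow identically):

- **random**: independent U(0.01, 0.6) h⁻¹ per OTU;
- **abundance-proportional** (default): the same uniform draws are
  rank-coupled to abundance. OTUs are ordered by weighted sampling without
  replacement (weights ∝ log₁₀(reads+1), Gumbel top-k) and sorted rates are
  assigned in descending order. This preserves the uniform marginal while
  making expected rate increase with abundance; the exact coupling used in
  the original study is not published, so this is one admissible scheme,
  exposed as a pluggable strategy.

Initial death is applied after rate assignment (the fast-biased mode needs
rates): mode `random` kills each lineage with probability p, mode
`fast_biased` kills lineages with µ > 0.25 h⁻¹ with probability 0.85.

Bead partition fixes the cell budget and derives bead counts: with N cells
and single-bead fraction f, n_pairs = round(N(1−f)/(2−f)); at the defaults
(N = 200,000, f = 0.75) that gives 120,000 single and 40,000 paired beads.

## Growth engine

Per step, rates are evaluated synchronously from the substrate at step start
(parallel update) and biomass grows exactly exponentially within the step:
X ← X·exp(µΔt). The consumed carbon is ΔX/yield; if a step would overdraw
the pool, all increments are scaled by a common factor so S lands at zero —
proportional scaling preserves relative competition, which matters for the
identity of the "winners". Below S_min growth stops. The update is exact in
the saturated regime (S ≫ K_s), conserves carbon to < 10⁻⁶ relative at
every step, and is deterministic; all stochasticity lives upstream.

The printed S₀ = 50 mg ml⁻¹ with yield 0.3 and 120 fg cells admits ~10¹¹
cells ml⁻¹ at depletion, above realistic experimental densities; the value
is used as stated and the discrepancy is inherited by design.

## Penalty direction

Two contradictory descriptions of the single-occupancy penalty circulate for
this model: "proportional to the initial OTU abundance" (hits abundant taxa)
versus "the slower the inherent growth rate, the more likely that OTU is
penalized" (hits slow, i.e. under abundance-coupled rates, rare taxa). Both
are implemented (`PenaltyModel.target = "abundant" | "rare"`), plus the
literal form µ ← 1.2/log₁₀(µ), which is negative for every µ < 1 h⁻¹ and
therefore stops all single-founder growth (kept as an explicit mode, never a
default). The default is `"rare"` (f = min(1, log₁₀(reads)/3.5)): it is the
only direction under which the simulation reproduces the model's published
qualitative outcome — stationary taxon richness low connectivity < high
connectivity < t = 0, significant by Welch's test across 5 repeats — and it
matches the prose description of the mechanism. The `"abundant"` form is
f = min(1, 1.2/log₁₀(reads)), with no penalty below 10^1.2 reads.

## Interaction scenarios

Factors multiply assigned rates, drawn independently per partner, applied
once at t = 0, and the result is capped at 0.6 h⁻¹:

| scenario | rule |
|---|---|
| null | factor 1 |
| bimodal | log₁₀ reads < 2.8: U(0.01, 1.0); otherwise U(1.0, 2.2) |
| biased_positive | 40%: U(0.4, 0.6); 60%: U(0.6, 1.4) |
| positive_on_slow | 40%: µ ← −ln(µ)·µ (boost > 1 only for µ < 1/e) |
| biased_negative | µ > 0.15: 20% chance, else 40% chance, of U(0.01, 0.1) |
| random | U(0.01, 1.25) |

The shape of the bimodal "interaction curve" is unpublished beyond its range
and threshold; two uniform modes split at the threshold are used, and the
distributions are configurable. Abundance thresholds are in log₁₀ read
counts (the 2.8 threshold is only consistent with that scale).

## Readouts and statistics

- **Subsampling** is multivariate hypergeometric (50,000 reads per OTU
  vector, 5,000 beads). numpy's samplers cap the population at 10⁹;
  stationary cell pools reach ~10¹¹, where a capacity-capped iterative
  multinomial is used instead (never exceeds input counts, preserves zeros,
  exact total; at target/total ≈ 5·10⁻⁷ the two laws are statistically
  indistinguishable).
- **PBP** is Σ(colony area × mean intensity) per bead; the simulation-side
  analog is the final cell count per lineage, with "no growth" meaning ≤ 1
  cell (no division) — both thresholds configurable.
- **Pair categories** use the no-growth cut 10^3.25 and balanced ratio band
  [0.125, 8]; partners are unordered, so size ratios are reported as
  max/min.
- **Diversity**: richness, Shannon (natural log), Simpson (Σp²), inverse
  Simpson, Pielou evenness — computed via scikit-bio. The original figure
  names "five alpha diversity measures" without listing them; this set is
  the conventional one. In this model the low-connectivity stationary
  community is *less rich but more even* than the high-connectivity one, so
  the low < high ordering holds for richness but can invert for
  entropy-based measures; analyses should state the measure used.
- **Monte-Carlo Fisher test** on binned PBP distributions: tables with the
  observed margins are sampled by the Patefield algorithm
  (`scipy.stats.random_table`) and p = (1 + #{P(table) ≤ P(observed)})/(n+1)
  with 2000 replicates, mirroring the standard simulated-p implementation.
- **Exceedance fractions** (PBP > 10× the t = 0 cohort median) use the
  cohort median at t = 0 as reference (the per-bead t = 0 value is not
  identifiable from end-point observation) and a normal-approximation CI
  across replicate fractions, with a bootstrap alternative.
- **Scenario ranking**: per scenario, 1000-ratio resamples from randomly
  chosen repeats build a per-bin 5th–95th percentile envelope of the
  |log₁₀| paired-size-ratio profile; observed mass below/above the envelope
  is deficit/excess, aggregated over three ranges (log₁₀ ratio [0, 0.5),
  [0.5, 2), [2, 6]; boundaries are a design default, configurable).
  Scenarios are ranked by total absolute deviation, PCA distance of mean
  profiles as tie-break. The recovery experiment pools six independent runs
  into the synthetic observation, mirroring the n = 6 experimental series;
  with single-run observations the profiles of similar scenarios
  (biased_positive vs random) are separated by less than sampling noise at
  50,000 cells.

## Seeding and problem sizes

Every stochastic stage derives its seed from
SeedSequence([master_seed, crc32(stage), repeat]); the engine itself is
deterministic, so whole experiments reproduce bit-for-bit from one integer.
Full-scale runs (200,000 cells, 120 steps) take well under a second each;
the test suite exercises the headline claims at full scale with 5 repeats
and uses 50,000-cell communities for the paired-interaction battery — the
scale at which the original paired simulations are reported.

## Known limitations

- No spatial structure inside beads, no diffusion limitation, no lag phase
  or maintenance energy; interactions are phenomenological constant rate
  multipliers fixed at t = 0.
- One global substrate pool also for beads (by construction), so bead-level
  substrate competition is not modeled.
- The generator matches richness means, not replicate heterogeneity; taxon
  labels are opaque strings with no phylogeny.
- Experimental image analysis (segmentation, channel alignment) is out of
  scope; analyses start from bead observation tables.
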
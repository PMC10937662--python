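# Methods

## Model representation and assumptions

A `FoodWebModel` is a steady-state, donor-receiver parameterization of
an ecosystem: functional groups of four kinds (living, nutrient pool,
detritus pool, fishing fleet), a square diet-composition matrix
`DC[prey, predator]`, a landings matrix, and pedigree CVs on every
parameter. The master balance is the Ecopath identity with import,
export and biomass accumulation fixed at zero:

    B_i (P/B)_i EE_i = Σ_j B_j (Q/B)_j DC[i,j] + Σ_f Y[i,f]

Primary producers are represented as consumers of nutrient pools
(`Q/B > 0`, diet supported on nutrient rows), so a single
production-fate machinery covers every living group, mirroring
end-to-end (nutrient-to-fleet) model designs. Units are declared
model-level tags (default `mt km^-2` and `yr^-1`); every derived
quantity is unit-covariant, so no conversion is attempted.

Key structural invariants, enforced by `validate_model` and preserved
by every editing operation (aggregation, trace insertion, pruning,
Monte Carlo draws): consumer diet columns sum to 1 within 1e-9
(columns are silently renormalized when drift is below 1e-6 and
rejected above); `pb ≤ ae·qb` for living groups; non-living groups
never appear as diet-column predators; production-fate rows sum to 1
within 1e-9.

## Production fates

Per living group with total consumption `Q = B·(Q/B)`, consumption is
split into egestion `1−ae` (to detritus pools), metabolism
`ae − pb/qb` (to nutrient pools), predation `q[g→j]/Q` per consumer or
fleet, and senescence `(pb/qb)(1−EE)` (to detritus). The split sums
to one identically because the predation total is `(pb/qb)·EE`.
Routing weights across multiple detritus or nutrient pools default to
uniform — per-pool routing is rarely reported and any supplied
weights are accepted as long as they sum to one per group.

## Trophic levels and network metrics

Trophic levels solve `(I − DCᵀ)·TL = 1` over the analyzed node set
with columns renormalized over that set; basal nodes (producers,
detritus, fleets — anything with an empty renormalized column) sit at
TL 1, and cycles (cannibalism, mutual predation) are handled by the
linear solve. A singular system means a consumer loop with no dietary
path to a basal node; the offending strongly connected component is
named in the error.

The analyzed node set by default includes living groups, detritus
pools and fleets and excludes nutrient pools; it is overridable. A
link is any strictly positive diet or landings cell — support, not
thresholded flux. The connectance denominator is `N²` (self-links are
possible), so an 86-node web has 7396 possible links; link density is
`L/N`, identically `connectance × N`.

The node bootstrap resamples `N` node indices with replacement and
evaluates both metrics on the induced matrix `A[s, :][:, s]`,
duplicate rows/columns kept. This induced-matrix construction is a
design choice (several constructions are defensible); it is seeded and
reproducible.

## Footprint and reach

With `φ[g→k]` the fraction of g's production consumed by k
(predation plus landings over `B_g·pb_g`) and `ψ[k→c] = DC[k,c]`, the
destined and pass-through fractions solve

    D[g] = φ[g→focal] + Σ_k φ[g→k]·D[k]
    P[c] = ψ[focal→c] + Σ_k ψ[k→c]·P[k]

with k ranging over living, non-focal groups outside the excluded
pools. Exclusions default to nutrient and detritus pools: energy
entering detritus is treated as leaving the living web and does not
re-enter a focal group's footprint or reach. That leakage (plus
metabolism and fishing) keeps the operator's spectral radius below
one, so the systems are solved exactly and remain valid under cycles;
a web with no leakage anywhere is reported as singular.

Aggregates: footprint is the production-weighted mean of `D` over
living groups excluding the focal from numerator and denominator;
reach is the production-weighted mean of `P` over living consumer
(non-producer) groups, counting the focal's own production with
`P[focal] = 1`. Fleets are terminal: flux into a fleet contributes to
`φ` but fleets never pass energy onward and are excluded from consumer
production. Focal sets (e.g. "all gelatinous zooplankton") are
handled by merging the focal nodes at the recursion boundary. Whether
the footprint denominator should exclude detritus-fueled production is
genuinely open; the default excludes nothing but the focal itself, and
the exclusion tuple is an argument for sensitivity analysis.

## Pedigree uncertainty and tests

Monte Carlo draws sample every CV-flagged parameter from
`Normal(base, cv·|base|)`, truncate negatives to zero, clip `ae` to
[0,1], cap `pb` at `ae·qb`, renormalize diet columns (with bounded
redraws of columns that collapse to zero), and re-derive balance
quantities. Parameter-level sampling is the default: the diet cells
and group parameters *are* the production matrix's degrees of freedom,
so their CVs propagate to every fate element. A lognormal
mean-preserving alternative (`lognormal=True`) avoids truncation bias
for large CVs. With all CVs zero every draw equals the base model
bitwise.

Across-state comparisons use the Welch (unequal-variance) t-test with
Satterthwaite degrees of freedom — the fractional df reported for
such comparisons identify the unequal-variance form — and a
conservative Bonferroni correction `min(1, m·p)` whose family size
defaults to the number of tests (each focal group × footprint and
reach). Defaults: 1000 draws for footprint/reach ensembles, 100
bootstrap replicates for network-metric comparisons.

## Two-model comparison

Harmonization aggregates groups under explicit per-model mapping
tables (biomass-weighted diet columns, summed prey rows and biomasses,
biomass-weighted `pb/qb/ae`, which conserves total consumption
exactly), inserts groups missing from one model at trace biomass
(1e-5 in mt km⁻² currency) with their diet column copied and
renormalized, and orders both models identically. Carryover pruning
zeroes every positive diet cell not present in an evidence set of
observed (prey, predator) pairs and renormalizes the affected columns
— leaving them unnormalized would break mass balance — erroring if a
consumer loses its whole diet.

The difference network is oriented second-over-first: node factor
`B_after/B_before` (above one = increase), edge delta
`q_after − q_before`. Biomasses are floored at the trace level before
the ratio, so inserted groups never divide by zero. Both the factor
and its log are emitted; styling is left to downstream plotting.

## Temperature scalings

`P/B = 1.06·exp(0.018·T)·K^0.75` links biomass turnover to
temperature through the von Bertalanffy growth parameter K; holding K
fixed, a state change multiplies every `P/B` by `exp(0.018·ΔT)` —
1.037 for +2 °C. Metabolism follows `Q10^{ΔT/10}` — 1.149 for
Q10 = 2 over +2 °C. Factors are reported to three decimals; full
precision is kept internally. `apply_temperature_scenario` is a
reporting tool, not a re-balancer: it scales `pb`, recomputes EE, and
flags groups whose assimilation margin `ae·qb − pb_scaled` cannot
absorb the metabolic increase `(m−1)·(ae·qb − pb)` — those groups
would need to raise consumption to stay viable — without clipping
anything. The constants of the turnover relationship are treated as
dimensionless-consistent as published.

## Synthetic generator

`generate_web` emulates a temperate upwelling ecosystem model's
structure: 80 living groups by default (guild proportions
0.10/0.30/0.40/0.20 producers/herbivores/omnivores/carnivores), 3
nutrient pools, 5 detritus pools, 2 fleets; log-normal biomass spread
(ln-SD 1.0) around guild medians 50/20/2/0.2 mt km⁻² declining up the
pyramid; per-guild `P/B` ranges (50–200, 5–30, 1–10, 0.1–2 yr⁻¹);
consumer gross growth efficiency 0.1–0.3 and assimilation efficiency
0.7–0.9 (producers 1.0); diet sparsity 0.35 with up to 20% detritivory
in herbivore/omnivore diets; pedigree CV classes 0.1/0.5/0.8 assigned
per group with probabilities 0.3/0.4/0.3. Balance is constructive:
consumers are processed in guild order and each may claim only a
random share (30–80%) of the production still available from each
prey under an EE cap of 0.95, so generated webs always validate and
balance. Fleets land part of the production left unclaimed in the
upper guilds.

What the generator does **not** emulate: real taxa and their measured
parameters, ontogenetic/multi-stanza structure, trophic cycles
(generated webs are acyclic by guild rank; cyclic behaviour is
covered by hand-built fixtures), import/export fluxes, or seasonal
variability. Passing tests therefore demonstrate correctness of the
machinery and recoverability of injected signals, not empirical claims
about any real ecosystem.

`generate_model_pair` applies a known perturbation (invader insertion,
biomass multipliers, diet rewiring) and re-balances by throttling the
qb of over-consumed prey's consumers (and landings), never touching
biomass — so injected biomass factors are recovered exactly by the
difference network, and injected link removals exactly by the pruning
report.

## Numerical choices and problem sizes

Normalization tolerance 1e-9 absolute everywhere, renormalize-and-warn
below 1e-6 drift; linear systems via LAPACK `solve` with an explicit
residual check (1e-8) backing the singularity diagnostics; seeds
expand to per-stage seeds via `SeedSequence(seed,
spawn_key=(crc32(stage),))` reduced to 31 bits, so pipeline stages are
independently reproducible. Tests and the acceptance script run webs
of 6–20 living groups (1000-web oracle sweeps at ≤ 8 living groups)
with the default 80-living structure exercised once per suite; these
sizes make the full suite complete in well under a minute while
covering the same code paths as study-scale models.

## Known limitations

No automated re-balancing of an unbalanced input model (imbalance is
detected and reported, not repaired); no spatial or time-dynamic
simulation; no mixed-trophic-impact or keystoneness indices; no
modularity/nestedness metrics; fleet "trophic levels" are reported as
basal (their diet columns are empty — landings are catch, not diet).
The exact node-set composition of a published network is a config
choice (`exclude` tuples) rather than a hard-coded rule.
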
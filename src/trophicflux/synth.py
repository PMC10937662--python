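"""Seeded generation of balanced synthetic food webs and perturbed pairs.

The generator emulates the structure of a temperate upwelling
ecosystem model: ~80 living functional groups organized into trophic
guilds (primary producers feeding on nutrient pools, herbivores,
omnivores, carnivores), 3 nutrient pools, 5 detritus pools and 2
fishing fleets; log-spread biomasses declining up the trophic pyramid;
production and consumption ratios consistent with mass balance; and
pedigree CV classes (0.1 / 0.5 / 0.8) standing in for data-quality
tiers.  Balance is constructive: consumers are assigned demand
bottom-up and capped against the production still available from each
prey, so ecotrophic efficiencies never exceed the cap (default 0.95).

``generate_model_pair`` additionally applies a known perturbation
(an invading group, biomass multipliers, diet rewiring) and returns
the ground-truth edit list, enabling end-to-end recovery tests of the
difference-network and pruning machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    FoodWebError,
    FoodWebModel,
    FunctionalGroup,
    PedigreeCV,
    TRACE_BIOMASS,
    add_trace_group,
    compute_ee,
    validate_model,
)

__all__ = [
    "SyntheticWebSpec",
    "PerturbationSpec",
    "PairGroundTruth",
    "generate_web",
    "generate_model_pair",
]

GUILDS = ("producer", "herbivore", "omnivore", "carnivore")

#: pedigree CV classes for well-, moderately and poorly sampled groups
CV_CLASSES = (0.1, 0.5, 0.8)


@dataclass
class SyntheticWebSpec:
    """Knobs of the synthetic ecosystem.

    Defaults mirror the structure of the emulated system: 80 living
    groups, 3 nutrient pools, 5 detritus pools, 2 fleets; P/B ranges
    per guild are in per-year units for a mt km^-2 currency.
    """

    n_living: int = 80
    n_nutrient: int = 3
    n_detritus: int = 5
    n_fleets: int = 2
    guild_proportions: tuple[float, float, float, float] = (0.10, 0.30, 0.40, 0.20)
    #: natural-log SD of biomass spread within a guild
    biomass_log_sd: float = 1.0
    #: guild-level median biomasses (trophic pyramid)
    biomass_medians: tuple[float, float, float, float] = (50.0, 20.0, 2.0, 0.2)
    pb_ranges: tuple[tuple[float, float], ...] = (
        (50.0, 200.0),
        (5.0, 30.0),
        (1.0, 10.0),
        (0.1, 2.0),
    )
    #: gross growth efficiency (pb/qb) range for consumers
    gge_range: tuple[float, float] = (0.1, 0.3)
    ae_range: tuple[float, float] = (0.7, 0.9)
    #: probability that an allowed prey is actually eaten
    diet_sparsity: float = 0.35
    #: max detritus share of herbivore/omnivore diets
    detritus_share_max: float = 0.2
    #: probabilities of assigning each pedigree CV class to a group
    cv_class_probs: tuple[float, float, float] = (0.3, 0.4, 0.3)
    #: cap on ecotrophic efficiency used while balancing
    ee_cap: float = 0.95
    topology: str = "guild"  # or "chain"
    seed: int = 0

    def validate(self) -> None:
        counts = (self.n_living, self.n_nutrient, self.n_detritus, self.n_fleets)
        if any(c < 0 for c in counts):
            raise FoodWebError("group counts must be >= 0")
        if self.n_living < 1:
            raise FoodWebError("need at least one living group")
        if abs(sum(self.guild_proportions) - 1.0) > 1e-9:
            raise FoodWebError("guild proportions must sum to 1")
        if not (0 < self.diet_sparsity <= 1):
            raise FoodWebError("diet sparsity must lie in (0, 1]")
        if not (0 < self.ee_cap <= 1):
            raise FoodWebError("ee cap must lie in (0, 1]")
        if self.topology not in ("guild", "chain"):
            raise FoodWebError(f"unknown topology {self.topology!r}")


@dataclass
class PerturbationSpec:
    """A known set of edits turning a 'before' model into an 'after' one."""

    #: (name, biomass, {prey id or name: fraction}) of an invading group
    invader: tuple[str, float, dict] | None = None
    invader_params: dict = field(default_factory=lambda: {"pb": 10.0, "qb": 40.0, "ae": 0.8})
    #: per-group biomass multiplication factors, id -> factor
    biomass_factors: dict[int, float] = field(default_factory=dict)
    #: diet links to remove, (prey_id, predator_id)
    link_removals: list[tuple[int, int]] = field(default_factory=list)
    #: diet links to add, (prey_id, predator_id, fraction of predator diet)
    link_additions: list[tuple[int, int, float]] = field(default_factory=list)


@dataclass
class PairGroundTruth:
    """The injected edits, for recovery checks downstream."""

    invader_id: int | None
    biomass_factors: dict[int, float]
    link_removals: list[tuple[int, int]]
    link_additions: list[tuple[int, int, float]]


def _guild_counts(spec: SyntheticWebSpec) -> list[int]:
    raw = [p * spec.n_living for p in spec.guild_proportions]
    counts = [int(np.floor(r)) for r in raw]
    # distribute the remainder to the largest fractional parts
    rem = spec.n_living - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])
    for k in range(rem):
        counts[order[k % 4]] += 1
    if counts[0] == 0 and sum(counts[1:]) > 0:
        # any feeding guild needs at least one producer beneath it
        donor = int(np.argmax(counts))
        counts[donor] -= 1
        counts[0] += 1
    if counts[3] > 0 and counts[1] + counts[2] == 0:
        raise FoodWebError("infeasible spec: carnivores but no prey guild")
    if (counts[1] > 0 or counts[2] > 0) and counts[0] == 0:
        raise FoodWebError("infeasible spec: herbivores/omnivores but no producers")
    return counts


def generate_web(spec: SyntheticWebSpec) -> FoodWebModel:
    """Generate a validated, balanced food-web model from a spec.

    Reproducible: the same spec (including seed) yields bitwise-equal
    models.  Postconditions: validate_model passes, every ecotrophic
    efficiency is <= the spec's cap, trophic levels are finite.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    if spec.topology == "chain":
        return _generate_chain(spec, rng)

    counts = _guild_counts(spec)
    guild_of: list[str] = []
    for g, c in zip(GUILDS, counts):
        guild_of += [g] * c

    groups: list[FunctionalGroup] = []
    gid = 1
    for i, guild in enumerate(guild_of):
        groups.append(
            FunctionalGroup(
                id=gid, name=f"{guild}_{i + 1}", group_type="living", biomass=0.0
            )
        )
        gid += 1
    for k in range(spec.n_nutrient):
        groups.append(FunctionalGroup(id=gid, name=f"nutrient_{k + 1}", group_type="nutrient"))
        gid += 1
    for k in range(spec.n_detritus):
        groups.append(FunctionalGroup(id=gid, name=f"detritus_{k + 1}", group_type="detritus"))
        gid += 1
    for k in range(spec.n_fleets):
        groups.append(FunctionalGroup(id=gid, name=f"fleet_{k + 1}", group_type="fleet"))
        gid += 1

    n = len(groups)
    n_liv = spec.n_living
    guild_idx = {g: [i for i, x in enumerate(guild_of) if x == g] for g in GUILDS}
    nut_idx = [i for i in range(n) if groups[i].group_type == "nutrient"]
    det_idx = [i for i in range(n) if groups[i].group_type == "detritus"]
    fleet_idx = [i for i in range(n) if groups[i].group_type == "fleet"]

    diet = np.zeros((n, n))
    # biomass, pb, ae per living group
    for g_name, median, pb_rng in zip(GUILDS, spec.biomass_medians, spec.pb_ranges):
        for i in guild_idx[g_name]:
            groups[i].biomass = float(
                median * np.exp(rng.normal(0.0, spec.biomass_log_sd))
            )
            groups[i].pb = float(rng.uniform(*pb_rng))
            groups[i].ae = 1.0 if g_name == "producer" else float(rng.uniform(*spec.ae_range))

    # producers: diet over nutrient pools; qb from pb and a nutrient-uptake
    # efficiency in (0.5, 0.9) so pb <= ae * qb always holds
    for i in guild_idx["producer"]:
        if not nut_idx:
            raise FoodWebError("infeasible spec: producers need a nutrient pool")
        w = rng.dirichlet(np.ones(len(nut_idx)))
        diet[nut_idx, i] = w
        uptake = rng.uniform(0.5, 0.9)
        groups[i].qb = float(groups[i].pb / (groups[i].ae * uptake))

    prey_menu = {
        "herbivore": guild_idx["producer"],
        "omnivore": guild_idx["producer"] + guild_idx["herbivore"],
        "carnivore": guild_idx["herbivore"] + guild_idx["omnivore"],
    }
    # production still available from each living prey, under the EE cap;
    # consumers register their own availability only once their final
    # pb/qb are fixed (guild order guarantees prey precede predators)
    remaining = np.zeros(n)
    for i in guild_idx["producer"]:
        remaining[i] = spec.ee_cap * groups[i].biomass * groups[i].pb

    for guild in ("herbivore", "omnivore", "carnivore"):
        for j in guild_idx[guild]:
            menu = prey_menu[guild]
            pick = [i for i in menu if rng.random() < spec.diet_sparsity]
            if not pick:
                pick = [menu[rng.integers(len(menu))]]
            w = rng.dirichlet(np.ones(len(pick)))
            det_share = 0.0
            if guild in ("herbivore", "omnivore") and det_idx and spec.detritus_share_max > 0:
                det_share = float(rng.uniform(0.0, spec.detritus_share_max))
                dw = rng.dirichlet(np.ones(len(det_idx)))
                diet[det_idx, j] = det_share * dw
            diet[pick, j] = (1.0 - det_share) * w

            gge = rng.uniform(*spec.gge_range)
            qb_want = float(rng.uniform(*spec.pb_ranges[GUILDS.index(guild)]) / gge)
            # cap demand against what every living prey can still supply
            # each consumer may claim only a random share of what is
            # still available, so one group cannot starve its guild
            share = rng.uniform(0.3, 0.8)
            qb_cap = qb_want
            for i in pick:
                if diet[i, j] > 0 and groups[j].biomass > 0:
                    qb_cap = min(
                        qb_cap,
                        share * max(remaining[i], 0.0) / (groups[j].biomass * diet[i, j]),
                    )
            # tiny floor keeps every living consumer feeding (fate rows defined)
            qb = max(min(qb_want, qb_cap), 1e-9)
            groups[j].qb = float(qb)
            groups[j].pb = float(gge * qb)
            for i in pick:
                remaining[i] -= groups[j].biomass * qb * diet[i, j]
            remaining[j] = spec.ee_cap * groups[j].biomass * groups[j].pb

    # fleets: land a share of the production still unclaimed in the
    # upper guilds
    landings = np.zeros((n, n))
    catchable = guild_idx["omnivore"] + guild_idx["carnivore"]
    for f in fleet_idx:
        targets = [i for i in catchable if rng.random() < 0.4 and remaining[i] > 0]
        for i in targets:
            take = float(rng.uniform(0.0, 0.5)) * remaining[i] / max(len(fleet_idx), 1)
            landings[i, f] = take
            remaining[i] -= take

    # pedigree classes per living group
    ped = PedigreeCV.zeros(n)
    classes = rng.choice(CV_CLASSES, size=n_liv, p=spec.cv_class_probs)
    for i in range(n_liv):
        cv = float(classes[i])
        ped.params[i, :] = cv
        ped.diet[:, i][diet[:, i] > 0] = cv

    model = FoodWebModel(
        groups=groups,
        diet=diet,
        landings=landings,
        pedigree=ped,
        provenance=f"synthetic guild web (seed={spec.seed})",
    )
    problems = validate_model(model)
    if problems:  # pragma: no cover - generator contract
        raise FoodWebError("generator produced an invalid model:\n" + "\n".join(problems))
    return model


def _generate_chain(spec: SyntheticWebSpec, rng: np.random.Generator) -> FoodWebModel:
    """A single linear chain: producer -> consumer -> ... (single-prey diets)."""
    n_liv = spec.n_living
    groups: list[FunctionalGroup] = []
    gid = 1
    for i in range(n_liv):
        groups.append(
            FunctionalGroup(id=gid, name=f"level_{i + 1}", group_type="living")
        )
        gid += 1
    for k in range(max(spec.n_nutrient, 1)):
        groups.append(FunctionalGroup(id=gid, name=f"nutrient_{k + 1}", group_type="nutrient"))
        gid += 1
    for k in range(max(spec.n_detritus, 1)):
        groups.append(FunctionalGroup(id=gid, name=f"detritus_{k + 1}", group_type="detritus"))
        gid += 1
    n = len(groups)
    nut0 = n_liv

    diet = np.zeros((n, n))
    b = 100.0
    pb = 100.0
    for i in range(n_liv):
        groups[i].biomass = b
        groups[i].pb = pb
        if i == 0:
            groups[i].ae = 1.0
            diet[nut0, 0] = 1.0
            groups[i].qb = pb / (groups[i].ae * 0.8)
        else:
            groups[i].ae = 0.8
            diet[i - 1, i] = 1.0
            # demand at most the EE cap of the prey's production
            qb = spec.ee_cap * groups[i - 1].biomass * groups[i - 1].pb / b
            groups[i].qb = qb
            groups[i].pb = min(0.25 * qb, groups[i].ae * qb)
            pb = groups[i].pb
        b = b / 10.0
    model = FoodWebModel(
        groups=groups, diet=diet, provenance=f"synthetic chain (seed={spec.seed})"
    )
    problems = validate_model(model)
    if problems:  # pragma: no cover
        raise FoodWebError("chain generator invalid:\n" + "\n".join(problems))
    return model


def generate_model_pair(
    spec: SyntheticWebSpec, perturbation: PerturbationSpec
) -> tuple[FoodWebModel, FoodWebModel, PairGroundTruth]:
    """A before/after model pair with a known injected perturbation.

    The 'after' model is the perturbed 'before' model, re-capped to
    balance by scaling consumer demand down where the perturbation
    over-consumes a prey (biomasses are never touched by re-capping, so
    injected biomass factors survive exactly).
    """
    before = generate_web(spec)
    after = before.copy()

    invader_id = None
    if perturbation.invader is not None:
        name, biomass, diet_col = perturbation.invader
        pars = perturbation.invader_params
        gid = int(after.ids.max()) + 1
        col = {after.ids[after.index_of(k)] if isinstance(k, str) else k: v
               for k, v in diet_col.items()}
        after = add_trace_group(
            after,
            FunctionalGroup(
                id=gid,
                name=name,
                group_type="living",
                biomass=biomass,
                pb=pars.get("pb", 10.0),
                qb=pars.get("qb", 40.0),
                ae=pars.get("ae", 0.8),
            ),
            diet_column=col,
            biomass=biomass,
        )
        invader_id = gid

    for gid, factor in perturbation.biomass_factors.items():
        if factor < 0:
            raise FoodWebError("biomass factors must be >= 0")
        g = after.groups[after.index_of(int(gid))]
        if g.group_type != "living":
            raise FoodWebError(f"can only scale living groups, not {g.group_type}")
        g.biomass *= factor

    for prey, pred in perturbation.link_removals:
        i, j = after.index_of(int(prey)), after.index_of(int(pred))
        if after.diet[i, j] <= 0:
            raise FoodWebError(f"cannot remove absent link ({prey}, {pred})")
        after.diet[i, j] = 0.0
        s = after.diet[:, j].sum()
        if s <= 0:
            raise FoodWebError(f"removal empties the diet of consumer {pred}")
        after.diet[:, j] /= s

    for prey, pred, frac in perturbation.link_additions:
        i, j = after.index_of(int(prey)), after.index_of(int(pred))
        if not (0 < frac < 1):
            raise FoodWebError("added link fraction must lie in (0, 1)")
        after.diet[:, j] *= 1.0 - frac
        after.diet[i, j] += frac

    _recap_balance(after, spec.ee_cap)

    truth = PairGroundTruth(
        invader_id=invader_id,
        biomass_factors=dict(perturbation.biomass_factors),
        link_removals=list(perturbation.link_removals),
        link_additions=list(perturbation.link_additions),
    )
    return before, after, truth


def _recap_balance(model: FoodWebModel, ee_cap: float, max_iter: int = 500) -> None:
    """Throttle demand until every living EE <= cap (in place).

    For each over-consumed prey, the qb of its living consumers and the
    landings taken from it are scaled down proportionally (biomasses are
    never touched, so injected biomass factors survive exactly); pb is
    re-capped at ae*qb where throttling makes it binding.  Diverging
    cases (demand structurally unsupportable) raise.
    """
    producer = model.is_producer()
    for _ in range(max_iter):
        ee = compute_ee(model, validate=False)
        living = model.living
        worst = np.nanmax(ee[living]) if living.any() else 0.0
        if worst <= ee_cap + 1e-9:
            return
        for i in np.flatnonzero(living):
            if not ee[i] > ee_cap:
                continue
            s = ee_cap / ee[i]
            for j in range(model.n):
                g = model.groups[j]
                if model.diet[i, j] > 0 and g.group_type == "living" and not producer[j]:
                    g.qb *= s
                    g.pb = min(g.pb, g.ae * g.qb)
            model.landings[i, :] *= s
    raise FoodWebError("perturbation breaks balance beyond repair")
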
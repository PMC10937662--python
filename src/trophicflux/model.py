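"""Core domain types and operations for mass-balanced food-web models.

A food web is described Ecopath-style: an ordered list of functional
groups (living groups, nutrient pools, detritus pools, fishing fleets),
a square diet-composition matrix ``DC[prey, predator]`` whose living
consumer columns sum to one, a landings matrix for fleet catches, and
pedigree coefficients of variation expressing data-quality uncertainty
on every parameter.

Conventions
-----------
* Primary producers are modelled as "consumers" of nutrient pools: a
  producer has ``qb > 0`` and a diet column supported on nutrient rows.
  One production-fate machinery then covers every living group.
* Import/export and biomass-accumulation terms of the full Ecopath
  master equation are fixed at zero: the models are steady state.
* Currency and time units are model-level tags (e.g. ``mt km^-2`` and
  ``yr^-1``); no automatic conversion is attempted.
* All normalization checks use an absolute tolerance of 1e-9; drift up
  to 1e-6 is silently renormalized where an operation edits diets,
  anything larger is an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GROUP_TYPES",
    "NORM_TOL",
    "RENORM_TOL",
    "FoodWebError",
    "ImbalanceError",
    "FunctionalGroup",
    "PedigreeCV",
    "FoodWebModel",
    "FluxNetwork",
    "ProductionFateMatrix",
    "validate_model",
    "compute_ee",
    "is_balanced",
    "consumption_flux_matrix",
    "build_production_fate",
    "aggregate_groups",
    "add_trace_group",
]

GROUP_TYPES = ("living", "nutrient", "detritus", "fleet")

#: absolute tolerance for sum-to-one checks
NORM_TOL = 1e-9
#: drift up to this bound is renormalized instead of rejected
RENORM_TOL = 1e-6

#: default biomass for trace-group insertion (mt km^-2)
TRACE_BIOMASS = 1e-5

PARAM_NAMES = ("biomass", "pb", "qb", "ae")


class FoodWebError(ValueError):
    """Structural or semantic error in a food-web model."""


class ImbalanceError(FoodWebError):
    """Predation demand cannot be met by production (EE undefined or > 1)."""


@dataclass
class FunctionalGroup:
    """One node of the food web.

    Parameters follow Ecopath notation: ``biomass`` (B), ``pb`` (P/B,
    biomass turnover per time unit), ``qb`` (Q/B, consumption per unit
    biomass), ``ae`` (assimilation efficiency), and the derived
    ecotrophic efficiency ``ee`` (fraction of production consumed by
    predators or fleets; ``None`` until computed).
    """

    id: int
    name: str
    group_type: str
    biomass: float = 0.0
    pb: float = 0.0
    qb: float = 0.0
    ae: float = 1.0
    ee: float | None = None

    def __post_init__(self) -> None:
        if self.group_type not in GROUP_TYPES:
            raise FoodWebError(
                f"group {self.id} ({self.name}): unknown group_type "
                f"{self.group_type!r}; expected one of {GROUP_TYPES}"
            )


@dataclass
class PedigreeCV:
    """Coefficient-of-variation pedigree for a model.

    ``diet`` is an (n, n) array of CVs aligned with the diet matrix;
    ``params`` is an (n, 4) array of CVs for (biomass, pb, qb, ae).
    A CV of zero pins the parameter.
    """

    diet: np.ndarray
    params: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "PedigreeCV":
        return cls(diet=np.zeros((n, n)), params=np.zeros((n, len(PARAM_NAMES))))

    def copy(self) -> "PedigreeCV":
        return PedigreeCV(diet=self.diet.copy(), params=self.params.copy())


@dataclass
class FoodWebModel:
    """A parameterized ecosystem state.

    ``diet[i, j]`` is the fraction of predator j's consumption taken
    from prey i.  ``landings[i, f]`` is the catch rate of group i by
    fleet f (nonzero only in fleet columns).
    """

    groups: list[FunctionalGroup]
    diet: np.ndarray
    landings: np.ndarray | None = None
    pedigree: PedigreeCV | None = None
    currency: str = "mt km^-2"
    time_unit: str = "yr^-1"
    provenance: str = ""

    def __post_init__(self) -> None:
        n = len(self.groups)
        self.diet = np.asarray(self.diet, dtype=float)
        if self.diet.shape != (n, n):
            raise FoodWebError(
                f"diet matrix shape {self.diet.shape} does not match "
                f"{n} groups (must be square and aligned)"
            )
        if self.landings is None:
            self.landings = np.zeros((n, n))
        self.landings = np.asarray(self.landings, dtype=float)
        if self.landings.shape != (n, n):
            raise FoodWebError(
                f"landings matrix shape {self.landings.shape} does not match {n} groups"
            )
        if self.pedigree is None:
            self.pedigree = PedigreeCV.zeros(n)

    # -- indexing helpers -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.groups)

    @property
    def ids(self) -> np.ndarray:
        return np.array([g.id for g in self.groups], dtype=int)

    @property
    def names(self) -> list[str]:
        return [g.name for g in self.groups]

    @property
    def types(self) -> np.ndarray:
        return np.array([g.group_type for g in self.groups], dtype=object)

    def mask(self, *group_types: str) -> np.ndarray:
        t = self.types
        return np.isin(t, group_types)

    @property
    def living(self) -> np.ndarray:
        return self.mask("living")

    def index_of(self, key: int | str) -> int:
        """Position of a group by id (int) or name (str)."""
        if isinstance(key, str):
            for i, g in enumerate(self.groups):
                if g.name == key:
                    return i
            raise KeyError(f"no group named {key!r}")
        ids = self.ids
        hits = np.flatnonzero(ids == key)
        if hits.size == 0:
            raise KeyError(f"no group with id {key}")
        return int(hits[0])

    def param(self, name: str) -> np.ndarray:
        return np.array([getattr(g, name) for g in self.groups], dtype=float)

    @property
    def biomass(self) -> np.ndarray:
        return self.param("biomass")

    def copy(self) -> "FoodWebModel":
        return FoodWebModel(
            groups=[replace(g) for g in self.groups],
            diet=self.diet.copy(),
            landings=self.landings.copy(),
            pedigree=self.pedigree.copy(),
            currency=self.currency,
            time_unit=self.time_unit,
            provenance=self.provenance,
        )

    def is_producer(self) -> np.ndarray:
        """Living groups whose diet is supported only on nutrient pools."""
        nut = self.mask("nutrient")
        has_living_prey = (self.diet[~nut, :] > 0).any(axis=0)
        return self.living & ~has_living_prey


@dataclass
class FluxNetwork:
    """Directed consumption-rate network.

    ``q[i, j]`` is the rate at which consumer j (or fleet j, via
    landings) removes biomass of group i, in the model's currency per
    time unit.
    """

    ids: np.ndarray
    names: list[str]
    types: np.ndarray
    biomass: np.ndarray
    q: np.ndarray
    currency: str = "mt km^-2"
    time_unit: str = "yr^-1"

    @property
    def n(self) -> int:
        return len(self.ids)

    def total_flux(self) -> float:
        return float(self.q.sum())


@dataclass
class ProductionFateMatrix:
    """Per-living-group split of total consumption Q = B*Q/B.

    ``fate[r, c]`` is the fraction of living group r's consumption
    routed to column group c: egestion and senescence go to detritus
    pools, metabolic losses to nutrient pools, and consumed production
    to each predator or fleet.  Rows sum to one (conservation of
    consumption).
    """

    living_ids: np.ndarray
    column_ids: np.ndarray
    fate: np.ndarray
    #: boolean masks over columns for the four fate channels
    detritus_cols: np.ndarray = field(default=None)
    nutrient_cols: np.ndarray = field(default=None)

    def row(self, group_id: int) -> np.ndarray:
        return self.fate[int(np.flatnonzero(self.living_ids == group_id)[0])]

    def fraction_to(self, group_id: int, cols: np.ndarray) -> float:
        """Total fate fraction of ``group_id`` routed into columns ``cols``."""
        return float(self.row(group_id)[cols].sum())

    def fraction_to_detritus(self, group_id: int) -> float:
        return self.fraction_to(group_id, self.detritus_cols)


# ---------------------------------------------------------------------------
# validation


def validate_model(model: FoodWebModel) -> list[str]:
    """Check every model invariant; return a list of human-readable violations.

    An empty list means the model is well formed.  Structural problems
    (non-square diet, mismatched shapes) raise :class:`FoodWebError`
    from the model constructor instead of being reported here.
    """
    v: list[str] = []
    ids = model.ids
    if len(set(ids.tolist())) != model.n:
        v.append("group ids are not unique")
    if (ids < 1).any():
        bad = ids[ids < 1].tolist()
        v.append(f"group ids must be >= 1, got {bad}")

    for g in model.groups:
        tag = f"group {g.id} ({g.name})"
        if g.biomass < 0:
            v.append(f"{tag}: biomass < 0")
        if g.pb < 0:
            v.append(f"{tag}: pb < 0")
        if g.qb < 0:
            v.append(f"{tag}: qb < 0")
        if not (0.0 <= g.ae <= 1.0):
            v.append(f"{tag}: ae outside [0, 1]")
        if g.group_type == "living" and g.qb > 0 and g.pb > g.ae * g.qb + NORM_TOL:
            v.append(
                f"{tag}: pb={g.pb} exceeds ae*qb={g.ae * g.qb} "
                "(production cannot exceed assimilated consumption)"
            )
        if g.ee is not None and not (-NORM_TOL <= g.ee <= 1.0 + NORM_TOL):
            v.append(f"{tag}: ee={g.ee} outside [0, 1] (unbalanced)")

    dc = model.diet
    if (dc < 0).any() or (dc > 1 + NORM_TOL).any():
        i, j = np.unravel_index(np.argmax(np.abs(dc - 0.5)), dc.shape)
        v.append(f"diet matrix has entries outside [0, 1] (e.g. cell [{ids[i]}, {ids[j]}])")

    qb = model.param("qb")
    consumer = model.living & (qb > 0)
    colsum = dc.sum(axis=0)
    for j in np.flatnonzero(consumer):
        if abs(colsum[j] - 1.0) > NORM_TOL:
            v.append(
                f"diet column of consumer {ids[j]} ({model.groups[j].name}) "
                f"sums to {colsum[j]:.12g}, expected 1"
            )
    nonliving = ~model.living
    for j in np.flatnonzero(nonliving):
        if colsum[j] > NORM_TOL:
            v.append(
                f"diet column of {model.groups[j].group_type} group {ids[j]} "
                f"({model.groups[j].name}) is non-zero; only living groups feed via diet"
            )

    y = model.landings
    if (y < 0).any():
        v.append("landings contain negative rates")
    fleet = model.mask("fleet")
    bad_cols = np.flatnonzero((~fleet) & (y.sum(axis=0) > 0))
    for j in bad_cols:
        v.append(
            f"landings column {ids[j]} ({model.groups[j].name}) is not a fleet"
        )
    return v


def _require_valid(model: FoodWebModel) -> None:
    problems = validate_model(model)
    if problems:
        raise FoodWebError(
            "model fails validation:\n  " + "\n  ".join(problems)
        )


# ---------------------------------------------------------------------------
# mass balance


def compute_ee(model: FoodWebModel, validate: bool = True) -> np.ndarray:
    """Ecotrophic efficiency of every living group.

    EE_i = (predation demand on i + landings of i) / (B_i * P/B_i),
    the Ecopath master equation solved for EE with import/export and
    biomass accumulation fixed at zero.  Entries for non-living groups
    are NaN.  A balanced model has all EE <= 1.

    Raises
    ------
    ImbalanceError
        If a living group with zero production is under positive
        demand (EE undefined).
    """
    if validate:
        _require_valid(model)
    b = model.biomass
    qb = model.param("qb")
    pb = model.param("pb")
    consumption = b * qb  # Q per group; zero for non-feeding groups
    demand = model.diet @ consumption + model.landings.sum(axis=1)
    production = b * pb

    ee = np.full(model.n, np.nan)
    for i in np.flatnonzero(model.living):
        if production[i] > 0:
            ee[i] = demand[i] / production[i]
        elif demand[i] <= NORM_TOL:
            ee[i] = 0.0
        else:
            g = model.groups[i]
            raise ImbalanceError(
                f"group {g.id} ({g.name}) has zero production but positive "
                f"predation/landings demand {demand[i]:.6g}"
            )
    return ee


def is_balanced(model: FoodWebModel, tol: float = NORM_TOL) -> bool:
    """True iff every living group's ecotrophic efficiency is <= 1."""
    ee = compute_ee(model)
    return bool(np.all(ee[model.living] <= 1.0 + tol))


# ---------------------------------------------------------------------------
# fluxes


def consumption_flux_matrix(model: FoodWebModel, validate: bool = True) -> FluxNetwork:
    """Directed consumption rates q[i -> j] = B_j * Q/B_j * DC[i, j].

    Fleet columns carry the landings rates instead (fleets take catch,
    not diet).  Node biomasses are copied from the model.
    """
    if validate:
        _require_valid(model)
    b = model.biomass
    qb = model.param("qb")
    q = model.diet * (b * qb)[np.newaxis, :]
    fleet = model.mask("fleet")
    q[:, fleet] = model.landings[:, fleet]
    return FluxNetwork(
        ids=model.ids,
        names=model.names,
        types=model.types,
        biomass=b,
        q=q,
        currency=model.currency,
        time_unit=model.time_unit,
    )


def build_production_fate(
    model: FoodWebModel,
    detritus_routing: np.ndarray | None = None,
    nutrient_routing: np.ndarray | None = None,
    validate: bool = True,
) -> ProductionFateMatrix:
    """Split each living group's consumption into its four fates.

    Per living group g with total consumption Q_g = B_g * Q/B_g:

    * egestion fraction ``1 - ae`` (non-assimilated), to detritus pools;
    * metabolism fraction ``ae - pb/qb`` (assimilated but respired /
      excreted), to nutrient pools;
    * predation fraction ``q[g -> j] / Q_g`` to each consumer or fleet;
    * senescence fraction ``(pb/qb) * (1 - ee)`` (unconsumed
      production), to detritus pools.

    Routing weights distribute the detritus- and nutrient-bound
    fractions across the respective pools; they default to uniform.
    Each row sums to one by construction.
    """
    if validate:
        _require_valid(model)
    ee = compute_ee(model, validate=False)
    living_idx = np.flatnonzero(model.living)
    det_cols = model.mask("detritus")
    nut_cols = model.mask("nutrient")
    n_det, n_nut = int(det_cols.sum()), int(nut_cols.sum())
    n_liv = living_idx.size

    def _routing(w, k, label):
        if k == 0:
            return np.zeros((n_liv, 0))
        if w is None:
            w = np.full((n_liv, k), 1.0 / k)
        w = np.atleast_2d(np.asarray(w, dtype=float))
        if w.shape[0] == 1:
            w = np.repeat(w, n_liv, axis=0)
        if w.shape != (n_liv, k):
            raise FoodWebError(f"{label} routing must have shape ({n_liv}, {k})")
        if np.abs(w.sum(axis=1) - 1.0).max() > NORM_TOL:
            raise FoodWebError(f"{label} routing weights must sum to 1 per group")
        return w

    detritus_routing = _routing(detritus_routing, n_det, "detritus")
    nutrient_routing = _routing(nutrient_routing, n_nut, "nutrient")

    flux = consumption_flux_matrix(model, validate=False)
    fate = np.zeros((n_liv, model.n))
    for r, g_idx in enumerate(living_idx):
        g = model.groups[g_idx]
        if g.qb <= 0:
            raise FoodWebError(
                f"group {g.id} ({g.name}) is living with qb=0; "
                "production fate is undefined without consumption"
            )
        pe = g.pb / g.qb  # production per unit consumption
        if g.ae < pe - NORM_TOL:
            raise FoodWebError(
                f"group {g.id} ({g.name}): negative metabolism "
                f"(ae={g.ae} < pb/qb={pe:.6g})"
            )
        if ee[g_idx] > 1.0 + NORM_TOL:
            raise ImbalanceError(
                f"group {g.id} ({g.name}) has ee={ee[g_idx]:.4g} > 1; "
                "balance the model before building production fates"
            )
        q_total = g.biomass * g.qb
        row = fate[r]
        to_detritus = (1.0 - g.ae) + pe * (1.0 - min(ee[g_idx], 1.0))
        to_nutrient = max(g.ae - pe, 0.0)
        if n_det == 0 and to_detritus > NORM_TOL:
            raise FoodWebError(
                f"group {g.id} ({g.name}) routes {to_detritus:.4g} of its "
                "consumption to detritus but the model has no detritus pool"
            )
        if n_nut == 0 and to_nutrient > NORM_TOL:
            raise FoodWebError(
                f"group {g.id} ({g.name}) routes {to_nutrient:.4g} of its "
                "consumption to nutrients but the model has no nutrient pool"
            )
        if n_det:
            row[det_cols] += to_detritus * detritus_routing[r]
        if n_nut:
            row[nut_cols] += to_nutrient * nutrient_routing[r]
        if q_total > 0:
            row += flux.q[g_idx, :] / q_total * (~(det_cols | nut_cols))
    return ProductionFateMatrix(
        living_ids=model.ids[model.living],
        column_ids=model.ids,
        fate=fate,
        detritus_cols=det_cols,
        nutrient_cols=nut_cols,
    )


# ---------------------------------------------------------------------------
# model editing


def _renormalize_column(col: np.ndarray, where: str) -> np.ndarray:
    s = col.sum()
    if s <= 0:
        raise FoodWebError(f"diet column of {where} cannot be renormalized (sum 0)")
    if abs(s - 1.0) > RENORM_TOL:
        raise FoodWebError(
            f"diet column of {where} sums to {s:.9g}; drift exceeds the "
            f"renormalization bound {RENORM_TOL}"
        )
    return col / s


def aggregate_groups(
    model: FoodWebModel,
    mapping: dict[int, int],
    names: dict[int, str] | None = None,
    validate: bool = True,
) -> FoodWebModel:
    """Merge functional groups under an old-id -> new-id mapping.

    Biomasses and landings are summed; diet columns are biomass-weighted
    means of member columns; prey rows are summed within each predator
    column; pb, qb and ae are biomass-weighted means (so merged
    consumption B*Q/B is conserved exactly).  Groups may only merge
    within the same group type.
    """
    if validate:
        _require_valid(model)
    ids = model.ids
    for gid in ids:
        if int(gid) not in mapping:
            raise FoodWebError(f"mapping is not total: group {gid} unmapped")
    names = names or {}

    # new groups in order of first appearance
    new_order: list[int] = []
    members: dict[int, list[int]] = {}
    for pos, gid in enumerate(ids):
        nid = mapping[int(gid)]
        if nid not in members:
            members[nid] = []
            new_order.append(nid)
        members[nid].append(pos)

    b = model.biomass
    new_groups: list[FunctionalGroup] = []
    weights: dict[int, np.ndarray] = {}
    for nid in new_order:
        pos = members[nid]
        gtypes = {model.groups[p].group_type for p in pos}
        if len(gtypes) > 1:
            raise FoodWebError(
                f"cannot merge across group types {sorted(gtypes)} into new group {nid}"
            )
        bsum = float(b[pos].sum())
        if len(pos) > 1 and bsum <= 0:
            merged = [model.groups[p].name for p in pos]
            raise FoodWebError(
                f"cannot merge all-zero-biomass groups {merged}: weights undefined"
            )
        w = b[pos] / bsum if bsum > 0 else np.ones(len(pos))
        weights[nid] = w
        g0 = model.groups[pos[0]]
        new_groups.append(
            FunctionalGroup(
                id=nid,
                name=names.get(nid, g0.name),
                group_type=g0.group_type,
                biomass=bsum,
                pb=float(np.dot(w, model.param("pb")[pos])),
                qb=float(np.dot(w, model.param("qb")[pos])),
                ae=float(np.dot(w, model.param("ae")[pos])),
            )
        )

    m = len(new_order)
    new_diet = np.zeros((m, m))
    new_land = np.zeros((m, m))
    new_diet_cv = np.zeros((m, m))
    new_param_cv = np.zeros((m, len(PARAM_NAMES)))
    for cj, nid_j in enumerate(new_order):
        pos_j = members[nid_j]
        w_j = weights[nid_j]
        # biomass-weighted mean over member predator columns, prey rows summed
        col = model.diet[:, pos_j] @ w_j
        cv_col = model.pedigree.diet[:, pos_j] @ w_j
        land_col = model.landings[:, pos_j].sum(axis=1)
        for ri, nid_i in enumerate(new_order):
            pos_i = members[nid_i]
            new_diet[ri, cj] = col[pos_i].sum()
            new_land[ri, cj] = land_col[pos_i].sum()
            new_diet_cv[ri, cj] = (
                float(np.dot(b[pos_i], cv_col[pos_i]) / b[pos_i].sum())
                if b[pos_i].sum() > 0
                else cv_col[pos_i].mean()
            )
    for ri, nid in enumerate(new_order):
        pos = members[nid]
        new_param_cv[ri] = weights[nid] @ model.pedigree.params[pos]

    # clean tiny weighted-sum drift on consumer columns
    qb_new = np.array([g.qb for g in new_groups])
    liv_new = np.array([g.group_type == "living" for g in new_groups])
    for j in np.flatnonzero(liv_new & (qb_new > 0)):
        s = new_diet[:, j].sum()
        if s > 0 and abs(s - 1.0) <= RENORM_TOL:
            new_diet[:, j] /= s

    return FoodWebModel(
        groups=new_groups,
        diet=new_diet,
        landings=new_land,
        pedigree=PedigreeCV(diet=new_diet_cv, params=new_param_cv),
        currency=model.currency,
        time_unit=model.time_unit,
        provenance=model.provenance,
    )


def add_trace_group(
    model: FoodWebModel,
    group: FunctionalGroup,
    diet_column: dict[int, float] | None = None,
    biomass: float | None = None,
    predator_epsilon: dict[int, float] | None = None,
    validate: bool = True,
) -> FoodWebModel:
    """Append a group at trace biomass (default 1e-5 in mt km^-2 currency).

    ``diet_column`` maps prey ids to raw weights; it is renormalized to
    sum to one.  ``predator_epsilon`` optionally shifts a small fraction
    epsilon of each listed predator's diet onto the new group, so the
    trace group registers as prey; affected columns stay normalized.
    """
    if validate:
        _require_valid(model)
    if group.name in model.names:
        raise FoodWebError(f"group name {group.name!r} already present")
    if int(group.id) in model.ids.tolist():
        raise FoodWebError(f"group id {group.id} already present")
    b = group.biomass if biomass is None else biomass
    if b <= 0:
        raise FoodWebError("trace group biomass must be > 0")

    n = model.n
    new = model.copy()
    g = replace(group, biomass=float(b))
    new.groups.append(g)

    diet = np.zeros((n + 1, n + 1))
    diet[:n, :n] = new.diet
    if group.group_type == "living" and g.qb > 0:
        if not diet_column:
            raise FoodWebError(
                f"living consumer {group.name!r} needs a diet column"
            )
        col = np.zeros(n + 1)
        for prey, frac in diet_column.items():
            if frac < 0:
                raise FoodWebError("diet fractions must be >= 0")
            col[model.index_of(prey)] = frac
        s = col.sum()
        if s <= 0:
            raise FoodWebError(f"diet column of {group.name!r} is not normalizable")
        diet[:, n] = col / s
    for pred, eps in (predator_epsilon or {}).items():
        j = model.index_of(pred)
        if not (0 <= eps < 1):
            raise FoodWebError("predator epsilon must be in [0, 1)")
        diet[:, j] *= 1.0 - eps
        diet[n, j] += eps

    land = np.zeros((n + 1, n + 1))
    land[:n, :n] = new.landings
    ped = PedigreeCV.zeros(n + 1)
    ped.diet[:n, :n] = new.pedigree.diet
    ped.params[:n] = new.pedigree.params
    out = FoodWebModel(
        groups=new.groups,
        diet=diet,
        landings=land,
        pedigree=ped,
        currency=model.currency,
        time_unit=model.time_unit,
        provenance=model.provenance,
    )
    _require_valid(out)
    return out
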
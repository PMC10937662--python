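"""Footprint and reach: tracing energy through direct and indirect pathways.

Two non-dimensional metrics summarize a focal group's role in the web:

* **footprint** — the fraction of total system production (of the
  other living groups) that supports the focal group through every
  direct and indirect living pathway.  Per source group g, the
  *destined fraction* D[g] is the share of g's production that
  eventually reaches the focal group.
* **reach** — the fraction of total consumer production that
  originated with, or passed through, the focal group.  Per consumer
  c, the *pass-through fraction* P[c] is the share of c's consumption
  (hence production) traceable back to the focal group.

Detritus and nutrient pools are excluded from the pathway recursion:
energy entering a detritus pool is treated as leaving the living web
and does not re-enter a focal group's footprint or reach.  That
leakage (plus metabolism and fishing) keeps the pathway operator's
spectral radius below one, so both recursions are solved exactly as
linear systems and remain valid under cycles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    FoodWebModel,
    FoodWebError,
    consumption_flux_matrix,
)

__all__ = [
    "DEFAULT_PATHWAY_EXCLUDE",
    "FootprintReachResult",
    "production_fraction_matrix",
    "destined_fractions",
    "pass_through_fractions",
    "footprint",
    "reach",
    "footprint_reach",
]

DEFAULT_PATHWAY_EXCLUDE = ("nutrient", "detritus")


@dataclass
class FootprintReachResult:
    """Footprint/reach of one focal group (or merged focal set)."""

    focal: tuple[int, ...]
    footprint: float
    reach: float
    destined: pd.Series  # D[g] per living group id
    pass_through: pd.Series  # P[c] per living group id


def _focal_positions(model: FoodWebModel, focal) -> list[int]:
    if isinstance(focal, (int, np.integer, str)):
        focal = [focal]
    pos = [model.index_of(f) for f in focal]
    if not pos:
        raise FoodWebError("focal set is empty")
    for p in pos:
        if model.groups[p].group_type != "living":
            raise FoodWebError(
                f"focal group {model.groups[p].name!r} is not a living group"
            )
    return pos


def production_fraction_matrix(model: FoodWebModel, validate: bool = True) -> np.ndarray:
    """phi[g, k]: fraction of g's production consumed by k.

    Production is B*P/B; consumption includes predation and fleet
    landings.  Rows of groups with zero production are zero.
    """
    flux = consumption_flux_matrix(model, validate=validate)
    prod = model.biomass * model.param("pb")
    phi = np.zeros_like(flux.q)
    pos = prod > 0
    phi[pos, :] = flux.q[pos, :] / prod[pos, np.newaxis]
    return phi


def _solve(lhs: np.ndarray, rhs: np.ndarray, what: str) -> np.ndarray:
    try:
        x = np.linalg.solve(lhs, rhs)
    except np.linalg.LinAlgError:
        x = None
    if x is None or not np.all(np.isfinite(x)) or (
        np.max(np.abs(lhs @ x - rhs)) > 1e-8 if x is not None else True
    ):
        raise FoodWebError(
            f"{what} system is singular: the web has a pathway loop with "
            "no leakage (no detritus, metabolic or fishery loss anywhere)"
        )
    return x


def destined_fractions(
    model: FoodWebModel,
    focal,
    exclude: tuple[str, ...] = DEFAULT_PATHWAY_EXCLUDE,
    validate: bool = True,
) -> pd.Series:
    """Fraction of each living group's production destined for the focal.

    Solves D[g] = phi[g, focal] + sum_k phi[g, k] D[k] over living
    non-focal groups k (fleets are terminal consumers: flux into a
    fleet is counted only when the fleet itself is focal, which it
    cannot be).  D[focal] = 1 by convention.
    """
    foc = _focal_positions(model, focal)
    phi = production_fraction_matrix(model, validate=validate)
    living = np.flatnonzero(model.living)
    excl = model.mask(*exclude) if exclude else np.zeros(model.n, dtype=bool)
    inner = [i for i in living if i not in foc and not excl[i]]

    b = phi[np.ix_(inner, foc)].sum(axis=1)
    a = phi[np.ix_(inner, inner)]
    d_inner = _solve(np.eye(len(inner)) - a, b, "destined-fraction")

    d = pd.Series(0.0, index=pd.Index(model.ids[living], name="group_id"))
    pos_of = {i: model.groups[i].id for i in range(model.n)}
    for i, val in zip(inner, d_inner):
        d[pos_of[i]] = float(val)
    for p in foc:
        d[pos_of[p]] = 1.0
    return d


def pass_through_fractions(
    model: FoodWebModel,
    focal,
    exclude: tuple[str, ...] = DEFAULT_PATHWAY_EXCLUDE,
    validate: bool = True,
) -> pd.Series:
    """Fraction of each consumer's production that passed through the focal.

    With psi[k, c] = DC[k, c] (share of c's consumption taken from k),
    solves P[c] = psi[focal, c] + sum_k psi[k, c] P[k] over living
    non-focal groups k outside the excluded pools.  P[focal] = 1.
    """
    foc = _focal_positions(model, focal)
    if validate:
        from .model import validate_model

        problems = validate_model(model)
        if problems:
            raise FoodWebError("model fails validation:\n  " + "\n  ".join(problems))
    psi = model.diet
    living = np.flatnonzero(model.living)
    excl = model.mask(*exclude) if exclude else np.zeros(model.n, dtype=bool)
    inner = [i for i in living if i not in foc and not excl[i]]

    b = psi[np.ix_(foc, inner)].sum(axis=0)
    a = psi[np.ix_(inner, inner)].T  # [c, k] orientation
    p_inner = _solve(np.eye(len(inner)) - a, b, "pass-through")

    p = pd.Series(0.0, index=pd.Index(model.ids[living], name="group_id"))
    pos_of = {i: model.groups[i].id for i in range(model.n)}
    for i, val in zip(inner, p_inner):
        p[pos_of[i]] = float(val)
    for f in foc:
        p[pos_of[f]] = 1.0
    return p


def footprint(
    model: FoodWebModel,
    focal,
    exclude: tuple[str, ...] = DEFAULT_PATHWAY_EXCLUDE,
    destined: pd.Series | None = None,
) -> float:
    """Production-weighted aggregate of destined fractions.

    footprint = sum_{g != focal} D[g] * Prod_g / sum_{g != focal} Prod_g
    over living groups, Prod_g = B_g * P/B_g.  The focal's own
    production is excluded from numerator and denominator.
    """
    foc = _focal_positions(model, focal)
    if destined is None:
        destined = destined_fractions(model, focal, exclude)
    living = np.flatnonzero(model.living)
    prod = model.biomass * model.param("pb")
    others = [i for i in living if i not in foc]
    total = sum(prod[i] for i in others)
    if total <= 0:
        raise FoodWebError("total non-focal production is zero")
    num = sum(destined[model.groups[i].id] * prod[i] for i in others)
    return float(num / total)


def reach(
    model: FoodWebModel,
    focal,
    exclude: tuple[str, ...] = DEFAULT_PATHWAY_EXCLUDE,
    pass_through: pd.Series | None = None,
) -> float:
    """Consumer-production-weighted aggregate of pass-through fractions.

    reach = sum_c P[c] * Prod_c / sum_c Prod_c over living consumer
    groups (non-producer living groups), counting the focal's own
    production with P[focal] = 1.
    """
    foc = _focal_positions(model, focal)
    if pass_through is None:
        pass_through = pass_through_fractions(model, focal, exclude)
    prod = model.biomass * model.param("pb")
    consumers = np.flatnonzero(model.living & ~model.is_producer())
    cons = set(consumers.tolist()) | set(foc)
    total = sum(prod[i] for i in cons)
    if total <= 0:
        raise FoodWebError("total consumer production is zero")
    num = sum(pass_through[model.groups[i].id] * prod[i] for i in cons)
    return float(num / total)


def footprint_reach(
    model: FoodWebModel,
    focal,
    exclude: tuple[str, ...] = DEFAULT_PATHWAY_EXCLUDE,
    validate: bool = True,
) -> FootprintReachResult:
    """Compute both metrics and their per-group trace vectors."""
    foc = _focal_positions(model, focal)
    d = destined_fractions(model, focal, exclude, validate=validate)
    p = pass_through_fractions(model, focal, exclude, validate=False)
    return FootprintReachResult(
        focal=tuple(model.groups[i].id for i in foc),
        footprint=footprint(model, focal, exclude, destined=d),
        reach=reach(model, focal, exclude, pass_through=p),
        destined=d,
        pass_through=p,
    )
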
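"""Harmonizing two ecosystem states and computing their difference network.

Two models built for different time periods rarely share an identical
group list.  Harmonization aggregates groups under explicit mapping
tables, inserts groups missing from one model at trace biomass, and
orders both models identically.  Carried-over diet links (present in
the second model only because its diet matrix was seeded from the
first) can be pruned against observed-diet evidence.  The difference
network then reports, per node, the biomass multiplication factor
(second state over first, so a factor above one is an increase) and,
per edge, the signed consumption-flux delta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    TRACE_BIOMASS,
    FoodWebError,
    FoodWebModel,
    FunctionalGroup,
    FluxNetwork,
    NORM_TOL,
    add_trace_group,
    aggregate_groups,
)

__all__ = [
    "DifferenceNetwork",
    "harmonize_models",
    "prune_carryover_links",
    "prune_model_carryover",
    "difference_network",
]


@dataclass
class DifferenceNetwork:
    """Node biomass factors and signed edge-flux deltas of two states."""

    ids: np.ndarray
    names: list[str]
    factor: np.ndarray  # B_after / B_before, trace-floored
    log_factor: np.ndarray
    edge_delta: np.ndarray  # q_after - q_before

    def node_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "name": self.names,
                "factor": self.factor,
                "log_factor": self.log_factor,
            }
        )

    def edge_frame(self, keep_zero: bool = False) -> pd.DataFrame:
        rows = []
        n = len(self.ids)
        for i in range(n):
            for j in range(n):
                d = self.edge_delta[i, j]
                if keep_zero or d != 0:
                    rows.append((self.ids[i], self.ids[j], d, int(np.sign(d))))
        return pd.DataFrame(rows, columns=["src", "dst", "delta", "sign"])


def harmonize_models(
    model_a: FoodWebModel,
    model_b: FoodWebModel,
    mapping: pd.DataFrame | None = None,
    trace_biomass: float = TRACE_BIOMASS,
) -> tuple[FoodWebModel, FoodWebModel]:
    """Bring two models onto one common, identically ordered group set.

    ``mapping`` has columns (old_id, model, new_id, new_name) with
    ``model`` in {'a', 'b'}; omitted groups map to themselves.  Any
    group present in only one model is inserted into the other at
    trace biomass, with its diet column copied (restricted to shared
    prey and renormalized).
    """
    def _apply(model: FoodWebModel, tag: str) -> FoodWebModel:
        full = {int(g.id): int(g.id) for g in model.groups}
        names: dict[int, str] = {}
        if mapping is not None:
            sub = mapping[mapping["model"].astype(str).str.lower() == tag]
            for _, row in sub.iterrows():
                old = int(row["old_id"])
                if old not in full:
                    raise FoodWebError(
                        f"mapping refers to unknown group {old} in model {tag!r}"
                    )
                full[old] = int(row["new_id"])
                if "new_name" in row and isinstance(row["new_name"], str):
                    names[int(row["new_id"])] = row["new_name"]
        return aggregate_groups(model, full, names=names)

    a = _apply(model_a, "a")
    b = _apply(model_b, "b")

    def _insert_missing(target: FoodWebModel, source: FoodWebModel) -> FoodWebModel:
        for g in source.groups:
            if int(g.id) in target.ids.tolist():
                continue
            diet_col = None
            if g.group_type == "living" and g.qb > 0:
                col = {}
                j = source.index_of(int(g.id))
                for i, prey in enumerate(source.groups):
                    frac = source.diet[i, j]
                    if frac > 0 and int(prey.id) in target.ids.tolist():
                        col[int(prey.id)] = frac
                if not col:
                    raise FoodWebError(
                        f"group {g.name!r} cannot be inserted: none of its "
                        "prey exist in the other model"
                    )
                diet_col = col
            target = add_trace_group(
                target,
                FunctionalGroup(
                    id=int(g.id),
                    name=g.name,
                    group_type=g.group_type,
                    biomass=trace_biomass,
                    pb=g.pb,
                    qb=g.qb,
                    ae=g.ae,
                ),
                diet_column=diet_col,
            )
        return target

    a = _insert_missing(a, b)
    b = _insert_missing(b, a)

    order = sorted(int(i) for i in a.ids)
    if order != sorted(int(i) for i in b.ids):
        missing = set(a.ids.tolist()) ^ set(b.ids.tolist())
        raise FoodWebError(f"unmappable groups remain after harmonization: {missing}")

    def _reorder(model: FoodWebModel) -> FoodWebModel:
        perm = [model.index_of(i) for i in order]
        ped = model.pedigree
        from .model import PedigreeCV

        return FoodWebModel(
            groups=[model.groups[p] for p in perm],
            diet=model.diet[np.ix_(perm, perm)],
            landings=model.landings[np.ix_(perm, perm)],
            pedigree=PedigreeCV(
                diet=ped.diet[np.ix_(perm, perm)], params=ped.params[perm]
            ),
            currency=model.currency,
            time_unit=model.time_unit,
            provenance=model.provenance,
        )

    return _reorder(a), _reorder(b)


def prune_carryover_links(
    diet: np.ndarray,
    ids: np.ndarray,
    evidence: set[tuple[int, int]],
    consumer_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Zero every positive diet cell not backed by observed evidence.

    ``evidence`` holds (prey_id, predator_id) pairs seen in the
    period's own diet data; any positive cell outside it is a carried-
    over link and is removed.  Affected columns are renormalized to
    one.  Returns the pruned matrix and a report of removed cells.

    Raises
    ------
    FoodWebError
        If a consumer loses its entire diet.
    """
    diet = np.asarray(diet, dtype=float).copy()
    ids = np.asarray(ids, dtype=int)
    id_set = set(ids.tolist())
    for prey, pred in evidence:
        if prey not in id_set or pred not in id_set:
            raise FoodWebError(
                f"evidence pair ({prey}, {pred}) outside the model's group ids"
            )
    removed = []
    n = len(ids)
    touched = set()
    for j in range(n):
        for i in range(n):
            if diet[i, j] > 0 and (int(ids[i]), int(ids[j])) not in evidence:
                removed.append((int(ids[i]), int(ids[j]), diet[i, j]))
                diet[i, j] = 0.0
                touched.add(j)
    for j in touched:
        had_diet = consumer_mask[j] if consumer_mask is not None else True
        s = diet[:, j].sum()
        if s <= 0:
            if had_diet:
                raise FoodWebError(
                    f"consumer {ids[j]} lost its entire diet during pruning"
                )
            continue
        diet[:, j] /= s
    report = pd.DataFrame(removed, columns=["prey_id", "predator_id", "removed_fraction"])
    return diet, report


def prune_model_carryover(
    model: FoodWebModel, evidence: set[tuple[int, int]]
) -> tuple[FoodWebModel, pd.DataFrame]:
    """Model-level wrapper around :func:`prune_carryover_links`."""
    qb = model.param("qb")
    consumer = model.living & (qb > 0)
    diet, report = prune_carryover_links(
        model.diet, model.ids, evidence, consumer_mask=consumer
    )
    out = model.copy()
    out.diet = diet
    return out, report


def difference_network(
    flux_a: FluxNetwork,
    flux_b: FluxNetwork,
    trace_floor: float = TRACE_BIOMASS,
) -> DifferenceNetwork:
    """Difference of two harmonized states: second argument over first.

    Node factor = B_b / B_a (a factor above one is an increase from
    the first to the second state); edge delta = q_b - q_a.  Biomasses
    are floored at the trace level before the ratio so inserted trace
    groups never divide by zero.
    """
    if flux_a.n != flux_b.n or (flux_a.ids != flux_b.ids).any():
        raise FoodWebError("difference network requires identical node sets and order")
    ba = np.maximum(flux_a.biomass, trace_floor)
    bb = np.maximum(flux_b.biomass, trace_floor)
    factor = bb / ba
    return DifferenceNetwork(
        ids=flux_a.ids.copy(),
        names=list(flux_a.names),
        factor=factor,
        log_factor=np.log(factor),
        edge_delta=flux_b.q - flux_a.q,
    )
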
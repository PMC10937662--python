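"""Food-web network metrics: trophic levels, connectance, link density.

The analyzed node set by default includes living groups, detritus pools
and fleets but excludes nutrient pools, matching the convention that
nutrient cycling is bookkeeping rather than trophic structure.  A link
is any strictly positive entry of the diet/landings support; the
connectance denominator is N^2 (self-links are possible, so an 86-node
web has 7396 possible links).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .model import FoodWebModel, FoodWebError

__all__ = [
    "DEFAULT_EXCLUDE",
    "NetworkMetricSet",
    "analyzed_mask",
    "adjacency",
    "trophic_levels",
    "mean_trophic_level",
    "biomass_weighted_tl",
    "connectance",
    "link_density",
    "possible_links",
    "compute_network_metrics",
    "bootstrap_metrics",
]

DEFAULT_EXCLUDE = ("nutrient",)


@dataclass
class NetworkMetricSet:
    """Summary metrics of one analyzed network."""

    n_nodes: int
    n_links: int
    connectance: float
    link_density: float
    mean_tl: float
    biomass_weighted_tl: float

    @property
    def n_possible(self) -> int:
        return self.n_nodes ** 2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_nodes": [self.n_nodes],
                "n_links": [self.n_links],
                "connectance": [self.connectance],
                "link_density": [self.link_density],
                "mean_tl": [self.mean_tl],
                "biomass_weighted_tl": [self.biomass_weighted_tl],
            }
        )


def analyzed_mask(model: FoodWebModel, exclude: tuple[str, ...] = DEFAULT_EXCLUDE) -> np.ndarray:
    """Boolean mask selecting the analyzed node set."""
    return ~model.mask(*exclude) if exclude else np.ones(model.n, dtype=bool)


def adjacency(
    model: FoodWebModel, exclude: tuple[str, ...] = DEFAULT_EXCLUDE
) -> np.ndarray:
    """Directed boolean adjacency (prey -> predator, group -> fleet).

    Built from the diet/landings support: A[i, j] is True wherever
    DC[i, j] > 0 or Y[i, j] > 0, restricted to the analyzed node set.
    """
    keep = analyzed_mask(model, exclude)
    a = (model.diet > 0) | (model.landings > 0)
    return a[np.ix_(keep, keep)]


def trophic_levels(
    diet: np.ndarray,
    group_types: np.ndarray | list[str],
    exclude: tuple[str, ...] = DEFAULT_EXCLUDE,
    names: list[str] | None = None,
) -> np.ndarray:
    """Diet-weighted trophic levels, TL_j = 1 + sum_i DC[i, j] * TL_i.

    Nutrient pools are dropped from the node set; diet columns are
    renormalized over the remaining nodes.  Nodes whose renormalized
    column is empty (producers, detritus, fleets) sit at TL 1; the
    system is solved as (I - DC^T) TL = 1, which handles cycles such
    as cannibalism or mutual predation.  Returns a full-length vector
    with NaN at excluded positions.

    Raises
    ------
    FoodWebError
        If the system is singular: some set of consumers forms a
        closed loop with no dietary path to a basal node.
    """
    group_types = np.asarray(group_types, dtype=object)
    n = len(group_types)
    diet = np.asarray(diet, dtype=float)
    if diet.shape != (n, n):
        raise FoodWebError(f"diet shape {diet.shape} does not match {n} nodes")
    keep = ~np.isin(group_types, exclude) if exclude else np.ones(n, dtype=bool)
    idx = np.flatnonzero(keep)
    d = diet[np.ix_(idx, idx)].copy()
    colsum = d.sum(axis=0)
    pos = colsum > 0
    d[:, pos] = d[:, pos] / colsum[pos]

    m = idx.size
    lhs = np.eye(m) - d.T
    rhs = np.ones(m)
    try:
        tl_sub = np.linalg.solve(lhs, rhs)
    except np.linalg.LinAlgError:
        tl_sub = None
    if tl_sub is None or not np.all(np.isfinite(tl_sub)) or np.max(
        np.abs(lhs @ tl_sub - rhs)
    ) > 1e-6:
        comp = _closed_loop(d, names=[names[i] for i in idx] if names else None)
        raise FoodWebError(
            "trophic-level system is singular: consumers "
            f"{comp} form a closed loop with no path to a basal node"
        )
    out = np.full(n, np.nan)
    out[idx] = tl_sub
    return out


def _closed_loop(d: np.ndarray, names: list[str] | None = None) -> list:
    """Name a strongly connected consumer component with no basal path."""
    g = nx.DiGraph(
        [(i, j) for i in range(len(d)) for j in range(len(d)) if d[i, j] > 0]
    )
    basal = {j for j in range(len(d)) if d[:, j].sum() == 0}
    for comp in nx.strongly_connected_components(g):
        if len(comp) < 2 and not any(d[c, c] > 0 for c in comp):
            continue
        reachable_basal = False
        for c in comp:
            if any(nx.has_path(g.reverse(), c, b) for b in basal if b in g):
                reachable_basal = True
                break
        if not reachable_basal:
            comp = sorted(comp)
            return [names[c] for c in comp] if names else comp
    return []


def mean_trophic_level(tl: np.ndarray) -> float:
    """Arithmetic mean trophic level over analyzed (non-NaN) nodes."""
    return float(np.nanmean(np.asarray(tl, dtype=float)))


def biomass_weighted_tl(tl: np.ndarray, biomass: np.ndarray) -> float:
    """Biomass-weighted mean trophic level, sum(B*TL)/sum(B)."""
    tl = np.asarray(tl, dtype=float)
    b = np.asarray(biomass, dtype=float)
    ok = ~np.isnan(tl)
    w = b[ok]
    if w.sum() <= 0:
        raise FoodWebError("biomass-weighted TL undefined for all-zero biomass")
    return float(np.dot(w, tl[ok]) / w.sum())


def possible_links(n_nodes: int) -> int:
    """Number of possible directed links, N^2 (self-links allowed)."""
    return int(n_nodes) ** 2


def connectance(adj: np.ndarray) -> float:
    """Realized links over possible links (N^2 denominator)."""
    adj = np.asarray(adj)
    n = adj.shape[0]
    if n == 0:
        raise FoodWebError("connectance undefined for an empty node set")
    return float(np.count_nonzero(adj) / possible_links(n))


def link_density(adj: np.ndarray) -> float:
    """Realized links per node."""
    adj = np.asarray(adj)
    n = adj.shape[0]
    if n == 0:
        raise FoodWebError("link density undefined for an empty node set")
    return float(np.count_nonzero(adj) / n)


def compute_network_metrics(
    model: FoodWebModel, exclude: tuple[str, ...] = DEFAULT_EXCLUDE
) -> NetworkMetricSet:
    """All Table-style metrics of one model on its analyzed node set."""
    keep = analyzed_mask(model, exclude)
    adj = adjacency(model, exclude)
    tl = trophic_levels(model.diet, model.types, exclude, names=model.names)
    return NetworkMetricSet(
        n_nodes=int(keep.sum()),
        n_links=int(np.count_nonzero(adj)),
        connectance=connectance(adj),
        link_density=link_density(adj),
        mean_tl=mean_trophic_level(tl),
        biomass_weighted_tl=biomass_weighted_tl(tl, model.biomass),
    )


def bootstrap_metrics(
    adj: np.ndarray, n_boot: int, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Node bootstrap of connectance and link density.

    Each replicate draws N node indices with replacement and evaluates
    both metrics on the induced matrix A[s, :][:, s] (duplicate rows and
    columns kept).  Returns a long-format frame with one row per
    (replicate, metric); summarize with ``groupby('metric')``.
    """
    if n_boot < 1:
        raise FoodWebError("n_boot must be >= 1")
    adj = np.asarray(adj)
    n = adj.shape[0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for r in range(n_boot):
        s = rng.integers(0, n, size=n)
        boot = adj[np.ix_(s, s)]
        rows.append((r, "connectance", connectance(boot)))
        rows.append((r, "link_density", link_density(boot)))
    return pd.DataFrame(rows, columns=["replicate", "metric", "value"])
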
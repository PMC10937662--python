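"""Footprint/reach tracing against exhaustive path enumeration."""

import networkx as nx
import numpy as np
import pytest

from trophicflux import (
    FunctionalGroup,
    add_trace_group,
    destined_fractions,
    footprint,
    footprint_reach,
    pass_through_fractions,
    reach,
)

from conftest import build_model, random_acyclic_model


def enumerate_destined(phi, nodes, focal):
    """Oracle: D[g] = sum over all simple paths g -> ... -> focal of
    the product of phi edge fractions (exact on a DAG)."""
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for (i, j), f in phi.items():
        g.add_edge(i, j, w=f)
    out = {}
    for src in nodes:
        if src == focal:
            out[src] = 1.0
            continue
        total = 0.0
        if src in g and focal in g:
            for path in nx.all_simple_paths(g, src, focal):
                total += np.prod([g[a][b]["w"] for a, b in zip(path, path[1:])])
        out[src] = total
    return out


def enumerate_pass_through(model, focal_pos):
    """Oracle: P[c] = sum over simple diet paths focal -> ... -> c of
    the product of diet fractions."""
    g = nx.DiGraph()
    living = np.flatnonzero(model.living)
    for i in living:
        for j in living:
            if model.diet[i, j] > 0:
                g.add_edge(i, j, w=model.diet[i, j])
    out = {}
    for c in living:
        if c == focal_pos:
            out[c] = 1.0
            continue
        total = 0.0
        if focal_pos in g and c in g:
            for path in nx.all_simple_paths(g, focal_pos, c):
                total += np.prod([g[a][b]["w"] for a, b in zip(path, path[1:])])
        out[c] = total
    return out


class TestDestinedFractions:
    def test_total_transfer_chain(self):
        # all of P's production to H, all of H's to C
        groups = [
            FunctionalGroup(id=1, name="n", group_type="nutrient"),
            FunctionalGroup(id=2, name="d", group_type="detritus"),
            FunctionalGroup(id=3, name="P", group_type="living", biomass=10.0, pb=1.0, qb=2.0, ae=1.0),
            FunctionalGroup(id=4, name="H", group_type="living", biomass=1.0, pb=2.5, qb=10.0, ae=0.8),
            FunctionalGroup(id=5, name="C", group_type="living", biomass=1.0, pb=0.5, qb=2.5, ae=0.8),
        ]
        diet = np.zeros((5, 5))
        diet[0, 2] = 1.0
        diet[2, 3] = 1.0
        diet[3, 4] = 1.0
        m = build_model(groups, diet)
        d = destined_fractions(m, "C")
        assert d[3] == pytest.approx(1.0)
        assert d[4] == pytest.approx(1.0)

    def test_group_without_path_gets_zero(self, branched_model):
        d = destined_fractions(branched_model, "H1")
        assert d[5] == 0.0  # H2 has no path into H1

    def test_branched_web_hand_enumeration(self, branched_model):
        d = destined_fractions(branched_model, "C")
        assert d[3] == pytest.approx(0.4)
        assert d[4] == pytest.approx(0.5)
        assert d[5] == pytest.approx(0.5)

    def test_matches_path_enumeration_on_random_dags(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            model, phi, _ = random_acyclic_model(rng)
            living = np.flatnonzero(model.living)
            focal = int(rng.choice(living))
            oracle = enumerate_destined(phi, living.tolist(), focal)
            d = destined_fractions(model, model.groups[focal].name)
            for pos in living:
                assert abs(d[model.groups[pos].id] - oracle[pos]) < 1e-9

    def test_adding_direct_edge_to_focal_cannot_decrease(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            model, phi, _ = random_acyclic_model(rng, n_living=6)
            living = np.flatnonzero(model.living)
            consumers = [j for j in living if model.diet[living, :][:, j].sum() > 0]
            if not consumers:
                continue
            focal = consumers[-1]
            src = int(living[0])
            if src == focal:
                continue
            before = destined_fractions(model, model.groups[focal].name)
            # add a brand-new flux edge src -> focal while leaving every
            # existing flux untouched (diet shift compensated through qb)
            eps = 0.2
            model.diet[:, focal] *= 1 - eps
            model.diet[src, focal] += eps
            model.groups[focal].qb /= 1 - eps
            after = destined_fractions(model, model.groups[focal].name)
            assert after[model.groups[src].id] >= before[model.groups[src].id] - 1e-12


class TestPassThrough:
    def test_chain_full_pass_through(self, branched_model):
        p = pass_through_fractions(branched_model, "P")
        assert p[4] == pytest.approx(1.0)
        assert p[6] == pytest.approx(1.0)

    def test_no_path_from_focal_gives_zero(self, branched_model):
        p = pass_through_fractions(branched_model, "H1")
        assert p[5] == 0.0

    def test_half_diet_pass_through(self, branched_model):
        p = pass_through_fractions(branched_model, "H1")
        assert p[6] == pytest.approx(0.5)

    def test_matches_path_enumeration_on_random_dags(self):
        rng = np.random.default_rng(321)
        for _ in range(100):
            model, _, _ = random_acyclic_model(rng)
            living = np.flatnonzero(model.living)
            focal = int(rng.choice(living))
            oracle = enumerate_pass_through(model, focal)
            p = pass_through_fractions(model, model.groups[focal].name)
            for pos in living:
                assert abs(p[model.groups[pos].id] - oracle[pos]) < 1e-9


class TestFootprintReach:
    def test_primary_producer_has_zero_footprint(self, branched_model):
        assert footprint(branched_model, "P") == 0.0

    def test_branched_footprint_weighted_sum(self, branched_model):
        # (0.4*10 + 0.5*2 + 0.5*2) / 14
        assert footprint(branched_model, "C") == pytest.approx(3 / 7)

    def test_branched_reach(self, branched_model):
        # (1*2 + 0*2 + 0.5*0.5) / 4.5
        assert reach(branched_model, "H1") == pytest.approx(0.5)

    def test_fractions_stay_in_unit_interval(self):
        rng = np.random.default_rng(77)
        for _ in range(30):
            model, _, _ = random_acyclic_model(rng)
            living = np.flatnonzero(model.living)
            focal = model.groups[int(rng.choice(living))].name
            r = footprint_reach(model, focal)
            assert 0.0 <= r.footprint <= 1.0
            assert 0.0 <= r.reach <= 1.0
            assert ((r.destined >= 0) & (r.destined <= 1 + 1e-12)).all()
            assert ((r.pass_through >= 0) & (r.pass_through <= 1 + 1e-12)).all()

    def test_focal_set_merges_nodes(self, branched_model):
        r = footprint_reach(branched_model, ["H1", "H2"])
        # both herbivore paths now lead to the focal set: D[P] = 0.8
        assert r.destined[3] == pytest.approx(0.8)
        # footprint over remaining groups P and C
        assert r.footprint == pytest.approx((0.8 * 10 + 0.0 * 0.5) / 10.5)

    def test_whole_community_footprint_approaches_one_without_leakage(self):
        # chain with full transfer: everything below the focal reaches it
        groups = [
            FunctionalGroup(id=1, name="n", group_type="nutrient"),
            FunctionalGroup(id=2, name="d", group_type="detritus"),
            FunctionalGroup(id=3, name="P", group_type="living", biomass=10.0, pb=1.0, qb=2.0, ae=1.0),
            FunctionalGroup(id=4, name="H", group_type="living", biomass=1.0, pb=2.5, qb=10.0, ae=0.8),
            FunctionalGroup(id=5, name="C", group_type="living", biomass=1.0, pb=0.5, qb=2.5, ae=0.8),
        ]
        diet = np.zeros((5, 5))
        diet[0, 2] = 1.0
        diet[2, 3] = 1.0
        diet[3, 4] = 1.0
        m = build_model(groups, diet)
        assert footprint(m, ["H", "C"]) == pytest.approx(1.0)
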
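"""Shared fixtures: small hand-balanced food webs with known arithmetic."""

import numpy as np
import pytest

from trophicflux import FoodWebModel, FunctionalGroup


def build_model(groups, diet, landings=None, **kw):
    return FoodWebModel(groups=groups, diet=np.array(diet, dtype=float),
                        landings=None if landings is None else np.array(landings, dtype=float),
                        **kw)


@pytest.fixture
def toy_model():
    """nutrient(1), detritus(2), producer P(3), herbivore H(4).

    P: B=10, pb=1, qb=2, ae=1 (eats nutrients).  H: B=1, qb=5, pb=1,
    ae=0.8, diet 100% P.  Hand balance: demand on P = 1*5 = 5,
    production of P = 10, so EE(P) = 0.5; EE(H) = 0.
    """
    groups = [
        FunctionalGroup(id=1, name="NH4", group_type="nutrient"),
        FunctionalGroup(id=2, name="detritus", group_type="detritus"),
        FunctionalGroup(id=3, name="P", group_type="living", biomass=10.0, pb=1.0, qb=2.0, ae=1.0),
        FunctionalGroup(id=4, name="H", group_type="living", biomass=1.0, pb=1.0, qb=5.0, ae=0.8),
    ]
    diet = [
        [0, 0, 1.0, 0],
        [0, 0, 0, 0],
        [0, 0, 0, 1.0],
        [0, 0, 0, 0],
    ]
    return build_model(groups, diet)


@pytest.fixture
def fate_model():
    """Focal group g with Q=10, ae=0.8, pb/qb=0.3, EE=0.8.

    g: B=1, qb=10, pb=3; predator C takes 2.4 = 0.8 * production(3).
    Fate split of g: egestion 0.2, metabolism 0.5, predation 0.24,
    senescence 0.06.
    """
    groups = [
        FunctionalGroup(id=1, name="NH4", group_type="nutrient"),
        FunctionalGroup(id=2, name="detritus", group_type="detritus"),
        FunctionalGroup(id=3, name="P", group_type="living", biomass=100.0, pb=1.0, qb=2.0, ae=1.0),
        FunctionalGroup(id=4, name="g", group_type="living", biomass=1.0, pb=3.0, qb=10.0, ae=0.8),
        FunctionalGroup(id=5, name="C", group_type="living", biomass=1.0, pb=0.6, qb=2.4, ae=0.8),
    ]
    diet = [
        [0, 0, 1.0, 0, 0],
        [0, 0, 0, 0, 0],
        [0, 0, 0, 1.0, 0],
        [0, 0, 0, 0, 1.0],
        [0, 0, 0, 0, 0],
    ]
    return build_model(groups, diet)


@pytest.fixture
def branched_model():
    """P -> {H1, H2} -> C with known production fractions.

    P: B=10, pb=1 (production 10); H1, H2 each consume 4 from P
    (phi[P->H] = 0.4 each) and produce 2; C consumes 1 from each
    (phi[H->C] = 0.5) with diet 50/50 and produces 0.5.

    Hand-enumerated destined fractions for focal C:
    D[H1] = D[H2] = 0.5, D[P] = 0.4*0.5 + 0.4*0.5 = 0.4;
    footprint(C) = (0.4*10 + 0.5*2 + 0.5*2) / 14 = 3/7.
    Pass-through for focal H1: P[C] = 0.5;
    reach(H1) = (1*2 + 0*2 + 0.5*0.5) / 4.5 = 0.5.
    """
    groups = [
        FunctionalGroup(id=1, name="NH4", group_type="nutrient"),
        FunctionalGroup(id=2, name="detritus", group_type="detritus"),
        FunctionalGroup(id=3, name="P", group_type="living", biomass=10.0, pb=1.0, qb=2.0, ae=1.0),
        FunctionalGroup(id=4, name="H1", group_type="living", biomass=1.0, pb=2.0, qb=4.0, ae=0.8),
        FunctionalGroup(id=5, name="H2", group_type="living", biomass=1.0, pb=2.0, qb=4.0, ae=0.8),
        FunctionalGroup(id=6, name="C", group_type="living", biomass=1.0, pb=0.5, qb=2.0, ae=0.8),
    ]
    diet = [
        [0, 0, 1.0, 0, 0, 0],
        [0, 0, 0, 0, 0, 0],
        [0, 0, 0, 1.0, 1.0, 0],
        [0, 0, 0, 0, 0, 0.5],
        [0, 0, 0, 0, 0, 0.5],
        [0, 0, 0, 0, 0, 0],
    ]
    return build_model(groups, diet)


def random_acyclic_model(rng, n_living=None):
    """Random balanced acyclic web with an exact, enumerable phi graph.

    Nodes are processed in topological order; roots are nutrient-fed
    producers with production 1.  Each node sends random production
    fractions (row sum <= 0.9, so there is leakage everywhere) to
    later nodes; a consumer's production is 0.25 of its consumption,
    so pb = 0.25 * qb < ae * qb.  Returns (model, phi) where
    phi[i][j] is the exact fraction of i's production consumed by j.
    """
    if n_living is None:
        n_living = int(rng.integers(3, 9))
    n = n_living + 2  # + nutrient + detritus
    groups = [
        FunctionalGroup(id=1, name="NH4", group_type="nutrient"),
        FunctionalGroup(id=2, name="detritus", group_type="detritus"),
    ]
    liv = list(range(2, n))
    # random DAG edges: i -> j for i < j in living order
    edges = {}
    for a in range(n_living):
        targets = [b for b in range(a + 1, n_living) if rng.random() < 0.5]
        if targets:
            raw = rng.uniform(0.1, 1.0, size=len(targets))
            raw = raw / raw.sum() * rng.uniform(0.3, 0.9)
            for b, f in zip(targets, raw):
                edges[(a, b)] = float(f)

    prod = np.zeros(n_living)
    cons = np.zeros(n_living)
    q = np.zeros((n_living, n_living))
    for a in range(n_living):
        incoming = [(i, f) for (i, b), f in edges.items() if b == a]
        if not incoming:
            prod[a] = 1.0
        else:
            for i, f in incoming:
                q[i, a] = f * prod[i]
            cons[a] = q[:, a].sum()
            prod[a] = 0.25 * cons[a]

    diet = np.zeros((n, n))
    for a in range(n_living):
        j = 2 + a
        if cons[a] == 0:  # producer
            diet[0, j] = 1.0
            groups.append(FunctionalGroup(id=j + 1, name=f"g{a}", group_type="living",
                                          biomass=1.0, pb=prod[a], qb=prod[a], ae=1.0))
        else:
            diet[2:, j] = q[:, a] / cons[a]
            groups.append(FunctionalGroup(id=j + 1, name=f"g{a}", group_type="living",
                                          biomass=1.0, pb=prod[a], qb=cons[a], ae=0.8))
    phi = {(2 + i, 2 + b): f for (i, b), f in edges.items()}
    model = FoodWebModel(groups=groups, diet=diet)
    return model, phi, prod
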
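"""Core model: validation, mass balance, fluxes, fates, editing."""

import numpy as np
import pytest

from trophicflux import (
    FoodWebError,
    FoodWebModel,
    FunctionalGroup,
    ImbalanceError,
    add_trace_group,
    aggregate_groups,
    build_production_fate,
    compute_ee,
    consumption_flux_matrix,
    is_balanced,
    validate_model,
)

from conftest import build_model


class TestValidation:
    def test_well_formed_model_has_empty_report(self, toy_model):
        assert validate_model(toy_model) == []

    def test_diet_column_not_summing_to_one_is_named(self, toy_model):
        toy_model.diet[2, 3] = 0.9  # H's column now sums to 0.9
        report = validate_model(toy_model)
        assert len(report) == 1
        assert "column of consumer 4" in report[0]

    def test_production_exceeding_assimilation_is_named(self, toy_model):
        toy_model.groups[3].pb = 4.5  # ae*qb = 0.8*5 = 4
        report = validate_model(toy_model)
        assert len(report) == 1 and "group 4" in report[0]

    def test_nonliving_predator_column_rejected(self, toy_model):
        toy_model.diet[2, 1] = 0.5  # detritus "eating" the producer
        assert any("detritus" in r for r in validate_model(toy_model))

    def test_non_square_diet_raises_structural_error(self):
        with pytest.raises(FoodWebError, match="square"):
            FoodWebModel(
                groups=[FunctionalGroup(id=1, name="x", group_type="living")],
                diet=np.zeros((1, 2)),
            )


class TestEcotrophicEfficiency:
    def test_hand_balanced_toy(self, toy_model):
        ee = compute_ee(toy_model)
        assert ee[toy_model.index_of(3)] == pytest.approx(0.5)  # demand 5 / production 10
        assert is_balanced(toy_model)

    def test_unconsumed_group_has_zero_ee(self, toy_model):
        assert compute_ee(toy_model)[toy_model.index_of(4)] == 0.0

    def test_overconsumption_gives_ee_above_one(self, toy_model):
        toy_model.groups[3].qb = 25.0
        toy_model.groups[3].pb = 4.0  # keep pb <= ae*qb valid
        ee = compute_ee(toy_model)
        assert ee[toy_model.index_of(3)] == pytest.approx(2.5)  # demand 25 / production 10
        assert not is_balanced(toy_model)

    def test_demand_on_zero_production_group_errors(self, toy_model):
        toy_model.groups[2].pb = 0.0
        with pytest.raises(ImbalanceError, match="P"):
            compute_ee(toy_model)

    def test_nonliving_groups_have_nan_ee(self, toy_model):
        ee = compute_ee(toy_model)
        assert np.isnan(ee[toy_model.index_of(1)])


class TestFluxNetwork:
    def test_flux_is_biomass_times_qb_times_diet(self, toy_model):
        # q[P -> H] = B_H * qb_H * DC = 1 * 5 * 1 = 5
        f = consumption_flux_matrix(toy_model)
        assert f.q[toy_model.index_of(3), toy_model.index_of(4)] == pytest.approx(5.0)

    def test_direct_product_example(self):
        # B_j=2, qb_j=10, DC[i,j]=0.25 -> q = 5
        groups = [
            FunctionalGroup(id=1, name="n", group_type="nutrient"),
            FunctionalGroup(id=2, name="d", group_type="detritus"),
            FunctionalGroup(id=3, name="prey", group_type="living", biomass=100.0, pb=1.0, qb=2.0, ae=1.0),
            FunctionalGroup(id=4, name="pred", group_type="living", biomass=2.0, pb=2.0, qb=10.0, ae=0.8),
        ]
        diet = [[0, 0, 1, 0.75], [0, 0, 0, 0], [0, 0, 0, 0.25], [0, 0, 0, 0]]
        diet[0][3] = 0.0
        diet[1][3] = 0.75  # pred takes 75% detritus, 25% prey
        diet[0][2] = 1.0
        m = build_model(groups, diet)
        f = consumption_flux_matrix(m)
        assert f.q[2, 3] == pytest.approx(5.0)
        assert f.q[0, 3] == 0.0

    def test_zero_diet_cell_gives_zero_flux(self, toy_model):
        f = consumption_flux_matrix(toy_model)
        assert f.q[toy_model.index_of(4), toy_model.index_of(3)] == 0.0

    def test_consumer_inflow_equals_total_consumption(self, branched_model):
        f = consumption_flux_matrix(branched_model)
        j = branched_model.index_of(6)
        assert f.q[:, j].sum() == pytest.approx(1.0 * 2.0)  # B_C * qb_C

    def test_fleet_column_carries_landings(self, toy_model):
        m = toy_model
        m.groups.append(FunctionalGroup(id=5, name="fleet", group_type="fleet"))
        n = m.n
        diet = np.zeros((n, n)); diet[: n - 1, : n - 1] = m.diet
        land = np.zeros((n, n)); land[m.index_of(4), n - 1] = 0.3
        m2 = FoodWebModel(groups=m.groups, diet=diet, landings=land)
        f = consumption_flux_matrix(m2)
        assert f.q[m2.index_of(4), n - 1] == pytest.approx(0.3)


class TestProductionFate:
    def test_hand_computed_fate_split(self, fate_model):
        pf = build_production_fate(fate_model)
        row = pf.row(4)  # g: Q=10, ae=0.8, pb/qb=0.3, ee=0.8
        det = pf.detritus_cols
        nut = pf.nutrient_cols
        assert row[nut].sum() == pytest.approx(0.5)  # metabolism
        # egestion 0.2 + senescence 0.06 both land in detritus
        assert row[det].sum() == pytest.approx(0.26)
        assert row[fate_model.index_of(5)] == pytest.approx(0.24)  # predation
        assert row.sum() == pytest.approx(1.0, abs=1e-9)

    def test_fully_consumed_group_has_zero_senescence(self, fate_model):
        m = fate_model
        m.groups[m.index_of(5)].qb = 3.0  # C now takes all 3 of g's production
        m.groups[m.index_of(5)].pb = 0.6
        pf = build_production_fate(m)
        # detritus share of g reduces to pure egestion
        assert pf.fraction_to_detritus(4) == pytest.approx(0.2)

    def test_perfect_transfer_boundary(self):
        # ae=1 and pb/qb=1: no egestion, no metabolism
        groups = [
            FunctionalGroup(id=1, name="n", group_type="nutrient"),
            FunctionalGroup(id=2, name="d", group_type="detritus"),
            FunctionalGroup(id=3, name="x", group_type="living", biomass=1.0, pb=2.0, qb=2.0, ae=1.0),
        ]
        diet = [[0, 0, 1.0], [0, 0, 0], [0, 0, 0]]
        pf = build_production_fate(build_model(groups, diet))
        row = pf.row(3)
        assert row[pf.nutrient_cols].sum() == pytest.approx(0.0)
        # everything is unconsumed production -> senescence to detritus
        assert row[pf.detritus_cols].sum() == pytest.approx(1.0)

    def test_unbalanced_model_refused(self, toy_model):
        toy_model.groups[3].qb = 25.0
        toy_model.groups[3].pb = 4.0
        with pytest.raises(ImbalanceError):
            build_production_fate(toy_model)

    def test_rows_sum_to_one(self, branched_model):
        pf = build_production_fate(branched_model)
        assert np.abs(pf.fate.sum(axis=1) - 1.0).max() < 1e-9


class TestAggregation:
    @pytest.fixture
    def two_predator_model(self):
        groups = [
            FunctionalGroup(id=1, name="n", group_type="nutrient"),
            FunctionalGroup(id=2, name="d", group_type="detritus"),
            FunctionalGroup(id=3, name="X", group_type="living", biomass=50.0, pb=10.0, qb=20.0, ae=1.0),
            FunctionalGroup(id=4, name="Y", group_type="living", biomass=50.0, pb=10.0, qb=20.0, ae=1.0),
            FunctionalGroup(id=5, name="A", group_type="living", biomass=2.0, pb=1.0, qb=4.0, ae=0.8),
            FunctionalGroup(id=6, name="B", group_type="living", biomass=8.0, pb=1.0, qb=4.0, ae=0.8),
        ]
        diet = [
            [0, 0, 1, 1, 0, 0],
            [0, 0, 0, 0, 0, 0],
            [0, 0, 0, 0, 1.0, 0.5],
            [0, 0, 0, 0, 0.0, 0.5],
            [0, 0, 0, 0, 0, 0],
            [0, 0, 0, 0, 0, 0],
        ]
        return build_model(groups, diet)

    def test_biomass_weighted_diet_merge(self, two_predator_model):
        # merge A (B=2, diet (1,0)) and B (B=8, diet (.5,.5)) -> (0.6, 0.4)
        merged = aggregate_groups(two_predator_model, {1: 1, 2: 2, 3: 3, 4: 4, 5: 5, 6: 5})
        j = merged.index_of(5)
        assert merged.diet[merged.index_of(3), j] == pytest.approx(0.6)
        assert merged.diet[merged.index_of(4), j] == pytest.approx(0.4)
        assert merged.groups[j].biomass == pytest.approx(10.0)

    def test_identity_mapping_preserves_model(self, two_predator_model):
        m = aggregate_groups(two_predator_model, {i: i for i in two_predator_model.ids})
        assert np.allclose(m.diet, two_predator_model.diet)
        assert m.names == two_predator_model.names

    def test_total_consumption_conserved(self, two_predator_model):
        before = consumption_flux_matrix(two_predator_model).total_flux()
        merged = aggregate_groups(two_predator_model, {1: 1, 2: 2, 3: 3, 4: 3, 5: 5, 6: 5})
        after = consumption_flux_matrix(merged).total_flux()
        assert after == pytest.approx(before, abs=1e-9)

    def test_prey_rows_summed(self, two_predator_model):
        merged = aggregate_groups(two_predator_model, {1: 1, 2: 2, 3: 3, 4: 3, 5: 5, 6: 6})
        # B's diet was 0.5 X + 0.5 Y -> all of merged prey
        assert merged.diet[merged.index_of(3), merged.index_of(6)] == pytest.approx(1.0)

    def test_cross_type_merge_rejected(self, two_predator_model):
        with pytest.raises(FoodWebError, match="group types"):
            aggregate_groups(two_predator_model, {1: 1, 2: 1, 3: 3, 4: 4, 5: 5, 6: 6})

    def test_partial_mapping_rejected(self, two_predator_model):
        with pytest.raises(FoodWebError, match="not total"):
            aggregate_groups(two_predator_model, {1: 1})

    def test_zero_biomass_merge_rejected(self, two_predator_model):
        for gid in (5, 6):
            two_predator_model.groups[two_predator_model.index_of(gid)].biomass = 0.0
        with pytest.raises(FoodWebError, match="zero-biomass"):
            aggregate_groups(two_predator_model, {1: 1, 2: 2, 3: 3, 4: 4, 5: 5, 6: 5})

    def test_diet_columns_stay_normalized(self, two_predator_model):
        merged = aggregate_groups(two_predator_model, {1: 1, 2: 2, 3: 3, 4: 3, 5: 5, 6: 5})
        assert validate_model(merged) == []


class TestTraceInsertion:
    def test_trace_group_appended_at_given_biomass(self, toy_model):
        m = add_trace_group(
            toy_model,
            FunctionalGroup(id=9, name="pyrosome", group_type="living", pb=10.0, qb=30.0, ae=0.8),
            diet_column={3: 1.0},
            biomass=1e-5,
        )
        assert m.n == toy_model.n + 1
        assert m.groups[m.index_of(9)].biomass == 1e-5
        assert validate_model(m) == []

    def test_zero_biomass_rejected(self, toy_model):
        with pytest.raises(FoodWebError, match="biomass"):
            add_trace_group(
                toy_model,
                FunctionalGroup(id=9, name="z", group_type="living", pb=1.0, qb=5.0, ae=0.8),
                diet_column={3: 1.0},
                biomass=0.0,
            )

    def test_duplicate_name_rejected(self, toy_model):
        with pytest.raises(FoodWebError, match="already present"):
            add_trace_group(
                toy_model,
                FunctionalGroup(id=9, name="H", group_type="living", pb=1.0, qb=5.0, ae=0.8),
                diet_column={3: 1.0},
                biomass=1e-5,
            )

    def test_diet_column_renormalized(self, toy_model):
        m = add_trace_group(
            toy_model,
            FunctionalGroup(id=9, name="z", group_type="living", pb=1.0, qb=5.0, ae=0.8),
            diet_column={3: 2.0, 4: 6.0},  # raw weights renormalize to 0.25/0.75
            biomass=1e-5,
        )
        assert m.diet[m.index_of(3), m.index_of(9)] == pytest.approx(0.25)

    def test_predator_epsilon_registers_trace_predation(self, toy_model):
        m = add_trace_group(
            toy_model,
            FunctionalGroup(id=9, name="z", group_type="living", pb=1.0, qb=5.0, ae=0.8),
            diet_column={3: 1.0},
            biomass=1e-5,
            predator_epsilon={4: 0.01},
        )
        j = m.index_of(4)
        assert m.diet[m.index_of(9), j] == pytest.approx(0.01)
        assert m.diet[:, j].sum() == pytest.approx(1.0, abs=1e-12)

    def test_insert_then_aggregate_conserves_biomass(self, toy_model):
        m = add_trace_group(
            toy_model,
            FunctionalGroup(id=9, name="z", group_type="living", pb=1.0, qb=5.0, ae=0.8),
            diet_column={3: 1.0},
            biomass=1e-5,
        )
        merged = aggregate_groups(m, {1: 1, 2: 2, 3: 3, 4: 4, 9: 4})
        assert merged.groups[merged.index_of(4)].biomass == pytest.approx(1.0 + 1e-5)
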
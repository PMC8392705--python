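"""Pathway costing, cost offsets and the time/travel layer."""

from __future__ import annotations

import pytest

from steppedcare import (
    ConfigurationError,
    ConsistencyError,
    compute_cost_offsets,
    compute_time_travel_costs,
    cost_cau_pathway,
    cost_csc_pathway,
    build_eligible_population,
)
from steppedcare.outcomes import StateTrajectory, arm_trajectories
from steppedcare.params import fixed

from conftest import make_cohort, make_stratum, minimal_params


def _pipeline(params, arm):
    strata = build_eligible_population(params)
    return strata, arm_trajectories(strata, params, arm)


def fake_trajectory(stratum, arm, ly_unremitted):
    n = stratum.n_persons
    return StateTrajectory(stratum=stratum, arm=arm,
                           remitted_at_interval_end=(0.0, 0.0, 0.0),
                           ly_remitted=n - ly_unremitted,
                           ly_unremitted=ly_unremitted)


class TestCscPathway:
    def test_all_mild_all_remit_no_step_up(self):
        # single all-mild cohort, everyone remits within 4 months
        params = minimal_params(
            csc_ps=(1.0, 0.0, 0.0),
            unit_costs={"CSC1a": 400.0, "CSC0": 20.0, "CSC9": 100.0,
                        "CSC2a": 500.0, "CSC2b": 500.0, "CSC2c": 500.0},
            cohort=make_cohort(severity=(1.0, 0.0, 0.0)),
            benzo=0.2)
        params.target = "depression_only"
        strata, traj = _pipeline(params, "CSC")
        res = cost_csc_pathway(strata, traj, params)
        n = sum(s.n_persons for s in strata)
        assert res.cost_by_category["CSC1a"] == pytest.approx(400.0 * n)
        assert res.cost_by_category["CSC0"] == pytest.approx(20.0 * n)
        assert res.cost_by_category["CSC9"] == pytest.approx(100.0 * 0.2 * n)
        for branch in ("CSC2a", "CSC2b", "CSC2c"):
            assert res.cost_by_category.get(branch, 0.0) == 0.0
        assert res.pathway_cost == pytest.approx((400.0 + 20.0 + 20.0) * n)

    def test_severe_enter_step_two_directly(self):
        params = minimal_params(
            unit_costs={"CSC1a": 400.0, "CSC1b": 500.0,
                        "CSC2a": 1000.0, "CSC2b": 1000.0, "CSC2c": 1000.0},
            cohort=make_cohort(severity=(0.0, 0.0, 1.0)))
        params.target = "depression_only"
        strata, traj = _pipeline(params, "CSC")
        res = cost_csc_pathway(strata, traj, params)
        n = sum(s.n_persons for s in strata)
        assert res.cost_by_category.get("CSC1a", 0.0) == 0.0
        assert res.cost_by_category.get("CSC1b", 0.0) == 0.0
        step2 = sum(res.cost_by_category[b] for b in ("CSC2a", "CSC2b", "CSC2c"))
        assert step2 == pytest.approx(1000.0 * n)

    def test_step_up_conservation(self, default_params):
        """Step-2 entrants equal severe persons plus 4-month non-remitters."""
        strata, traj = _pipeline(default_params, "CSC")
        res = cost_csc_pathway(strata, traj, default_params)
        per_entrant = sum(
            default_params.cost_item(b).per_person_cost()
            * default_params.allocation("CSC").branch_props[b].point
            for b in ("CSC2a", "CSC2b", "CSC2c"))
        step2_cost = sum(res.cost_by_category[b]
                         for b in ("CSC2a", "CSC2b", "CSC2c"))
        expected_entrants = sum(
            s.n_persons if s.severity == "severe" else t.stepup_persons
            for s, t in zip(strata, traj))
        assert step2_cost / per_entrant == pytest.approx(expected_entrants)

    def test_halving_training_cost_halves_training_line(self, default_params):
        strata, traj = _pipeline(default_params, "CSC")
        full = cost_csc_pathway(strata, traj, default_params)
        halved_params = default_params.copy()
        halved_params.cost_item("CSC0").unit_cost.point /= 2.0
        halved = cost_csc_pathway(strata, traj, halved_params)
        assert halved.cost_by_category["CSC0"] == pytest.approx(
            full.cost_by_category["CSC0"] / 2.0)
        assert full.pathway_cost - halved.pathway_cost == pytest.approx(
            full.cost_by_category["CSC0"] / 2.0)

    def test_fixed_program_training_mode(self, default_params):
        params = default_params.copy()
        params.training_mode = "fixed_program"
        strata, traj = _pipeline(params, "CSC")
        res = cost_csc_pathway(strata, traj, params)
        item = params.cost_item("CSC0")
        assert res.cost_by_category["CSC0"] == pytest.approx(
            item.unit_cost.point * item.quantity)

    def test_category_additivity(self, default_params):
        strata, traj = _pipeline(default_params, "CSC")
        res = cost_csc_pathway(strata, traj, default_params)
        assert res.pathway_cost == pytest.approx(
            sum(res.cost_by_category.values()), abs=1e-6)

    def test_misaligned_trajectories_rejected(self, default_params):
        strata, traj = _pipeline(default_params, "CSC")
        with pytest.raises(ConsistencyError):
            cost_csc_pathway(strata, traj[:-1], default_params)
        cau_traj = arm_trajectories(strata, default_params, "CAU")
        with pytest.raises(ConsistencyError, match="expected CSC"):
            cost_csc_pathway(strata, cau_traj, default_params)


class TestCauPathway:
    def test_single_branch_allocation(self):
        params = minimal_params(unit_costs={"CAU1": 360.0, "CAU9": 100.0},
                                benzo=0.2)
        alloc = params.allocation("CAU")
        alloc.branch_props["CAU1"] = fixed(1.0)
        alloc.branch_props["CAU2"] = fixed(0.0)
        alloc.branch_props["CAU3"] = fixed(0.0)
        strata, traj = _pipeline(params, "CAU")
        res = cost_cau_pathway(strata, traj, params)
        n = sum(s.n_persons for s in strata)
        assert res.pathway_cost == pytest.approx((360.0 + 100.0 * 0.2) * n)

    def test_all_untreated_zero_cost(self):
        params = minimal_params()
        alloc = params.allocation("CAU")
        alloc.branch_props["CAU1"] = fixed(0.0)
        alloc.branch_props["CAU2"] = fixed(0.0)
        alloc.branch_props["CAU3"] = fixed(1.0)
        strata, traj = _pipeline(params, "CAU")
        res = cost_cau_pathway(strata, traj, params)
        assert res.pathway_cost == 0.0

    def test_degree_one_homogeneity_in_unit_costs(self, default_params):
        k = 3.0
        scaled = default_params.copy()
        for item in scaled.costs:
            item.unit_cost.point *= k
        for arm, coster in (("CSC", cost_csc_pathway), ("CAU", cost_cau_pathway)):
            strata, traj = _pipeline(default_params, arm)
            base = coster(strata, traj, default_params)
            strata2, traj2 = _pipeline(scaled, arm)
            scaled_res = coster(strata2, traj2, scaled)
            assert scaled_res.pathway_cost == pytest.approx(
                k * base.pathway_cost, rel=1e-12)
            for cat, value in base.cost_by_category.items():
                assert scaled_res.cost_by_category[cat] == pytest.approx(
                    k * value, rel=1e-12)


class TestCostOffsets:
    def test_identical_trajectories_zero_offset(self, default_params):
        strata, traj = _pipeline(default_params, "CSC")
        assert compute_cost_offsets(traj, traj, default_params) == 0.0

    def test_oracle_arithmetic(self):
        params = minimal_params(unit_costs={"OFFSET_ANNUAL": 1000.0})
        stratum = make_stratum(100.0)
        csc = [fake_trajectory(stratum, "CSC", 43.75)]
        cau = [fake_trajectory(stratum, "CAU", 60.0)]
        assert compute_cost_offsets(csc, cau, params) == pytest.approx(-16_250.0)

    def test_zero_annual_cost_zero_offset(self):
        params = minimal_params()
        stratum = make_stratum(100.0)
        csc = [fake_trajectory(stratum, "CSC", 40.0)]
        cau = [fake_trajectory(stratum, "CAU", 60.0)]
        assert compute_cost_offsets(csc, cau, params) == 0.0

    def test_mismatched_strata_rejected(self, default_params):
        _, csc = _pipeline(default_params, "CSC")
        params2 = default_params.copy()
        _, cau = _pipeline(params2, "CAU")
        with pytest.raises(ConsistencyError, match="different strata"):
            compute_cost_offsets(csc, cau, default_params)

    def test_end_of_year_basis(self):
        params = minimal_params(unit_costs={"OFFSET_ANNUAL": 1000.0})
        params.offset_basis = "end_of_year_cases"
        stratum = make_stratum(100.0)
        csc = [StateTrajectory(stratum, "CSC", (50.0, 75.0, 87.5), 56.25, 43.75)]
        cau = [StateTrajectory(stratum, "CAU", (30.0, 51.0, 65.7), 36.45, 63.55)]
        # 12.5 vs 34.3 unremitted cases at 12 months
        assert compute_cost_offsets(csc, cau, params) == pytest.approx(
            1000.0 * (12.5 - 34.3))


class TestTimeTravel:
    def test_direct_product(self):
        params = minimal_params(unit_costs={"TIME_TRAVEL": 20.0})
        for item in params.costs:
            if item.category_id == "TIME_TRAVEL":
                item.quantity = 5.0
        stratum = make_stratum(100.0)
        traj = [fake_trajectory(stratum, "CSC", 50.0)]
        assert compute_time_travel_costs([stratum], traj, params, "CSC") == \
            pytest.approx(100.0 * 5.0 * 20.0)

    def test_zero_unit_costs_zero(self):
        params = minimal_params()
        stratum = make_stratum(100.0)
        traj = [fake_trajectory(stratum, "CSC", 50.0)]
        assert compute_time_travel_costs([stratum], traj, params, "CSC") == 0.0

    def test_disabled_scenario_leaves_field_zero(self, default_params):
        strata, traj = _pipeline(default_params, "CSC")
        res = cost_csc_pathway(strata, traj, default_params,
                               include_time_travel=False)
        assert res.time_travel_cost == 0.0

    def test_missing_items_raise(self, default_params):
        params = default_params.copy()
        params.costs = [c for c in params.costs if c.category_id != "TIME_TRAVEL"]
        strata, traj = _pipeline(params, "CSC")
        with pytest.raises(ConfigurationError, match="TIME_TRAVEL"):
            compute_time_travel_costs(strata, traj, params, "CSC")
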
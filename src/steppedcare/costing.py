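"""Pathway costing for both arms, cost offsets, and the time/travel layer.

Stepped-care (CSC) pathway: mild cases start guided self-help (CSC1a),
moderate cases guided self-help plus antidepressants (CSC1b); those still
unremitted at 4 months step up to specialised care, split over CSC2a/2b/2c
by the step-2 allocation; severe cases enter step 2 directly at month 0.
Provider training (CSC0) is amortised per treated person under steady-state
assumptions (an alternative fixed-program mode charges it as a lump sum).
A benzodiazepine add-on (CSC9) reaches the configured proportion of all
patients.  Care-as-usual (CAU) splits all patients over antidepressants
only / specialised care / no treatment (CAU1/2/3, dropouts in CAU3) with
its own benzodiazepine add-on (CAU9).

Every line item is ``unit_cost x quantity x coverage x persons in branch``;
costs are additive across categories, hence exactly degree-1 homogeneous in
unit costs.

Cost offsets value the difference in unremitted burden between arms at the
annual treatment cost per unremitted case (OFFSET_ANNUAL); the default
burden measure is unremitted person-years from the AUC engine, with
end-of-year case counts available behind a switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ConfigurationError, ConsistencyError
from .outcomes import StateTrajectory, total_unremitted_person_years
from .params import CAU_BRANCHES, CSC_STEP2, ModelParameters, PathwayCostItem
from .population import EligibleStratum


@dataclass
class ArmCostResult:
    arm: str
    pathway_cost: float
    cost_by_category: dict[str, float]
    unremitted_treatment_cost: float
    time_travel_cost: float = 0.0
    n_treated: float = 0.0


def _check_aligned(strata: list[EligibleStratum],
                   trajectories: list[StateTrajectory], arm: str) -> None:
    if len(strata) != len(trajectories):
        raise ConsistencyError(
            f"{len(strata)} strata but {len(trajectories)} trajectories")
    for s, t in zip(strata, trajectories):
        if t.stratum is not s:
            raise ConsistencyError("trajectories are not aligned with strata")
        if t.arm != arm:
            raise ConsistencyError(f"expected {arm} trajectories, got {t.arm}")


def _annual_unremitted_cost_per_case(params: ModelParameters,
                                     arm: str | None = None) -> float:
    items = [i for i in params.costs if i.category_id == "OFFSET_ANNUAL"
             and (arm is None or i.arm in (None, arm))]
    return sum(i.per_person_cost() for i in items)


def _unremitted_burden(trajectories: list[StateTrajectory],
                       basis: str) -> float:
    if basis == "person_years":
        return total_unremitted_person_years(trajectories)
    if basis == "end_of_year_cases":
        return sum(t.unremitted_at_end for t in trajectories)
    raise ConfigurationError(f"unknown offset basis {basis!r}")


def cost_csc_pathway(strata: list[EligibleStratum],
                     trajectories: list[StateTrajectory],
                     params: ModelParameters,
                     include_time_travel: bool = False) -> ArmCostResult:
    """Cost the stepped-care pathway over its 8-month delivery period."""
    _check_aligned(strata, trajectories, "CSC")
    alloc = params.allocation("CSC")
    for branch in CSC_STEP2:
        if branch not in alloc.branch_props:
            raise ConfigurationError(f"CSC allocation missing step-2 branch {branch!r}")
    by_cat: dict[str, float] = {}

    def add(category: str, amount: float) -> None:
        by_cat[category] = by_cat.get(category, 0.0) + amount

    n_total = sum(s.n_persons for s in strata)
    step2_entrants = 0.0
    for s, t in zip(strata, trajectories):
        if s.severity == "mild":
            add("CSC1a", params.cost_item("CSC1a").per_person_cost() * s.n_persons)
            step2_entrants += t.stepup_persons
        elif s.severity == "moderate":
            add("CSC1b", params.cost_item("CSC1b").per_person_cost() * s.n_persons)
            step2_entrants += t.stepup_persons
        else:  # severe: direct entry to step 2
            step2_entrants += s.n_persons
    for branch in CSC_STEP2:
        share = alloc.branch_props[branch].point
        add(branch, params.cost_item(branch).per_person_cost()
            * share * step2_entrants)

    training = params.cost_item("CSC0")
    if params.training_mode == "per_person":
        add("CSC0", training.per_person_cost() * n_total)
    else:  # fixed_program: one lump sum regardless of throughput
        add("CSC0", training.unit_cost.point * training.quantity)

    benzo = params.cost_item("CSC9")
    add("CSC9", benzo.per_person_cost() * alloc.benzodiazepine.point * n_total)

    pathway = sum(by_cat.values())
    tt = compute_time_travel_costs(strata, trajectories, params, "CSC") \
        if include_time_travel else 0.0
    return ArmCostResult(
        arm="CSC", pathway_cost=pathway, cost_by_category=by_cat,
        unremitted_treatment_cost=(
            _annual_unremitted_cost_per_case(params, "CSC")
            * _unremitted_burden(trajectories, params.offset_basis)),
        time_travel_cost=tt, n_treated=n_total)


def cost_cau_pathway(strata: list[EligibleStratum],
                     trajectories: list[StateTrajectory],
                     params: ModelParameters,
                     include_time_travel: bool = False) -> ArmCostResult:
    """Cost the care-as-usual pathway."""
    _check_aligned(strata, trajectories, "CAU")
    alloc = params.allocation("CAU")
    for branch in CAU_BRANCHES:
        if branch not in alloc.branch_props:
            raise ConfigurationError(f"CAU allocation missing branch {branch!r}")
    by_cat: dict[str, float] = {}
    n_total = sum(s.n_persons for s in strata)
    for branch in CAU_BRANCHES:
        share = alloc.branch_props[branch].point
        by_cat[branch] = (params.cost_item(branch).per_person_cost()
                          * share * n_total)
    benzo = params.cost_item("CAU9")
    by_cat["CAU9"] = benzo.per_person_cost() * alloc.benzodiazepine.point * n_total

    pathway = sum(by_cat.values())
    tt = compute_time_travel_costs(strata, trajectories, params, "CAU") \
        if include_time_travel else 0.0
    return ArmCostResult(
        arm="CAU", pathway_cost=pathway, cost_by_category=by_cat,
        unremitted_treatment_cost=(
            _annual_unremitted_cost_per_case(params, "CAU")
            * _unremitted_burden(trajectories, params.offset_basis)),
        time_travel_cost=tt, n_treated=n_total)


def compute_cost_offsets(traj_csc: list[StateTrajectory],
                         traj_cau: list[StateTrajectory],
                         params: ModelParameters) -> float:
    """Avoided-treatment cost offset, negative when CSC leaves less burden.

    ``offset = annual cost per unremitted case x (burden_CSC - burden_CAU)``
    where burden is unremitted person-years (default) or unremitted cases at
    12 months.
    """
    if len(traj_csc) != len(traj_cau):
        raise ConsistencyError(
            f"arm trajectory lists differ in length: "
            f"{len(traj_csc)} vs {len(traj_cau)}")
    for a, b in zip(traj_csc, traj_cau):
        if a.stratum is not b.stratum:
            raise ConsistencyError("arms were computed on different strata")
    annual = _annual_unremitted_cost_per_case(params)
    burden_csc = _unremitted_burden(traj_csc, params.offset_basis)
    burden_cau = _unremitted_burden(traj_cau, params.offset_basis)
    return annual * (burden_csc - burden_cau)


def compute_time_travel_costs(strata: list[EligibleStratum],
                              trajectories: list[StateTrajectory],
                              params: ModelParameters, arm: str) -> float:
    """Patient time and travel costs for one arm (scenario layer only)."""
    items = [i for i in params.costs if i.category_id == "TIME_TRAVEL"
             and i.arm in (None, arm)]
    if not items:
        raise ConfigurationError(
            f"time/travel scenario requested but no TIME_TRAVEL items "
            f"configured for arm {arm!r}")
    n_total = sum(s.n_persons for s in strata)
    return sum(i.per_person_cost() for i in items) * n_total


def cost_frame(results: list[ArmCostResult]) -> pd.DataFrame:
    """Tabular export of cost lines per arm and category."""
    rows = []
    for res in results:
        for cat, value in sorted(res.cost_by_category.items()):
            rows.append({"arm": res.arm, "category": cat, "cost": value})
        rows.append({"arm": res.arm, "category": "TOTAL_PATHWAY",
                     "cost": res.pathway_cost})
        if res.time_travel_cost:
            rows.append({"arm": res.arm, "category": "TIME_TRAVEL",
                         "cost": res.time_travel_cost})
    return pd.DataFrame(rows)
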
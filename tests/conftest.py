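"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import pytest

from steppedcare import (
    CohortSpec,
    DisabilityWeights,
    EligibleStratum,
    ModelParameters,
    PathwayAllocation,
    PathwayCostItem,
    RemissionSchedule,
    SyntheticConfig,
    UncertainValue,
    generate_parameters,
)
from steppedcare.params import (
    ARMS,
    CAU_BRANCHES,
    COST_CATEGORIES,
    CSC_STEP2,
    DISORDERS,
    SEVERITIES,
)
from steppedcare.params import fixed


@pytest.fixture(scope="session")
def default_params() -> ModelParameters:
    """One realistic synthetic parameter set, shared read-only."""
    return generate_parameters(SyntheticConfig(seed=7))


@pytest.fixture()
def params(default_params) -> ModelParameters:
    """Mutable copy of the session parameter set."""
    return default_params.copy()


@pytest.fixture(scope="session")
def small_params() -> ModelParameters:
    """A two-cohort set for sweeps that rerun the model many times."""
    return generate_parameters(SyntheticConfig(seed=11, n_cohorts=2))


def make_cohort(population: float = 100_000.0, consult: float = 0.10,
                prevalence: float = 0.05,
                severity=(0.4, 0.4, 0.2)) -> CohortSpec:
    """Minimal cohort with identical fixed inputs for both disorders."""
    return CohortSpec(
        age_group="18+", sex="female", population=population,
        gp_mh_consult_prop=fixed(consult),
        prevalence={d: fixed(prevalence) for d in DISORDERS},
        severity_split={d: {s: fixed(p) for s, p in zip(SEVERITIES, severity)}
                        for d in DISORDERS},
    )


def make_stratum(n: float, disorder: str = "depression",
                 severity: str = "mild") -> EligibleStratum:
    return EligibleStratum(cohort=make_cohort(population=n), disorder=disorder,
                           severity=severity, n_persons=n)


def make_schedule(ps, arm: str = "CSC",
                  disorder: str = "depression") -> RemissionSchedule:
    return RemissionSchedule(arm=arm, disorder=disorder,
                             p_interval=tuple(fixed(p) for p in ps))


def make_weights(dw_unremitted: float = 0.3, dw_remitted: float = 0.0,
                 dw_background: float = 0.0) -> DisabilityWeights:
    return DisabilityWeights(
        unremitted={d: {s: fixed(dw_unremitted) for s in SEVERITIES}
                    for d in DISORDERS},
        remitted={d: fixed(dw_remitted) for d in DISORDERS},
        background=fixed(dw_background),
    )


def minimal_params(csc_ps=(0.5, 0.5, 0.5), cau_ps=(0.3, 0.3, 0.3),
                   unit_costs: dict | None = None,
                   cohort: CohortSpec | None = None,
                   benzo: float = 0.0) -> ModelParameters:
    """Hand-built single-cohort parameter set with fixed uncertainty.

    ``unit_costs`` maps category ids to unit costs (quantity 1); anything
    unlisted costs zero.
    """
    unit_costs = unit_costs or {}
    costs = [
        PathwayCostItem(category_id=cat, unit_cost=fixed(unit_costs.get(cat, 0.0)),
                        quantity=1.0, coverage=1.0)
        for cat in COST_CATEGORIES if cat != "TIME_TRAVEL"
    ]
    costs += [
        PathwayCostItem(category_id="TIME_TRAVEL",
                        unit_cost=fixed(unit_costs.get("TIME_TRAVEL", 0.0)),
                        quantity=1.0, coverage=1.0, arm=arm)
        for arm in ARMS
    ]
    schedules = [
        make_schedule(csc_ps if arm == "CSC" else cau_ps, arm=arm, disorder=d)
        for arm in ARMS for d in DISORDERS
    ]
    allocations = [
        PathwayAllocation(
            arm="CSC",
            branch_props={b: fixed(p) for b, p in
                          zip(CSC_STEP2, (0.5, 0.3, 0.2))},
            benzodiazepine=fixed(benzo)),
        PathwayAllocation(
            arm="CAU",
            branch_props={b: fixed(p) for b, p in
                          zip(CAU_BRANCHES, (0.5, 0.3, 0.2))},
            benzodiazepine=fixed(benzo)),
    ]
    params = ModelParameters(
        cohorts=[cohort or make_cohort()],
        remission=schedules,
        weights=make_weights(dw_unremitted=0.3, dw_remitted=0.0,
                             dw_background=0.0),
        costs=costs,
        allocations=allocations,
    )
    params.validate()
    return params


def fix_all_families(params: ModelParameters) -> ModelParameters:
    """Copy with every uncertainty distribution degenerated to its point."""
    from steppedcare.params import iter_uncertain_values

    out = params.copy()
    for _, uv in iter_uncertain_values(out):
        uv.family = "fixed"
        uv.params = ()
    out.validate()
    return out
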
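"""Remission propagation and DALY computation.

Each eligible stratum moves through three 4-month intervals under its arm's
remission schedule.  Interval probabilities are conditional per-interval
remission probabilities among the still-unremitted; remission is absorbing
within the 1-year horizon (no relapse, no mortality, no discounting).

Person-time in each health state is accumulated by the midpoint
(area-under-the-curve) convention: a person remitting during an interval
contributes half the interval (1/6 year) to each state; a person already
remitted contributes the whole interval (1/3 year) to the remitted state.
This is exactly the trapezoid rule applied to the piecewise-linear
unremitted-count curve evaluated at interval boundaries.

Health gain is expressed as healthy-equivalent life years ("DALYs
averted"): ``(1 - DW) x LY`` summed over the two states, with both state
weights adjusted multiplicatively for background morbidity.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConsistencyError, ValidationError
from .params import DisabilityWeights, ModelParameters, RemissionSchedule
from .population import EligibleStratum

N_INTERVALS = 3


@dataclass
class StateTrajectory:
    """Remitted/unremitted person counts and person-time for one stratum x arm."""

    stratum: EligibleStratum
    arm: str
    remitted_at_interval_end: tuple[float, float, float]  # cumulative persons
    ly_remitted: float
    ly_unremitted: float

    @property
    def n_persons(self) -> float:
        return self.stratum.n_persons

    @property
    def unremitted_at_end(self) -> float:
        return self.stratum.n_persons - self.remitted_at_interval_end[-1]

    @property
    def stepup_persons(self) -> float:
        """Persons unremitted at 4 months (candidates for step-up in CSC)."""
        return self.stratum.n_persons - self.remitted_at_interval_end[0]


@dataclass
class HealthOutcome:
    trajectory: StateTrajectory
    dw_unremitted_adj: float
    dw_remitted_adj: float
    dalys_averted: float


def conditional_probabilities(schedule: RemissionSchedule,
                              reading: str = "conditional") -> tuple[float, ...]:
    """Interval probabilities as conditional per-interval values.

    Under the ``cumulative`` reading the schedule stores cumulative
    proportions remitted by each interval end; they are converted with
    ``c_t = (P_t - P_{t-1}) / (1 - P_{t-1})`` (clamped to keep counts
    monotone if the cumulative inputs are non-monotone).
    """
    points = tuple(uv.point for uv in schedule.p_interval)
    if reading == "conditional":
        return points
    if reading != "cumulative":
        raise ValidationError(f"unknown remission reading {reading!r}")
    conditional = []
    prev = 0.0
    for p in points:
        p = max(p, prev)  # enforce monotone cumulative proportions
        c = 0.0 if prev >= 1.0 else (p - prev) / (1.0 - prev)
        conditional.append(min(max(c, 0.0), 1.0))
        prev = p
    return tuple(conditional)


def propagate_remission(stratum: EligibleStratum, schedule: RemissionSchedule,
                        reading: str = "conditional",
                        horizon_years: float = 1.0) -> StateTrajectory:
    """Run the interval recursion and accumulate midpoint person-time."""
    if schedule.disorder != stratum.disorder:
        raise ConsistencyError(
            f"schedule for {schedule.disorder!r} applied to a "
            f"{stratum.disorder!r} stratum")
    ps = conditional_probabilities(schedule, reading)
    n = stratum.n_persons
    unremitted = n
    remitted_cum = []
    weighted = 0.0  # person-intervals in the remitted state
    for p in ps:
        newly = unremitted * p
        already = n - unremitted
        # midpoint convention: new remitters get half the interval remitted
        weighted += already + newly / 2.0
        unremitted -= newly
        remitted_cum.append(n - unremitted)
    # single division keeps simple rational inputs exact
    ly_remitted = weighted * horizon_years / N_INTERVALS
    ly_unremitted = n * horizon_years - ly_remitted
    return StateTrajectory(
        stratum=stratum, arm=schedule.arm,
        remitted_at_interval_end=tuple(remitted_cum),
        ly_remitted=ly_remitted, ly_unremitted=ly_unremitted)


def combine_disability_weights(dw_condition: float, dw_background: float) -> float:
    """Multiplicative background-morbidity adjustment.

    ``DW_adj = 1 - (1 - dw_condition) x (1 - dw_background)``; the result
    lies in [max(inputs), 1).
    """
    for name, dw in (("dw_condition", dw_condition), ("dw_background", dw_background)):
        if not 0.0 <= dw < 1.0:
            raise ValidationError(f"{name} {dw} outside [0, 1)")
    return 1.0 - (1.0 - dw_condition) * (1.0 - dw_background)


def compute_dalys_averted(trajectory: StateTrajectory,
                          weights: DisabilityWeights) -> HealthOutcome:
    """Healthy-equivalent life years ``(1 - DW) x LY`` summed over states."""
    d = trajectory.stratum.disorder
    s = trajectory.stratum.severity
    dw_bg = weights.background.point
    dw_u = combine_disability_weights(weights.unremitted[d][s].point, dw_bg)
    dw_r = combine_disability_weights(weights.remitted[d].point, dw_bg)
    dalys = (1.0 - dw_u) * trajectory.ly_unremitted + (1.0 - dw_r) * trajectory.ly_remitted
    return HealthOutcome(trajectory=trajectory, dw_unremitted_adj=dw_u,
                         dw_remitted_adj=dw_r, dalys_averted=dalys)


def arm_trajectories(strata: list[EligibleStratum], params: ModelParameters,
                     arm: str) -> list[StateTrajectory]:
    """Propagate every stratum under the given arm's schedules."""
    return [
        propagate_remission(s, params.schedule(arm, s.disorder),
                            reading=params.remission_reading,
                            horizon_years=params.horizon_years)
        for s in strata
    ]


def total_dalys_averted(trajectories: list[StateTrajectory],
                        weights: DisabilityWeights) -> float:
    return sum(compute_dalys_averted(t, weights).dalys_averted
               for t in trajectories)


def total_unremitted_person_years(trajectories: list[StateTrajectory]) -> float:
    return sum(t.ly_unremitted for t in trajectories)
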
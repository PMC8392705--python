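"""Remission propagation (midpoint AUC) and DALY computation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from steppedcare import (
    ConsistencyError,
    ValidationError,
    combine_disability_weights,
    compute_dalys_averted,
    propagate_remission,
)
from steppedcare.outcomes import conditional_probabilities

from conftest import make_schedule, make_stratum, make_weights

probs = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


def trapezoid_person_time(n: float, ps, horizon: float = 1.0):
    """Independent oracle: trapezoid rule on the piecewise-linear
    unremitted-count curve evaluated at interval boundaries."""
    length = horizon / len(ps)
    unremitted = [n]
    for p in ps:
        unremitted.append(unremitted[-1] * (1.0 - p))
    ly_unrem = sum((a + b) / 2.0 * length
                   for a, b in zip(unremitted, unremitted[1:]))
    return n * horizon - ly_unrem, ly_unrem


def microsimulate(n_individuals: int, ps, seed: int = 0):
    """Individual-level simulation of the same interval process."""
    rng = np.random.default_rng(seed)
    k = len(ps)
    u = rng.random((n_individuals, k))
    remits = u < np.asarray(ps)
    first = np.where(remits.any(axis=1), remits.argmax(axis=1), k)
    interval = 1.0 / k
    # remitting in interval j contributes half of it plus all later intervals
    ly_rem_per = np.where(first < k,
                          interval / 2.0 + (k - 1 - first) * interval, 0.0)
    return ly_rem_per


class TestPropagateRemission:
    def test_hand_computed_midpoint_oracle(self):
        traj = propagate_remission(make_stratum(100.0),
                                   make_schedule((0.5, 0.5, 0.5)))
        assert traj.remitted_at_interval_end == pytest.approx((50.0, 75.0, 87.5))
        assert traj.ly_remitted == pytest.approx(56.25)
        assert traj.ly_unremitted == pytest.approx(43.75)

    def test_no_remission(self):
        traj = propagate_remission(make_stratum(100.0),
                                   make_schedule((0.0, 0.0, 0.0)))
        assert traj.ly_unremitted == pytest.approx(100.0)
        assert traj.ly_remitted == 0.0

    def test_everyone_remits_in_first_interval(self):
        traj = propagate_remission(make_stratum(100.0),
                                   make_schedule((1.0, 0.0, 0.0)))
        assert traj.ly_remitted == pytest.approx(100.0 * (1 / 6 + 1 / 3 + 1 / 3))
        assert traj.ly_unremitted == pytest.approx(100.0 / 6.0)

    def test_disorder_mismatch_raises(self):
        with pytest.raises(ConsistencyError, match="anxiety"):
            propagate_remission(make_stratum(10.0, disorder="depression"),
                                make_schedule((0.5, 0.5, 0.5),
                                              disorder="anxiety"))

    @given(n=st.floats(min_value=0.0, max_value=1e6, allow_nan=False),
           p1=probs, p2=probs, p3=probs)
    @settings(max_examples=200, deadline=None)
    def test_person_time_conservation(self, n, p1, p2, p3):
        traj = propagate_remission(make_stratum(n), make_schedule((p1, p2, p3)))
        assert traj.ly_remitted + traj.ly_unremitted == pytest.approx(
            n, abs=max(1e-9, 1e-12 * n))
        ends = traj.remitted_at_interval_end
        assert 0.0 <= ends[0] <= ends[1] <= ends[2] <= n + 1e-9

    @given(p1=probs, p2=probs, p3=probs)
    @settings(max_examples=200, deadline=None)
    def test_midpoint_equals_trapezoid_rule(self, p1, p2, p3):
        traj = propagate_remission(make_stratum(100.0),
                                   make_schedule((p1, p2, p3)))
        ly_rem, ly_unrem = trapezoid_person_time(100.0, (p1, p2, p3))
        assert traj.ly_remitted == pytest.approx(ly_rem, abs=1e-9)
        assert traj.ly_unremitted == pytest.approx(ly_unrem, abs=1e-9)

    @pytest.mark.parametrize("ps", [(0.5, 0.5, 0.5), (0.35, 0.25, 0.2),
                                    (0.8, 0.1, 0.6)])
    def test_microsimulation_agrees_within_three_se(self, ps):
        n_ind = 200_000
        ly_rem_per = microsimulate(n_ind, ps, seed=123)
        traj = propagate_remission(make_stratum(float(n_ind)), make_schedule(ps))
        se = ly_rem_per.std(ddof=1) / np.sqrt(n_ind)
        assert abs(ly_rem_per.mean() - traj.ly_remitted / n_ind) < 3 * se

    def test_cumulative_reading_matches_equivalent_conditional(self):
        # cumulative 0.5, 0.75, 0.875 is the conditional (0.5, 0.5, 0.5) process
        sched = make_schedule((0.5, 0.75, 0.875))
        assert conditional_probabilities(sched, "cumulative") == pytest.approx(
            (0.5, 0.5, 0.5))
        traj = propagate_remission(make_stratum(100.0), sched,
                                   reading="cumulative")
        assert traj.ly_remitted == pytest.approx(56.25)


class TestDisabilityWeights:
    @pytest.mark.parametrize(("dw_c", "dw_b", "expected"),
                             [(0.3, 0.0, 0.3), (0.0, 0.1, 0.1), (0.3, 0.1, 0.37)])
    def test_multiplicative_combination(self, dw_c, dw_b, expected):
        assert combine_disability_weights(dw_c, dw_b) == pytest.approx(expected)

    @given(dw_c=st.floats(min_value=0.0, max_value=0.999),
           dw_b=st.floats(min_value=0.0, max_value=0.999))
    @settings(max_examples=100, deadline=None)
    def test_result_bounded_by_inputs_and_one(self, dw_c, dw_b):
        combined = combine_disability_weights(dw_c, dw_b)
        assert max(dw_c, dw_b) - 1e-12 <= combined < 1.0

    @pytest.mark.parametrize("bad", [1.0, 1.5, -0.1])
    def test_domain_error(self, bad):
        with pytest.raises(ValidationError, match="outside"):
            combine_disability_weights(bad, 0.1)


class TestComputeDalysAverted:
    def test_zero_weights_return_person_years(self):
        traj = propagate_remission(make_stratum(100.0),
                                   make_schedule((0.5, 0.5, 0.5)))
        outcome = compute_dalys_averted(traj, make_weights(0.0, 0.0, 0.0))
        assert outcome.dalys_averted == pytest.approx(100.0)

    def test_oracle_trajectory_arithmetic(self):
        # 0.7 x 43.75 unremitted + 1.0 x 56.25 remitted
        traj = propagate_remission(make_stratum(100.0),
                                   make_schedule((0.5, 0.5, 0.5)))
        outcome = compute_dalys_averted(traj, make_weights(0.3, 0.0, 0.0))
        assert outcome.dalys_averted == pytest.approx(86.875)

    def test_linearity_in_population(self):
        sched = make_schedule((0.4, 0.3, 0.2))
        weights = make_weights(0.3, 0.05, 0.05)
        one = compute_dalys_averted(
            propagate_remission(make_stratum(100.0), sched), weights)
        two = compute_dalys_averted(
            propagate_remission(make_stratum(200.0), sched), weights)
        assert two.dalys_averted == pytest.approx(2 * one.dalys_averted)

    @given(low=probs, high=probs, interval=st.integers(min_value=0, max_value=2))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_remission_probability(self, low, high, interval):
        """More remission never reduces health gain when the remitted state
        carries the lighter weight."""
        if low > high:
            low, high = high, low
        weights = make_weights(dw_unremitted=0.3, dw_remitted=0.05,
                               dw_background=0.1)
        ps_low = [0.3, 0.3, 0.3]
        ps_high = list(ps_low)
        ps_low[interval] = low
        ps_high[interval] = high
        d_low = compute_dalys_averted(
            propagate_remission(make_stratum(100.0), make_schedule(ps_low)),
            weights).dalys_averted
        d_high = compute_dalys_averted(
            propagate_remission(make_stratum(100.0), make_schedule(ps_high)),
            weights).dalys_averted
        assert d_high >= d_low - 1e-9

    @given(dw=st.floats(min_value=0.0, max_value=0.99),
           p1=probs, p2=probs, p3=probs)
    @settings(max_examples=100, deadline=None)
    def test_formula_identity_on_grid(self, dw, p1, p2, p3):
        """(1 - DW) x LY reproduced exactly from the trajectory pieces."""
        traj = propagate_remission(make_stratum(1000.0),
                                   make_schedule((p1, p2, p3)))
        weights = make_weights(dw_unremitted=dw, dw_remitted=0.0,
                               dw_background=0.0)
        outcome = compute_dalys_averted(traj, weights)
        expected = (1.0 - dw) * traj.ly_unremitted + 1.0 * traj.ly_remitted
        assert outcome.dalys_averted == pytest.approx(expected, abs=1e-12 * 1000)
        assert 0.0 <= outcome.dalys_averted <= traj.n_persons + 1e-9
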
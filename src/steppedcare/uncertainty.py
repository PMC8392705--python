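"""Probabilistic sensitivity analysis.

Monte Carlo propagation of all parameter uncertainty through the model:
each iteration draws every uncertain parameter from its stated family
(jointly independently unless a rank-correlation hook is supplied), runs
the full deterministic pipeline on the drawn values, and records the
(net incremental cost, incremental DALYs averted) pair.  Summaries cover
95% uncertainty intervals, the cost-effectiveness plane (quadrant
proportions, probability below the willingness-to-pay threshold) and the
cost-effectiveness acceptability curve.

Reproducibility: one master seed; iteration ``i`` uses the substream
``SeedSequence(seed, spawn_key=(i,))``, so results do not depend on
execution order.  Severity splits and branch allocations are renormalised
to sum to one after their independent beta draws.  Cost-effectiveness at a
threshold ``lambda`` is defined by net monetary benefit
``lambda x dE - dC >= 0``, which handles all four quadrants coherently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cea import DOMINANT, DOMINATED, IncrementalResult, classify_icer, run_base_case
from .errors import ConfigurationError
from .params import ModelParameters, UncertainValue, _leaves, iter_uncertain_values
from .synthetic import sample_uncertain

_MAX_REDRAWS = 100


@dataclass
class PSAResult:
    draws: np.ndarray                       # (n, 2): net dC, dE
    base: IncrementalResult
    wtp: float
    ui_cost: tuple[float, float]
    ui_dalys: tuple[float, float]
    icer_summary: dict
    quadrant_props: dict[str, float]
    prob_cost_effective: list[tuple[float, float]]
    prob_dominated: float
    below_threshold_prop: float
    n_rejected: int = 0
    boundary_ties: int = 0

    @property
    def n_iterations(self) -> int:
        return len(self.draws)

    def draws_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.draws,
                            columns=["net_delta_cost", "delta_dalys_averted"])

    def ceac_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.prob_cost_effective,
                            columns=["wtp", "prob_cost_effective"])


# ---------------------------------------------------------------------------
# Drawing

def _probability_paths(params: ModelParameters) -> set[str]:
    return {path[: -len(".point")] for path, leaf in _leaves(params).items()
            if path.endswith(".point") and leaf.is_probability}


def _renormalise_groups(params: ModelParameters) -> None:
    """Rescale severity splits and branch allocations to sum to one."""
    for cohort in params.cohorts:
        for split in cohort.severity_split.values():
            total = sum(uv.point for uv in split.values())
            if total > 0:
                for uv in split.values():
                    uv.point /= total
    for alloc in params.allocations:
        total = sum(alloc.branch_props[b].point
                    for b in alloc.expected_branches())
        if total > 0:
            for b in alloc.expected_branches():
                alloc.branch_props[b].point /= total


def draw_parameters(working: ModelParameters,
                    uncertain: list[tuple[str, UncertainValue]],
                    prob_paths: set[str],
                    rng: np.random.Generator,
                    baseline: dict[str, float] | None = None) -> int:
    """Redraw every uncertain point estimate of ``working`` in place.

    Returns the number of rejected (out-of-range) draws.  ``uncertain``
    must come from :func:`iter_uncertain_values` on the same object.
    ``baseline`` restores fixed-family members of renormalised groups to
    their original points between iterations.
    """
    rejected = 0
    for path, uv in uncertain:
        if uv.family == "fixed":
            if baseline is not None:
                uv.point = baseline[path]
            continue
        value = sample_uncertain(uv, rng)
        if path in prob_paths:
            attempts = 0
            while not 0.0 <= value <= 1.0:
                rejected += 1
                attempts += 1
                if attempts > _MAX_REDRAWS:
                    raise ConfigurationError(
                        f"{path}: could not draw a value in [0, 1] after "
                        f"{_MAX_REDRAWS} attempts (family {uv.family!r})")
                value = sample_uncertain(uv, rng)
        uv.point = value
    _renormalise_groups(working)
    return rejected


def _rank_correlate(draws: np.ndarray, idx_pairs: list[tuple[int, int, float]],
                    rng: np.random.Generator) -> np.ndarray:
    """Iman-Conover reordering to induce rank correlation between columns.

    ``draws`` is (n, k); each entry of ``idx_pairs`` is
    ``(col_a, col_b, rho)``.  Marginals are preserved exactly.
    """
    n, k = draws.shape
    target = np.eye(k)
    for a, b, rho in idx_pairs:
        target[a, b] = target[b, a] = rho
    chol = np.linalg.cholesky(target)
    scores = rng.standard_normal((n, k)) @ chol.T
    out = draws.copy()
    for j in range(k):
        order = np.argsort(np.argsort(scores[:, j]))
        out[:, j] = np.sort(draws[:, j])[order]
    return out


# ---------------------------------------------------------------------------
# Summaries

def ceac(draws: np.ndarray, wtp_grid) -> list[tuple[float, float]]:
    """Probability of cost-effectiveness at each threshold (NMB >= 0)."""
    wtp_grid = list(wtp_grid)
    if len(wtp_grid) == 0:
        raise ConfigurationError("empty willingness-to-pay grid")
    dc = draws[:, 0]
    de = draws[:, 1]
    return [(float(lam), float(np.mean(lam * de - dc >= 0.0)))
            for lam in wtp_grid]


def _order_key(dc: float, de: float) -> tuple[int, float]:
    """Plane ordering for ICER percentiles: dominant < numeric < dominated."""
    quadrant, icer = classify_icer(dc, de)
    if icer == DOMINANT or (quadrant is None and dc <= 0):
        return (0, 0.0)
    if icer == DOMINATED or quadrant is None:
        return (2, 0.0)
    return (1, float(icer))


def _percentile_entry(ordered: list[tuple[int, float]], q: float) -> float | str:
    n = len(ordered)
    pos = q * (n - 1)
    lo, hi = math.floor(pos), math.ceil(pos)
    if ordered[lo][0] == 1 and ordered[hi][0] == 1:
        frac = pos - lo
        return ordered[lo][1] * (1 - frac) + ordered[hi][1] * frac
    rank, value = ordered[int(round(pos))]
    return DOMINANT if rank == 0 else (value if rank == 1 else DOMINATED)


def summarise_icer_ui(draws: np.ndarray, params: ModelParameters,
                      point: float | str | None = None) -> dict:
    """Point ICER plus 95% UI endpoints under the plane ordering.

    ICER percentiles are not well defined when iteration ICERs change sign,
    so draws are ranked dominant < numeric (ascending) < dominated and the
    2.5th/97.5th positions of that ordering are reported, as numbers where
    both interpolation neighbours are numeric and as dominance labels
    otherwise.
    """
    if len(draws) == 0:
        raise ConfigurationError("no PSA draws to summarise")
    if point is None:
        point = run_base_case(params).icer
    ordered = sorted(_order_key(dc, de) for dc, de in draws)
    return {"point": point,
            "lower": _percentile_entry(ordered, 0.025),
            "upper": _percentile_entry(ordered, 0.975)}


@dataclass
class PlaneStats:
    quadrant_props: dict[str, float]
    below_threshold_prop: float
    boundary_ties: int


def plane_statistics(draws: np.ndarray, wtp: float) -> PlaneStats:
    """Quadrant proportions and the fraction of draws below the threshold.

    Boundary draws (a zero incremental cost or effect) are assigned to the
    more favourable quadrant, with the number of such ties reported.
    """
    if len(draws) == 0:
        raise ConfigurationError("no PSA draws to summarise")
    counts = {"NE": 0, "SE": 0, "SW": 0, "NW": 0}
    ties = 0
    for dc, de in draws:
        if dc == 0.0 or de == 0.0:
            ties += 1
        if de > 0:
            counts["NE" if dc > 0 else "SE"] += 1
        elif de < 0:
            counts["SW" if dc < 0 else "NW"] += 1
        else:
            counts["SE" if dc <= 0 else "NW"] += 1
    n = len(draws)
    props = {q: c / n for q, c in counts.items()}
    dc = draws[:, 0]
    de = draws[:, 1]
    below = float(np.mean(wtp * de - dc >= 0.0))
    return PlaneStats(quadrant_props=props, below_threshold_prop=below,
                      boundary_ties=ties)


# ---------------------------------------------------------------------------
# Main loop

def run_psa(params: ModelParameters, n_iterations: int | None = None,
            seed: int | None = None, wtp_grid=None,
            correlation: list[tuple[str, str, float]] | None = None) -> PSAResult:
    """Monte Carlo uncertainty analysis over all uncertain parameters.

    ``correlation`` optionally lists ``(path_a, path_b, rank_corr)`` triples
    applied by Iman-Conover reordering (off by default; parameters are
    otherwise drawn independently).
    """
    params.validate()
    n = int(n_iterations if n_iterations is not None else params.n_iterations)
    master_seed = int(seed if seed is not None else params.seed)
    if wtp_grid is None:
        wtp_grid = np.linspace(0.0, 2.0 * params.wtp, 101)

    base = run_base_case(params)

    working = params.copy()
    uncertain = iter_uncertain_values(working)
    prob_paths = _probability_paths(working)
    baseline = {path: uv.point for path, uv in uncertain}

    results = np.empty((n, 2), dtype=float)
    rejected = 0

    if correlation:
        rejected += _run_correlated(working, uncertain, prob_paths, n,
                                    master_seed, correlation, results, baseline)
    else:
        for i in range(n):
            rng = np.random.default_rng(
                np.random.SeedSequence(master_seed, spawn_key=(i,)))
            rejected += draw_parameters(working, uncertain, prob_paths, rng,
                                        baseline)
            res = run_base_case(working)
            results[i, 0] = res.net_delta_cost
            results[i, 1] = res.delta_dalys_averted

    stats = plane_statistics(results, params.wtp)
    ui_cost = tuple(np.percentile(results[:, 0], [2.5, 97.5]))
    ui_dalys = tuple(np.percentile(results[:, 1], [2.5, 97.5]))
    return PSAResult(
        draws=results, base=base, wtp=params.wtp,
        ui_cost=(float(ui_cost[0]), float(ui_cost[1])),
        ui_dalys=(float(ui_dalys[0]), float(ui_dalys[1])),
        icer_summary=summarise_icer_ui(results, params, point=base.icer),
        quadrant_props=stats.quadrant_props,
        prob_cost_effective=ceac(results, wtp_grid),
        prob_dominated=stats.quadrant_props["NW"],
        below_threshold_prop=stats.below_threshold_prop,
        n_rejected=rejected, boundary_ties=stats.boundary_ties)


def _run_correlated(working: ModelParameters, uncertain, prob_paths,
                    n: int, master_seed: int,
                    correlation: list[tuple[str, str, float]],
                    results: np.ndarray,
                    baseline: dict[str, float]) -> int:
    """Correlated variant: draw all iterations up front, reorder, then run."""
    active = [(path, uv) for path, uv in uncertain if uv.family != "fixed"]
    index = {path: j for j, (path, _) in enumerate(active)}
    idx_pairs = []
    for a, b, rho in correlation:
        if a not in index or b not in index:
            raise ConfigurationError(
                f"correlation refers to unknown or fixed parameter: {a!r}/{b!r}")
        idx_pairs.append((index[a], index[b], float(rho)))

    matrix = np.empty((n, len(active)), dtype=float)
    rejected = 0
    for i in range(n):
        rng = np.random.default_rng(
            np.random.SeedSequence(master_seed, spawn_key=(i,)))
        for j, (path, uv) in enumerate(active):
            value = sample_uncertain(uv, rng)
            attempts = 0
            while path in prob_paths and not 0.0 <= value <= 1.0:
                rejected += 1
                attempts += 1
                if attempts > _MAX_REDRAWS:
                    raise ConfigurationError(
                        f"{path}: could not draw a value in [0, 1]")
                value = sample_uncertain(uv, rng)
            matrix[i, j] = value
    reorder_rng = np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(n,)))
    matrix = _rank_correlate(matrix, idx_pairs, reorder_rng)

    for i in range(n):
        for path, uv in uncertain:
            if uv.family == "fixed":
                uv.point = baseline[path]
        for j, (path, uv) in enumerate(active):
            uv.point = matrix[i, j]
        _renormalise_groups(working)
        res = run_base_case(working)
        results[i, 0] = res.net_delta_cost
        results[i, 1] = res.delta_dalys_averted
    return rejected
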
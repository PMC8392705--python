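"""Incremental cost-effectiveness analysis.

Combines the outcome and costing engines into the incremental comparison:
net incremental cost (pathway cost difference plus cost offsets),
incremental DALYs averted, and the ICER with dominance classification on
the cost-effectiveness plane (x: incremental DALYs averted, y: net
incremental cost, origin = comparator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .costing import (
    ArmCostResult,
    compute_cost_offsets,
    cost_cau_pathway,
    cost_csc_pathway,
)
from .errors import ValidationError
from .outcomes import arm_trajectories, total_dalys_averted
from .params import ModelParameters
from .population import build_eligible_population, total_eligible

DOMINANT = "dominant"
DOMINATED = "dominated"
INDETERMINATE = "indeterminate"
EQUIVALENT = "equivalent"


@dataclass
class IncrementalResult:
    """Base-case (or scenario) incremental comparison of CSC vs CAU."""

    delta_cost_pathway: float
    cost_offset: float
    net_delta_cost: float
    delta_dalys_averted: float
    icer: float | str
    quadrant: str | None
    # per-arm detail for reporting
    target: str = "both"
    eligible_n: float = 0.0
    cost_csc: ArmCostResult | None = None
    cost_cau: ArmCostResult | None = None
    dalys_csc: float = 0.0
    dalys_cau: float = 0.0

    @property
    def icer_label(self) -> str:
        return f"{self.icer:.0f}" if isinstance(self.icer, float) else str(self.icer)

    def to_frame(self) -> pd.DataFrame:
        """Result table mirroring a base-case cost-effectiveness summary."""
        rows = [
            ("eligible population (persons)", self.eligible_n),
            ("CSC pathway cost (A$)",
             self.cost_csc.pathway_cost if self.cost_csc else float("nan")),
            ("CAU pathway cost (A$)",
             self.cost_cau.pathway_cost if self.cost_cau else float("nan")),
            ("incremental pathway cost (A$)", self.delta_cost_pathway),
            ("cost offsets (A$)", self.cost_offset),
            ("net incremental cost (A$)", self.net_delta_cost),
            ("CSC DALYs averted", self.dalys_csc),
            ("CAU DALYs averted", self.dalys_cau),
            ("incremental DALYs averted", self.delta_dalys_averted),
            ("ICER (A$/DALY averted)", self.icer),
        ]
        return pd.DataFrame(rows, columns=["quantity", "value"])


def classify_icer(net_delta_cost: float,
                  delta_dalys_averted: float) -> tuple[str | None, float | str]:
    """Quadrant and ICER value/label for one point on the CE plane.

    North-east (more costly, more effective) and south-west (cheaper, less
    effective) yield numeric ICERs; the south-east quadrant is *dominant*
    (cheaper and more effective) and the north-west *dominated*.  Boundary
    ties go to the more favourable label (SE over NE, NW over SW).  A zero
    effect difference yields no quadrant: *equivalent* when costs also tie,
    otherwise *indeterminate*.
    """
    dc, de = net_delta_cost, delta_dalys_averted
    if not (math.isfinite(dc) and math.isfinite(de)):
        raise ValidationError(f"non-finite incremental values ({dc}, {de})")
    if de > 0:
        if dc > 0:
            return "NE", dc / de
        return "SE", DOMINANT
    if de < 0:
        if dc < 0:
            return "SW", dc / de
        return "NW", DOMINATED
    return None, (EQUIVALENT if dc == 0 else INDETERMINATE)


def run_base_case(params: ModelParameters,
                  include_offsets: bool = True,
                  include_time_travel: bool = False) -> IncrementalResult:
    """Deterministic point-estimate run of the full pipeline.

    ``include_offsets=False`` reproduces scenario SA1 (no cost offsets);
    ``include_time_travel=True`` scenario SA2 (patient time and travel
    costs added to both arms' pathway costs).
    """
    strata = build_eligible_population(params)
    traj_csc = arm_trajectories(strata, params, "CSC")
    traj_cau = arm_trajectories(strata, params, "CAU")

    dalys_csc = total_dalys_averted(traj_csc, params.weights)
    dalys_cau = total_dalys_averted(traj_cau, params.weights)

    cost_csc = cost_csc_pathway(strata, traj_csc, params,
                                include_time_travel=include_time_travel)
    cost_cau = cost_cau_pathway(strata, traj_cau, params,
                                include_time_travel=include_time_travel)

    delta_pathway = (cost_csc.pathway_cost + cost_csc.time_travel_cost
                     - cost_cau.pathway_cost - cost_cau.time_travel_cost)
    offset = compute_cost_offsets(traj_csc, traj_cau, params) \
        if include_offsets else 0.0
    net = delta_pathway + offset
    delta_e = dalys_csc - dalys_cau
    quadrant, icer = classify_icer(net, delta_e)
    return IncrementalResult(
        delta_cost_pathway=delta_pathway, cost_offset=offset,
        net_delta_cost=net, delta_dalys_averted=delta_e,
        icer=icer, quadrant=quadrant, target=params.target,
        eligible_n=total_eligible(strata),
        cost_csc=cost_csc, cost_cau=cost_cau,
        dalys_csc=dalys_csc, dalys_cau=dalys_cau)
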
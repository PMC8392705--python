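"""Univariate (tornado) and scenario sensitivity analyses.

The tornado analysis perturbs each point estimate by +/-10% (uncertainty
families untouched), reruns the deterministic base case, and reports the
resulting ICER swing per parameter, sorted descending.  Scenario analyses
rerun the base case with structural modifications: SA1 excludes cost
offsets from net incremental costs; SA2 adds patient time and travel
costs to both arms' pathway costs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .cea import IncrementalResult, run_base_case
from .errors import ConfigurationError
from .params import ModelParameters, iter_point_estimates, scale_parameter


@dataclass
class TornadoEntry:
    parameter_id: str
    icer_low: float | str       # ICER at x0.9
    icer_high: float | str      # ICER at x1.1
    swing: float                # |icer_high - icer_low|, nan if either is a label
    relative_change: float      # max |ICER - base| / |base|, nan if non-numeric

    @property
    def numeric(self) -> bool:
        return math.isfinite(self.swing)


@dataclass
class TornadoResult:
    base_icer: float | str
    entries: list[TornadoEntry]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter_id": [e.parameter_id for e in self.entries],
                "icer_low": [e.icer_low for e in self.entries],
                "icer_high": [e.icer_high for e in self.entries],
                "swing": [e.swing for e in self.entries],
                "relative_change": [e.relative_change for e in self.entries],
            }
        )


def tornado(params: ModelParameters,
            parameter_ids: list[str] | None = None,
            factors: tuple[float, float] = (0.9, 1.1)) -> TornadoResult:
    """Rerun the base case at ``x0.9`` and ``x1.1`` for each parameter.

    Defaults to all addressable point estimates.  Entries whose perturbed
    run yields a dominance label carry ``swing = nan`` and sort after all
    numeric entries, with a warning.
    """
    if parameter_ids is None:
        parameter_ids = list(iter_point_estimates(params))
    base = run_base_case(params)
    base_icer = base.icer
    entries: list[TornadoEntry] = []
    for pid in parameter_ids:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # probability clipping
            low = run_base_case(scale_parameter(params, pid, factors[0])).icer
            high = run_base_case(scale_parameter(params, pid, factors[1])).icer
        if isinstance(low, float) and isinstance(high, float):
            swing = abs(high - low)
            if isinstance(base_icer, float) and base_icer != 0:
                rel = max(abs(low - base_icer), abs(high - base_icer)) \
                    / abs(base_icer)
            else:
                rel = math.nan
        else:
            warnings.warn(
                f"tornado: {pid} produced a dominance label at a "
                f"perturbed run; excluded from numeric ranking",
                UserWarning, stacklevel=2)
            swing = math.nan
            rel = math.nan
        entries.append(TornadoEntry(parameter_id=pid, icer_low=low,
                                    icer_high=high, swing=swing,
                                    relative_change=rel))
    entries.sort(key=lambda e: (not e.numeric, -e.swing if e.numeric else 0.0))
    return TornadoResult(base_icer=base_icer, entries=entries)


@dataclass
class Modification:
    """One structured edit applied by a scenario."""

    kind: str                       # drop_offsets | enable_time_travel | scale
    parameter_id: str | None = None
    factor: float | None = None


@dataclass
class ScenarioSpec:
    id: str                         # SA1 | SA2 | custom
    description: str
    modifications: list[Modification] = field(default_factory=list)


def scenario_sa1() -> ScenarioSpec:
    return ScenarioSpec(id="SA1", description="exclude cost offsets",
                        modifications=[Modification(kind="drop_offsets")])


def scenario_sa2() -> ScenarioSpec:
    return ScenarioSpec(id="SA2",
                        description="include patient time and travel costs",
                        modifications=[Modification(kind="enable_time_travel")])


@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    result: IncrementalResult
    base: IncrementalResult


def run_scenario(params: ModelParameters, scenario: ScenarioSpec) -> ScenarioResult:
    """Run one scenario; the input parameter set is never mutated."""
    include_offsets = True
    include_time_travel = False
    modified = params
    for mod in scenario.modifications:
        if mod.kind == "drop_offsets":
            include_offsets = False
        elif mod.kind == "enable_time_travel":
            if not params.has_cost_item("TIME_TRAVEL"):
                raise ConfigurationError(
                    "time/travel scenario requested but no TIME_TRAVEL "
                    "cost items are configured")
            include_time_travel = True
        elif mod.kind == "scale":
            if mod.parameter_id is None or mod.factor is None:
                raise ConfigurationError(
                    "scale modification needs parameter_id and factor")
            modified = scale_parameter(modified, mod.parameter_id, mod.factor)
        else:
            raise ConfigurationError(f"unknown modification kind {mod.kind!r}")
    result = run_base_case(modified, include_offsets=include_offsets,
                           include_time_travel=include_time_travel)
    base = run_base_case(params)
    return ScenarioResult(spec=scenario, result=result, base=base)
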
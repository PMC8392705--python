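"""Model/Results facade over the cost-utility pipeline.

:class:`CostUtilityModel` wraps a validated parameter set; ``fit()``
evaluates the deterministic base case and returns :class:`CEAResults`,
which carries the incremental estimates, exposes a ``summary()`` table,
and hangs the uncertainty and sensitivity analyses off the fitted state.
The model is a decision-analytic structure evaluated on declared
parameters rather than estimated from data, so ``fit`` is deterministic
and uncertainty enters through the probabilistic sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cea import IncrementalResult, run_base_case
from .params import ModelParameters, load_parameters
from .sensitivity import (
    ScenarioResult,
    ScenarioSpec,
    TornadoResult,
    run_scenario,
    scenario_sa1,
    scenario_sa2,
    tornado,
)
from .synthetic import SyntheticConfig, generate_parameters
from .uncertainty import PSAResult, run_psa


class CostUtilityModel:
    """Decision-tree cost-utility comparison of stepped care vs usual care."""

    def __init__(self, params: ModelParameters):
        params.validate()
        self.params = params

    @classmethod
    def from_file(cls, path) -> "CostUtilityModel":
        return cls(load_parameters(path))

    @classmethod
    def from_synthetic(cls, config: SyntheticConfig | int | None = None
                       ) -> "CostUtilityModel":
        if isinstance(config, int):
            config = SyntheticConfig(seed=config)
        return cls(generate_parameters(config))

    def with_target(self, target: str) -> "CostUtilityModel":
        """Copy of the model restricted to one targeting variant."""
        params = self.params.copy()
        params.target = target
        return CostUtilityModel(params)

    def fit(self) -> "CEAResults":
        """Evaluate the deterministic base case."""
        return CEAResults(self, run_base_case(self.params))


@dataclass
class CEAResults:
    model: CostUtilityModel
    incremental: IncrementalResult

    @property
    def icer(self) -> float | str:
        return self.incremental.icer

    @property
    def params(self) -> ModelParameters:
        return self.model.params

    def summary(self) -> str:
        inc = self.incremental
        lines = [
            "Cost-utility analysis: collaborative stepped care vs care-as-usual",
            f"  target: {inc.target}    currency: 2019 A$    horizon: 1 year",
            f"  eligible population: {inc.eligible_n:,.0f} persons",
            "",
            f"  CSC pathway cost:          A$ {inc.cost_csc.pathway_cost:>16,.0f}",
            f"  CAU pathway cost:          A$ {inc.cost_cau.pathway_cost:>16,.0f}",
            f"  incremental pathway cost:  A$ {inc.delta_cost_pathway:>16,.0f}",
            f"  cost offsets:              A$ {inc.cost_offset:>16,.0f}",
            f"  net incremental cost:      A$ {inc.net_delta_cost:>16,.0f}",
            "",
            f"  CSC DALYs averted:            {inc.dalys_csc:>16,.0f}",
            f"  CAU DALYs averted:            {inc.dalys_cau:>16,.0f}",
            f"  incremental DALYs averted:    {inc.delta_dalys_averted:>16,.0f}",
            "",
            f"  ICER: {inc.icer_label} A$/DALY averted"
            + (f"   (quadrant {inc.quadrant})" if inc.quadrant else ""),
            f"  WTP threshold: A$ {self.params.wtp:,.0f}/DALY",
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return self.incremental.to_frame()

    # -- downstream analyses hang off the fitted results -----------------

    def psa(self, n_iterations: int | None = None, seed: int | None = None,
            **kwargs) -> PSAResult:
        return run_psa(self.params, n_iterations=n_iterations, seed=seed,
                       **kwargs)

    def tornado(self, parameter_ids: list[str] | None = None) -> TornadoResult:
        return tornado(self.params, parameter_ids)

    def scenario(self, spec: ScenarioSpec | str) -> ScenarioResult:
        if isinstance(spec, str):
            spec = {"SA1": scenario_sa1, "SA2": scenario_sa2}[spec]()
        return run_scenario(self.params, spec)
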
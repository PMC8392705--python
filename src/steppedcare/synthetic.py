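"""Synthetic parameter-set generator.

Real applications of this model are driven by supplementary data tables:
population demography, adjusted prevalences and severity distributions,
trial remission probabilities, disability weights, and costed pathway
items, each with an uncertainty distribution.  This module generates
complete, internally consistent :class:`~steppedcare.params.ModelParameters`
sets with the same structure so that every downstream stage is exercisable
and testable without those tables.

Conventions (standard probabilistic-sensitivity-analysis practice):

* probabilities and proportions get **beta** distributions, moment-matched
  to the point estimate with a spread dial ``s`` via
  ``alpha + beta = 1/s**2 - 1`` (so the standard deviation is
  ``s * sqrt(m * (1 - m))`` for mean ``m``, valid for any ``m`` in (0, 1));
* unit costs get **gamma** distributions with coefficient of variation
  ``s`` (``shape = 1/s**2``, ``scale = mean * s**2``).

Default magnitudes are loosely modelled on the 2019 Australian adult
population, GBD-style severity distributions and disability weights, and
plausible 2019 A$ primary-care unit costs.  They are stand-ins chosen to
put the model in a realistic operating regime; they are not the values of
any published analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, GenerationError
from .params import (
    ARMS,
    CAU_BRANCHES,
    CSC_STEP2,
    DISORDERS,
    SEVERITIES,
    SEXES,
    CohortSpec,
    DisabilityWeights,
    ModelParameters,
    PathwayAllocation,
    PathwayCostItem,
    RemissionSchedule,
    UncertainValue,
)


@dataclass
class SyntheticConfig:
    """Dials for the synthetic generator.

    ``csc_remission_advantage`` is the additive probability increment of the
    stepped-care arm over care-as-usual in each 4-month interval;
    ``uncertainty_spread`` the CV-like width dial for all distributions.
    """

    seed: int = 0
    n_cohorts: int = 14
    csc_remission_advantage: float = 0.15
    cost_scale: float = 1.0
    uncertainty_spread: float = 0.10

    def validate(self) -> None:
        if self.n_cohorts <= 0 or self.n_cohorts % 2 != 0:
            raise GenerationError(
                f"n_cohorts must be an even positive integer, got {self.n_cohorts}")
        if self.cost_scale <= 0:
            raise GenerationError(f"cost_scale must be positive, got {self.cost_scale}")
        if not 0.0 < self.uncertainty_spread < 1.0:
            raise GenerationError(
                f"uncertainty_spread must be in (0, 1), got {self.uncertainty_spread}")


def beta_from_point(point: float, spread: float) -> UncertainValue:
    """Beta UncertainValue with mean ``point``; degenerate points stay fixed."""
    if point <= 0.0 or point >= 1.0:
        return UncertainValue(point=point, family="fixed")
    nu = 1.0 / spread**2 - 1.0
    return UncertainValue(point=point, family="beta",
                          params=(point * nu, (1.0 - point) * nu))


def gamma_from_point(point: float, spread: float) -> UncertainValue:
    """Gamma UncertainValue with mean ``point`` and CV ``spread``."""
    if point <= 0.0:
        return UncertainValue(point=point, family="fixed")
    shape = 1.0 / spread**2
    return UncertainValue(point=point, family="gamma", params=(shape, point / shape))


def sample_uncertain(value: UncertainValue, rng: np.random.Generator) -> float:
    """One draw from the value's uncertainty distribution.

    ``fixed`` returns the point estimate without consuming random state, so
    degenerate parameter sets reproduce the base case draw-for-draw.
    """
    p = value.params
    if value.family == "fixed":
        return value.point
    if value.family == "beta":
        return float(rng.beta(p[0], p[1]))
    if value.family == "gamma":
        return float(rng.gamma(p[0]) * p[1])
    if value.family == "lognormal":
        return float(rng.lognormal(p[0], p[1]))
    if value.family == "uniform":
        return float(rng.uniform(p[0], p[1]))
    raise ConfigurationError(f"unsupported distribution family {value.family!r}")


# ---------------------------------------------------------------------------
# Default magnitudes (see module docstring)

# baseline conditional 4-month remission probabilities for care-as-usual,
# per disorder and interval (0-4, 4-8, 8-12 months)
_CAU_REMISSION = {
    "depression": (0.35, 0.25, 0.20),
    "anxiety": (0.30, 0.22, 0.18),
}

_SEVERITY_POINTS = {
    "depression": {"mild": 0.45, "moderate": 0.40, "severe": 0.15},
    "anxiety": {"mild": 0.55, "moderate": 0.35, "severe": 0.10},
}

# GBD-2019-flavoured disability weights per disorder and severity
_DW_UNREMITTED = {
    "depression": {"mild": 0.145, "moderate": 0.396, "severe": 0.658},
    "anxiety": {"mild": 0.030, "moderate": 0.133, "severe": 0.523},
}
_DW_REMITTED = {"depression": 0.05, "anxiety": 0.02}
_DW_BACKGROUND = 0.05

# (unit cost 2019 A$, quantity, coverage) per cost category
_COST_TABLE = {
    "CSC0": (20.0, 1.0, 1.0),     # training, amortised per treated person
    "CSC1a": (70.0, 5.0, 1.0),    # nurse-guided self-help sessions
    "CSC1b": (95.0, 5.0, 1.0),    # guided self-help + antidepressants
    "CSC2a": (120.0, 4.0, 1.0),   # specialised care: antidepressants
    "CSC2b": (150.0, 6.0, 1.0),   # specialised care: psychotherapy
    "CSC2c": (190.0, 6.0, 1.0),   # specialised care: combined
    "CSC9": (25.0, 4.0, 1.0),     # benzodiazepine add-on scripts
    "CAU1": (60.0, 6.0, 1.0),     # antidepressants + GP reviews
    "CAU2": (150.0, 6.0, 1.0),    # specialised mental healthcare
    "CAU3": (0.0, 0.0, 1.0),      # no treatment
    "CAU9": (25.0, 4.0, 1.0),
    "OFFSET_ANNUAL": (220.0, 12.0, 1.0),  # annual cost per unremitted case
}
# per-visit time+travel cost x visit count; stepped care involves more
# contacts (guided self-help sessions plus step-up referrals) than usual care
_TIME_TRAVEL = {"CSC": (25.0, 8.0, 1.0), "CAU": (25.0, 5.0, 1.0)}

_ALLOC_CSC_STEP2 = {"CSC2a": 0.25, "CSC2b": 0.40, "CSC2c": 0.35}
_ALLOC_CAU = {"CAU1": 0.35, "CAU2": 0.25, "CAU3": 0.40}
_BENZO_PROP = 0.20

_GP_MH_CONSULT = 0.11            # saw a GP for mental health in the past year
_PREVALENCE = {"depression": 0.30, "anxiety": 0.35}  # primary diagnosis, among them

# adult population ~19.6M spread over 10-year bands with a declining profile
_TOTAL_ADULTS = 19_600_000.0
_BAND_WEIGHTS = (1.15, 1.25, 1.20, 1.05, 0.95, 0.75, 0.65)


def _age_bands(n_bands: int) -> list[str]:
    bands = []
    lower = 18
    for i in range(n_bands):
        if i == n_bands - 1:
            bands.append(f"{lower}+")
        else:
            bands.append(f"{lower}-{lower + 9}")
            lower += 10
    return bands


def generate_parameters(config: SyntheticConfig | None = None) -> ModelParameters:
    """Generate a complete, validated ModelParameters set.

    Deterministic in ``config.seed``; the stepped-care arm's remission
    probabilities exceed care-as-usual by ``csc_remission_advantage`` in
    every interval, and all probability/proportion parameters carry beta
    uncertainty while unit costs carry gamma uncertainty.
    """
    config = config or SyntheticConfig()
    config.validate()
    spread = config.uncertainty_spread
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    # remission schedules; fail loudly if the advantage leaves [0, 1]
    schedules = []
    for disorder in DISORDERS:
        for arm in ARMS:
            ps = []
            for p_cau in _CAU_REMISSION[disorder]:
                p = p_cau + (config.csc_remission_advantage if arm == "CSC" else 0.0)
                if not 0.0 <= p <= 1.0:
                    raise GenerationError(
                        f"csc_remission_advantage {config.csc_remission_advantage} "
                        f"pushes {disorder} probability to {p:.4g}, outside [0, 1]")
                ps.append(beta_from_point(p, spread))
            schedules.append(RemissionSchedule(arm=arm, disorder=disorder,
                                               p_interval=tuple(ps)))

    # age-sex cohorts with mild seeded jitter around the demographic profile
    n_bands = config.n_cohorts // 2
    bands = _age_bands(n_bands)
    weights = np.array([_BAND_WEIGHTS[i % len(_BAND_WEIGHTS)] for i in range(n_bands)])
    weights = weights / weights.sum()
    cohorts = []
    for band, w in zip(bands, weights):
        for sex in SEXES:
            pop = _TOTAL_ADULTS * float(w) / 2.0 * float(rng.uniform(0.95, 1.05))
            consult = _GP_MH_CONSULT * float(rng.uniform(0.9, 1.1))
            # women consult somewhat more often for mental health
            consult *= 1.15 if sex == "female" else 0.85
            prevalence = {
                d: beta_from_point(_PREVALENCE[d] * float(rng.uniform(0.9, 1.1)),
                                   spread)
                for d in DISORDERS
            }
            severity = {}
            for d in DISORDERS:
                raw = np.array([_SEVERITY_POINTS[d][s] for s in SEVERITIES])
                raw = raw * rng.uniform(0.9, 1.1, size=3)
                raw = raw / raw.sum()
                severity[d] = {s: beta_from_point(float(v), spread)
                               for s, v in zip(SEVERITIES, raw)}
            cohorts.append(CohortSpec(
                age_group=band, sex=sex, population=round(pop, 1),
                gp_mh_consult_prop=beta_from_point(consult, spread),
                prevalence=prevalence, severity_split=severity))

    weights_dw = DisabilityWeights(
        unremitted={d: {s: beta_from_point(_DW_UNREMITTED[d][s], spread)
                        for s in SEVERITIES} for d in DISORDERS},
        remitted={d: beta_from_point(_DW_REMITTED[d], spread) for d in DISORDERS},
        background=beta_from_point(_DW_BACKGROUND, spread),
    )

    costs = []
    for cat, (unit, qty, cov) in _COST_TABLE.items():
        costs.append(PathwayCostItem(
            category_id=cat,
            unit_cost=gamma_from_point(unit * config.cost_scale, spread),
            quantity=qty, coverage=cov, price_year=2019))
    for arm in ARMS:
        unit, qty, cov = _TIME_TRAVEL[arm]
        costs.append(PathwayCostItem(
            category_id="TIME_TRAVEL",
            unit_cost=gamma_from_point(unit * config.cost_scale, spread),
            quantity=qty, coverage=cov, arm=arm, price_year=2019))

    allocations = [
        PathwayAllocation(
            arm="CSC",
            branch_props={b: beta_from_point(_ALLOC_CSC_STEP2[b], spread)
                          for b in CSC_STEP2},
            benzodiazepine=beta_from_point(_BENZO_PROP, spread)),
        PathwayAllocation(
            arm="CAU",
            branch_props={b: beta_from_point(_ALLOC_CAU[b], spread)
                          for b in CAU_BRANCHES},
            benzodiazepine=beta_from_point(_BENZO_PROP, spread)),
    ]

    params = ModelParameters(
        cohorts=cohorts, remission=schedules, weights=weights_dw,
        costs=costs, allocations=allocations, seed=config.seed)
    params.validate()
    return params
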
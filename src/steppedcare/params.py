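"""Declarative model parameters: containers, validation, (de)serialisation.

The whole cost-utility model is driven by a single :class:`ModelParameters`
object holding point estimates plus uncertainty-distribution specifications
for every input: the eligible-population construction (age-sex cohorts,
GP mental-health consultation proportions, primary-diagnosis prevalences,
severity splits), the 4-monthly remission schedules for both trial arms,
GBD-style disability weights, pathway cost items, and branch allocation
proportions.  Parameter files are YAML documents with named sections
mirroring the container classes; ``load_parameters``/``write_parameters``
round-trip them at full precision.

Every stored scalar that the univariate sensitivity analysis may perturb is
addressable by a dotted identifier (e.g. ``costs.CSC1a.unit_cost.point``);
see :func:`iter_point_estimates` and :func:`scale_parameter`.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass

import yaml

from .errors import ParameterLookupError, SchemaError, ValidationError

SCHEMA_VERSION = "steppedcare-parameters-v1"

ARMS = ("CSC", "CAU")
DISORDERS = ("depression", "anxiety")
SEVERITIES = ("mild", "moderate", "severe")
SEXES = ("female", "male")
TARGETS = ("both", "depression_only", "anxiety_only")

#: Pathway cost categories.  CSC0 is provider training; CSC1a/1b the
#: guided-self-help first step (without/with antidepressants); CSC2a/2b/2c
#: specialised-care second step (antidepressants / psychotherapy / combined);
#: CAU1/2/3 antidepressants-only / specialised care / no treatment;
#: CSC9/CAU9 benzodiazepine add-ons; OFFSET_ANNUAL the annual treatment cost
#: per unremitted case used for cost offsets; TIME_TRAVEL the per-patient
#: time and travel layer used only in scenario analysis.
COST_CATEGORIES = (
    "CSC0", "CSC1a", "CSC1b", "CSC2a", "CSC2b", "CSC2c", "CSC9",
    "CAU1", "CAU2", "CAU3", "CAU9", "OFFSET_ANNUAL", "TIME_TRAVEL",
)
CSC_STEP2 = ("CSC2a", "CSC2b", "CSC2c")
CAU_BRANCHES = ("CAU1", "CAU2", "CAU3")

DISTRIBUTION_FAMILIES = ("beta", "gamma", "lognormal", "uniform", "fixed")

_SUM_TOL = 1e-9


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ValidationError(message)


@dataclass
class UncertainValue:
    """A point estimate plus the distribution used for it in the PSA.

    ``params`` are family specific: beta ``(alpha, beta)``; gamma
    ``(shape, scale)``; lognormal ``(mu, sigma)`` of the underlying normal;
    uniform ``(low, high)``; fixed takes none.
    """

    point: float
    family: str = "fixed"
    params: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        self.point = float(self.point)
        self.params = tuple(float(p) for p in self.params)

    def validate(self, context: str = "UncertainValue") -> None:
        _require(math.isfinite(self.point),
                 f"{context}: point estimate {self.point!r} is not finite")
        if self.family not in DISTRIBUTION_FAMILIES:
            raise ValidationError(
                f"{context}: unknown distribution family {self.family!r}")
        p = self.params
        if self.family == "beta":
            _require(0.0 <= self.point <= 1.0,
                     f"{context}: beta point {self.point} outside [0, 1]")
            _require(len(p) == 2 and p[0] > 0 and p[1] > 0,
                     f"{context}: beta requires positive (alpha, beta), got {p}")
        elif self.family == "gamma":
            _require(self.point >= 0.0,
                     f"{context}: gamma point {self.point} is negative")
            _require(len(p) == 2 and p[0] > 0 and p[1] > 0,
                     f"{context}: gamma requires positive (shape, scale), got {p}")
        elif self.family == "lognormal":
            _require(self.point >= 0.0,
                     f"{context}: lognormal point {self.point} is negative")
            _require(len(p) == 2 and p[1] > 0,
                     f"{context}: lognormal requires (mu, sigma>0), got {p}")
        elif self.family == "uniform":
            _require(len(p) == 2 and p[0] <= p[1],
                     f"{context}: uniform requires low <= high, got {p}")
        elif self.family == "fixed":
            _require(len(p) == 0,
                     f"{context}: fixed takes no distribution params, got {p}")

    def mean(self) -> float:
        """Analytic mean of the uncertainty distribution."""
        p = self.params
        if self.family == "beta":
            return p[0] / (p[0] + p[1])
        if self.family == "gamma":
            return p[0] * p[1]
        if self.family == "lognormal":
            return math.exp(p[0] + p[1] ** 2 / 2.0)
        if self.family == "uniform":
            return (p[0] + p[1]) / 2.0
        return self.point

    def to_dict(self) -> dict:
        d: dict = {"point": self.point, "family": self.family}
        if self.params:
            d["params"] = list(self.params)
        return d

    @classmethod
    def from_dict(cls, d: dict, context: str = "UncertainValue") -> "UncertainValue":
        if not isinstance(d, dict) or "point" not in d:
            raise SchemaError(f"{context}: expected a mapping with a 'point' field, got {d!r}")
        return cls(point=d["point"], family=d.get("family", "fixed"),
                   params=tuple(d.get("params", ())))


def fixed(point: float) -> UncertainValue:
    """Shorthand for a degenerate (no-uncertainty) value."""
    return UncertainValue(point=point, family="fixed")


@dataclass
class CohortSpec:
    """One age-sex stratum of the eligible adult population.

    ``gp_mh_consult_prop`` is the proportion who visited a GP clinic in the
    past year for mental-health treatment; ``prevalence`` the
    primary-diagnosis prevalence of each disorder among them; and
    ``severity_split`` the mild/moderate/severe distribution per disorder
    (sums to one).
    """

    age_group: str
    sex: str
    population: float
    gp_mh_consult_prop: UncertainValue
    prevalence: dict[str, UncertainValue]
    severity_split: dict[str, dict[str, UncertainValue]]

    @property
    def key(self) -> str:
        return f"{self.age_group}.{self.sex}"

    def validate(self) -> None:
        ctx = f"CohortSpec[{self.key}]"
        _require(self.sex in SEXES, f"{ctx}: sex {self.sex!r} not in {SEXES}")
        _require(self.population >= 0,
                 f"{ctx}: population {self.population} is negative")
        self.gp_mh_consult_prop.validate(f"{ctx}.gp_mh_consult_prop")
        _require(0.0 <= self.gp_mh_consult_prop.point <= 1.0,
                 f"{ctx}: gp_mh_consult_prop {self.gp_mh_consult_prop.point} outside [0, 1]")
        for disorder in DISORDERS:
            if disorder not in self.prevalence:
                raise SchemaError(f"{ctx}: missing prevalence for {disorder!r}")
            uv = self.prevalence[disorder]
            uv.validate(f"{ctx}.prevalence.{disorder}")
            _require(0.0 <= uv.point <= 1.0,
                     f"{ctx}: prevalence.{disorder} {uv.point} outside [0, 1]")
            if disorder not in self.severity_split:
                raise SchemaError(f"{ctx}: missing severity_split for {disorder!r}")
            split = self.severity_split[disorder]
            for severity in SEVERITIES:
                if severity not in split:
                    raise SchemaError(
                        f"{ctx}: severity_split.{disorder} missing {severity!r}")
                suv = split[severity]
                suv.validate(f"{ctx}.severity_split.{disorder}.{severity}")
                _require(0.0 <= suv.point <= 1.0,
                         f"{ctx}: severity_split.{disorder}.{severity} "
                         f"{suv.point} outside [0, 1]")
            total = sum(split[s].point for s in SEVERITIES)
            _require(abs(total - 1.0) <= _SUM_TOL,
                     f"{ctx}: severity_split.{disorder} sums to {total:.12g}")
        prev_total = sum(self.prevalence[d].point for d in DISORDERS)
        _require(prev_total <= 1.0 + _SUM_TOL,
                 f"{ctx}: primary-diagnosis prevalences sum to {prev_total:.12g} > 1")

    def to_dict(self) -> dict:
        return {
            "age_group": self.age_group,
            "sex": self.sex,
            "population": self.population,
            "gp_mh_consult_prop": self.gp_mh_consult_prop.to_dict(),
            "prevalence": {d: uv.to_dict() for d, uv in self.prevalence.items()},
            "severity_split": {
                d: {s: uv.to_dict() for s, uv in split.items()}
                for d, split in self.severity_split.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        try:
            return cls(
                age_group=str(d["age_group"]),
                sex=str(d["sex"]),
                population=float(d["population"]),
                gp_mh_consult_prop=UncertainValue.from_dict(
                    d["gp_mh_consult_prop"], "gp_mh_consult_prop"),
                prevalence={k: UncertainValue.from_dict(v, f"prevalence.{k}")
                            for k, v in d["prevalence"].items()},
                severity_split={
                    k: {s: UncertainValue.from_dict(v, f"severity_split.{k}.{s}")
                        for s, v in split.items()}
                    for k, split in d["severity_split"].items()
                },
            )
        except KeyError as exc:
            raise SchemaError(f"CohortSpec: missing field {exc.args[0]!r}") from exc


@dataclass
class RemissionSchedule:
    """Arm x disorder probabilities of remission over the three 4-month intervals.

    Probabilities are conditional per-interval remission probabilities among
    the still-unremitted (see ``ModelParameters.remission_reading`` for the
    alternative cumulative reading).
    """

    arm: str
    disorder: str
    p_interval: tuple[UncertainValue, UncertainValue, UncertainValue]

    def __post_init__(self) -> None:
        self.p_interval = tuple(self.p_interval)  # type: ignore[assignment]

    def validate(self) -> None:
        ctx = f"RemissionSchedule[{self.arm}.{self.disorder}]"
        _require(self.arm in ARMS, f"{ctx}: arm {self.arm!r} not in {ARMS}")
        _require(self.disorder in DISORDERS,
                 f"{ctx}: disorder {self.disorder!r} not in {DISORDERS}")
        if len(self.p_interval) != 3:
            raise ValidationError(
                f"{ctx}: expected exactly 3 interval probabilities, "
                f"got {len(self.p_interval)}")
        for i, uv in enumerate(self.p_interval, start=1):
            uv.validate(f"{ctx}.p{i}")
            _require(0.0 <= uv.point <= 1.0,
                     f"{ctx}: p{i} {uv.point} outside [0, 1]")

    def to_dict(self) -> dict:
        return {"arm": self.arm, "disorder": self.disorder,
                "p_interval": [uv.to_dict() for uv in self.p_interval]}

    @classmethod
    def from_dict(cls, d: dict) -> "RemissionSchedule":
        try:
            ps = d["p_interval"]
        except KeyError as exc:
            raise SchemaError("RemissionSchedule: missing field 'p_interval'") from exc
        return cls(arm=str(d.get("arm", "")), disorder=str(d.get("disorder", "")),
                   p_interval=tuple(UncertainValue.from_dict(p, "p_interval")
                                    for p in ps))


@dataclass
class DisabilityWeights:
    """GBD-style disability weights with background-morbidity adjustment.

    ``unremitted`` maps disorder -> severity -> weight; ``remitted`` holds a
    small residual weight per disorder for the remitted state; ``background``
    is the background-morbidity weight combined multiplicatively with the
    condition weight.
    """

    unremitted: dict[str, dict[str, UncertainValue]]
    remitted: dict[str, UncertainValue]
    background: UncertainValue

    def validate(self) -> None:
        ctx = "DisabilityWeights"
        for disorder in DISORDERS:
            if disorder not in self.unremitted:
                raise SchemaError(f"{ctx}: missing unremitted weights for {disorder!r}")
            for severity in SEVERITIES:
                if severity not in self.unremitted[disorder]:
                    raise SchemaError(
                        f"{ctx}: unremitted.{disorder} missing {severity!r}")
                uv = self.unremitted[disorder][severity]
                uv.validate(f"{ctx}.unremitted.{disorder}.{severity}")
                _require(0.0 <= uv.point < 1.0,
                         f"{ctx}: unremitted.{disorder}.{severity} "
                         f"{uv.point} outside [0, 1)")
            if disorder not in self.remitted:
                raise SchemaError(f"{ctx}: missing remitted weight for {disorder!r}")
            r = self.remitted[disorder]
            r.validate(f"{ctx}.remitted.{disorder}")
            _require(0.0 <= r.point < 1.0,
                     f"{ctx}: remitted.{disorder} {r.point} outside [0, 1)")
            floor = min(self.unremitted[disorder][s].point for s in SEVERITIES)
            _require(r.point <= floor + _SUM_TOL,
                     f"{ctx}: remitted.{disorder} {r.point} exceeds the mildest "
                     f"unremitted weight {floor}")
        self.background.validate(f"{ctx}.background")
        _require(0.0 <= self.background.point < 1.0,
                 f"{ctx}: background {self.background.point} outside [0, 1)")

    def to_dict(self) -> dict:
        return {
            "unremitted": {d: {s: uv.to_dict() for s, uv in sev.items()}
                           for d, sev in self.unremitted.items()},
            "remitted": {d: uv.to_dict() for d, uv in self.remitted.items()},
            "background": self.background.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DisabilityWeights":
        try:
            return cls(
                unremitted={k: {s: UncertainValue.from_dict(v, f"unremitted.{k}.{s}")
                                for s, v in sev.items()}
                            for k, sev in d["unremitted"].items()},
                remitted={k: UncertainValue.from_dict(v, f"remitted.{k}")
                          for k, v in d["remitted"].items()},
                background=UncertainValue.from_dict(d["background"], "background"),
            )
        except KeyError as exc:
            raise SchemaError(f"DisabilityWeights: missing field {exc.args[0]!r}") from exc


@dataclass
class PathwayCostItem:
    """One costed pathway branch: unit cost x quantity x coverage per person.

    ``arm`` is only meaningful for TIME_TRAVEL (and optionally OFFSET_ANNUAL)
    items, which may be configured per arm; ``None`` applies to both arms.
    ``price_year`` documents the source price year of the unit cost; all
    values are expected to be expressed in 2019 A$ at load time, with any
    deflation applied as pre-processing.
    """

    category_id: str
    unit_cost: UncertainValue
    quantity: float
    coverage: float = 1.0
    arm: str | None = None
    price_year: int | None = None

    @property
    def key(self) -> str:
        return self.category_id if self.arm is None else f"{self.category_id}_{self.arm}"

    def validate(self) -> None:
        ctx = f"PathwayCostItem[{self.key}]"
        _require(self.category_id in COST_CATEGORIES,
                 f"{ctx}: category_id {self.category_id!r} not in {COST_CATEGORIES}")
        self.unit_cost.validate(f"{ctx}.unit_cost")
        _require(self.unit_cost.point >= 0,
                 f"{ctx}: unit_cost {self.unit_cost.point} is negative")
        _require(self.quantity >= 0, f"{ctx}: quantity {self.quantity} is negative")
        _require(0.0 <= self.coverage <= 1.0,
                 f"{ctx}: coverage {self.coverage} outside [0, 1]")
        if self.arm is not None:
            _require(self.arm in ARMS, f"{ctx}: arm {self.arm!r} not in {ARMS}")

    def per_person_cost(self) -> float:
        """Point-estimate cost per person in the branch."""
        return self.unit_cost.point * self.quantity * self.coverage

    def to_dict(self) -> dict:
        d: dict = {"category_id": self.category_id,
                   "unit_cost": self.unit_cost.to_dict(),
                   "quantity": self.quantity, "coverage": self.coverage}
        if self.arm is not None:
            d["arm"] = self.arm
        if self.price_year is not None:
            d["price_year"] = self.price_year
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PathwayCostItem":
        try:
            return cls(
                category_id=str(d["category_id"]),
                unit_cost=UncertainValue.from_dict(d["unit_cost"], "unit_cost"),
                quantity=float(d["quantity"]),
                coverage=float(d.get("coverage", 1.0)),
                arm=d.get("arm"),
                price_year=d.get("price_year"),
            )
        except KeyError as exc:
            raise SchemaError(f"PathwayCostItem: missing field {exc.args[0]!r}") from exc


@dataclass
class PathwayAllocation:
    """Branch allocation proportions for one arm.

    For CSC, ``branch_props`` splits step-2 entrants over CSC2a/2b/2c (the
    first step is structural: mild -> 1a, moderate -> 1b, severe -> step 2
    directly).  For CAU it splits all patients over CAU1/2/3, with dropouts
    folded into CAU3.  ``benzodiazepine`` is the proportion of all patients
    receiving the benzodiazepine add-on (CSC9/CAU9).
    """

    arm: str
    branch_props: dict[str, UncertainValue]
    benzodiazepine: UncertainValue

    def expected_branches(self) -> tuple[str, ...]:
        return CSC_STEP2 if self.arm == "CSC" else CAU_BRANCHES

    def validate(self) -> None:
        ctx = f"PathwayAllocation[{self.arm}]"
        _require(self.arm in ARMS, f"{ctx}: arm {self.arm!r} not in {ARMS}")
        expected = self.expected_branches()
        for branch in expected:
            if branch not in self.branch_props:
                raise SchemaError(f"{ctx}: missing branch proportion {branch!r}")
            uv = self.branch_props[branch]
            uv.validate(f"{ctx}.{branch}")
            _require(0.0 <= uv.point <= 1.0,
                     f"{ctx}: {branch} {uv.point} outside [0, 1]")
        total = sum(self.branch_props[b].point for b in expected)
        _require(abs(total - 1.0) <= _SUM_TOL,
                 f"{ctx}: branch proportions sum to {total:.12g}")
        self.benzodiazepine.validate(f"{ctx}.benzodiazepine")
        _require(0.0 <= self.benzodiazepine.point <= 1.0,
                 f"{ctx}: benzodiazepine {self.benzodiazepine.point} outside [0, 1]")

    def to_dict(self) -> dict:
        return {"arm": self.arm,
                "branch_props": {b: uv.to_dict() for b, uv in self.branch_props.items()},
                "benzodiazepine": self.benzodiazepine.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "PathwayAllocation":
        try:
            return cls(
                arm=str(d["arm"]),
                branch_props={b: UncertainValue.from_dict(v, f"branch_props.{b}")
                              for b, v in d["branch_props"].items()},
                benzodiazepine=UncertainValue.from_dict(
                    d["benzodiazepine"], "benzodiazepine"),
            )
        except KeyError as exc:
            raise SchemaError(f"PathwayAllocation: missing field {exc.args[0]!r}") from exc


@dataclass
class ModelParameters:
    """The complete declarative parameter set for one model run."""

    cohorts: list[CohortSpec]
    remission: list[RemissionSchedule]
    weights: DisabilityWeights
    costs: list[PathwayCostItem]
    allocations: list[PathwayAllocation]
    wtp: float = 50_000.0
    horizon_years: float = 1.0
    n_iterations: int = 3000
    seed: int = 0
    target: str = "both"
    # structural switches (see docs/methods.md)
    remission_reading: str = "conditional"   # or "cumulative"
    training_mode: str = "per_person"        # or "fixed_program"
    offset_basis: str = "person_years"       # or "end_of_year_cases"

    def validate(self) -> None:
        ctx = "ModelParameters"
        if not self.cohorts:
            raise ValidationError(f"{ctx}: cohort list is empty")
        for cohort in self.cohorts:
            cohort.validate()
        seen = set()
        for sched in self.remission:
            sched.validate()
            key = (sched.arm, sched.disorder)
            _require(key not in seen, f"{ctx}: duplicate remission schedule for {key}")
            seen.add(key)
        expected = {(a, d) for a in ARMS for d in DISORDERS}
        missing = expected - seen
        _require(not missing, f"{ctx}: missing remission schedules for {sorted(missing)}")
        self.weights.validate()
        item_keys = set()
        for item in self.costs:
            item.validate()
            _require(item.key not in item_keys,
                     f"{ctx}: duplicate cost item {item.key!r}")
            item_keys.add(item.key)
        alloc_arms = set()
        for alloc in self.allocations:
            alloc.validate()
            _require(alloc.arm not in alloc_arms,
                     f"{ctx}: duplicate allocation for arm {alloc.arm!r}")
            alloc_arms.add(alloc.arm)
        _require(alloc_arms == set(ARMS),
                 f"{ctx}: allocations present for {sorted(alloc_arms)}, need both arms")
        _require(self.wtp > 0, f"{ctx}: wtp {self.wtp} must be positive")
        _require(self.horizon_years == 1.0,
                 f"{ctx}: horizon_years {self.horizon_years} is fixed at 1")
        _require(int(self.n_iterations) >= 1,
                 f"{ctx}: n_iterations {self.n_iterations} must be >= 1")
        _require(self.target in TARGETS,
                 f"{ctx}: target {self.target!r} not in {TARGETS}")
        _require(self.remission_reading in ("conditional", "cumulative"),
                 f"{ctx}: remission_reading {self.remission_reading!r} unknown")
        _require(self.training_mode in ("per_person", "fixed_program"),
                 f"{ctx}: training_mode {self.training_mode!r} unknown")
        _require(self.offset_basis in ("person_years", "end_of_year_cases"),
                 f"{ctx}: offset_basis {self.offset_basis!r} unknown")

    # -- lookups ---------------------------------------------------------

    def schedule(self, arm: str, disorder: str) -> RemissionSchedule:
        for sched in self.remission:
            if sched.arm == arm and sched.disorder == disorder:
                return sched
        raise ParameterLookupError(f"no remission schedule for ({arm}, {disorder})")

    def cost_item(self, key: str) -> PathwayCostItem:
        for item in self.costs:
            if item.key == key:
                return item
        raise ParameterLookupError(f"no cost item {key!r}")

    def has_cost_item(self, category_id: str, arm: str | None = None) -> bool:
        return any(item.category_id == category_id
                   and (arm is None or item.arm in (None, arm))
                   for item in self.costs)

    def allocation(self, arm: str) -> PathwayAllocation:
        for alloc in self.allocations:
            if alloc.arm == arm:
                return alloc
        raise ParameterLookupError(f"no allocation for arm {arm!r}")

    def active_disorders(self) -> tuple[str, ...]:
        if self.target == "depression_only":
            return ("depression",)
        if self.target == "anxiety_only":
            return ("anxiety",)
        return DISORDERS

    # -- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema": SCHEMA_VERSION,
            "cohorts": [c.to_dict() for c in self.cohorts],
            "remission": [r.to_dict() for r in self.remission],
            "weights": self.weights.to_dict(),
            "costs": [c.to_dict() for c in self.costs],
            "allocations": [a.to_dict() for a in self.allocations],
            "wtp": self.wtp,
            "horizon_years": self.horizon_years,
            "n_iterations": int(self.n_iterations),
            "seed": int(self.seed),
            "target": self.target,
            "remission_reading": self.remission_reading,
            "training_mode": self.training_mode,
            "offset_basis": self.offset_basis,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        if not isinstance(d, dict):
            raise SchemaError(f"parameter document must be a mapping, got {type(d).__name__}")
        schema = d.get("schema")
        if schema != SCHEMA_VERSION:
            raise SchemaError(f"unsupported schema {schema!r}; expected {SCHEMA_VERSION!r}")
        for section in ("cohorts", "remission", "weights", "costs", "allocations"):
            if section not in d:
                raise SchemaError(f"parameter document missing section {section!r}")
        params = cls(
            cohorts=[CohortSpec.from_dict(c) for c in d["cohorts"]],
            remission=[RemissionSchedule.from_dict(r) for r in d["remission"]],
            weights=DisabilityWeights.from_dict(d["weights"]),
            costs=[PathwayCostItem.from_dict(c) for c in d["costs"]],
            allocations=[PathwayAllocation.from_dict(a) for a in d["allocations"]],
            wtp=float(d.get("wtp", 50_000.0)),
            horizon_years=float(d.get("horizon_years", 1.0)),
            n_iterations=int(d.get("n_iterations", 3000)),
            seed=int(d.get("seed", 0)),
            target=str(d.get("target", "both")),
            remission_reading=str(d.get("remission_reading", "conditional")),
            training_mode=str(d.get("training_mode", "per_person")),
            offset_basis=str(d.get("offset_basis", "person_years")),
        )
        return params

    def copy(self) -> "ModelParameters":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# File I/O

def load_parameters(path) -> ModelParameters:
    """Read and fully validate a YAML parameter file."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    params = ModelParameters.from_dict(doc)
    params.validate()
    return params


def write_parameters(params: ModelParameters, path) -> None:
    """Validate then write ``params`` to a YAML file readable by load_parameters."""
    params.validate()
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False, default_flow_style=False)


def dumps_parameters(params: ModelParameters) -> str:
    """Canonical YAML serialisation (used for digests and purity checks)."""
    return yaml.safe_dump(params.to_dict(), sort_keys=False, default_flow_style=False)


# ---------------------------------------------------------------------------
# Dotted-path parameter addressing
#
# Identifiers:
#   cohorts.<age_group>.<sex>.population
#   cohorts.<age_group>.<sex>.gp_mh_consult_prop.point
#   cohorts.<age_group>.<sex>.prevalence.<disorder>.point
#   cohorts.<age_group>.<sex>.severity_split.<disorder>.<severity>.point
#   remission.<arm>.<disorder>.p<1|2|3>.point
#   weights.unremitted.<disorder>.<severity>.point
#   weights.remitted.<disorder>.point
#   weights.background.point
#   costs.<item key>.unit_cost.point | .quantity | .coverage
#   allocations.<arm>.<branch>.point
#   allocations.<arm>.benzodiazepine.point

@dataclass
class _Leaf:
    get: object          # () -> float
    set: object          # (float) -> None
    is_probability: bool


def _leaves(params: ModelParameters) -> dict[str, _Leaf]:
    leaves: dict[str, _Leaf] = {}

    def uv_leaf(path: str, uv: UncertainValue, prob: bool) -> None:
        leaves[f"{path}.point"] = _Leaf(
            get=lambda uv=uv: uv.point,
            set=lambda v, uv=uv: setattr(uv, "point", float(v)),
            is_probability=prob)

    def plain_leaf(path: str, obj, attr: str, prob: bool) -> None:
        leaves[path] = _Leaf(
            get=lambda obj=obj, attr=attr: getattr(obj, attr),
            set=lambda v, obj=obj, attr=attr: setattr(obj, attr, float(v)),
            is_probability=prob)

    for cohort in params.cohorts:
        base = f"cohorts.{cohort.key}"
        plain_leaf(f"{base}.population", cohort, "population", prob=False)
        uv_leaf(f"{base}.gp_mh_consult_prop", cohort.gp_mh_consult_prop, prob=True)
        for d, uv in cohort.prevalence.items():
            uv_leaf(f"{base}.prevalence.{d}", uv, prob=True)
        for d, split in cohort.severity_split.items():
            for s, uv in split.items():
                uv_leaf(f"{base}.severity_split.{d}.{s}", uv, prob=True)
    for sched in params.remission:
        for i, uv in enumerate(sched.p_interval, start=1):
            uv_leaf(f"remission.{sched.arm}.{sched.disorder}.p{i}", uv, prob=True)
    for d, sev in params.weights.unremitted.items():
        for s, uv in sev.items():
            uv_leaf(f"weights.unremitted.{d}.{s}", uv, prob=True)
    for d, uv in params.weights.remitted.items():
        uv_leaf(f"weights.remitted.{d}", uv, prob=True)
    uv_leaf("weights.background", params.weights.background, prob=True)
    for item in params.costs:
        base = f"costs.{item.key}"
        uv_leaf(f"{base}.unit_cost", item.unit_cost, prob=False)
        plain_leaf(f"{base}.quantity", item, "quantity", prob=False)
        plain_leaf(f"{base}.coverage", item, "coverage", prob=True)
    for alloc in params.allocations:
        base = f"allocations.{alloc.arm}"
        for b, uv in alloc.branch_props.items():
            uv_leaf(f"{base}.{b}", uv, prob=True)
        uv_leaf(f"{base}.benzodiazepine", alloc.benzodiazepine, prob=True)
    return leaves


def iter_point_estimates(params: ModelParameters) -> dict[str, float]:
    """All addressable point estimates as ``{dotted id: value}`` (fixed order)."""
    return {path: leaf.get() for path, leaf in _leaves(params).items()}


def scale_parameter(params: ModelParameters, parameter_id: str,
                    factor: float) -> ModelParameters:
    """Return a copy of ``params`` with one point estimate multiplied by ``factor``.

    Probability-type values are clipped to [0, 1] with a warning.  No other
    stored value changes; group sum-to-one invariants are deliberately not
    re-enforced so that univariate perturbations stay univariate.
    """
    if factor <= 0:
        raise ValidationError(f"scale factor {factor} must be positive")
    out = params.copy()
    leaves = _leaves(out)
    if parameter_id not in leaves:
        raise ParameterLookupError(
            f"unknown parameter id {parameter_id!r}; see iter_point_estimates()")
    leaf = leaves[parameter_id]
    value = leaf.get() * factor
    if leaf.is_probability and value > 1.0:
        warnings.warn(f"{parameter_id}: scaled value {value:.6g} clipped to 1.0",
                      UserWarning, stacklevel=2)
        value = 1.0
    leaf.set(value)
    return out


def iter_uncertain_values(params: ModelParameters) -> list[tuple[str, UncertainValue]]:
    """Every UncertainValue in the set with its dotted path (fixed order).

    The PSA draws parameters in this order, so the order is part of the
    reproducibility contract.
    """
    out: list[tuple[str, UncertainValue]] = []
    for cohort in params.cohorts:
        base = f"cohorts.{cohort.key}"
        out.append((f"{base}.gp_mh_consult_prop", cohort.gp_mh_consult_prop))
        for d in sorted(cohort.prevalence):
            out.append((f"{base}.prevalence.{d}", cohort.prevalence[d]))
        for d in sorted(cohort.severity_split):
            for s, uv in cohort.severity_split[d].items():
                out.append((f"{base}.severity_split.{d}.{s}", uv))
    for sched in params.remission:
        for i, uv in enumerate(sched.p_interval, start=1):
            out.append((f"remission.{sched.arm}.{sched.disorder}.p{i}", uv))
    for d in sorted(params.weights.unremitted):
        for s, uv in params.weights.unremitted[d].items():
            out.append((f"weights.unremitted.{d}.{s}", uv))
    for d in sorted(params.weights.remitted):
        out.append((f"weights.remitted.{d}", params.weights.remitted[d]))
    out.append(("weights.background", params.weights.background))
    for item in params.costs:
        out.append((f"costs.{item.key}.unit_cost", item.unit_cost))
    for alloc in params.allocations:
        for b, uv in alloc.branch_props.items():
            out.append((f"allocations.{alloc.arm}.{b}", uv))
        out.append((f"allocations.{alloc.arm}.benzodiazepine", alloc.benzodiazepine))
    return out
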
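"""Eligible-population construction.

The eligible population is adults who visited a GP clinic in the past year
for mental-health treatment and have an in-scope depressive or anxiety
disorder.  Each age-sex cohort is expanded into disorder x severity strata
by multiplying population, consultation proportion, primary-diagnosis
prevalence and severity split.  Counts are expected persons and stay real
valued (cohort model, not microsimulation).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .params import SEVERITIES, CohortSpec, ModelParameters


@dataclass
class EligibleStratum:
    """Expected persons in one cohort x disorder x severity cell."""

    cohort: CohortSpec
    disorder: str
    severity: str
    n_persons: float


def build_eligible_population(params: ModelParameters) -> list[EligibleStratum]:
    """Expand cohorts into eligible strata for the configured target.

    ``n = population x gp_mh_consult_prop x prevalence(disorder)
    x severity_split(severity)``; disorders outside ``params.target`` are
    omitted.  Linear in every factor, so disorder streams are additive.
    """
    disorders = params.active_disorders()
    strata: list[EligibleStratum] = []
    for cohort in params.cohorts:
        base = cohort.population * cohort.gp_mh_consult_prop.point
        for disorder in disorders:
            n_disorder = base * cohort.prevalence[disorder].point
            for severity in SEVERITIES:
                n = n_disorder * cohort.severity_split[disorder][severity].point
                strata.append(EligibleStratum(
                    cohort=cohort, disorder=disorder, severity=severity,
                    n_persons=n))
    return strata


def total_eligible(strata: list[EligibleStratum]) -> float:
    return sum(s.n_persons for s in strata)


def strata_frame(strata: list[EligibleStratum]) -> pd.DataFrame:
    """Tabular export: one row per stratum."""
    return pd.DataFrame(
        {
            "age_group": [s.cohort.age_group for s in strata],
            "sex": [s.cohort.sex for s in strata],
            "disorder": [s.disorder for s in strata],
            "severity": [s.severity for s in strata],
            "n_persons": [s.n_persons for s in strata],
        }
    )
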
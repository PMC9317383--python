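"""The prevalence cascade: population at risk → potential cases → sub-cohorts.

The annual cohort sizes are derived by applying rates to integer populations:
an incidence rate to the at-risk population (ages 0–29) gives potential cases;
a care-seeking fraction of potential cases gives cases receiving treatment;
an untreated-mortality fraction gives premature deaths; and the same incidence
applied to the working-age and marriageable-female subpopulations gives the
cohorts behind the productivity and marriage costs.

Every stage rounds DOWN to a whole person.  The convention matters: nearest
rounding would disagree with the published cohort sizes this model is checked
against (e.g. 16,540,452 × 0.0064 = 105,858.89 must give 105,858, not
105,859).  All products are computed with exact rational arithmetic before the
floor, so a product that lands exactly on an integer is never nudged across
the boundary by binary floating point.
"""

from __future__ import annotations

from decimal import Decimal
from fractions import Fraction
from typing import Union

from pydantic import BaseModel, ConfigDict, Field

from .country_profile import (
    CostComponent,
    CountryProfile,
    Eligibility,
    EpidemiologicalParams,
)

__all__ = [
    "CascadeResult",
    "cohort_cases",
    "potential_cases",
    "run_cascade",
    "sub_cohort",
    "treated_cases",
    "untreated_deaths",
]

Rate = Union[Decimal, Fraction, int, str]


def _to_fraction(rate: Rate) -> Fraction:
    if isinstance(rate, Fraction):
        return rate
    if isinstance(rate, Decimal):
        return Fraction(rate)
    if isinstance(rate, int):
        return Fraction(rate)
    if isinstance(rate, str):
        return Fraction(Decimal(rate))
    if isinstance(rate, float):
        # floats are accepted through their shortest decimal literal so that
        # 0.0064 means 64/10000 exactly
        return Fraction(Decimal(repr(rate)))
    raise TypeError(f"cannot interpret {type(rate).__name__} as a rate")


def _floor_scale(count: int, rate: Rate) -> int:
    """floor(count × rate) in exact rational arithmetic."""
    if count < 0:
        raise ValueError(f"negative population: {count}")
    x = count * _to_fraction(rate)
    if x < 0:
        raise ValueError(f"negative rate applied to population {count}")
    return x.numerator // x.denominator


def potential_cases(population_at_risk: int, incidence_rate: Rate) -> int:
    """Annual potential cases: floor(population at risk × incidence rate)."""
    return _floor_scale(population_at_risk, incidence_rate)


def treated_cases(potential: int, care_fraction: Rate) -> int:
    """Cases receiving (or needing) care: floor(potential × care fraction)."""
    return _floor_scale(potential, care_fraction)


def untreated_deaths(potential: int, mortality: Rate) -> int:
    """Premature deaths among untreated cases: floor(potential × mortality)."""
    return _floor_scale(potential, mortality)


def cohort_cases(subpopulation: int, incidence_rate: Rate) -> int:
    """Potential cases within a demographic subgroup (working-age or
    marriageable-female population): floor(subpopulation × incidence)."""
    return _floor_scale(subpopulation, incidence_rate)


def sub_cohort(base: int, eligibility: Eligibility) -> int:
    """Resolve an eligibility rule against its base cohort.

    ``absolute_count`` pins a head count (validated against the base);
    ``fraction_of_treated`` floors a fraction of the base; ``all_treated``
    passes the base through.
    """
    if base < 0:
        raise ValueError(f"negative base cohort: {base}")
    if eligibility.kind == "all_treated":
        return base
    if eligibility.kind == "fraction_of_treated":
        return _floor_scale(base, eligibility.fraction)
    assert eligibility.kind == "absolute_count"
    if eligibility.count > base:
        raise ValueError(
            f"absolute_count {eligibility.count} exceeds its base cohort {base}"
        )
    return eligibility.count


class CascadeResult(BaseModel):
    """All derived cohort counts for one country-year."""

    model_config = ConfigDict(frozen=True)

    population_at_risk: int = Field(ge=0)
    potential_cases: int = Field(ge=0)
    treated_cases: int = Field(ge=0)
    untreated_deaths: int = Field(ge=0)
    working_age_cases: int = Field(ge=0)
    female_marriageable_cases: int = Field(ge=0)
    sub_cohorts: dict[str, int] = Field(default_factory=dict)

    def base_count(self, base: str) -> int:
        return {
            "treated": self.treated_cases,
            "potential": self.potential_cases,
            "untreated_deaths": self.untreated_deaths,
            "working_age": self.working_age_cases,
            "marriageable_female": self.female_marriageable_cases,
        }[base]


def run_cascade(
    profile: CountryProfile,
    params: EpidemiologicalParams,
    schedule: tuple[CostComponent, ...] = (),
) -> CascadeResult:
    """Compose the cascade for a profile and resolve every schedule cohort."""
    potential = potential_cases(profile.population_at_risk, params.incidence_rate)
    treated = treated_cases(potential, params.care_fraction)
    deaths = untreated_deaths(potential, params.untreated_mortality)
    working = cohort_cases(profile.population_working_age, params.incidence_rate)
    marriageable = cohort_cases(
        profile.female_population_marriageable, params.incidence_rate
    )
    partial = CascadeResult(
        population_at_risk=profile.population_at_risk,
        potential_cases=potential,
        treated_cases=treated,
        untreated_deaths=deaths,
        working_age_cases=working,
        female_marriageable_cases=marriageable,
    )
    cohorts: dict[str, int] = {}
    for component in schedule:
        if component.category == "intangible":
            continue
        base = partial.base_count(component.count_base)
        cohorts[component.id] = sub_cohort(base, component.eligibility)
    return partial.model_copy(update={"sub_cohorts": cohorts})
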
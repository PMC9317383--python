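"""Synthetic country profiles with known ground truth.

The generator emulates the statistical shape of the inputs the model
consumes — a national population with nested at-risk (0–29), working-age
(15–29) and marriageable-female subpopulations carved out as shares, a mean
annual income and life expectancy in Sahelian ranges, and a unit-cost
schedule of integer dollar amounts — so every pipeline stage can be exercised
end to end and its output verified against an independently computed
closed-form expectation.

Defaults mirror the magnitudes of the two study countries: a population of
about twenty million with roughly 74% aged 0–29, an incidence of 6.4 per
1000 person-years, 10% care-seeking and 90% untreated mortality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from fractions import Fraction


import numpy as np

from .cascade import run_cascade
from .costs import report_from_config
from .country_profile import (
    CostComponent,
    CountryConfig,
    CountryProfile,
    Eligibility,
    EpidemiologicalParams,
    SCHEMA_VERSION,
)

__all__ = ["SyntheticSpec", "SyntheticInstance", "generate_profile", "recovery_check"]


def _dec(x) -> Decimal:
    return x if isinstance(x, Decimal) else Decimal(repr(x) if isinstance(x, float) else str(x))


def _floor_share(total: int, share: Decimal) -> int:
    f = total * Fraction(share)
    return f.numerator // f.denominator


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth parameters for one synthetic country-year.

    Shares are deterministic (the nested populations are exact floors of the
    shares); incomes, life expectancy and unit costs are drawn from the given
    ranges by the seeded generator.
    """

    seed: int = 0
    total_population: int = 20_000_000
    at_risk_share: Decimal = Decimal("0.74")
    working_age_share_of_risk: Decimal = Decimal("0.27")
    female_share_of_working_age: Decimal = Decimal("0.50")
    income_range: tuple[int, int] = (400, 900)
    life_expectancy_range: tuple[Decimal, Decimal] = (Decimal("55"), Decimal("65"))
    n_direct_components: int = 4
    unit_cost_range: tuple[int, int] = (50, 1200)
    incidence_rate: Decimal = Decimal("0.0064")
    care_fraction: Decimal = Decimal("0.10")
    untreated_mortality: Decimal = Decimal("0.90")
    mean_age_at_death: Decimal = Decimal("6")
    dowry_cost: int = 1000

    def __post_init__(self) -> None:
        for name in ("at_risk_share", "working_age_share_of_risk",
                     "female_share_of_working_age"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.total_population < 0:
            raise ValueError("total_population must be non-negative")
        if self.n_direct_components < 1:
            raise ValueError("need at least one direct component")


@dataclass(frozen=True)
class SyntheticInstance:
    """A generated scenario plus the ground truth that produced it."""

    config: CountryConfig
    spec: SyntheticSpec
    truth: dict = field(default_factory=dict)

    @property
    def profile(self) -> CountryProfile:
        return self.config.profile

    @property
    def params(self) -> EpidemiologicalParams:
        return self.config.params

    @property
    def schedule(self) -> tuple[CostComponent, ...]:
        return self.config.schedule


def generate_profile(spec: SyntheticSpec) -> SyntheticInstance:
    """Generate a validated synthetic country-year; deterministic in the seed."""
    rng = np.random.default_rng(spec.seed)
    at_risk = _floor_share(spec.total_population, spec.at_risk_share)
    working = _floor_share(at_risk, spec.working_age_share_of_risk)
    female = _floor_share(working, spec.female_share_of_working_age)
    income = int(rng.integers(spec.income_range[0], spec.income_range[1] + 1))
    le_lo, le_hi = spec.life_expectancy_range
    life_expectancy = (
        _dec(le_lo)
        + Decimal(int(rng.integers(0, int((_dec(le_hi) - _dec(le_lo)) * 10) + 1))) / 10
    )
    profile = CountryProfile(
        name=f"Synthetica-{spec.seed}",
        year=2018,
        total_population=spec.total_population,
        population_at_risk=at_risk,
        population_working_age=working,
        female_population_marriageable=female,
        life_expectancy_at_birth=life_expectancy,
        mean_annual_income=income,
        currency_label="USD synthetic",
    )
    params = EpidemiologicalParams(
        incidence_rate=spec.incidence_rate,
        care_fraction=spec.care_fraction,
        untreated_mortality=spec.untreated_mortality,
        mean_age_at_death=spec.mean_age_at_death,
    )
    schedule: list[CostComponent] = []
    unit_costs: dict[str, int] = {}
    fractions: dict[str, Decimal] = {}
    for i in range(spec.n_direct_components):
        cid = f"direct_{i}"
        unit = int(rng.integers(spec.unit_cost_range[0], spec.unit_cost_range[1] + 1))
        unit_costs[cid] = unit
        if i == 0:
            eligibility = Eligibility(kind="all_treated")
        else:
            frac = Decimal(int(rng.integers(1, 100))) / 100
            fractions[cid] = frac
            eligibility = Eligibility(kind="fraction_of_treated", fraction=frac)
        schedule.append(
            CostComponent(
                id=cid,
                label=f"Synthetic direct component {i}",
                category="direct",
                unit_cost_usd=unit,
                count_base="treated",
                eligibility=eligibility,
            )
        )
    schedule += [
        CostComponent(
            id="lost_production",
            label="Costs of loss of production",
            category="indirect",
            unit_cost_rule="mean_annual_income",
            count_base="working_age",
        ),
        CostComponent(
            id="premature_death",
            label="Costs related to premature death",
            category="indirect",
            unit_cost_rule="income_times_yll",
            count_base="untreated_deaths",
        ),
        CostComponent(
            id="inability_to_marry",
            label="Costs of inability to marry",
            category="indirect",
            unit_cost_usd=spec.dowry_cost,
            count_base="marriageable_female",
        ),
        CostComponent(id="intangible", label="Intangible costs", category="intangible"),
    ]
    config = CountryConfig(
        schema_version=SCHEMA_VERSION,
        profile=profile,
        params=params,
        schedule=tuple(schedule),
    )
    truth = {
        "at_risk": at_risk,
        "working_age": working,
        "female_marriageable": female,
        "income": income,
        "life_expectancy": life_expectancy,
        "unit_costs": unit_costs,
        "fractions": fractions,
    }
    return SyntheticInstance(config=config, spec=spec, truth=truth)


def _oracle_floor(count: int, rate: Decimal) -> int:
    """Independent flooring: pure integer arithmetic on the rate's decimal digits."""
    sign, digits, exponent = rate.as_tuple()
    numerator = int("".join(map(str, digits)) or "0")
    if exponent >= 0:
        return count * numerator * 10**exponent
    return (count * numerator) // 10**(-exponent)


def recovery_check(instance: SyntheticInstance) -> dict[str, bool]:
    """Run the full model and verify every output against closed-form truth.

    The expectations are recomputed here with plain integer arithmetic
    (digit-shift flooring, integer products), independently of the cascade
    and cost modules, so a pass means the pipeline agrees exactly with the
    generating parameters.
    """
    config = instance.config
    spec = instance.spec
    cascade = run_cascade(config.profile, config.params, config.schedule)
    report = report_from_config(config)

    expected_potential = _oracle_floor(config.profile.population_at_risk, spec.incidence_rate)
    expected_treated = _oracle_floor(expected_potential, spec.care_fraction)
    expected_deaths = _oracle_floor(expected_potential, spec.untreated_mortality)
    expected_working = _oracle_floor(config.profile.population_working_age, spec.incidence_rate)
    expected_female = _oracle_floor(
        config.profile.female_population_marriageable, spec.incidence_rate
    )

    checks: dict[str, bool] = {
        "potential_cases": cascade.potential_cases == expected_potential,
        "treated_cases": cascade.treated_cases == expected_treated,
        "untreated_deaths": cascade.untreated_deaths == expected_deaths,
        "working_age_cases": cascade.working_age_cases == expected_working,
        "female_marriageable_cases": cascade.female_marriageable_cases == expected_female,
    }

    income = instance.truth["income"]
    yll_tenths = int((instance.truth["life_expectancy"] - spec.mean_age_at_death) * 10)
    for cid, unit in instance.truth["unit_costs"].items():
        if cid in instance.truth["fractions"]:
            expected_count = _oracle_floor(expected_treated, instance.truth["fractions"][cid])
        else:
            expected_count = expected_treated
        checks[f"count:{cid}"] = cascade.sub_cohorts[cid] == expected_count
        checks[f"line:{cid}"] = report.direct.line(cid).total_usd == expected_count * unit
    checks["lost_production"] = (
        report.indirect["lost_production"].total_usd == expected_working * income
    )
    checks["premature_death"] = (
        report.indirect["premature_death"].total_usd * 10
        == expected_deaths * income * yll_tenths
    )
    checks["inability_to_marry"] = (
        report.indirect["inability_to_marry"].total_usd
        == expected_female * spec.dowry_cost
    )
    expected_direct_total = sum(
        (_oracle_floor(expected_treated, instance.truth["fractions"][cid])
         if cid in instance.truth["fractions"] else expected_treated) * unit
        for cid, unit in instance.truth["unit_costs"].items()
    )
    checks["direct_total"] = report.direct.direct_total_usd == expected_direct_total
    return checks
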
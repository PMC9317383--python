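"""Direct-cost ledger and human-capital indirect costs.

Direct costs are per-person unit costs multiplied by cohort head counts.
Indirect costs follow the human capital approach: lost production values one
year of mean income per working-age case; premature death values the full
remaining life expectancy (years of life lost, YLL = life expectancy at birth
− mean age at death) at mean annual income per untreated death; the inability
of female survivors to marry is valued at the customary dowry per case.
Intangible costs (pain, stigma, discrimination) are carried as an explicit
"not computed" sentinel — they are acknowledged, never silently zero.

All money arithmetic is exact decimal arithmetic; ledger totals are exact
sums of exact products.  An optional discounting extension converts the
undiscounted human-capital value into a present value; the default discount
rate is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, localcontext
from fractions import Fraction
from typing import Literal, Optional, Union

from .cascade import CascadeResult, run_cascade
from .country_profile import (
    CostComponent,
    CountryConfig,
    CountryProfile,
    EpidemiologicalParams,
)

__all__ = [
    "NOT_COMPUTED",
    "NotComputed",
    "CostLine",
    "CostLedger",
    "CountryCostReport",
    "OverrideDelta",
    "YearsOfLifeLost",
    "build_report",
    "cost_line",
    "direct_ledger",
    "discounted_human_capital",
    "lost_production_cost",
    "marriage_cost",
    "premature_death_cost",
    "report_from_config",
    "years_of_life_lost",
]

Money = Decimal
Number = Union[int, Decimal]


def _dec(value: Union[int, str, Decimal, float]) -> Decimal:
    if isinstance(value, Decimal):
        return value
    if isinstance(value, float):
        return Decimal(repr(value))
    return Decimal(value)


class NotComputed:
    """Sentinel for cost categories acknowledged but never monetised."""

    _instance: Optional["NotComputed"] = None

    def __new__(cls) -> "NotComputed":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "NOT_COMPUTED"

    def __str__(self) -> str:
        return "NN"


NOT_COMPUTED = NotComputed()


def years_of_life_lost(
    life_expectancy: Number, mean_age_at_death: Number
) -> Decimal:
    """YLL per death: life expectancy at birth minus mean age at death."""
    yll = _dec(life_expectancy) - _dec(mean_age_at_death)
    if yll < 0:
        raise ValueError(
            f"mean age at death ({mean_age_at_death}) exceeds life expectancy "
            f"({life_expectancy})"
        )
    return yll


@dataclass(frozen=True)
class YearsOfLifeLost:
    life_expectancy: Decimal
    mean_age_at_death: Decimal
    yll: Decimal

    @classmethod
    def compute(cls, life_expectancy: Number, mean_age_at_death: Number) -> "YearsOfLifeLost":
        le, ad = _dec(life_expectancy), _dec(mean_age_at_death)
        return cls(le, ad, years_of_life_lost(le, ad))


@dataclass(frozen=True)
class CostLine:
    """One ledger row: a cohort count, a unit cost and their exact product.

    ``value_source`` is ``"computed"`` when the total is count × unit cost and
    ``"printed_override"`` when a published figure was pinned in its place.
    ``unit_display`` carries the human-readable unit (e.g. ``"750 × 55.2"``
    for an income × YLL human-capital line).
    """

    component_id: str
    label: str
    count: int
    unit_cost_usd: Optional[Decimal]
    total_usd: Decimal
    value_source: Literal["computed", "printed_override"] = "computed"
    unit_display: str = ""

    def __post_init__(self) -> None:
        if self.total_usd < 0:
            raise ValueError(f"negative cost line {self.component_id}")
        if (
            self.value_source == "computed"
            and self.unit_cost_usd is not None
            and self.total_usd != self.count * self.unit_cost_usd
        ):
            raise ValueError(
                f"line {self.component_id}: total {self.total_usd} is not "
                f"{self.count} × {self.unit_cost_usd}"
            )

    @property
    def computed_total(self) -> Optional[Decimal]:
        """count × unit cost, regardless of any override."""
        if self.unit_cost_usd is None:
            return None
        return self.count * self.unit_cost_usd


def cost_line(
    component_id: str,
    count: int,
    unit_cost: Number,
    label: str = "",
) -> CostLine:
    """Build a computed ledger row: total = count × unit cost, exactly."""
    if count < 0:
        raise ValueError("negative cohort count")
    unit = _dec(unit_cost)
    if unit < 0:
        raise ValueError("negative unit cost")
    return CostLine(
        component_id=component_id,
        label=label or component_id,
        count=count,
        unit_cost_usd=unit,
        total_usd=count * unit,
        unit_display=_fmt_unit(unit),
    )


def _fmt_unit(unit: Decimal) -> str:
    return str(int(unit)) if unit == unit.to_integral_value() else str(unit)


@dataclass(frozen=True)
class CostLedger:
    """The direct-cost section of a country report."""

    country: str
    year: int
    lines: tuple[CostLine, ...]
    direct_total_usd: Decimal
    intangible: NotComputed = NOT_COMPUTED

    def line(self, component_id: str) -> CostLine:
        for ln in self.lines:
            if ln.component_id == component_id:
                return ln
        raise KeyError(component_id)


def direct_ledger(
    cascade: CascadeResult,
    schedule: tuple[CostComponent, ...],
    overrides: Optional[dict[str, Decimal]] = None,
    country: str = "",
    year: int = 0,
) -> CostLedger:
    """Assemble the direct-cost ledger from resolved cohorts and unit costs.

    ``overrides`` pins a published total in place of count × unit cost for a
    component (the row is marked ``printed_override`` and the discrepancy is
    surfaced by validation, never silently absorbed).  The direct total is the
    exact sum of the line totals as they stand in the ledger.
    """
    overrides = dict(overrides or {})
    unknown = set(overrides) - {c.id for c in schedule}
    if unknown:
        raise KeyError(f"overrides for unknown components: {sorted(unknown)}")
    lines: list[CostLine] = []
    for component in schedule:
        if component.category != "direct":
            continue
        if component.id not in cascade.sub_cohorts:
            raise KeyError(
                f"cascade has no resolved cohort for component {component.id!r}"
            )
        count = cascade.sub_cohorts[component.id]
        line = cost_line(component.id, count, component.unit_cost_usd, component.label)
        if component.id in overrides:
            line = CostLine(
                component_id=line.component_id,
                label=line.label,
                count=line.count,
                unit_cost_usd=line.unit_cost_usd,
                total_usd=_dec(overrides[component.id]),
                value_source="printed_override",
                unit_display=line.unit_display,
            )
        lines.append(line)
    total = sum((ln.total_usd for ln in lines), Decimal(0))
    return CostLedger(
        country=country, year=year, lines=tuple(lines), direct_total_usd=total
    )


def lost_production_cost(working_age_cases: int, mean_annual_income: Number) -> Decimal:
    """Morbidity cost: one year of mean income per working-age potential case."""
    if working_age_cases < 0:
        raise ValueError("negative cohort count")
    return working_age_cases * _dec(mean_annual_income)


def premature_death_cost(
    deaths: int, mean_annual_income: Number, yll: Number
) -> Decimal:
    """Mortality cost under the human capital approach, undiscounted.

    deaths × mean annual income × years of life lost, in exact decimal
    arithmetic so published dollar totals are matched to the dollar.
    """
    if deaths < 0:
        raise ValueError("negative death count")
    return deaths * _dec(mean_annual_income) * _dec(yll)


def marriage_cost(female_marriageable_cases: int, dowry_cost: Number) -> Decimal:
    """Foregone dowry and related marriage transfers per female case."""
    if female_marriageable_cases < 0:
        raise ValueError("negative cohort count")
    return female_marriageable_cases * _dec(dowry_cost)


def discounted_human_capital(
    deaths: int,
    income: Number,
    yll: Number,
    discount_rate: Number,
    start_offset: int = 1,
) -> Decimal:
    """Present value of the human-capital mortality cost.

    Each of the ``yll`` lost years contributes one year of income discounted
    at ``discount_rate``, starting ``start_offset`` years out; a fractional
    final year contributes its fractional share.  At a zero rate this equals
    :func:`premature_death_cost` exactly.  Non-terminating present values are
    rounded half-even to the cent.
    """
    r = Fraction(_dec(discount_rate))
    if not 0 <= r < 1:
        raise ValueError(f"discount rate {discount_rate} outside [0, 1)")
    y = Fraction(_dec(yll))
    if y < 0:
        raise ValueError("negative years of life lost")
    if deaths < 0:
        raise ValueError("negative death count")
    full_years = y.numerator // y.denominator
    fractional = y - full_years
    v = 1 / (1 + r)
    annuity = Fraction(0)
    for k in range(full_years):
        annuity += v ** (start_offset + k)
    if fractional:
        annuity += fractional * v ** (start_offset + full_years)
    total = Fraction(deaths) * Fraction(_dec(income)) * annuity
    with localcontext() as ctx:
        ctx.prec = 40
        value = Decimal(total.numerator) / Decimal(total.denominator)
    return value.quantize(Decimal("0.01")) if r else value


@dataclass(frozen=True)
class OverrideDelta:
    """A component whose ledger value was pinned to a published figure."""

    component_id: str
    computed_usd: Decimal
    override_usd: Decimal

    @property
    def delta_usd(self) -> Decimal:
        return self.override_usd - self.computed_usd


@dataclass(frozen=True)
class CountryCostReport:
    """The assembled model output for one country-year."""

    profile: CountryProfile
    params: EpidemiologicalParams
    cascade: CascadeResult
    yll: YearsOfLifeLost
    direct: CostLedger
    indirect: dict[str, CostLine] = field(default_factory=dict)
    intangible: NotComputed = NOT_COMPUTED
    override_deltas: tuple[OverrideDelta, ...] = ()
    discount_rate: Decimal = Decimal(0)

    @property
    def indirect_total_usd(self) -> Decimal:
        return sum((ln.total_usd for ln in self.indirect.values()), Decimal(0))

    @property
    def grand_total_usd(self) -> Decimal:
        return self.direct.direct_total_usd + self.indirect_total_usd

    def line(self, component_id: str) -> CostLine:
        if component_id in self.indirect:
            return self.indirect[component_id]
        return self.direct.line(component_id)


def _indirect_line(
    component: CostComponent,
    count: int,
    profile: CountryProfile,
    yll: YearsOfLifeLost,
    discount_rate: Decimal,
) -> CostLine:
    income = profile.mean_annual_income
    if component.unit_cost_rule == "mean_annual_income":
        total = lost_production_cost(count, income)
        unit: Optional[Decimal] = income
        unit_display = _fmt_unit(income)
    elif component.unit_cost_rule == "income_times_yll":
        if discount_rate:
            total = discounted_human_capital(count, income, yll.yll, discount_rate)
        else:
            total = premature_death_cost(count, income, yll.yll)
        unit = None
        unit_display = f"{_fmt_unit(income)} × {yll.yll}"
    else:
        total = marriage_cost(count, component.unit_cost_usd)
        unit = component.unit_cost_usd
        unit_display = _fmt_unit(component.unit_cost_usd)
    return CostLine(
        component_id=component.id,
        label=component.label,
        count=count,
        unit_cost_usd=unit,
        total_usd=total,
        unit_display=unit_display,
    )


def build_report(
    profile: CountryProfile,
    params: EpidemiologicalParams,
    schedule: tuple[CostComponent, ...],
    overrides: Optional[dict[str, Decimal]] = None,
    discount_rate: Number = 0,
) -> CountryCostReport:
    """Run the cascade and every cost operation for one country-year."""
    overrides = dict(overrides or {})
    cascade = run_cascade(profile, params, schedule)
    yll = YearsOfLifeLost.compute(
        profile.life_expectancy_at_birth, params.mean_age_at_death
    )
    ledger = direct_ledger(
        cascade,
        schedule,
        overrides={k: v for k, v in overrides.items() if _is_direct(schedule, k)},
        country=profile.name,
        year=profile.year,
    )
    rate = _dec(discount_rate)
    indirect: dict[str, CostLine] = {}
    for component in schedule:
        if component.category != "indirect":
            continue
        count = cascade.sub_cohorts[component.id]
        line = _indirect_line(component, count, profile, yll, rate)
        if component.id in overrides:
            line = CostLine(
                component_id=line.component_id,
                label=line.label,
                count=line.count,
                unit_cost_usd=line.unit_cost_usd,
                total_usd=_dec(overrides[component.id]),
                value_source="printed_override",
                unit_display=line.unit_display,
            )
        indirect[component.id] = line
    deltas = []
    for cid, value in overrides.items():
        try:
            ln = indirect[cid] if cid in indirect else ledger.line(cid)
        except KeyError:
            raise KeyError(f"override for unknown component {cid!r}") from None
        computed = ln.computed_total
        if computed is not None:
            deltas.append(
                OverrideDelta(
                    component_id=cid, computed_usd=computed, override_usd=_dec(value)
                )
            )
    return CountryCostReport(
        profile=profile,
        params=params,
        cascade=cascade,
        yll=yll,
        direct=ledger,
        indirect=indirect,
        intangible=NOT_COMPUTED,
        override_deltas=tuple(deltas),
        discount_rate=rate,
    )


def _is_direct(schedule: tuple[CostComponent, ...], component_id: str) -> bool:
    return any(c.id == component_id and c.category == "direct" for c in schedule)


def report_from_config(config: CountryConfig, discount_rate: Number = 0) -> CountryCostReport:
    """Convenience: :func:`build_report` straight from a loaded config."""
    return build_report(
        config.profile,
        config.params,
        config.schedule,
        overrides=config.overrides,
        discount_rate=discount_rate,
    )
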
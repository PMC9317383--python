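"""Country parameter profiles: demography, economy, epidemiology and unit costs.

Everything the cost model consumes is exogenous — population totals and
age-banded counts, life expectancy, mean annual income, epidemiological rates
and a unit-cost schedule — and arrives through one structured configuration
file per country-year.  This module defines the validated in-memory types and
the loaders.

Monetary amounts and rates are carried as :class:`decimal.Decimal` (never
binary floats): every downstream total is an exact product or sum, and the
model's outputs are bit-exact integer dollar figures.
"""

from __future__ import annotations

import json
from decimal import Decimal, InvalidOperation
from pathlib import Path
from typing import Any, Literal, Optional, Sequence, Union

import yaml
from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    ValidationError,
    field_validator,
    model_validator,
)

SCHEMA_VERSION = "1.0"

__all__ = [
    "SCHEMA_VERSION",
    "ConfigError",
    "AlignmentError",
    "AgeBand",
    "AgeBandedPopulation",
    "CountryProfile",
    "EpidemiologicalParams",
    "Eligibility",
    "CostComponent",
    "CountryConfig",
    "bundled_config_path",
    "config_from_raw",
    "config_to_raw",
    "derive_population_at_risk",
    "load_config",
    "load_profile",
]


class ConfigError(ValueError):
    """A configuration file is missing, malformed, or fails validation."""


class AlignmentError(ValueError):
    """An age range cuts through an age band; no interpolation is attempted."""


def _as_decimal(value: Any) -> Decimal:
    """Coerce numbers to Decimal through their shortest decimal literal.

    Floats go through ``repr`` so a YAML ``0.0064`` becomes exactly
    ``Decimal('0.0064')`` rather than the nearest binary float.
    """
    if isinstance(value, Decimal):
        return value
    if isinstance(value, bool):
        raise TypeError("boolean is not a number")
    if isinstance(value, float):
        return Decimal(repr(value))
    if isinstance(value, (int, str)):
        try:
            return Decimal(value)
        except InvalidOperation as exc:
            raise ValueError(f"not a decimal number: {value!r}") from exc
    raise TypeError(f"cannot convert {type(value).__name__} to Decimal")


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    @field_validator("*", mode="before")
    @classmethod
    def _coerce_decimals(cls, v: Any, info) -> Any:
        field = cls.model_fields.get(info.field_name)
        if field is not None and field.annotation in (Decimal, Optional[Decimal]):
            if v is None:
                return v
            return _as_decimal(v)
        return v


class AgeBand(_Model):
    """One band of an age pyramid; both endpoints are inclusive years."""

    start_age: int = Field(ge=0)
    end_age: int = Field(ge=0)
    count: int = Field(ge=0)

    @model_validator(mode="after")
    def _ordered(self) -> "AgeBand":
        if self.end_age < self.start_age:
            raise ValueError(f"band [{self.start_age}, {self.end_age}] is inverted")
        return self


class AgeBandedPopulation(_Model):
    """An ordered, non-overlapping age pyramid."""

    bands: tuple[AgeBand, ...]

    @model_validator(mode="after")
    def _sorted_disjoint(self) -> "AgeBandedPopulation":
        for prev, cur in zip(self.bands, self.bands[1:]):
            if cur.start_age <= prev.end_age:
                raise ValueError(
                    f"bands [{prev.start_age},{prev.end_age}] and "
                    f"[{cur.start_age},{cur.end_age}] overlap or are unsorted"
                )
        return self

    @property
    def total(self) -> int:
        return sum(b.count for b in self.bands)


def derive_population_at_risk(
    pyramid: AgeBandedPopulation, age_range: tuple[int, int]
) -> int:
    """Sum the band counts lying wholly inside the inclusive ``age_range``.

    Raises :class:`AlignmentError` if a band straddles a range boundary —
    ages are reported in bands and splitting one would require an age
    interpolation model the data does not support.
    """
    lo, hi = age_range
    if lo > hi:
        return 0
    total = 0
    for band in pyramid.bands:
        inside = lo <= band.start_age and band.end_age <= hi
        disjoint = band.end_age < lo or band.start_age > hi
        if inside:
            total += band.count
        elif not disjoint:
            raise AlignmentError(
                f"age range [{lo}, {hi}] cuts through band "
                f"[{band.start_age}, {band.end_age}]"
            )
    return total


class CountryProfile(_Model):
    """Demographic and economic indicators for one country-year."""

    name: str
    year: int
    total_population: int = Field(ge=0)
    population_at_risk: int = Field(ge=0)
    population_working_age: int = Field(ge=0)
    female_population_marriageable: int = Field(ge=0)
    life_expectancy_at_birth: Decimal = Field(gt=0)
    mean_annual_income: Decimal = Field(ge=0)
    currency_label: str = "USD"

    @model_validator(mode="after")
    def _nested_populations(self) -> "CountryProfile":
        if self.population_at_risk > self.total_population:
            raise ValueError(
                f"population_at_risk ({self.population_at_risk}) exceeds "
                f"total_population ({self.total_population})"
            )
        if self.population_working_age > self.population_at_risk:
            raise ValueError(
                f"population_working_age ({self.population_working_age}) exceeds "
                f"population_at_risk ({self.population_at_risk})"
            )
        if self.female_population_marriageable > self.population_at_risk:
            raise ValueError(
                f"female_population_marriageable "
                f"({self.female_population_marriageable}) exceeds "
                f"population_at_risk ({self.population_at_risk})"
            )
        return self


class EpidemiologicalParams(_Model):
    """Incidence, care-seeking, untreated mortality and the age conventions.

    All age ranges are inclusive of both endpoints (the at-risk population is
    ages 0–29, the working-age and marriageable cohorts 15–29).
    """

    incidence_rate: Decimal = Field(ge=0, le=1)
    care_fraction: Decimal = Field(ge=0, le=1)
    untreated_mortality: Decimal = Field(ge=0, le=1)
    mean_age_at_death: Decimal = Field(ge=0)
    at_risk_age_range: tuple[int, int] = (0, 29)
    working_age_range: tuple[int, int] = (15, 29)
    marriageable_age_range: tuple[int, int] = (15, 29)

    @model_validator(mode="after")
    def _death_age_in_risk_range(self) -> "EpidemiologicalParams":
        if self.mean_age_at_death >= self.at_risk_age_range[1]:
            raise ValueError(
                f"mean_age_at_death ({self.mean_age_at_death}) must be below "
                f"the upper at-risk age {self.at_risk_age_range[1]}"
            )
        return self


class Eligibility(_Model):
    """Which members of a component's base cohort incur its unit cost.

    ``all_treated`` charges the whole base cohort; ``fraction_of_treated``
    a floor-rounded fraction of it; ``absolute_count`` a fixed head count
    (used when the source prints cohort sizes without a generating rule).
    """

    kind: Literal["all_treated", "fraction_of_treated", "absolute_count"]
    fraction: Optional[Decimal] = None
    count: Optional[int] = Field(default=None, ge=0)

    @model_validator(mode="before")
    @classmethod
    def _normalise(cls, v: Any) -> Any:
        if isinstance(v, str):
            return {"kind": v}
        if isinstance(v, dict) and "kind" not in v:
            if "fraction_of_treated" in v:
                return {"kind": "fraction_of_treated", "fraction": v["fraction_of_treated"]}
            if "absolute_count" in v:
                return {"kind": "absolute_count", "count": v["absolute_count"]}
        return v

    @model_validator(mode="after")
    def _fields_match_kind(self) -> "Eligibility":
        if self.kind == "fraction_of_treated":
            if self.fraction is None or not (0 <= self.fraction <= 1):
                raise ValueError("fraction_of_treated requires a fraction in [0, 1]")
        elif self.kind == "absolute_count":
            if self.count is None:
                raise ValueError("absolute_count requires a count")
        return self


ALL_TREATED = Eligibility(kind="all_treated")

CountBase = Literal[
    "treated", "potential", "untreated_deaths", "working_age", "marriageable_female"
]
UnitCostRule = Literal["mean_annual_income", "income_times_yll"]


class CostComponent(_Model):
    """One row of the unit-cost schedule.

    A component either carries an explicit per-person ``unit_cost_usd`` or a
    ``unit_cost_rule`` resolved against the country profile at ledger time
    (``mean_annual_income`` for one year of lost production per case,
    ``income_times_yll`` for the human-capital value of one premature death).
    ``count_base`` names the cascade cohort the eligibility rule draws from.
    Intangible components carry no cost at all — they are tracked so reports
    can state explicitly that they were not monetised.
    """

    id: str
    label: str
    category: Literal["direct", "indirect", "intangible"]
    unit_cost_usd: Optional[Decimal] = Field(default=None, ge=0)
    unit_cost_rule: Optional[UnitCostRule] = None
    count_base: CountBase = "treated"
    eligibility: Eligibility = ALL_TREATED
    native_amount: Optional[Decimal] = None
    native_currency: Optional[str] = None
    conversion_note: Optional[str] = None

    @model_validator(mode="after")
    def _cost_source(self) -> "CostComponent":
        if self.category == "intangible":
            if self.unit_cost_usd is not None or self.unit_cost_rule is not None:
                raise ValueError("intangible components are never priced")
            return self
        if (self.unit_cost_usd is None) == (self.unit_cost_rule is None):
            raise ValueError(
                f"component {self.id!r}: exactly one of unit_cost_usd / "
                f"unit_cost_rule is required"
            )
        return self


class CountryConfig(_Model):
    """A fully validated country-year scenario: profile, epidemiology,
    unit-cost schedule and any printed-value overrides."""

    schema_version: str
    profile: CountryProfile
    params: EpidemiologicalParams
    schedule: tuple[CostComponent, ...]
    overrides: dict[str, Decimal] = Field(default_factory=dict)
    provenance: dict[str, str] = Field(default_factory=dict)

    @field_validator("overrides", mode="before")
    @classmethod
    def _decimal_overrides(cls, v: Any) -> Any:
        if isinstance(v, dict):
            return {k: _as_decimal(x) for k, x in v.items()}
        return v

    @model_validator(mode="after")
    def _override_ids_known(self) -> "CountryConfig":
        known = {c.id for c in self.schedule}
        unknown = set(self.overrides) - known
        if unknown:
            raise ValueError(f"overrides name unknown components: {sorted(unknown)}")
        return self

    def component(self, component_id: str) -> CostComponent:
        for c in self.schedule:
            if c.id == component_id:
                return c
        raise KeyError(component_id)


_DEMOGRAPHY_KEYS = {
    "name",
    "year",
    "total_population",
    "population_at_risk",
    "population_working_age",
    "female_population_marriageable",
    "life_expectancy_at_birth",
    "age_pyramid",
}
_ECONOMY_KEYS = {"mean_annual_income", "currency_label"}


def _require(section: dict, key: str, where: str) -> Any:
    if key not in section or section[key] is None:
        raise ConfigError(f"missing required field {where}.{key}")
    return section[key]


def _pyramid_from_raw(raw: Sequence[Sequence[int]]) -> AgeBandedPopulation:
    bands = [AgeBand(start_age=b[0], end_age=b[1], count=b[2]) for b in raw]
    return AgeBandedPopulation(bands=tuple(bands))


def config_from_raw(raw: dict, schema_version: str = SCHEMA_VERSION) -> CountryConfig:
    """Validate a parsed configuration mapping into a :class:`CountryConfig`.

    Direct aggregate populations take precedence; the 0–29 at-risk and 15–29
    working-age aggregates are derived from ``age_pyramid`` only when absent.
    Unknown keys anywhere are rejected.
    """
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    declared = raw.get("schema_version")
    if declared is None:
        raise ConfigError("missing required field schema_version")
    if str(declared) != schema_version:
        raise ConfigError(
            f"schema_version {declared!r} is not the supported {schema_version!r}"
        )
    allowed_top = {
        "schema_version", "demography", "economy", "epidemiology",
        "cost_schedule", "overrides", "provenance",
    }
    unknown = set(raw) - allowed_top
    if unknown:
        raise ConfigError(f"unknown top-level sections: {sorted(unknown)}")

    demo = dict(raw.get("demography") or {})
    econ = dict(raw.get("economy") or {})
    epi = dict(raw.get("epidemiology") or {})
    schedule_raw = raw.get("cost_schedule")
    if schedule_raw is None:
        raise ConfigError("missing required field cost_schedule")

    unknown = set(demo) - _DEMOGRAPHY_KEYS
    if unknown:
        raise ConfigError(f"unknown demography keys: {sorted(unknown)}")
    unknown = set(econ) - _ECONOMY_KEYS
    if unknown:
        raise ConfigError(f"unknown economy keys: {sorted(unknown)}")

    try:
        params = EpidemiologicalParams(**epi)
    except ValidationError as exc:
        raise ConfigError(f"epidemiology: {exc}") from exc

    pyramid = None
    if demo.get("age_pyramid") is not None:
        pyramid = _pyramid_from_raw(demo["age_pyramid"])

    def _population(key: str, age_range: tuple[int, int]) -> int:
        if demo.get(key) is not None:
            return demo[key]
        if pyramid is not None:
            return derive_population_at_risk(pyramid, age_range)
        raise ConfigError(f"missing required field demography.{key}")

    try:
        profile = CountryProfile(
            name=_require(demo, "name", "demography"),
            year=_require(demo, "year", "demography"),
            total_population=_require(demo, "total_population", "demography"),
            population_at_risk=_population("population_at_risk", params.at_risk_age_range),
            population_working_age=_population(
                "population_working_age", params.working_age_range
            ),
            female_population_marriageable=_require(
                demo, "female_population_marriageable", "demography"
            ),
            life_expectancy_at_birth=_require_life_expectancy(demo, econ),
            mean_annual_income=_require(econ, "mean_annual_income", "economy"),
            currency_label=econ.get("currency_label", "USD"),
        )
    except ValidationError as exc:
        raise ConfigError(f"demography/economy: {exc}") from exc

    try:
        schedule = tuple(CostComponent(**c) for c in schedule_raw)
    except ValidationError as exc:
        raise ConfigError(f"cost_schedule: {exc}") from exc

    try:
        return CountryConfig(
            schema_version=str(declared),
            profile=profile,
            params=params,
            schedule=schedule,
            overrides=raw.get("overrides") or {},
            provenance=raw.get("provenance") or {},
        )
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def _require_life_expectancy(demo: dict, econ: dict) -> Any:
    # life expectancy is demographic but tolerated under economy for
    # backwards-compatible configs
    for section, name in ((demo, "demography"), (econ, "economy")):
        if section.get("life_expectancy_at_birth") is not None:
            return section["life_expectancy_at_birth"]
    raise ConfigError("missing required field demography.life_expectancy_at_birth")


def _num(value: Decimal) -> Union[int, str]:
    """Render a Decimal for serialization: int when integral, else string."""
    if value == value.to_integral_value():
        return int(value)
    return str(value)


def config_to_raw(config: CountryConfig) -> dict:
    """Serialize a config back to its file structure (inverse of loading,
    up to key order and numeric spelling)."""
    p, e = config.profile, config.params
    raw: dict[str, Any] = {
        "schema_version": config.schema_version,
        "demography": {
            "name": p.name,
            "year": p.year,
            "total_population": p.total_population,
            "population_at_risk": p.population_at_risk,
            "population_working_age": p.population_working_age,
            "female_population_marriageable": p.female_population_marriageable,
            "life_expectancy_at_birth": _num(p.life_expectancy_at_birth),
        },
        "economy": {
            "mean_annual_income": _num(p.mean_annual_income),
            "currency_label": p.currency_label,
        },
        "epidemiology": {
            "incidence_rate": _num(e.incidence_rate),
            "care_fraction": _num(e.care_fraction),
            "untreated_mortality": _num(e.untreated_mortality),
            "mean_age_at_death": _num(e.mean_age_at_death),
            "at_risk_age_range": list(e.at_risk_age_range),
            "working_age_range": list(e.working_age_range),
            "marriageable_age_range": list(e.marriageable_age_range),
        },
        "cost_schedule": [],
    }
    for c in config.schedule:
        row: dict[str, Any] = {"id": c.id, "label": c.label, "category": c.category}
        if c.unit_cost_usd is not None:
            row["unit_cost_usd"] = _num(c.unit_cost_usd)
        if c.unit_cost_rule is not None:
            row["unit_cost_rule"] = c.unit_cost_rule
        if c.category != "intangible":
            row["count_base"] = c.count_base
            el = c.eligibility
            if el.kind == "all_treated":
                row["eligibility"] = "all_treated"
            elif el.kind == "fraction_of_treated":
                row["eligibility"] = {"fraction_of_treated": _num(el.fraction)}
            else:
                row["eligibility"] = {"absolute_count": el.count}
        for key in ("native_amount", "native_currency", "conversion_note"):
            val = getattr(c, key)
            if val is not None:
                row[key] = _num(val) if isinstance(val, Decimal) else val
        raw["cost_schedule"].append(row)
    if config.overrides:
        raw["overrides"] = {k: _num(v) for k, v in config.overrides.items()}
    if config.provenance:
        raw["provenance"] = dict(config.provenance)
    return raw


def load_config(
    path: Union[str, Path], schema_version: str = SCHEMA_VERSION
) -> CountryConfig:
    """Read and validate a YAML or JSON country-year configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    return config_from_raw(raw, schema_version=schema_version)


def load_profile(
    path: Union[str, Path], schema_version: str = SCHEMA_VERSION
) -> CountryProfile:
    """Load only the validated :class:`CountryProfile` from a config file."""
    return load_config(path, schema_version=schema_version).profile


def bundled_config_path(name: str) -> Path:
    """Path to a bundled country-year fixture (``burkina_2018``, ``niger_2018``)."""
    from importlib import resources

    base = resources.files("nomacost") / "data" / f"{name}.yaml"
    with resources.as_file(base) as p:
        return Path(p)
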
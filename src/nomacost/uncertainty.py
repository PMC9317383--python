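"""One-way and Monte-Carlo sensitivity analysis over model parameters.

Incidence and care-seeking are the parameters whose published evidence spans
the widest range (incidence estimates run from 8.3 per 100,000 to 7 per 1000
persons at risk; only 10–15% of survivors are thought to seek care), so the
shipped defaults perturb those two.  Any numeric scalar addressable by a
dotted path into the configuration — including unit costs — can be varied.

Each draw reruns the full deterministic model, floor-rounding and all, so
uncertainty propagates *through* the integer cascade rather than being
bolted on around it.  Sampling uses one explicitly seeded NumPy generator and
results are bit-reproducible for a given (config, seed, replicates).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from decimal import ROUND_UP, Decimal, localcontext
from typing import Literal, Optional, Sequence, Union

import numpy as np

from .cascade import run_cascade
from .costs import CountryCostReport, report_from_config
from .country_profile import ConfigError, CountryConfig, config_from_raw, config_to_raw

__all__ = [
    "DEFAULT_DISTRIBUTIONS",
    "MonteCarloSummary",
    "OneWaySwing",
    "ParameterDistribution",
    "SensitivityResult",
    "monte_carlo",
    "one_way",
    "select_output",
]

Number = Union[int, float, Decimal]


@dataclass(frozen=True)
class ParameterDistribution:
    """An uncertainty distribution for one configuration scalar.

    ``parameter_path`` is dotted into the config sections, e.g.
    ``epidemiology.incidence_rate`` or ``cost_schedule.treatment.unit_cost_usd``.
    ``point`` keeps the parameter fixed; ``uniform`` and ``triangular`` give
    the usual bounded densities in the parameter's native units.
    """

    parameter_path: str
    kind: Literal["point", "uniform", "triangular"]
    lo: Optional[Number] = None
    mode: Optional[Number] = None
    hi: Optional[Number] = None

    def __post_init__(self) -> None:
        if self.kind == "point":
            if self.mode is None:
                raise ValueError("point distribution requires a mode value")
        elif self.kind == "uniform":
            if self.lo is None or self.hi is None or not self.lo <= self.hi:
                raise ValueError("uniform distribution requires lo <= hi")
        else:
            ok = (
                self.lo is not None
                and self.mode is not None
                and self.hi is not None
                and self.lo <= self.mode <= self.hi
            )
            if not ok:
                raise ValueError("triangular distribution requires lo <= mode <= hi")

    @property
    def low(self) -> Number:
        return self.mode if self.kind == "point" else self.lo

    @property
    def high(self) -> Number:
        return self.mode if self.kind == "point" else self.hi

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "point":
            return float(self.mode)
        if self.kind == "uniform":
            return float(rng.uniform(float(self.lo), float(self.hi)))
        return float(
            rng.triangular(float(self.lo), float(self.mode), float(self.hi))
        )


#: Shipped defaults: the published incidence spread and care-seeking range.
DEFAULT_DISTRIBUTIONS: tuple[ParameterDistribution, ...] = (
    ParameterDistribution(
        "epidemiology.incidence_rate", "triangular", lo=8.3e-5, mode=6.4e-3, hi=7e-3
    ),
    ParameterDistribution(
        "epidemiology.care_fraction", "uniform", lo=0.10, hi=0.15
    ),
)


def _set_path(raw: dict, path: str, value: Number) -> None:
    parts = path.split(".")
    if parts[0] == "cost_schedule":
        if len(parts) != 3:
            raise ConfigError(
                f"cost_schedule paths are cost_schedule.<id>.<field>: {path!r}"
            )
        _, component_id, key = parts
        for row in raw.get("cost_schedule", []):
            if row.get("id") == component_id:
                if key not in row:
                    raise ConfigError(f"unresolvable parameter path: {path!r}")
                row[key] = value
                return
        raise ConfigError(f"unresolvable parameter path: {path!r}")
    node = raw
    for part in parts[:-1]:
        if not isinstance(node, dict) or part not in node:
            raise ConfigError(f"unresolvable parameter path: {path!r}")
        node = node[part]
    if not isinstance(node, dict) or parts[-1] not in node:
        raise ConfigError(f"unresolvable parameter path: {path!r}")
    node[parts[-1]] = value


def _scalable_raw(config: CountryConfig) -> dict:
    """Config dict in which pinned absolute cohorts scale with the scenario.

    Pinned head counts are source data tied to the baseline cohort sizes; a
    perturbed scenario (say, a lower incidence) shrinks the base cohort below
    the pin, which the deterministic model rightly rejects.  For sensitivity
    runs each pin is therefore re-expressed as its implied share of the
    baseline base cohort.  The share is rounded up at 30 significant digits so
    that at the baseline parameters the flooring reproduces the pinned count
    exactly.
    """
    cascade = run_cascade(config.profile, config.params, config.schedule)
    raw = copy.deepcopy(config_to_raw(config))
    for row in raw["cost_schedule"]:
        eligibility = row.get("eligibility")
        if isinstance(eligibility, dict) and "absolute_count" in eligibility:
            component = config.component(row["id"])
            base = cascade.base_count(component.count_base)
            pinned = eligibility["absolute_count"]
            if base == 0:
                share = Decimal(0) if pinned == 0 else Decimal(1)
            else:
                with localcontext() as ctx:
                    ctx.prec = 30
                    ctx.rounding = ROUND_UP
                    share = Decimal(pinned) / Decimal(base)
            row["eligibility"] = {"fraction_of_treated": str(min(share, Decimal(1)))}
    return raw


def _perturbed(config: CountryConfig, assignments: dict[str, Number]) -> CountryConfig:
    raw = _scalable_raw(config)
    for path, value in assignments.items():
        _set_path(raw, path, value)
    return config_from_raw(raw)


def select_output(report: CountryCostReport, target: str) -> Decimal:
    """Resolve an output selector against a report.

    Selectors: ``direct_total``, ``indirect_total``, ``grand_total``,
    ``cascade.<field>`` (e.g. ``cascade.potential_cases``) and
    ``line.<component_id>.total``.
    """
    if target == "direct_total":
        return report.direct.direct_total_usd
    if target == "indirect_total":
        return report.indirect_total_usd
    if target == "grand_total":
        return report.grand_total_usd
    if target.startswith("cascade."):
        return Decimal(getattr(report.cascade, target.split(".", 1)[1]))
    if target.startswith("line.") and target.endswith(".total"):
        component_id = target.split(".")[1]
        return report.line(component_id).total_usd
    raise ConfigError(f"unknown output selector: {target!r}")


@dataclass(frozen=True)
class OneWaySwing:
    parameter_path: str
    low_input: Number
    high_input: Number
    low_output: Decimal
    high_output: Decimal

    @property
    def swing(self) -> Decimal:
        return abs(self.high_output - self.low_output)


@dataclass(frozen=True)
class MonteCarloSummary:
    seed: int
    replicates: int
    samples: tuple[Decimal, ...]
    percentiles: dict[str, float]

    @property
    def minimum(self) -> Decimal:
        return min(self.samples)

    @property
    def maximum(self) -> Decimal:
        return max(self.samples)


@dataclass(frozen=True)
class SensitivityResult:
    target: str
    baseline: Decimal
    one_way: tuple[OneWaySwing, ...] = ()
    monte_carlo: Optional[MonteCarloSummary] = None


def one_way(
    baseline_config: CountryConfig,
    distributions: Sequence[ParameterDistribution],
    target: str,
    discount_rate: Number = 0,
) -> SensitivityResult:
    """Tornado analysis: each parameter swept to its bounds, others at baseline.

    Swings come back ranked widest first (ties broken by parameter path so
    the ordering is deterministic).
    """
    baseline = select_output(
        report_from_config(baseline_config, discount_rate), target
    )
    swings: list[OneWaySwing] = []
    for dist in distributions:
        low_rep = report_from_config(
            _perturbed(baseline_config, {dist.parameter_path: dist.low}),
            discount_rate,
        )
        high_rep = report_from_config(
            _perturbed(baseline_config, {dist.parameter_path: dist.high}),
            discount_rate,
        )
        swings.append(
            OneWaySwing(
                parameter_path=dist.parameter_path,
                low_input=dist.low,
                high_input=dist.high,
                low_output=select_output(low_rep, target),
                high_output=select_output(high_rep, target),
            )
        )
    swings.sort(key=lambda s: (-s.swing, s.parameter_path))
    return SensitivityResult(target=target, baseline=baseline, one_way=tuple(swings))


def monte_carlo(
    baseline_config: CountryConfig,
    distributions: Sequence[ParameterDistribution],
    target: str,
    replicates: int,
    seed: int,
    discount_rate: Number = 0,
) -> SensitivityResult:
    """Joint parameter uncertainty: independent draws, full model per draw."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    baseline = select_output(
        report_from_config(baseline_config, discount_rate), target
    )
    rng = np.random.default_rng(seed)
    samples: list[Decimal] = []
    for _ in range(replicates):
        assignments = {d.parameter_path: d.sample(rng) for d in distributions}
        report = report_from_config(
            _perturbed(baseline_config, assignments), discount_rate
        )
        samples.append(select_output(report, target))
    arr = np.array([float(s) for s in samples])
    percentiles = {
        "p2.5": float(np.percentile(arr, 2.5)),
        "p50": float(np.percentile(arr, 50)),
        "p97.5": float(np.percentile(arr, 97.5)),
    }
    mc = MonteCarloSummary(
        seed=seed,
        replicates=replicates,
        samples=tuple(samples),
        percentiles=percentiles,
    )
    return SensitivityResult(target=target, baseline=baseline, monte_carlo=mc)
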
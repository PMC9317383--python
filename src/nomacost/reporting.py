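"""Table rendering, CSV/JSON artifacts, and cell-by-cell validation
against the published country tables.

Machine outputs carry un-grouped numbers (``3562428600``); human-readable
summaries group thousands (``3,562,428,600``) with a fixed convention, never
the process locale.  Rendering is pure: the same report always yields
byte-identical artifacts.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass
from decimal import Decimal
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import yaml

from .costs import NOT_COMPUTED, CostLine, CountryCostReport


__all__ = [
    "ValidationDelta",
    "load_printed_values",
    "render_cascade_csv",
    "render_costs_csv",
    "render_report_json",
    "render_summary",
    "render_validation_csv",
    "validate_against_printed",
    "write_report_artifacts",
]

INTANGIBLE_MARK = "NN"


def _plain(value: Decimal) -> str:
    """Un-grouped machine rendering; integral decimals drop the point."""
    if value == value.to_integral_value():
        return str(int(value))
    return str(value)


def _grouped(value: Decimal) -> str:
    if value == value.to_integral_value():
        return f"{int(value):,}"
    return f"{value:,f}"


@dataclass(frozen=True)
class ValidationDelta:
    """One published cell compared against the model's computed value.

    ``delta`` is printed − computed.  ``match`` means the model reproduces
    the cell exactly; ``printed_override_used`` marks a cell whose published
    total contradicts its own count × unit cost and was pinned by an
    override; ``discrepancy`` marks a published cell the arithmetic cannot
    reproduce.
    """

    table: str
    row: str
    printed_value: Decimal
    computed_value: Decimal
    classification: Literal["match", "printed_override_used", "discrepancy"]

    @property
    def delta(self) -> Decimal:
        return self.printed_value - self.computed_value


def load_printed_values(name: str) -> dict:
    """Published table cells for a bundled scenario (``burkina_2018`` ...)."""
    from importlib import resources

    text = (resources.files("nomacost") / "data" / "printed_2018.yaml").read_text()
    data = yaml.safe_load(text)
    if name not in data:
        raise KeyError(f"no printed values for scenario {name!r}")
    return data[name]


def _classify(printed: Decimal, computed: Decimal, overridden: bool) -> str:
    if overridden and printed != computed:
        return "printed_override_used"
    return "match" if printed == computed else "discrepancy"


def validate_against_printed(
    report: CountryCostReport, printed: dict
) -> tuple[ValidationDelta, ...]:
    """Compare every published cell with the model's value.

    Cohort counts and line totals are compared against the computed
    count × unit cost; the direct total is compared against the ledger as
    built (overrides included), since the override is itself part of the
    published table's internal arithmetic.
    """
    deltas: list[ValidationDelta] = []
    cascade = report.cascade
    computed_cascade = {
        "total_population": report.profile.total_population,
        "population_at_risk": cascade.population_at_risk,
        "potential_cases": cascade.potential_cases,
        "treated_cases": cascade.treated_cases,
    }
    for row, printed_value in printed.get("cascade", {}).items():
        computed = Decimal(computed_cascade[row])
        deltas.append(
            ValidationDelta(
                table="cascade",
                row=row,
                printed_value=Decimal(str(printed_value)),
                computed_value=computed,
                classification=_classify(Decimal(str(printed_value)), computed, False),
            )
        )
    indicators = printed.get("indicators", {})
    if "years_of_life_lost" in indicators:
        printed_yll = Decimal(str(indicators["years_of_life_lost"]))
        deltas.append(
            ValidationDelta(
                table="indicators",
                row="years_of_life_lost",
                printed_value=printed_yll,
                computed_value=report.yll.yll,
                classification=_classify(printed_yll, report.yll.yll, False),
            )
        )
    overridden_ids = {d.component_id for d in report.override_deltas}
    for cid, cells in printed.get("lines", {}).items():
        line = report.line(cid)
        computed_total = line.computed_total
        if computed_total is None:  # rule-priced line: ledger value is the computation
            computed_total = line.total_usd
        printed_total = Decimal(str(cells["total"]))
        deltas.append(
            ValidationDelta(
                table="costs",
                row=f"{cid}.total",
                printed_value=printed_total,
                computed_value=computed_total,
                classification=_classify(
                    printed_total, computed_total, cid in overridden_ids
                ),
            )
        )
        if "count" in cells:
            printed_count = Decimal(str(cells["count"]))
            deltas.append(
                ValidationDelta(
                    table="costs",
                    row=f"{cid}.count",
                    printed_value=printed_count,
                    computed_value=Decimal(line.count),
                    classification=_classify(printed_count, Decimal(line.count), False),
                )
            )
    if "direct_total" in printed:
        printed_total = Decimal(str(printed["direct_total"]))
        computed = report.direct.direct_total_usd
        deltas.append(
            ValidationDelta(
                table="costs",
                row="direct_total",
                printed_value=printed_total,
                computed_value=computed,
                classification=_classify(printed_total, computed, False),
            )
        )
    return tuple(deltas)


def render_cascade_csv(report: CountryCostReport) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["indicator", report.profile.name])
    writer.writerow(["Total population", report.profile.total_population])
    writer.writerow(["Population at risk of noma", report.cascade.population_at_risk])
    writer.writerow(["Potential noma cases", report.cascade.potential_cases])
    writer.writerow(
        ["Potential noma cases receiving treatment", report.cascade.treated_cases]
    )
    return buf.getvalue()


def _cost_rows(report: CountryCostReport) -> list[tuple[str, str, str, str, str]]:
    rows = []
    for line in report.direct.lines:
        rows.append(
            (
                "direct",
                line.label,
                str(line.count),
                line.unit_display,
                _plain(line.total_usd),
            )
        )
    for line in report.indirect.values():
        rows.append(
            (
                "indirect",
                line.label,
                str(line.count),
                line.unit_display,
                _plain(line.total_usd),
            )
        )
    rows.append(("intangible", "Intangible costs", INTANGIBLE_MARK, INTANGIBLE_MARK, INTANGIBLE_MARK))
    return rows


def render_costs_csv(report: CountryCostReport) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(
        ["Category", "Cost Category", "Population", "Mean Cost per Person in USD", "Total Costs in USD"]
    )
    writer.writerow(
        ["direct", "Direct costs (total)", str(report.cascade.treated_cases), "", _plain(report.direct.direct_total_usd)]
    )
    for row in _cost_rows(report):
        writer.writerow(row)
    return buf.getvalue()


def _dedupe_names(reports: Sequence[CountryCostReport]) -> list[str]:
    names, seen = [], {}
    for report in reports:
        base = report.profile.name
        seen[base] = seen.get(base, 0) + 1
        names.append(base if seen[base] == 1 else f"{base} ({seen[base]})")
    return names


def render_summary(
    reports: Sequence[CountryCostReport], grouped: bool = False
) -> str:
    """Side-by-side country summary (CSV).  The intangible row is the
    explicit not-computed marker, never a number."""
    if not reports:
        raise ValueError("render_summary needs at least one report")
    fmt = _grouped if grouped else _plain
    names = _dedupe_names(reports)
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    header = ["Cost Categories"]
    for name in names:
        header += [f"{name} Population", f"{name} Costs in USD"]
    writer.writerow(header)

    def row(label: str, cells: list[tuple[Optional[int], Optional[Decimal]]]) -> None:
        out = [label]
        for count, total in cells:
            out.append("" if count is None else f"{count:,}" if grouped else str(count))
            out.append("" if total is None else fmt(total))
        writer.writerow(out)

    row(
        "1. Direct costs",
        [(r.cascade.treated_cases, r.direct.direct_total_usd) for r in reports],
    )
    for cid in [ln.component_id for ln in reports[0].direct.lines]:
        row(
            reports[0].direct.line(cid).label,
            [
                (r.direct.line(cid).count, r.direct.line(cid).total_usd)
                for r in reports
            ],
        )
    writer.writerow(["2. Indirect costs"] + ["", ""] * len(reports))
    for cid in reports[0].indirect:
        row(
            reports[0].indirect[cid].label,
            [(r.indirect[cid].count, r.indirect[cid].total_usd) for r in reports],
        )
    writer.writerow(
        ["3. Intangible costs"] + [INTANGIBLE_MARK, INTANGIBLE_MARK] * len(reports)
    )
    return buf.getvalue()


def render_validation_csv(deltas: Sequence[ValidationDelta]) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["table", "row", "printed", "computed", "delta", "classification"])
    for d in deltas:
        writer.writerow(
            [d.table, d.row, _plain(d.printed_value), _plain(d.computed_value),
             _plain(d.delta), d.classification]
        )
    return buf.getvalue()


def _line_dict(line: CostLine) -> dict:
    return {
        "component_id": line.component_id,
        "label": line.label,
        "count": line.count,
        "unit_cost_usd": None if line.unit_cost_usd is None else _plain(line.unit_cost_usd),
        "unit_display": line.unit_display,
        "total_usd": _plain(line.total_usd),
        "value_source": line.value_source,
    }


def render_report_json(report: CountryCostReport) -> str:
    payload = {
        "country": report.profile.name,
        "year": report.profile.year,
        "cascade": report.cascade.model_dump(),
        "years_of_life_lost": _plain(report.yll.yll),
        "discount_rate": _plain(report.discount_rate),
        "direct": {
            "total_usd": _plain(report.direct.direct_total_usd),
            "lines": [_line_dict(ln) for ln in report.direct.lines],
        },
        "indirect": {
            "total_usd": _plain(report.indirect_total_usd),
            "lines": [_line_dict(ln) for ln in report.indirect.values()],
        },
        "intangible": str(NOT_COMPUTED),
        "grand_total_usd": _plain(report.grand_total_usd),
        "override_deltas": [
            {
                "component_id": d.component_id,
                "computed_usd": _plain(d.computed_usd),
                "override_usd": _plain(d.override_usd),
                "delta_usd": _plain(d.delta_usd),
            }
            for d in report.override_deltas
        ],
    }
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def write_report_artifacts(
    report: CountryCostReport,
    out_dir: Union[str, Path],
    deltas: Optional[Sequence[ValidationDelta]] = None,
) -> list[Path]:
    """Write the per-country CSV/JSON artifacts; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    slug = report.profile.name.lower().replace(" ", "_")
    written = []
    for name, text in (
        (f"{slug}_table2_cascade.csv", render_cascade_csv(report)),
        (f"{slug}_table4_5_costs.csv", render_costs_csv(report)),
        (f"{slug}_report.json", render_report_json(report)),
    ):
        path = out / name
        path.write_text(text)
        written.append(path)
    if deltas is not None:
        path = out / f"{slug}_validation.csv"
        path.write_text(render_validation_csv(deltas))
        written.append(path)
    return written
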
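"""The direct-cost ledger and the human-capital indirect costs."""

from decimal import Decimal
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nomacost import (
    NOT_COMPUTED,
    cost_line,
    direct_ledger,
    discounted_human_capital,
    lost_production_cost,
    marriage_cost,
    premature_death_cost,
    run_cascade,
    years_of_life_lost,
)


class TestYearsOfLifeLost:
    @pytest.mark.parametrize(
        "life_expectancy, age, expected",
        [
            (Decimal("61.2"), 6, Decimal("55.2")),
            (Decimal("62.0"), 6, Decimal("56.0")),
            (70, 70, Decimal(0)),
        ],
    )
    def test_exact_difference(self, life_expectancy, age, expected):
        assert years_of_life_lost(life_expectancy, age) == expected

    def test_death_age_above_expectancy_rejected(self):
        with pytest.raises(ValueError):
            years_of_life_lost(Decimal(50), 60)


class TestCostLine:
    @pytest.mark.parametrize(
        "count, unit, expected",
        [
            (9_561, 345, 3_298_545),
            (5_737, 765, 4_388_805),
            (0, 85_000, 0),
        ],
    )
    def test_total_is_exact_product(self, count, unit, expected):
        line = cost_line("x", count, unit)
        assert line.total_usd == expected
        assert line.value_source == "computed"


class TestDirectLedger:
    def test_burkina_with_shipped_override(self, burkina_report):
        ledger = burkina_report.direct
        assert ledger.direct_total_usd == 28_179_901
        line = ledger.line("income_assistance")
        assert line.total_usd == 1_406_398
        assert line.value_source == "printed_override"
        assert line.computed_total == 1_405_565

    def test_burkina_without_override(self, burkina):
        cascade = run_cascade(burkina.profile, burkina.params, burkina.schedule)
        ledger = direct_ledger(cascade, burkina.schedule)
        assert ledger.line("income_assistance").total_usd == 1_405_565
        assert ledger.direct_total_usd == 28_179_068

    def test_empty_schedule_is_empty_ledger(self, burkina):
        cascade = run_cascade(burkina.profile, burkina.params, ())
        ledger = direct_ledger(cascade, ())
        assert ledger.lines == () and ledger.direct_total_usd == 0

    def test_override_for_unknown_component_rejected(self, burkina):
        cascade = run_cascade(burkina.profile, burkina.params, burkina.schedule)
        with pytest.raises(KeyError):
            direct_ledger(cascade, burkina.schedule, overrides={"nope": Decimal(1)})

    def test_total_invariant_under_line_permutation(self, burkina):
        cascade = run_cascade(burkina.profile, burkina.params, burkina.schedule)
        forward = direct_ledger(cascade, burkina.schedule)
        reversed_schedule = tuple(reversed(burkina.schedule))
        backward = direct_ledger(cascade, reversed_schedule)
        assert forward.direct_total_usd == backward.direct_total_usd


class TestIndirectCosts:
    @pytest.mark.parametrize(
        "cases, income, expected",
        [(25_870, 750, 19_402_500), (28_581, 570, 16_291_170), (7, 0, 0)],
    )
    def test_lost_production(self, cases, income, expected):
        assert lost_production_cost(cases, income) == expected

    @pytest.mark.parametrize(
        "deaths, income, yll, expected",
        [
            (86_049, 750, Decimal("55.2"), 3_562_428_600),
            (95_272, 570, Decimal("56.0"), 3_041_082_240),
            (0, 750, Decimal("55.2"), 0),
        ],
    )
    def test_premature_death(self, deaths, income, yll, expected):
        assert premature_death_cost(deaths, income, yll) == expected

    @pytest.mark.parametrize(
        "cases, dowry, expected",
        [(14_820, 1_000, 14_820_000), (13_356, 1_000, 13_356_000), (0, 1_000, 0)],
    )
    def test_marriage(self, cases, dowry, expected):
        assert marriage_cost(cases, dowry) == expected

    def test_report_indirect_lines(self, burkina_report, niger_report):
        assert burkina_report.indirect["premature_death"].total_usd == 3_562_428_600
        assert burkina_report.indirect["lost_production"].total_usd == 19_402_500
        assert burkina_report.indirect["inability_to_marry"].total_usd == 13_356_000
        assert niger_report.indirect["premature_death"].total_usd == 3_041_082_240

    def test_intangible_is_never_a_number(self, burkina_report):
        assert burkina_report.intangible is NOT_COMPUTED
        assert str(burkina_report.intangible) == "NN"
        assert not isinstance(burkina_report.intangible, (int, float, Decimal))


class TestDiscountedHumanCapital:
    def test_zero_discount_equals_undiscounted(self):
        assert discounted_human_capital(
            86_049, 750, Decimal("55.2"), 0, 1
        ) == premature_death_cost(86_049, 750, Decimal("55.2"))

    def test_two_year_annuity_at_fifty_percent(self):
        # 100/1.5 + 100/2.25 = 111.11 to the cent
        assert discounted_human_capital(1, 100, 2, Decimal("0.5"), 1) == Decimal("111.11")

    def test_zero_deaths(self):
        assert discounted_human_capital(0, 750, Decimal("55.2"), Decimal("0.03")) == 0

    @settings(max_examples=60, deadline=None)
    @given(
        deaths=st.integers(min_value=0, max_value=20),
        income=st.integers(min_value=0, max_value=2_000),
        yll_tenths=st.integers(min_value=0, max_value=105),
        rate_pct=st.integers(min_value=0, max_value=50),
        start=st.integers(min_value=0, max_value=3),
    )
    def test_against_per_person_per_year_summation(
        self, deaths, income, yll_tenths, rate_pct, start
    ):
        """Brute-force oracle: accumulate income person by person, year by
        year, discounting each year separately; the fractional final year
        contributes its fractional share."""
        yll = Decimal(yll_tenths) / 10
        rate = Decimal(rate_pct) / 100
        v = Fraction(1, 1) / (1 + Fraction(rate))
        expected = Fraction(0)
        for _person in range(deaths):
            year, remaining = 0, Fraction(yll)
            while remaining > 0:
                share = min(remaining, Fraction(1))
                expected += share * income * v ** (start + year)
                remaining -= share
                year += 1
        got = discounted_human_capital(deaths, income, yll, rate, start)
        assert abs(Fraction(got) - expected) <= Fraction(1, 100)

    @settings(max_examples=500, deadline=None)
    @given(
        deaths=st.integers(min_value=0, max_value=10**6),
        income=st.integers(min_value=0, max_value=5_000),
        yll_tenths=st.integers(min_value=0, max_value=800),
    )
    def test_zero_discount_equivalence_randomised(self, deaths, income, yll_tenths):
        yll = Decimal(yll_tenths) / 10
        assert discounted_human_capital(
            deaths, income, yll, 0, 1
        ) == premature_death_cost(deaths, income, yll)


@settings(max_examples=100, deadline=None)
@given(
    count=st.integers(min_value=0, max_value=10**6),
    unit=st.integers(min_value=0, max_value=10**5),
)
def test_cost_operations_are_degree_one_homogeneous(count, unit):
    """Doubling the cohort doubles every cost exactly."""
    assert cost_line("x", 2 * count, unit).total_usd == 2 * cost_line("x", count, unit).total_usd
    assert lost_production_cost(2 * count, unit) == 2 * lost_production_cost(count, unit)
    assert marriage_cost(2 * count, unit) == 2 * marriage_cost(count, unit)
    yll = Decimal("55.2")
    assert premature_death_cost(2 * count, unit, yll) == 2 * premature_death_cost(
        count, unit, yll
    )
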
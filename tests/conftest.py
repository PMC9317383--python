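from decimal import Decimal

import pytest

from nomacost import (
    CountryConfig,
    bundled_config_path,
    load_config,
    report_from_config,
)


@pytest.fixture(scope="session")
def burkina() -> CountryConfig:
    return load_config(bundled_config_path("burkina_2018"))


@pytest.fixture(scope="session")
def niger() -> CountryConfig:
    return load_config(bundled_config_path("niger_2018"))


@pytest.fixture(scope="session")
def burkina_report(burkina):
    return report_from_config(burkina)


@pytest.fixture(scope="session")
def niger_report(niger):
    return report_from_config(niger)


@pytest.fixture()
def minimal_raw() -> dict:
    """Smallest valid configuration mapping, for mutation in error tests."""
    return {
        "schema_version": "1.0",
        "demography": {
            "name": "Testland",
            "year": 2018,
            "total_population": 1_000_000,
            "population_at_risk": 700_000,
            "population_working_age": 200_000,
            "female_population_marriageable": 100_000,
            "life_expectancy_at_birth": 60.0,
        },
        "economy": {"mean_annual_income": 500, "currency_label": "USD"},
        "epidemiology": {
            "incidence_rate": 0.0064,
            "care_fraction": 0.10,
            "untreated_mortality": 0.90,
            "mean_age_at_death": 6,
        },
        "cost_schedule": [
            {
                "id": "treatment",
                "label": "Costs of treatment",
                "category": "direct",
                "unit_cost_usd": 345,
                "count_base": "treated",
                "eligibility": "all_treated",
            },
        ],
    }


ZERO = Decimal(0)
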
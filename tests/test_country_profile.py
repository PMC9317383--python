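"""Configuration loading, invariant enforcement and age-pyramid derivation."""

from decimal import Decimal

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nomacost import (
    AgeBand,
    AgeBandedPopulation,
    AlignmentError,
    ConfigError,
    config_from_raw,
    config_to_raw,
    derive_population_at_risk,
)


class TestFixtureLoading:
    def test_burkina_profile_values(self, burkina):
        p = burkina.profile
        assert p.name == "Burkina Faso"
        assert p.total_population == 20_244_080
        assert p.population_at_risk == 14_939_063
        assert p.female_population_marriageable == 2_086_964
        assert p.life_expectancy_at_birth == Decimal("61.2")
        assert p.mean_annual_income == 750

    def test_niger_profile_values(self, niger):
        p = niger.profile
        assert p.total_population == 22_442_948
        assert p.population_at_risk == 16_540_452
        assert p.mean_annual_income == 570

    def test_rates_are_exact_decimals(self, burkina):
        e = burkina.params
        assert e.incidence_rate == Decimal("0.0064")
        assert e.care_fraction == Decimal("0.10")
        assert e.untreated_mortality == Decimal("0.90")
        assert e.at_risk_age_range == (0, 29)
        assert e.working_age_range == (15, 29)

    def test_schedule_has_eight_direct_components(self, burkina):
        direct = [c for c in burkina.schedule if c.category == "direct"]
        assert len(direct) == 8
        assert burkina.component("care_abroad").unit_cost_usd == 85_000
        assert burkina.component("care_abroad").eligibility.count == 172

    def test_burkina_ships_income_assistance_override(self, burkina):
        assert burkina.overrides == {"income_assistance": Decimal(1406398)}

    def test_intangible_component_carries_no_price(self, burkina):
        c = burkina.component("intangible")
        assert c.category == "intangible"
        assert c.unit_cost_usd is None and c.unit_cost_rule is None


class TestValidation:
    def test_negative_income_rejected(self, minimal_raw):
        minimal_raw["economy"]["mean_annual_income"] = -5
        with pytest.raises(ConfigError, match="mean_annual_income"):
            config_from_raw(minimal_raw)

    def test_missing_field_named_in_error(self, minimal_raw):
        del minimal_raw["demography"]["total_population"]
        with pytest.raises(ConfigError, match="total_population"):
            config_from_raw(minimal_raw)

    def test_unknown_keys_rejected(self, minimal_raw):
        minimal_raw["demography"]["hdi_rank"] = 182
        with pytest.raises(ConfigError, match="hdi_rank"):
            config_from_raw(minimal_raw)

    def test_wrong_schema_version_rejected(self, minimal_raw):
        minimal_raw["schema_version"] = "0.9"
        with pytest.raises(ConfigError, match="schema_version"):
            config_from_raw(minimal_raw)

    def test_at_risk_cannot_exceed_total(self, minimal_raw):
        minimal_raw["demography"]["population_at_risk"] = 2_000_000
        with pytest.raises(ConfigError, match="population_at_risk"):
            config_from_raw(minimal_raw)

    def test_override_for_unknown_component_rejected(self, minimal_raw):
        minimal_raw["overrides"] = {"surgery": 1}
        with pytest.raises(ConfigError, match="surgery"):
            config_from_raw(minimal_raw)

    def test_mean_age_at_death_must_be_inside_risk_range(self, minimal_raw):
        minimal_raw["epidemiology"]["mean_age_at_death"] = 35
        with pytest.raises(ConfigError, match="mean_age_at_death"):
            config_from_raw(minimal_raw)


PYRAMID = AgeBandedPopulation(
    bands=(
        AgeBand(start_age=0, end_age=14, count=9_000_000),
        AgeBand(start_age=15, end_age=29, count=5_939_063),
        AgeBand(start_age=30, end_age=59, count=5_000_000),
    )
)


class TestPyramid:
    def test_in_range_bands_summed(self):
        assert derive_population_at_risk(PYRAMID, (0, 29)) == 14_939_063

    def test_single_band_covers_range(self):
        pyramid = AgeBandedPopulation(
            bands=(AgeBand(start_age=0, end_age=29, count=16_540_452),)
        )
        assert derive_population_at_risk(pyramid, (0, 29)) == 16_540_452

    def test_empty_range_is_zero(self):
        assert derive_population_at_risk(PYRAMID, (20, 10)) == 0

    def test_range_cutting_band_raises(self):
        with pytest.raises(AlignmentError):
            derive_population_at_risk(PYRAMID, (0, 20))

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ValueError):
            AgeBandedPopulation(
                bands=(
                    AgeBand(start_age=0, end_age=14, count=1),
                    AgeBand(start_age=10, end_age=29, count=1),
                )
            )

    def test_profile_derived_from_pyramid_when_aggregate_absent(self, minimal_raw):
        del minimal_raw["demography"]["population_at_risk"]
        del minimal_raw["demography"]["population_working_age"]
        minimal_raw["demography"]["age_pyramid"] = [
            [0, 14, 400_000],
            [15, 29, 300_000],
            [30, 59, 200_000],
        ]
        config = config_from_raw(minimal_raw)
        assert config.profile.population_at_risk == 700_000
        assert config.profile.population_working_age == 300_000

    def test_direct_aggregate_takes_precedence_over_pyramid(self, minimal_raw):
        minimal_raw["demography"]["age_pyramid"] = [[0, 29, 123]]
        config = config_from_raw(minimal_raw)
        assert config.profile.population_at_risk == 700_000

    @settings(deadline=None)
    @given(
        counts=st.lists(st.integers(min_value=0, max_value=10**6), min_size=1, max_size=6),
        data=st.data(),
    )
    def test_additive_over_disjoint_partitions(self, counts, data):
        """Band counts are additive: summing over any partition of the range
        equals the whole-range derivation."""
        width = 5
        bands = tuple(
            AgeBand(start_age=i * width, end_age=(i + 1) * width - 1, count=c)
            for i, c in enumerate(counts)
        )
        pyramid = AgeBandedPopulation(bands=bands)
        full = (0, len(counts) * width - 1)
        split = data.draw(st.integers(min_value=1, max_value=len(counts)))
        mid = split * width - 1
        left = derive_population_at_risk(pyramid, (0, mid))
        right = derive_population_at_risk(pyramid, (mid + 1, full[1]))
        assert left + right == derive_population_at_risk(pyramid, full)


class TestRoundTrip:
    @pytest.mark.parametrize("name", ["burkina", "niger"])
    def test_serialize_load_is_identity(self, name, request):
        config = request.getfixturevalue(name)
        assert config_from_raw(config_to_raw(config)) == config
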
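# Burkina Faso, 2018 country-year scenario.
schema_version: "1.0"
demography:
  name: Burkina Faso
  year: 2018
  total_population: 20244080
  population_at_risk: 14939063          # ages 0-29
  population_working_age: 4042188       # ages 15-29; consistent with cohort 25,870
  female_population_marriageable: 2086964   # women 15-29 at risk
  life_expectancy_at_birth: 61.2
economy:
  mean_annual_income: 750
  currency_label: USD 2018
epidemiology:
  incidence_rate: 0.0064                # 6.4 cases per 1000 person-years
  care_fraction: 0.10
  untreated_mortality: 0.90
  mean_age_at_death: 6
  at_risk_age_range: [0, 29]
  working_age_range: [15, 29]
  marriageable_age_range: [15, 29]
cost_schedule:
  - id: treatment
    label: Costs of treatment
    category: direct
    unit_cost_usd: 345
    count_base: treated
    eligibility: all_treated
    conversion_note: mean 255,000 FCFA (2001) converted at the 2001 rate
  - id: surgery
    label: Costs of surgery
    category: direct
    unit_cost_usd: 400
    count_base: treated
    eligibility: {absolute_count: 5737}
    native_amount: 393
    native_currency: CHF
    conversion_note: CHF 393 converted to USD 2020
  - id: accommodation
    label: Costs of accommodation
    category: direct
    unit_cost_usd: 765
    count_base: treated
    eligibility: {absolute_count: 5737}
    native_amount: 752
    native_currency: CHF
  - id: psychological_management
    label: Costs of psychological management
    category: direct
    unit_cost_usd: 65
    count_base: treated
    eligibility: {absolute_count: 5737}
    native_amount: 58
    native_currency: CHF
  - id: physiotherapy
    label: Costs of physiotherapy
    category: direct
    unit_cost_usd: 254
    count_base: treated
    eligibility: {absolute_count: 5737}
    native_amount: 64
    native_currency: CHF
    conversion_note: >-
      source prints CHF 64 against USD 254; the USD figure is canonical, the
      CHF figure kept as provenance only (inconsistent with the ~1.02
      conversion of every other row)
  - id: income_assistance
    label: Costs of assist. w. income-gen. activities
    category: direct
    unit_cost_usd: 245
    count_base: treated
    eligibility: {absolute_count: 5737}
    native_amount: 233
    native_currency: CHF
  - id: schooling
    label: Costs of schooling/vocational training
    category: direct
    unit_cost_usd: 175
    count_base: treated
    eligibility: {absolute_count: 1950}
    native_amount: 163
    native_currency: CHF
  - id: care_abroad
    label: Costs of care abroad
    category: direct
    unit_cost_usd: 85000
    count_base: treated
    eligibility: {absolute_count: 172}
    native_amount: 77850
    native_currency: CHF
    conversion_note: mean cost of transfer and care in Switzerland, all charges
  - id: lost_production
    label: Costs of loss of production
    category: indirect
    unit_cost_rule: mean_annual_income
    count_base: working_age
    eligibility: all_treated
  - id: premature_death
    label: Costs related to premature death
    category: indirect
    unit_cost_rule: income_times_yll
    count_base: untreated_deaths
    eligibility: all_treated
  - id: inability_to_marry
    label: Costs of inability to marry
    category: indirect
    unit_cost_usd: 1000
    count_base: marriageable_female
    eligibility: all_treated
    conversion_note: mean dowry and related marriage expenses, two independent informants
  - id: intangible
    label: Intangible costs
    category: intangible
overrides:
  # published income-assistance total; 5737 x 245 = 1,405,565 (delta 833)
  income_assistance: 1406398
provenance:
  population_working_age: >-
    back-computed: smallest printed-consistent population whose potential-case
    cohort at 6.4/1000 is the published 25,870
  female_population_marriageable: published (women 15-29 at risk of noma)
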
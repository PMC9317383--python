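# Niger, 2018 country-year scenario.
schema_version: "1.0"
demography:
  name: Niger
  year: 2018
  total_population: 22442948
  population_at_risk: 16540452          # ages 0-29
  population_working_age: 4465782       # ages 15-29; back-computed, see provenance
  female_population_marriageable: 2315625   # women 15-29; back-computed
  life_expectancy_at_birth: 62.0
economy:
  mean_annual_income: 570
  currency_label: USD 2018
epidemiology:
  incidence_rate: 0.0064
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
    eligibility: {absolute_count: 6372}
    native_amount: 393
    native_currency: CHF
  - id: accommodation
    label: Costs of accommodation
    category: direct
    unit_cost_usd: 765
    count_base: treated
    eligibility: {absolute_count: 6372}
    native_amount: 752
    native_currency: CHF
  - id: psychological_management
    label: Costs of psychological management
    category: direct
    unit_cost_usd: 65
    count_base: treated
    eligibility: {absolute_count: 6372}
    native_amount: 58
    native_currency: CHF
  - id: physiotherapy
    label: Costs of physiotherapy
    category: direct
    unit_cost_usd: 254
    count_base: treated
    eligibility: {absolute_count: 6372}
    native_amount: 64
    native_currency: CHF
    conversion_note: USD figure canonical; CHF figure provenance only
  - id: income_assistance
    label: Costs of assist. w. income-gen. activities
    category: direct
    unit_cost_usd: 245
    count_base: treated
    eligibility: {absolute_count: 6372}
    native_amount: 233
    native_currency: CHF
  - id: schooling
    label: Costs of schooling/vocational training
    category: direct
    unit_cost_usd: 175
    count_base: treated
    eligibility: {absolute_count: 2166}
    native_amount: 163
    native_currency: CHF
  - id: care_abroad
    label: Costs of care abroad
    category: direct
    unit_cost_usd: 85000
    count_base: treated
    eligibility: {absolute_count: 185}
    native_amount: 77850
    native_currency: CHF
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
  - id: intangible
    label: Intangible costs
    category: intangible
provenance:
  population_working_age: >-
    back-computed: smallest population whose potential-case cohort at 6.4/1000
    is the published 28,581 (no 15-29 count is published for Niger)
  female_population_marriageable: >-
    back-computed: 14,820 / 0.0064 exactly; no published female 15-29 count
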
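# Published 2018 figures for the two study countries, cell by cell, used by
# validation mode to classify every computed value as match /
# printed_override_used / discrepancy.  Several published cells are internally
# inconsistent (they disagree with their own count x unit-cost products or
# column sums); validation surfaces those deltas rather than reproducing them.
burkina_2018:
  cascade:
    total_population: 20244080
    population_at_risk: 14939063
    potential_cases: 95610
    treated_cases: 9561
  indicators:
    life_expectancy_at_birth: 61.2
    mean_age_at_death: 6.0
    years_of_life_lost: 55.2
    untreated_mortality_pct: 90.0
    mean_annual_income: 750.0
  direct_total: 28179901
  lines:
    treatment: {count: 9561, unit: 345, total: 3298545}
    surgery: {count: 5737, unit: 400, total: 2294800}
    accommodation: {count: 5737, unit: 765, total: 4388805}
    psychological_management: {count: 5737, unit: 65, total: 372905}
    physiotherapy: {count: 5737, unit: 254, total: 1457198}
    income_assistance: {count: 5737, unit: 245, total: 1406398}
    schooling: {count: 1950, unit: 175, total: 341250}
    care_abroad: {count: 172, unit: 85000, total: 14620000}
    lost_production: {count: 25870, unit: 750, total: 19402500}
    premature_death: {count: 86049, total: 3562428600}
    inability_to_marry: {count: 13356, unit: 1000, total: 13365000}
niger_2018:
  cascade:
    total_population: 22442948
    population_at_risk: 16540452
    potential_cases: 105858
    treated_cases: 10585
  indicators:
    life_expectancy_at_birth: 62.0
    mean_age_at_death: 6.0
    years_of_life_lost: 56.0
    untreated_mortality_pct: 90.0
    mean_annual_income: 570.0
  direct_total: 30746063
  lines:
    treatment: {count: 10585, unit: 345, total: 3651825}
    surgery: {count: 6372, unit: 400, total: 2548800}
    accommodation: {count: 6372, unit: 765, total: 4874580}
    psychological_management: {count: 6372, unit: 65, total: 414180}
    physiotherapy: {count: 6372, unit: 254, total: 1618488}
    income_assistance: {count: 6372, unit: 245, total: 1561140}
    schooling: {count: 2166, unit: 175, total: 379050}
    care_abroad: {count: 185, unit: 85000, total: 15725000}
    lost_production: {count: 28581, unit: 570, total: 16291170}
    premature_death: {count: 95272, total: 3041082240}
    inability_to_marry: {count: 14820, unit: 1000, total: 14820000}
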
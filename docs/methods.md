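# Methods

## Scope and model structure

`nomacost` computes a single-year, single-country snapshot of the economic
and social burden of noma. The model has three stages — a prevalence
cascade, a direct-cost ledger, and three human-capital indirect costs — and
deliberately nothing more: no epidemic dynamics, no progression through
clinical stages, no cohort ageing or multi-year accumulation. Each
country-year is computed independently from its configuration file.

## Prevalence cascade

The population at risk is persons aged 0–29 (noma is overwhelmingly a
disease of young children, with survivors carrying sequelae into early
adulthood; age ranges are inclusive of both endpoints and configurable).
Applying the annual incidence rate gives potential cases; the care-seeking
fraction of potential cases gives cases receiving (or needing) treatment;
the untreated-mortality fraction of potential cases gives premature deaths.
The same incidence applied to the working-age (15–29) and
marriageable-female (women 15–29) subpopulations gives the cohorts behind
the lost-production and marriage costs.

**Rounding.** Every cascade stage floors to a whole person. This is not a
free choice: the bundled scenarios only reproduce the published cohort
sizes under flooring (16,540,452 × 0.0064 = 105,858.89 → 105,858, and
105,858 × 0.10 = 10,585.8 → 10,585; nearest rounding gives 105,859 and
10,586). Products are evaluated as exact rationals (`fractions.Fraction`
over decimal literals) before flooring, so a product that lands exactly on
an integer — e.g. 4,042,188 × 0.0064 = 25,870.00 — can never be truncated
to 25,869 by binary floating point.

**Pinned sub-cohorts.** The care sub-cohorts of the bundled scenarios
(surgery/accommodation/psychology/physiotherapy/income-assistance: 5,737
Burkina Faso, 6,372 Niger; schooling: 1,950 / 2,166; care abroad: 172 /
185) are shipped as absolute head counts because the source tables print
them without a generating rule (they are near, but not exactly, fixed
fractions of the treated cohort — 60% of 10,585 floors to 6,351, not
6,372). A `fraction_of_treated` eligibility rule is available for synthetic
scenarios. An absolute count exceeding its base cohort is a validation
error.

## Costs

All money is `decimal.Decimal`; ledger totals are exact sums of exact
products, rendered as integer USD (the underlying sources carry no cents).
Floats in configuration files are interpreted through their shortest
decimal literal (`0.0064` means 64/10⁴ exactly).

**Direct costs** price eight care and social components per person against
their cohorts. Unit costs in the bundled scenarios are USD conversions of
CHF amounts from the service records of a foundation operating in both
countries (kept as `native_amount`/`conversion_note` provenance); the
physiotherapy row's CHF figure is inconsistent with every other row's
conversion factor, so the USD figure is treated as canonical and the CHF
figure is provenance only.

**Indirect costs** follow the human capital approach and are computed on
*potential*-case cohorts (not treated cases) — encoded in each component's
declared `count_base`, not hard-coded:

- *Lost production*: one year of mean annual income per working-age case.
- *Premature death*: deaths × income × YLL, where YLL = life expectancy at
  birth − mean age at death (61.2 − 6 = 55.2 years for Burkina Faso,
  62.0 − 6 = 56.0 for Niger).
- *Inability to marry*: the foregone dowry and related marriage transfers
  (USD 1000) per marriageable-female case.

**Discounting** is opt-in and defaults to zero (the headline estimates are
undiscounted). The discounted variant values each lost year at
`(1+ρ)^(−t)` starting `start_offset` years out, with a fractional final
year weighted by its fraction; at ρ = 0 it equals the undiscounted product
exactly (enforced by property test). Non-terminating present values are
rounded half-even to the cent.

**Printed overrides.** The Burkina Faso income-assistance line ships as a
`printed_override` of 1,406,398 because the published total contradicts its
own 5,737 × 245 = 1,405,565. Overrides never hide anything: the row is
marked, the 833-dollar delta is reported, and validation mode classifies
every published cell as `match` / `printed_override_used` / `discrepancy`
(delta = printed − computed). Two further published cells are reproducibly
wrong and are *flagged rather than reproduced*: the Burkina marriage total
(13,365,000 printed vs 13,356 × 1000 = 13,356,000; an apparent digit
transposition) and the Niger direct total (30,746,063 printed vs a column
sum of 30,773,063; Δ 27,000).

**Intangible costs** (pain, suffering, stigma, discrimination) are carried
as a non-numeric `NOT_COMPUTED` sentinel so no report can render them as 0.

## Parameters

| Parameter | Default | Units | Basis |
|---|---|---|---|
| incidence_rate | 0.0064 | cases/person-year | consensus estimate for the region; published studies span 8.3×10⁻⁵ to 7×10⁻³ |
| care_fraction | 0.10 | proportion | lower end of the 10–15% of survivors thought to seek care |
| untreated_mortality | 0.90 | proportion | untreated case fatality |
| mean_age_at_death | 6 | years | case series range 4–7.6 years |
| at-risk ages | 0–29 | years | affected age span |
| working ages | 15–29 | years | legal working age within the at-risk span |
| dowry | 1000 | USD | two independent in-country informants |
| discount rate | 0 | /year | headline estimates are undiscounted |

Demography and economy (population 0–29, 15–29, female 15–29, life
expectancy, mean income) are country-year configuration values with
provenance notes. The Niger 15–29 and female-15–29 populations are not
published anywhere in the source tables; the bundled values (4,465,782 and
2,315,625) are back-computed as the populations whose floored potential-case
cohorts reproduce the published 28,581 and 14,820, and are marked as such in
the fixture's provenance section.

## Sensitivity analysis

One-way analysis sweeps each parameter to its distribution bounds holding
the rest at baseline and returns swings ranked widest first; Monte-Carlo
analysis draws all distributions independently per replicate and reruns the
*full* deterministic model — floors included — so uncertainty propagates
through the integer cascade. Sampling uses a single `numpy` generator
seeded explicitly; the seed is recorded in the result and reruns are
bit-identical. Default distributions: incidence triangular(8.3×10⁻⁵,
6.4×10⁻³, 7×10⁻³) and care fraction uniform(0.10, 0.15); unit costs default
to point masses (no published ranges exist) and any cost ranges are
user-supplied.

Because pinned absolute cohorts cannot exceed their base cohort, a
low-incidence draw would make them infeasible. Inside sensitivity runs each
pin is therefore re-expressed as its implied share of the *baseline* base
cohort and scales with the scenario; the share is computed at 30
significant digits rounded up so that at baseline parameters the flooring
reproduces the pinned count exactly. The deterministic path is untouched.

## Synthetic scenarios

The generator emulates what the model actually consumes — nested population
aggregates as exact floored shares of a total (not full age pyramids),
integer incomes and unit costs, life expectancy to one decimal — with the
epidemiological defaults above, so generated instances resemble the study
countries in magnitude. `recovery_check` recomputes every output with
independent digit-shift integer arithmetic from the generating ground truth
and must agree exactly, with no tolerance. Passing synthetic recovery shows
the pipeline's arithmetic is faithful to its inputs; it says nothing about
how well any real country's surveillance measures those inputs (synthetic
profiles have no age-structure error, no income dispersion, no reporting
bias).

## Numerical and design choices

- Exact arithmetic everywhere on the value path: `Fraction` for
  rate × population floors, `Decimal` for money; floats never touch a
  ledger.
- Direct aggregates take precedence over an age pyramid when both are
  given (the bundled scenarios publish aggregates, and inventing an age
  structure would add nothing); a range cutting through a pyramid band is
  an error, never interpolated.
- Machine outputs (CSV/JSON) render numbers un-grouped; human-readable
  summaries group thousands with a fixed convention independent of the
  process locale. Rendering is pure — identical reports give byte-identical
  files. Duplicate country names in a summary are suffixed deterministically.
- Reported problem sizes: the bundled scenarios are desk-scale (populations
  ≈ 2×10⁷, 8–12 schedule rows); property tests use 100–1000 randomized
  draws and 100 synthetic seeds; shipped Monte-Carlo examples use tens to
  a thousand replicates.

## Known limitations

- Costs excluded by design: pre-hospital/traditional-medicine care,
  prevention programmes, funeral costs, unpaid household labour,
  friction-cost or willingness-to-pay valuations, and any monetisation of
  intangible costs.
- The single incidence, care-seeking and mortality proportions hide stage
  structure and regional heterogeneity; incidence estimates in the
  literature span nearly two orders of magnitude, which the sensitivity
  defaults make explicit.
- Mean annual income ignores income dispersion; the human capital approach
  values lost life-years at market income only.
- The female-marriageable cohort is a direct configuration value; no
  sex-ratio model is applied.
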
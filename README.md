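# nomacost

A cost-of-illness model for **noma** (cancrum oris, ICD-11 DAOC.31), the
gangrenous orofacial disease of malnourished children in the Sahel's "noma
belt". The package estimates the annual economic and social burden of noma
for a country-year from a handful of published indicators, and ships
ready-to-run 2018 scenarios for Burkina Faso and Niger whose outputs it
reproduces to the dollar.

It is written for health economists and NTD (neglected tropical disease)
researchers who need a transparent, auditable burden estimate — every number
in the output is an exact integer/decimal computation from configuration
inputs, and every place where the published tables are internally
inconsistent is *flagged*, not silently papered over.

## The model

**Step 1 — prevalence cascade.** With population at risk `P` (ages 0–29),
annual incidence `r` (default 6.4/1000 person-years), care-seeking fraction
`c` (default 10%) and untreated mortality `m` (default 90%):

```
potential cases     N  = ⌊P·r⌋
cases treated       T  = ⌊N·c⌋
untreated deaths    D  = ⌊N·m⌋
working-age cases   W  = ⌊P₁₅₋₂₉·r⌋        marriageable-female cases  F = ⌊P♀,₁₅₋₂₉·r⌋
```

Every stage floors to a whole person; products are evaluated as exact
rationals first, so a product landing exactly on an integer is never
perturbed by floating point.

**Step 2 — direct costs.** A unit-cost schedule (treatment, surgery,
accommodation, psychological care, physiotherapy, income-generating
assistance, schooling, transfer and care abroad) is applied to its cohorts:
each ledger line is `count × unit cost` in exact decimal arithmetic.

**Step 3 — indirect costs** (human capital approach), with mean annual
income `y`, life expectancy at birth `e`, mean age at death `a`, and years
of life lost `YLL = e − a`:

```
lost production     W · y
premature death     D · y · YLL        (optionally discounted at rate ρ)
inability to marry  F · dowry
```

Intangible costs (pain, stigma, discrimination) are represented by an
explicit not-computed marker (`NN`), never a number.

One-way (tornado) and Monte-Carlo sensitivity analysis propagate parameter
uncertainty — e.g. incidence estimates spanning 8.3/100,000 to 7/1000 —
*through* the integer cascade, and a synthetic-scenario generator with known
ground truth exercises the whole pipeline.

## Worked example

```python
from nomacost import bundled_config_path, load_config, report_from_config

config = load_config(bundled_config_path("burkina_2018"))
report = report_from_config(config)
print("potential cases:", report.cascade.potential_cases)
print("receiving care:", report.cascade.treated_cases)
print("direct costs USD:", report.direct.direct_total_usd)
print("premature-death cost USD:", report.indirect["premature_death"].total_usd)
print("YLL per death:", report.yll.yll)
```

prints

```
potential cases: 95610
receiving care: 9561
direct costs USD: 28179901
premature-death cost USD: 3562428600
YLL per death: 55.2
```

i.e. for Burkina Faso 2018: 95,610 potential cases (14,939,063 at risk ×
6.4/1000), 9,561 of them reaching care, USD 28.2 million in annual direct
care and social costs, and USD 3.56 billion in human-capital losses from the
86,049 untreated deaths (86,049 × 750 × 55.2).

The same model from the shell, with cell-by-cell validation against the
published country tables:

```sh
nomacost run --config src/nomacost/data/burkina_2018.yaml \
             --config src/nomacost/data/niger_2018.yaml \
             --validate --out out/
nomacost run --config src/nomacost/data/burkina_2018.yaml \
             --sensitivity mc --mc-reps 1000 --seed 1 --out out/
nomacost synth --seed 7 --out out/        # synthetic scenario config
```

`--validate` classifies every published cell as `match`,
`printed_override_used` or `discrepancy` with its exact delta; the bundled
scenarios surface three known inconsistencies in the published tables (the
Burkina income-assistance line, the Burkina marriage total, and the Niger
direct-total column sum).

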
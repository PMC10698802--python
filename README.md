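# dmclaims

A tested, reusable re-implementation of the claims-data analysis used to
estimate type 1 and type 2 diabetes incidence from German statutory health
insurance (SHI) routine data: cohort construction, m2Q incident-case
detection, rule-based diabetes-type classification, and stratified,
age-standardised, extrapolated incidence estimation — exercised end to end
on a synthetic claims generator, because real SHI claims cannot be
redistributed.

It is written for epidemiologists and health-services researchers who work
with administrative claims: the pipeline stages are the familiar ones
(eligibility filters, diagnosis-free lead time, case-ascertainment
criterion, phenotyping algorithm, direct standardisation), and each stage
is exposed as a plain function over pandas tables.

## The method

**Risk set.** For each reporting year the denominator contains every
insured person fully observable through the year (or from birth to 31 Dec
for in-year newborns) *and* through the preceding calendar year, with no
diabetes evidence in that pre-observation year: no confirmed outpatient or
any inpatient ICD-10 E10–E14 diagnosis and no ATC A10A/A10B prescription.

**m2Q case detection.** A person becomes an incident case if an inpatient
main E10–E14 diagnosis appears in any quarter of the year, or a confirmed
outpatient / inpatient secondary E10–E14 diagnosis in quarter *q* is
confirmed by a further E10–E14 diagnosis in quarters *q+1 … q+3* (the
window crosses the year boundary). The first documented diagnosis fixes
the diagnosis quarter.

**Type classification.** Each case's diagnosis window (diagnosis quarter
plus three subsequent quarters) is summarised into counts *E10 amb*,
*E10 stat*, …, *E14 stat* (amb = confirmed outpatient + inpatient
secondary; stat = inpatient main), A10A and A10B prescription counts, and
age. A published 16-rule decision list (six type 1 cases, ten type 2
cases) assigns type 1 / type 2 / other; type 2 cases with an A10
prescription in the window are flagged as medicated.

**Estimation.** Incidence = cases / risk-set members, with Clopper–Pearson
95 % intervals. Directly age-standardised rates use 1-year age × sex
weights from a standard population table, summed into reporting age
groups; extrapolated counts scale sample cases to a national reference
population cell by cell:

- standardised rate: `r_std = Σ_a w_a · (x_a / n_a)`, `w_a ∝` standard count of cell *a*
- extrapolated count: `X = Σ_a x_a · N_a / n_a`

**Synthetic claims.** A `ScenarioConfig` fixes the generative truth:
age/sex structure, type-specific incidence rates, seasonal diagnosis
multipliers, per-quarter pandemic disruption of care-seeking (which delays
documentation, not disease onset), a district-level deprivation gradient,
prevalent persons, enrollment churn and coding noise. Every downstream
estimate can therefore be checked against known truth.

## Worked example

```python
from dmclaims import ScenarioConfig, run_pipeline

config = ScenarioConfig(
    n_persons=50_000, years=(2019, 2021), rng_seed=1,
    disruption={"2020Q2": 0.4, "2020Q3": 0.8, "2020Q4": 0.8, "2021Q1": 0.9},
    catch_up_prob=0.5,
)
result = run_pipeline(config, "demo_run")
```

The age-standardised annual trend (`result.annual`, totals only) printed:

```
 year diabetes_type   scale  numerator   rate  ci_low  ci_high
 2019         type1 per100k        6.0 14.274   2.842   25.706
 2019         type2 percent      288.0  0.673   0.596    0.751
 2020         type1 per100k        5.0 12.387   1.545   23.228
 2020         type2 percent      286.0  0.685   0.605    0.765
 2021         type1 per100k        8.0 19.798   6.035   33.561
 2021         type2 percent      322.0  0.781   0.695    0.868
```

Type 1 is reported per 100,000 persons, type 2 in percent. With only ~50 k
insured persons the type 1 strata are small and their intervals wide; the
type 2 series shows the configured 2021 catch-up (0.78 % vs 0.67 % in
2019). The quarterly series for 2020 (`result.quarterly`) shows the
configured second-quarter care disruption as a dip in documented type 2
incidence:

```
 year  quarter diabetes_type   rate  ci_low  ci_high
 2020        1         type2 0.1981  0.1550   0.2412
 2020        2         type2 0.0792  0.0523   0.1061
 2020        3         type2 0.2167  0.1718   0.2615
 2020        4         type2 0.1911  0.1487   0.2334
```

The same run is available from the shell:

```bash
dmclaims run --out demo_run --seed 1          # full pipeline, default scenario
dmclaims simulate --out claims --seed 1       # claims tables only
dmclaims classify profiles.csv --out labelled.csv
dmclaims report demo_run
```

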
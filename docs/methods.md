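# Methods

This note documents the models and procedures implemented in `dmclaims`,
the assumptions behind them, the parameters that matter, and the places
where the design was genuinely open.

## 1. Analysis pipeline

### Risk set (denominator)

For reporting year *Y*, persons qualify if (in flowchart order):

1. insured at least one day in *Y*;
2. fully observable over *Y* — enrollment spells cover 1 Jan *Y* to
   31 Dec *Y* without a gap of a day or more, or from the birth date to
   31 Dec *Y* for persons born in *Y*;
3. fully observable over *Y−1* (the pre-observation period), again from
   birth for persons born in *Y−1*; persons born in *Y* satisfy this
   vacuously (the inclusion-from-birth rule is impossible otherwise);
4. no diabetes evidence in the four quarters of *Y−1*: no confirmed
   outpatient E10–E14 diagnosis, no inpatient main or secondary E10–E14
   diagnosis, no A10A/A10B prescription.

Counts surviving each stage are logged; by construction they are
non-increasing. Age is completed years on 31 Dec of *Y* (equivalently,
*Y* minus birth year), the single age convention used for eligibility,
classification, standardisation and extrapolation. Denominators are
whole-year member counts, not person-time; quarterly estimates reuse the
full-year denominator because the denominator is defined as all persons at
risk in the year.

ICD matching is on the three-character prefix (E10–E14). Outpatient
diagnoses carry a four-level certainty flag (confirmed / suspected /
excluded / status post) mirroring German outpatient coding; only
"confirmed" counts anywhere. ATC matching is by prefix (A10, A10A, A10B).

### m2Q detection

An inpatient main diagnosis in *Y* qualifies immediately, with no
survival or continued-enrollment requirement afterwards. An outpatient
confirmed or inpatient secondary diagnosis in quarter *q* of *Y* (the
"amb" pool) qualifies iff any further qualifying E10–E14 record falls in
*q+1 … q+3*. Two records in the same quarter never satisfy m2Q. The
confirmation window deliberately crosses the year boundary (a Q4 index can
be confirmed in the next year's Q1–Q3): the generator therefore emits
claims through Q3 of the year after the last reporting year so that
late-Q4 cases remain confirmable. Confirmation is not required to repeat
the same three-character code — typing is the classifier's job. Persons
disenrolled before confirmation simply fail m2Q; this reproduces the
under-ascertainment any confirmation-based criterion has near the end of
observation.

The implementation is a vectorised person-quarter join; a brute-force
enumeration of all (index, confirmation) quarter pairs serves as an
independent oracle in the test suite.

### Type classification

Profiles count records over the diagnosis quarter plus the three
subsequent quarters — chosen to coincide with the m2Q confirmation window
and with the explicitly defined medication window; the source algorithm's
counting window is not restated in the surveillance context, so the window
is one deliberate, documented choice rather than a config axis.
Prescriptions in the index quarter count even though sub-quarter ordering
(before vs after the diagnosis) is not representable in quarter-resolved
data.

The decision list is implemented verbatim: six type 1 rules, ten type 2
rules, "other" when none fires. Two readings were fixed deliberately:

* Type 2 case 9's compound bracket is read as
  `(E12 amb + E14 amb ≥ 1) OR (E12 stat + E14 stat ≥ 1)` — the most
  literal parse of the printed operationalisation.
* Type 1 rules are evaluated before type 2 rules. This matters: the
  printed rules are **not** disjoint. Exhaustive enumeration over bounded
  profiles (all counts 0–3, ages 10 and 30) shows that type 1 cases 4 and
  6 can co-fire with type 2 case 10 (which constrains neither E10 stat nor
  E11 stat); e.g. *E10 amb 1, E10 stat 1, E11 amb 2, A10A 1, age 30*
  satisfies both families. With type-1 precedence classification remains
  total and single-labelled; the enumeration is kept in the test suite as
  a permanent audit, where the disjointness assertion documents the
  overlap rather than hiding it.

The medicated-type-2 flag is one A10 prescription in the diagnosis quarter
or the three subsequent quarters, evaluated only for type 2 cases.

### Deprivation linkage

Districts carry a single deprivation score (higher = more deprived) and
are split 20/60/20 **by district count** — the categories are defined as
percentages of districts, not of population. On counts not divisible by
five the remainder goes to medium, preserving the extremes' definition;
score ties break by district code. Persons in unscored or unknown
districts are dropped from deprivation-stratified outputs only.

### Estimation

* Crude rate: cases / members, reported per 100,000 (type 1) or percent
  (type 2); all computation on the proportion scale.
* CI: Clopper–Pearson exact (`scipy.stats.beta` quantiles). "Assuming a
  binomial distribution" admits several intervals; the exact interval was
  chosen because pediatric type 1 strata have single-digit counts where
  Wald intervals are invalid. Cross-checked in tests against statsmodels'
  independent beta-quantile implementation.
* Standardisation: direct, with 1-year age × sex weights from the
  standard population, summed within reporting age groups (type 1:
  <7, 7–10, 11–13, 14–17, 18–34, 35–49, ≥50; type 2: <18, 18–34, 35–49,
  50–64, 65–79, ≥80; collapsed variants are provided). Standard cells
  with no sample members are reweighted to zero with a warning and the
  remaining weights renormalised. The CI of a standardised rate combines
  cell-level binomial variances under the same weights with a normal
  approximation truncated to [0, 1]; this is isolated in one function so a
  gamma-type interval could be swapped in. CIs are computed on crude cell
  counts before standardisation.
* Extrapolation: `Σ x_a N_a / n_a` over 1-year age × sex cells; reference
  cells without sample members contribute 0 with a warning. Sex-specific
  counts add exactly to totals.
* The shipped standard/reference table is synthetic — a Destatis-like
  national pyramid built from the same band structure as the default
  insured population (~82–83 M, drifting +150 k/year). Any CSV with
  age/sex/count columns can replace it.

## 2. Synthetic claims generator

The generator emulates the *structure* of SHI routine data, not Germany's
billing system: quarter-resolved outpatient diagnoses with certainty
flags, dated enrollment spells, inpatient main/secondary diagnoses,
ATC-coded prescriptions, district assignment, and a latent onset process
whose truth is recorded for parameter-recovery testing.

Key mechanisms and the reasoning behind them:

* **Onset vs observation.** Onsets follow quarterly hazards (annual rate /
  4 × deprivation multiplier). Seasonality and pandemic disruption act on
  the probability that an onset is *documented* in a quarter
  (`min(1, seasonal_q × disruption_yq)`), never on the onset itself —
  the 2020 dip in documented incidence reflects reduced utilisation, not
  reduced disease. Suppressed index diagnoses are re-attempted each later
  quarter with `catch_up_prob` on top of that quarter's multiplier,
  producing the 2021 catch-up qualitatively.
* **Prevalent persons** (default 9 %, the approximate share of otherwise
  eligible insured persons excluded for pre-existing diabetes) emit a
  confirmed outpatient E11 in every enrolled quarter plus an annual A10B
  prescription, starting in the pre-observation year. They are excluded by
  the same record-based filter used on real data, not by a status flag.
  Persons born in the first reporting year cannot be prevalent.
* **Coding noise.** With `misc_coding_prob` an incident case is coded
  E12/E13/E14 instead of its type-consistent E10/E11, feeding the "other"
  category. Type 1 cases receive insulin (A10A) prescriptions; a
  configurable fraction of type 2 cases (default 0.5) receives A10B.
  Filler noise adds non-diabetes diagnoses, *suspected* diabetes codes
  (which no rule may count) and non-A10 prescriptions.
* **Enrollment.** One spell per person, entering at the later of birth and
  1 Jan of the pre-observation year, truncated by annual disenrollment
  (2 %) and death (1 %) hazards.
* **Deprivation gradient.** District scores are uniform; the true-hazard
  multiplier is 1 / √ratio / ratio for low/medium/high categories.
  Because the high and low strata are finite samples, the recovered
  high/low rate ratio scatters around the truth with SE ≈
  ratio·√(1/x_high + 1/x_low); annual-from-quarterly hazard concavity
  attenuates the expected ratio by <1 % at realistic rates.

Default truth values describe the German SHI setting of the late 2010s:
age/sex structure and type-specific incidence bands follow published
claims-based tables for 2021 (type 1 peaking at 40–60/100,000 in
childhood; type 2 rising from ~0.014 % under 18 to ~2 % at 65–79), a mild
first-quarter seasonal peak ([1.1, 0.95, 0.95, 1.0]), and a
high-vs-low-deprivation rate ratio of 1.3. The canned
`ScenarioConfig.pandemic()` scenario uses disruption multipliers
{2020Q2: 0.4, 2020Q3: 0.8, 2020Q4: 0.8, 2021Q1: 0.9} with
`catch_up_prob = 0.5`, chosen to mirror the reported sharp second-quarter
2020 dip, the milder second winter wave, and 2021 catch-up.
`ScenarioConfig.noiseless()` (full observation, uniform seasonality,
certain confirmation, no miscoding) is the regime in which detected cases
equal latent onsets exactly and classified types equal true types; the
uniform seasonal multipliers are part of that regime because seasonal
factors act on the same observation probability as disruption.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: fee-schedule billing structure, day-level
hospital episodes, re-enrollment after gaps, births during later study
years, migration between districts, correlated comorbidity coding, and
any causal effect of infection on diabetes risk. Recovery results show the
*estimators* are correct under the stated generative model, not that the
case definitions are clinically valid.

## 3. Numerical and reproducibility choices

* All randomness flows from one integer seed through three independent
  spawned streams (population, onsets, claims). Two configs differing only
  in observation parameters (e.g. disruption) share identical populations
  and onsets, so scenario contrasts are paired; fixed-size draws keep the
  streams aligned across configurations.
* Re-running with the same config and seed reproduces byte-identical CSV
  outputs; the manifest records the config hash, seed, per-stage row
  counts and output list.
* Quarters are integers `4·year + quarter − 1` internally and `YYYYQn`
  labels in CSV; dates are ISO-8601.
* Ties and degenerate inputs: district-score ties break lexicographically;
  empty strata yield NaN rates with a flag rather than raising; a stratum
  with cases but an empty denominator raises a data-integrity error;
  `binomial_ci` pins the bounds at 0 and 1 for x = 0 and x = n.
* Test and acceptance problem sizes (10⁵–2×10⁵ persons, 500 CI
  replicates at n = 50,000) are the scales at which the quoted 3-SD
  Monte-Carlo bounds are meaningful for the rates involved; exact
  Clopper–Pearson coverage at n = 50,000, p = 0.001 is 95.3 %, inside the
  93–97 % acceptance band.

## 4. Known limitations

* The diagnosis-free lead time is one year; first-ever lifetime diagnoses
  beyond that window are not distinguished, so incidence is overestimated
  relative to longer lead times.
* Quarterly denominators ignore within-year person-time.
* The deprivation split is by district count; population-weighted
  quantiles would shift category boundaries.
* The standardised-rate CI is a normal approximation; exact or
  gamma-based intervals would differ in very small strata.
* Printed-table reproduction is limited to arithmetic identities: the
  real risk population is proprietary, and no attempt is made to match
  its absolute incidence estimates.
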
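# Methods

## Data model

The pipeline operates on five flat tables (CSV, UTF-8, ISO-8601 dates):

* `practices(practice_id, year, listed_patients, registration_weeks, coded_fraction)`
* `patients(patient_id, practice_id, sex, birth_year, birth_quarter, reg_start, reg_end)`
* `episodes(episode_id, patient_id, icpc, start_date, end_date?)`
* `care_events(event_id, patient_id, episode_id?, date, type)` with
  `type ∈ {consultation, home visit, telephone, prescription}`
* `prescriptions(rx_id, patient_id, atc, date, episode_id?)`

Dates are date-precision only. Birth dates are deliberately coarsened
to year + quarter, as privacy-conscious registries export them; all age
logic therefore uses a **mid-quarter imputed birth date** (day 15 of the
quarter's middle month: Feb/May/Aug/Nov 15). This is the least-biased
deterministic choice: the imputation error is at most ±46 days and
symmetric for births uniform within a quarter.

## Cohort selection

A practice-year passes quality control iff `listed_patients ≥ 500`,
`registration_weeks ≥ 46` and `coded_fraction ≥ 0.70` (all inclusive).
A child enters the denominator population when it is aged 0–18 for some
part of its registration inside the study window (default
2002-01-01..2014-12-31). Exclusion is quality-first:

1. **quality** — none of the child's practice-years overlapping its
   registration passes (a `strict` switch instead excludes on any
   failing overlapping year);
2. **follow-up** — observed follow-up, `min(reg_end, window_end) −
   max(reg_start, window_start)`, is below 1095 days ("3 years" made
   unambiguous as calendar days).

A child failing both is counted once, under quality, so the categories
sum exactly to eligible − final. Attrition shares are reported against
the eligible count, rounded to one decimal.

## Episode reconstruction

Per child and disorder, all recorded episodes are merged into one
canonical record: the first-diagnosis date is the minimum start date (a
child is incident only once), and overlapping or abutting intervals are
unioned. An episode without a closing date is treated as open until the
end of the child's follow-up (`min(reg_end, window_end)`) under every
strategy — the permissive reading, flagged in the output header.

* **Strategy 1** accepts the merged record as is (evidence counts are
  recorded but not enforced).
* **Strategy 2** accepts iff the record has ≥2 episode-linked care
  events of any type *and* ≥2 prescriptions whose ATC code starts with a
  definition prefix (D07; R03; R01AC/R01AD/R06). Prescriptions are
  matched record-wide, not via episode links, because EHRs often fail to
  link repeat medication; an optional ±N-day window around the recorded
  intervals is available for sensitivity analyses. Prescription-type
  events count toward the contact criterion even when they correspond to
  the same dispensing counted as medication evidence; a
  `strict_contacts` flag demands two non-prescription contacts instead.
  Contacts are counted as records, not distinct dates. A rejected child
  stays in the population at risk (denominator only), and its case
  status is retrospective: validation anywhere in the record makes it a
  case on every reference date its recorded episode covers.
* **Strategies 3/4** replace the accepted intervals of 1/2 with a single
  interval from first diagnosis to follow-up end (never shortening
  coverage), which makes the Jan-1 estimator a cumulative incidence.
* **Atopic triad** — built only when all three disorders are accepted
  under the same strategy; starts at the earliest first diagnosis of any
  of the three and closes at the last recorded atopic contact (under the
  chronic strategies, at follow-up end).

## Prevalence estimation

For every January 1 in the window, the age-*a* denominator counts
children registered on that date (`reg_start ≤ d ≤ reg_end`) with
completed imputed age *a* ∈ 0..18; the numerator counts those whose
validated interval covers the date (closed interval on both ends).
Numerators and denominators are pooled over the thirteen reference dates
into one per-age curve (per-year output behind a flag). Ages with zero
denominator are reported as undefined (NaN), never 0%. Percentages are
rounded to one decimal, two for the triad (an order of magnitude
smaller). Denominator eligibility uses overall cohort membership; a
child need not yet have accrued its three follow-up years by a given
reference date.

Four ordering invariants hold by construction and are asserted
dataset-wide in the tests: s2 ≤ s1, s4 ≤ s3, s3 ≥ s1, s4 ≥ s2 at every
age and disorder.

## Co-occurrence and remission

Period case status (strategy 2 by default) marks each cohort child with
the subset of disorders for which it has ≥1 validated episode in the
window; the 8 Venn regions partition the cohort and each marginal equals
the sum of its four regions. The triad share expected under
independence is the product of the three marginal proportions; fold
enrichment is observed/expected, reported unrounded with the
integer-rounded headline alongside.

The remission rate at age *a* is `100·(S4 − S2)/S4` from the pooled
percentages at that age — the share of ever-validated children without
a currently open validated episode. The formula is an interpretation of
the strategy contrast: it is exact when the same children underlie both
curves, and it reproduces the published age-18 contrasts from their
printed inputs. It requires S2 ≤ S4, which the ordering invariant
guarantees; violating inputs raise an error rather than clamp.

## Synthetic registry generator

The generator emulates the *structure* and first-order statistics of a
national GP registry; it is the test bed for the pipeline, not a
demographic model of any real population.

Disease model: per child and disorder, first onset occurs at age `a`
with annual probability `incidence_hazards[disorder][a]` (defaults shaped
after the clinical course: eczema front-loaded in infancy, asthma mostly
pre-school, rhinitis accruing through school age, giving lifetime
cumulative incidences of roughly 15–25% by age 18). An open episode
closes with a constant annual remission hazard (defaults 0.25 / 0.15 /
0.08 for eczema / asthma / rhinitis, mirroring their relative tendencies
to remit) and may recur once (probability 0.3). A latent "atopy-prone"
stratum (default 10% of children, hazards ×3) induces the excess triple
co-occurrence seen in real cohorts; set the fraction to 0 for exactly
independent disorders. Onset is simulated from birth, but the GP
records an episode only from registration onward and only if it is still
open when observation begins — so the synthetic registry exhibits
left-truncation, exactly like real retrospective extracts.

Observation model: each open episode-year generates Poisson(2.5)
contacts; each contact after the diagnosis consultation dispenses
definition-matching medication with probability 0.6 (emitted **both** as
a prescription row and as a prescription-type care event — one
observation viewed through two tables — with 20% of prescription rows
left unlinked to their episode). Unrelated consultations occur for 77%
of children per year — the published contact frequency of Dutch general
practice — and irrelevant prescriptions at 0.8/patient-year. Practices
violate each quality criterion independently with probability 0.0125,
making roughly 4% of practices defective overall, in line with the small
quality-based attrition such registries report. Children enter late
with probability 0.25 and deregister at 3%/year. A simulated remission
closes the exported episode at the last contact date; an unremitted
episode exports an empty closing date, exercising the downstream
missing-closure rule.

Determinism: a single `numpy` generator seeded from the config drives
every draw in a fixed order; identical config + seed reproduces every
table byte for byte. A `generate_with_truth` variant also returns the
simulation ground truth (exact birth dates, true onset/remission dates)
for calibration tests only.

What passing on synthetic data does **not** show: the generator has no
free-text, no coding-style heterogeneity between practices, no
medication without diagnosis (the R03-without-R96 under-ascertainment
problem), no seasonality, and Dutch demography is reduced to uniform
birth dates — so the tests validate the estimators' logic and
calibration, not the clinical accuracy of the case definitions.

## Numerical and design choices

* Problem sizes: module tests use 1,200-child simulations; calibration
  and co-occurrence properties use 10,000 children (20 practices × 500),
  asserted within 3 Monte-Carlo standard errors of the closed forms
  (`1 − Π(1 − h(t))` for cumulative incidence; binomial SE for
  proportions; independence for fold enrichment).
* Hazard-recovery checks use hazards that vanish above a cutoff age so
  the closed-form plateau is exact at the measured ages, avoiding
  partial-year ambiguity on Jan-1 reference dates.
* Interval union treats abutting intervals (gap ≤ 1 day) as one; an
  open interval absorbs everything after its start.
* Rounding of reported integer percentages uses round-half-away-from-zero
  (`floor(x + 0.5)`), so e.g. a remission contrast of 89.58% prints 90%.
* The pipeline writes fixed-precision CSVs so identical runs diff clean;
  the run log carries timestamps and is excluded from byte comparisons.
* Strategy validation is retrospective over the whole record (no
  time-dependent case status), matching a correct-then-estimate design.

## Known limitations

* Year+quarter birth coarsening makes per-age denominators fuzzy by up
  to ±46 days around each birthday; at registry scale this averages out,
  at toy scale it can shift single children between adjacent ages.
* With whole-practice quality defects and few practices, the quality
  attrition share is lumpy (multiples of 1/n_practices).
* The cumulative curves of strategies 3/4 under-estimate true lifetime
  prevalence for children first observed after infancy (left-truncated
  histories) — visible in the synthetic study and intrinsic to
  retrospective registries with incomplete early-life coverage.
* Pooling calendar years assumes no secular trend; per-year output
  exists but no trend estimator is provided.
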
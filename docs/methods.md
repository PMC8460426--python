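# Methods

## Scope and model structure

`inhalerbim` is a deterministic, prevalence-based budget-impact model of
the clinician time needed to move asthma and COPD patients off pressurised
metered-dose inhalers (pMDIs) onto dry powder inhalers (DPIs). It costs
the *management* of the switch — invitations, counselling contacts, GP
escalations, follow-ups — from a payer perspective. Drug acquisition
costs, carbon accounting, clinical outcomes (exacerbations, disutility)
and multi-year phasing are deliberately out of scope.

The pipeline has two stages.

**Population estimation.** For each condition, patients = population ×
prevalence/100; an overlap correction removes the share of patients with
a concurrent diagnosis of the other condition so nobody is counted twice
(applied to asthma only in the baseline; the COPD register is left
intact, matching the convention of the reference tables). The adjusted
count is split into two device cohorts — pMDI-only users and mixed
pMDI+DPI users — either by usage fractions or by authoritative exact
counts, and every cell is rescaled to the target population by
`n_target / n_reference`. All intermediate values are floating-point;
integers exist only in the `displayed_count` column (round-half-up, the
convention under which 3 405 363.5 persons displays as 3 405 364).

**Costing.** A contact costs `duration/60 × hourly rate`; the rate is a
single pharmacist rate or a pharmacist/nurse blend (baseline: 25% × £54/h
+ 75% × £42/h = £45/h). A service model is a declarative spec: an initial
contact for everyone, an escalation pathway for a nonadherent fraction
(flat-rate GP consultation or a timed contact), and a planned follow-up
for an uptake fraction of all patients. Nonadherent patients are pooled
across conditions within each device cohort before the fraction is
applied; attributing them back to conditions is presentational only —
pooling is what the reference cohort tables do, and for linear costs the
two orders agree anyway up to rounding of displayed counts.

## Baseline inputs

The built-in baseline (`england_baseline()`) is the published England 2020
analysis this package re-implements:

| parameter | value | note |
|---|---|---|
| reference population | 56 287 000 | England, mid-2020 |
| target population | 50 000 | hypothetical primary care network (PCN) |
| asthma / COPD prevalence | 6.05% / 1.93% | QOF 2018/19 |
| asthma–COPD overlap | 14.8% | applied to asthma only |
| cohort counts (England) | 2 069 796 / 75 002 / 425 498 / 173 658 | authoritative exact counts |
| pharmacist / nurse rate | £54 / £42 per hour | PSSRU 2018/19 |
| GP consultation | £39.23 | flat rate, length unspecified |

The printed usage percentages (71/3/39/16) are rounded and do **not**
regenerate the printed cohort counts (2 901 370 × 0.71 ≠ 2 069 796), and
the unrounded fractions behind them are not recoverable, so the baseline
carries the counts themselves as `exact_counts`; fraction mode exists for
generalising to other populations. Currency is GBP 2018/19 throughout; no
inflation or discounting.

Six service models are configured. Model 1 (minimal service) costs the
switch letter as 5 minutes of pharmacist time per patient — the only
reading that reproduces the published £9 314 082 asthma line — with
0/20/40% of patients (variants 1/1a/1b) escalating to a GP consultation.
Model 2a is a 10-minute blended contact: the reference input table says
5 minutes, but the published cost table is headed "10 minutes" and only
10 min × £45/h matches its cells, so 10 minutes is the baseline (5 is one
config edit away). Model 2b adds a 15-minute follow-up for 60% of
patients. Model 3 is a 15-minute blended contact plus a 15-minute
follow-up for everyone; its tabulated 10% nonadherence feeds no cost
because no escalation pathway is specified for it.

## Totaling conventions

The published grand totals contain two internal inconsistencies, so every
report carries a named convention:

* `corrected` — each component (initial, escalation, follow-up) summed
  exactly once, rounded once at the end.
* `as_published` — reproduces the published headline totals: Model 2b's
  total adds the initial contacts twice (its follow-up sub-table repeats
  them and is then added to Model 2a's total), and Model 3's total
  contains only the initial contacts even though follow-up columns are
  tabulated. These quirks are declared per model spec
  (`published_double_counts_initial`, `published_excludes_followup`), not
  inferred from ids; for models without quirks the conventions coincide.

Under `corrected`, Model 2b costs £34 734 per PCN (not £53 015) and
Model 3 £54 843 (not £27 422). Whether the Model 3 omission was
intentional cannot be determined from the source tables; both numbers are
first-class outputs. One further discrepancy: the Model 2a England total
appears as 20 597 654 in its table but 20 579 654 in the accompanying
text; the component sum supports the text value, which is the reference
used here.

## Numerical choices

* Round-half-up (via `decimal` on the value's shortest repr) for all
  display: persons and pounds to integers, percentages to 2 dp. Built-in
  banker's rounding would display 3 405 363.5 as 3 405 364 too, but fails
  on e.g. 2.5 → 2; financial tables round halves up.
* No rounded value is ever fed back into arithmetic; a test asserts the
  target-geography cells equal the exact product chain to 1e-12 relative.
* Reproduction tolerance: a recomputed cell passes at
  max(5 £/persons, 1e-5 relative) against its published value. The
  pipeline is exact; the slack absorbs the reference tables' own rounding
  of intermediate counts (observed deviations ≤ £3).
* Degenerate inputs: zero prevalence, zero durations or zero fractions
  flow through to £0 totals; validation rejects only inadmissible values
  (negative rates, fractions outside [0,1], usage fractions summing
  past 1, a follow-up uptake without a follow-up contact).
* Percentage increase between two totals is computed on unrounded totals
  and rounded half-up to an integer percent.

## Synthetic scenario generator

`generate_scenarios(seed, n)` draws admissible configurations for
property testing: reference population log-uniform on 10⁴–10⁸ and target
population log-uniform between 10³ and the reference; prevalence 0.1–20%;
overlap 0–50%; usage fractions jointly ≤ 1; hourly rates and the GP rate
£20–£100; contact durations 0–60 min; behavioural fractions 0–1; one to
four service models with random delivery mixes, escalation pathways,
follow-ups and published-quirk flags. Ranges bracket the baseline by
roughly an order of magnitude each way. Draws use
`numpy.random.SeedSequence` spawning, each sample recording the child
seed that regenerates it; identical seeds give bit-identical serialised
configs across processes. Drawn values are rounded to 4 decimals purely
for readable YAML.

The generator emulates the *structure* of real inputs, not their joint
distribution: parameters are drawn independently, populations are not
age-structured, and nonadherence is a deterministic fraction rather than
patient-level behaviour. Passing property suites therefore demonstrates
the pipeline's algebraic correctness (linearity, monotonicity,
per-patient additivity, scale invariance) over the admissible input
space, not calibration to any real system.

## Verification

The test suite checks, per module, the worked single-operation values and
validation behaviour; property tests (hypothesis, derandomised) cover
homogeneity of degree 1 in populations and cohort counts, monotonicity in
every rate, duration and fraction, commutativity of scaling with usage
segmentation, and exact target/reference ratio invariance. An independent
per-patient oracle — a literal loop adding each patient's contacts one at
a time, with escalation allocated as count × fraction — agrees with the
closed-form aggregate to 1e-6 relative over 100 random scenarios with
small integer cohorts (≤ 500 per cell, chosen so enumeration stays a
genuine per-patient loop at a few seconds' cost). The full suite runs in
a few seconds on one CPU.

## Limitations

Deterministic only: no probabilistic sensitivity analysis, no
distributions over inputs. Single-year, single-payer perspective; no
phasing, no age/sex stratification, no diagnosed-vs-true prevalence
correction, and no downstream costs of inhaler-technique errors or
exacerbations. The `as_published` convention intentionally reproduces
internally inconsistent totals; use `corrected` for any decision-facing
arithmetic.
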
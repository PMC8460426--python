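# inhalerbim

A deterministic budget-impact model of switching asthma and COPD patients
from pressurised metered-dose inhalers (pMDIs, which use high
global-warming-potential propellants) to propellant-free dry powder
inhalers (DPIs) in English primary care. It is written for health
economists and medicines-optimisation teams who need to cost the *service*
side of an environmentally driven device switch — the clinician time spent
inviting, counselling and following up patients — rather than drug
acquisition costs, which are out of scope.

## The model

The target population is estimated by a prevalence chain carried at full
floating-point precision, with rounding applied only for display
(half-up):

```
patients      = N · p/100                  population × prevalence
adjusted      = patients · (1 − v/100)     remove asthma–COPD dual diagnoses
cohort        = adjusted · f  (or exact authoritative counts)
target cohort = cohort · n_target / N      per-capita scaling, e.g. to a
                                           50 000-patient primary care network
```

Costs are time-driven: a patient contact costs `d/60 · r`, where `d` is
its duration in minutes and `r` either a single pharmacist hourly rate or
a staff-mix blend `w_ph·r_ph + w_nu·r_nu`. A service model combines an
initial contact for every in-scope patient, optional escalation of a
nonadherent fraction `q` (pooled across conditions within each device
cohort) to a flat-rate GP consultation or a timed follow-up, and an
optional planned follow-up for an uptake fraction `u` of all patients:

```
total = Σ_cohorts n·c_initial + Σ_device q·n_pooled·c_esc + Σ_cohorts u·n·c_followup
```

Grand totals support two conventions: `corrected` counts every component
once; `as_published` reproduces the totaling quirks of the published
baseline tables (one model double-counts initial contacts in its headline
total, another omits its follow-up costs). Everything is linear in the
cohort counts, so totals scale exactly with population size.

## Worked example

```python
from inhalerbim import england_baseline

config = england_baseline().config        # built-in England 2020 baseline
cohorts = config.cohort_table()
print(cohorts.displayed("asthma", "pmdi_only", "target"))   # 1839
for model_id in ("1", "1a", "1b", "2a", "2b", "3"):
    print(model_id, config.run_model(model_id, "target").grand_total)
```

prints

```
1839
1 10969
1a 30093
1b 49217
2a 18281
2b 53015
3 27422
```

i.e. a 50 000-patient primary care network holds about 1839 pMDI-only
asthma patients, and managing the switch costs it between £10 969 (a
mailed invitation that every patient accepts) and £53 015 (opportunistic
counselling with a 15-minute follow-up for 60% of patients), with the
dedicated gold-standard service at £27 422. The same runs with
`geography="reference"` give the England-wide figures (£12.3m–£59.7m).

The `examples/` directory holds one short script per capability —
population estimation, service-model costing, one-way sensitivity sweeps
and random scenario generation — and `examples/england_baseline.yaml` is
the baseline configuration in the YAML dialect the pipeline reads, for use
with the thin CLI:

```
inhaler-bim run --config examples/england_baseline.yaml --model 2b --geography target
inhaler-bim sweep --param models.1a.nonadherent_fraction --grid 0,0.2,0.4 --model 1a
inhaler-bim reproduce
```

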
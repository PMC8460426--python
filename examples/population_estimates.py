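"""Estimate the inhaler-switch target population for England and a PCN.

Builds the baseline scenario (England mid-2020 population, QOF asthma/COPD
prevalences, 14.8% asthma–COPD overlap, authoritative inhaler-usage cohort
counts) and prints the cohort table. The counts are the number of patients
whose pressurised metered-dose inhalers would be in scope for a switch to
dry powder inhalers: roughly 2.74 million people in England, of whom a
50 000-patient primary care network's share is about 2 437.
"""

from inhalerbim import england_baseline, render_tables

config = england_baseline().config
cohorts = config.cohort_table()

print(render_tables(cohorts))
print(f"Patients in scope, England: {round(cohorts.total('reference')):,}")
print(f"Patients in scope, 50k PCN: {round(cohorts.total('target')):,}")
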
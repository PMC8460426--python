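"""Cost every service model for managing the pMDI-to-DPI switch.

Prints the grand total of each configured service model for England and
for a 50 000-patient primary care network, under its published totaling
convention and under the corrected convention (each cost component counted
exactly once). The two differ only for the models whose published totals
double-count initial contacts (2b) or omit follow-up (3).
"""

from inhalerbim import england_baseline

config = england_baseline().config

print(f"{'model':<6}{'England (£)':>14}{'PCN (£)':>10}{'PCN corrected (£)':>19}")
for spec in config.models:
    england = config.run_model(spec.model_id, "reference").grand_total
    pcn = config.run_model(spec.model_id, "target").grand_total
    corrected = config.run_model(spec.model_id, "target", convention="corrected").grand_total
    print(f"{spec.model_id:<6}{england:>14,}{pcn:>10,}{corrected:>19,}")

print(
    "\nEach row is one way of managing the switch, from a mailed invitation"
    "\n(1, with 0/20/40% of patients escalating to a GP consultation in"
    "\n1/1a/1b) to a dedicated appointment plus follow-up for everyone (3)."
)
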
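"""One-way sensitivity of minimal-service costs to patient nonadherence.

Sweeps the fraction of patients who reject the mailed switch and request a
GP consultation, and prints the PCN grand total at each point. Moving from
20% to 40% nonadherence raises management costs by about two thirds —
escalation, not the initial contact, dominates the budget.
"""

from inhalerbim import england_baseline, one_way_sweep, percentage_increase

config = england_baseline().config
grid = [0.0, 0.1, 0.2, 0.3, 0.4]
result = one_way_sweep(
    config, "models.1a.nonadherent_fraction", grid, model_id="1a", geography="target"
)

for _, row in result.iterrows():
    print(f"nonadherent {row['value']:>4.0%}: £{int(row['grand_total']):,}")

at_20 = result.loc[result["value"] == 0.2, "grand_total_unrounded"].item()
at_40 = result.loc[result["value"] == 0.4, "grand_total_unrounded"].item()
print(f"20% -> 40% increase: {percentage_increase(at_20, at_40)}%")
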
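"""Generate random admissible scenarios and cost them.

Draws three scenario configurations from the documented parameter ranges
(population, prevalences, usage fractions, staff rates, model structure)
and prints each model's target-population grand total. The draws are
seeded, so rerunning this script reproduces the same numbers; they stress
the pipeline's invariants rather than describe any real population.
"""

from inhalerbim import generate_scenarios

for sample in generate_scenarios(seed=2026, n=3):
    config = sample.config
    pop = config.population
    print(
        f"scenario seed={sample.seed}: reference population "
        f"{pop.reference_population:,.0f}, target {pop.target_population:,.0f}"
    )
    for spec in config.models:
        total = config.run_model(spec.model_id, "target").grand_total
        print(f"  model {spec.model_id}: £{total:,}")
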
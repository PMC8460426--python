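"""Scenario fixtures: the England 2020 baseline and random admissible inputs.

``england_baseline`` returns the fully specified baseline scenario this
package re-implements: the June 2020 England population, QOF 2018/19
asthma and COPD prevalences, the 14.8% asthma–COPD overlap correction,
authoritative inhaler-usage cohort counts, 2018/19 PSSRU staff rates and
the six published service-model variants, evaluated for a hypothetical
50 000-patient primary care network and for England as a whole.

``generate_scenarios`` draws random but admissible scenario configurations
from documented parameter ranges (each bracketing the baseline by roughly
an order of magnitude). They exist to exercise the pipeline's invariants —
linearity, monotonicity, per-patient additivity — over diverse inputs, not
to represent any real population.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Literal

import numpy as np

from .config import ScenarioConfig

#: Admissible ranges for randomly generated scenarios.
RANGES = {
    "reference_population": (1e4, 1e8),   # log-uniform
    "prevalence_pct": (0.1, 20.0),
    "overlap_pct": (0.0, 50.0),
    "rate_per_hour": (20.0, 100.0),       # pharmacist, nurse hourly
    "gp_per_consultation": (20.0, 100.0),
    "duration_min": (0.0, 60.0),
}


@dataclass(frozen=True)
class ScenarioSample:
    """A scenario configuration together with its provenance."""

    config: ScenarioConfig
    seed: int | None
    provenance: Literal["baseline_published", "random"]

    def save(self, path) -> None:
        """Write the config in the same YAML/JSON dialect the pipeline reads."""
        self.config.save(path)


def england_baseline() -> ScenarioSample:
    """The published England/PCN baseline scenario, exactly as tabulated."""
    config = ScenarioConfig.model_validate(
        {
            "population": {
                "reference_population": 56_287_000,  # England, mid-2020
                "target_population": 50_000,         # hypothetical PCN
            },
            "epidemiology": {
                "asthma": {"prevalence_pct": 6.05, "overlap_pct": 14.8},
                "copd": {"prevalence_pct": 1.93, "overlap_pct": 0.0},
            },
            "usage": {
                # Printed percentages are rounded; the authoritative cohort
                # counts are supplied as exact_counts and take precedence.
                "asthma": {
                    "pmdi_only_fraction": 0.71,
                    "pmdi_and_dpi_fraction": 0.03,
                    "exact_counts": {"pmdi_only": 2_069_796, "pmdi_and_dpi": 75_002},
                },
                "copd": {
                    "pmdi_only_fraction": 0.39,
                    "pmdi_and_dpi_fraction": 0.16,
                    "exact_counts": {"pmdi_only": 425_498, "pmdi_and_dpi": 173_658},
                },
            },
            "rates": {
                "pharmacist_per_hour": 54.00,
                "nurse_per_hour": 42.00,
                "gp_per_consultation": 39.23,
            },
            "models": _baseline_models(),
        }
    )
    return ScenarioSample(config=config, seed=None, provenance="baseline_published")


def _baseline_models() -> list[dict]:
    blended = {"pharmacist_fraction": 0.25, "nurse_fraction": 0.75}
    minimal = {
        # Minimal service: the switch letter is costed as 5 minutes of
        # pharmacist time per patient; nonadherent patients escalate to a
        # flat-rate GP consultation.
        "initial_contact": {"duration_min": 5, "delivery": "pharmacist"},
        "escalation": "gp_consultation",
        "totaling_convention": "as_published",
    }
    return [
        {"model_id": "1", "nonadherent_fraction": 0.0, **minimal},
        {"model_id": "1a", "nonadherent_fraction": 0.20, **minimal},
        {"model_id": "1b", "nonadherent_fraction": 0.40, **minimal},
        {
            # Opportunistic switch during the annual review: 10 minutes of
            # blended pharmacist/nurse time per patient.
            "model_id": "2a",
            "initial_contact": {"duration_min": 10, "delivery": blended},
            "totaling_convention": "as_published",
        },
        {
            # 2a plus a 15-minute follow-up for 60% of patients. The
            # published grand total adds the initial contacts twice.
            "model_id": "2b",
            "initial_contact": {"duration_min": 10, "delivery": blended},
            "followup_uptake": 0.60,
            "followup_contact": {"duration_min": 15, "delivery": blended},
            "totaling_convention": "as_published",
            "published_double_counts_initial": True,
        },
        {
            # Gold standard: 15-minute dedicated appointment for everyone
            # plus a 15-minute follow-up (uptake 1). The published grand
            # total contains the initial contacts only. The tabulated 10%
            # nonadherence drives no cost (no escalation pathway).
            "model_id": "3",
            "initial_contact": {"duration_min": 15, "delivery": blended},
            "nonadherent_fraction": 0.10,
            "followup_uptake": 1.0,
            "followup_contact": {"duration_min": 15, "delivery": blended},
            "totaling_convention": "as_published",
            "published_excludes_followup": True,
        },
    ]


def _round4(x: float) -> float:
    return float(np.round(x, 4))


def _random_contact(rng: np.random.Generator) -> dict:
    duration = _round4(rng.uniform(*RANGES["duration_min"]))
    if rng.random() < 0.5:
        return {"duration_min": duration, "delivery": "pharmacist"}
    p = _round4(rng.uniform(0, 1))
    return {
        "duration_min": duration,
        "delivery": {"pharmacist_fraction": p, "nurse_fraction": _round4(1 - p)},
    }


def _random_model(rng: np.random.Generator, model_id: str) -> dict:
    spec: dict = {
        "model_id": model_id,
        "initial_contact": _random_contact(rng),
        "totaling_convention": "as_published" if rng.random() < 0.5 else "corrected",
    }
    escalation_kind = rng.choice(["none", "gp_consultation", "contact"])
    if escalation_kind != "none":
        spec["nonadherent_fraction"] = _round4(rng.uniform(0, 1))
        spec["escalation"] = (
            "gp_consultation" if escalation_kind == "gp_consultation"
            else _random_contact(rng)
        )
    if rng.random() < 0.5:
        spec["followup_uptake"] = _round4(rng.uniform(0, 1))
        spec["followup_contact"] = _random_contact(rng)
        spec["published_double_counts_initial"] = bool(rng.random() < 0.25)
        spec["published_excludes_followup"] = bool(rng.random() < 0.25)
    return spec


def _random_config(rng: np.random.Generator) -> ScenarioConfig:
    lo, hi = RANGES["reference_population"]
    reference = float(np.round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
    target = float(np.round(np.exp(rng.uniform(np.log(1e3), np.log(reference)))))

    epidemiology, usage = {}, {}
    for condition in ("asthma", "copd"):
        epidemiology[condition] = {
            "prevalence_pct": _round4(rng.uniform(*RANGES["prevalence_pct"])),
            "overlap_pct": _round4(rng.uniform(*RANGES["overlap_pct"])),
        }
        f1 = _round4(rng.uniform(0, 1))
        f2 = _round4(rng.uniform(0, 1 - f1))
        if f1 + f2 > 1:
            f2 = _round4(1 - f1)
        usage[condition] = {"pmdi_only_fraction": f1, "pmdi_and_dpi_fraction": f2}

    n_models = int(rng.integers(1, 5))
    return ScenarioConfig.model_validate(
        {
            "population": {"reference_population": reference, "target_population": target},
            "epidemiology": epidemiology,
            "usage": usage,
            "rates": {
                "pharmacist_per_hour": _round4(rng.uniform(*RANGES["rate_per_hour"])),
                "nurse_per_hour": _round4(rng.uniform(*RANGES["rate_per_hour"])),
                "gp_per_consultation": _round4(rng.uniform(*RANGES["gp_per_consultation"])),
            },
            "models": [_random_model(rng, f"m{i + 1}") for i in range(n_models)],
        }
    )


def generate_scenarios(seed: int, n: int) -> List[ScenarioSample]:
    """Draw ``n`` admissible random scenarios, reproducibly for a given seed.

    Each sample records the child seed that produced it, so any single
    scenario can be regenerated in isolation.
    """
    if n < 0:
        raise ValueError(f"n must be nonnegative, got {n}")
    root = np.random.SeedSequence(seed)
    samples = []
    for child in root.spawn(n):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(child_seed)
        samples.append(
            ScenarioSample(config=_random_config(rng), seed=child_seed, provenance="random")
        )
    return samples
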
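"""Prevalence-based estimation of the inhaler-switch target population.

This module turns a reference population, condition prevalences, an
asthma–COPD overlap correction and inhaler-usage data into unrounded patient
counts per condition (asthma, COPD), device cohort (pMDI-only users, mixed
pMDI+DPI users) and geography (the national reference population and a
scaled-down target population such as a 50 000-patient primary care
network).

The calculation chain is::

    patients   = population x prevalence/100
    adjusted   = patients x (1 - overlap/100)      # remove dual diagnoses
    cohort     = adjusted x usage_fraction         # or authoritative counts
    target row = reference row x target/reference  # per-capita scaling

Every quantity is carried at full precision; integers appear only in the
``displayed_count`` column (round-half-up). Usage data may be supplied
either as fractions of the adjusted condition population or as exact
authoritative cohort counts, which take precedence — published cohort
counts are usually derived from sources with more precision than the
percentages printed alongside them.
"""

from __future__ import annotations

import math
from typing import Dict, Literal, Mapping, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .rounding import display_persons

Condition = Literal["asthma", "copd"]
Cohort = Literal["pmdi_only", "pmdi_and_dpi"]
Geography = Literal["reference", "target"]

CONDITIONS: tuple[Condition, ...] = ("asthma", "copd")
COHORTS: tuple[Cohort, ...] = ("pmdi_only", "pmdi_and_dpi")
GEOGRAPHIES: tuple[Geography, ...] = ("reference", "target")


class PopulationFrame(BaseModel):
    """Reference (national) and target (e.g. PCN) population sizes."""

    model_config = ConfigDict(frozen=True)

    reference_population: float = Field(gt=0, description="persons")
    target_population: float = Field(gt=0, description="persons")

    @property
    def scaling_ratio(self) -> float:
        """target / reference; multiplies any reference count to its target equivalent."""
        ratio = self.target_population / self.reference_population
        if not math.isfinite(ratio) or ratio <= 0:
            raise ValueError("scaling ratio must be finite and positive")
        return ratio


class ConditionEpidemiology(BaseModel):
    """Prevalence and dual-diagnosis overlap for one condition.

    ``overlap_pct`` is the share of this condition's patients who also carry
    a diagnosis of the other condition and must be removed once to avoid
    double counting (the overlap-syndrome correction). Conventionally the
    correction is applied to asthma only, so a COPD block has overlap 0.
    """

    model_config = ConfigDict(frozen=True)

    prevalence_pct: float = Field(ge=0, le=100)
    overlap_pct: float = Field(default=0.0, ge=0, le=100)


class ExactCounts(BaseModel):
    """Authoritative reference-geography cohort counts, overriding fractions."""

    model_config = ConfigDict(frozen=True)

    pmdi_only: float = Field(ge=0)
    pmdi_and_dpi: float = Field(ge=0)


class UsageSplit(BaseModel):
    """How one condition's patients divide across inhaler-device cohorts."""

    model_config = ConfigDict(frozen=True)

    pmdi_only_fraction: float = Field(ge=0, le=1)
    pmdi_and_dpi_fraction: float = Field(ge=0, le=1)
    exact_counts: Optional[ExactCounts] = None

    @model_validator(mode="after")
    def _fractions_sum_at_most_one(self) -> "UsageSplit":
        total = self.pmdi_only_fraction + self.pmdi_and_dpi_fraction
        if total > 1 + 1e-12:
            raise ValueError(
                f"usage fractions sum to {total:.6g}; must not exceed 1"
            )
        return self


class EpidemiologyInputs(BaseModel):
    """The epidemiology block of a scenario: populations, prevalences, usage."""

    model_config = ConfigDict(frozen=True)

    population: PopulationFrame
    epidemiology: Mapping[Condition, ConditionEpidemiology]
    usage: Mapping[Condition, UsageSplit]

    @model_validator(mode="after")
    def _conditions_match(self) -> "EpidemiologyInputs":
        if set(self.epidemiology) != set(self.usage):
            raise ValueError(
                "epidemiology and usage must cover the same conditions; "
                f"got {sorted(self.epidemiology)} vs {sorted(self.usage)}"
            )
        return self


def _check_pct(name: str, value: float) -> None:
    if not 0 <= value <= 100:
        raise ValueError(f"{name} must lie in [0, 100], got {value!r}")


def adjusted_prevalence(prevalence_pct: float, overlap_pct: float) -> float:
    """Prevalence net of the dual-diagnosis overlap, in percent.

    ``prevalence x (1 - overlap/100)``, full precision. Display with
    :func:`inhalerbim.rounding.display_percent`.
    """
    _check_pct("prevalence_pct", prevalence_pct)
    _check_pct("overlap_pct", overlap_pct)
    return prevalence_pct * (1 - overlap_pct / 100)


def patient_count(population: float, prevalence_pct: float) -> float:
    """Unrounded number of patients: population x prevalence/100."""
    if population <= 0:
        raise ValueError(f"population must be positive, got {population!r}")
    _check_pct("prevalence_pct", prevalence_pct)
    return population * prevalence_pct / 100


def apply_overlap(count: float, overlap_pct: float) -> float:
    """Remove the dual-diagnosis share from an unrounded patient count."""
    if count < 0:
        raise ValueError(f"count must be nonnegative, got {count!r}")
    _check_pct("overlap_pct", overlap_pct)
    return count * (1 - overlap_pct / 100)


def scale_count(count: float, frame: PopulationFrame) -> float:
    """Rescale a reference-geography count to the target population."""
    return count * frame.scaling_ratio


def segment_by_usage(adjusted_count: float, usage: UsageSplit) -> Dict[Cohort, float]:
    """Split an adjusted condition count into device cohorts (reference geography).

    Exact authoritative counts, when present, are used verbatim; otherwise
    each cohort is ``adjusted_count x fraction``.
    """
    if usage.exact_counts is not None:
        return {
            "pmdi_only": usage.exact_counts.pmdi_only,
            "pmdi_and_dpi": usage.exact_counts.pmdi_and_dpi,
        }
    return {
        "pmdi_only": adjusted_count * usage.pmdi_only_fraction,
        "pmdi_and_dpi": adjusted_count * usage.pmdi_and_dpi_fraction,
    }


class CohortTable:
    """Unrounded patient counts keyed by (condition, cohort, geography).

    Thin wrapper around a tidy :class:`pandas.DataFrame` with columns
    ``condition, cohort, geography, unrounded_count, displayed_count``.
    ``displayed_count`` is round-half-up of the unrounded value and is never
    used in downstream arithmetic.
    """

    def __init__(self, counts: Mapping[tuple[Condition, Cohort, Geography], float]):
        for key, value in counts.items():
            if value < 0:
                raise ValueError(f"negative cohort count for {key}: {value!r}")
        self._counts = dict(counts)

    @classmethod
    def from_reference_counts(
        cls,
        reference_counts: Mapping[tuple[Condition, Cohort], float],
        frame: PopulationFrame,
    ) -> "CohortTable":
        """Build both geographies from reference counts and a population frame."""
        counts: Dict[tuple[Condition, Cohort, Geography], float] = {}
        for (condition, cohort), value in reference_counts.items():
            counts[(condition, cohort, "reference")] = value
            counts[(condition, cohort, "target")] = scale_count(value, frame)
        return cls(counts)

    def count(self, condition: Condition, cohort: Cohort, geography: Geography) -> float:
        """Full-precision count for one cell."""
        return self._counts[(condition, cohort, geography)]

    def displayed(self, condition: Condition, cohort: Cohort, geography: Geography) -> int:
        return display_persons(self.count(condition, cohort, geography))

    def conditions(self) -> list[Condition]:
        return sorted({key[0] for key in self._counts})

    def cohort_total(self, cohort: Cohort, geography: Geography) -> float:
        """Count pooled across conditions within one device cohort."""
        return sum(
            value
            for (cond, coh, geo), value in self._counts.items()
            if coh == cohort and geo == geography
        )

    def total(self, geography: Geography) -> float:
        return sum(
            value for (_, _, geo), value in self._counts.items() if geo == geography
        )

    def scaled(self, factor: float) -> "CohortTable":
        """A new table with every count multiplied by ``factor``."""
        if factor < 0:
            raise ValueError("scale factor must be nonnegative")
        return CohortTable({key: value * factor for key, value in self._counts.items()})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "condition": condition,
                "cohort": cohort,
                "geography": geography,
                "unrounded_count": value,
                "displayed_count": display_persons(value),
            }
            for (condition, cohort, geography), value in sorted(self._counts.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["condition", "cohort", "geography", "unrounded_count", "displayed_count"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def __iter__(self):
        return iter(sorted(self._counts.items()))

    def __len__(self) -> int:
        return len(self._counts)


def build_cohort_table(inputs: EpidemiologyInputs) -> CohortTable:
    """Run the full chain: prevalence -> overlap -> usage split -> scaling."""
    reference_counts: Dict[tuple[Condition, Cohort], float] = {}
    for condition, epi in inputs.epidemiology.items():
        raw = patient_count(inputs.population.reference_population, epi.prevalence_pct)
        adjusted = apply_overlap(raw, epi.overlap_pct)
        for cohort, value in segment_by_usage(adjusted, inputs.usage[condition]).items():
            reference_counts[(condition, cohort)] = value
    return CohortTable.from_reference_counts(reference_counts, inputs.population)
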
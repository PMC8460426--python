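"""Service-model costing for an inhaler device switch.

Given a cohort table of patients to be switched, staff unit costs and a
declarative service-model specification, this module computes the cost of
managing the transition. Three families of service model are supported:

* a *minimal service* — a letter inviting the switch, costed as a short
  pharmacist contact per patient, with a fraction of nonadherent patients
  escalating to a GP consultation;
* an *opportunistic* switch — counselling folded into the annual review,
  delivered by a pharmacist/practice-nurse mix, optionally followed by a
  follow-up appointment for a fraction of patients;
* a *gold standard* — a dedicated blended-staff appointment for every
  patient plus a follow-up.

Costs are time-driven: a contact costs ``duration/60 x hourly rate``, where
the rate is either a single pharmacist rate or a staff-mix-weighted blend.
GP escalation is a flat per-consultation charge. Nonadherent patients are
pooled across conditions within each device cohort before escalation is
costed; the per-condition split is presentational only.

Two grand-totaling conventions are provided. ``corrected`` sums every cost
component exactly once. ``as_published`` reproduces the totaling quirks
found in published versions of this analysis, declared per model spec:
a model may double-count its initial contacts in the headline total
(``published_double_counts_initial``) or omit its follow-up costs from it
(``published_excludes_followup``). For models without such quirks the two
conventions coincide.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import List, Literal, Optional, Sequence, Tuple, Union

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .epidemiology import COHORTS, Cohort, CohortTable, Geography
from .rounding import display_currency, display_persons

Convention = Literal["as_published", "corrected"]


class StaffRates(BaseModel):
    """Unit costs of the staff who deliver the switch (GBP, 2018/19 pay rates)."""

    model_config = ConfigDict(frozen=True)

    pharmacist_per_hour: float = Field(gt=0)
    nurse_per_hour: float = Field(gt=0)
    gp_per_consultation: float = Field(gt=0)


class StaffMix(BaseModel):
    """Share of contacts delivered by pharmacist vs practice nurse."""

    model_config = ConfigDict(frozen=True)

    pharmacist_fraction: float = Field(ge=0, le=1)
    nurse_fraction: float = Field(ge=0, le=1)

    @model_validator(mode="after")
    def _sums_to_one(self) -> "StaffMix":
        if abs(self.pharmacist_fraction + self.nurse_fraction - 1) > 1e-9:
            raise ValueError("staff-mix fractions must sum to 1")
        return self


class ContactSpec(BaseModel):
    """One patient contact: its length and who delivers it.

    ``delivery`` is the literal ``"pharmacist"`` for a single-staff contact
    or a :class:`StaffMix` for a blended one.
    """

    model_config = ConfigDict(frozen=True)

    duration_min: float = Field(ge=0)
    delivery: Union[Literal["pharmacist"], StaffMix] = "pharmacist"

    @model_validator(mode="after")
    def _finite_duration(self) -> "ContactSpec":
        if not math.isfinite(self.duration_min):
            raise ValueError("duration_min must be finite")
        return self


class ServiceModelSpec(BaseModel):
    """Declarative description of one switch-management scenario."""

    model_config = ConfigDict(frozen=True, protected_namespaces=())

    model_id: str
    initial_contact: ContactSpec
    #: Fraction of switched patients who do not accept the switch and
    #: require an extra clinician contact.
    nonadherent_fraction: float = Field(default=0.0, ge=0, le=1)
    #: What the extra contact is: nothing, a flat-rate GP consultation, or a
    #: timed follow-up contact (single-staff or blended).
    escalation: Union[Literal["none", "gp_consultation"], ContactSpec] = "none"
    #: Fraction of all switched patients who receive a planned follow-up.
    followup_uptake: float = Field(default=0.0, ge=0, le=1)
    followup_contact: Optional[ContactSpec] = None
    totaling_convention: Convention = "corrected"
    #: as_published quirks (see module docstring).
    published_double_counts_initial: bool = False
    published_excludes_followup: bool = False

    @model_validator(mode="after")
    def _consistent(self) -> "ServiceModelSpec":
        if self.followup_uptake > 0 and self.followup_contact is None:
            raise ValueError(
                f"model {self.model_id!r}: followup_uptake > 0 requires followup_contact"
            )
        return self


@dataclass(frozen=True)
class CostLine:
    """One unrounded cost component for one cohort cell."""

    geography: Geography
    condition: str
    cohort: Cohort
    component: Literal["initial_counselling", "followup_counselling", "escalation"]
    cost: float

    @property
    def displayed(self) -> int:
        return display_currency(self.cost)


def blended_hourly_rate(mix: StaffMix, rates: StaffRates) -> float:
    """Staff-mix-weighted hourly cost in GBP/h."""
    return (
        mix.pharmacist_fraction * rates.pharmacist_per_hour
        + mix.nurse_fraction * rates.nurse_per_hour
    )


def per_patient_contact_cost(contact: ContactSpec, rates: StaffRates) -> float:
    """Cost of one contact: duration in hours times the delivering rate."""
    if contact.delivery == "pharmacist":
        rate = rates.pharmacist_per_hour
    else:
        rate = blended_hourly_rate(contact.delivery, rates)
    return contact.duration_min / 60 * rate


def counselling_costs(
    cohorts: CohortTable,
    contact: ContactSpec,
    rates: StaffRates,
    geography: Geography,
    component: Literal["initial_counselling", "followup_counselling"] = "initial_counselling",
    uptake: float = 1.0,
) -> List[CostLine]:
    """Per-cohort contact costs: count x uptake x per-patient cost."""
    unit = per_patient_contact_cost(contact, rates)
    return [
        CostLine(geography, condition, cohort, component, count * uptake * unit)
        for (condition, cohort, geo), count in cohorts
        if geo == geography
    ]


def nonadherent_counts(
    cohorts: CohortTable, fraction: float, geography: Geography
) -> dict[Cohort, float]:
    """Nonadherent patients per device cohort, pooled across conditions.

    Pooling (asthma + COPD within a cohort, then the fraction) is the
    convention used in published cohort tables; attributing nonadherence
    back to individual conditions is display-only.
    """
    if not 0 <= fraction <= 1:
        raise ValueError(f"nonadherent fraction must lie in [0, 1], got {fraction!r}")
    return {
        cohort: fraction * cohorts.cohort_total(cohort, geography)
        for cohort in COHORTS
    }


def escalation_cost(count: float, spec: ServiceModelSpec, rates: StaffRates) -> float:
    """Cost of the extra contacts for ``count`` nonadherent patients."""
    if spec.escalation == "none":
        raise ValueError(
            f"model {spec.model_id!r} has no escalation pathway configured"
        )
    if spec.escalation == "gp_consultation":
        return count * rates.gp_per_consultation
    return count * per_patient_contact_cost(spec.escalation, rates)


def followup_costs(
    cohorts: CohortTable,
    uptake: float,
    followup_contact: ContactSpec,
    rates: StaffRates,
    geography: Geography,
) -> List[CostLine]:
    """Planned follow-up costs: count x uptake x per-patient follow-up cost."""
    if not 0 <= uptake <= 1:
        raise ValueError(f"followup uptake must lie in [0, 1], got {uptake!r}")
    return counselling_costs(
        cohorts, followup_contact, rates, geography,
        component="followup_counselling", uptake=uptake,
    )


@dataclass
class CostReport:
    """Per-cohort cost lines and totals for one model run.

    ``grand_total_unrounded`` follows the report's totaling convention;
    displayed values are round-half-up to the nearest pound.
    """

    model_id: str
    geography: Geography
    convention: Convention
    lines: List[CostLine]
    nonadherent: dict[Cohort, float] = field(default_factory=dict)
    grand_total_unrounded: float = 0.0

    @property
    def grand_total(self) -> int:
        return display_currency(self.grand_total_unrounded)

    def component_total(self, component: str) -> float:
        return sum(line.cost for line in self.lines if line.component == component)

    def cohort_subtotal(self, cohort: Cohort) -> float:
        """All components for one device cohort, each counted once."""
        return sum(line.cost for line in self.lines if line.cohort == cohort)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "model": self.model_id,
                "geography": line.geography,
                "condition": line.condition,
                "cohort": line.cohort,
                "component": line.component,
                "unrounded": line.cost,
                "displayed": line.displayed,
            }
            for line in self.lines
        ]
        for cohort, count in sorted(self.nonadherent.items()):
            rows.append(
                {
                    "model": self.model_id,
                    "geography": self.geography,
                    "condition": "all",
                    "cohort": cohort,
                    "component": "nonadherent_patients",
                    "unrounded": count,
                    "displayed": display_persons(count),
                }
            )
        rows.append(
            {
                "model": self.model_id,
                "geography": self.geography,
                "condition": "all",
                "cohort": "all",
                "component": f"grand_total[{self.convention}]",
                "unrounded": self.grand_total_unrounded,
                "displayed": self.grand_total,
            }
        )
        return pd.DataFrame(
            rows,
            columns=["model", "geography", "condition", "cohort", "component",
                     "unrounded", "displayed"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_service_model(
    cohorts: CohortTable,
    spec: ServiceModelSpec,
    rates: StaffRates,
    geography: Geography,
    convention: Optional[Convention] = None,
) -> CostReport:
    """Cost one service model for one geography.

    The grand total combines initial counselling, escalation of nonadherent
    patients and planned follow-ups according to the totaling convention
    (the spec's own, unless overridden).
    """
    convention = convention or spec.totaling_convention

    lines = counselling_costs(cohorts, spec.initial_contact, rates, geography)
    initial_total = sum(line.cost for line in lines)

    nonadherent: dict[Cohort, float] = {}
    escalation_total = 0.0
    if spec.nonadherent_fraction > 0 and spec.escalation != "none":
        nonadherent = nonadherent_counts(cohorts, spec.nonadherent_fraction, geography)
        for cohort, count in nonadherent.items():
            cost = escalation_cost(count, spec, rates)
            escalation_total += cost
            lines.append(CostLine(geography, "all", cohort, "escalation", cost))

    followup_total = 0.0
    if spec.followup_uptake > 0 and spec.followup_contact is not None:
        followup_lines = followup_costs(
            cohorts, spec.followup_uptake, spec.followup_contact, rates, geography
        )
        lines.extend(followup_lines)
        followup_total = sum(line.cost for line in followup_lines)

    if convention == "corrected":
        grand = initial_total + escalation_total + followup_total
    else:
        grand = (
            initial_total * (2 if spec.published_double_counts_initial else 1)
            + escalation_total
            + (0.0 if spec.published_excludes_followup else followup_total)
        )

    return CostReport(
        model_id=spec.model_id,
        geography=geography,
        convention=convention,
        lines=lines,
        nonadherent=nonadherent,
        grand_total_unrounded=grand,
    )


def percentage_increase(total_a: float, total_b: float) -> int:
    """Integer-rounded percentage change from ``total_a`` to ``total_b``."""
    if total_a == 0:
        raise ZeroDivisionError("percentage increase undefined for a zero base total")
    from .rounding import round_half_up

    return int(round_half_up((total_b - total_a) / total_a * 100, 0))


def _resolve_parent(config_dict: dict, path: str) -> Tuple[object, object]:
    """Walk a dotted path; list steps accept an index or a model_id."""
    tokens = path.replace("]", "").replace("[", ".").split(".")
    node: object = config_dict
    trail: list[str] = []
    for token in tokens[:-1]:
        trail.append(token)
        if isinstance(node, list):
            node = _index_list(node, token, trail)
        elif isinstance(node, dict) and token in node:
            node = node[token]
        else:
            raise KeyError(f"cannot resolve {'.'.join(trail)!r} in parameter path {path!r}")
    return node, tokens[-1]


def _index_list(node: list, token: str, trail: list[str]) -> object:
    if token.isdigit() and int(token) < len(node):
        return node[int(token)]
    for item in node:
        if isinstance(item, dict) and item.get("model_id") == token:
            return item
    raise KeyError(f"cannot resolve {'.'.join(trail)!r}: no such index or model_id")


def one_way_sweep(
    config,
    parameter_path: str,
    grid: Sequence[float],
    model_id: str,
    geography: Geography,
    convention: Optional[Convention] = None,
) -> pd.DataFrame:
    """Deterministic one-way sensitivity sweep over one scalar parameter.

    ``parameter_path`` is a dotted path into the scenario configuration,
    e.g. ``"models.1a.nonadherent_fraction"`` or
    ``"rates.gp_per_consultation"`` (list steps accept an index or a
    model_id). Returns a frame of ``(value, grand_total_unrounded,
    grand_total)``; the input configuration is left unmodified.
    """
    from .config import ScenarioConfig  # deferred: config depends on this module

    base = config.model_dump()
    records = []
    for value in grid:
        modified = copy.deepcopy(base)
        parent, leaf = _resolve_parent(modified, parameter_path)
        if isinstance(parent, dict):
            if leaf not in parent:
                raise KeyError(f"cannot resolve leaf {leaf!r} in parameter path {parameter_path!r}")
            parent[leaf] = value
        else:
            raise KeyError(f"parameter path {parameter_path!r} does not end at a scalar field")
        scenario = ScenarioConfig.model_validate(modified)
        report = scenario.run_model(model_id, geography, convention=convention)
        records.append(
            {
                "value": value,
                "grand_total_unrounded": report.grand_total_unrounded,
                "grand_total": report.grand_total,
            }
        )
    return pd.DataFrame(records, columns=["value", "grand_total_unrounded", "grand_total"])
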
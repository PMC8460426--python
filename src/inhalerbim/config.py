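"""Scenario configuration: the full serialisable input bundle.

A :class:`ScenarioConfig` collects everything one budget-impact run needs —
population frame, per-condition epidemiology, inhaler-usage splits, staff
rates, service-model specs and display options — and round-trips losslessly
through YAML or JSON. Percentages are stored as percent (prevalence 6.05
means 6.05%) and behavioural shares as proportions (nonadherent_fraction
0.2), mirroring how each is conventionally tabulated; field names say
which.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .costing import (
    Convention,
    CostReport,
    ServiceModelSpec,
    StaffRates,
    run_service_model,
)
from .epidemiology import (
    CohortTable,
    Condition,
    ConditionEpidemiology,
    EpidemiologyInputs,
    Geography,
    PopulationFrame,
    UsageSplit,
    build_cohort_table,
)


class DisplayOptions(BaseModel):
    """Presentation settings; they never affect computed values."""

    model_config = ConfigDict(frozen=True)

    currency_symbol: str = "£"
    thousands_separator: str = " "  # thin space


class ScenarioConfig(BaseModel):
    """Validated input bundle for one budget-impact scenario."""

    model_config = ConfigDict(frozen=True, protected_namespaces=())

    population: PopulationFrame
    epidemiology: Dict[Condition, ConditionEpidemiology]
    usage: Dict[Condition, UsageSplit]
    rates: StaffRates
    models: List[ServiceModelSpec]
    display: DisplayOptions = Field(default_factory=DisplayOptions)

    @model_validator(mode="after")
    def _consistent(self) -> "ScenarioConfig":
        if set(self.epidemiology) != set(self.usage):
            raise ValueError(
                "epidemiology and usage must cover the same conditions; "
                f"got {sorted(self.epidemiology)} vs {sorted(self.usage)}"
            )
        ids = [spec.model_id for spec in self.models]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate model ids: {ids}")
        return self

    # -- derived quantities ------------------------------------------------

    def epidemiology_inputs(self) -> EpidemiologyInputs:
        return EpidemiologyInputs(
            population=self.population,
            epidemiology=self.epidemiology,
            usage=self.usage,
        )

    def cohort_table(self) -> CohortTable:
        """Patient counts per condition, device cohort and geography."""
        return build_cohort_table(self.epidemiology_inputs())

    def model_spec(self, model_id: str) -> ServiceModelSpec:
        for spec in self.models:
            if spec.model_id == model_id:
                return spec
        available = ", ".join(spec.model_id for spec in self.models)
        raise KeyError(f"unknown model id {model_id!r}; available: {available}")

    def run_model(
        self,
        model_id: str,
        geography: Geography,
        convention: Optional[Convention] = None,
    ) -> CostReport:
        """Cost one configured service model for one geography."""
        return run_service_model(
            self.cohort_table(),
            self.model_spec(model_id),
            self.rates,
            geography,
            convention=convention,
        )

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return self.model_dump(mode="json")

    def save(self, path) -> None:
        """Write YAML (``.yaml``/``.yml``) or JSON, by extension."""
        path = Path(path)
        data = self.to_dict()
        if path.suffix in {".yaml", ".yml"}:
            path.write_text(yaml.safe_dump(data, sort_keys=False))
        else:
            path.write_text(json.dumps(data, indent=2) + "\n")


def load_config(path) -> ScenarioConfig:
    """Load and validate a scenario configuration from YAML or JSON.

    Parse failures surface with the parser's line information; validation
    failures name the offending field path (pydantic's error locations).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such config file: {path}")
    text = path.read_text()
    if path.suffix == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return ScenarioConfig.model_validate(data)
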
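"""Table rendering and reproduction checking.

``render_tables`` lays out the cohort estimates and cost reports as plain
text in the style of published budget-impact tables (thin-space thousands
grouping, display rounding); CSV export lives on the objects themselves
(:meth:`CohortTable.to_csv`, :meth:`CostReport.to_csv`) and uses plain
digits.

``reproduce_baseline`` re-runs the England 2020 baseline from its built-in
inputs and compares every headline number against the published reference
values, producing a :class:`ReproductionReport`. A value passes when its
displayed form agrees with the reference within max(5 units, 1e-5
relative) — published tables round some intermediate counts, so component
cells can drift by a few pounds even though the pipeline itself carries
full precision throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import pandas as pd

from .config import DisplayOptions, ScenarioConfig
from .costing import CostReport, percentage_increase
from .epidemiology import (
    CohortTable,
    adjusted_prevalence,
    apply_overlap,
    patient_count,
    scale_count,
)
from .rounding import display_percent, display_persons, group_thousands
from .scenarios import england_baseline

#: Published reference values for the England 2020 baseline.
#: Epidemiology cells are persons or percent; cost cells are GBP.
REFERENCE_VALUES = {
    "adjusted_prevalence_asthma_pct": 5.15,
    "patients_reference_asthma": 3_405_364,
    "patients_reference_copd": 1_086_339,
    "patients_target_asthma": 3025,
    "patients_target_copd": 965,
    "overlap_adjusted_reference_asthma": 2_901_370,
    "overlap_adjusted_target_asthma": 2577,
    "pmdi_only_target_asthma": 1839,
    "pmdi_only_target_copd": 378,
    "pmdi_and_dpi_target_asthma": 67,
    "pmdi_and_dpi_target_copd": 154,
    "model_1_total_reference": 12_347_793,
    "model_1_total_target": 10_969,
    "model_1a_total_reference": 33_876_855,
    "model_1a_total_target": 30_093,
    "model_1b_total_reference": 55_405_917,
    "model_1b_total_target": 49_217,
    "model_2a_total_reference": 20_579_654,
    "model_2a_total_target": 18_281,
    "model_2b_total_reference": 59_680_997,
    "model_2b_total_target": 53_015,
    "model_3_total_reference": 30_869_481,
    "model_3_total_target": 27_422,
    "model_1_nonadherence_20_to_40_increase_pct": 64,
}


def _fmt(value: int, display: DisplayOptions) -> str:
    return group_thousands(value, display.thousands_separator)


def render_tables(
    cohorts: CohortTable,
    reports: Sequence[CostReport] = (),
    display: DisplayOptions | None = None,
) -> str:
    """Plain-text rendering of cohort estimates and cost reports.

    Byte-identical output for identical inputs; all values displayed under
    the package's rounding conventions.
    """
    display = display or DisplayOptions()
    out: List[str] = []

    out.append("Population estimates")
    out.append("=" * 68)
    header = f"{'condition':<10}{'cohort':<16}{'geography':<12}{'patients, n':>14}"
    out.append(header)
    out.append("-" * 68)
    for (condition, cohort, geography), _ in cohorts:
        shown = _fmt(cohorts.displayed(condition, cohort, geography), display)
        out.append(f"{condition:<10}{cohort:<16}{geography:<12}{shown:>14}")

    for report in reports:
        sym = display.currency_symbol
        out.append("")
        out.append(
            f"Model {report.model_id} — {report.geography} "
            f"({report.convention})"
        )
        out.append("=" * 68)
        for line in sorted(
            report.lines, key=lambda l: (l.component, l.condition, l.cohort)
        ):
            out.append(
                f"{line.component:<22}{line.condition:<10}{line.cohort:<16}"
                f"{sym + _fmt(line.displayed, display):>14}"
            )
        for cohort, count in sorted(report.nonadherent.items()):
            out.append(
                f"{'nonadherent patients':<22}{'all':<10}{cohort:<16}"
                f"{_fmt(display_persons(count), display):>14}"
            )
        out.append("-" * 68)
        out.append(
            f"{'Grand total':<48}{sym + _fmt(report.grand_total, display):>14}"
        )
    return "\n".join(out) + "\n"


@dataclass(frozen=True)
class ReproductionRow:
    name: str
    computed_unrounded: float
    computed_displayed: float
    reference: float

    @property
    def abs_deviation(self) -> float:
        return abs(self.computed_displayed - self.reference)

    @property
    def rel_deviation(self) -> float:
        if self.reference == 0:
            return float("inf") if self.abs_deviation else 0.0
        return self.abs_deviation / abs(self.reference)


@dataclass
class ReproductionReport:
    """Computed-vs-published comparison for every baseline headline value."""

    rows: List[ReproductionRow]
    tolerance_abs: float
    tolerance_rel: float

    def row_passes(self, row: ReproductionRow) -> bool:
        allowed = max(self.tolerance_abs, self.tolerance_rel * abs(row.reference))
        return row.abs_deviation <= allowed

    @property
    def passed(self) -> bool:
        return all(self.row_passes(row) for row in self.rows)

    def failures(self) -> List[ReproductionRow]:
        return [row for row in self.rows if not self.row_passes(row)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "name": row.name,
                    "computed_unrounded": row.computed_unrounded,
                    "computed_displayed": row.computed_displayed,
                    "reference": row.reference,
                    "abs_deviation": row.abs_deviation,
                    "rel_deviation": row.rel_deviation,
                    "passed": self.row_passes(row),
                }
                for row in self.rows
            ]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _epidemiology_rows(config: ScenarioConfig) -> List[ReproductionRow]:
    rows: List[ReproductionRow] = []
    frame = config.population
    table = config.cohort_table()

    adj = adjusted_prevalence(
        config.epidemiology["asthma"].prevalence_pct,
        config.epidemiology["asthma"].overlap_pct,
    )
    rows.append(
        ReproductionRow(
            "adjusted_prevalence_asthma_pct", adj, display_percent(adj),
            REFERENCE_VALUES["adjusted_prevalence_asthma_pct"],
        )
    )
    for condition in ("asthma", "copd"):
        raw = patient_count(
            frame.reference_population, config.epidemiology[condition].prevalence_pct
        )
        rows.append(
            ReproductionRow(
                f"patients_reference_{condition}", raw, display_persons(raw),
                REFERENCE_VALUES[f"patients_reference_{condition}"],
            )
        )
        scaled = scale_count(raw, frame)
        rows.append(
            ReproductionRow(
                f"patients_target_{condition}", scaled, display_persons(scaled),
                REFERENCE_VALUES[f"patients_target_{condition}"],
            )
        )
        adjusted = apply_overlap(raw, config.epidemiology[condition].overlap_pct)
        if condition == "asthma":
            rows.append(
                ReproductionRow(
                    "overlap_adjusted_reference_asthma",
                    adjusted, display_persons(adjusted),
                    REFERENCE_VALUES["overlap_adjusted_reference_asthma"],
                )
            )
            adjusted_scaled = scale_count(adjusted, frame)
            rows.append(
                ReproductionRow(
                    "overlap_adjusted_target_asthma",
                    adjusted_scaled, display_persons(adjusted_scaled),
                    REFERENCE_VALUES["overlap_adjusted_target_asthma"],
                )
            )
        for cohort in ("pmdi_only", "pmdi_and_dpi"):
            name = f"{cohort}_target_{condition}"
            value = table.count(condition, cohort, "target")
            rows.append(
                ReproductionRow(
                    name, value, display_persons(value), REFERENCE_VALUES[name]
                )
            )
    return rows


def _cost_rows(config: ScenarioConfig) -> List[ReproductionRow]:
    rows: List[ReproductionRow] = []
    for model_id in ("1", "1a", "1b", "2a", "2b", "3"):
        for geography in ("reference", "target"):
            report = config.run_model(model_id, geography)
            name = f"model_{model_id}_total_{geography}"
            rows.append(
                ReproductionRow(
                    name, report.grand_total_unrounded, report.grand_total,
                    REFERENCE_VALUES[name],
                )
            )
    low = config.run_model("1a", "target").grand_total_unrounded
    high = config.run_model("1b", "target").grand_total_unrounded
    increase = percentage_increase(low, high)
    rows.append(
        ReproductionRow(
            "model_1_nonadherence_20_to_40_increase_pct",
            (high - low) / low * 100, increase,
            REFERENCE_VALUES["model_1_nonadherence_20_to_40_increase_pct"],
        )
    )
    return rows


def reproduce_baseline(
    tolerance_abs: float = 5.0, tolerance_rel: float = 1e-5
) -> ReproductionReport:
    """Recompute every published baseline value from built-in inputs."""
    config = england_baseline().config
    rows = _epidemiology_rows(config) + _cost_rows(config)
    return ReproductionReport(rows, tolerance_abs, tolerance_rel)
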
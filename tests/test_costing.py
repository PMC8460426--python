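"""Time-driven costing: contact costs, escalation, totals, sweeps."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from inhalerbim import (
    CohortTable,
    ContactSpec,
    PopulationFrame,
    ServiceModelSpec,
    StaffMix,
    StaffRates,
    blended_hourly_rate,
    counselling_costs,
    escalation_cost,
    followup_costs,
    nonadherent_counts,
    one_way_sweep,
    per_patient_contact_cost,
    percentage_increase,
    run_service_model,
)

RATES = StaffRates(pharmacist_per_hour=54, nurse_per_hour=42, gp_per_consultation=39.23)
BLEND = StaffMix(pharmacist_fraction=0.25, nurse_fraction=0.75)


@pytest.mark.parametrize(
    "mix, rates, expected",
    [
        ((0.25, 0.75), (54, 42), 45.0),
        ((1.0, 0.0), (54, 42), 54.0),
        ((0.5, 0.5), (60, 40), 50.0),
    ],
)
def test_blended_hourly_rate(mix, rates, expected):
    staff_mix = StaffMix(pharmacist_fraction=mix[0], nurse_fraction=mix[1])
    staff_rates = StaffRates(
        pharmacist_per_hour=rates[0], nurse_per_hour=rates[1], gp_per_consultation=39.23
    )
    assert blended_hourly_rate(staff_mix, staff_rates) == pytest.approx(expected)


@pytest.mark.parametrize(
    "duration, delivery, expected",
    [
        (5, "pharmacist", 4.50),    # the switch letter: 5 min of pharmacist time
        (10, BLEND, 7.50),          # 10 min at the £45/h pharmacist/nurse blend
        (0, "pharmacist", 0.0),
        (15, BLEND, 11.25),
    ],
)
def test_per_patient_contact_cost(duration, delivery, expected):
    contact = ContactSpec(duration_min=duration, delivery=delivery)
    assert per_patient_contact_cost(contact, RATES) == pytest.approx(expected)


def test_counselling_costs_per_cohort(baseline_cohorts):
    contact = ContactSpec(duration_min=5, delivery="pharmacist")
    lines = counselling_costs(baseline_cohorts, contact, RATES, "reference")
    by_cell = {(l.condition, l.cohort): l.cost for l in lines}
    assert by_cell[("asthma", "pmdi_only")] == pytest.approx(9_314_082)
    # printed value is 781 463; the pipeline's exact product differs by < £5
    assert by_cell[("copd", "pmdi_and_dpi")] == pytest.approx(781_461, abs=0.5)


def test_counselling_cost_zero_count_cohort(identity_frame):
    table = CohortTable.from_reference_counts(
        {("asthma", "pmdi_only"): 0, ("asthma", "pmdi_and_dpi"): 0}, identity_frame
    )
    contact = ContactSpec(duration_min=5, delivery="pharmacist")
    assert all(l.cost == 0 for l in counselling_costs(table, contact, RATES, "target"))


def test_nonadherent_counts_pool_conditions(baseline_cohorts):
    counts = nonadherent_counts(baseline_cohorts, 0.2, "reference")
    assert counts["pmdi_only"] == pytest.approx(0.2 * (2_069_796 + 425_498))
    assert counts["pmdi_and_dpi"] == pytest.approx(0.2 * (75_002 + 173_658))


def test_nonadherent_zero_fraction(baseline_cohorts):
    assert all(v == 0 for v in nonadherent_counts(baseline_cohorts, 0.0, "target").values())


def test_gp_escalation_cost():
    spec = ServiceModelSpec(
        model_id="x",
        initial_contact={"duration_min": 5},
        nonadherent_fraction=0.2,
        escalation="gp_consultation",
    )
    assert escalation_cost(499_058.8, spec, RATES) == pytest.approx(19_578_076.724)
    assert escalation_cost(0.0, spec, RATES) == 0.0


def test_escalation_without_pathway_is_an_error():
    spec = ServiceModelSpec(model_id="x", initial_contact={"duration_min": 5})
    with pytest.raises(ValueError, match="escalation"):
        escalation_cost(10, spec, RATES)


def test_followup_costs(baseline_cohorts):
    followup = ContactSpec(duration_min=15, delivery=BLEND)
    lines = followup_costs(baseline_cohorts, 0.6, followup, RATES, "reference")
    by_cell = {(l.condition, l.cohort): l.cost for l in lines}
    assert by_cell[("asthma", "pmdi_only")] == pytest.approx(13_971_123)
    assert by_cell[("copd", "pmdi_only")] == pytest.approx(2_872_111.5)


def test_followup_zero_uptake(baseline_cohorts):
    followup = ContactSpec(duration_min=15, delivery=BLEND)
    lines = followup_costs(baseline_cohorts, 0.0, followup, RATES, "target")
    assert sum(l.cost for l in lines) == 0.0


@pytest.mark.parametrize(
    "a, b, expected", [(30_093, 49_217, 64), (100, 100, 0), (100, 150, 50)]
)
def test_percentage_increase(a, b, expected):
    assert percentage_increase(a, b) == expected


def test_percentage_increase_zero_base_is_undefined():
    with pytest.raises(ZeroDivisionError):
        percentage_increase(0, 10)


def test_unknown_model_id_lists_available(baseline_config):
    with pytest.raises(KeyError, match="1a"):
        baseline_config.run_model("nope", "target")


def test_conventions_coincide_except_for_declared_quirks(baseline_config):
    for model_id in ("1", "1a", "1b", "2a"):
        published = baseline_config.run_model(model_id, "target", convention="as_published")
        corrected = baseline_config.run_model(model_id, "target", convention="corrected")
        assert published.grand_total_unrounded == pytest.approx(
            corrected.grand_total_unrounded
        )
    # the opportunistic follow-up model double-counts initial contacts as
    # published; the corrected total counts them once
    m2b_pub = baseline_config.run_model("2b", "target", convention="as_published")
    m2b_cor = baseline_config.run_model("2b", "target", convention="corrected")
    assert m2b_pub.grand_total == 53_015
    assert m2b_cor.grand_total == 34_734
    # the gold-standard model omits follow-up as published
    m3_pub = baseline_config.run_model("3", "target", convention="as_published")
    m3_cor = baseline_config.run_model("3", "target", convention="corrected")
    assert m3_cor.grand_total_unrounded == pytest.approx(
        2 * m3_pub.grand_total_unrounded
    )


def test_cost_report_frame_layout(baseline_config):
    frame = baseline_config.run_model("1a", "target").to_frame()
    assert list(frame.columns) == [
        "model", "geography", "condition", "cohort", "component", "unrounded", "displayed",
    ]
    assert (frame["geography"] == "target").all()
    assert "nonadherent_patients" in set(frame["component"])


def test_one_way_sweep_over_nonadherence(baseline_config):
    result = one_way_sweep(
        baseline_config, "models.1a.nonadherent_fraction", [0.0, 0.2, 0.4], "1a", "target"
    )
    assert result["grand_total_unrounded"].tolist() == pytest.approx(
        [10_969, 30_093, 49_217], abs=2
    )


def test_one_way_sweep_leaves_config_unmodified(baseline_config):
    before = baseline_config.model_dump()
    one_way_sweep(baseline_config, "rates.gp_per_consultation", [10.0], "1a", "target")
    assert baseline_config.model_dump() == before


def test_one_way_sweep_empty_grid(baseline_config):
    result = one_way_sweep(baseline_config, "rates.gp_per_consultation", [], "1", "target")
    assert result.empty


def test_one_way_sweep_irrelevant_parameter_is_constant(baseline_config):
    # the GP rate never enters Model 3 (no escalation pathway)
    result = one_way_sweep(
        baseline_config, "rates.gp_per_consultation", [20.0, 50.0, 90.0], "3", "target"
    )
    assert result["grand_total_unrounded"].nunique() == 1


def test_one_way_sweep_bad_path_names_it(baseline_config):
    with pytest.raises(KeyError, match="no_such"):
        one_way_sweep(baseline_config, "rates.no_such_field", [1.0], "1", "target")


def _flat_spec(duration, fraction, uptake):
    return ServiceModelSpec(
        model_id="p",
        initial_contact={"duration_min": duration},
        nonadherent_fraction=fraction,
        escalation="gp_consultation",
        followup_uptake=uptake,
        followup_contact={"duration_min": 15, "delivery": BLEND.model_dump()},
        totaling_convention="corrected",
    )


def test_zero_model_costs_nothing(small_cohorts):
    spec = ServiceModelSpec(
        model_id="zero", initial_contact={"duration_min": 0}, totaling_convention="corrected"
    )
    assert run_service_model(small_cohorts, spec, RATES, "target").grand_total_unrounded == 0.0


@given(
    duration=st.floats(min_value=0, max_value=60),
    fraction=st.floats(min_value=0, max_value=1),
    uptake=st.floats(min_value=0, max_value=1),
    bump=st.floats(min_value=0, max_value=0.5),
)
def test_grand_total_monotone_in_parameters(small_cohorts, duration, fraction, uptake, bump):
    base = run_service_model(
        small_cohorts, _flat_spec(duration, fraction, uptake), RATES, "target"
    ).grand_total_unrounded
    more_time = run_service_model(
        small_cohorts, _flat_spec(duration + 10, fraction, uptake), RATES, "target"
    ).grand_total_unrounded
    more_escalation = run_service_model(
        small_cohorts, _flat_spec(duration, min(1, fraction + bump), uptake), RATES, "target"
    ).grand_total_unrounded
    more_followup = run_service_model(
        small_cohorts, _flat_spec(duration, fraction, min(1, uptake + bump)), RATES, "target"
    ).grand_total_unrounded
    assert more_time >= base
    assert more_escalation >= base
    assert more_followup >= base


@given(scale=st.floats(min_value=1e-3, max_value=1e3))
def test_grand_total_homogeneous_in_counts(small_cohorts, scale):
    spec = _flat_spec(10, 0.3, 0.5)
    base = run_service_model(small_cohorts, spec, RATES, "target").grand_total_unrounded
    scaled = run_service_model(
        small_cohorts.scaled(scale), spec, RATES, "target"
    ).grand_total_unrounded
    assert scaled == pytest.approx(base * scale, rel=1e-9)


def test_target_total_is_reference_total_times_population_ratio(baseline_config):
    ratio = (
        baseline_config.population.target_population
        / baseline_config.population.reference_population
    )
    for model_id in ("1", "1a", "1b", "2a", "2b", "3"):
        reference = baseline_config.run_model(model_id, "reference").grand_total_unrounded
        target = baseline_config.run_model(model_id, "target").grand_total_unrounded
        assert target == pytest.approx(reference * ratio, rel=1e-9)


def enumerate_patients(cohorts, spec, rates, geography):
    """Independent per-patient oracle for integer cohort counts.

    Adds each patient's contact costs one at a time; escalation of
    nonadherent patients is allocated deterministically as count x fraction
    per pooled device cohort.
    """
    total = 0.0
    initial_unit = per_patient_contact_cost(spec.initial_contact, rates)
    followup_unit = (
        per_patient_contact_cost(spec.followup_contact, rates)
        if spec.followup_contact is not None
        else 0.0
    )
    for (_, _, geo), count in cohorts:
        if geo != geography:
            continue
        for _ in range(int(count)):
            total += initial_unit
            total += spec.followup_uptake * followup_unit
    if spec.escalation != "none" and spec.nonadherent_fraction > 0:
        for cohort in ("pmdi_only", "pmdi_and_dpi"):
            pooled = cohorts.cohort_total(cohort, geography)
            total += escalation_cost(pooled * spec.nonadherent_fraction, spec, rates)
    return total


def test_per_patient_enumeration_matches_closed_form(small_cohorts):
    spec = _flat_spec(7, 0.25, 0.6)
    aggregate = run_service_model(
        small_cohorts, spec, RATES, "target", convention="corrected"
    ).grand_total_unrounded
    oracle = enumerate_patients(small_cohorts, spec, RATES, "target")
    assert aggregate == pytest.approx(oracle, rel=1e-9)
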
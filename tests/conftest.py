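import pytest
from hypothesis import HealthCheck, settings

from inhalerbim import CohortTable, PopulationFrame, england_baseline

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def baseline():
    return england_baseline()


@pytest.fixture(scope="session")
def baseline_config(baseline):
    return baseline.config


@pytest.fixture(scope="session")
def baseline_cohorts(baseline_config):
    return baseline_config.cohort_table()


@pytest.fixture(scope="session")
def identity_frame():
    return PopulationFrame(reference_population=1.0, target_population=1.0)


@pytest.fixture(scope="session")
def small_cohorts(identity_frame):
    """A tiny cohort table with integer counts, both geographies identical."""
    return CohortTable.from_reference_counts(
        {
            ("asthma", "pmdi_only"): 100,
            ("asthma", "pmdi_and_dpi"): 10,
            ("copd", "pmdi_only"): 40,
            ("copd", "pmdi_and_dpi"): 16,
        },
        identity_frame,
    )
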
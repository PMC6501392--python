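import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from faitkit import CohortParams, CostLedger, EconParams, EpiParams
from faitkit.datasets import fixture_path

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params() -> CohortParams:
    return CohortParams()


@pytest.fixture()
def hand_cohort() -> pd.DataFrame:
    """Four high-risk individuals, two per arm: SBP 150/150 vs 140/136."""
    return pd.DataFrame(
        {
            "id": range(4),
            "arm": ["control", "control", "intervention", "intervention"],
            "screened": [True] * 4,
            "high_risk": [True] * 4,
            "treated": [False, False, True, True],
            "sbp": [150.0, 150.0, 140.0, 136.0],
            "age": [59.0] * 4,
        }
    )


@pytest.fixture(scope="session")
def epi_demo() -> EpiParams:
    return EpiParams(baseline_event_risk=0.10, case_fatality=0.3)


@pytest.fixture(scope="session")
def econ_demo() -> EconParams:
    return EconParams(gni_per_capita=3500.0, hosp_cost_per_event=4500.0)


@pytest.fixture(scope="session")
def table_ledger() -> CostLedger:
    """Published cost ledger: a = 1M, b = 328.3M (USD, 5-year horizon)."""
    return CostLedger(
        research_cost_a=1.0e6,
        implementation_cost_b=328.3e6,
        currency_label="USD",
        horizon=5,
    )


@pytest.fixture(scope="session")
def smarthealth_config_path():
    return fixture_path("smarthealth_config")


@pytest.fixture(scope="session")
def pacific_config_path():
    return fixture_path("pacific_salt_config")
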
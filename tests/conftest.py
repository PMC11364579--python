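import pytest
from hypothesis import HealthCheck, settings

from renalcea.config import ModelOptions, bundled_life_table, default_parameters

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def life_table():
    return bundled_life_table()


@pytest.fixture(scope="session")
def plain_options():
    """All structural switches off: annual-inclusive utilities, FP surgery
    only, no half-cycle correction."""
    return ModelOptions(
        fp_includes_biopsy=False, compose_monthly_qol=False, half_cycle=False
    )
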
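import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def soil_table():
    from pahrisk import load_fixture

    return load_fixture("table1")


@pytest.fixture(scope="session")
def pefs():
    from pahrisk import load_pef_table

    return load_pef_table()
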
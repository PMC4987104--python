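import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def discovery_world():
    """The standard 100 kb six-species world with 20 planted elements."""
    from hcnskit.pipeline import default_discovery_world

    return default_discovery_world(seed=1)


@pytest.fixture(scope="session")
def discovery_result(discovery_world):
    from hcnskit.pipeline import run_discovery

    return run_discovery(discovery_world)
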
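import pytest
from hypothesis import HealthCheck, settings

import cernascreen as cs

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def scenario():
    """The default synthetic scenario (seed 42) shared across tests."""
    return cs.default_scenario()


@pytest.fixture(scope="session")
def screen_results(scenario):
    """A fitted four-gate screen on the default scenario."""
    screen = cs.CeRNAScreen(
        scenario.matrix,
        scenario.design,
        scenario.interactions,
        scenario.annotations,
        scenario.truth.seed_id,
    )
    return screen.fit()
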
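import pytest
from hypothesis import HealthCheck, settings

from eprsim import builtin_base_case

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def base_config():
    return builtin_base_case()


@pytest.fixture(scope="session")
def base_trajectory(base_config):
    from eprsim import run_simulation

    return run_simulation(base_config)
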
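import pytest
from hypothesis import HealthCheck, settings

from steroidratio import builtin_table1, default_config, simulate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def table1():
    return builtin_table1()


@pytest.fixture(scope="session")
def synthetic71():
    """Default study-condition cohort (20 PCa / 20 BPH / 31 HC), seed 1."""
    return simulate_cohort(default_config(1))
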
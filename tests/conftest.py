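import pytest
from hypothesis import HealthCheck, settings

from divegas import load_ecotype

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def sarasota():
    return load_ecotype("sarasota")


@pytest.fixture(scope="session")
def bermuda():
    return load_ecotype("bermuda")
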
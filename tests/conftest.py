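import pytest
from hypothesis import HealthCheck, settings

from pipo import default_enzymes, default_fixture, default_tag_enzymes

settings.register_profile(
    "package",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")


@pytest.fixture(scope="session")
def enzymes():
    return default_enzymes()


@pytest.fixture(scope="session")
def by_name(enzymes):
    return {e.name: e for e in enzymes}


@pytest.fixture(scope="session")
def tag_enzymes():
    return default_tag_enzymes()


@pytest.fixture(scope="session")
def world():
    """Default synthetic design world: (locus, backbone, params), seed 1."""
    return default_fixture(1)
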
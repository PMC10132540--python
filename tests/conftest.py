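import pytest
from hypothesis import HealthCheck, settings

from rrcompare import PopulationSpec, ScramblerSpec

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def pop():
    """The comparison-grid population: mu_Y = 10, var_Y = 2."""
    return PopulationSpec(mu=10.0, var=2.0)


@pytest.fixture
def additive_block1():
    return ScramblerSpec(kind="additive", variance=6.0)


@pytest.fixture
def multiplicative_block1():
    return ScramblerSpec(kind="multiplicative", variance=8.0, family="gamma")
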
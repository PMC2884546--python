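import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

from mdfba import (  # noqa: E402
    Condition,
    MDFBAConfig,
    Medium,
    apply_condition,
    figure1_network,
)


@pytest.fixture
def fig1():
    return figure1_network()


@pytest.fixture
def medium_ax():
    return Medium({"A": 1.0, "X": 10.0}, name="AX")


@pytest.fixture
def medium_a():
    return Medium({"A": 1.0}, name="A")


@pytest.fixture
def fig1_ax(fig1, medium_ax):
    """Figure-style network with A and X available."""
    return apply_condition(fig1, Condition(medium_ax, label="AX"))


@pytest.fixture
def fig1_a(fig1, medium_a):
    """Figure-style network with only A available."""
    return apply_condition(fig1, Condition(medium_a, label="A"))


@pytest.fixture
def config():
    return MDFBAConfig()
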
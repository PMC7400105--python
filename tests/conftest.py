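import pytest

from etdrift.simulate import scenario, simulate


@pytest.fixture(scope="session")
def baseline_exp():
    """Default 6-session drifting experiment, seed 1."""
    return simulate(scenario("baseline_drift"))


@pytest.fixture(scope="session")
def baseline_ms(baseline_exp):
    return baseline_exp.observed
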
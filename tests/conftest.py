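import pytest

from flowloop import gen_hr_scenario, gen_score_scenario


@pytest.fixture(scope="session")
def fig7():
    return gen_score_scenario("fig7_constant")


@pytest.fixture(scope="session")
def fig8():
    return gen_score_scenario("fig8_upward")


@pytest.fixture(scope="session")
def fig9():
    return gen_score_scenario("fig9_downward")


@pytest.fixture(scope="session")
def fig10():
    return gen_hr_scenario("fig10_rising")
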
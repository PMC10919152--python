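import pytest

from crcscreen import config
from crcscreen.economics import EconInputs
from crcscreen.params import central_params
from crcscreen.screening import TestPerformance, load_scenarios, load_strategies

TestPerformance.__test__ = False  # dataclass, not a pytest test class


@pytest.fixture(scope="session")
def life_table():
    return config.load_life_table()


@pytest.fixture(scope="session")
def central():
    return central_params()


@pytest.fixture(scope="session")
def perf():
    return TestPerformance.default()


@pytest.fixture(scope="session")
def econ():
    return EconInputs.default()


@pytest.fixture(scope="session")
def econ_undiscounted(econ):
    import dataclasses

    return dataclasses.replace(econ, discount_rate=0.0)


@pytest.fixture(scope="session")
def strategies():
    return load_strategies()


@pytest.fixture(scope="session")
def scenarios():
    return load_scenarios()
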
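import numpy as np
import pytest

from normsim import (
    ModelSpec,
    RateParameters,
    StimulationProtocol,
    pretreatment_protocol,
    single_dose,
)


@pytest.fixture(scope="session")
def spec2():
    return ModelSpec(2)


@pytest.fixture(scope="session")
def spec3():
    return ModelSpec(3)


@pytest.fixture(scope="session")
def spec4():
    return ModelSpec(4)


@pytest.fixture
def params3():
    return RateParameters(alpha=0.1, beta=0.3, beta2=0.1, gamma1=0.4)


@pytest.fixture
def params4():
    return RateParameters(alpha=0.1, beta=0.3, beta2=0.1, gamma1=0.4, gamma2=0.05)


@pytest.fixture
def two_dose_protocol():
    # 1000 ng/ml at 0 h, washout + 1000 ng/ml at 24 h
    return pretreatment_protocol(1000.0)


@pytest.fixture
def one_dose_protocol():
    return single_dose(1000.0)


def random_rates(rng: np.random.Generator, n_states: int = 4) -> RateParameters:
    a, b, b2, g1, g2 = rng.uniform(0.01, 1.0, 5)
    if n_states < 4:
        g2 = 0.0
    if n_states < 3:
        b2 = g1 = 0.0
    return RateParameters(alpha=a, beta=b, beta2=b2, gamma1=g1, gamma2=g2)
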
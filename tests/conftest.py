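import numpy as np
import pytest

from watermaze import (
    FreeModelParams,
    ParamGain,
    TankGeometry,
    build_continuous_model,
    cost_from_gain,
    discretize_cost,
    discretize_dynamics,
    expand_param_gain,
)

DT = 0.2

#: reference parameter estimates used as generative truth throughout
TRUE_PARAMS = FreeModelParams(k=3.7, gamma=0.47, m=20.0, sigma_q=1.1, sigma_p=4.5)
TRUE_GAIN = ParamGain(K_r=0.20, K_t=0.38, K_alpha=0.89)


@pytest.fixture(scope="session")
def params():
    return TRUE_PARAMS


@pytest.fixture(scope="session")
def geometry():
    return TankGeometry()


@pytest.fixture(scope="session")
def cmodel(params):
    return build_continuous_model(params)


@pytest.fixture(scope="session")
def dmodel(cmodel):
    return discretize_dynamics(cmodel, DT)


@pytest.fixture(scope="session")
def gain():
    return expand_param_gain(TRUE_GAIN)


@pytest.fixture(scope="session")
def cost(gain):
    return cost_from_gain(gain)


@pytest.fixture(scope="session")
def dcost(cmodel, cost):
    return discretize_cost(cmodel, cost, DT)
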
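import numpy as np
import pytest

import stratopt as sp


@pytest.fixture
def unit_uniform_design():
    return sp.BivariateDesign(sp.uniform_density(0, 1), sp.uniform_density(0, 1))


@pytest.fixture
def cauchy_power_design():
    """Standard Cauchy (unrenormalized, [0,1]) × standard power δ=3, θ=1."""
    return sp.BivariateDesign(sp.cauchy_density(0.0, 1.0), sp.power_density(3.0, 1.0))


@pytest.fixture
def unit_model():
    return sp.LinearSuperpopModel(intercept=0.0, coef1=1.0, coef2=1.0)


@pytest.fixture
def worked_example_costs():
    return sp.CostModel(0.0, np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]), 1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
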
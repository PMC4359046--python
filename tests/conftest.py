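import numpy as np
import pytest

from ccm import CoupledLogisticSpec, TimeSeries, coupled_logistic


@pytest.fixture
def tiny_series():
    return TimeSeries([1.0, 2.0, 3.0, 4.0], name="x")


@pytest.fixture
def logistic_pair():
    """Unidirectionally forced chaotic pair (X drives Y), n=200."""
    return coupled_logistic(CoupledLogisticSpec(n=200, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
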
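import numpy as np
import pytest

from l4ei import InputSpec, NetworkSpec, NeuronParams, build_connectivity


@pytest.fixture(scope="session")
def table1_neuron() -> NeuronParams:
    return NeuronParams()


@pytest.fixture(scope="session")
def table1_input() -> InputSpec:
    return InputSpec()


@pytest.fixture(scope="session")
def small_spec() -> NetworkSpec:
    """200-neuron network with proportional in-degrees for fast tests."""
    return NetworkSpec.scaled(200)


@pytest.fixture(scope="session")
def small_conn(small_spec):
    return build_connectivity(small_spec, seed=1234)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
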
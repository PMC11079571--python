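import numpy as np
import pytest

from hemonet import prep, synthetic as sv


@pytest.fixture(scope="session")
def tiny_network():
    """Smallest legal topology: 1 inlet, 1 bifurcation, 1 merger, 1 outlet."""
    return sv.generate_network(1, seed=1)


@pytest.fixture(scope="session")
def small_network():
    return sv.generate_network(3, seed=7)


@pytest.fixture(scope="session")
def small_flow(small_network):
    return sv.solve_flow(small_network, seed=7)


@pytest.fixture(scope="session")
def small_fields(small_flow):
    return sv.render_network(small_flow, ng=32, seed=42)


@pytest.fixture(scope="session")
def small_dataset_2d(small_network, small_flow, small_fields):
    return prep.build_dataset(small_network, small_flow, small_fields,
                              mode="2d")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
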
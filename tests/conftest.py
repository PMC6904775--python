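import numpy as np
import pytest

from fumet.network import build_network, linear_chain_network


@pytest.fixture
def net():
    """Fresh full 22-reaction network (function-scoped: tests may mutate)."""
    return build_network()


@pytest.fixture(scope="session")
def default_trajectory():
    """One default forced-ATP run shared by read-only tests."""
    from fumet.simulator import simulate
    return simulate(build_network())


@pytest.fixture(scope="session")
def default_steady_state():
    """Converged long-run steady state of the default model."""
    from fumet.simulator import steady_state
    ss = steady_state(build_network(), tol=1e-9)
    assert ss.converged, ss.message
    return ss


@pytest.fixture
def chain():
    """Small 3-step MM chain for cheap simulation tests."""
    return linear_chain_network([(300.0, 400.0), (150.0, 200.0), (80.0, 100.0)],
                                [400.0, 150.0, 60.0, 10.0])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
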
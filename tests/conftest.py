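import pytest
from hypothesis import settings

from parrondonet.graph import NetworkGraph

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")
from parrondonet.netgen import make_lattice


@pytest.fixture(scope="session")
def four_cycle() -> NetworkGraph:
    return NetworkGraph.from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)])


@pytest.fixture(scope="session")
def k4() -> NetworkGraph:
    return NetworkGraph.from_edges(
        4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    )


@pytest.fixture(scope="session")
def lattice5() -> NetworkGraph:
    return make_lattice(5)


@pytest.fixture(scope="session")
def lattice30() -> NetworkGraph:
    return make_lattice(30)
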
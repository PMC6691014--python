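import numpy as np
import pytest

from netembed import (
    UndirectedGraph,
    generate_er,
    generate_voronoi_adjacency,
    sample_attractiveness,
)


@pytest.fixture(scope="session")
def voronoi20():
    """20-node spatial-adjacency location network on the unit square."""
    g, pos = generate_voronoi_adjacency(20, seed=1)
    return g


@pytest.fixture(scope="session")
def f20():
    """Uniform(1, 100) rescaled attractiveness for the 20-node B."""
    return sample_attractiveness(20, 1.0, 100.0, seed=2)


@pytest.fixture(scope="session")
def er300():
    """One ER(300, 0.02) realization of network A."""
    return generate_er(300, 0.02, seed=3)


@pytest.fixture(scope="session")
def path10():
    """10-node path graph as a degenerate location network."""
    edges = np.array([(i, i + 1) for i in range(9)])
    return UndirectedGraph(10, edges)
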
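import numpy as np
import pytest

from comorbmap.areal import lattice_graph
from comorbmap.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def path3():
    from comorbmap.areal import StateGraph

    return StateGraph.from_edges(3, [(0, 1), (1, 2)])


@pytest.fixture(scope="session")
def lattice37():
    return lattice_graph(6, 6, 1)


@pytest.fixture(scope="session")
def small_dataset():
    """12-area, 150-children-per-area dataset with default sharing."""
    graph = lattice_graph(3, 4, 0)
    config = SimulationConfig(graph=graph, children_per_area=150, seed=42)
    records, truth = simulate_dataset(config)
    return records, truth, config


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
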
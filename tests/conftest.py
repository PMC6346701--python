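import networkx as nx
import numpy as np
import pytest

from cdmnet import (
    MultilayerTensor,
    OntologyDAG,
    PlantedModuleSpec,
    WeightedDiseaseNetwork,
    generate_multilayer,
)


@pytest.fixture
def chain_dag() -> OntologyDAG:
    """C is_a B is_a A with the default is_a factor 0.8."""
    return OntologyDAG.from_edges([("C", "B", "is_a"), ("B", "A", "is_a")])


@pytest.fixture
def diamond_dag() -> OntologyDAG:
    """Two paths C->A: via B1 (is_a, is_a) and via B2 (is_a, part_of)."""
    return OntologyDAG.from_edges(
        [
            ("C", "B1", "is_a"),
            ("C", "B2", "is_a"),
            ("B1", "A", "is_a"),
            ("B2", "A", "part_of"),
        ]
    )


@pytest.fixture
def path_interactome() -> nx.Graph:
    """Unweighted path a-b-c-d."""
    return nx.path_graph(["a", "b", "c", "d"])


@pytest.fixture
def two_layer_tensor() -> MultilayerTensor:
    """3 nodes, 2 layers; edge (D1, D2) weighted 1.0 in layer A, 0.5 in layer B."""
    values = np.zeros((3, 3, 2))
    values[0, 1, 0] = values[1, 0, 0] = 1.0
    values[0, 1, 1] = values[1, 0, 1] = 0.5
    return MultilayerTensor(["D1", "D2", "D3"], ["A", "B"], values)


@pytest.fixture
def planted_tensor():
    """30-node, 3-layer background tensor with one planted 6-node module."""
    return generate_multilayer(
        n_nodes=30, m_layers=3, specs=[PlantedModuleSpec(members=6)], seed=11
    )


def make_network(edges, name="net", nodes=None) -> WeightedDiseaseNetwork:
    return WeightedDiseaseNetwork.from_edges(name, edges, nodes=nodes)


@pytest.fixture
def triangle_network() -> WeightedDiseaseNetwork:
    return make_network([("D1", "D2", 0.1), ("D2", "D3", 0.5), ("D1", "D3", 0.9)])
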
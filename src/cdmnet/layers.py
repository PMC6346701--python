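"""Layer assembly: weighted disease networks and the multilayer tensor.

A *layer* is one weighted, undirected disease-disease similarity network
(e.g. interactome-separation based, symptom based, or ontology based).
Before module extraction the layers are filtered, restricted to their
common disease set, optionally rescaled, and packed into a third-order
tensor ``a[i, j, k]`` — the weight of edge (i, j) in layer k — over a
shared, lexicographic node order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "WeightedDiseaseNetwork",
    "MultilayerTensor",
    "filter_edges_by_weight",
    "restrict_to_common_nodes",
    "normalize_layer",
    "build_tensor",
]


class WeightedDiseaseNetwork:
    """An undirected disease-disease network with nonnegative edge weights.

    Wraps a :class:`networkx.Graph`; nodes are opaque disease identifiers
    (MeSH-style strings allowed but never parsed), edges carry a ``weight``
    attribute. Self-loops and negative weights are rejected on construction.
    """

    def __init__(self, name: str, graph: nx.Graph | None = None):
        self.name = name
        self.graph = graph if graph is not None else nx.Graph()
        self._validate()

    def _validate(self) -> None:
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise ValueError(f"layer {self.name!r}: self-loop on node {u!r}")
            w = data.get("weight")
            if w is None:
                raise ValueError(f"layer {self.name!r}: edge ({u!r}, {v!r}) has no weight")
            if w < 0:
                raise ValueError(
                    f"layer {self.name!r}: negative weight {w} on edge ({u!r}, {v!r})"
                )

    @classmethod
    def from_edges(
        cls,
        name: str,
        edges: Iterable[tuple[str, str, float]],
        nodes: Iterable[str] | None = None,
    ) -> "WeightedDiseaseNetwork":
        g = nx.Graph()
        if nodes is not None:
            g.add_nodes_from(nodes)
        for a, b, w in edges:
            if g.has_edge(a, b):
                raise ValueError(f"duplicate pair ({a!r}, {b!r})")
            g.add_edge(a, b, weight=float(w))
        return cls(name, g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def weight(self, a: str, b: str) -> float:
        """Edge weight, 0.0 for an absent edge."""
        data = self.graph.get_edge_data(a, b)
        return 0.0 if data is None else data["weight"]

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Iterate edges once per unordered pair, endpoints in lexicographic order."""
        for u, v, data in self.graph.edges(data=True):
            a, b = (u, v) if str(u) <= str(v) else (v, u)
            yield a, b, data["weight"]

    def copy(self) -> "WeightedDiseaseNetwork":
        return WeightedDiseaseNetwork(self.name, self.graph.copy())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"WeightedDiseaseNetwork({self.name!r}, n={self.graph.number_of_nodes()}, "
            f"edges={self.graph.number_of_edges()})"
        )


@dataclass
class MultilayerTensor:
    """Third-order tensor ``a[i, j, k]`` of a multilayer disease network.

    ``values`` has shape (n, n, m) with per-layer symmetric slices and zero
    diagonal; ``node_order`` and ``layer_order`` fix the index meaning.
    """

    node_order: list[str]
    layer_order: list[str]
    values: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n, m = len(self.node_order), len(self.layer_order)
        if self.values.shape != (n, n, m):
            raise ValueError(
                f"tensor shape {self.values.shape} does not match "
                f"{n} nodes x {m} layers"
            )
        if np.any(self.values < 0):
            raise ValueError("tensor entries must be nonnegative")
        if not np.allclose(self.values, self.values.transpose(1, 0, 2)):
            raise ValueError("tensor slices must be symmetric in (i, j)")
        diag = self.values[np.arange(n), np.arange(n), :]
        if np.any(diag != 0):
            raise ValueError("tensor diagonal must be zero (no self-weights)")
        self._index = {node: i for i, node in enumerate(self.node_order)}

    @property
    def n(self) -> int:
        return len(self.node_order)

    @property
    def m(self) -> int:
        return len(self.layer_order)

    def node_index(self, node: str) -> int:
        return self._index[node]

    def indices(self, nodes: Iterable[str]) -> np.ndarray:
        return np.asarray([self._index[v] for v in nodes], dtype=int)

    def to_networks(self) -> list[WeightedDiseaseNetwork]:
        """Unpack the tensor back into one weighted network per layer."""
        out = []
        iu, ju = np.triu_indices(self.n, k=1)
        for k, layer in enumerate(self.layer_order):
            g = nx.Graph()
            g.add_nodes_from(self.node_order)
            w = self.values[iu, ju, k]
            nz = np.nonzero(w)[0]
            for t in nz:
                g.add_edge(self.node_order[iu[t]], self.node_order[ju[t]], weight=float(w[t]))
            out.append(WeightedDiseaseNetwork(layer, g))
        return out

    def copy(self) -> "MultilayerTensor":
        return MultilayerTensor(list(self.node_order), list(self.layer_order), self.values.copy())


def filter_edges_by_weight(
    network: WeightedDiseaseNetwork, min_weight: float
) -> WeightedDiseaseNetwork:
    """Drop edges below ``min_weight``; nodes are kept even if isolated.

    Isolated nodes still count toward the common-disease intersection of
    the layers, so they are deliberately retained.
    """
    if min_weight < 0:
        raise ValueError("min_weight must be >= 0")
    g = nx.Graph()
    g.add_nodes_from(network.graph.nodes)
    for a, b, w in network.edges():
        if w >= min_weight:
            g.add_edge(a, b, weight=w)
    return WeightedDiseaseNetwork(network.name, g)


def restrict_to_common_nodes(
    networks: Sequence[WeightedDiseaseNetwork],
) -> tuple[list[WeightedDiseaseNetwork], set[str]]:
    """Intersect the node sets and return the induced spanning subnetworks."""
    if len(networks) < 2:
        raise ValueError("need at least 2 networks to intersect")
    common: set[str] = set.intersection(*(net.nodes for net in networks))
    if not common:
        raise ValueError("networks share no common nodes")
    restricted = []
    for net in networks:
        sub = nx.Graph()
        sub.add_nodes_from(common)
        for a, b, w in net.edges():
            if a in common and b in common:
                sub.add_edge(a, b, weight=w)
        restricted.append(WeightedDiseaseNetwork(net.name, sub))
    logger.info("restricted %d layers to %d common diseases", len(networks), len(common))
    return restricted, common


def normalize_layer(
    network: WeightedDiseaseNetwork, method: str = "max"
) -> WeightedDiseaseNetwork:
    """Rescale a layer's weights to make heterogeneous layers commensurable.

    ``"max"`` divides by the layer's maximum weight (range becomes [0, 1]);
    ``"none"`` is the identity.
    """
    if method == "none":
        return network.copy()
    if method != "max":
        raise ValueError(f"unknown normalization method {method!r}")
    weights = [w for _, _, w in network.edges()]
    if not weights or max(weights) == 0:
        raise ValueError(f"layer {network.name!r} has no positive weight to normalize by")
    top = max(weights)
    g = nx.Graph()
    g.add_nodes_from(network.graph.nodes)
    for a, b, w in network.edges():
        g.add_edge(a, b, weight=w / top)
    return WeightedDiseaseNetwork(network.name, g)


def build_tensor(networks: Sequence[WeightedDiseaseNetwork]) -> MultilayerTensor:
    """Pack layers sharing one node set into a (n, n, m) tensor.

    Node order is lexicographic; missing edges become zeros. Run
    :func:`restrict_to_common_nodes` first if node sets differ.
    """
    if not networks:
        raise ValueError("no networks given")
    node_sets = [net.nodes for net in networks]
    if any(s != node_sets[0] for s in node_sets[1:]):
        raise ValueError("all layers must share an identical node set")
    node_order = sorted(node_sets[0], key=str)
    index = {v: i for i, v in enumerate(node_order)}
    n, m = len(node_order), len(networks)
    values = np.zeros((n, n, m))
    for k, net in enumerate(networks):
        for a, b, w in net.edges():
            i, j = index[a], index[b]
            values[i, j, k] = values[j, i, k] = w
    return MultilayerTensor(node_order, [net.name for net in networks], values)
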
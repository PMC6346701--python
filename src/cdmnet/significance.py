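"""Statistical null models for conserved disease modules.

Two complementary nulls:

1. *Structural*: randomize every layer with degree-preserving double-edge
   swaps (weights travel with their edges) and rerun the full extraction;
   on randomized layers the extraction should find nothing passing the
   size/weight thresholds.
2. *Weight permutation*: compare a module's induced edge-weight sum in a
   reference similarity network with the sums of same-size node sets drawn
   uniformly at random; the add-one permutation p-value
   (1 + #{null >= observed}) / (1 + n_draws) is never exactly zero.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .extraction import SolverConfig, extract_all_cdms
from .layers import WeightedDiseaseNetwork, build_tensor

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationResult",
    "degree_preserving_rewire",
    "null_extraction_test",
    "module_weight_pvalue",
]


@dataclass(frozen=True)
class PermutationResult:
    """Permutation test outcome for one module."""

    module_id: str
    observed_weight: float
    null_weights: tuple[float, ...]
    p_value: float


def degree_preserving_rewire(
    network: WeightedDiseaseNetwork,
    swap_factor: float = 10.0,
    seed: int = 0,
) -> WeightedDiseaseNetwork:
    """Randomize a layer by double-edge swaps that keep every node's degree.

    A swap replaces edges (u, v), (s, t) by (u, s), (v, t); each new edge
    inherits the weight of the removed edge it shares a ``u``/``t``
    endpoint with. ``swap_factor * n_edges`` swaps are attempted; graphs
    admitting no valid swap (e.g. a star) are returned unchanged with a
    warning.
    """
    g = network.graph.copy()
    m = g.number_of_edges()
    if m < 2:
        logger.warning("layer %r: fewer than 2 edges, rewiring skipped", network.name)
        return network.copy()
    rng = np.random.default_rng(seed)
    attempts = int(swap_factor * m)
    performed = 0
    for _ in range(attempts):
        edges = list(g.edges(data="weight"))
        (u, v, w1), (s, t, w2) = (edges[i] for i in rng.choice(len(edges), 2, replace=False))
        if rng.random() < 0.5:
            s, t, w2 = t, s, w2
        if len({u, v, s, t}) < 4:
            continue
        if g.has_edge(u, s) or g.has_edge(v, t):
            continue
        g.remove_edge(u, v)
        g.remove_edge(s, t)
        g.add_edge(u, s, weight=w1)
        g.add_edge(v, t, weight=w2)
        performed += 1
    if performed == 0:
        logger.warning("layer %r: no valid degree-preserving swap found", network.name)
    return WeightedDiseaseNetwork(network.name, g)


def null_extraction_test(
    networks: Sequence[WeightedDiseaseNetwork],
    extraction_config: SolverConfig,
    n_reps: int,
    seed: int = 0,
    swap_factor: float = 10.0,
) -> Counter:
    """Rewire every layer, rebuild the tensor, rerun extraction; repeat.

    Returns the histogram (Counter) of module counts over ``n_reps``
    repetitions. On layers without genuine conserved structure the mass
    should concentrate at zero.
    """
    counts: Counter = Counter()
    rng = np.random.default_rng(seed)
    for rep in range(n_reps):
        layer_seeds = rng.integers(0, 2**31 - 1, size=len(networks))
        rewired = [
            degree_preserving_rewire(net, swap_factor=swap_factor, seed=int(s))
            for net, s in zip(networks, layer_seeds)
        ]
        tensor = build_tensor(rewired)
        rep_config = SolverConfig(
            **{
                **extraction_config.__dict__,
                "seed": int(rng.integers(0, 2**31 - 1)),
            }
        )
        try:
            modules = extract_all_cdms(tensor, rep_config)
        except ValueError:
            modules = []
        counts[len(modules)] += 1
        logger.debug("null rep %d: %d modules", rep, len(modules))
    return counts


def _induced_weight(adj: np.ndarray, idx: np.ndarray) -> float:
    return float(adj[np.ix_(idx, idx)].sum() / 2.0)


def module_weight_pvalue(
    reference_network: WeightedDiseaseNetwork,
    members: Iterable[str],
    n_draws: int = 10_000,
    seed: int = 0,
    module_id: str = "module",
) -> PermutationResult:
    """Add-one permutation p-value for a module's induced weight sum.

    Each draw picks ``|members|`` distinct nodes uniformly from the
    reference network and sums the edge weights they induce;
    p = (1 + #{null >= observed}) / (1 + n_draws).
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    members = sorted(set(members))
    nodelist = sorted(reference_network.nodes, key=str)
    missing = [v for v in members if v not in reference_network.nodes]
    if missing:
        raise ValueError(f"module members absent from reference network: {missing}")
    if len(members) > len(nodelist):
        raise ValueError("module larger than the reference network")
    adj = nx.to_numpy_array(reference_network.graph, nodelist=nodelist, weight="weight")
    index = {v: i for i, v in enumerate(nodelist)}
    observed = _induced_weight(adj, np.asarray([index[v] for v in members]))
    rng = np.random.default_rng(seed)
    size = len(members)
    null = np.empty(n_draws)
    for d in range(n_draws):
        idx = rng.choice(len(nodelist), size=size, replace=False)
        null[d] = _induced_weight(adj, idx)
    exceed = int(np.count_nonzero(null >= observed))
    p = (1 + exceed) / (1 + n_draws)
    return PermutationResult(module_id, observed, tuple(null.tolist()), p)
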
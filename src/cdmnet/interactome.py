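"""Interactome-based disease similarity via network separation of gene sets.

Each disease is represented by the set of its genes mapped onto an
unweighted protein-protein interaction network. Following the network
medicine separation measure, for gene sets A and B:

* internal distance <d_AA>: mean over genes in A of the shortest-path
  distance to the nearest *other* gene of A;
* cross distance <d_AB>: mean, pooled over all |A| + |B| genes, of the
  distance to the nearest gene of the other set;
* separation s_AB = <d_AB> - (<d_AA> + <d_BB>) / 2.

Negative s_AB means the two disease modules overlap topologically. Gene
pairs with no connecting path (the interactome is incomplete) are excluded
from the means and counted. A monotonically decreasing transform maps
s_AB into a [0, 1] edge weight for the layer.
"""

from __future__ import annotations

import logging
from collections import deque
from typing import Callable, Iterable, Mapping

import networkx as nx
import numpy as np
from scipy.special import expit

from .layers import WeightedDiseaseNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "UndefinedDistanceError",
    "internal_distance",
    "cross_distance",
    "separation",
    "build_interactome_layer",
    "map_genes_to_interactome",
]


class UndefinedDistanceError(ValueError):
    """Raised when a module distance has no finite defining term."""


def _nearest_in_set(graph: nx.Graph, source, targets: set) -> float:
    """Hop distance from ``source`` to the nearest node in ``targets`` (inf if none)."""
    if source in targets:
        return 0.0
    seen = {source}
    frontier = deque([(source, 0)])
    while frontier:
        node, d = frontier.popleft()
        for nbr in graph[node]:
            if nbr in seen:
                continue
            if nbr in targets:
                return float(d + 1)
            seen.add(nbr)
            frontier.append((nbr, d + 1))
    return float("inf")


def _distances_to_set(graph: nx.Graph, targets: set) -> dict:
    """Multi-source BFS: hop distance from every reachable node to ``targets``."""
    dist = {t: 0 for t in targets if t in graph}
    frontier = deque(dist)
    while frontier:
        node = frontier.popleft()
        for nbr in graph[node]:
            if nbr not in dist:
                dist[nbr] = dist[node] + 1
                frontier.append(nbr)
    return dist


def internal_distance(genes: Iterable, interactome: nx.Graph) -> float:
    """<d_AA>: mean nearest-neighbor distance within one gene set.

    Genes with no finite path to any other member are excluded from the
    mean; fewer than 2 mapped genes, or no finite pair at all, is an error.
    """
    members = {g for g in genes if g in interactome}
    if len(members) < 2:
        raise UndefinedDistanceError(
            f"internal distance needs >= 2 mapped genes, got {len(members)}"
        )
    terms = []
    for g in members:
        d = _nearest_in_set(interactome, g, members - {g})
        if np.isfinite(d):
            terms.append(d)
    if not terms:
        raise UndefinedDistanceError("no connected gene pair within the module")
    return float(np.mean(terms))


def cross_distance(a: Iterable, b: Iterable, interactome: nx.Graph) -> float:
    """<d_AB>: pooled mean nearest-cross-set distance over all |A|+|B| genes."""
    set_a = {g for g in a if g in interactome}
    set_b = {g for g in b if g in interactome}
    if not set_a or not set_b:
        raise UndefinedDistanceError("both gene sets must map onto the interactome")
    to_b = _distances_to_set(interactome, set_b)
    to_a = _distances_to_set(interactome, set_a)
    terms = [to_b[g] for g in set_a if g in to_b]
    terms += [to_a[g] for g in set_b if g in to_a]
    excluded = (len(set_a) + len(set_b)) - len(terms)
    if not terms:
        raise UndefinedDistanceError("no finite cross distance between the modules")
    if excluded:
        logger.debug("cross_distance: excluded %d genes with no finite path", excluded)
    return float(np.mean(terms))


def separation(
    a: Iterable,
    b: Iterable,
    interactome: nx.Graph,
    singleton_internal: float = 0.0,
) -> float:
    """Network separation s_AB = <d_AB> - (<d_AA> + <d_BB>) / 2.

    A singleton module has no internal distance; by default it contributes
    ``singleton_internal`` (0.0) instead of aborting.
    """
    set_a = {g for g in a if g in interactome}
    set_b = {g for g in b if g in interactome}
    d_ab = cross_distance(set_a, set_b, interactome)
    d_aa = singleton_internal if len(set_a) == 1 else internal_distance(set_a, interactome)
    d_bb = singleton_internal if len(set_b) == 1 else internal_distance(set_b, interactome)
    return d_ab - (d_aa + d_bb) / 2.0


def _logistic(s: float) -> float:
    return float(expit(-s))


def _rectified(s: float) -> float:
    return min(1.0, max(0.0, -s))


TRANSFORMS: dict[str, Callable[[float], float]] = {
    "logistic": _logistic,
    "neg": _rectified,
}


def map_genes_to_interactome(
    disease_gene_map: Mapping[str, Iterable],
    interactome: nx.Graph,
) -> dict[str, set]:
    """Restrict each disease's gene set to interactome nodes (drops logged)."""
    mapped = {}
    for disease, genes in disease_gene_map.items():
        genes = set(genes)
        kept = {g for g in genes if g in interactome}
        if len(kept) < len(genes):
            logger.debug(
                "disease %r: %d of %d genes not in interactome",
                disease,
                len(genes) - len(kept),
                len(genes),
            )
        if kept:
            mapped[disease] = kept
        else:
            logger.warning("disease %r dropped: no gene maps to the interactome", disease)
    return mapped


def build_interactome_layer(
    disease_gene_map: Mapping[str, Iterable],
    interactome: nx.Graph,
    transform: str = "logistic",
    layer_name: str = "interactome",
) -> WeightedDiseaseNetwork:
    """Pairwise separation of disease gene sets, mapped to [0, 1] edge weights.

    Transforms (all monotonically decreasing in s_AB):

    * ``"logistic"`` (default): 1 / (1 + exp(s_AB)); 0.5 at s = 0.
    * ``"neg"``: max(0, -s_AB) — nonzero only for overlapping modules.
    * ``"minmax"``: min-max rescaling of -s_AB across all computed pairs.

    Pairs with undefined separation are omitted and logged.
    """
    if transform not in TRANSFORMS and transform != "minmax":
        raise ValueError(f"unknown transform {transform!r}")
    mapped = map_genes_to_interactome(disease_gene_map, interactome)
    diseases = sorted(mapped)
    seps: dict[tuple[str, str], float] = {}
    skipped = 0
    for i, a in enumerate(diseases):
        for b in diseases[i + 1 :]:
            try:
                seps[(a, b)] = separation(mapped[a], mapped[b], interactome)
            except UndefinedDistanceError:
                skipped += 1
    if skipped:
        logger.warning("interactome layer: %d disease pairs had undefined separation", skipped)
    g = nx.Graph()
    g.add_nodes_from(diseases)
    if transform == "minmax":
        if seps:
            vals = np.array(list(seps.values()))
            lo, hi = vals.min(), vals.max()
            span = hi - lo if hi > lo else 1.0
            for (a, b), s in seps.items():
                w = (hi - s) / span
                if w > 0:
                    g.add_edge(a, b, weight=float(w))
    else:
        fn = TRANSFORMS[transform]
        for (a, b), s in seps.items():
            w = fn(s)
            if w > 0:
                g.add_edge(a, b, weight=w)
    return WeightedDiseaseNetwork(layer_name, g)
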
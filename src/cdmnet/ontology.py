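"""Wang-style semantic similarity over a typed ontology DAG.

An ontology (GO- or DO-like) is a directed acyclic graph whose edges point
from a child term to its parent and carry a relation type, ``is_a`` or
``part_of``. Each relation type has a *semantic contribution factor*
w_e in (0, 1): walking one edge away from a term multiplies that term's
contribution by w_e, so contributions decay with ancestor distance.

For a term i with ancestor closure T_i, the contribution of t in T_i is

    S_i(i) = 1
    S_i(t) = max{ w_e * S_i(t') : t' a child of t inside T_i }

and the semantic value SV(i) = sum over T_i of S_i(t). The similarity of
two terms is the shared-ancestor mass normalized by the semantic values:

    S(i, j) = sum_{t in T_i ∩ T_j} (S_i(t) + S_j(t)) / (SV(i) + SV(j))

Term-set similarity averages the best-match similarities in both
directions, which turns disease -> term-set annotations into a weighted
disease-disease similarity layer.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import networkx as nx

from .layers import WeightedDiseaseNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "OntologyDAG",
    "DEFAULT_CONTRIBUTION_FACTORS",
    "ancestor_closure",
    "contribution_map",
    "semantic_value",
    "term_similarity",
    "termset_similarity",
    "build_ontology_layer",
]

#: Wang et al. convention: is_a edges decay less than part_of edges.
DEFAULT_CONTRIBUTION_FACTORS: dict[str, float] = {"is_a": 0.8, "part_of": 0.6}


class OntologyDAG:
    """Typed ontology DAG: child -> parent edges labelled is_a / part_of."""

    def __init__(
        self,
        graph: nx.DiGraph,
        contribution_factors: Mapping[str, float] | None = None,
    ):
        factors = dict(contribution_factors or DEFAULT_CONTRIBUTION_FACTORS)
        for rel, w in factors.items():
            if not 0 < w < 1:
                raise ValueError(
                    f"contribution factor for {rel!r} must be in (0, 1), got {w}"
                )
        for u, v, data in graph.edges(data=True):
            rel = data.get("relation")
            if rel not in factors:
                raise ValueError(
                    f"edge ({u!r}, {v!r}) has relation {rel!r} with no contribution factor"
                )
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise ValueError(f"ontology contains a cycle: {cycle}")
        self.graph = graph
        self.contribution_factors = factors

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, str]],
        terms: Iterable[str] | None = None,
        contribution_factors: Mapping[str, float] | None = None,
    ) -> "OntologyDAG":
        """Build from (child, parent, relation) triples."""
        g = nx.DiGraph()
        if terms is not None:
            g.add_nodes_from(terms)
        for child, parent, rel in edges:
            g.add_edge(child, parent, relation=rel)
        return cls(g, contribution_factors=contribution_factors)

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def edge_factor(self, child: str, parent: str) -> float:
        return self.contribution_factors[self.graph[child][parent]["relation"]]


def ancestor_closure(term: str, dag: OntologyDAG) -> set[str]:
    """The term plus every ancestor reachable via child->parent edges."""
    if term not in dag:
        raise KeyError(f"unknown term {term!r}")
    return {term} | nx.descendants(dag.graph, term)


def contribution_map(term: str, dag: OntologyDAG) -> dict[str, float]:
    """S-values of the anchor term over its ancestor closure.

    Dynamic programming in topological order from the anchor toward the
    roots: each ancestor's S-value is the best decayed path product from
    the anchor.
    """
    closure = ancestor_closure(term, dag)
    sub = dag.graph.subgraph(closure)
    s = {term: 1.0}
    # edges point child -> parent, so topological order visits children first
    for t in nx.topological_sort(sub):
        st = s.get(t)
        if st is None:  # unreachable within closure cannot happen, guard anyway
            continue
        for parent in sub.successors(t):
            cand = dag.edge_factor(t, parent) * st
            if cand > s.get(parent, 0.0):
                s[parent] = cand
    return s


def semantic_value(term: str, dag: OntologyDAG) -> float:
    """SV(i): total contribution of the term's closure to the term itself (>= 1)."""
    return sum(contribution_map(term, dag).values())


def term_similarity(
    i: str,
    j: str,
    dag: OntologyDAG,
    _cache: dict[str, dict[str, float]] | None = None,
) -> float:
    """Semantic similarity of two terms; 1 for identical, 0 for disjoint closures."""
    if _cache is not None:
        si = _cache.get(i) or _cache.setdefault(i, contribution_map(i, dag))
        sj = _cache.get(j) or _cache.setdefault(j, contribution_map(j, dag))
    else:
        si, sj = contribution_map(i, dag), contribution_map(j, dag)
    shared = si.keys() & sj.keys()
    if not shared:
        return 0.0
    return sum(si[t] + sj[t] for t in shared) / (sum(si.values()) + sum(sj.values()))


def termset_similarity(
    g1: Iterable[str],
    g2: Iterable[str],
    dag: OntologyDAG,
    _cache: dict[str, dict[str, float]] | None = None,
) -> float:
    """Best-match-average similarity between two nonempty term sets.

    Sim(G1, G2) = [ sum_{s in G1} max_{t in G2} S(s, t)
                  + sum_{t in G2} max_{s in G1} S(t, s) ] / (|G1| + |G2|)
    """
    set1, set2 = sorted(set(g1)), sorted(set(g2))
    if not set1 or not set2:
        raise ValueError("term sets must be nonempty")
    cache = _cache if _cache is not None else {}
    pair_sim = {
        (s, t): term_similarity(s, t, dag, _cache=cache) for s in set1 for t in set2
    }
    forward = sum(max(pair_sim[(s, t)] for t in set2) for s in set1)
    backward = sum(max(pair_sim[(s, t)] for s in set1) for t in set2)
    return (forward + backward) / (len(set1) + len(set2))


def build_ontology_layer(
    annotations: Mapping[str, Iterable[str]],
    dag: OntologyDAG,
    layer_name: str = "ontology",
) -> WeightedDiseaseNetwork:
    """Disease-disease similarity layer from disease -> term-set annotations.

    Terms absent from the DAG are ignored; diseases left with no usable
    terms are dropped (logged). Only pairs with positive similarity are
    emitted — the tensor treats missing edges as zero.
    """
    usable: dict[str, list[str]] = {}
    for disease, terms in annotations.items():
        kept = sorted(t for t in set(terms) if t in dag)
        if kept:
            usable[disease] = kept
        else:
            logger.warning(
                "disease %r dropped: none of its terms are in the ontology", disease
            )
    diseases = sorted(usable)
    cache: dict[str, dict[str, float]] = {}
    g = nx.Graph()
    g.add_nodes_from(diseases)
    for a_idx, a in enumerate(diseases):
        for b in diseases[a_idx + 1 :]:
            sim = termset_similarity(usable[a], usable[b], dag, _cache=cache)
            if sim > 0:
                g.add_edge(a, b, weight=sim)
    return WeightedDiseaseNetwork(layer_name, g)
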
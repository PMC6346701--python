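"""Semantic similarity: hand-derived values, invariants, brute-force oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdmnet import (
    OntologyDAG,
    ancestor_closure,
    build_ontology_layer,
    contribution_map,
    semantic_value,
    term_similarity,
    termset_similarity,
)


def brute_force_contribution(term, dag):
    """Max decayed path product over *all* child->parent paths (oracle)."""
    best = {term: 1.0}
    frontier = [(term, 1.0)]
    while frontier:
        node, value = frontier.pop()
        for parent in dag.graph.successors(node):
            cand = dag.edge_factor(node, parent) * value
            if cand > best.get(parent, 0.0) - 1e-15:
                if cand > best.get(parent, 0.0):
                    best[parent] = cand
                frontier.append((parent, cand))
    return best


def random_dag(n_terms, rng):
    edges = []
    for i in range(1, n_terms):
        for p in rng.choice(i, size=min(1 + rng.integers(2), i), replace=False):
            rel = "is_a" if rng.random() < 0.5 else "part_of"
            edges.append((f"t{i}", f"t{int(p)}", rel))
    return OntologyDAG.from_edges(edges, terms=[f"t{i}" for i in range(n_terms)])


class TestContribution:
    def test_chain_hand_values(self, chain_dag):
        assert contribution_map("C", chain_dag) == pytest.approx(
            {"C": 1.0, "B": 0.8, "A": 0.64}
        )

    def test_diamond_takes_max_over_paths(self, diamond_dag):
        # via B1: 0.8*0.8 = 0.64; via B2: 0.8*0.6 = 0.48
        s = contribution_map("C", diamond_dag)
        assert s["A"] == pytest.approx(0.64)

    def test_root_anchor_is_trivial(self, chain_dag):
        assert contribution_map("A", chain_dag) == {"A": 1.0}
        assert semantic_value("A", chain_dag) == 1.0

    def test_ancestor_closure_chain(self, chain_dag):
        assert ancestor_closure("C", chain_dag) == {"A", "B", "C"}
        assert ancestor_closure("A", chain_dag) == {"A"}

    def test_unknown_term_raises(self, chain_dag):
        with pytest.raises(KeyError):
            ancestor_closure("missing", chain_dag)

    def test_contribution_decays_along_chain(self):
        dag = OntologyDAG.from_edges(
            [(f"n{i}", f"n{i+1}", "is_a") for i in range(6)]
        )
        s = contribution_map("n0", dag)
        values = [s[f"n{i}"] for i in range(7)]
        assert all(a > b for a, b in zip(values, values[1:]))

    @pytest.mark.parametrize("seed", range(5))
    def test_dp_matches_path_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        dag = random_dag(10, rng)
        for term in dag.terms:
            expected = brute_force_contribution(term, dag)
            assert contribution_map(term, dag) == pytest.approx(expected)


class TestSemanticValue:
    def test_chain_sum(self, chain_dag):
        assert semantic_value("C", chain_dag) == pytest.approx(2.44)
        assert semantic_value("B", chain_dag) == pytest.approx(1.8)

    def test_always_at_least_one(self):
        rng = np.random.default_rng(3)
        dag = random_dag(12, rng)
        assert all(semantic_value(t, dag) >= 1.0 for t in dag.terms)


class TestTermSimilarity:
    def test_identity_is_one(self, chain_dag):
        for t in chain_dag.terms:
            assert term_similarity(t, t, chain_dag) == pytest.approx(1.0)

    def test_chain_hand_value(self, chain_dag):
        assert term_similarity("B", "A", chain_dag) == pytest.approx(1.8 / 2.8)

    def test_disjoint_closures_give_zero(self):
        dag = OntologyDAG.from_edges([("B", "A", "is_a"), ("Y", "X", "is_a")])
        assert term_similarity("B", "Y", dag) == 0.0

    @pytest.mark.parametrize("seed", range(4))
    def test_symmetry_on_random_dags(self, seed):
        rng = np.random.default_rng(seed)
        dag = random_dag(9, rng)
        terms = sorted(dag.terms)
        for i, j in itertools.combinations(terms, 2):
            assert term_similarity(i, j, dag) == pytest.approx(
                term_similarity(j, i, dag), abs=1e-14
            )


class TestTermsetSimilarity:
    def test_identical_sets_give_one(self, chain_dag):
        assert termset_similarity({"A", "B"}, {"A", "B"}, chain_dag) == pytest.approx(1.0)

    def test_singleton_sets_reduce_to_term_similarity(self, chain_dag):
        assert termset_similarity({"B"}, {"A"}, chain_dag) == pytest.approx(
            term_similarity("B", "A", chain_dag)
        )

    def test_disjoint_components_give_zero(self):
        dag = OntologyDAG.from_edges([("B", "A", "is_a"), ("Y", "X", "is_a")])
        assert termset_similarity({"A", "B"}, {"X", "Y"}, dag) == 0.0

    def test_empty_set_rejected(self, chain_dag):
        with pytest.raises(ValueError):
            termset_similarity(set(), {"A"}, chain_dag)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_bounded_and_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        dag = random_dag(8, rng)
        terms = sorted(dag.terms)
        g1 = set(rng.choice(terms, size=3, replace=False))
        g2 = set(rng.choice(terms, size=2, replace=False))
        s12 = termset_similarity(g1, g2, dag)
        assert 0.0 <= s12 <= 1.0 + 1e-12
        assert s12 == pytest.approx(termset_similarity(g2, g1, dag), abs=1e-14)


class TestOntologyLayer:
    def test_identical_annotations_weight_one(self, chain_dag):
        layer = build_ontology_layer({"d1": {"B", "C"}, "d2": {"B", "C"}}, chain_dag)
        assert layer.weight("d1", "d2") == pytest.approx(1.0)

    def test_disease_without_known_terms_dropped(self, chain_dag, caplog):
        with caplog.at_level("WARNING"):
            layer = build_ontology_layer(
                {"d1": {"B"}, "d2": {"unknown-term"}}, chain_dag
            )
        assert layer.nodes == {"d1"}
        assert any("d2" in r.message for r in caplog.records)

    def test_matches_direct_termset_evaluation(self, chain_dag):
        ann = {"d1": {"C"}, "d2": {"B"}, "d3": {"A", "B"}}
        layer = build_ontology_layer(ann, chain_dag)
        for a, b in itertools.combinations(sorted(ann), 2):
            assert layer.weight(a, b) == pytest.approx(
                termset_similarity(ann[a], ann[b], chain_dag)
            )

    def test_invalid_contribution_factor_rejected(self):
        with pytest.raises(ValueError, match="contribution factor"):
            OntologyDAG.from_edges(
                [("B", "A", "is_a")], contribution_factors={"is_a": 1.0, "part_of": 0.6}
            )
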
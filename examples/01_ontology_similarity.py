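"""Semantic similarity on a toy ontology DAG.

Builds a three-term chain C is_a B is_a A, walks through the contribution
map, semantic values and term/term-set similarities, then derives a
disease-disease similarity layer from annotations.
"""

from cdmnet import (
    OntologyDAG,
    build_ontology_layer,
    contribution_map,
    semantic_value,
    term_similarity,
    termset_similarity,
)

dag = OntologyDAG.from_edges([("C", "B", "is_a"), ("B", "A", "is_a")])

print("Contribution of each ancestor to term C (decays by 0.8 per is_a edge):")
for term, s in sorted(contribution_map("C", dag).items()):
    print(f"  S_C({term}) = {s:.4f}")
print(f"Semantic value SV(C) = {semantic_value('C', dag):.4f}  (sum of contributions)")
print(f"Term similarity S(B, A) = {term_similarity('B', 'A', dag):.4f}")
print(f"Term-set similarity Sim({{B}}, {{A}}) = {termset_similarity({'B'}, {'A'}, dag):.4f}")

# two diseases annotated to overlapping term sets -> a weighted layer edge
annotations = {"disease1": {"B", "C"}, "disease2": {"A", "B"}}
layer = build_ontology_layer(annotations, dag)
w = layer.weight("disease1", "disease2")
print(f"\nDerived layer edge weight(disease1, disease2) = {w:.4f}")
print("A weight of 1.0 would mean identical annotation sets; 0 means the")
print("two diseases' terms share no ancestors at all.")
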
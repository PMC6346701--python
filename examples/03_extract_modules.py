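"""Conserved module extraction from a synthetic multilayer tensor.

Plants one 8-disease heavy module in a 200-disease, 4-layer background and
recovers it with the constrained tensor solver.
"""

from cdmnet import (
    PlantedModuleSpec,
    SolverConfig,
    extract_all_cdms,
    generate_multilayer,
)

tensor, truth = generate_multilayer(
    n_nodes=200, m_layers=4, specs=[PlantedModuleSpec(members=8)], seed=42
)
print(f"Tensor: {tensor.n} diseases x {tensor.m} layers")
print(f"Planted module: {truth['planted']}")

modules = extract_all_cdms(tensor, SolverConfig(seed=0))
for mod in modules:
    print(f"\n{mod.module_id}: {mod.size} diseases, total weight {mod.total_weight:.2f}")
    for layer, w in sorted(mod.per_layer_weight.items()):
        print(f"  {layer}: induced weight {w:.2f}")
    recovered = set(mod.members) == set(truth["planted"])
    print(f"  members match planted truth: {recovered}")
print("\nEach per-layer weight is the module's induced edge-weight sum in that")
print("layer; a conserved module must be heavy in every layer, and the")
print("background (mean pair weight ~1e-4) contributes almost nothing.")
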
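"""End-to-end pipeline: layers -> tensor -> modules -> significance -> annotation.

A run is configured by a single declarative :class:`PipelineConfig` whose
seeds are all explicit; rerunning the same config reproduces the outputs
bit for bit. Every stage logs its parameters and the run writes a JSON
manifest with input paths, parameters and output digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as cio
from .annotation import classify_module, gene_frequency, repositioning_candidates
from .extraction import SolverConfig, extract_all_cdms
from .layers import (
    build_tensor,
    filter_edges_by_weight,
    normalize_layer,
    restrict_to_common_nodes,
)
from .significance import module_weight_pvalue

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Declarative description of one full pipeline run."""

    layer_paths: dict[str, str]
    out_dir: str
    min_edge_weight: dict[str, float] = field(default_factory=dict)
    normalize: str = "max"
    solver: SolverConfig = field(default_factory=SolverConfig)
    pvalue_reference_layer: str | None = None
    pvalue_draws: int = 10_000
    pvalue_seed: int = 0
    class_map_path: str | None = None
    gene_map_path: str | None = None
    drug_table_path: str | None = None
    min_drug_score: float = 0.6

    def validate_paths(self) -> None:
        missing = [
            p
            for p in [
                *self.layer_paths.values(),
                self.class_map_path,
                self.gene_map_path,
                self.drug_table_path,
            ]
            if p is not None and not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing input paths: {missing}")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write the module report, annotations and manifest.

    Returns a summary dict (module count, output paths, digests).
    """
    config.validate_paths()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # stage 1: load, filter, restrict, normalize, pack
    layers = []
    for name in sorted(config.layer_paths):
        net = cio.read_weighted_edge_list(config.layer_paths[name])
        net.name = name
        cutoff = config.min_edge_weight.get(name, 0.0)
        if cutoff > 0:
            net = filter_edges_by_weight(net, cutoff)
        logger.info("layer %s: %d nodes, %d edges after filtering", name, len(net.nodes), net.n_edges)
        layers.append(net)
    restricted, common = restrict_to_common_nodes(layers)
    restricted = [normalize_layer(net, config.normalize) for net in restricted]
    tensor = build_tensor(restricted)
    logger.info("tensor: %d diseases x %d layers", tensor.n, tensor.m)

    # stage 2: extraction
    modules = extract_all_cdms(tensor, config.solver)
    logger.info("extracted %d modules", len(modules))

    # stage 3: permutation significance against a reference layer
    p_values: dict[str, float] = {}
    if modules:
        ref_name = config.pvalue_reference_layer or restricted[0].name
        reference = next(net for net in restricted if net.name == ref_name)
        for i, module in enumerate(modules):
            result = module_weight_pvalue(
                reference,
                module.members,
                n_draws=config.pvalue_draws,
                seed=config.pvalue_seed + i,
                module_id=module.module_id,
            )
            p_values[module.module_id] = result.p_value

    # stage 4: annotation
    class_map = cio.read_class_map(config.class_map_path) if config.class_map_path else None
    gene_map = cio.read_annotations(config.gene_map_path) if config.gene_map_path else None
    drug_table = cio.read_drug_table(config.drug_table_path) if config.drug_table_path else None

    rows = []
    annotation_lines = []
    for module in modules:
        label = ""
        if class_map is not None:
            cls = classify_module(module.members, class_map)
            label = cls.label
        rows.append(
            cio.ModuleRow(
                module_id=module.module_id,
                members=module.members,
                per_layer_weight=tuple(sorted(module.per_layer_weight.items())),
                total_weight=module.total_weight,
                class_label=label,
                p_value=p_values.get(module.module_id),
            )
        )
        if gene_map is not None:
            _, top_genes = gene_frequency(module.members, gene_map)
            annotation_lines.append(
                f"{module.module_id}\tmax_frequency_genes\t{';'.join(top_genes)}"
            )
        if drug_table is not None:
            for rec in repositioning_candidates(
                list(module.members),
                drug_table,
                min_score=config.min_drug_score,
                module_id=module.module_id,
            ):
                annotation_lines.append(
                    f"{module.module_id}\tdrug\t{rec.drug_name}\t{float(rec.score):g}"
                    f"\t{';'.join(rec.uncovered)}"
                )

    report_path = out_dir / "modules.tsv"
    cio.write_modules(rows, report_path)
    outputs = {"modules": str(report_path)}
    if annotation_lines:
        ann_path = out_dir / "annotations.tsv"
        ann_path.write_text("\n".join(annotation_lines) + "\n")
        outputs["annotations"] = str(ann_path)

    manifest = {
        "inputs": {name: str(p) for name, p in sorted(config.layer_paths.items())},
        "common_diseases": len(common),
        "normalize": config.normalize,
        "solver": {k: v for k, v in config.solver.__dict__.items()},
        "pvalue_draws": config.pvalue_draws,
        "pvalue_seed": config.pvalue_seed,
        "n_modules": len(modules),
        "outputs": {k: _digest(Path(v)) for k, v in outputs.items()},
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {
        "n_modules": len(modules),
        "modules": modules,
        "p_values": p_values,
        "outputs": outputs,
        "manifest": str(manifest_path),
        "digests": manifest["outputs"],
    }
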
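"""Readers and writers for every on-disk artifact the pipeline touches.

All formats are plain text: TSV edge lists (one row per unordered disease
pair), an OBO-format subset for ontologies, GMT-style annotation tables,
CTD-style drug-disease association tables, and the module report.
Validation is strict — malformed rows fail with a line number rather than
being silently skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet

from .layers import WeightedDiseaseNetwork
from .ontology import OntologyDAG

logger = logging.getLogger(__name__)

__all__ = [
    "DrugAssociationRecord",
    "read_weighted_edge_list",
    "write_weighted_edge_list",
    "read_ontology",
    "read_annotations",
    "write_annotations",
    "read_drug_table",
    "read_class_map",
    "write_modules",
    "read_modules",
    "ModuleRow",
]

#: CTD-style association markers: T = therapeutic (the drug treats the
#: disease), M = marker/mechanism.
DRUG_MARKERS = frozenset({"T", "M"})


@dataclass(frozen=True)
class DrugAssociationRecord:
    """One curated drug-disease association with its category flag."""

    drug_id: str
    drug_name: str
    disease_id: str
    marker: str


def _split_row(line: str, delimiter: str) -> list[str]:
    return [c.strip() for c in line.rstrip("\n").split(delimiter)]


def read_weighted_edge_list(
    path: str | Path, delimiter: str = "\t"
) -> WeightedDiseaseNetwork:
    """Read a TSV edge list (header ``node_a  node_b  weight``) into a layer.

    Each unordered pair may appear once; self-loops and negative weights are
    rejected with the offending line number.
    """
    path = Path(path)
    g = nx.Graph()
    with path.open() as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"{path}: empty file, expected a header row")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cols = _split_row(line, delimiter)
            if len(cols) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 columns, got {len(cols)}"
                )
            a, b, raw_w = cols
            try:
                w = float(raw_w)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: unparseable weight {raw_w!r}")
            if a == b:
                raise ValueError(f"{path}:{lineno}: self-loop on node {a!r}")
            if w < 0:
                raise ValueError(f"{path}:{lineno}: negative weight {w}")
            if g.has_edge(a, b):
                raise ValueError(f"{path}:{lineno}: duplicate pair ({a!r}, {b!r})")
            g.add_edge(a, b, weight=w)
    return WeightedDiseaseNetwork(path.stem, g)


def write_weighted_edge_list(
    network: WeightedDiseaseNetwork, path: str | Path, delimiter: str = "\t"
) -> None:
    """Write a layer as a TSV edge list, one unordered pair per row.

    Rows are sorted lexicographically on (node_a, node_b) so write-read
    round trips are byte-stable.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(delimiter.join(["node_a", "node_b", "weight"]) + "\n")
        for a, b, w in sorted(network.edges()):
            fh.write(delimiter.join([a, b, repr(w)]) + "\n")


def read_ontology(
    path: str | Path,
    contribution_factors: Mapping[str, float] | None = None,
) -> OntologyDAG:
    """Parse an OBO-format ontology into a typed DAG.

    Only ``is_a`` and ``relationship: part_of`` edges are kept; other
    relation types are dropped with a logged count. Cycles abort the load.
    """
    path = Path(path)
    multi = obonet.read_obo(str(path))
    g = nx.DiGraph()
    g.add_nodes_from(multi.nodes)
    dropped = 0
    for child, parent, rel in multi.edges(keys=True):
        if rel not in ("is_a", "part_of"):
            dropped += 1
            continue
        if g.has_edge(child, parent):
            # parallel is_a + part_of between one pair: keep is_a, the
            # stronger semantic relation
            if g[child][parent]["relation"] == "is_a":
                continue
        g.add_edge(child, parent, relation=rel)
    if dropped:
        logger.warning("%s: dropped %d edges with unsupported relation types", path, dropped)
    return OntologyDAG(g, contribution_factors=contribution_factors)


def read_annotations(path: str | Path, delimiter: str = "\t") -> dict[str, set[str]]:
    """Read a GMT-style table: ``entity <tab> member <tab> member ...``.

    Members are deduplicated; a repeated entity row or an empty member list
    is an error.
    """
    path = Path(path)
    out: dict[str, set[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cols = _split_row(line, delimiter)
            entity, members = cols[0], [c for c in cols[1:] if c]
            if not entity:
                raise ValueError(f"{path}:{lineno}: empty entity id")
            if not members:
                raise ValueError(f"{path}:{lineno}: entity {entity!r} has no members")
            if entity in out:
                raise ValueError(f"{path}:{lineno}: duplicate entity {entity!r}")
            out[entity] = set(members)
    return out


def write_annotations(
    annotations: Mapping[str, Iterable[str]], path: str | Path, delimiter: str = "\t"
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for entity in sorted(annotations):
            members = sorted(set(annotations[entity]))
            fh.write(delimiter.join([entity, *members]) + "\n")


def read_drug_table(path: str | Path, delimiter: str = "\t") -> list[DrugAssociationRecord]:
    """Read a drug-disease association TSV.

    Columns: ``drug_id  drug_name  disease_id  marker``; marker must come
    from the closed vocabulary (T = therapeutic, M = marker/mechanism) and
    each (drug, disease) pair may appear once.
    """
    path = Path(path)
    records: list[DrugAssociationRecord] = []
    seen: set[tuple[str, str]] = set()
    with path.open() as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"{path}: empty file, expected a header row")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cols = _split_row(line, delimiter)
            if len(cols) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(cols)}")
            drug_id, drug_name, disease_id, marker = cols
            if marker not in DRUG_MARKERS:
                raise ValueError(
                    f"{path}:{lineno}: marker {marker!r} not in {sorted(DRUG_MARKERS)}"
                )
            key = (drug_id, disease_id)
            if key in seen:
                raise ValueError(f"{path}:{lineno}: duplicate (drug, disease) pair {key}")
            seen.add(key)
            records.append(DrugAssociationRecord(drug_id, drug_name, disease_id, marker))
    return records


def write_drug_table(
    records: Sequence[DrugAssociationRecord], path: str | Path, delimiter: str = "\t"
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(delimiter.join(["drug_id", "drug_name", "disease_id", "marker"]) + "\n")
        for r in sorted(records, key=lambda r: (r.drug_id, r.disease_id)):
            fh.write(delimiter.join([r.drug_id, r.drug_name, r.disease_id, r.marker]) + "\n")


def read_class_map(path: str | Path, delimiter: str = "\t") -> dict[str, str]:
    """Read a two-column ``disease_id  class`` TSV (MeSH-style labels)."""
    path = Path(path)
    out: dict[str, str] = {}
    with path.open() as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"{path}: empty file, expected a header row")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cols = _split_row(line, delimiter)
            if len(cols) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(cols)}")
            disease, label = cols
            if disease in out:
                raise ValueError(f"{path}:{lineno}: duplicate disease {disease!r}")
            out[disease] = label
    return out


@dataclass(frozen=True)
class ModuleRow:
    """One row of the module report (round-trips through the TSV losslessly)."""

    module_id: str
    members: tuple[str, ...]
    per_layer_weight: tuple[tuple[str, float], ...]
    total_weight: float
    class_label: str = ""
    p_value: float | None = None


def write_modules(modules: Sequence[ModuleRow], path: str | Path) -> None:
    """Write the module report TSV.

    Columns: module id, semicolon-joined members, semicolon-joined
    ``layer=weight`` pairs, total weight, class label, p-value.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            "\t".join(
                ["module_id", "members", "per_layer_weight", "total_weight", "class", "p_value"]
            )
            + "\n"
        )
        for mod in modules:
            layer_field = ";".join(f"{name}={repr(w)}" for name, w in mod.per_layer_weight)
            fh.write(
                "\t".join(
                    [
                        mod.module_id,
                        ";".join(mod.members),
                        layer_field,
                        repr(mod.total_weight),
                        mod.class_label,
                        "" if mod.p_value is None else repr(mod.p_value),
                    ]
                )
                + "\n"
            )


def read_modules(path: str | Path) -> list[ModuleRow]:
    path = Path(path)
    rows: list[ModuleRow] = []
    with path.open() as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"{path}: empty file, expected a header row")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(cols)}")
            module_id, members, layer_field, total, label, pval = cols
            per_layer = []
            if layer_field:
                for item in layer_field.split(";"):
                    name, _, w = item.partition("=")
                    per_layer.append((name, float(w)))
            rows.append(
                ModuleRow(
                    module_id=module_id,
                    members=tuple(members.split(";")) if members else (),
                    per_layer_weight=tuple(per_layer),
                    total_weight=float(total),
                    class_label=label,
                    p_value=float(pval) if pval else None,
                )
            )
    return rows
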
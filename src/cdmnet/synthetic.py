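"""Synthetic inputs with known ground truth for every pipeline stage.

The real study inputs (curated disease-gene tables, a reference
interactome, a symptom similarity network, GO/DO releases, CTD drug
associations) are large external resources; these generators emulate their
statistical shape at desk scale so that recovery, null behavior and
scoring can be tested against planted truth:

* multilayer tensors: sparse noisy background plus planted heavy modules
  recurring across layers;
* random typed ontology DAGs with disease annotations whose group
  structure induces high semantic similarity;
* preferential-attachment interactomes with clustered or scattered disease
  gene sets (low vs high network separation);
* drug association tables with tunable therapeutic coverage per module.

Default scale: 200 diseases over 4 layers — the study's 399-disease
four-layer shape at roughly half size. Background edges have density 0.01
with truncated-exponential weights (mean 0.01, capped at 1); planted
modules are fully connected within the module at weight mean 0.6. The
background is deliberately thin enough that the heaviest background-only
small subset stays clearly below the module weight threshold (0.3),
mirroring data in which randomized layers contain no conserved module.
All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .io import DrugAssociationRecord
from .layers import MultilayerTensor, WeightedDiseaseNetwork
from .ontology import OntologyDAG

__all__ = [
    "PlantedModuleSpec",
    "SyntheticWorld",
    "generate_multilayer",
    "generate_ontology_world",
    "generate_interactome_world",
    "generate_drug_table",
    "generate_world",
    "DEFAULT_BACKGROUND_MEAN",
    "DEFAULT_BACKGROUND_DENSITY",
    "DEFAULT_PLANTED_MEAN",
]

DEFAULT_BACKGROUND_MEAN = 0.01
DEFAULT_BACKGROUND_DENSITY = 0.01
DEFAULT_PLANTED_MEAN = 0.6
DEFAULT_PLANTED_SPREAD = 0.1


@dataclass(frozen=True)
class PlantedModuleSpec:
    """Ground truth for one planted heavy recurrent module.

    ``members`` is either a node count (allocated automatically) or an
    explicit id list; ``layers`` restricts which layers carry the heavy
    block (None = all layers); weights are drawn Normal(mean, spread)
    truncated to positive.
    """

    members: int | tuple[str, ...]
    mean: float = DEFAULT_PLANTED_MEAN
    spread: float = DEFAULT_PLANTED_SPREAD
    layers: tuple[int, ...] | None = None
    label: str = "planted"

    def size(self) -> int:
        return self.members if isinstance(self.members, int) else len(self.members)


@dataclass
class SyntheticWorld:
    """A complete synthetic input stack with its planted truth."""

    interactome: nx.Graph
    disease_gene_map: dict[str, set[str]]
    ontology: OntologyDAG
    term_annotations: dict[str, set[str]]
    disease_ontology: OntologyDAG
    disease_term_annotations: dict[str, set[str]]
    symptom_layer: WeightedDiseaseNetwork
    drug_table: list[DrugAssociationRecord]
    class_map: dict[str, str]
    truth: dict[str, tuple[str, ...]] = field(default_factory=dict)


def _truncated_exponential(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    return np.minimum(rng.exponential(mean, size=size), 1.0)


def _positive_normal(rng: np.random.Generator, mean: float, spread: float, size: int) -> np.ndarray:
    w = rng.normal(mean, spread, size=size)
    return np.maximum(w, 1e-6)


def generate_multilayer(
    n_nodes: int = 200,
    m_layers: int = 4,
    specs: Sequence[PlantedModuleSpec] = (),
    background_mean: float = DEFAULT_BACKGROUND_MEAN,
    background_density: float = DEFAULT_BACKGROUND_DENSITY,
    seed: int = 0,
) -> tuple[MultilayerTensor, dict[str, tuple[str, ...]]]:
    """Sparse noisy multilayer tensor with planted heavy recurrent modules.

    Background edges appear independently per layer with probability
    ``background_density`` and truncated-exponential weights around
    ``background_mean``. Each planted module is a full block of heavy
    weights in its designated layers. Returns the tensor and the
    label -> member-tuple truth map. Planted modules must be disjoint.
    """
    if background_mean < 0:
        raise ValueError("background_mean must be >= 0")
    rng = np.random.default_rng(seed)
    node_order = [f"D{idx:04d}" for idx in range(n_nodes)]
    values = np.zeros((n_nodes, n_nodes, m_layers))
    iu, ju = np.triu_indices(n_nodes, k=1)
    for k in range(m_layers):
        present = rng.random(len(iu)) < background_density
        weights = np.where(present, _truncated_exponential(rng, background_mean, len(iu)), 0.0)
        values[iu, ju, k] = weights
        values[ju, iu, k] = weights

    truth: dict[str, tuple[str, ...]] = {}
    used: set[int] = set()
    free = list(range(n_nodes))
    rng.shuffle(free)
    free_iter = iter(free)
    for spec in specs:
        if spec.mean <= background_mean:
            raise ValueError("planted weight mean must exceed the background mean")
        if isinstance(spec.members, int):
            ids = []
            for _ in range(spec.members):
                idx = next(i for i in free_iter if i not in used)
                ids.append(idx)
        else:
            ids = [node_order.index(v) for v in spec.members]
        if used & set(ids):
            raise ValueError(f"planted module {spec.label!r} overlaps an earlier one")
        used.update(ids)
        layer_ids = range(m_layers) if spec.layers is None else spec.layers
        ids_arr = np.asarray(sorted(ids))
        bi, bj = np.triu_indices(len(ids_arr), k=1)
        for k in layer_ids:
            w = _positive_normal(rng, spec.mean, spec.spread, len(bi))
            values[ids_arr[bi], ids_arr[bj], k] = w
            values[ids_arr[bj], ids_arr[bi], k] = w
        truth[spec.label] = tuple(node_order[i] for i in sorted(ids))
    layer_order = [f"layer{k}" for k in range(m_layers)]
    return MultilayerTensor(node_order, layer_order, values), truth


def generate_ontology_world(
    n_terms: int = 60,
    n_diseases: int = 20,
    seed: int = 0,
    n_groups: int = 2,
    core_size: int = 4,
    terms_per_disease: int = 6,
    n_roots: int = 6,
) -> tuple[OntologyDAG, dict[str, set[str]], dict[str, tuple[str, ...]]]:
    """Random typed DAG plus disease annotations with group structure.

    The DAG grows as a forest of ``n_roots`` disconnected branches
    (mirroring an ontology's disjoint top-level branches): each new term
    attaches to 1-2 existing parents *within its branch*, with
    is_a/part_of relations sampled at random. Terms in different branches
    share no ancestors, so their similarity is exactly zero — random term
    sets therefore have a realistically low baseline similarity.

    Diseases are split into ``n_groups`` groups; each group shares a core
    of ``core_size`` terms from a single branch (inducing high
    within-group semantic similarity) and pads with random terms. Returns
    (dag, annotations, group truth).
    """
    if n_terms < 2:
        raise ValueError("need at least 2 terms")
    n_roots = min(n_roots, n_terms)
    rng = np.random.default_rng(seed)
    terms = [f"T{idx:04d}" for idx in range(n_terms)]
    branches: list[list[int]] = [[r] for r in range(n_roots)]
    edges: list[tuple[str, str, str]] = []
    for idx in range(n_roots, n_terms):
        branch = branches[idx % n_roots]
        n_parents = 1 + int(rng.random() < 0.4)
        parents = rng.choice(len(branch), size=min(n_parents, len(branch)), replace=False)
        for p in np.atleast_1d(parents):
            rel = "is_a" if rng.random() < 0.7 else "part_of"
            edges.append((terms[idx], terms[branch[int(p)]], rel))
        branch.append(idx)
    dag = OntologyDAG.from_edges(edges, terms=terms)

    annotations: dict[str, set[str]] = {}
    truth: dict[str, tuple[str, ...]] = {}
    diseases = [f"D{idx:04d}" for idx in range(n_diseases)]
    group_cores = []
    for g in range(n_groups):
        branch = branches[g % n_roots]
        pool = [terms[i] for i in branch]
        group_cores.append(
            set(rng.choice(pool, size=min(core_size, len(pool)), replace=False))
        )
    for d_idx, disease in enumerate(diseases):
        group = d_idx % n_groups
        padding = set(
            rng.choice(terms, size=max(terms_per_disease - core_size, 0), replace=False)
        )
        annotations[disease] = set(group_cores[group]) | padding
        truth.setdefault(f"group{group}", ())
        truth[f"group{group}"] += (disease,)
    return dag, annotations, truth


def generate_interactome_world(
    n_genes: int = 500,
    n_diseases: int = 20,
    clustering: float = 0.5,
    seed: int = 0,
    genes_per_disease: int = 8,
) -> tuple[nx.Graph, dict[str, set[str]], dict[str, list[str]]]:
    """Preferential-attachment interactome with clustered/scattered gene sets.

    A fraction ``clustering`` of diseases draw their genes from *one
    shared* small network neighborhood — these diseases' gene modules
    interleave, giving low (often negative) pairwise separation. The rest
    scatter genes uniformly over the whole network. Returns (interactome,
    disease -> genes, truth) where truth lists the related ("clustered")
    and unrelated ("scattered") disease ids.
    """
    if n_genes < 10:
        raise ValueError("need at least 10 genes")
    rng = np.random.default_rng(seed)
    graph = nx.barabasi_albert_graph(n_genes, 3, seed=int(rng.integers(2**31 - 1)))
    graph = nx.relabel_nodes(graph, {i: f"G{i:05d}" for i in graph.nodes})
    nodes = sorted(graph.nodes)
    # one shared, deliberately tight breadth-first neighborhood for all
    # clustered diseases: the pool is only 1.5x the per-disease gene count,
    # so clustered gene sets overlap and interleave (negative separation)
    pool_size = max(genes_per_disease + 2, int(1.5 * genes_per_disease))
    center = nodes[int(rng.integers(len(nodes)))]
    neighborhood = [center]
    frontier = [center]
    seen = {center}
    while len(neighborhood) < pool_size and frontier:
        nxt = []
        for v in frontier:
            for nbr in sorted(graph[v]):
                if nbr not in seen:
                    seen.add(nbr)
                    neighborhood.append(nbr)
                    nxt.append(nbr)
        frontier = nxt
    neighborhood = neighborhood[:pool_size]
    disease_gene_map: dict[str, set[str]] = {}
    truth: dict[str, list[str]] = {"clustered": [], "scattered": []}
    n_clustered = int(round(clustering * n_diseases))
    for d_idx in range(n_diseases):
        disease = f"D{d_idx:04d}"
        if d_idx < n_clustered:
            pick = rng.choice(
                len(neighborhood),
                size=min(genes_per_disease, len(neighborhood)),
                replace=False,
            )
            disease_gene_map[disease] = {neighborhood[i] for i in pick}
            truth["clustered"].append(disease)
        else:
            pick = rng.choice(len(nodes), size=genes_per_disease, replace=False)
            disease_gene_map[disease] = {nodes[i] for i in pick}
            truth["scattered"].append(disease)
    return graph, disease_gene_map, truth


def generate_drug_table(
    modules: Mapping[str, Sequence[str]],
    coverage: float = 0.8,
    seed: int = 0,
    drugs_per_module: int = 20,
) -> list[DrugAssociationRecord]:
    """Synthetic CTD-style associations with known therapeutic coverage.

    For each module, ``drugs_per_module`` drugs are linked therapeutically
    to each member independently with probability ``coverage``, so the
    expected Drug_score equals ``coverage``. A sprinkling of non-therapeutic
    (marker M) rows is added as realistic noise.
    """
    if not 0 <= coverage <= 1:
        raise ValueError("coverage must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    records: list[DrugAssociationRecord] = []
    drug_no = 0
    for label in sorted(modules):
        members = sorted(modules[label])
        for _ in range(drugs_per_module):
            drug_id = f"DR{drug_no:05d}"
            drug_no += 1
            for disease in members:
                if rng.random() < coverage:
                    records.append(
                        DrugAssociationRecord(drug_id, f"drug-{drug_id}", disease, "T")
                    )
                elif rng.random() < 0.1:
                    records.append(
                        DrugAssociationRecord(drug_id, f"drug-{drug_id}", disease, "M")
                    )
    return records


def generate_world(
    n_diseases: int = 24,
    module_size: int = 6,
    seed: int = 0,
) -> SyntheticWorld:
    """A full synthetic input stack with one planted disease group.

    The first ``module_size`` diseases form the planted group: their gene
    sets share an interactome neighborhood, their ontology annotations
    share term cores, and the symptom layer carries a heavy block over
    them — so the group is heavy in every derived layer.
    """
    rng = np.random.default_rng(seed)
    diseases = [f"D{idx:04d}" for idx in range(n_diseases)]
    planted = tuple(diseases[:module_size])

    interactome, gene_map, _ = generate_interactome_world(
        n_genes=400, n_diseases=n_diseases, clustering=0.0, seed=int(rng.integers(2**31 - 1))
    )
    # overwrite the planted group's gene sets with one shared neighborhood
    nodes = sorted(interactome.nodes)
    center = nodes[int(rng.integers(len(nodes)))]
    neighborhood = list(nx.single_source_shortest_path_length(interactome, center, cutoff=2))
    for disease in planted:
        pick = rng.choice(len(neighborhood), size=min(8, len(neighborhood)), replace=False)
        gene_map[disease] = {neighborhood[i] for i in pick}

    # background diseases get independent random annotations (one "group"
    # per disease); the planted group is overwritten with a shared core
    ontology, term_ann, _ = generate_ontology_world(
        n_terms=80,
        n_diseases=n_diseases,
        seed=int(rng.integers(2**31 - 1)),
        n_groups=n_diseases,
    )
    disease_ontology, dterm_ann, _ = generate_ontology_world(
        n_terms=80,
        n_diseases=n_diseases,
        seed=int(rng.integers(2**31 - 1)),
        n_groups=n_diseases,
    )
    core = set(rng.choice(sorted(ontology.terms), size=5, replace=False))
    dcore = set(rng.choice(sorted(disease_ontology.terms), size=5, replace=False))
    for disease in planted:
        term_ann[disease] = core | set(
            rng.choice(sorted(ontology.terms), size=2, replace=False)
        )
        dterm_ann[disease] = dcore | set(
            rng.choice(sorted(disease_ontology.terms), size=2, replace=False)
        )

    # symptom layer: heavy planted block on a weak random background
    g = nx.Graph()
    g.add_nodes_from(diseases)
    for i, a in enumerate(diseases):
        for b in diseases[i + 1 :]:
            if a in planted and b in planted:
                g.add_edge(a, b, weight=float(_positive_normal(rng, 0.7, 0.1, 1)[0]))
            elif rng.random() < 0.05:
                g.add_edge(a, b, weight=float(_truncated_exponential(rng, 0.05, 1)[0]))
    symptom_layer = WeightedDiseaseNetwork("symptoms", g)

    drug_table = generate_drug_table(
        {"planted": planted}, coverage=0.8, seed=int(rng.integers(2**31 - 1))
    )
    class_map = {
        d: ("PlantedClass" if d in planted else f"Class{(i % 4)}")
        for i, d in enumerate(diseases)
    }
    return SyntheticWorld(
        interactome=interactome,
        disease_gene_map=gene_map,
        ontology=ontology,
        term_annotations=term_ann,
        disease_ontology=disease_ontology,
        disease_term_annotations=dterm_ann,
        symptom_layer=symptom_layer,
        drug_table=drug_table,
        class_map=class_map,
        truth={"planted": planted},
    )
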
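"""Post-extraction module annotation and drug repositioning.

Given extracted modules this provides: majority-class labeling against a
MeSH-style disease classification, gene-frequency analysis over the
members' gene lists, therapeutic-drug-set Jaccard similarity between
diseases, and the Drug_score used to nominate repositioning candidates:

    Drug_score = n_T / N

where N is the module size and n_T the number of member diseases the drug
is curated to treat (therapeutic "T" marker). Scores are kept as exact
rationals; drugs scoring at least 0.6 (i.e. covering at least 60% of a
module) are repositioning candidates for the uncovered members.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from .io import DrugAssociationRecord

__all__ = [
    "ModuleClassification",
    "DrugScoreRecord",
    "JaccardResult",
    "classify_module",
    "gene_frequency",
    "therapeutic_drug_sets",
    "drug_jaccard",
    "drug_score",
    "repositioning_candidates",
]

THERAPEUTIC_MARKER = "T"


@dataclass(frozen=True)
class ModuleClassification:
    """Majority-class call for a module: label and the off-class members."""

    label: str
    majority_fraction: float
    minority: tuple[str, ...]

    @property
    def is_mixed(self) -> bool:
        return self.label == "mixed"


@dataclass(frozen=True)
class DrugScoreRecord:
    """Drug_score of one drug over one module (exact rational)."""

    drug_id: str
    drug_name: str
    module_id: str
    n_t: int
    module_size: int
    score: Fraction
    uncovered: tuple[str, ...]

    @property
    def score_float(self) -> float:
        return float(self.score)


@dataclass(frozen=True)
class JaccardResult:
    """Therapeutic-drug-set Jaccard index for a disease pair."""

    disease_a: str
    disease_b: str
    value: float | None
    defined: bool


def classify_module(
    members: Iterable[str],
    class_map: Mapping[str, str],
    threshold: float = 0.6,
) -> ModuleClassification:
    """Label a module with the class shared by *more than* ``threshold`` of it.

    A module is labeled class F if strictly more than 60% (default) of its
    diseases carry class F; otherwise it is "mixed". Members absent from
    the class map count as their own singleton classes. The returned
    minority list holds the members outside the top class (the module's
    candidate novel disease relationships).
    """
    members = sorted(set(members))
    if not members:
        raise ValueError("module has no members")
    labels = {d: class_map.get(d, f"<unclassified:{d}>") for d in members}
    tally = Counter(labels.values())
    top_label, top_count = max(tally.items(), key=lambda kv: (kv[1], kv[0]))
    fraction = top_count / len(members)
    minority = tuple(d for d in members if labels[d] != top_label)
    if fraction > threshold:
        return ModuleClassification(top_label, fraction, minority)
    return ModuleClassification("mixed", fraction, minority)


def gene_frequency(
    members: Iterable[str],
    disease_gene_map: Mapping[str, Iterable[str]],
) -> tuple[dict[str, int], tuple[str, ...]]:
    """Count, per gene, how many member gene lists contain it.

    Returns the full count map and the (tied) set of maximum-frequency
    genes — the module's candidate shared causal genes.
    """
    counts: Counter = Counter()
    for disease in sorted(set(members)):
        counts.update(set(disease_gene_map.get(disease, ())))
    if not counts:
        return {}, ()
    top = max(counts.values())
    winners = tuple(sorted(g for g, c in counts.items() if c == top))
    return dict(counts), winners


def therapeutic_drug_sets(
    drug_table: Iterable[DrugAssociationRecord],
) -> dict[str, set[str]]:
    """disease -> set of drug ids with a therapeutic (T) link."""
    sets: dict[str, set[str]] = defaultdict(set)
    for rec in drug_table:
        if rec.marker == THERAPEUTIC_MARKER:
            sets[rec.disease_id].add(rec.drug_id)
    return dict(sets)


def drug_jaccard(
    d1: str,
    d2: str,
    drug_table: Iterable[DrugAssociationRecord],
) -> JaccardResult:
    """Jaccard index of two diseases' therapeutic drug sets.

    Undefined (flagged, value None) when either disease has no therapeutic
    drug at all.
    """
    sets = therapeutic_drug_sets(drug_table)
    s1, s2 = sets.get(d1, set()), sets.get(d2, set())
    if not s1 or not s2:
        return JaccardResult(d1, d2, None, defined=False)
    value = len(s1 & s2) / len(s1 | s2)
    return JaccardResult(d1, d2, value, defined=True)


def drug_score(
    drug_id: str,
    members: Sequence[str],
    drug_table: Iterable[DrugAssociationRecord],
    module_id: str = "module",
) -> DrugScoreRecord:
    """Drug_score = n_T / N for one drug over a module (exact rational)."""
    members = tuple(sorted(set(members)))
    if not members:
        raise ValueError("module has no members")
    name = drug_id
    treated: set[str] = set()
    for rec in drug_table:
        if rec.drug_id != drug_id:
            continue
        name = rec.drug_name
        if rec.marker == THERAPEUTIC_MARKER and rec.disease_id in members:
            treated.add(rec.disease_id)
    n_t, n = len(treated), len(members)
    uncovered = tuple(d for d in members if d not in treated)
    return DrugScoreRecord(drug_id, name, module_id, n_t, n, Fraction(n_t, n), uncovered)


def repositioning_candidates(
    members: Sequence[str],
    drug_table: Iterable[DrugAssociationRecord],
    min_score: float | Fraction = Fraction(3, 5),
    module_id: str = "module",
) -> list[DrugScoreRecord]:
    """All drugs covering at least ``min_score`` of the module, ranked.

    Every drug with a therapeutic link to at least one member is scored;
    those with score >= min_score (inclusive, default 0.6) are returned
    sorted by descending score then drug name. Each record's ``uncovered``
    diseases are the repositioning targets.
    """
    if not 0 <= float(min_score) <= 1:
        raise ValueError("min_score must lie in [0, 1]")
    members_set = set(members)
    table = list(drug_table)
    linked = {
        rec.drug_id
        for rec in table
        if rec.marker == THERAPEUTIC_MARKER and rec.disease_id in members_set
    }
    records = [drug_score(d, list(members), table, module_id=module_id) for d in sorted(linked)]
    kept = [r for r in records if r.score >= min_score]
    kept.sort(key=lambda r: (-r.score, r.drug_name))
    return kept
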
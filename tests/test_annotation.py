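"""Module classification, gene frequency, Jaccard and drug scoring."""

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdmnet import (
    classify_module,
    drug_jaccard,
    drug_score,
    gene_frequency,
    repositioning_candidates,
)
from cdmnet.datasets import cardiovascular_drug_table, cardiovascular_module
from cdmnet.io import DrugAssociationRecord


def table(rows):
    return [DrugAssociationRecord(*r) for r in rows]


class TestClassify:
    CARDIO_CLASSES = {
        "CM": "Cardiovascular Diseases",
        "DCM": "Cardiovascular Diseases",
        "HCM": "Cardiovascular Diseases",
        "HF": "Cardiovascular Diseases",
        "RA": "Musculoskeletal Diseases",
    }

    def test_four_of_five_majority(self):
        cls = classify_module(cardiovascular_module(), self.CARDIO_CLASSES)
        assert cls.label == "Cardiovascular Diseases"
        assert cls.minority == ("RA",)

    def test_unanimous_module(self):
        cls = classify_module(["A", "B"], {"A": "X", "B": "X"})
        assert cls.label == "X"
        assert cls.minority == ()

    def test_exact_sixty_percent_is_mixed(self):
        class_map = {"A": "X", "B": "X", "C": "X", "D": "Y", "E": "Z"}
        cls = classify_module(["A", "B", "C", "D", "E"], class_map)
        assert cls.is_mixed  # strict "more than 60%"

    def test_member_order_invariance(self):
        members = ["E", "C", "A", "D", "B"]
        class_map = {m: ("X" if m != "E" else "Y") for m in members}
        a = classify_module(members, class_map)
        b = classify_module(sorted(members), class_map)
        assert (a.label, a.minority) == (b.label, b.minority)

    def test_missing_members_become_singletons(self):
        cls = classify_module(["A", "B", "C"], {"A": "X", "B": "X"})
        assert cls.label == "X"
        assert "C" in cls.minority

    def test_empty_module_rejected(self):
        with pytest.raises(ValueError):
            classify_module([], {})


class TestGeneFrequency:
    def test_counts_and_max_set(self):
        gene_map = {"d1": {"g1", "g2"}, "d2": {"g1"}, "d3": {"g1", "g3"}}
        counts, top = gene_frequency(["d1", "d2", "d3"], gene_map)
        assert counts == {"g1": 3, "g2": 1, "g3": 1}
        assert top == ("g1",)

    def test_ties_all_reported(self):
        gene_map = {"d1": {"g1", "g2"}, "d2": {"g1", "g2"}}
        _, top = gene_frequency(["d1", "d2"], gene_map)
        assert top == ("g1", "g2")

    def test_empty_lists(self):
        counts, top = gene_frequency(["d1"], {"d1": set()})
        assert counts == {} and top == ()


class TestJaccard:
    def test_identical_sets(self):
        t = table([("DR1", "a", "d1", "T"), ("DR1", "a", "d2", "T")])
        assert drug_jaccard("d1", "d2", t).value == 1.0

    def test_disjoint_sets(self):
        t = table([("DR1", "a", "d1", "T"), ("DR2", "b", "d2", "T")])
        assert drug_jaccard("d1", "d2", t).value == 0.0

    def test_two_of_five(self):
        rows = [
            ("DR1", "a", "d1", "T"), ("DR2", "b", "d1", "T"), ("DR3", "c", "d1", "T"),
            ("DR1", "a", "d2", "T"), ("DR2", "b", "d2", "T"),
            ("DR4", "d", "d2", "T"), ("DR5", "e", "d2", "T"),
        ]
        assert drug_jaccard("d1", "d2", table(rows)).value == pytest.approx(0.4)

    def test_therapeutic_only(self):
        t = table([("DR1", "a", "d1", "T"), ("DR1", "a", "d2", "M")])
        result = drug_jaccard("d1", "d2", t)
        assert not result.defined and result.value is None

    def test_symmetric(self):
        t = table([("DR1", "a", "d1", "T"), ("DR1", "a", "d2", "T"), ("DR2", "b", "d2", "T")])
        assert drug_jaccard("d1", "d2", t).value == drug_jaccard("d2", "d1", t).value


class TestDrugScore:
    @pytest.mark.parametrize(
        "drug_id, expected",
        [
            ("D019808", Fraction(1)),       # Losartan: all five diseases
            ("C059514", Fraction(1)),       # Resveratrol
            ("C043211", Fraction(4, 5)),    # Carvedilol: all but RA
            ("D017257", Fraction(4, 5)),    # Ramipril
            ("D009020", Fraction(3, 5)),    # Morphine
            ("C089730", Fraction(3, 5)),    # Rosiglitazone
        ],
    )
    def test_cardiovascular_worked_examples(self, drug_id, expected):
        rec = drug_score(drug_id, cardiovascular_module(), cardiovascular_drug_table())
        assert rec.score == expected

    def test_unlinked_drug_scores_zero(self):
        rec = drug_score("UNKNOWN", cardiovascular_module(), cardiovascular_drug_table())
        assert rec.score == 0
        assert rec.uncovered == tuple(sorted(cardiovascular_module()))

    @given(n_t=st.integers(0, 40), extra=st.integers(1, 960))
    @settings(max_examples=40, deadline=None)
    def test_exact_rational_arithmetic(self, n_t, extra):
        n = n_t + extra
        members = [f"d{i}" for i in range(n)]
        t = table([(f"DR1", "x", f"d{i}", "T") for i in range(n_t)])
        rec = drug_score("DR1", members, t)
        assert rec.score * rec.module_size == rec.n_t
        assert 0 <= rec.score <= 1


class TestRepositioning:
    def test_thirty_candidates_at_default_threshold(self):
        cands = repositioning_candidates(
            list(cardiovascular_module()), cardiovascular_drug_table()
        )
        assert len(cands) == 30
        assert [c.drug_name for c in cands[:2]] == ["Losartan", "Resveratrol"]

    def test_score_point_six_rows_retained_inclusively(self):
        cands = repositioning_candidates(
            list(cardiovascular_module()), cardiovascular_drug_table(), min_score=0.6
        )
        assert sum(1 for c in cands if c.score == Fraction(3, 5)) == 22

    def test_min_score_one_keeps_full_coverage_only(self):
        cands = repositioning_candidates(
            list(cardiovascular_module()), cardiovascular_drug_table(), min_score=1.0
        )
        assert {c.drug_name for c in cands} == {"Losartan", "Resveratrol"}

    def test_uncovered_diseases_flagged(self):
        cands = repositioning_candidates(
            list(cardiovascular_module()), cardiovascular_drug_table()
        )
        carvedilol = next(c for c in cands if c.drug_name == "Carvedilol")
        assert carvedilol.uncovered == ("RA",)

    def test_empty_table(self):
        assert repositioning_candidates(["d1", "d2"], []) == []

    def test_sorted_by_score_then_name(self):
        cands = repositioning_candidates(
            list(cardiovascular_module()), cardiovascular_drug_table()
        )
        keys = [(-c.score, c.drug_name) for c in cands]
        assert keys == sorted(keys)
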
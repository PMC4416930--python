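"""Disease annotation ratio, location-weighted score, and novel-pair extraction."""

from __future__ import annotations

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regcascade.cascades import CascadeSet
from regcascade.scoring import (
    DiseaseAnnotationMap,
    annotate_cascades,
    dar,
    extract_novel_pairs,
    load_annotations,
    n_distinct_cascades,
    retrieve_high_dar,
    score,
)


def ann_from(pairs: list[tuple[str, str]], etype: str = "TF") -> DiseaseAnnotationMap:
    ann = DiseaseAnnotationMap()
    for element, disease in pairs:
        ann.add(element, etype, disease)
    return ann


class TestWorkedExamples:
    def test_breast_cancer_cascade_score_and_dar(self, worked):
        s = score(worked.breast_cascade, "breast cancer", worked.annotations)
        assert round(s, 3) == 2.468
        assert s == pytest.approx(1 + 1 / 2 + 1 / 3 + 1 / 5 + 1 / 6 + 1 / 7 + 1 / 8)
        assert dar(worked.breast_cascade, "breast cancer", worked.annotations) == pytest.approx(7 / 9)

    def test_lymphoma_cascade_dar(self, worked):
        assert dar(worked.lymphoma_cascade, "lymphoma", worked.annotations) == 7 / 8

    def test_fully_annotated_cascade_scores_harmonic_number(self, worked):
        c = worked.pten_trio[0]  # all 7 elements annotated to breast cancer
        assert score(c, "breast cancer", worked.annotations) == pytest.approx(
            sum(1 / i for i in range(1, 8))
        )

    def test_unannotated_disease_gives_zero(self, worked):
        assert dar(worked.breast_cascade, "scurvy", worked.annotations) == 0
        assert score(worked.breast_cascade, "scurvy", worked.annotations) == 0


class TestScoreProperties:
    def test_adding_annotation_at_position_i_adds_reciprocal_i(self):
        cascade = ("A", "B", "C", "D", "E")
        ann = ann_from([("A", "d")])
        base = score(cascade, "d", ann)
        for i, element in enumerate(cascade[1:], start=2):
            ann2 = ann_from([("A", "d"), (element, "d")])
            assert score(cascade, "d", ann2) == pytest.approx(base + 1 / i)

    def test_score_is_position_sensitive_under_reversal(self):
        cascade = ("A", "B", "C")
        ann = ann_from([("A", "d")])
        assert score(cascade, "d", ann) == 1.0
        assert score(cascade[::-1], "d", ann) == pytest.approx(1 / 3)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(flags=st.lists(st.booleans(), min_size=3, max_size=14))
    def test_dar_times_en_is_integral_and_score_bounded(self, flags):
        cascade = tuple(f"e{i}" for i in range(len(flags)))
        ann = ann_from([(e, "d") for e, f in zip(cascade, flags) if f])
        d = dar(cascade, "d", ann)
        s = score(cascade, "d", ann)
        assert d * len(cascade) == pytest.approx(sum(flags), abs=1e-12)
        assert 0 <= s <= sum(1 / i for i in range(1, len(cascade) + 1)) + 1e-12
        assert (s == 0) == (d == 0)

    def test_disease_names_match_case_insensitively(self):
        ann = ann_from([("A", "Breast Cancer")])
        assert dar(("A", "B", "C"), "breast cancer", ann) == pytest.approx(1 / 3)


class TestLoadAnnotations:
    def test_merged_map_with_types(self):
        tf = "element_id\telement_type\tdisease\nMYC\tTF\tlymphoma\nMYC\tTF\tlymphoma\n"
        mir = "element_id\telement_type\tdisease\nmiR-21\tmiRNA\tlymphoma\n"
        ann = load_annotations(tf, mir)
        assert len(ann) == 2
        assert ann.element_type("myc") == "TF"
        assert ann.diseases_of("MYC") == {"lymphoma"}  # duplicate rows collapse

    def test_empty_files_give_empty_map(self):
        header = "element_id\telement_type\tdisease\n"
        assert len(load_annotations(header, header)) == 0

    def test_malformed_row_error_names_line(self):
        with pytest.raises(ValueError, match="line 2"):
            load_annotations("element_id\telement_type\tdisease\nMYC\tTF\n")

    def test_type_conflict_across_files_rejected(self):
        tf = "element_id\telement_type\tdisease\nX\tTF\td1\n"
        mir = "element_id\telement_type\tdisease\nX\tmiRNA\td2\n"
        with pytest.raises(ValueError, match="typed"):
            load_annotations(tf, mir)


class TestAnnotateCascades:
    def test_one_cascade_two_diseases_gives_two_records_dn2(self):
        cs = CascadeSet([("A", "B", "C")])
        ann = ann_from([("A", "d1"), ("B", "d2")])
        records = annotate_cascades(cs, ann)
        assert len(records) == 2
        assert all(r.dn == 2 for r in records)
        assert {r.disease for r in records} == {"d1", "d2"}

    def test_empty_annotation_map_gives_no_records(self):
        cs = CascadeSet([("A", "B", "C")])
        assert annotate_cascades(cs, DiseaseAnnotationMap()) == []

    def test_sorted_by_score_then_dar(self):
        cs = CascadeSet([("A", "B", "C"), ("X", "Y", "Z")])
        ann = ann_from([("A", "d"), ("Z", "d"), ("Y", "d")])
        records = annotate_cascades(cs, ann)
        scores = [r.score for r in records]
        assert scores == sorted(scores, reverse=True)

    def test_disease_filter_restricts_records(self):
        cs = CascadeSet([("A", "B", "C")])
        ann = ann_from([("A", "d1"), ("B", "d2")])
        records = annotate_cascades(cs, ann, diseases=["D1"])
        assert [r.disease for r in records] == ["d1"]
        assert records[0].dn == 2  # DN counts all diseases on the cascade


class TestHighDarRetrieval:
    def test_threshold_is_strict(self):
        cs = CascadeSet([("A", "B", "C", "D", "E"), ("F", "G", "H", "I", "J"), ("K", "L", "M", "N", "O")])
        ann = ann_from(
            [(e, "d") for e in "ABCDE"]          # DAR 1.0
            + [(e, "d") for e in "FGHI"]          # DAR 0.8
            + [(e, "d") for e in "KL"]            # DAR 0.4
        )
        records = annotate_cascades(cs, ann)
        high = retrieve_high_dar(records, 0.8)
        assert len(high) == 1 and high[0].dar == 1.0

    def test_threshold_one_keeps_nothing(self):
        cs = CascadeSet([("A", "B", "C")])
        records = annotate_cascades(cs, ann_from([(e, "d") for e in "ABC"]))
        assert retrieve_high_dar(records, 1.0) == []

    def test_lower_threshold_retrieves_superset(self):
        cs = CascadeSet([("A", "B", "C"), ("D", "E", "F")])
        ann = ann_from([("A", "d"), ("B", "d"), ("D", "d"), ("E", "d"), ("F", "d")])
        records = annotate_cascades(cs, ann)
        assert set(map(id, retrieve_high_dar(records, 0.9))) <= set(
            map(id, retrieve_high_dar(records, 0.5))
        )

    def test_distinct_cascade_count_collapses_diseases(self):
        cs = CascadeSet([("A", "B", "C")])
        ann = ann_from([(e, "d1") for e in "ABC"] + [(e, "d2") for e in "ABC"])
        high = retrieve_high_dar(annotate_cascades(cs, ann), 0.8)
        assert len(high) == 2 and n_distinct_cascades(high) == 1


class TestNovelPairs:
    def test_fully_annotated_record_contributes_nothing(self):
        cs = CascadeSet([("A", "B", "C")])
        ann = ann_from([(e, "d") for e in "ABC"])
        high = retrieve_high_dar(annotate_cascades(cs, ann), 0.8)
        assert extract_novel_pairs(high, ann) == []

    def test_shared_missing_pair_deduplicated_with_two_supports(self):
        cs = CascadeSet(
            [("A", "B", "C", "D", "X"), ("E", "F", "G", "H", "X")]
        )
        ann = ann_from([(e, "d") for e in "ABCDEFGH"])
        high = retrieve_high_dar(annotate_cascades(cs, ann), 0.75)  # DAR 4/5 passes
        pairs = extract_novel_pairs(high, ann)
        assert len(pairs) == 1
        assert pairs[0].element_id == "X" and len(pairs[0].supporting) == 2
        assert all(d > 0.75 for _, d in pairs[0].supporting)

    def test_pairs_partition_by_element_type(self, worked):
        cs = CascadeSet([worked.breast_cascade])
        records = annotate_cascades(cs, worked.annotations, diseases=["breast cancer"])
        high = retrieve_high_dar(records, 0.7)
        pairs = extract_novel_pairs(high, worked.annotations, worked.network())
        by_type = {(p.element_id, p.element_type) for p in pairs}
        assert by_type == {("YBX1", "TF"), ("miR-181c", "miRNA")}
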
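"""Codebook integrity and the encode/decode codec."""

import dataclasses
import json

import pytest

from crcdss.derived_features import MISSING
from crcdss.errors import CodeCollisionError, DecodingError, EncodingError, SchemaError
from crcdss.mds_schema import (CodeBook, EncodedVector, FieldSpec, RawPatientRecord,
                               decode_vector, default_codebook, encode_record,
                               load_codebook, tumor_size_class, validate_record)

# Every label/code pair the default codebook must carry, including the
# documented remaps (Ethnicity Other 1->5; topology resequenced 1..10).
EXPECTED_PAIRS = {
    "Current age": {"<45": 1, "45-64": 2, ">=65": 3},
    "Sex": {"Female": 1, "Male": 2, "Transsexual": 3},
    "Education level": {"Illiterate": 1, "Primary school": 2, "High school": 3, "University": 4},
    "Marital status": {"Married": 1, "Single": 2, "Divorced": 3, "Widowed": 4},
    "Ethnicity": {"Fars": 1, "Turk": 2, "Kord": 3, "Lor": 4, "Other": 5},
    "Religion": {"Muslim": 1, "Christian": 2, "Jewish": 3, "Zoroastrian": 4, "Other": 5},
    "Location": {"City": 1, "Village": 2},
    "BMI": {"<18.5": 1, "18.5-24.9": 2, "25-29.9": 3, ">=30": 4},
    "Tobacco use": {"Yes": 1, "No": 0, "Unknown": 3},
    "Alcohol use": {"Yes": 1, "No": 0, "Unknown": 3},
    "NSAIDs use": {"Yes": 1, "No": 0, "Unknown": 3},
    "Tumor size": {"Below threshold": 1, "Above threshold": 2},
    "Tumor topology": {"Cecum": 1, "Ascending colon": 2, "Hepatic flexure": 3,
                       "Transverse colon": 4, "Splenic flexure": 5, "Descending colon": 6,
                       "Sigmoid colon": 7, "Colon": 8, "Rectosigmoid junction": 9,
                       "Rectum": 10},
    "Tumor morphology": {"Adenocarcinoma": 1, "Mucinous adenocarcinoma": 2,
                         "Signet ring cell carcinoma": 3, "Squamous cell carcinoma": 4,
                         "Squamous-cell adenocarcinoma": 5, "Medullary carcinoma": 6},
    "Histological grade": {"Undetermined grade": 1, "Well differentiated": 2,
                           "Moderately differentiated": 3, "Poorly differentiated": 4,
                           "Undifferentiated": 5},
    "pT stage": {"T0": 0, "T1": 1, "T2": 2, "T3": 3, "T4": 4},
    "pN stage": {"N0": 0, "N1": 1, "N2": 2},
    "pM stage": {"M0": 0, "M1": 1},
    "Pathologic grade": {"I": 1, "II": 2, "III": 3, "IV": 4},
    "Advancing grade": {"Primary grade": 1, "Advanced grade": 2},
    "Treatment": {"Surgery": 1, "Chemotherapy-Radiotherapy": 2, "Biopsy": 3},
    "HNPCC": {"Yes": 1, "No": 0},
    "FAP": {"Yes": 1, "No": 0},
    "Diabetes mellitus": {"Yes": 1, "No": 0, "Unknown": 3},
    "IBD": {"Yes": 1, "No": 0, "Unknown": 3},
    "Family history of CRC": {"Yes": 1, "No": 0, "Unknown": 3},
    "Rectal bleeding": {"Yes": 1, "No": 0},
    "Weight loss": {"Yes": 1, "No": 0},
    "Survival quality": {"Normal activity": 1, "Non normal activity": 2, "Dead": 3},
    "Vital status": {"Alive": 1, "Dead": 0},
}


class TestCodeBook:
    def test_every_expected_pair_present(self):
        book = default_codebook()
        for field_name, pairs in EXPECTED_PAIRS.items():
            spec = book.field(field_name)
            for label, code in pairs.items():
                assert spec.code_for(label) == code, (field_name, label)

    def test_codes_distinct_within_every_field(self):
        for spec in default_codebook():
            codes = [c for _, c in spec.codes]
            assert len(set(codes)) == len(codes)

    def test_collision_raises(self):
        with pytest.raises(CodeCollisionError) as exc:
            FieldSpec("Broken", "x", (("A", 4), ("B", 4)))
        assert "Broken" in str(exc.value)

    def test_duplicate_field_names_raise(self):
        spec = FieldSpec("Dup", "x", (("A", 1),))
        with pytest.raises(SchemaError):
            CodeBook([spec, spec])

    def test_json_roundtrip_behaves_identically(self):
        book = default_codebook()
        clone = CodeBook.from_json(book.to_json())
        assert clone.field_names == book.field_names
        for spec in book:
            assert clone.field(spec.name).codes == spec.codes

    def test_load_codebook_rejects_collision_document(self):
        doc = [{"name": "F", "attr": "x", "codes": [["A", 4], ["B", 4]]}]
        with pytest.raises(CodeCollisionError):
            load_codebook(json.dumps(doc))

    def test_load_codebook_rejects_empty_label_set(self):
        doc = [{"name": "F", "attr": "x", "codes": []}]
        with pytest.raises(SchemaError):
            load_codebook(json.dumps(doc))


class TestTumorSizeClass:
    def test_grade_dependent_cut(self):
        # 25 mm exceeds the grade-I 20 mm cut but not the grade-II 35 mm cut
        assert tumor_size_class(25, "Well differentiated") == "Above threshold"
        assert tumor_size_class(25, "Moderately differentiated") == "Below threshold"


def _minimal_record(**overrides):
    base = dict(patient_id="p1", weight=70.0, height=175.0,
                birthdate_persian="1370-01-01", sex="Female", tobacco="Unknown",
                vital_status="Alive", survival_quality="Normal activity")
    base.update(overrides)
    return RawPatientRecord(**base)


class TestEncode:
    def test_unknown_label_encodes_to_three(self):
        book = default_codebook()
        vec = encode_record(_minimal_record(), book, reference_year=2017)
        assert vec.codes[book.slot_index("Tobacco use")] == 3

    def test_bmi_slot(self):
        book = default_codebook()
        vec = encode_record(_minimal_record(), book, reference_year=2017)
        assert vec.codes[book.slot_index("BMI")] == 2

    def test_age_slot_and_reference_year(self):
        book = default_codebook()
        vec = encode_record(_minimal_record(), book, reference_year=2017)
        assert vec.codes[book.slot_index("Current age")] == 1  # age 26
        vec2 = encode_record(_minimal_record(), book, reference_year=2056)
        assert vec2.codes[book.slot_index("Current age")] == 3  # age 65, oldest band

    def test_deterministic(self):
        r = _minimal_record()
        assert encode_record(r) == encode_record(r)

    def test_missing_maps_to_sentinel_not_zero(self):
        book = default_codebook()
        vec = encode_record(_minimal_record(alcohol=None), book)
        assert vec.codes[book.slot_index("Alcohol use")] == MISSING

    def test_case_insensitive_labels(self):
        book = default_codebook()
        vec = encode_record(_minimal_record(sex="fEMALE"), book)
        assert vec.codes[book.slot_index("Sex")] == 1

    def test_unknown_label_raises_naming_field(self):
        with pytest.raises(EncodingError) as exc:
            encode_record(_minimal_record(sex="Martian"))
        assert "Sex" in str(exc.value) and "Martian" in str(exc.value)


class TestDecode:
    def test_sex_code_two_is_male(self):
        book = default_codebook()
        vec = encode_record(_minimal_record(sex="Male"), book)
        assert decode_vector(vec, book)["Sex"] == "Male"

    def test_unknown_code_raises(self):
        book = default_codebook()
        bad = EncodedVector("p", tuple([99] * len(book)))
        with pytest.raises(DecodingError):
            decode_vector(bad, book)

    def test_bmi_category_decodes_to_bin_label(self):
        book = default_codebook()
        vec = encode_record(_minimal_record(weight=100.0), book)  # BMI 32.7
        assert decode_vector(vec, book)["BMI"] == ">=30"

    def test_roundtrip_on_synthetic_cohort(self, small_cohort):
        """encode -> decode recovers every categorical label; re-encode is identity."""
        records, _ = small_cohort
        book = default_codebook()
        for record in records[:200]:
            vec = encode_record(record, book, reference_year=2017)
            decoded = decode_vector(vec, book)
            for spec in book:
                if spec.derived:
                    continue
                raw = getattr(record, spec.attr)
                if raw is None:
                    assert decoded[spec.name] is None
                else:
                    assert decoded[spec.name].lower() == str(raw).lower()
            rebuilt = dataclasses.replace(
                record, **{spec.attr: decoded[spec.name] for spec in book
                           if not spec.derived})
            assert encode_record(rebuilt, book, 2017) == vec


class TestValidate:
    def test_clean_record_has_no_findings(self):
        assert validate_record(_minimal_record()) == []

    def test_negative_weight_is_error(self):
        findings = validate_record(_minimal_record(weight=-5.0))
        assert any(f.severity == "error" and f.field == "weight" for f in findings)

    def test_dead_with_normal_activity_warns(self):
        findings = validate_record(_minimal_record(vital_status="Dead",
                                                   survival_quality="Normal activity"))
        assert any(f.severity == "warning" and f.field == "survival_quality"
                   for f in findings)
        assert not any(f.severity == "error" for f in findings)

    def test_unknown_label_is_error_finding(self):
        findings = validate_record(_minimal_record(religion="Jedi"))
        assert any(f.severity == "error" and f.field == "religion" for f in findings)

    def test_synthetic_cohort_validates_clean(self, small_cohort):
        records, _ = small_cohort
        for record in records:
            assert [f for f in validate_record(record) if f.severity == "error"] == []
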
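"""Minimum data set (MDS) for the CRC screening registry: codebook and codec.

The registry stores one record per screened person covering socio-demographics,
lifestyle, tumour classification, past medical history, symptoms and vital
status.  Every categorical field has a fixed integer coding; the ordered vector
of those codes (plus the derived BMI and age categories) is what the
similarity-based survival estimator consumes, so field order and code values
are a frozen contract, serialised with the codebook.

Two quirks of the source coding scheme are resolved here and recorded in the
codebook document itself:

* the ethnicity field assigned "Other" the same code as "Fars"; "Other" is
  remapped to 5;
* the tumour-topology field listed duplicate and colliding codes; the shipped
  codebook assigns the ten distinct anatomical sites strictly sequential codes
  1..10 (caecum through rectum).

Tumour size is coded 1/2 against a grade-dependent cut (20 mm for histological
grade I, 35 mm for grade II); see :func:`tumor_size_class`.

Missing values encode to the sentinel ``-1``, never ``0`` (0 is the live code
for "No" and for stage T0/N0/M0).  The coded label "Unknown" (3) is a real
observation, distinct from missing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence, Tuple

from .derived_features import (MISSING, age_category_from_age, compute_age_category,
                               compute_bmi, parse_persian_date)
from .errors import CodeCollisionError, DecodingError, EncodingError, SchemaError
from .risk_rules import MolecularFindings, RelativeCancer, HNPCC_SITES

__all__ = [
    "FieldSpec", "CodeBook", "RawPatientRecord", "EncodedVector", "Finding",
    "load_codebook", "default_codebook", "encode_record", "decode_vector",
    "validate_record", "tumor_size_class",
]

YES_NO_UNKNOWN = (("Yes", 1), ("No", 0), ("Unknown", 3))
YES_NO = (("Yes", 1), ("No", 0))


@dataclass(frozen=True)
class FieldSpec:
    """One MDS field: its name, record attribute, and ordered label→code pairs."""

    name: str
    attr: Optional[str]  # RawPatientRecord attribute; None for derived fields
    codes: Tuple[Tuple[str, int], ...]
    derived: bool = False
    allow_missing: bool = True

    def __post_init__(self):
        seen: Dict[int, str] = {}
        labels = set()
        for label, code in self.codes:
            if code in seen:
                raise CodeCollisionError(self.name, code)
            if label.lower() in labels:
                raise SchemaError(f"field {self.name!r}: duplicate label {label!r}")
            seen[code] = label
            labels.add(label.lower())

    def code_for(self, label: str) -> int:
        low = label.strip().lower()
        for lab, code in self.codes:
            if lab.lower() == low:
                return code
        raise EncodingError(f"field {self.name!r}: unknown label {label!r}")

    def label_for(self, code: int) -> str:
        for lab, c in self.codes:
            if c == code:
                return lab
        raise DecodingError(f"field {self.name!r}: unknown code {code}")

    @property
    def code_set(self) -> frozenset:
        return frozenset(c for _, c in self.codes)


class CodeBook:
    """Ordered collection of FieldSpecs; the encoding contract of a registry."""

    def __init__(self, fields: Sequence[FieldSpec]):
        names = [f.name for f in fields]
        if len(set(n.lower() for n in names)) != len(names):
            raise SchemaError("duplicate field names in codebook")
        self.fields: Tuple[FieldSpec, ...] = tuple(fields)
        self._by_name = {f.name.lower(): f for f in self.fields}

    def __len__(self) -> int:
        return len(self.fields)

    def __iter__(self):
        return iter(self.fields)

    def field(self, name: str) -> FieldSpec:
        try:
            return self._by_name[name.lower()]
        except KeyError:
            raise SchemaError(f"no field named {name!r} in codebook") from None

    @property
    def field_names(self) -> Tuple[str, ...]:
        return tuple(f.name for f in self.fields)

    def slot_index(self, name: str) -> int:
        low = name.lower()
        for i, f in enumerate(self.fields):
            if f.name.lower() == low:
                return i
        raise SchemaError(f"no field named {name!r} in codebook")

    # -- serialisation -----------------------------------------------------
    def to_json(self) -> str:
        doc = [{"name": f.name, "attr": f.attr, "derived": f.derived,
                "allow_missing": f.allow_missing,
                "codes": [[lab, code] for lab, code in f.codes]}
               for f in self.fields]
        return json.dumps(doc, indent=2, ensure_ascii=False)

    @classmethod
    def from_json(cls, text: str) -> "CodeBook":
        doc = json.loads(text)
        fields = []
        for entry in doc:
            if not entry.get("codes"):
                raise SchemaError(f"field {entry.get('name')!r} has no labels")
            fields.append(FieldSpec(
                name=entry["name"], attr=entry.get("attr"),
                codes=tuple((lab, int(code)) for lab, code in entry["codes"]),
                derived=bool(entry.get("derived", False)),
                allow_missing=bool(entry.get("allow_missing", True))))
        return cls(fields)


def load_codebook(source=None) -> CodeBook:
    """Load a codebook from a JSON string, path, or parsed document.

    With ``source=None`` returns the built-in default codebook.
    """
    if source is None:
        return default_codebook()
    if isinstance(source, CodeBook):
        return source
    if isinstance(source, (list, tuple)):
        return CodeBook.from_json(json.dumps(list(source)))
    text = str(source)
    if not text.lstrip().startswith("["):
        with open(text, "r", encoding="utf-8") as fh:
            text = fh.read()
    return CodeBook.from_json(text)


# ---------------------------------------------------------------------------
# Default codebook: the MDS fields in their canonical top-to-bottom order.
# ---------------------------------------------------------------------------

AGE_BINS = (("<45", 1), ("45-64", 2), (">=65", 3))
BMI_BINS = (("<18.5", 1), ("18.5-24.9", 2), ("25-29.9", 3), (">=30", 4))

_DEFAULT_FIELDS: Tuple[FieldSpec, ...] = (
    FieldSpec("Current age", None, AGE_BINS, derived=True),
    FieldSpec("Diagnosis age", None, AGE_BINS, derived=True),
    FieldSpec("Sex", "sex", (("Female", 1), ("Male", 2), ("Transsexual", 3))),
    FieldSpec("Education level", "education",
              (("Illiterate", 1), ("Primary school", 2), ("High school", 3), ("University", 4))),
    FieldSpec("Marital status", "marital_status",
              (("Married", 1), ("Single", 2), ("Divorced", 3), ("Widowed", 4))),
    # "Other" collided with "Fars"; remapped to 5
    FieldSpec("Ethnicity", "ethnicity",
              (("Fars", 1), ("Turk", 2), ("Kord", 3), ("Lor", 4), ("Other", 5))),
    FieldSpec("Religion", "religion",
              (("Muslim", 1), ("Christian", 2), ("Jewish", 3), ("Zoroastrian", 4), ("Other", 5))),
    FieldSpec("Location", "location", (("City", 1), ("Village", 2))),
    FieldSpec("BMI", None, BMI_BINS, derived=True),
    FieldSpec("Chemical exposure", "chemical_exposure", YES_NO_UNKNOWN),
    FieldSpec("Tobacco use", "tobacco", YES_NO_UNKNOWN),
    FieldSpec("Alcohol use", "alcohol", YES_NO_UNKNOWN),
    FieldSpec("Oral narcotic use", "oral_narcotic", YES_NO_UNKNOWN),
    FieldSpec("IV drug use", "iv_drug", YES_NO_UNKNOWN),
    FieldSpec("NSAIDs use", "nsaids", YES_NO_UNKNOWN),
    FieldSpec("Tumor size", "tumor_size",
              (("Below threshold", 1), ("Above threshold", 2))),
    # collisions and duplicates in the source list resolved to sequential 1..10
    FieldSpec("Tumor topology", "tumor_topology",
              (("Cecum", 1), ("Ascending colon", 2), ("Hepatic flexure", 3),
               ("Transverse colon", 4), ("Splenic flexure", 5), ("Descending colon", 6),
               ("Sigmoid colon", 7), ("Colon", 8), ("Rectosigmoid junction", 9),
               ("Rectum", 10))),
    # user-extensible (the source list is open-ended)
    FieldSpec("Tumor morphology", "tumor_morphology",
              (("Adenocarcinoma", 1), ("Mucinous adenocarcinoma", 2),
               ("Signet ring cell carcinoma", 3), ("Squamous cell carcinoma", 4),
               ("Squamous-cell adenocarcinoma", 5), ("Medullary carcinoma", 6))),
    FieldSpec("Histological grade", "histological_grade",
              (("Undetermined grade", 1), ("Well differentiated", 2),
               ("Moderately differentiated", 3), ("Poorly differentiated", 4),
               ("Undifferentiated", 5))),
    FieldSpec("pT stage", "pt_stage",
              (("T0", 0), ("T1", 1), ("T2", 2), ("T3", 3), ("T4", 4))),
    FieldSpec("pN stage", "pn_stage", (("N0", 0), ("N1", 1), ("N2", 2))),
    FieldSpec("pM stage", "pm_stage", (("M0", 0), ("M1", 1))),
    FieldSpec("Pathologic grade", "pathologic_grade",
              (("I", 1), ("II", 2), ("III", 3), ("IV", 4))),
    FieldSpec("Advancing grade", "advancing_grade",
              (("Primary grade", 1), ("Advanced grade", 2))),
    FieldSpec("Treatment", "treatment",
              (("Surgery", 1), ("Chemotherapy-Radiotherapy", 2), ("Biopsy", 3))),
    FieldSpec("HNPCC", "hnpcc", YES_NO),
    FieldSpec("FAP", "fap", YES_NO),
    FieldSpec("Diabetes mellitus", "diabetes", YES_NO_UNKNOWN),
    FieldSpec("Hypertension", "hypertension", YES_NO_UNKNOWN),
    FieldSpec("IBD", "ibd", YES_NO_UNKNOWN),
    FieldSpec("Personal history of CRC", "personal_crc_history", YES_NO_UNKNOWN),
    FieldSpec("Family history of CRC", "family_crc_history", YES_NO_UNKNOWN),
    FieldSpec("Abdominal perforation", "sym_perforation", YES_NO),
    FieldSpec("FUO", "sym_fuo", YES_NO),
    FieldSpec("Obstructive symptoms", "sym_obstruction", YES_NO),
    FieldSpec("Abdominal pain", "sym_abdominal_pain", YES_NO),
    FieldSpec("Anemia", "sym_anemia", YES_NO),
    FieldSpec("Rectal bleeding", "sym_rectal_bleeding", YES_NO),
    FieldSpec("Change in bowel habit", "sym_bowel_habit_change", YES_NO),
    FieldSpec("Weakness", "sym_weakness", YES_NO),
    FieldSpec("Weight loss", "sym_weight_loss", YES_NO),
    FieldSpec("Survival quality", "survival_quality",
              (("Normal activity", 1), ("Non normal activity", 2), ("Dead", 3))),
    FieldSpec("Vital status", "vital_status", (("Alive", 1), ("Dead", 0))),
)


def default_codebook() -> CodeBook:
    return CodeBook(_DEFAULT_FIELDS)


#: Codebook slots describing outcome rather than presentation; the survival
#: estimator excludes them from its similarity features by default.
OUTCOME_FIELDS = ("Survival quality", "Vital status")


def tumor_size_class(size_mm: float, histological_grade: str,
                     cut_grade1: float = 20.0, cut_grade2: float = 35.0) -> str:
    """Grade-dependent size dichotomy: grade I uses the 20 mm cut, others 35 mm."""
    cut = cut_grade1 if "well" in histological_grade.lower() else cut_grade2
    return "Below threshold" if size_mm < cut else "Above threshold"


# ---------------------------------------------------------------------------
# Record model
# ---------------------------------------------------------------------------


@dataclass
class RawPatientRecord:
    """One person's un-coded registry facts.

    Categorical attributes hold codebook labels (case-insensitive match on
    encode); ``None`` means missing.  ``survival_time`` is months and stays
    outside the coded vector.  ``referral_type`` is an uncoded categorical
    passthrough.  ``adenoma_count`` (cumulative colorectal adenomas) feeds the
    polyposis rules.
    """

    patient_id: str
    weight: Optional[float] = None          # kg
    height: Optional[float] = None          # cm
    birthdate_persian: Optional[str] = None  # "YYYY-MM-DD", Solar Hijri
    diagnosis_age: Optional[float] = None   # years
    sex: Optional[str] = None
    education: Optional[str] = None
    marital_status: Optional[str] = None
    ethnicity: Optional[str] = None
    religion: Optional[str] = None
    location: Optional[str] = None
    chemical_exposure: Optional[str] = None
    tobacco: Optional[str] = None
    alcohol: Optional[str] = None
    oral_narcotic: Optional[str] = None
    iv_drug: Optional[str] = None
    nsaids: Optional[str] = None
    tumor_size: Optional[str] = None
    tumor_topology: Optional[str] = None
    tumor_morphology: Optional[str] = None
    histological_grade: Optional[str] = None
    pt_stage: Optional[str] = None
    pn_stage: Optional[str] = None
    pm_stage: Optional[str] = None
    pathologic_grade: Optional[str] = None
    advancing_grade: Optional[str] = None
    treatment: Optional[str] = None
    hnpcc: Optional[str] = None
    fap: Optional[str] = None
    diabetes: Optional[str] = None
    hypertension: Optional[str] = None
    ibd: Optional[str] = None
    personal_crc_history: Optional[str] = None
    family_crc_history: Optional[str] = None
    sym_perforation: Optional[str] = None
    sym_fuo: Optional[str] = None
    sym_obstruction: Optional[str] = None
    sym_abdominal_pain: Optional[str] = None
    sym_anemia: Optional[str] = None
    sym_rectal_bleeding: Optional[str] = None
    sym_bowel_habit_change: Optional[str] = None
    sym_weakness: Optional[str] = None
    sym_weight_loss: Optional[str] = None
    survival_quality: Optional[str] = None
    vital_status: Optional[str] = None
    survival_time: Optional[int] = None     # months
    referral_type: Optional[str] = None
    adenoma_count: Optional[int] = None
    family_history: List[RelativeCancer] = dc_field(default_factory=list)
    molecular: MolecularFindings = dc_field(default_factory=MolecularFindings)

    def is_deceased(self) -> bool:
        return (self.vital_status or "").strip().lower() == "dead"


SCALAR_COLUMNS: Tuple[str, ...] = tuple(
    f.name for f in dataclasses.fields(RawPatientRecord)
    if f.name not in ("family_history", "molecular"))


@dataclass(frozen=True)
class EncodedVector:
    """Ordered integer codes aligned to a codebook (missing slots = sentinel)."""

    patient_id: str
    codes: Tuple[int, ...]

    def __len__(self) -> int:
        return len(self.codes)


@dataclass(frozen=True)
class Finding:
    severity: str  # "error" | "warning"
    field: str
    message: str


def encode_record(record: RawPatientRecord, book: Optional[CodeBook] = None,
                  reference_year: int = 2017, bmi_mode: str = "strict") -> EncodedVector:
    """Map a record onto the codebook's ordered integer vector.

    The derived slots (current-age category, diagnosis-age category, BMI
    category) are computed here; ``reference_year`` is explicit so encoding is
    reproducible.  Deterministic: identical inputs give identical vectors.
    """
    book = book or default_codebook()
    codes: List[int] = []
    for spec in book:
        if spec.derived:
            codes.append(_derived_code(spec, record, reference_year, bmi_mode))
            continue
        value = getattr(record, spec.attr, None)
        if value is None or (isinstance(value, str) and not value.strip()):
            if spec.allow_missing:
                codes.append(MISSING)
                continue
            raise EncodingError(f"field {spec.name!r} missing and not allowed to be")
        codes.append(spec.code_for(str(value)))
    return EncodedVector(record.patient_id, tuple(codes))


def _derived_code(spec: FieldSpec, record: RawPatientRecord,
                  reference_year: int, bmi_mode: str) -> int:
    name = spec.name.lower()
    if name == "current age":
        if not record.birthdate_persian:
            return MISSING
        return compute_age_category(record.birthdate_persian, reference_year).category
    if name == "diagnosis age":
        if record.diagnosis_age is None:
            return MISSING
        return age_category_from_age(int(record.diagnosis_age))
    if name == "bmi":
        return compute_bmi(record.weight, record.height, mode=bmi_mode).category
    raise SchemaError(f"unknown derived field {spec.name!r}")


def decode_vector(vector: EncodedVector, book: Optional[CodeBook] = None) -> Dict[str, Optional[str]]:
    """Inverse of :func:`encode_record` on the categorical fields.

    Derived slots decode to their bin labels (not raw weight/height or
    birthdate); missing slots decode to ``None``.
    """
    book = book or default_codebook()
    if len(vector.codes) != len(book):
        raise DecodingError(
            f"vector length {len(vector.codes)} does not match codebook ({len(book)})")
    out: Dict[str, Optional[str]] = {}
    for spec, code in zip(book, vector.codes):
        out[spec.name] = None if code == MISSING else spec.label_for(code)
    return out


_SITE_VOCAB = HNPCC_SITES | {"other"}


def validate_record(record: RawPatientRecord,
                    book: Optional[CodeBook] = None) -> List[Finding]:
    """Check record invariants; returns findings instead of raising.

    Empty result means the record is valid.  Warnings flag suspicious but
    admissible states (e.g. vital status dead with a non-dead quality-of-life
    label).
    """
    book = book or default_codebook()
    findings: List[Finding] = []

    def err(fieldname, msg):
        findings.append(Finding("error", fieldname, msg))

    def warn(fieldname, msg):
        findings.append(Finding("warning", fieldname, msg))

    if not record.patient_id or not str(record.patient_id).strip():
        err("patient_id", "patient_id must be nonempty")
    for attr in ("weight", "height", "survival_time", "diagnosis_age", "adenoma_count"):
        v = getattr(record, attr)
        if v is not None and v < 0:
            err(attr, f"{attr} must be nonnegative, got {v}")
    if record.birthdate_persian:
        try:
            parse_persian_date(record.birthdate_persian)
        except Exception as exc:
            err("birthdate_persian", str(exc))
    for spec in book:
        if spec.derived or spec.attr is None:
            continue
        value = getattr(record, spec.attr, None)
        if value is None or (isinstance(value, str) and not value.strip()):
            continue
        try:
            spec.code_for(str(value))
        except EncodingError as exc:
            err(spec.attr, str(exc))
    vs = (record.vital_status or "").strip().lower()
    sq = (record.survival_quality or "").strip().lower()
    if vs == "dead" and sq and sq != "dead":
        warn("survival_quality",
             f"vital status is Dead but survival quality is {record.survival_quality!r}")
    if vs == "alive" and sq == "dead":
        warn("survival_quality", "vital status is Alive but survival quality is Dead")
    for i, rel in enumerate(record.family_history):
        if rel.age_at_diagnosis is not None and rel.age_at_diagnosis <= 0:
            err(f"family_history[{i}]", "age_at_diagnosis must be positive")
        if rel.cancer_site.strip().lower() not in _SITE_VOCAB:
            err(f"family_history[{i}]", f"cancer_site {rel.cancer_site!r} not in vocabulary")
        if rel.relation_degree not in ("first", "second"):
            err(f"family_history[{i}]", f"relation_degree {rel.relation_degree!r} invalid")
    return findings
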
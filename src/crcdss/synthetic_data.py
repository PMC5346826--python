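"""Reproducible synthetic CRC screening registries with planted prognosis.

The generator emulates the kind of registry the decision-support system runs
on: every patient carries a complete coded minimum data set, the high-risk
subgroups are represented at configurable proportions (constructed so the rule
engine provably assigns the intended subgroup), and a *planted* survival
probability gives each registry a known prognosis structure:

    risk score  s_i = Σ_f  w_f · code_f(i)        (w: planted_risk_weights)
    death prob  q_i = σ(s_i − c)                   (σ: logistic)
    vital status    ~ Bernoulli(q_i)

The intercept ``c`` is solved by bisection so that the *expected* deceased
fraction equals ``deceased_fraction`` exactly.  The planted weights live on
staging and clinical fields (pT/pN/pM dominate, then histological grade,
advancing grade, age, alarm symptoms) — a logistic mechanism deliberately
different from the cosine-similarity estimator, so calibration tests measure
recovery of structure the estimator was never handed.

Everything is driven by one :class:`numpy.random.Generator` seeded from the
config; identical configs give byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .mds_schema import RawPatientRecord, default_codebook, encode_record
from .risk_rules import (DEFAULT_CONFIG, MolecularFindings, RelativeCancer,
                         apply_molecular_update, classify_risk, meets_amsterdam_ii)

#: Clinically motivated default weights on encoded codes (higher score = worse
#: prognosis): metastasis and nodal/tumour stage dominate, then grade,
#: presentation and age.  Only fields without an "Unknown" code carry weight,
#: so the score is never distorted by Unknown=3.
DEFAULT_RISK_WEIGHTS: Dict[str, float] = {
    "pM stage": 2.0,
    "pN stage": 0.8,
    "pT stage": 0.6,
    "Histological grade": 0.45,
    "Advancing grade": 0.8,
    "Current age": 0.5,
    "Weight loss": 0.5,
    "Obstructive symptoms": 0.4,
    "Anemia": 0.3,
}

DEFAULT_SUBGROUP_MIX: Dict[str, float] = {
    "average": 0.72, "IBD": 0.08, "Suspected HNPCC": 0.05, "Suspected FAP": 0.05,
    "HNPCC": 0.03, "FAP": 0.03, "AFAP": 0.02, "MYH": 0.02,
}

#: Fields eligible for missingness injection (never outcome, never the fields
#: the rule engine or the planted truth depends on).
_MISSABLE = ("education", "marital_status", "ethnicity", "religion", "location",
             "chemical_exposure", "tobacco", "alcohol", "oral_narcotic", "iv_drug",
             "nsaids", "tumor_morphology", "treatment")


@dataclass
class SimulationConfig:
    seed: int
    n_patients: int = 500
    subgroup_mix: Dict[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_SUBGROUP_MIX))
    deceased_fraction: float = 0.3
    planted_risk_weights: Dict[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_RISK_WEIGHTS))
    missingness_rate: float = 0.05

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if abs(sum(self.subgroup_mix.values()) - 1.0) > 1e-9:
            raise ValueError("subgroup_mix proportions must sum to 1")
        if not 0.0 < self.deceased_fraction < 1.0:
            raise ValueError("deceased_fraction must lie in (0, 1)")
        if not 0.0 <= self.missingness_rate < 1.0:
            raise ValueError("missingness_rate must lie in [0, 1)")


@dataclass(frozen=True)
class PedigreeSample:
    relatives: Tuple[RelativeCancer, ...]
    meets_amsterdam: bool
    failed_clause: Optional[str]  # None when the pedigree qualifies


_FAILURE_MODES = ("too-few-relatives", "no-early-diagnosis", "no-verification",
                  "single-generation", "non-hnpcc-sites")


def generate_pedigree(meets_amsterdam: bool, seed=None) -> PedigreeSample:
    """Construct a family history that provably meets (or fails) Amsterdam II.

    The result is checked against the rule engine at generation time; for a
    failing pedigree the deliberately broken clause is recorded.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sites = ["CRC", "CRC", "endometrial", "small bowel", "ureter/renal pelvis"]

    def rel(degree, gen, site, age, verified):
        return RelativeCancer(degree, gen, site, float(age), verified)

    if meets_amsterdam:
        relatives = [
            rel("first", 1, "CRC", rng.integers(30, 50), True),       # parent, dx < 50
            rel("first", 0, str(rng.choice(sites)), rng.integers(35, 70),
                bool(rng.random() < 0.5)),                             # sibling
            rel("second", 2, str(rng.choice(sites)), rng.integers(45, 80),
                bool(rng.random() < 0.5)),                             # grandparent
        ]
        if rng.random() < 0.3:
            relatives.append(rel("second", 2, str(rng.choice(sites)),
                                 rng.integers(50, 85), False))
        ok, trace = meets_amsterdam_ii(relatives, fap_excluded=True)
        assert ok, f"construction bug: qualifying pedigree rejected: {trace}"
        return PedigreeSample(tuple(relatives), True, None)

    mode = str(rng.choice(_FAILURE_MODES))
    if mode == "too-few-relatives":
        relatives = [rel("first", 1, "CRC", rng.integers(30, 50), True)]
        if rng.random() < 0.5:
            relatives.append(rel("second", 2, "CRC", rng.integers(50, 80), True))
    elif mode == "no-early-diagnosis":
        relatives = [rel("first", 1, "CRC", rng.integers(55, 80), True),
                     rel("first", 0, "CRC", rng.integers(52, 75), True),
                     rel("second", 2, "CRC", rng.integers(60, 85), True)]
    elif mode == "no-verification":
        relatives = [rel("first", 1, "CRC", rng.integers(30, 50), False),
                     rel("first", 0, "CRC", rng.integers(35, 70), False),
                     rel("second", 2, "CRC", rng.integers(45, 80), False)]
    elif mode == "single-generation":
        relatives = [rel("first", 0, "CRC", rng.integers(30, 50), True),
                     rel("first", 0, "CRC", rng.integers(35, 70), True),
                     rel("first", 0, "endometrial", rng.integers(35, 70), False)]
    else:  # non-hnpcc-sites
        relatives = [rel("first", 1, "other", rng.integers(30, 50), True),
                     rel("first", 0, "other", rng.integers(35, 70), True),
                     rel("second", 2, "other", rng.integers(45, 80), True)]
    ok, trace = meets_amsterdam_ii(relatives, fap_excluded=True)
    assert not ok, f"construction bug: non-qualifying pedigree accepted ({mode})"
    failed = next(name for name, passed in trace.items() if not passed)
    return PedigreeSample(tuple(relatives), False, failed)


# ---------------------------------------------------------------------------
# Record sampling
# ---------------------------------------------------------------------------


def _choice(rng, options, p=None) -> str:
    return str(rng.choice(options, p=p))


def _sample_base_record(rng: np.random.Generator, pid: str) -> RawPatientRecord:
    yn = ("Yes", "No", "Unknown")
    ynu_p = (0.2, 0.7, 0.1)
    birth_year = int(rng.integers(1310, 1376))
    birthdate = f"{birth_year:04d}-{int(rng.integers(1, 13)):02d}-{int(rng.integers(1, 29)):02d}"
    grade = _choice(rng, ["Undetermined grade", "Well differentiated",
                          "Moderately differentiated", "Poorly differentiated",
                          "Undifferentiated"], p=(0.05, 0.3, 0.4, 0.2, 0.05))
    return RawPatientRecord(
        patient_id=pid,
        weight=abs(float(np.round(rng.normal(72, 13), 1))),
        height=abs(float(np.round(rng.normal(168, 9), 1))),
        birthdate_persian=birthdate,
        diagnosis_age=float(int(rng.integers(50, 80))),
        sex=_choice(rng, ["Female", "Male", "Transsexual"], p=(0.47, 0.525, 0.005)),
        education=_choice(rng, ["Illiterate", "Primary school", "High school", "University"],
                          p=(0.15, 0.3, 0.35, 0.2)),
        marital_status=_choice(rng, ["Married", "Single", "Divorced", "Widowed"],
                               p=(0.7, 0.15, 0.05, 0.1)),
        ethnicity=_choice(rng, ["Fars", "Turk", "Kord", "Lor", "Other"],
                          p=(0.5, 0.22, 0.12, 0.08, 0.08)),
        religion=_choice(rng, ["Muslim", "Christian", "Jewish", "Zoroastrian", "Other"],
                         p=(0.96, 0.015, 0.005, 0.005, 0.015)),
        location=_choice(rng, ["City", "Village"], p=(0.72, 0.28)),
        chemical_exposure=_choice(rng, yn, p=(0.08, 0.82, 0.1)),
        tobacco=_choice(rng, yn, p=ynu_p),
        alcohol=_choice(rng, yn, p=(0.08, 0.82, 0.1)),
        oral_narcotic=_choice(rng, yn, p=(0.06, 0.84, 0.1)),
        iv_drug=_choice(rng, yn, p=(0.02, 0.88, 0.1)),
        nsaids=_choice(rng, yn, p=(0.25, 0.65, 0.1)),
        tumor_size=_choice(rng, ["Below threshold", "Above threshold"], p=(0.45, 0.55)),
        tumor_topology=_choice(rng, ["Cecum", "Ascending colon", "Hepatic flexure",
                                     "Transverse colon", "Splenic flexure",
                                     "Descending colon", "Sigmoid colon", "Colon",
                                     "Rectosigmoid junction", "Rectum"]),
        tumor_morphology=_choice(rng, ["Adenocarcinoma", "Mucinous adenocarcinoma",
                                       "Signet ring cell carcinoma", "Squamous cell carcinoma",
                                       "Squamous-cell adenocarcinoma", "Medullary carcinoma"],
                                 p=(0.7, 0.12, 0.06, 0.05, 0.04, 0.03)),
        histological_grade=grade,
        pt_stage=_choice(rng, ["T0", "T1", "T2", "T3", "T4"], p=(0.05, 0.15, 0.25, 0.35, 0.2)),
        pn_stage=_choice(rng, ["N0", "N1", "N2"], p=(0.5, 0.3, 0.2)),
        pm_stage=_choice(rng, ["M0", "M1"], p=(0.82, 0.18)),
        pathologic_grade=_choice(rng, ["I", "II", "III", "IV"], p=(0.2, 0.35, 0.3, 0.15)),
        advancing_grade=_choice(rng, ["Primary grade", "Advanced grade"], p=(0.6, 0.4)),
        treatment=_choice(rng, ["Surgery", "Chemotherapy-Radiotherapy", "Biopsy"],
                          p=(0.5, 0.4, 0.1)),
        hnpcc="No", fap="No",
        diabetes=_choice(rng, yn, p=(0.15, 0.75, 0.1)),
        hypertension=_choice(rng, yn, p=(0.25, 0.65, 0.1)),
        ibd="No",
        personal_crc_history=_choice(rng, yn, p=(0.05, 0.9, 0.05)),
        family_crc_history="No",
        sym_perforation=_choice(rng, ("Yes", "No"), p=(0.03, 0.97)),
        sym_fuo=_choice(rng, ("Yes", "No"), p=(0.05, 0.95)),
        sym_obstruction=_choice(rng, ("Yes", "No"), p=(0.15, 0.85)),
        sym_abdominal_pain=_choice(rng, ("Yes", "No"), p=(0.45, 0.55)),
        sym_anemia=_choice(rng, ("Yes", "No"), p=(0.3, 0.7)),
        sym_rectal_bleeding=_choice(rng, ("Yes", "No"), p=(0.35, 0.65)),
        sym_bowel_habit_change=_choice(rng, ("Yes", "No"), p=(0.4, 0.6)),
        sym_weakness=_choice(rng, ("Yes", "No"), p=(0.35, 0.65)),
        sym_weight_loss=_choice(rng, ("Yes", "No"), p=(0.3, 0.7)),
        referral_type=_choice(rng, ["screening program", "physician referral",
                                    "self referral"], p=(0.5, 0.3, 0.2)),
    )


def _apply_subgroup(record: RawPatientRecord, subgroup: str,
                    rng: np.random.Generator) -> None:
    """Overwrite the fields that pin the record to its intended risk subgroup."""
    if subgroup == "HNPCC":
        if rng.random() < 0.5:
            record.hnpcc = "Yes"
        else:
            record.molecular = MolecularFindings("yes", "MMR", "abnormal", "MSI-high")
        record.family_history = list(generate_pedigree(True, rng).relatives)
        record.family_crc_history = "Yes"
        record.diagnosis_age = float(int(rng.integers(30, 55)))
    elif subgroup == "Suspected HNPCC":
        record.family_history = list(generate_pedigree(True, rng).relatives)
        record.family_crc_history = "Yes"
        record.diagnosis_age = float(int(rng.integers(35, 60)))
        record.molecular = MolecularFindings()  # untested: stays suspected
    elif subgroup == "FAP":
        record.fap = "Yes"
        record.molecular = MolecularFindings("yes", "APC")
        record.adenoma_count = int(rng.integers(100, 1000))
        record.diagnosis_age = float(int(rng.integers(25, 45)))
    elif subgroup == "AFAP":
        record.molecular = MolecularFindings("yes", "APC")
        record.adenoma_count = int(rng.integers(10, 100))
        record.diagnosis_age = float(int(rng.integers(40, 60)))
    elif subgroup == "Suspected FAP":
        record.adenoma_count = int(rng.integers(10, 200))
        record.diagnosis_age = float(int(rng.integers(55, 75)))
    elif subgroup == "MYH":
        record.molecular = MolecularFindings("yes", "MUTYH-biallelic")
        record.adenoma_count = int(rng.integers(10, 100))
    elif subgroup == "IBD":
        record.ibd = "Yes"
    elif subgroup == "average":
        if rng.random() < 0.15:  # some non-qualifying, non-CRC family history
            record.family_history = [r for r in generate_pedigree(False, rng).relatives
                                     if r.cancer_site.lower() != "crc"]
    else:
        raise ValueError(f"unknown subgroup {subgroup!r}")
    # keep diagnosis-age-driven Bethesda clauses away from non-Lynch groups
    if subgroup not in ("HNPCC", "Suspected HNPCC") and (record.diagnosis_age or 99) < 50:
        record.diagnosis_age = float(int(rng.integers(55, 75)))


def generate_registry(config: SimulationConfig,
                      reference_year: int = 2017) -> Tuple[List[RawPatientRecord], pd.DataFrame]:
    """Generate records plus the planted truth table (never ingested).

    Returns ``(records, truth)`` where ``truth`` has one row per patient:
    intended subgroup, planted risk score, survival/death probability and the
    drawn vital status.
    """
    rng = np.random.default_rng(config.seed)
    book = default_codebook()
    names = list(config.subgroup_mix)
    probs = np.array([config.subgroup_mix[n] for n in names], dtype=float)

    records: List[RawPatientRecord] = []
    subgroups: List[str] = []
    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        subgroup = names[int(rng.choice(len(names), p=probs))]
        record = _sample_base_record(rng, pid)
        _apply_subgroup(record, subgroup, rng)
        got = apply_molecular_update(classify_risk(record, DEFAULT_CONFIG),
                                     record.molecular)
        got_key = got.subgroup if got.subgroup != "none" else got.group
        assert got_key == subgroup, (
            f"construction bug: intended {subgroup}, rule engine assigned {got_key}")
        records.append(record)
        subgroups.append(subgroup)

    # planted prognosis: logistic in the encoded features
    weights = config.planted_risk_weights
    slot_weight = {book.slot_index(f): w for f, w in weights.items()}
    scores = np.zeros(len(records))
    for i, record in enumerate(records):
        codes = encode_record(record, book, reference_year).codes
        scores[i] = sum(w * max(codes[s], 0) for s, w in slot_weight.items())

    intercept = _solve_intercept(scores, config.deceased_fraction)
    death_prob = _sigmoid(scores - intercept)
    dead = rng.random(len(records)) < death_prob

    for i, record in enumerate(records):
        if dead[i]:
            record.vital_status = "Dead"
            record.survival_quality = "Dead"
            record.survival_time = int(rng.integers(1, 121))
        else:
            record.vital_status = "Alive"
            record.survival_quality = _choice(rng, ["Normal activity", "Non normal activity"],
                                              p=(0.7, 0.3))
            record.survival_time = None

    if config.missingness_rate > 0:
        for record in records:
            for attr in _MISSABLE:
                if rng.random() < config.missingness_rate:
                    setattr(record, attr, None)

    truth = pd.DataFrame({
        "patient_id": [r.patient_id for r in records],
        "subgroup": subgroups,
        "risk_score": scores,
        "death_prob": death_prob,
        "survival_prob": 1.0 - death_prob,
        "vital_status": ["Dead" if d else "Alive" for d in dead],
    })
    return records, truth


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _solve_intercept(scores: np.ndarray, target: float) -> float:
    """Bisect c so that mean(sigmoid(scores - c)) == target (expected fraction)."""
    lo, hi = scores.min() - 60.0, scores.max() + 60.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _sigmoid(scores - mid).mean() > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def write_synthetic_registry(config: SimulationConfig, path: str,
                             reference_year: int = 2017) -> Tuple[str, str, str]:
    """Emit registry.csv + families.json (ingestable) and truth.csv (never ingested)."""
    import os

    from .registry import write_registry_files

    records, truth = generate_registry(config, reference_year)
    csv_path, json_path = write_registry_files(records, path)
    truth_path = os.path.join(path, "truth.csv")
    truth.to_csv(truth_path, index=False)
    return csv_path, json_path, truth_path
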
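"""Registry storage, ingest, search and export for the screening system.

A :class:`Registry` keeps, per patient: the raw record, its encoded vector,
the risk assignment (after molecular updates) and the current survival
estimate, plus per-group survival statistics.  Every mutation goes through
:meth:`Registry.upsert`, which re-encodes, re-classifies and refreshes exactly
the estimates the change can influence, leaving the registry in the same state
a full recomputation would produce.

Two search modes are provided: *global search* (case-insensitive substring
match over every decoded label, the patient id, risk group and subgroup) and
*special search* (exact-match conjunction over id, screening recommendation
fields, risk and survival status, plus a survival-percent range).

Persistence is a single directory: ``registry.csv`` (one row per patient,
scalar fields), ``families.json`` (family history + molecular findings keyed
by patient_id) and ``derived.json`` (estimates and statistics, regenerable).
All mutating operations emit a structured log line (revision, operation,
patient_id).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field as dc_field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import survival_estimator as se
from .similarity import codebook_scaler, normalize_codes
from .errors import InsufficientReferenceError, QueryError, RegistryLookupError
from .mds_schema import (SCALAR_COLUMNS, CodeBook, EncodedVector, RawPatientRecord,
                         decode_vector, default_codebook, encode_record,
                         validate_record, OUTCOME_FIELDS)
from .risk_rules import (DEFAULT_CONFIG, MolecularFindings, RelativeCancer,
                         RiskAssignment, RuleConfig, apply_molecular_update,
                         classify_risk, recommend_screening)

log = logging.getLogger("crcdss.registry")


@dataclass
class PatientEntry:
    record: RawPatientRecord
    vector: EncodedVector
    assignment: RiskAssignment
    estimate: Optional[se.SurvivalEstimate] = None
    features: Optional["np.ndarray"] = None  # similarity features (scaled codes)

    @property
    def group_key(self) -> str:
        """Statistics key: the subgroup name, or the tier for unassigned patients."""
        return (self.assignment.subgroup if self.assignment.subgroup != "none"
                else self.assignment.group)


@dataclass
class IngestReport:
    accepted: int = 0
    rejected: List[Tuple[int, str, str]] = dc_field(default_factory=list)  # row, id, reason

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


class Registry:
    """Mutable patient collection with consistent derived state."""

    def __init__(self, codebook: Optional[CodeBook] = None, k: int = se.DEFAULT_K,
                 mode: str = se.DECEASED_DISTANCE, reference_year: int = 2017,
                 bmi_mode: str = "strict", subgroup_restricted: bool = True,
                 normalize_features: bool = True,
                 rule_config: RuleConfig = DEFAULT_CONFIG):
        self.codebook = codebook or default_codebook()
        self.normalize_features = normalize_features
        self._feat_min, self._feat_range = codebook_scaler(self.codebook)
        self.k = k
        self.mode = mode
        self.reference_year = reference_year
        self.bmi_mode = bmi_mode
        self.subgroup_restricted = subgroup_restricted
        self.rule_config = rule_config
        self.entries: Dict[str, PatientEntry] = {}
        self.stats: Dict[str, se.GroupStats] = {}
        self.revision = 0
        outcome = {n.lower() for n in OUTCOME_FIELDS}
        self.feature_slots: Tuple[int, ...] = tuple(
            i for i, f in enumerate(self.codebook) if f.name.lower() not in outcome)

    # -- construction ------------------------------------------------------

    def scaled_codes(self, codes) -> "np.ndarray":
        """Similarity features of a coded vector (min-max scaled when enabled)."""
        if self.normalize_features:
            return normalize_codes(codes, self._feat_min, self._feat_range)
        return np.asarray(codes, dtype=float)

    def _build_entry(self, record: RawPatientRecord) -> PatientEntry:
        vector = encode_record(record, self.codebook, self.reference_year, self.bmi_mode)
        assignment = apply_molecular_update(
            classify_risk(record, self.rule_config), record.molecular)
        return PatientEntry(record, vector, assignment,
                            features=self.scaled_codes(vector.codes))

    def upsert(self, record: RawPatientRecord) -> Set[str]:
        """Insert or replace a patient; returns the ids whose estimates changed."""
        findings = validate_record(record, self.codebook)
        errors = [f for f in findings if f.severity == "error"]
        if errors:
            raise ValueError(f"invalid record {record.patient_id!r}: "
                             + "; ".join(f"{f.field}: {f.message}" for f in errors))
        old = self.entries.get(record.patient_id)
        entry = self._build_entry(record)
        self.entries[record.patient_id] = entry
        force_full = old is not None and (
            old.record.is_deceased() or old.group_key != entry.group_key
            or old.vector.codes != entry.vector.codes)
        self.revision += 1
        log.info("revision=%d op=upsert patient_id=%s", self.revision, record.patient_id)
        return self._refresh(record.patient_id, force_full=force_full)

    def remove(self, patient_id: str) -> Set[str]:
        if patient_id not in self.entries:
            raise RegistryLookupError(patient_id)
        entry = self.entries.pop(patient_id)
        self.revision += 1
        log.info("revision=%d op=remove patient_id=%s", self.revision, patient_id)
        if entry.record.is_deceased() or self.mode == se.OUTCOME_WEIGHTED:
            return self._recompute_all_estimates()
        self._recompute_stats()
        return set()

    def bulk_load(self, records: Iterable[RawPatientRecord]) -> None:
        """Load many validated records, then derive estimates and stats once."""
        for record in records:
            self.entries[record.patient_id] = self._build_entry(record)
        self.revision += 1
        log.info("revision=%d op=bulk_load n=%d", self.revision, len(self.entries))
        self._recompute_all_estimates()

    # -- derived-state maintenance ------------------------------------------

    def update_on_change(self, changed_patient_id: str) -> Tuple[Set[str], Dict[str, se.GroupStats]]:
        """Refresh estimates/stats after an external change to one patient."""
        if changed_patient_id not in self.entries:
            raise RegistryLookupError(changed_patient_id)
        self.revision += 1
        log.info("revision=%d op=update_on_change patient_id=%s",
                 self.revision, changed_patient_id)
        refreshed = self._refresh(changed_patient_id, force_full=False)
        return refreshed, dict(self.stats)

    def _refresh(self, changed_id: str, force_full: bool) -> Set[str]:
        entry = self.entries[changed_id]
        touches_pool = (entry.record.is_deceased() or self.mode == se.OUTCOME_WEIGHTED
                        or force_full)
        if touches_pool:
            return self._recompute_all_estimates()
        # a living patient only feeds its own estimate under deceased-distance
        changed = self._recompute_estimates([changed_id])
        self._recompute_stats()
        return changed

    def _estimate_entry(self, entry: PatientEntry) -> Optional[se.SurvivalEstimate]:
        if entry.record.is_deceased():
            return None  # the deceased are the reference pool, not queries
        try:
            return se.estimate_survival(entry.vector, self, k=self.k, mode=self.mode)
        except InsufficientReferenceError:
            return None

    def _recompute_estimates(self, ids: Sequence[str]) -> Set[str]:
        changed: Set[str] = set()
        for pid in ids:
            entry = self.entries[pid]
            new = self._estimate_entry(entry)
            if new != entry.estimate:
                entry.estimate = new
                changed.add(pid)
        return changed

    def _recompute_all_estimates(self) -> Set[str]:
        changed = self._recompute_estimates(sorted(self.entries))
        self._recompute_stats()
        return changed

    def _recompute_stats(self) -> None:
        groups = sorted({e.group_key for e in self.entries.values()})
        self.stats = {g: se.group_mean_survival(self, g) for g in groups}

    def recompute_from_scratch(self) -> None:
        """Rebuild every derived object from the raw records (consistency oracle)."""
        records = [e.record for _, e in sorted(self.entries.items())]
        self.entries = {}
        for record in records:
            self.entries[record.patient_id] = self._build_entry(record)
        self._recompute_all_estimates()

    def group_stats(self, subgroup: str) -> se.GroupStats:
        return se.group_mean_survival(self, subgroup)

    # -- search --------------------------------------------------------------

    def _haystack(self, entry: PatientEntry) -> str:
        decoded = decode_vector(entry.vector, self.codebook)
        parts = [entry.record.patient_id, entry.assignment.group,
                 entry.assignment.subgroup, entry.record.referral_type or ""]
        parts.extend(v for v in decoded.values() if v)
        return "\n".join(parts).lower()

    def global_search(self, query: str) -> List[str]:
        """Case-insensitive substring search across all decoded fields and ids."""
        needle = (query or "").lower()
        return sorted(pid for pid, e in self.entries.items()
                      if needle in self._haystack(e))

    _SPECIAL_KEYS = frozenset({"id", "screening_method", "screening_start_age",
                               "screening_interval", "risk_group", "subgroup",
                               "survival_status", "survival_percent_range"})

    def special_search(self, **criteria) -> List[str]:
        """Exact-match conjunction over id / screening / risk / survival criteria."""
        unknown = set(criteria) - self._SPECIAL_KEYS
        if unknown:
            raise QueryError(f"unknown search criteria: {sorted(unknown)}")
        if not criteria:
            raise QueryError("special_search needs at least one criterion")
        out = []
        for pid in sorted(self.entries):
            e = self.entries[pid]
            if "id" in criteria and pid != criteria["id"]:
                continue
            if any(k in criteria for k in
                   ("screening_method", "screening_start_age", "screening_interval")):
                rec = recommend_screening(e.assignment)
                if criteria.get("screening_method", rec.method) != rec.method:
                    continue
                if int(criteria.get("screening_start_age", rec.start_age)) != rec.start_age:
                    continue
                if int(criteria.get("screening_interval", rec.interval)) != rec.interval:
                    continue
            if "risk_group" in criteria and e.assignment.group != criteria["risk_group"]:
                continue
            if "subgroup" in criteria and e.assignment.subgroup != criteria["subgroup"]:
                continue
            if "survival_status" in criteria:
                status = "dead" if e.record.is_deceased() else "alive"
                if status != str(criteria["survival_status"]).lower():
                    continue
            if "survival_percent_range" in criteria:
                lo, hi = criteria["survival_percent_range"]
                if e.estimate is None or not (lo <= e.estimate.percent <= hi):
                    continue
            out.append(pid)
        return out

    # -- ingest / persistence -------------------------------------------------

    def ingest(self, csv_path: str, families_json: Optional[str] = None) -> IngestReport:
        """Load a registry CSV (+ companion family/molecular JSON) row by row."""
        frame = pd.read_csv(csv_path, dtype=str, keep_default_na=False)
        companions = {}
        if families_json and os.path.exists(families_json):
            with open(families_json, "r", encoding="utf-8") as fh:
                companions = json.load(fh)
        report = IngestReport()
        accepted: List[RawPatientRecord] = []
        seen: Set[str] = set(self.entries)
        for i, row in enumerate(frame.to_dict(orient="records")):
            try:
                record = record_from_row(row, companions.get(str(row.get("patient_id", ""))))
            except Exception as exc:
                report.rejected.append((i, str(row.get("patient_id", "")), str(exc)))
                continue
            if record.patient_id in seen:
                report.rejected.append((i, record.patient_id, "duplicate patient_id"))
                continue
            findings = validate_record(record, self.codebook)
            errors = [f for f in findings if f.severity == "error"]
            if errors:
                f0 = errors[0]
                report.rejected.append((i, record.patient_id, f"{f0.field}: {f0.message}"))
                continue
            seen.add(record.patient_id)
            accepted.append(record)
        if accepted:
            self.bulk_load(accepted)
        report.accepted = len(accepted)
        log.info("op=ingest accepted=%d rejected=%d", report.accepted, report.n_rejected)
        return report

    def to_dir(self, path: str) -> None:
        os.makedirs(path, exist_ok=True)
        records = [self.entries[pid].record for pid in sorted(self.entries)]
        write_registry_files(records, path)
        derived = {
            "revision": self.revision,
            "estimates": {pid: dataclasses.asdict(e.estimate)
                          for pid, e in sorted(self.entries.items()) if e.estimate},
            "stats": {g: dataclasses.asdict(s) for g, s in sorted(self.stats.items())},
        }
        with open(os.path.join(path, "derived.json"), "w", encoding="utf-8") as fh:
            json.dump(derived, fh, indent=2)

    @classmethod
    def from_dir(cls, path: str, **kwargs) -> "Registry":
        reg = cls(**kwargs)
        reg.ingest(os.path.join(path, "registry.csv"), os.path.join(path, "families.json"))
        return reg

    def estimates_frame(self) -> pd.DataFrame:
        rows = [{"patient_id": pid, "percent": e.estimate.percent,
                 "subgroup": e.group_key, "k_used": e.estimate.k_used,
                 "mode": e.estimate.estimator_mode}
                for pid, e in sorted(self.entries.items()) if e.estimate]
        return pd.DataFrame(rows, columns=["patient_id", "percent", "subgroup",
                                           "k_used", "mode"])


# ---------------------------------------------------------------------------
# Row <-> record plumbing
# ---------------------------------------------------------------------------

_NUMERIC = {"weight": float, "height": float, "diagnosis_age": float,
            "survival_time": int, "adenoma_count": int}


def record_from_row(row: dict, companion: Optional[dict] = None) -> RawPatientRecord:
    """Build a record from one CSV row plus its optional companion JSON entry."""
    kwargs = {}
    for col in SCALAR_COLUMNS:
        raw = row.get(col, "")
        if raw is None or str(raw).strip() == "":
            kwargs[col] = None
            continue
        conv = _NUMERIC.get(col)
        kwargs[col] = conv(float(raw)) if conv else str(raw)
    record = RawPatientRecord(**kwargs)
    if companion:
        record.family_history = [RelativeCancer(**rel)
                                 for rel in companion.get("family_history", [])]
        if companion.get("molecular"):
            record.molecular = MolecularFindings(**companion["molecular"])
    return record


def record_to_row(record: RawPatientRecord) -> dict:
    out = {}
    for col in SCALAR_COLUMNS:
        v = getattr(record, col)
        out[col] = "" if v is None else v
    return out


def write_registry_files(records: Sequence[RawPatientRecord], path: str) -> Tuple[str, str]:
    """Write ``registry.csv`` and ``families.json`` for a record collection."""
    os.makedirs(path, exist_ok=True)
    csv_path = os.path.join(path, "registry.csv")
    json_path = os.path.join(path, "families.json")
    pd.DataFrame([record_to_row(r) for r in records],
                 columns=list(SCALAR_COLUMNS)).to_csv(csv_path, index=False)
    companions = {}
    for r in records:
        if r.family_history or r.molecular != MolecularFindings():
            companions[r.patient_id] = {
                "family_history": [dataclasses.asdict(rel) for rel in r.family_history],
                "molecular": dataclasses.asdict(r.molecular),
            }
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(companions, fh, indent=2)
    return csv_path, json_path
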
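"""Guideline rule engine: hereditary-CRC risk stratification and screening advice.

Screening risk is assigned by a deterministic, priority-ordered cascade over
the registry record, its family history and molecular findings:

1. mutation-confirmed syndromes — Lynch syndrome (HNPCC; germline mismatch-
   repair mutation or registry designation), familial adenomatous polyposis
   (FAP, germline APC with a classical adenoma burden), attenuated FAP (APC
   with 10–99 adenomas), and MUTYH-associated polyposis (MYH, biallelic
   MUTYH);
2. suspected syndromes — Suspected HNPCC when the pedigree meets the
   Amsterdam II criteria *and* any revised Bethesda clause fires; Suspected
   FAP on an unexplained polyposis burden;
3. inflammatory bowel disease (IBD), a high-risk state in its own right;
4. a moderate tier for family CRC history short of the criteria;
5. average risk otherwise.

Molecular evidence can upgrade a Suspected HNPCC assignment to confirmed HNPCC
(identified germline mutation, or abnormal mismatch-repair IHC together with
MSI-high).  Clause sets, polyposis thresholds and the surveillance
recommendation table are configuration, shipped with published defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Optional, Sequence, Tuple

from .errors import ConfigurationError

#: Tumour sites counted as HNPCC-associated by both criteria sets.
HNPCC_SITES = frozenset({"crc", "endometrial", "small bowel", "ureter/renal pelvis"})

SUBGROUPS = ("FAP", "AFAP", "Suspected FAP", "HNPCC", "Suspected HNPCC", "MYH", "IBD")


@dataclass(frozen=True)
class RelativeCancer:
    """One affected relative in the proband's family history.

    ``lineage_id`` is a generation index (0 = proband's generation, 1 =
    parents, 2 = grandparents); successive integers are successive
    generations.
    """

    relation_degree: str          # "first" | "second"
    lineage_id: int
    cancer_site: str              # controlled vocabulary; see HNPCC_SITES
    age_at_diagnosis: Optional[float] = None
    pathology_verified: bool = False

    def is_hnpcc_site(self) -> bool:
        return self.cancer_site.strip().lower() in HNPCC_SITES


@dataclass(frozen=True)
class MolecularFindings:
    """Germline and tumour molecular work-up; "untested" is distinct from negative."""

    germline_mutation_identified: str = "untested"  # yes | no | untested
    gene: Optional[str] = None                      # "MMR" | "APC" | "MUTYH-biallelic"
    ihc_result: str = "untested"                    # normal | abnormal | untested
    msi_status: str = "untested"                    # MSI-high | MSI-low | MSS | untested


@dataclass(frozen=True)
class RiskAssignment:
    group: str                       # average | moderate | high
    subgroup: str                    # one of SUBGROUPS or "none"
    fired_rules: Tuple[str, ...] = ()

    def __post_init__(self):
        if self.subgroup != "none" and self.group != "high":
            raise ValueError("a named subgroup implies high risk group")
        if self.subgroup != "none" and not self.fired_rules:
            raise ValueError("subgroup assignment requires a nonempty rule trace")


@dataclass(frozen=True)
class ScreeningRecommendation:
    method: str
    start_age: int      # years
    interval: int       # months

    def __post_init__(self):
        if self.start_age <= 0 or self.interval <= 0:
            raise ValueError("start_age and interval must be positive")


@dataclass(frozen=True)
class RuleConfig:
    """Tunable guideline thresholds and clause toggles."""

    fap_adenoma_min: int = 100          # classical FAP burden
    polyposis_suspect_min: int = 10     # unexplained burden -> Suspected FAP
    amsterdam_min_relatives: int = 3
    amsterdam_age_cut: float = 50.0
    bethesda_age_cut: float = 50.0
    bethesda_msi_age_cut: float = 60.0
    bethesda_clauses: Tuple[str, ...] = (
        "crc-before-50", "synchronous-metachronous", "msi-high-before-60",
        "fdr-hnpcc-before-50", "two-relatives-hnpcc")
    moderate_tier_enabled: bool = True

    @classmethod
    def from_json(cls, doc: dict) -> "RuleConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        bad = set(doc) - known
        if bad:
            raise ConfigurationError(f"unknown rule-config keys: {sorted(bad)}")
        if "bethesda_clauses" in doc:
            doc = {**doc, "bethesda_clauses": tuple(doc["bethesda_clauses"])}
        return cls(**doc)


DEFAULT_CONFIG = RuleConfig()


def _yes(value: Optional[str]) -> bool:
    return (value or "").strip().lower() == "yes"


# ---------------------------------------------------------------------------
# Amsterdam II
# ---------------------------------------------------------------------------


def meets_amsterdam_ii(history: Sequence[RelativeCancer], fap_excluded: bool,
                       config: RuleConfig = DEFAULT_CONFIG) -> Tuple[bool, Dict[str, bool]]:
    """Evaluate the Amsterdam II pedigree criteria with a per-clause trace.

    All clauses must hold: at least three relatives with HNPCC-associated
    tumours; one of them a first-degree relative of the other two (evaluated on
    the flat relative list: an affected first-degree relative with at least two
    other affected relatives within one generation of it); at least two
    successive generations affected; at least one diagnosis before 50; FAP
    excluded; pathology verified in at least one case.
    """
    affected = [r for r in history if r.is_hnpcc_site()]
    trace = {
        "three-affected-relatives": len(affected) >= config.amsterdam_min_relatives,
        "first-degree-link": _first_degree_link(affected),
        "two-successive-generations": _successive_generations(affected),
        "one-diagnosis-before-50": any(
            r.age_at_diagnosis is not None and r.age_at_diagnosis < config.amsterdam_age_cut
            for r in affected),
        "fap-excluded": bool(fap_excluded),
        "pathology-verified": any(r.pathology_verified for r in affected),
    }
    return all(trace.values()), trace


def _first_degree_link(affected: Sequence[RelativeCancer]) -> bool:
    for r in affected:
        if r.relation_degree != "first":
            continue
        near = sum(1 for o in affected
                   if o is not r and abs(o.lineage_id - r.lineage_id) <= 1)
        if near >= 2:
            return True
    return False


def _successive_generations(affected: Sequence[RelativeCancer]) -> bool:
    gens = sorted({r.lineage_id for r in affected})
    return any(b - a == 1 for a, b in zip(gens, gens[1:]))


# ---------------------------------------------------------------------------
# Revised Bethesda
# ---------------------------------------------------------------------------


def meets_bethesda(record, history: Optional[Sequence[RelativeCancer]] = None,
                   config: RuleConfig = DEFAULT_CONFIG) -> Tuple[bool, Dict[str, bool]]:
    """Evaluate the revised Bethesda triggers; any enabled clause suffices."""
    history = record.family_history if history is None else history
    affected = [r for r in history if r.is_hnpcc_site()]
    dx = record.diagnosis_age
    molecular = record.molecular
    clauses = {
        "crc-before-50": dx is not None and dx < config.bethesda_age_cut,
        "synchronous-metachronous": _yes(getattr(record, "personal_crc_history", None)),
        "msi-high-before-60": (molecular.msi_status == "MSI-high"
                               and dx is not None and dx < config.bethesda_msi_age_cut),
        "fdr-hnpcc-before-50": any(
            r.relation_degree == "first" and r.age_at_diagnosis is not None
            and r.age_at_diagnosis < config.bethesda_age_cut for r in affected),
        "two-relatives-hnpcc": len(affected) >= 2,
    }
    trace = {name: clauses[name] for name in config.bethesda_clauses}
    return any(trace.values()), trace


# ---------------------------------------------------------------------------
# Risk cascade
# ---------------------------------------------------------------------------


def classify_risk(record, config: RuleConfig = DEFAULT_CONFIG) -> RiskAssignment:
    """Assign the risk group/subgroup by the fixed priority cascade.

    Pure and deterministic: the same record always yields the same assignment,
    and exactly one subgroup (or none) is chosen.  ``fired_rules`` records the
    decisive rule first, then the molecular-update trail if any.
    """
    mol = record.molecular
    adenomas = getattr(record, "adenoma_count", None)
    germline = mol.germline_mutation_identified == "yes"

    # 1. mutation-confirmed subgroups
    if _yes(getattr(record, "hnpcc", None)):
        return RiskAssignment("high", "HNPCC", ("registry-hnpcc-designation",))
    if germline and mol.gene == "MMR":
        return RiskAssignment("high", "HNPCC", ("confirmed-mmr-mutation",))
    if germline and mol.gene == "APC":
        if adenomas is not None and adenomas < config.fap_adenoma_min:
            return RiskAssignment("high", "AFAP", ("apc-mutation-attenuated-burden",))
        return RiskAssignment("high", "FAP", ("apc-mutation-classical-burden",))
    if germline and mol.gene == "MUTYH-biallelic":
        return RiskAssignment("high", "MYH", ("biallelic-mutyh-mutation",))
    if _yes(getattr(record, "fap", None)):
        return RiskAssignment("high", "FAP", ("registry-fap-designation",))

    # 2. suspected subgroups
    fap_excluded = not (_yes(getattr(record, "fap", None))
                        or (adenomas is not None and adenomas >= config.polyposis_suspect_min))
    ams_ok, ams_trace = meets_amsterdam_ii(record.family_history, fap_excluded, config)
    if ams_ok:
        beth_ok, _ = meets_bethesda(record, config=config)
        if beth_ok:
            return RiskAssignment("high", "Suspected HNPCC",
                                  ("amsterdam-ii-met", "bethesda-met"))
    if adenomas is not None and adenomas >= config.polyposis_suspect_min:
        return RiskAssignment("high", "Suspected FAP", ("polyposis-burden-unexplained",))

    # 3. IBD
    if _yes(getattr(record, "ibd", None)):
        return RiskAssignment("high", "IBD", ("ibd-present",))

    # 4. moderate: family history short of criteria
    if config.moderate_tier_enabled and (
            _yes(getattr(record, "family_crc_history", None))
            or any(r.cancer_site.strip().lower() == "crc" for r in record.family_history)):
        return RiskAssignment("moderate", "none", ("family-history-without-criteria",))

    return RiskAssignment("average", "none", ())


def apply_molecular_update(current: RiskAssignment,
                           molecular: MolecularFindings) -> RiskAssignment:
    """Upgrade Suspected HNPCC to HNPCC on molecular confirmation; idempotent."""
    if current.subgroup != "Suspected HNPCC":
        return current
    if molecular.germline_mutation_identified == "yes":
        rule = "molecular-upgrade:germline-mutation"
    elif molecular.ihc_result == "abnormal" and molecular.msi_status == "MSI-high":
        rule = "molecular-upgrade:abnormal-ihc-msi-high"
    else:
        return current
    return replace(current, subgroup="HNPCC", fired_rules=current.fired_rules + (rule,))


# ---------------------------------------------------------------------------
# Surveillance recommendations
# ---------------------------------------------------------------------------

#: Shipped surveillance defaults (fully overridable): classical published
#: intervals — annual sigmoido/colonoscopy from adolescence for (suspected)
#: FAP, 1–2-yearly colonoscopy from the early twenties for (suspected) Lynch,
#: and stool-based average-risk screening from 50.
DEFAULT_RECOMMENDATIONS: Tuple[dict, ...] = (
    {"group": "high", "subgroup": "FAP", "method": "colonoscopy", "start_age": 12, "interval_months": 12},
    {"group": "high", "subgroup": "AFAP", "method": "colonoscopy", "start_age": 18, "interval_months": 24},
    {"group": "high", "subgroup": "Suspected FAP", "method": "colonoscopy", "start_age": 12, "interval_months": 12},
    {"group": "high", "subgroup": "HNPCC", "method": "colonoscopy", "start_age": 20, "interval_months": 12},
    {"group": "high", "subgroup": "Suspected HNPCC", "method": "colonoscopy", "start_age": 20, "interval_months": 24},
    {"group": "high", "subgroup": "MYH", "method": "colonoscopy", "start_age": 25, "interval_months": 24},
    {"group": "high", "subgroup": "IBD", "method": "colonoscopy", "start_age": 25, "interval_months": 24},
    {"group": "moderate", "subgroup": "none", "method": "colonoscopy", "start_age": 40, "interval_months": 60},
    {"group": "average", "subgroup": "none", "method": "FIT", "start_age": 50, "interval_months": 12},
)


def recommend_screening(assignment: RiskAssignment, age: Optional[float] = None,
                        rules: Optional[Sequence[dict]] = None) -> ScreeningRecommendation:
    """Look up the surveillance advice for a risk assignment.

    ``rules`` rows are ``{group, subgroup, method, start_age, interval_months}``;
    the lookup is exact on (group, subgroup) and raises
    :class:`~crcdss.errors.ConfigurationError` when uncovered.  ``age`` is
    accepted for interface symmetry (the advice itself is assignment-driven).
    """
    table = DEFAULT_RECOMMENDATIONS if rules is None else rules
    for row in table:
        if row["group"] == assignment.group and row["subgroup"] == assignment.subgroup:
            return ScreeningRecommendation(row["method"], int(row["start_age"]),
                                           int(row["interval_months"]))
    raise ConfigurationError(
        f"recommendation table has no row for group={assignment.group!r} "
        f"subgroup={assignment.subgroup!r}")
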
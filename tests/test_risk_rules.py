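"""Amsterdam II / Bethesda evaluation and the risk cascade."""

import itertools

import pytest

from crcdss.errors import ConfigurationError
from crcdss.mds_schema import RawPatientRecord
from crcdss.risk_rules import (DEFAULT_RECOMMENDATIONS, MolecularFindings, RelativeCancer,
                               RiskAssignment, apply_molecular_update, classify_risk,
                               meets_amsterdam_ii, meets_bethesda, recommend_screening)
from crcdss.synthetic_data import generate_pedigree


def qualifying_pedigree():
    return [
        RelativeCancer("first", 1, "CRC", 45, True),      # parent, dx < 50, verified
        RelativeCancer("first", 0, "CRC", 55, False),     # sibling
        RelativeCancer("second", 2, "endometrial", 60, False),  # grandparent
    ]


class TestAmsterdamII:
    def test_qualifying_pedigree(self):
        ok, trace = meets_amsterdam_ii(qualifying_pedigree(), fap_excluded=True)
        assert ok and all(trace.values())

    def test_empty_history_fails_every_pedigree_clause(self):
        ok, trace = meets_amsterdam_ii([], fap_excluded=False)
        assert not ok
        assert not any(v for k, v in trace.items())

    def test_single_clause_flip_on_age(self):
        ped = [RelativeCancer(r.relation_degree, r.lineage_id, r.cancer_site,
                              max(r.age_at_diagnosis, 55), r.pathology_verified)
               for r in qualifying_pedigree()]
        ok, trace = meets_amsterdam_ii(ped, fap_excluded=True)
        assert not ok
        failed = [k for k, v in trace.items() if not v]
        assert failed == ["one-diagnosis-before-50"]

    def test_fap_exclusion_is_required(self):
        ok, trace = meets_amsterdam_ii(qualifying_pedigree(), fap_excluded=False)
        assert not ok and not trace["fap-excluded"]

    def test_non_hnpcc_sites_do_not_count(self):
        ped = [RelativeCancer("first", 1, "other", 45, True),
               RelativeCancer("first", 0, "other", 40, True),
               RelativeCancer("second", 2, "other", 60, True)]
        ok, trace = meets_amsterdam_ii(ped, fap_excluded=True)
        assert not ok and not trace["three-affected-relatives"]


class TestBethesda:
    def test_young_proband_triggers_age_clause(self):
        record = RawPatientRecord("p", diagnosis_age=42)
        ok, trace = meets_bethesda(record)
        assert ok and trace["crc-before-50"]

    def test_old_sporadic_mss_fires_nothing(self):
        record = RawPatientRecord("p", diagnosis_age=70, personal_crc_history="No",
                                  molecular=MolecularFindings(msi_status="MSS"))
        ok, trace = meets_bethesda(record)
        assert not ok and not any(trace.values())

    def test_msi_high_under_sixty(self):
        record = RawPatientRecord("p", diagnosis_age=55,
                                  molecular=MolecularFindings(msi_status="MSI-high"))
        ok, trace = meets_bethesda(record)
        assert ok and trace["msi-high-before-60"]

    def test_msi_high_at_sixty_plus_does_not(self):
        record = RawPatientRecord("p", diagnosis_age=65,
                                  molecular=MolecularFindings(msi_status="MSI-high"))
        _, trace = meets_bethesda(record)
        assert not trace["msi-high-before-60"]


class TestClassifyCascade:
    def test_amsterdam_plus_bethesda_without_mutation_is_suspected(self):
        record = RawPatientRecord("p", diagnosis_age=48,
                                  family_history=qualifying_pedigree())
        a = classify_risk(record)
        assert (a.group, a.subgroup) == ("high", "Suspected HNPCC")
        assert "amsterdam-ii-met" in a.fired_rules

    def test_ibd_alone_is_high_risk(self):
        a = classify_risk(RawPatientRecord("p", ibd="Yes"))
        assert (a.group, a.subgroup) == ("high", "IBD")

    def test_no_findings_is_average(self):
        a = classify_risk(RawPatientRecord("p"))
        assert (a.group, a.subgroup) == ("average", "none")

    def test_family_history_without_criteria_is_moderate(self):
        a = classify_risk(RawPatientRecord("p", family_crc_history="Yes"))
        assert (a.group, a.subgroup) == ("moderate", "none")

    def test_confirmed_mutations_outrank_suspected(self):
        record = RawPatientRecord(
            "p", diagnosis_age=45, family_history=qualifying_pedigree(),
            molecular=MolecularFindings("yes", "MMR"))
        a = classify_risk(record)
        assert a.subgroup == "HNPCC"

    def test_apc_burden_split(self):
        apc = MolecularFindings("yes", "APC")
        assert classify_risk(RawPatientRecord("p", molecular=apc,
                                              adenoma_count=500)).subgroup == "FAP"
        assert classify_risk(RawPatientRecord("p", molecular=apc,
                                              adenoma_count=40)).subgroup == "AFAP"

    def test_unexplained_polyposis_is_suspected_fap(self):
        assert classify_risk(RawPatientRecord("p", adenoma_count=30)).subgroup == "Suspected FAP"

    def test_pure_function(self):
        record = RawPatientRecord("p", ibd="Yes", family_crc_history="Yes")
        assert classify_risk(record) == classify_risk(record)

    def test_exactly_one_subgroup_over_flag_grid(self):
        """Exhaustive sweep over a small combinatorial grid of rule inputs."""
        peds = {"none": [], "qualifying": qualifying_pedigree()}
        for hnpcc, fap, ibd, fam, gene, adenomas, ped, dx in itertools.product(
                ("Yes", "No"), ("Yes", "No"), ("Yes", "No"), ("Yes", "No"),
                (None, "MMR", "APC", "MUTYH-biallelic"), (None, 5, 50, 500),
                peds, (40.0, 70.0)):
            mol = (MolecularFindings() if gene is None
                   else MolecularFindings("yes", gene))
            record = RawPatientRecord(
                "p", hnpcc=hnpcc, fap=fap, ibd=ibd, family_crc_history=fam,
                adenoma_count=adenomas, diagnosis_age=dx,
                family_history=peds[ped], molecular=mol)
            a = classify_risk(record)
            assert a.group in ("average", "moderate", "high")
            if a.subgroup != "none":
                assert a.group == "high" and a.fired_rules


class TestMolecularUpdate:
    sus = RiskAssignment("high", "Suspected HNPCC", ("amsterdam-ii-met", "bethesda-met"))

    def test_germline_mutation_upgrades(self):
        out = apply_molecular_update(self.sus, MolecularFindings("yes", "MMR"))
        assert out.subgroup == "HNPCC"
        assert out.fired_rules[-1] == "molecular-upgrade:germline-mutation"

    def test_ihc_msi_combination_upgrades(self):
        out = apply_molecular_update(
            self.sus, MolecularFindings(ihc_result="abnormal", msi_status="MSI-high"))
        assert out.subgroup == "HNPCC"

    def test_partial_molecular_evidence_does_not(self):
        out = apply_molecular_update(
            self.sus, MolecularFindings(ihc_result="normal", msi_status="MSI-high"))
        assert out == self.sus

    def test_idempotent(self):
        mol = MolecularFindings("yes", "MMR")
        once = apply_molecular_update(self.sus, mol)
        assert apply_molecular_update(once, mol) == once

    def test_other_subgroups_untouched(self):
        fap = RiskAssignment("high", "FAP", ("registry-fap-designation",))
        assert apply_molecular_update(fap, MolecularFindings("yes", "MMR")) == fap


class TestRecommendations:
    def test_every_subgroup_covered_by_default_table(self):
        for subgroup in ("FAP", "AFAP", "Suspected FAP", "HNPCC", "Suspected HNPCC",
                         "MYH", "IBD"):
            rec = recommend_screening(
                RiskAssignment("high", subgroup, ("r",)))
            assert rec.method and rec.start_age > 0 and rec.interval > 0

    def test_hnpcc_row(self):
        rec = recommend_screening(RiskAssignment("high", "HNPCC", ("r",)), age=30)
        assert rec.method == "colonoscopy" and rec.start_age == 20

    def test_average_row(self):
        rec = recommend_screening(RiskAssignment("average", "none"), age=40)
        assert rec.method == "FIT" and rec.start_age == 50

    def test_missing_row_is_configuration_error(self):
        table = [r for r in DEFAULT_RECOMMENDATIONS if r["subgroup"] != "MYH"]
        with pytest.raises(ConfigurationError):
            recommend_screening(RiskAssignment("high", "MYH", ("r",)), rules=table)


class TestGeneratedPedigrees:
    @pytest.mark.parametrize("target", [True, False])
    def test_generator_agrees_with_rule_engine(self, target):
        for seed in range(50):
            sample = generate_pedigree(target, seed)
            ok, _ = meets_amsterdam_ii(list(sample.relatives), fap_excluded=True)
            assert ok is target
            if not target:
                assert sample.failed_clause is not None
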
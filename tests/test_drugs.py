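"""Stage 4: drug-target overlap, status classification, candidate summary."""

import pytest

from gwas2drug import drugs
from gwas2drug.types import (
    DiseaseStatus,
    DrugStatus,
    DrugTargetRecord,
    RepurposingCandidate,
    TrialPhase,
    TrialRecord,
)


def rec(drug_id, name, gene, pharm=True, status=DrugStatus.APPROVED, indication=""):
    return DrugTargetRecord(drug_id, name, gene, pharm, status, indication)


class TestOverlapDrugs:
    def test_empty_table_gives_no_candidates(self):
        assert drugs.overlap_drugs({"A"}, []) == []

    def test_pharm_action_filter(self):
        table = [
            rec("D1", "alpha", "A"),
            rec("D2", "beta", "A", pharm=False),
            rec("D3", "gamma", "B"),
        ]
        cands = drugs.overlap_drugs({"A", "B"}, table)
        assert {c.drug_name for c in cands} == {"alpha", "gamma"}

    def test_pharm_filter_can_be_disabled(self):
        table = [rec("D2", "beta", "A", pharm=False)]
        assert drugs.overlap_drugs({"A"}, table, require_pharm_action=False)

    def test_targets_outside_network_do_not_qualify(self):
        cands = drugs.overlap_drugs({"A"}, [rec("D1", "alpha", "Z")])
        assert cands == []

    def test_direct_flag_reflects_seed_membership(self):
        table = [rec("D1", "alpha", "SEED"), rec("D2", "beta", "ADDED")]
        cands = drugs.overlap_drugs({"SEED", "ADDED"}, table, seeds={"SEED"})
        by_name = {c.drug_name: c for c in cands}
        assert by_name["alpha"].direct
        assert not by_name["beta"].direct

    def test_all_targets_are_network_members(self):
        table = [rec("D1", "alpha", "A"), rec("D1", "alpha2", "Z")]
        # same drug_id, one in-network target: candidate lists only that target
        cands = drugs.overlap_drugs({"A"}, table)
        assert cands[0].target_genes == frozenset({"A"})

    def test_druggable_genes_union(self):
        table = [rec("D1", "a", "A"), rec("D2", "b", "A"), rec("D3", "c", "B")]
        cands = drugs.overlap_drugs({"A", "B"}, table)
        assert drugs.druggable_genes(cands) == frozenset({"A", "B"})

    @pytest.mark.parametrize(
        "allowed",
        [
            frozenset({DrugStatus.APPROVED}),
            frozenset({DrugStatus.APPROVED, DrugStatus.CLINICAL}),
            frozenset(DrugStatus),
        ],
    )
    def test_shrinking_status_set_never_grows_candidates(self, allowed):
        table = [
            rec("D1", "a", "A", status=DrugStatus.APPROVED),
            rec("D2", "b", "A", status=DrugStatus.CLINICAL),
            rec("D3", "c", "A", status=DrugStatus.EXPERIMENTAL),
        ]
        full = drugs.overlap_drugs({"A"}, table, allowed_status=frozenset(DrugStatus))
        sub = drugs.overlap_drugs({"A"}, table, allowed_status=allowed)
        assert {c.drug_id for c in sub} <= {c.drug_id for c in full}


class TestClassifyStatus:
    def cand(self, name):
        return RepurposingCandidate("D1", name, frozenset({"A"}), direct=True)

    def test_absent_from_trials_is_no_evidence(self):
        out = drugs.classify_status([self.cand("alpha")], [], "atopic dermatitis")
        assert out[0].disease_status is DiseaseStatus.NO_EVIDENCE

    def test_phase3_trial_marks_in_trial(self):
        trials = [TrialRecord("Alpha", "Atopic Dermatitis", TrialPhase.PHASE3, "NCT1")]
        out = drugs.classify_status([self.cand("alpha")], trials, "atopic dermatitis")
        assert out[0].disease_status is DiseaseStatus.IN_TRIAL_FOR_DISEASE

    def test_best_record_wins(self):
        trials = [
            TrialRecord("alpha", "atopic dermatitis", TrialPhase.PHASE2, "NCT1"),
            TrialRecord("alpha", "atopic dermatitis", TrialPhase.APPROVED, "NCT2"),
        ]
        out = drugs.classify_status([self.cand("alpha")], trials, "atopic dermatitis")
        assert out[0].disease_status is DiseaseStatus.APPROVED_FOR_DISEASE

    def test_synonym_conditions_match(self):
        trials = [TrialRecord("alpha", "atopic eczema", TrialPhase.CASE_REPORT, "PMID1")]
        out = drugs.classify_status(
            [self.cand("alpha")], trials, "atopic dermatitis", synonyms=("atopic eczema",)
        )
        assert out[0].disease_status is DiseaseStatus.CASE_REPORT

    def test_other_disease_trials_ignored(self):
        trials = [TrialRecord("alpha", "asthma", TrialPhase.PHASE3, "NCT1")]
        out = drugs.classify_status([self.cand("alpha")], trials, "atopic dermatitis")
        assert out[0].disease_status is DiseaseStatus.NO_EVIDENCE


class TestSummarize:
    def test_empty_gives_header_only(self):
        df = drugs.summarize([])
        assert len(df) == 0 and "drug_name" in df.columns

    def test_approved_listed_first(self):
        a = RepurposingCandidate("D1", "zeta", frozenset({"A"}), True,
                                 disease_status=DiseaseStatus.APPROVED_FOR_DISEASE)
        b = RepurposingCandidate("D2", "alpha", frozenset({"A"}), True,
                                 disease_status=DiseaseStatus.NO_EVIDENCE)
        df = drugs.summarize([b, a])
        assert list(df.drug_name) == ["zeta", "alpha"]


def test_expansion_only_target_still_recovered(mini_bundle):
    """A drug whose sole target entered via PPI expansion appears, direct=False,
    and lands at the top of the report when approved for the disease."""
    m = mini_bundle.manifest
    cands = drugs.overlap_drugs(
        m.expected_members, mini_bundle.drug_targets, seeds=m.seed_symbols
    )
    cands = drugs.classify_status(
        cands, mini_bundle.trials, "mini dermatitis"
    )
    planted = [c for c in cands if c.drug_name == m.planted_drug.drug_name]
    assert len(planted) == 1
    assert not planted[0].direct
    assert planted[0].target_genes == frozenset({m.planted_drug.target_gene})
    assert planted[0].disease_status is DiseaseStatus.APPROVED_FOR_DISEASE
    assert drugs.summarize(cands).iloc[0].drug_name == m.planted_drug.drug_name
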
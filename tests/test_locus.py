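"""Stage 1: p-value filtering, LD expansion, variant classes, gene mapping."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gwas2drug import locus
from gwas2drug.types import Consequence, LdProxy, RiskSnpSet, VariantAnnotation, VariantAssociation


def assoc(rsid, p):
    return VariantAssociation(rsid=rsid, p_value=p)


class TestFilterAssociations:
    def test_empty_in_empty_out(self):
        assert locus.filter_associations([], 1e-5) == []

    def test_strict_threshold_on_ten_records(self):
        # 4 of 10 lie strictly below 1e-5; 1e-5 itself is excluded
        records = [
            assoc("rs1", 1e-9), assoc("rs2", 5e-8), assoc("rs3", 9.9e-6),
            assoc("rs4", 2e-7), assoc("rs5", 1e-5), assoc("rs6", 3e-5),
            assoc("rs7", 1e-4), assoc("rs8", 0.03), assoc("rs9", 0.5),
            assoc("rs10", 1.0),
        ]
        kept = locus.filter_associations(records, 1e-5)
        assert {a.rsid for a in kept} == {"rs1", "rs2", "rs3", "rs4"}

    def test_duplicate_rsid_keeps_smallest_p(self):
        kept = locus.filter_associations(
            [
                VariantAssociation("rs1", 1e-6, trait="a"),
                VariantAssociation("rs1", 1e-9, trait="b"),
            ],
            1e-5,
        )
        assert len(kept) == 1 and kept[0].p_value == 1e-9

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            locus.filter_associations([], 1.0)

    @given(
        ps=st.lists(st.floats(min_value=1e-30, max_value=1.0), max_size=30),
        thr_lo=st.floats(min_value=1e-10, max_value=1e-3),
        thr_hi=st.floats(min_value=1e-10, max_value=1e-3),
    )
    @settings(deadline=None, max_examples=50)
    def test_lowering_threshold_never_grows_the_set(self, ps, thr_lo, thr_hi):
        lo, hi = sorted((thr_lo, thr_hi))
        records = [assoc(f"rs{i}", p) for i, p in enumerate(ps)]
        kept_lo = {a.rsid for a in locus.filter_associations(records, lo)}
        kept_hi = {a.rsid for a in locus.filter_associations(records, hi)}
        assert kept_lo <= kept_hi


class TestExpandLd:
    def test_self_pairs_only_gives_leads_back(self):
        ld = [LdProxy("L1", "L1", 1.0, "ASN"), LdProxy("L2", "L2", 1.0, "ASN")]
        out = locus.expand_ld({"L1", "L2"}, ld, r2_min=1.0)
        assert out.all_snps == frozenset({"L1", "L2"})
        assert out.provenance == {}

    def test_threshold_is_inclusive(self):
        ld = [LdProxy("L1", "P1", 0.85, "ASN"), LdProxy("L1", "P2", 0.79, "ASN"),
              LdProxy("L1", "P3", 0.8, "ASN")]
        out = locus.expand_ld({"L1"}, ld, r2_min=0.8)
        assert out.all_snps == frozenset({"L1", "P1", "P3"})

    def test_lead_absent_from_table_retained_alone(self):
        out = locus.expand_ld({"L9"}, [LdProxy("L1", "P1", 0.9, "ASN")], 0.8)
        assert out.all_snps == frozenset({"L9"})

    def test_population_is_exact_match(self):
        ld = [LdProxy("L1", "P1", 0.95, "EUR")]
        out = locus.expand_ld({"L1"}, ld, 0.8, population="ASN")
        assert out.all_snps == frozenset({"L1"})

    def test_proxy_from_two_leads_records_both_provenances(self):
        ld = [LdProxy("L1", "P1", 0.9, "ASN"), LdProxy("L2", "P1", 0.85, "ASN")]
        out = locus.expand_ld({"L1", "L2"}, ld, 0.8)
        assert out.provenance["P1"] == frozenset({("L1", 0.9), ("L2", 0.85)})

    @given(r2a=st.floats(0, 1), r2b=st.floats(0, 1), r2s=st.lists(st.floats(0, 1), max_size=20))
    @settings(deadline=None, max_examples=50)
    def test_lowering_r2_min_never_shrinks_all_snps(self, r2a, r2b, r2s):
        lo, hi = sorted((r2a, r2b))
        ld = [LdProxy("L1", f"P{i}", r2, "ASN") for i, r2 in enumerate(r2s)]
        snps_lo = locus.expand_ld({"L1"}, ld, lo).all_snps
        snps_hi = locus.expand_ld({"L1"}, ld, hi).all_snps
        assert snps_hi <= snps_lo


class TestClassifyVariants:
    def make_set(self, rsids):
        return RiskSnpSet(lead_snps=frozenset(rsids), all_snps=frozenset(rsids))

    def test_annotated_snp_passes_through(self):
        snps = self.make_set(["rs1"])
        ann = [VariantAnnotation("rs1", Consequence.MISSENSE_NONSENSE)]
        classes = locus.classify_variants(snps, ann)
        assert classes["rs1"].consequence is Consequence.MISSENSE_NONSENSE

    def test_missing_snp_defaults_to_noncoding_non_eqtl(self):
        classes = locus.classify_variants(self.make_set(["rs1"]), [])
        assert classes["rs1"].consequence is Consequence.NONCODING
        assert not classes["rs1"].eqtl

    def test_six_snp_fixture_tally(self):
        # 2 missense, 1 synonymous, 3 noncoding of which 2 are eQTLs
        snps = self.make_set([f"rs{i}" for i in range(1, 7)])
        ann = [
            VariantAnnotation("rs1", Consequence.MISSENSE_NONSENSE),
            VariantAnnotation("rs2", Consequence.MISSENSE_NONSENSE),
            VariantAnnotation("rs3", Consequence.SYNONYMOUS),
            VariantAnnotation("rs4", Consequence.NONCODING, eqtl=True, eqtl_tissue="whole_blood"),
            VariantAnnotation("rs5", Consequence.NONCODING, eqtl=True, eqtl_tissue="whole_blood"),
            VariantAnnotation("rs6", Consequence.NONCODING),
        ]
        tally = locus.variant_class_tally(locus.classify_variants(snps, ann))
        assert tally == {"missense_nonsense": 2, "synonymous": 1, "noncoding": 3, "eqtl": 2}


class TestMapToGenes:
    def test_two_snps_same_gene_group_into_one_record(self):
        snps = RiskSnpSet(frozenset({"rs1", "rs2"}), frozenset({"rs1", "rs2"}))
        ann = [
            VariantAnnotation("rs1", Consequence.NONCODING, gene_id="E1", gene_symbol="A"),
            VariantAnnotation("rs2", Consequence.NONCODING, gene_id="E1", gene_symbol="A"),
        ]
        genes = locus.map_to_genes(snps, ann)
        assert len(genes) == 1
        assert genes[0].supporting_snps == frozenset({"rs1", "rs2"})

    def test_snp_without_gene_contributes_nothing(self):
        snps = RiskSnpSet(frozenset({"rs1"}), frozenset({"rs1"}))
        ann = [VariantAnnotation("rs1", Consequence.NONCODING)]
        assert locus.map_to_genes(snps, ann) == []

    def test_annotation_outside_risk_set_ignored(self):
        snps = RiskSnpSet(frozenset({"rs1"}), frozenset({"rs1"}))
        ann = [VariantAnnotation("rs9", Consequence.NONCODING, gene_id="E1", gene_symbol="A")]
        assert locus.map_to_genes(snps, ann) == []

    def test_output_sorted_and_bounded_by_distinct_gene_ids(self):
        snps = RiskSnpSet(frozenset({"rs1", "rs2", "rs3"}), frozenset({"rs1", "rs2", "rs3"}))
        ann = [
            VariantAnnotation("rs1", Consequence.NONCODING, gene_id="E2", gene_symbol="B"),
            VariantAnnotation("rs2", Consequence.NONCODING, gene_id="E1", gene_symbol="A"),
            VariantAnnotation("rs3", Consequence.NONCODING, gene_id="E2", gene_symbol="B"),
        ]
        genes = locus.map_to_genes(snps, ann)
        assert [g.gene_id for g in genes] == ["E1", "E2"]
        assert len(genes) <= len({a.gene_id for a in ann})
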
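"""Locus expansion: from GWAS hits to risk genes.

Builds a six-SNP toy association list, expands the significant leads to their
LD proxies at r2 >= 0.8 (ASN), and maps the risk SNPs to genes.
"""

from gwas2drug import classify_variants, expand_ld, filter_associations, map_to_genes
from gwas2drug.types import Consequence, LdProxy, VariantAnnotation, VariantAssociation

associations = [
    VariantAssociation("rs100", 3e-9),   # lead
    VariantAssociation("rs200", 8e-7),   # lead
    VariantAssociation("rs300", 2e-4),   # above the p < 1e-5 threshold
]
ld = [
    LdProxy("rs100", "rs101", r2=0.92, population="ASN"),
    LdProxy("rs100", "rs102", r2=0.55, population="ASN"),   # too weak
    LdProxy("rs200", "rs201", r2=0.95, population="EUR"),   # wrong population
]
annotations = [
    VariantAnnotation("rs100", Consequence.NONCODING, gene_id="E1", gene_symbol="IL7R"),
    VariantAnnotation("rs101", Consequence.MISSENSE_NONSENSE, gene_id="E1", gene_symbol="IL7R"),
    VariantAnnotation("rs200", Consequence.NONCODING, gene_id="E2", gene_symbol="STAT3"),
]

leads = filter_associations(associations, p_threshold=1e-5)
snps = expand_ld((a.rsid for a in leads), ld, r2_min=0.8, population="ASN")
classes = classify_variants(snps, annotations)
genes = map_to_genes(snps, annotations)

print(f"leads passing p < 1e-5: {sorted(a.rsid for a in leads)}")
print(f"risk SNPs after LD expansion: {sorted(snps.all_snps)}")
for g in genes:
    print(f"  risk gene {g.symbol}: supported by {sorted(g.supporting_snps)}")
# rs300 is filtered out, rs102 (r2 < 0.8) and rs201 (EUR) never enter; the
# two remaining loci map to two risk genes, one carrying a missense proxy.
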
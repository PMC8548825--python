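# gwas2drug

Genetics-driven drug repurposing for atopic dermatitis (and, with other
snapshots, any GWAS-studied disease).  The package turns a catalogue of
disease-associated SNPs into a ranked list of repurposing candidates by
walking a four-stage pipeline over local snapshot tables — no web services,
fully deterministic, every stage testable in isolation.

**Who it is for:** computational geneticists and translational
bioinformaticians who have flattened snapshots of a GWAS catalogue, an LD
reference, variant annotations, gene-set collections (GMT), a scored PPI
edge list (STRING-style) and drug-target tables (DrugBank/TTD-style), and
want a reproducible path from loci to drugs.

## The method

1. **Locus expansion.** Keep associations with `p < 1e-5`; expand each lead
   SNP to its linkage-disequilibrium proxies with `r² ≥ 0.8` in the ASN
   population; map leads ∪ proxies to their assigned genes — the *risk genes*.
2. **Six-criterion scoring.** Each risk gene earns one point per criterion:
   (i) any missense/nonsense risk SNP; (ii) any whole-blood cis-eQTL risk
   SNP; (iii)–(v) membership in a knockout-mouse phenotype (MP) term, GO
   biological-process term, or KEGG pathway over-represented among the risk
   genes; (vi) membership in a significant primary-immunodeficiency (PID)
   gene set.  Over-representation of a term of size *K* in a universe of *N*
   genes against a query of *n* risk genes uses the exact hypergeometric
   upper tail

   P(X ≥ k) = Σ_{i≥k} C(K,i)·C(N−K,n−i) / C(N,n),

   with Benjamini–Hochberg control at FDR < 0.05 across each collection's
   terms (raw p < 0.05 for the PID list).  Genes with score ≥ 2 are the
   *biological risk genes*.
3. **Network expansion.** The biological genes (deduplicated by symbol) seed
   one shell of PPI expansion: up to 50 first-shell interactors, ranked by
   (best seed-edge confidence, seed-degree, symbol).  The members are the
   *drug target genes*; edges among members are the induced interaction pairs.
4. **Drug overlap.** Drugs whose filtered targets (pharmacological action;
   approved/clinical/experimental status) hit a network member become
   candidates, classified by their best clinical evidence for the disease
   (approved > in trial > case report > preclinical > none).  A drug whose
   only target entered via expansion is still recovered — flagged
   `direct=False` — which is how an already-approved biologic hitting an
   interactor of the seed genes validates the whole chain.

A synthetic-fixture generator (`gwas2drug.synthetic`) emits internally
consistent bundles of all input tables with planted, exactly recoverable
ground truth, including a constructed 94-gene preset whose marginals match
the study shape the pipeline was built around.

## Worked example

`examples/` contains one short script per capability.  The end-to-end run
(`python examples/05_full_pipeline.py`) generates the study-shape preset and
pushes it through all four stages:

```
             leads: 70
         risk_snps: 125
        risk_genes: 94
  biological_genes: 27
   network_members: 76
     induced_pairs: 2053
   druggable_genes: 25
             drugs: 53
```

70 associations survive the p-value filter; LD expansion and gene mapping
yield 94 risk genes, of which 27 score ≥ 2 (48 score 0, 19 score 1).  Their
26 unique symbols plus 50 PPI interactors give 76 drug target genes with
2053 interaction pairs among them, and the drug-target snapshot maps 25 of
those genes to 53 drugs — including one approved drug whose sole target is
an expansion-added gene.

The same pipeline runs from the shell:

```bash
gwas2drug simulate --preset mini-study --out fixtures/
gwas2drug expand --assoc fixtures/associations.tsv --ld fixtures/ld.tsv \
    --ann fixtures/annotations.tsv --out results/
gwas2drug score --genes results/risk_genes.tsv --variants fixtures/annotations.tsv \
    --mp fixtures/ko_mouse.gmt --go fixtures/go_bp.gmt --kegg fixtures/kegg.gmt \
    --pid fixtures/pid.gmt --universe fixtures/universe.txt --out results/
gwas2drug network --seeds results/biological_genes.tsv --edges fixtures/edges.tsv --out results/
gwas2drug drugs --members results/network_members.tsv \
    --drug-targets fixtures/drug_targets.tsv --trials fixtures/trials.tsv \
    --disease "mini dermatitis" --out results/
```

or in one shot with `gwas2drug run --config pipeline.yaml`.

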
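# Methods

## Model and assumptions

The pipeline treats drug repurposing as a set-expansion problem over four
deterministic maps:

    associations --(p filter, LD expansion, gene assignment)--> risk genes
    risk genes   --(six-criterion scoring, score >= 2)--------> biological genes
    biological genes --(one PPI shell, <= 50 interactors)-----> drug target genes
    drug target genes --(drug-target overlap, trial lookup)---> ranked candidates

It assumes the inputs are *frozen snapshots*: an association table with
per-SNP p-values, an LD table with precomputed r² (the package never
estimates LD from genotypes), a variant-annotation table carrying a single
gene assignment per SNP, flat GMT gene sets (no ontology DAG propagation),
an undirected scored edge list, and flattened drug-target/trial tables.
Everything downstream is a pure function of those tables, so identical
inputs give byte-identical outputs.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `p_threshold` | 1e-5 | GWAS significance; strict `<` |
| `r2_min` | 0.8 | LD proxy inclusion; inclusive `>=` |
| `population` | ASN | exact-match LD population tag |
| `eqtl_tissue` | whole_blood | tissue required for the cis-eQTL criterion |
| `fdr_threshold` | 0.05 | BH threshold for MP/GO/KEGG enrichment |
| `pid_p_threshold` | 0.05 | raw hypergeometric threshold for the PID list |
| `biological_score_min` | 2 | criteria needed to call a gene biological |
| `max_interactors` | 50 | first-shell expansion cap |
| `edge_score_min` | 0.0 | PPI confidence cutoff (none by default) |
| `min_term_size` | 1 | smallest term tested in enrichment |

The r² boundary is taken inclusive (`>=`), the p-value boundary strict
(`<`); both are exposed in `PipelineConfig` rather than hard-coded, as is
the LD population, the eQTL tissue and the disease-synonym list used for
trial matching.

## Statistical choices

*Enrichment* is the exact hypergeometric upper tail (scipy's survival
function; no normal approximation), with the Benjamini–Hochberg step-up
(via statsmodels) applied **within each collection separately** — the six
criteria are independent points, so each collection carries its own multiple-
testing burden.  The PID criterion uses the raw p-value, as primary-
immunodeficiency lists are small curated sets rather than term systems.
The enrichment background defaults to the collection's own universe (union
of annotated genes) and can be overridden with an explicit universe file;
query genes outside the universe are excluded from the query size *n* and
can never earn that collection's flag (logged, not errored).

*Gene identity.* Scoring stages key on Ensembl-style gene IDs (two IDs may
share a symbol); the network and drug stages key on symbols, mirroring how
PPI and drug-target snapshots are keyed.  Seeds are therefore deduplicated
by symbol before expansion.

*Expansion ranking.* Snapshot edge lists define no canonical "top 50", so
the package ranks candidate interactors by (max edge confidence to any seed,
number of distinct seed neighbours, ascending symbol).  The full ordering
has no unresolved ties, making expansion deterministic.  A single shell is
expanded; there is no iterative growth.

*Edge normalization.* STRING-style integer scores (0–1000) are detected
when any score exceeds 1 and divided by 1000; the convention can be forced
via `score_convention`.  Unordered duplicate pairs keep the maximum score;
self-loops are dropped with a logged count.  Normalization is idempotent.

*Drug filters.* "Pharmacological activity, human efficacy, approved /
clinical / experimental" is represented by the pharmacological-action flag
plus membership in the harmonized status set — flattened snapshots carry no
separate machine-readable human-efficacy column, a documented limitation.
Compound vocabulary labels ("approved; investigational", "Phase 2", …)
harmonize to the strongest of {approved, clinical, experimental}; unknown
labels map to experimental with a warning.  Trial conditions match
case-insensitively against a configurable synonym list ("atopic dermatitis",
"atopic eczema" by default).

## The synthetic-data generator

The generator emulates the *structure* of the real inputs — LD blocks around
lead SNPs, a disease gene module with elevated criterion probabilities,
enrichment collections containing a signal term plus zero-overlap decoys, a
PPI graph with confident edges around the module, drug tables with planted
recoveries — and verifies, before returning, that re-applying the
definitional scoring rules to the emitted tables reproduces the planted
truth exactly.  Signal terms consist of exactly the flagged genes; the
background universe is automatically enlarged until every signal term is
decisively significant under its selection rule, so planted flags are never
lost to multiple-testing noise.

It deliberately does **not** emulate realistic allele frequencies, LD decay,
STRING score distributions, or ontology overlap between terms.  Passing
tests therefore demonstrate the correctness of the pipeline's logic —
filtering, counting, ranking, set algebra, statistics — not robustness to
the annotation noise and redundancy of real databases.

Two regimes:

* **Stochastic** (`generate`): samples loci, flags, edges and drugs from the
  configured probabilities; used for property and regression tests.  The
  module comprises the anchor genes of the first `disease_module_size`
  leads.  With `planted_expansion_drug`, one approved drug's sole target is
  a non-seed gene attached to several seeds at confidence 0.999 (all other
  edges are capped at 0.95), guaranteeing it enters the first shell — the
  recovery pattern of an approved biologic found only via expansion.
* **Constructed preset** (`mini_study`): a noise-free 94-gene universe laid
  out combinatorially so that the marginals are exact, not in expectation:
  70 leads; score histogram {0: 48, 1: 19, ≥2: 27} with the biological score
  multiset (6, 5, 4×4, 3×10, 2×11); per-criterion flag counts
  (11, 20, 19, 26, 19, 3) summing, like the scores, to 98; two biological
  gene IDs sharing one symbol (26 seed symbols, so 26 + 50 = 76 members);
  exactly 2053 member-member edges; 53 qualifying drugs over exactly 25
  member genes; and a planted approved drug targeting only an
  expansion-added gene.  The flag matrix is produced by a greedy
  largest-remaining-capacity fill over the six criterion columns and
  asserted exact at generation time.  A pair of genes sharing a symbol must
  agree on the four set-based criteria (those flags attach to symbols), so
  the duplicated pair differs by the missense flag only.

## Numerical and degenerate-input conventions

* `filter_associations` deduplicates by rsID keeping the smallest p-value;
  empty input yields empty output.
* Leads missing from the LD table are retained alone; a proxy reachable from
  two leads records both provenances.
* Risk SNPs missing from the annotation table default to noncoding,
  non-eQTL (logged); SNPs without a gene assignment contribute no gene.
* `select_biological` tolerates impossible thresholds (returns empty) and is
  idempotent; output order is (descending score, symbol, gene ID).
* All writers emit primary-key-sorted UTF-8 TSV; reading a written table
  reproduces the in-memory objects exactly.
* Exit codes of the CLI: 0 ok, 1 usage error, 2 data/validation error.

## Problem sizes

Tests and the acceptance script run on the constructed 94-gene preset and on
stochastic universes of ~300 genes, 40 leads, ~1000-gene enrichment
backgrounds, ~100-node PPI graphs and ~40 drugs — sizes at which every
stage's expected output is enumerable by hand or by the generator's
manifest, while each full pipeline run stays around a tenth of a second.
The planted-drug recovery check aggregates 20 independent stochastic
universes.

## Known limitations

* No ontology ancestry propagation: a gene annotated only to a child GO term
  is invisible to a parent-term set, unlike propagated real-world GMTs.
* The DrugBank/TTD "human efficacy" filter cannot be reconstructed from
  flattened snapshots; the pharm-action + status interpretation is the
  package's own and is configurable.
* Trial matching is exact (plus synonyms); free-text condition strings from
  real registries would need upstream normalization.
* LD r² values are consumed as given; multi-population tables must be
  pre-tagged, and population matching is an exact string comparison.
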
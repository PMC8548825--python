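"""Stage 2 — the six-criterion functional-annotation scoring system.

Each risk gene earns one point per fulfilled criterion:

(i)   any supporting risk SNP is missense/nonsense;
(ii)  any supporting risk SNP is a cis-eQTL in the configured tissue
      (whole blood by default);
(iii) membership in >= 1 knockout-mouse phenotype (MP) term enriched at
      FDR < 0.05 among the risk genes;
(iv)  membership in >= 1 enriched GO biological-process term (FDR < 0.05);
(v)   membership in >= 1 enriched KEGG pathway (FDR < 0.05);
(vi)  membership in a primary-immunodeficiency (PID) gene set significant at
      raw hypergeometric p < 0.05.

Enrichment is the exact hypergeometric upper tail with Benjamini-Hochberg
adjustment across each collection's tested terms (each collection is adjusted
separately, since the criteria are independent points).  Genes scoring >= 2
are selected as "biological" risk genes and seed the network expansion.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .types import (
    CRITERIA,
    Consequence,
    CriterionVector,
    EnrichmentResult,
    GeneRecord,
    GeneSetCollection,
    VariantAnnotation,
)

logger = logging.getLogger(__name__)


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N is the universe size, K the term size, n the query size and k the
    overlap.  k = 0 gives 1.0; K = N gives 1.0 for any feasible k.
    """
    if min(k, K, n, N) < 0:
        raise ValueError("all arguments must be non-negative")
    if k > min(K, n) or K > N or n > N:
        raise ValueError(f"infeasible arguments k={k} K={K} n={n} N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values, returned in input order.

    q(i) = min_{j >= i} (p(j) * m / j) over the ascending-sorted p-values,
    capped at 1.
    """
    if len(pvals) == 0:
        return []
    arr = np.asarray(pvals, dtype=float)
    if np.any((arr <= 0) | (arr > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(arr, method="fdr_bh")
    return [float(x) for x in q]


def enrich(
    query: Iterable[str],
    coll: GeneSetCollection,
    *,
    min_term_size: int = 1,
    fdr_threshold: float = 0.05,
    raw_p_selection: bool = False,
    p_threshold: float = 0.05,
) -> list[EnrichmentResult]:
    """Test every term of a collection for over-representation of the query.

    Query genes outside the collection's universe are excluded from the
    effective query size n (logged).  The ``enriched`` flag uses BH q <
    ``fdr_threshold``; with ``raw_p_selection`` (the PID rule) it uses raw
    p < ``p_threshold`` instead.  Terms smaller than ``min_term_size`` are
    not tested.
    """
    query_set = frozenset(query)
    universe = coll.universe
    assert universe is not None
    effective = query_set & universe
    dropped = len(query_set - universe)
    if dropped:
        logger.info(
            "%s: %d query gene(s) outside the universe excluded from n", coll.name, dropped
        )
    if not effective:
        raise ValueError(f"{coll.name}: no query genes in the collection universe")
    N = len(universe)
    n = len(effective)
    terms = [t for t in sorted(coll.sets) if len(coll.sets[t]) >= min_term_size]
    pvals = []
    overlaps = []
    for t in terms:
        members = coll.sets[t]
        k = len(effective & members)
        overlaps.append(k)
        pvals.append(hypergeom_upper(k, len(members), n, N))
    qvals = bh_adjust(pvals)
    results = []
    for t, k, p, q in zip(terms, overlaps, pvals, qvals):
        enriched = (p < p_threshold) if raw_p_selection else (q < fdr_threshold)
        results.append(
            EnrichmentResult(
                collection=coll.name,
                term_id=t,
                k=k,
                K=len(coll.sets[t]),
                n=n,
                N=N,
                p=p,
                q=q,
                enriched=enriched,
            )
        )
    return results


def enriched_genes(coll: GeneSetCollection, results: Iterable[EnrichmentResult]) -> frozenset[str]:
    """Union of members over the collection's enriched terms."""
    out: set[str] = set()
    for r in results:
        if r.enriched:
            out |= coll.sets[r.term_id]
    return frozenset(out)


def assign_flags(
    genes: Sequence[GeneRecord],
    variant_classes: Mapping[str, VariantAnnotation],
    flag_gene_sets: Mapping[str, frozenset[str]],
    *,
    eqtl_tissue: str = "whole_blood",
) -> list[CriterionVector]:
    """Build the per-gene six-criterion vector.

    ``flag_gene_sets`` maps the criterion names ``ko_mouse``/``go_bp``/
    ``kegg``/``pid`` to the symbol sets earning that flag (members of enriched
    terms); the missense and eqtl flags come from the gene's supporting SNPs.
    Output order follows the input gene order.
    """
    vectors = []
    for g in genes:
        anns = [variant_classes[s] for s in g.supporting_snps if s in variant_classes]
        missense = any(a.consequence is Consequence.MISSENSE_NONSENSE for a in anns)
        eqtl = any(a.eqtl and a.eqtl_tissue == eqtl_tissue for a in anns)
        vectors.append(
            CriterionVector(
                gene_id=g.gene_id,
                symbol=g.symbol,
                missense=missense,
                eqtl=eqtl,
                ko_mouse=g.symbol in flag_gene_sets.get("ko_mouse", frozenset()),
                go_bp=g.symbol in flag_gene_sets.get("go_bp", frozenset()),
                kegg=g.symbol in flag_gene_sets.get("kegg", frozenset()),
                pid=g.symbol in flag_gene_sets.get("pid", frozenset()),
            )
        )
    return vectors


def select_biological(
    vectors: Iterable[CriterionVector], score_min: int = 2
) -> list[CriterionVector]:
    """Genes with score >= score_min, sorted by descending score then symbol."""
    if not (0 <= score_min <= 7):
        raise ValueError("score_min must lie in [0, 7]")
    kept = [v for v in vectors if v.score >= score_min]
    return sorted(kept, key=lambda v: (-v.score, v.symbol, v.gene_id))


def score_histogram(vectors: Iterable[CriterionVector]) -> dict[int, int]:
    """Gene counts per score 0..6 (all seven bins present, possibly zero)."""
    hist = {s: 0 for s in range(7)}
    for v in vectors:
        hist[v.score] += 1
    return hist


def flag_counts(vectors: Iterable[CriterionVector]) -> dict[str, int]:
    """Per-criterion counts of genes carrying each flag."""
    counts = dict.fromkeys(CRITERIA, 0)
    for v in vectors:
        for c, f in zip(CRITERIA, v.flags):
            counts[c] += int(f)
    return counts
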
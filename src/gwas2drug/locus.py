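"""Stage 1 — from GWAS hits to risk genes.

Lead SNPs are the associations passing the genome-wide suggestive threshold
(p < 1e-5 by default, strict).  Each lead is expanded to its linkage-
disequilibrium proxies at r2 >= 0.8 in the configured population; leads plus
proxies form the risk-SNP set.  Risk SNPs are then classified by coding
consequence and cis-eQTL status and grouped by their assigned gene into the
risk-gene list that the scoring stage consumes.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Mapping

from .types import (
    Consequence,
    GeneRecord,
    LdProxy,
    RiskSnpSet,
    VariantAnnotation,
    VariantAssociation,
)

logger = logging.getLogger(__name__)


def filter_associations(
    assocs: Iterable[VariantAssociation], p_threshold: float = 1e-5
) -> list[VariantAssociation]:
    """Keep associations with p strictly below the threshold, deduplicated by
    rsid keeping the smallest p-value.  Output is sorted by (p_value, rsid)."""
    if not (0.0 < p_threshold < 1.0):
        raise ValueError("p_threshold must lie in (0, 1)")
    best: dict[str, VariantAssociation] = {}
    for a in assocs:
        if a.p_value < p_threshold:
            cur = best.get(a.rsid)
            if cur is None or a.p_value < cur.p_value:
                best[a.rsid] = a
    return sorted(best.values(), key=lambda a: (a.p_value, a.rsid))


def expand_ld(
    leads: Iterable[str],
    ld: Iterable[LdProxy],
    r2_min: float = 0.8,
    population: str = "ASN",
) -> RiskSnpSet:
    """Expand lead SNPs to LD proxies at r2 >= r2_min in the given population.

    Leads absent from the LD table are retained alone (with empty provenance).
    A proxy reachable from two leads records both (lead, r2) provenances.
    """
    if not (0.0 <= r2_min <= 1.0):
        raise ValueError("r2_min must lie in [0, 1]")
    lead_set = frozenset(leads)
    prov: dict[str, set[tuple[str, float]]] = defaultdict(set)
    for link in ld:
        if link.lead_rsid not in lead_set:
            continue
        if link.population != population:
            continue
        if link.r2 < r2_min:
            continue
        if link.proxy_rsid == link.lead_rsid:
            continue
        prov[link.proxy_rsid].add((link.lead_rsid, link.r2))
    all_snps = lead_set | set(prov)
    return RiskSnpSet(
        lead_snps=lead_set,
        all_snps=frozenset(all_snps),
        provenance={p: frozenset(v) for p, v in prov.items()},
    )


def classify_variants(
    snps: RiskSnpSet, ann: Iterable[VariantAnnotation]
) -> dict[str, VariantAnnotation]:
    """Assign every risk SNP a consequence class and eQTL status.

    SNPs missing from the annotation table default to noncoding / non-eQTL
    (logged); the returned map covers all of ``snps.all_snps``.
    """
    by_rsid = {a.rsid: a for a in ann}
    out: dict[str, VariantAnnotation] = {}
    missing = 0
    for rsid in sorted(snps.all_snps):
        if rsid in by_rsid:
            out[rsid] = by_rsid[rsid]
        else:
            missing += 1
            out[rsid] = VariantAnnotation(rsid=rsid, consequence=Consequence.NONCODING)
    if missing:
        logger.info("%d risk SNP(s) without annotation defaulted to noncoding", missing)
    return out


def map_to_genes(
    snps: RiskSnpSet, ann: Iterable[VariantAnnotation]
) -> list[GeneRecord]:
    """Group risk-SNP annotations by assigned gene into GeneRecords.

    SNPs without a gene assignment contribute no record.  One record per
    distinct gene_id, sorted by gene_id; supporting_snps collects every risk
    SNP assigned to that gene.
    """
    snp_set = snps.all_snps
    support: dict[str, set[str]] = defaultdict(set)
    symbol: dict[str, str] = {}
    for a in ann:
        if a.rsid not in snp_set or not a.gene_id:
            continue
        support[a.gene_id].add(a.rsid)
        if a.gene_symbol:
            symbol.setdefault(a.gene_id, a.gene_symbol)
    return [
        GeneRecord(
            gene_id=gid,
            symbol=symbol.get(gid, gid),
            supporting_snps=frozenset(support[gid]),
        )
        for gid in sorted(support)
    ]


def variant_class_tally(classes: Mapping[str, VariantAnnotation]) -> dict[str, int]:
    """Summary counts: missense/nonsense, synonymous, noncoding, and eQTL SNPs."""
    tally = {"missense_nonsense": 0, "synonymous": 0, "noncoding": 0, "eqtl": 0}
    for a in classes.values():
        tally[a.consequence.value] += 1
        if a.eqtl:
            tally["eqtl"] += 1
    return tally
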
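"""Internally consistent synthetic fixture universes with planted ground truth.

Every pipeline input — GWAS associations, LD proxies, variant annotations,
the four gene-set collections, a scored PPI edge table, drug-target and
clinical-trial snapshots — is generated together with a :class:`TruthManifest`
recording what the pipeline must recover: lead count, risk genes, per-gene
criterion flags and scores, the biological gene set, the expansion members and
the planted drug.

Two generators are provided:

* :func:`generate` — stochastic universes for property tests.  A disease gene
  module (the anchor genes of the first leads) receives criterion flags at
  elevated probabilities; enrichment signal terms, missense/eQTL variants and
  boosted PPI edges are then laid down so that the planted flags are exactly
  recoverable by the scoring rules.  With ``planted_expansion_drug`` the
  bundle contains an approved drug whose sole target is reachable only
  through network expansion — the pattern by which an already-approved
  biologic validates the pipeline.
* :func:`mini_study` — a constructed (noise-free) 94-gene preset whose score
  histogram is exactly {0: 48, 1: 19, >=2: 27}, whose per-criterion flag
  counts are exactly (11, 20, 19, 26, 19, 3), and whose downstream stages
  yield 76 network members, 2053 induced pairs and 25 druggable genes bound
  by 53 drugs.  Marginals are satisfied by explicit combinatorial layout, not
  in expectation.

Both generators verify the manifest against the emitted tables by re-applying
the definitional scoring rules before returning; an inconsistent bundle is a
bug, not a fixture.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import edges_to_frame, write_gmt, write_universe
from .scoring import hypergeom_upper
from .types import (
    CRITERIA,
    Consequence,
    DiseaseStatus,
    DrugStatus,
    DrugTargetRecord,
    GeneSetCollection,
    InteractionEdge,
    LdProxy,
    TrialPhase,
    TrialRecord,
    VariantAnnotation,
    VariantAssociation,
)

SET_CRITERIA = ("ko_mouse", "go_bp", "kegg", "pid")

#: Table-style score multiset of the biological (score >= 2) genes in the
#: mini-study preset: one 6, one 5, four 4s, ten 3s, eleven 2s.
_MINI_BIOLOGICAL_SCORES = (6, 5, 4, 4, 4, 4) + (3,) * 10 + (2,) * 11
_MINI_FLAG_TARGETS = {
    "missense": 11,
    "eqtl": 20,
    "ko_mouse": 19,
    "go_bp": 26,
    "kegg": 19,
    "pid": 3,
}


class GenerationError(RuntimeError):
    """The generated bundle failed its internal consistency verification."""


@dataclass
class PpiModel:
    """Edge-probability parameters of the synthetic PPI graph."""

    n_interactor_pool: int = 80
    pool_score_range: tuple[float, float] = (0.3, 0.95)
    seed_clique_prob: float = 0.5
    seed_clique_score_range: tuple[float, float] = (0.6, 0.95)
    background_edge_prob: float = 0.05
    background_score_range: tuple[float, float] = (0.15, 0.9)
    planted_edge_score: float = 0.999


def _default_flag_profile() -> dict[str, tuple[float, float]]:
    # per criterion: (module gene probability, background gene probability)
    return {
        "missense": (0.45, 0.05),
        "eqtl": (0.55, 0.08),
        "ko_mouse": (0.55, 0.05),
        "go_bp": (0.65, 0.10),
        "kegg": (0.45, 0.05),
        "pid": (0.20, 0.01),
    }


@dataclass
class GeneratorParams:
    """Knobs of the stochastic fixture generator.

    The disease module comprises the anchor genes of the first
    ``disease_module_size`` lead SNPs, so ``disease_module_size`` may not
    exceed ``n_leads``.
    """

    n_genes: int = 300
    n_leads: int = 40
    proxies_per_lead: float = 2.0
    frac_sub_threshold: float = 0.25
    disease_module_size: int = 15
    planted_flag_profile: dict[str, tuple[float, float]] = field(
        default_factory=_default_flag_profile
    )
    n_terms_per_collection: int = 6
    term_size_range: tuple[int, int] = (4, 20)
    ppi_model: PpiModel = field(default_factory=PpiModel)
    n_drugs: int = 40
    planted_expansion_drug: bool = True
    p_threshold: float = 1e-5
    r2_min: float = 0.8
    population: str = "ASN"
    eqtl_tissue: str = "whole_blood"
    fdr_threshold: float = 0.05
    pid_p_threshold: float = 0.05
    biological_score_min: int = 2
    max_interactors: int = 50
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.disease_module_size > self.n_leads:
            raise ValueError("disease_module_size may not exceed n_leads")
        if self.disease_module_size > self.n_genes or self.n_leads > self.n_genes:
            raise ValueError("universe too small for the requested leads/module")
        for crit, (pm, pb) in self.planted_flag_profile.items():
            if crit not in CRITERIA:
                raise ValueError(f"unknown criterion {crit!r}")
            if not (0 <= pm <= 1 and 0 <= pb <= 1):
                raise ValueError("flag probabilities must lie in [0, 1]")


@dataclass
class PlantedDrug:
    drug_id: str
    drug_name: str
    target_gene: str
    expected_direct: bool
    expected_status: DiseaseStatus


@dataclass
class TruthManifest:
    """Everything the pipeline is expected to recover from the fixture bundle."""

    expected_lead_count: int
    risk_gene_ids: frozenset[str]
    flag_vectors: dict[str, tuple[bool, bool, bool, bool, bool, bool]]
    scores: dict[str, int]
    biological_ids: frozenset[str]
    seed_symbols: frozenset[str]
    expected_members: frozenset[str]
    expected_induced_pairs: int
    expected_druggable_genes: frozenset[str]
    expected_drug_names: frozenset[str]
    planted_drug: PlantedDrug | None = None

    def to_json(self) -> str:
        d = {
            "expected_lead_count": self.expected_lead_count,
            "risk_gene_ids": sorted(self.risk_gene_ids),
            "flag_vectors": {g: list(v) for g, v in sorted(self.flag_vectors.items())},
            "scores": dict(sorted(self.scores.items())),
            "biological_ids": sorted(self.biological_ids),
            "seed_symbols": sorted(self.seed_symbols),
            "expected_members": sorted(self.expected_members),
            "expected_induced_pairs": self.expected_induced_pairs,
            "expected_druggable_genes": sorted(self.expected_druggable_genes),
            "expected_drug_names": sorted(self.expected_drug_names),
            "planted_drug": (
                None
                if self.planted_drug is None
                else {
                    "drug_id": self.planted_drug.drug_id,
                    "drug_name": self.planted_drug.drug_name,
                    "target_gene": self.planted_drug.target_gene,
                    "expected_direct": self.planted_drug.expected_direct,
                    "expected_status": self.planted_drug.expected_status.value,
                }
            ),
        }
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class FixtureBundle:
    """In-memory fixture universe; ``write`` emits it in the standard formats."""

    associations: list[VariantAssociation]
    ld: list[LdProxy]
    annotations: list[VariantAnnotation]
    collections: dict[str, GeneSetCollection]
    universe: frozenset[str]
    edges: list[InteractionEdge]
    drug_targets: list[DrugTargetRecord]
    trials: list[TrialRecord]
    manifest: TruthManifest

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        assoc = pd.DataFrame(
            [
                {
                    "rsid": a.rsid,
                    "chrom": a.chrom,
                    "pos": "" if a.pos is None else a.pos,
                    "p_value": repr(a.p_value),
                    "mapped_gene": a.mapped_gene,
                    "trait": a.trait,
                }
                for a in sorted(self.associations, key=lambda a: a.rsid)
            ],
            columns=["rsid", "chrom", "pos", "p_value", "mapped_gene", "trait"],
        )
        paths["associations"] = out / "associations.tsv"
        assoc.to_csv(paths["associations"], sep="\t", index=False)

        ld = pd.DataFrame(
            [
                {
                    "lead_rsid": l.lead_rsid,
                    "proxy_rsid": l.proxy_rsid,
                    "r2": repr(l.r2),
                    "population": l.population,
                }
                for l in sorted(self.ld, key=lambda l: (l.lead_rsid, l.proxy_rsid, l.population))
            ],
            columns=["lead_rsid", "proxy_rsid", "r2", "population"],
        )
        paths["ld"] = out / "ld.tsv"
        ld.to_csv(paths["ld"], sep="\t", index=False)

        ann = pd.DataFrame(
            [
                {
                    "rsid": a.rsid,
                    "consequence": a.consequence.value,
                    "gene_id": a.gene_id,
                    "gene_symbol": a.gene_symbol,
                    "eqtl": str(a.eqtl).lower(),
                    "eqtl_tissue": a.eqtl_tissue,
                }
                for a in sorted(self.annotations, key=lambda a: (a.rsid, a.gene_id))
            ],
            columns=["rsid", "consequence", "gene_id", "gene_symbol", "eqtl", "eqtl_tissue"],
        )
        paths["annotations"] = out / "annotations.tsv"
        ann.to_csv(paths["annotations"], sep="\t", index=False)

        for crit, coll in self.collections.items():
            paths[crit] = out / f"{crit}.gmt"
            write_gmt(coll, paths[crit])
        paths["universe"] = out / "universe.txt"
        write_universe(self.universe, paths["universe"])

        edges = edges_to_frame(sorted(self.edges, key=lambda e: e.pair))
        edges["combined_score"] = edges["combined_score"].map(repr)
        paths["edges"] = out / "edges.tsv"
        edges.to_csv(paths["edges"], sep="\t", index=False)

        drugs = pd.DataFrame(
            [
                {
                    "drug_id": d.drug_id,
                    "drug_name": d.drug_name,
                    "target_gene": d.target_gene,
                    "pharmacological_action": str(d.pharmacological_action).lower(),
                    "status": d.status.value,
                    "indication": d.indication,
                }
                for d in sorted(self.drug_targets, key=lambda d: (d.drug_id, d.target_gene))
            ],
            columns=[
                "drug_id",
                "drug_name",
                "target_gene",
                "pharmacological_action",
                "status",
                "indication",
            ],
        )
        paths["drug_targets"] = out / "drug_targets.tsv"
        drugs.to_csv(paths["drug_targets"], sep="\t", index=False)

        trials = pd.DataFrame(
            [
                {
                    "drug_name": t.drug_name,
                    "condition": t.condition,
                    "phase": t.phase.value,
                    "registry_id": t.registry_id,
                }
                for t in sorted(self.trials, key=lambda t: (t.drug_name, t.condition, t.phase.value))
            ],
            columns=["drug_name", "condition", "phase", "registry_id"],
        )
        paths["trials"] = out / "trials.tsv"
        trials.to_csv(paths["trials"], sep="\t", index=False)

        paths["manifest"] = out / "truth.json"
        paths["manifest"].write_text(self.manifest.to_json() + "\n", encoding="utf-8")
        return paths


# ---------------------------------------------------------------------------
# shared construction helpers


def _universe_size(n_query: int, signal_ks: Iterable[int], m_terms: int,
                   fdr: float, pid_p: float) -> int:
    """Background size making every planted signal term decisively significant.

    The signal term of a collection equals its flagged gene set (K = k), so
    its upper-tail p is C(n, k) / C(N, k); N doubles until p * m stays below
    half the FDR threshold for every planted k (and below half the raw-p
    threshold, the stricter of the two bounds for the PID rule).
    """
    N = max(1000, 10 * n_query)
    thr = min(fdr, pid_p)
    for k in signal_ks:
        if k == 0:
            continue
        while hypergeom_upper(k, k, n_query, N) * m_terms >= thr / 2:
            N *= 2
    return N


def _build_collections(
    flagged_symbols: dict[str, set[str]],
    risk_symbols: Sequence[str],
    n_terms: int,
    term_size_range: tuple[int, int],
    rng: np.random.Generator,
    fdr: float,
    pid_p: float,
) -> tuple[dict[str, GeneSetCollection], frozenset[str]]:
    """One collection per set-based criterion: a signal term holding exactly
    the flagged symbols plus zero-overlap decoy terms from background genes."""
    n_query = len(set(risk_symbols))
    N = _universe_size(
        n_query, [len(v) for v in flagged_symbols.values()], n_terms, fdr, pid_p
    )
    n_background = N - n_query
    background = [f"BG{i:06d}" for i in range(n_background)]
    universe = frozenset(risk_symbols) | frozenset(background)
    collections: dict[str, GeneSetCollection] = {}
    lo, hi = term_size_range
    for crit in SET_CRITERIA:
        sets: dict[str, frozenset[str]] = {}
        flagged = flagged_symbols.get(crit, set())
        if flagged:
            sets[f"{crit.upper()}_SIGNAL"] = frozenset(flagged)
        n_decoys = n_terms - len(sets)
        for j in range(n_decoys):
            size = int(rng.integers(lo, hi + 1))
            members = rng.choice(len(background), size=min(size, len(background)),
                                 replace=False)
            sets[f"{crit.upper()}_DECOY{j:02d}"] = frozenset(
                background[int(i)] for i in members
            )
        collections[crit] = GeneSetCollection(name=crit, sets=sets, universe=universe)
    return collections, universe


def _rank_interactors(
    seeds: frozenset[str],
    triples: Sequence[tuple[str, str, float]],
    max_interactors: int,
) -> frozenset[str]:
    """Definitional first-shell ranking: (max seed-edge score, seed-degree,
    ascending symbol), top ``max_interactors``."""
    best: dict[str, float] = {}
    nbrs: dict[str, set[str]] = {}
    for a, b, s in triples:
        for cand, seed in ((a, b), (b, a)):
            if seed in seeds and cand not in seeds:
                if s > best.get(cand, -1.0):
                    best[cand] = s
                nbrs.setdefault(cand, set()).add(seed)
    ranked = sorted(best, key=lambda g: (-best[g], -len(nbrs[g]), g))
    return seeds | frozenset(ranked[:max_interactors])


def _count_induced(members: frozenset[str], triples: Sequence[tuple[str, str, float]]) -> int:
    pairs = {
        tuple(sorted((a, b))) for a, b, _ in triples if a in members and b in members
    }
    return len(pairs)


def _verify_flags(
    manifest: TruthManifest,
    annotations: Sequence[VariantAnnotation],
    collections: dict[str, GeneSetCollection],
    all_snps: frozenset[str],
    symbols: dict[str, str],
    *,
    eqtl_tissue: str,
    fdr: float,
    pid_p: float,
) -> None:
    """Re-derive each gene's flags from the emitted tables (definitional rules)
    and compare with the manifest; raise GenerationError on any mismatch."""
    by_gene: dict[str, list[VariantAnnotation]] = {}
    for a in annotations:
        if a.rsid in all_snps and a.gene_id:
            by_gene.setdefault(a.gene_id, []).append(a)
    if frozenset(by_gene) != manifest.risk_gene_ids:
        raise GenerationError("risk-gene set mismatch between tables and manifest")
    # significance of each planted signal term under the scoring rules
    enriched_members: dict[str, frozenset[str]] = {}
    n_query = len({symbols[g] for g in manifest.risk_gene_ids})
    for crit, coll in collections.items():
        assert coll.universe is not None
        N = len(coll.universe)
        m = len(coll.sets)
        members: set[str] = set()
        for term, genes in coll.sets.items():
            k = len(genes & {symbols[g] for g in manifest.risk_gene_ids})
            p = hypergeom_upper(k, len(genes), n_query, N)
            significant = p < pid_p if crit == "pid" else p * m < fdr
            if significant:
                members |= genes
        enriched_members[crit] = frozenset(members)
    for gid in manifest.risk_gene_ids:
        anns = by_gene[gid]
        derived = (
            any(a.consequence is Consequence.MISSENSE_NONSENSE for a in anns),
            any(a.eqtl and a.eqtl_tissue == eqtl_tissue for a in anns),
            symbols[gid] in enriched_members["ko_mouse"],
            symbols[gid] in enriched_members["go_bp"],
            symbols[gid] in enriched_members["kegg"],
            symbols[gid] in enriched_members["pid"],
        )
        if derived != manifest.flag_vectors[gid]:
            raise GenerationError(
                f"{gid}: derived flags {derived} != planted {manifest.flag_vectors[gid]}"
            )
        if sum(derived) != manifest.scores[gid]:
            raise GenerationError(f"{gid}: score mismatch")


# ---------------------------------------------------------------------------
# stochastic generator


def generate(params: GeneratorParams | None = None) -> FixtureBundle:
    """Sample a stochastic fixture universe with planted, exactly recoverable
    ground truth.  Identical ``rng_seed`` gives an identical bundle."""
    params = params or GeneratorParams()
    rng = np.random.default_rng(params.rng_seed)
    ppi = params.ppi_model

    # --- loci: leads, sub-threshold associations, LD proxies ---------------
    leads = [f"rs{100000 + i}" for i in range(params.n_leads)]
    associations = [
        VariantAssociation(
            rsid=rsid,
            p_value=float(10.0 ** rng.uniform(-12, -5.2)),
            chrom=str(1 + i % 22),
            trait="synthetic trait",
        )
        for i, rsid in enumerate(leads)
    ]
    n_sub = int(round(params.n_leads * params.frac_sub_threshold
                      / max(1e-9, 1.0 - params.frac_sub_threshold)))
    for j in range(n_sub):
        associations.append(
            VariantAssociation(
                rsid=f"rs{900000 + j}",
                p_value=float(10.0 ** rng.uniform(-4.8, -2)),
                chrom=str(1 + j % 22),
                trait="synthetic trait",
            )
        )

    gene_ids = [f"ENSG{i:011d}" for i in range(params.n_genes)]
    gene_symbols = [f"G{i:04d}" for i in range(params.n_genes)]
    symbols = dict(zip(gene_ids, gene_symbols))

    ld: list[LdProxy] = []
    annotations: list[VariantAnnotation] = []
    risk_gene_locus: dict[str, int] = {}  # gene_id -> lead index
    next_gene = params.n_leads  # indices beyond the anchors
    proxy_serial = 0

    def new_proxy(lead_idx: int, r2: float, population: str) -> str:
        nonlocal proxy_serial
        rsid = f"rs{500000 + proxy_serial}"
        proxy_serial += 1
        ld.append(LdProxy(leads[lead_idx], rsid, round(float(r2), 4), population))
        return rsid

    for i in range(params.n_leads):
        gid = gene_ids[i]
        risk_gene_locus[gid] = i
        annotations.append(
            VariantAnnotation(
                rsid=leads[i],
                consequence=Consequence.NONCODING,
                gene_id=gid,
                gene_symbol=symbols[gid],
            )
        )
        for _ in range(int(rng.poisson(params.proxies_per_lead))):
            r2 = float(rng.uniform(0.5, 1.0))
            pop = params.population if rng.random() < 0.85 else "EUR"
            rsid = new_proxy(i, r2, pop)
            qualifies = r2 >= params.r2_min and pop == params.population
            u = rng.random()
            if qualifies and u < 0.35 and next_gene < params.n_genes:
                gid_new = gene_ids[next_gene]
                risk_gene_locus[gid_new] = i
                next_gene += 1
                annotations.append(
                    VariantAnnotation(
                        rsid=rsid,
                        consequence=Consequence.NONCODING,
                        gene_id=gid_new,
                        gene_symbol=symbols[gid_new],
                    )
                )
            elif u < 0.7:
                # proxy annotated to the locus gene (or, if it does not
                # qualify, to a decoy assignment that must never surface)
                target = gid if qualifies else gene_ids[params.n_genes - 1 - i]
                annotations.append(
                    VariantAnnotation(
                        rsid=rsid,
                        consequence=Consequence.SYNONYMOUS if u < 0.45 else Consequence.NONCODING,
                        gene_id=target,
                        gene_symbol=symbols[target],
                    )
                )

    risk_ids = sorted(risk_gene_locus)
    module_ids = set(gene_ids[: params.disease_module_size])

    # --- planted criterion flags ------------------------------------------
    flag_vectors: dict[str, tuple[bool, ...]] = {}
    for gid in risk_ids:
        row = []
        for crit in CRITERIA:
            pm, pb = params.planted_flag_profile[crit]
            row.append(bool(rng.random() < (pm if gid in module_ids else pb)))
        flag_vectors[gid] = tuple(row)

    # realize missense / eQTL flags as extra annotated proxies of the locus lead
    for gid in risk_ids:
        flags = dict(zip(CRITERIA, flag_vectors[gid]))
        locus = risk_gene_locus[gid]
        if flags["missense"]:
            rsid = new_proxy(locus, rng.uniform(params.r2_min, 1.0), params.population)
            annotations.append(
                VariantAnnotation(
                    rsid=rsid,
                    consequence=Consequence.MISSENSE_NONSENSE,
                    gene_id=gid,
                    gene_symbol=symbols[gid],
                )
            )
        if flags["eqtl"]:
            rsid = new_proxy(locus, rng.uniform(params.r2_min, 1.0), params.population)
            annotations.append(
                VariantAnnotation(
                    rsid=rsid,
                    consequence=Consequence.NONCODING,
                    gene_id=gid,
                    gene_symbol=symbols[gid],
                    eqtl=True,
                    eqtl_tissue=params.eqtl_tissue,
                )
            )
        elif rng.random() < 0.1:
            # wrong-tissue eQTL noise: must not earn the flag
            rsid = new_proxy(locus, rng.uniform(params.r2_min, 1.0), params.population)
            annotations.append(
                VariantAnnotation(
                    rsid=rsid,
                    consequence=Consequence.NONCODING,
                    gene_id=gid,
                    gene_symbol=symbols[gid],
                    eqtl=True,
                    eqtl_tissue="skin",
                )
            )

    # --- gene-set collections ---------------------------------------------
    flagged_symbols = {
        crit: {symbols[g] for g in risk_ids if flag_vectors[g][CRITERIA.index(crit)]}
        for crit in SET_CRITERIA
    }
    risk_symbols = [symbols[g] for g in risk_ids]
    collections, universe = _build_collections(
        flagged_symbols,
        risk_symbols,
        params.n_terms_per_collection,
        params.term_size_range,
        rng,
        params.fdr_threshold,
        params.pid_p_threshold,
    )

    # --- PPI graph ---------------------------------------------------------
    scores = {g: sum(flag_vectors[g]) for g in risk_ids}
    biological_ids = frozenset(
        g for g in risk_ids if scores[g] >= params.biological_score_min
    )
    seeds = frozenset(symbols[g] for g in biological_ids)
    triples: list[tuple[str, str, float]] = []
    seen_pairs: set[tuple[str, str]] = set()

    def add_edge(a: str, b: str, s: float) -> None:
        if a == b:
            return
        pair = tuple(sorted((a, b)))
        if pair in seen_pairs:
            return
        seen_pairs.add(pair)
        triples.append((pair[0], pair[1], round(float(s), 4)))

    seed_list = sorted(seeds)
    pool = [f"INT{i:04d}" for i in range(ppi.n_interactor_pool)]
    if seed_list:
        lo, hi = ppi.seed_clique_score_range
        for i in range(len(seed_list)):
            for j in range(i + 1, len(seed_list)):
                if rng.random() < ppi.seed_clique_prob:
                    add_edge(seed_list[i], seed_list[j], rng.uniform(lo, hi))
        lo, hi = ppi.pool_score_range
        for g in pool:
            for idx in rng.choice(
                len(seed_list), size=min(len(seed_list), int(rng.integers(1, 4))),
                replace=False,
            ):
                add_edge(g, seed_list[int(idx)], rng.uniform(lo, hi))
    lo, hi = ppi.background_score_range
    for i in range(len(pool)):
        for j in range(i + 1, len(pool)):
            if rng.random() < ppi.background_edge_prob:
                add_edge(pool[i], pool[j], rng.uniform(lo, hi))

    planted: PlantedDrug | None = None
    planted_target = "EXPTGT01"
    if params.planted_expansion_drug and seed_list and params.max_interactors >= 1:
        for s in seed_list[: min(3, len(seed_list))]:
            add_edge(planted_target, s, ppi.planted_edge_score)
        planted = PlantedDrug(
            drug_id="DRPLANT",
            drug_name="Plantumab",
            target_gene=planted_target,
            expected_direct=False,
            expected_status=DiseaseStatus.APPROVED_FOR_DISEASE,
        )

    expected_members = _rank_interactors(seeds, triples, params.max_interactors)
    edges = [InteractionEdge(a, b, s) for a, b, s in triples]

    # --- drugs and trials --------------------------------------------------
    disease = "synthetic dermatitis"
    drug_targets: list[DrugTargetRecord] = []
    trials: list[TrialRecord] = []
    if planted is not None:
        drug_targets.append(
            DrugTargetRecord(
                drug_id=planted.drug_id,
                drug_name=planted.drug_name,
                target_gene=planted.target_gene,
                pharmacological_action=True,
                status=DrugStatus.APPROVED,
                indication="synthetic asthma",
            )
        )
        trials.append(
            TrialRecord(planted.drug_name, disease, TrialPhase.APPROVED, "NCT-PLANT"))
    statuses = list(DrugStatus)
    target_pool = sorted(set(expected_members) | set(pool[:10]))
    indications = ["synthetic asthma", "synthetic arthritis", "synthetic psoriasis"]
    for j in range(params.n_drugs):
        name = f"Drug{j:03d}"
        n_targets = int(rng.integers(1, 3))
        chosen = rng.choice(len(target_pool), size=min(n_targets, len(target_pool)),
                            replace=False)
        for idx in chosen:
            tgt = target_pool[int(idx)]
            if planted is not None and tgt == planted.target_gene:
                continue  # keep the planted gene the exclusive target of Plantumab
            drug_targets.append(
                DrugTargetRecord(
                    drug_id=f"DB{j:05d}",
                    drug_name=name,
                    target_gene=tgt,
                    pharmacological_action=bool(rng.random() < 0.8),
                    status=statuses[int(rng.integers(0, 3))],
                    indication=indications[int(rng.integers(0, len(indications)))],
                )
            )
        if rng.random() < 0.2:
            phase = [TrialPhase.PHASE2, TrialPhase.PHASE3, TrialPhase.CASE_REPORT,
                     TrialPhase.PRECLINICAL][int(rng.integers(0, 4))]
            condition = disease if rng.random() < 0.5 else "synthetic arthritis"
            trials.append(TrialRecord(name, condition, phase, f"NCT{j:08d}"))

    qualifying = [
        d for d in drug_targets
        if d.pharmacological_action and d.target_gene in expected_members
    ]
    expected_druggable = frozenset(d.target_gene for d in qualifying)
    expected_drug_names = frozenset(d.drug_name for d in qualifying)

    manifest = TruthManifest(
        expected_lead_count=params.n_leads,
        risk_gene_ids=frozenset(risk_ids),
        flag_vectors=flag_vectors,
        scores=scores,
        biological_ids=biological_ids,
        seed_symbols=seeds,
        expected_members=expected_members,
        expected_induced_pairs=_count_induced(expected_members, triples),
        expected_druggable_genes=expected_druggable,
        expected_drug_names=expected_drug_names,
        planted_drug=planted,
    )

    all_snps = frozenset(leads) | frozenset(
        l.proxy_rsid
        for l in ld
        if l.r2 >= params.r2_min and l.population == params.population
    )
    _verify_flags(
        manifest, annotations, collections, all_snps, symbols,
        eqtl_tissue=params.eqtl_tissue,
        fdr=params.fdr_threshold,
        pid_p=params.pid_p_threshold,
    )

    return FixtureBundle(
        associations=associations,
        ld=ld,
        annotations=annotations,
        collections=collections,
        universe=universe,
        edges=edges,
        drug_targets=drug_targets,
        trials=trials,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# constructed mini-study preset


def _greedy_flag_matrix(
    scores: Sequence[int], capacities: dict[str, int]
) -> list[tuple[bool, ...]]:
    """Rows with the given sums, columns with the given totals, by the greedy
    fill-largest-remaining-capacity construction; raises if it cannot close."""
    if sum(scores) != sum(capacities.values()):
        raise GenerationError("row and column totals disagree")
    remaining = dict(capacities)
    rows: list[tuple[bool, ...]] = []
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    out: dict[int, tuple[bool, ...]] = {}
    for i in order:
        s = scores[i]
        cols = sorted(CRITERIA, key=lambda c: (-remaining[c], CRITERIA.index(c)))[:s]
        if any(remaining[c] <= 0 for c in cols):
            raise GenerationError("greedy layout ran out of column capacity")
        for c in cols:
            remaining[c] -= 1
        out[i] = tuple(c in cols for c in CRITERIA)
    if any(v != 0 for v in remaining.values()):
        raise GenerationError(f"greedy layout left capacity: {remaining}")
    for i in range(len(scores)):
        rows.append(out[i])
    return rows


def mini_study(seed: int = 0) -> FixtureBundle:
    """The constructed 94-gene preset reproducing the study's printed marginals.

    Exact by construction: 70 lead SNPs; 94 risk genes; score histogram
    {0: 48, 1: 19, >=2: 27}; flag counts (11, 20, 19, 26, 19, 3); two of the
    27 biological gene IDs share one symbol (26 seed symbols); expansion at 50
    interactors gives 76 members and 2053 induced pairs; 53 filtered drugs bind
    25 member genes; one approved drug is reachable only through expansion.
    ``seed`` only relabels nothing — the preset is deterministic — but is kept
    so callers can treat both generators uniformly.
    """
    rng = np.random.default_rng(seed)
    n_genes, n_leads = 94, 70

    scores = list(_MINI_BIOLOGICAL_SCORES) + [1] * 19 + [0] * 48
    assert len(scores) == n_genes

    # duplicate-symbol pair: a score-3 and a score-2 gene sharing one symbol
    # must agree on the set-based flags, so they differ by missense only.
    dup_hi, dup_lo = 15, 26  # last score-3 row, last score-2 row
    forced = {
        dup_hi: ("missense", "eqtl", "go_bp"),
        dup_lo: ("eqtl", "go_bp"),
    }
    capacities = dict(_MINI_FLAG_TARGETS)
    for cols in forced.values():
        for c in cols:
            capacities[c] -= 1
    free_idx = [i for i in range(n_genes) if i not in forced]
    free_rows = _greedy_flag_matrix([scores[i] for i in free_idx], capacities)
    matrix: dict[int, tuple[bool, ...]] = {
        i: tuple(c in forced[i] for c in CRITERIA) for i in forced
    }
    matrix.update(dict(zip(free_idx, free_rows)))
    for i, s in enumerate(scores):
        assert sum(matrix[i]) == s

    gene_ids = [f"ENSG9{i:010d}" for i in range(n_genes)]
    gene_symbols = [f"ADG{i:03d}" for i in range(n_genes)]
    gene_symbols[dup_lo] = gene_symbols[dup_hi]  # the shared-symbol quirk
    symbols = dict(zip(gene_ids, gene_symbols))

    # --- loci --------------------------------------------------------------
    leads = [f"rsL{i:03d}" for i in range(n_leads)]
    associations = [
        VariantAssociation(
            rsid=rsid,
            p_value=float(10.0 ** -(6.0 + (i % 30) * 0.3)),
            chrom=str(1 + i % 22),
            trait="mini study trait",
        )
        for i, rsid in enumerate(leads)
    ]
    for j in range(10):
        associations.append(
            VariantAssociation(
                rsid=f"rsS{j:03d}", p_value=1e-4, chrom=str(1 + j), trait="mini study trait"
            )
        )

    ld: list[LdProxy] = []
    annotations: list[VariantAnnotation] = []
    for i, gid in enumerate(gene_ids):
        locus = i if i < n_leads else i - n_leads
        flags = dict(zip(CRITERIA, matrix[i]))
        if i < n_leads:
            anchor = leads[i]
        else:
            anchor = f"rsX{i:03d}"
            ld.append(LdProxy(leads[locus], anchor, 0.9, "ASN"))
        anchor_cons = (
            Consequence.SYNONYMOUS if (scores[i] == 0 and i % 10 == 0) else Consequence.NONCODING
        )
        annotations.append(
            VariantAnnotation(anchor, anchor_cons, gene_id=gid, gene_symbol=symbols[gid])
        )
        if flags["missense"]:
            rsid = f"rsM{i:03d}"
            ld.append(LdProxy(leads[locus], rsid, 0.85, "ASN"))
            annotations.append(
                VariantAnnotation(
                    rsid, Consequence.MISSENSE_NONSENSE, gene_id=gid, gene_symbol=symbols[gid]
                )
            )
        if flags["eqtl"]:
            rsid = f"rsE{i:03d}"
            ld.append(LdProxy(leads[locus], rsid, 0.82, "ASN"))
            annotations.append(
                VariantAnnotation(
                    rsid,
                    Consequence.NONCODING,
                    gene_id=gid,
                    gene_symbol=symbols[gid],
                    eqtl=True,
                    eqtl_tissue="whole_blood",
                )
            )
    # below-threshold LD decoys: r2 too small or wrong population
    for i in range(0, n_leads, 7):
        ld.append(LdProxy(leads[i], f"rsD{i:03d}", 0.5, "ASN"))
        ld.append(LdProxy(leads[i], f"rsF{i:03d}", 0.95, "EUR"))

    # --- collections -------------------------------------------------------
    flagged_symbols = {
        crit: {symbols[gene_ids[i]] for i in range(n_genes) if matrix[i][CRITERIA.index(crit)]}
        for crit in SET_CRITERIA
    }
    collections, universe = _build_collections(
        flagged_symbols,
        gene_symbols,
        n_terms=6,
        term_size_range=(4, 20),
        rng=rng,
        fdr=0.05,
        pid_p=0.05,
    )

    # --- PPI: 26 seeds + exactly 50 interactors, 2053 induced pairs --------
    biological_ids = frozenset(gene_ids[i] for i in range(27))
    seeds = frozenset(symbols[g] for g in biological_ids)
    assert len(seeds) == 26
    seed_list = sorted(seeds)
    added = [f"PPI{i:03d}" for i in range(50)]
    candidate_pairs: list[tuple[str, str, float]] = []
    for g in added:  # every interactor touches every seed: 1300 edges
        for s in seed_list:
            candidate_pairs.append((s, g, 0.9))
    for i in range(len(seed_list)):  # seed-seed: 325 edges
        for j in range(i + 1, len(seed_list)):
            candidate_pairs.append((seed_list[i], seed_list[j], 0.6))
    extra = []
    for i in range(len(added)):  # interactor-interactor filler pool: 1225
        for j in range(i + 1, len(added)):
            extra.append((added[i], added[j], 0.5))
    target_pairs = 2053
    triples = candidate_pairs + extra[: target_pairs - len(candidate_pairs)]
    assert len(triples) == target_pairs
    # decoy component, disconnected from the seeds: never counted
    for i in range(6):
        a, b = sorted((f"DEC{i:02d}", f"DEC{(i + 1) % 6:02d}"))
        triples.append((a, b, 0.4))
    edges = [InteractionEdge(a, b, s) for a, b, s in triples]

    expected_members = _rank_interactors(seeds, triples, max_interactors=50)
    assert expected_members == seeds | frozenset(added)
    assert _count_induced(expected_members, triples) == target_pairs

    # --- drugs: 53 qualifying drugs over exactly 25 member genes -----------
    druggable = [added[0]] + seed_list[:12] + added[1:13]  # 25 genes, mixed roles
    assert len(set(druggable)) == 25
    planted = PlantedDrug(
        drug_id="DRPLANT",
        drug_name="Plantumab",
        target_gene=added[0],
        expected_direct=False,
        expected_status=DiseaseStatus.APPROVED_FOR_DISEASE,
    )
    drug_targets = [
        DrugTargetRecord(
            drug_id="DRPLANT",
            drug_name="Plantumab",
            target_gene=added[0],
            pharmacological_action=True,
            status=DrugStatus.APPROVED,
            indication="mini asthma",
        )
    ]
    statuses = [DrugStatus.APPROVED, DrugStatus.CLINICAL, DrugStatus.EXPERIMENTAL]
    for j in range(1, 53):
        tgt = druggable[1 + (j - 1) % 24]  # cycle over the other 24 genes
        drug_targets.append(
            DrugTargetRecord(
                drug_id=f"DB{j:05d}",
                drug_name=f"Minidrug{j:03d}",
                target_gene=tgt,
                pharmacological_action=True,
                status=statuses[j % 3],
                indication=["mini asthma", "mini arthritis", "mini psoriasis"][j % 3],
            )
        )
    # decoys: no pharmacological action, or target outside the network
    drug_targets.append(
        DrugTargetRecord(
            drug_id="DBNOPHA",
            drug_name="Nopharmib",
            target_gene=seed_list[0],
            pharmacological_action=False,
            status=DrugStatus.APPROVED,
            indication="mini arthritis",
        )
    )
    drug_targets.append(
        DrugTargetRecord(
            drug_id="DBOUT",
            drug_name="Outsidib",
            target_gene="DEC00",
            pharmacological_action=True,
            status=DrugStatus.APPROVED,
            indication="mini arthritis",
        )
    )
    disease = "mini dermatitis"
    trials = [
        TrialRecord("Plantumab", disease, TrialPhase.APPROVED, "NCT-PLANT"),
        TrialRecord("Minidrug001", disease, TrialPhase.PHASE3, "NCT00000001"),
        TrialRecord("Minidrug002", disease, TrialPhase.CASE_REPORT, "NCT00000002"),
        TrialRecord("Minidrug003", "mini arthritis", TrialPhase.PHASE3, "NCT00000003"),
    ]
    qualifying = [
        d for d in drug_targets
        if d.pharmacological_action and d.target_gene in expected_members
    ]
    expected_druggable = frozenset(d.target_gene for d in qualifying)
    expected_drug_names = frozenset(d.drug_name for d in qualifying)
    assert len(expected_druggable) == 25 and len(expected_drug_names) == 53

    flag_vectors = {gene_ids[i]: matrix[i] for i in range(n_genes)}
    manifest = TruthManifest(
        expected_lead_count=n_leads,
        risk_gene_ids=frozenset(gene_ids),
        flag_vectors=flag_vectors,
        scores={gene_ids[i]: scores[i] for i in range(n_genes)},
        biological_ids=biological_ids,
        seed_symbols=seeds,
        expected_members=expected_members,
        expected_induced_pairs=target_pairs,
        expected_druggable_genes=expected_druggable,
        expected_drug_names=expected_drug_names,
        planted_drug=planted,
    )

    all_snps = frozenset(leads) | frozenset(
        l.proxy_rsid for l in ld if l.r2 >= 0.8 and l.population == "ASN"
    )
    _verify_flags(
        manifest, annotations, collections, all_snps, symbols,
        eqtl_tissue="whole_blood", fdr=0.05, pid_p=0.05,
    )

    return FixtureBundle(
        associations=associations,
        ld=ld,
        annotations=annotations,
        collections=collections,
        universe=universe,
        edges=edges,
        drug_targets=drug_targets,
        trials=trials,
        manifest=manifest,
    )
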
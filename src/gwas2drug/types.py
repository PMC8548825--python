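"""Domain types shared by every pipeline stage.

The pipeline moves from GWAS association records through linkage-disequilibrium
(LD) proxy expansion, variant classification, six-criterion functional-annotation
scoring, protein-protein interaction (PPI) network expansion and finally
drug-target overlap.  Each stage consumes and produces the small record types
defined here; all of them are plain frozen dataclasses so that tables round-trip
deterministically through the TSV readers/writers in :mod:`gwas2drug.io`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping


class Consequence(str, Enum):
    """Coding consequence class of a risk variant."""

    MISSENSE_NONSENSE = "missense_nonsense"
    SYNONYMOUS = "synonymous"
    NONCODING = "noncoding"


class DrugStatus(str, Enum):
    """Development status of a drug in the harmonized 3-value vocabulary."""

    APPROVED = "approved"
    CLINICAL = "clinical"
    EXPERIMENTAL = "experimental"


class TrialPhase(str, Enum):
    """Clinical-evidence level of a trial/registry record."""

    PRECLINICAL = "preclinical"
    CASE_REPORT = "case_report"
    PHASE1 = "phase1"
    PHASE2 = "phase2"
    PHASE3 = "phase3"
    PHASE4 = "phase4"
    APPROVED = "approved"


class DiseaseStatus(str, Enum):
    """Clinical standing of a repurposing candidate for the disease of interest.

    Ordered from strongest to weakest evidence; ``rank()`` gives the sort key.
    """

    APPROVED_FOR_DISEASE = "approved_for_disease"
    IN_TRIAL_FOR_DISEASE = "in_trial_for_disease"
    CASE_REPORT = "case_report"
    PRECLINICAL = "preclinical"
    NO_EVIDENCE = "no_evidence"

    def rank(self) -> int:
        order = [
            DiseaseStatus.APPROVED_FOR_DISEASE,
            DiseaseStatus.IN_TRIAL_FOR_DISEASE,
            DiseaseStatus.CASE_REPORT,
            DiseaseStatus.PRECLINICAL,
            DiseaseStatus.NO_EVIDENCE,
        ]
        return order.index(self)


@dataclass(frozen=True)
class VariantAssociation:
    """One GWAS hit: a SNP associated with the trait at some p-value."""

    rsid: str
    p_value: float
    chrom: str = ""
    pos: int | None = None
    mapped_gene: str = ""
    trait: str = ""

    def __post_init__(self) -> None:
        if not self.rsid:
            raise ValueError("rsid must be non-empty")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value!r} outside (0, 1]")


@dataclass(frozen=True)
class LdProxy:
    """An LD link between a lead SNP and a proxy SNP with squared correlation r2."""

    lead_rsid: str
    proxy_rsid: str
    r2: float
    population: str = "ASN"

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0):
            raise ValueError(f"r2 {self.r2!r} outside [0, 1]")
        if self.lead_rsid == self.proxy_rsid and self.r2 != 1.0:
            raise ValueError("a lead self-pair must have r2 = 1")


@dataclass(frozen=True)
class VariantAnnotation:
    """Functional annotation of one SNP: consequence class, gene assignment, eQTL."""

    rsid: str
    consequence: Consequence
    gene_id: str = ""
    gene_symbol: str = ""
    eqtl: bool = False
    eqtl_tissue: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.consequence, Consequence):
            object.__setattr__(self, "consequence", Consequence(self.consequence))
        if self.eqtl and not self.eqtl_tissue:
            raise ValueError(f"{self.rsid}: eqtl_tissue required when eqtl is true")
        if not self.eqtl and self.eqtl_tissue:
            raise ValueError(f"{self.rsid}: eqtl_tissue set but eqtl is false")


@dataclass
class GeneRecord:
    """A risk gene together with the risk SNPs that support it."""

    gene_id: str
    symbol: str
    supporting_snps: frozenset[str] = frozenset()


@dataclass
class GeneSetCollection:
    """A named gene-set collection (GMT) plus its background universe.

    ``universe`` defaults to the union of all set members; an explicit,
    larger background may be supplied (e.g. all annotated human genes).
    """

    name: str
    sets: dict[str, frozenset[str]]
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.universe is None:
            members: set[str] = set()
            for genes in self.sets.values():
                members |= genes
            self.universe = frozenset(members)
        else:
            self.universe = frozenset(self.universe)
        for term, genes in self.sets.items():
            if not genes:
                raise ValueError(f"term {term!r} is empty")
            stray = genes - self.universe
            if stray:
                raise ValueError(
                    f"term {term!r} has members outside the universe: {sorted(stray)[:5]}"
                )


@dataclass(frozen=True, order=True)
class InteractionEdge:
    """A scored undirected PPI edge; identity is the unordered gene pair."""

    gene_a: str
    gene_b: str
    combined_score: float

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-loop on {self.gene_a!r}")
        if not (0.0 <= self.combined_score <= 1.0):
            raise ValueError(f"combined_score {self.combined_score!r} outside [0, 1]")

    @property
    def pair(self) -> tuple[str, str]:
        a, b = sorted((self.gene_a, self.gene_b))
        return (a, b)


@dataclass(frozen=True)
class DrugTargetRecord:
    """One drug → target-gene link from a DrugBank/TTD-style snapshot."""

    drug_id: str
    drug_name: str
    target_gene: str
    pharmacological_action: bool
    status: DrugStatus
    indication: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.status, DrugStatus):
            object.__setattr__(self, "status", DrugStatus(self.status))


@dataclass(frozen=True)
class TrialRecord:
    """A clinical-evidence record for a drug in some condition."""

    drug_name: str
    condition: str
    phase: TrialPhase
    registry_id: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.phase, TrialPhase):
            object.__setattr__(self, "phase", TrialPhase(self.phase))


@dataclass
class RiskSnpSet:
    """Lead SNPs plus their LD proxies, with per-proxy provenance.

    ``provenance`` maps each proxy to the set of ``(lead, r2)`` pairs through
    which it entered; a proxy reachable from two leads records both.
    """

    lead_snps: frozenset[str]
    all_snps: frozenset[str]
    provenance: dict[str, frozenset[tuple[str, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.lead_snps <= self.all_snps:
            raise ValueError("lead_snps must be a subset of all_snps")


@dataclass(frozen=True)
class EnrichmentResult:
    """One gene-set term tested for over-representation of the query genes.

    k of the n query genes fall in a term of size K drawn from a universe of
    N genes; p is the hypergeometric upper tail P(X >= k) and q the
    Benjamini-Hochberg adjusted value across the collection's tested terms.
    """

    collection: str
    term_id: str
    k: int
    K: int
    n: int
    N: int
    p: float
    q: float
    enriched: bool


CRITERIA = ("missense", "eqtl", "ko_mouse", "go_bp", "kegg", "pid")


@dataclass(frozen=True)
class CriterionVector:
    """Per-gene six-criterion annotation flags and their sum (score 0-6)."""

    gene_id: str
    symbol: str
    missense: bool = False
    eqtl: bool = False
    ko_mouse: bool = False
    go_bp: bool = False
    kegg: bool = False
    pid: bool = False

    @property
    def flags(self) -> tuple[bool, ...]:
        return tuple(getattr(self, c) for c in CRITERIA)

    @property
    def score(self) -> int:
        return sum(self.flags)


@dataclass
class ExpandedNetwork:
    """Seed genes plus interactors added in one PPI expansion shell."""

    seed_genes: frozenset[str]
    added_genes: frozenset[str]
    induced_edges: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        if self.seed_genes & self.added_genes:
            raise ValueError("seed and added gene sets must be disjoint")

    @property
    def members(self) -> frozenset[str]:
        return self.seed_genes | self.added_genes


@dataclass
class RepurposingCandidate:
    """A drug hitting >= 1 gene of the expanded network, with clinical standing."""

    drug_id: str
    drug_name: str
    target_genes: frozenset[str]
    direct: bool
    original_indication: str = ""
    disease_status: DiseaseStatus = DiseaseStatus.NO_EVIDENCE

    def __post_init__(self) -> None:
        if not self.target_genes:
            raise ValueError(f"{self.drug_name}: target_genes must be non-empty")


@dataclass
class PipelineConfig:
    """Every numeric constant and vocabulary choice of the pipeline.

    Defaults are the study conditions: GWAS significance p < 1e-5, LD proxy
    inclusion at r2 >= 0.8 in the ASN population, whole-blood cis-eQTLs,
    enrichment FDR < 0.05 (raw p < 0.05 for the PID list), biological-gene
    selection at score >= 2, and a 50-interactor expansion shell.
    """

    p_threshold: float = 1e-5
    r2_min: float = 0.8
    population: str = "ASN"
    eqtl_tissue: str = "whole_blood"
    fdr_threshold: float = 0.05
    pid_p_threshold: float = 0.05
    biological_score_min: int = 2
    max_interactors: int = 50
    edge_score_min: float = 0.0
    min_term_size: int = 1
    require_pharm_action: bool = True
    allowed_status: frozenset[DrugStatus] = frozenset(
        (DrugStatus.APPROVED, DrugStatus.CLINICAL, DrugStatus.EXPERIMENTAL)
    )
    disease: str = "atopic dermatitis"
    disease_synonyms: tuple[str, ...] = ("atopic dermatitis", "atopic eczema")
    score_convention: str = "auto"  # "auto" | "unit" | "string1000"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold < 1.0):
            raise ValueError("p_threshold must lie in (0, 1)")
        for name in ("r2_min", "fdr_threshold", "pid_p_threshold", "edge_score_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.max_interactors < 0:
            raise ValueError("max_interactors must be >= 0")
        if not (0 <= self.biological_score_min <= 7):
            raise ValueError("biological_score_min must lie in [0, 7]")
        if self.score_convention not in ("auto", "unit", "string1000"):
            raise ValueError(f"unknown score_convention {self.score_convention!r}")
        self.allowed_status = frozenset(DrugStatus(s) for s in self.allowed_status)

    @classmethod
    def from_mapping(cls, data: Mapping[str, object]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        if "disease_synonyms" in kwargs:
            kwargs["disease_synonyms"] = tuple(kwargs["disease_synonyms"])  # type: ignore[arg-type]
        if "allowed_status" in kwargs:
            kwargs["allowed_status"] = frozenset(
                DrugStatus(s) for s in kwargs["allowed_status"]  # type: ignore[union-attr]
            )
        return cls(**kwargs)  # type: ignore[arg-type]
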
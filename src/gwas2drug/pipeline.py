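"""End-to-end orchestration: expand → score → network → drugs.

:func:`run_all` executes the four stages in order on snapshot tables, writes
every intermediate result table, and returns a :class:`RunManifest` with the
per-stage record counts and input checksums.  Each stage failure aborts the
run with the stage name attached; stages share no hidden state, so the run
equals the composition of the individual stage functions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__, io, locus, network, scoring
from . import drugs as drugs_mod
from .types import CRITERIA, CriterionVector, PipelineConfig

logger = logging.getLogger(__name__)

STAGES = ("expand", "score", "network", "drugs")


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelinePaths:
    """Input table locations.  ``mp``/``go_bp``/``kegg``/``pid`` are GMT files;
    ``universe`` optionally supplies an explicit enrichment background shared
    by all four collections."""

    associations: Path
    ld: Path
    annotations: Path
    mp: Path
    go_bp: Path
    kegg: Path
    pid: Path
    edges: Path
    drug_targets: Path
    trials: Path
    universe: Path | None = None

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v is not None:
                setattr(self, f.name, Path(v))

    @classmethod
    def from_dir(cls, d: str | Path) -> "PipelinePaths":
        """Conventional layout as written by the fixture generators."""
        d = Path(d)
        return cls(
            associations=d / "associations.tsv",
            ld=d / "ld.tsv",
            annotations=d / "annotations.tsv",
            mp=d / "ko_mouse.gmt",
            go_bp=d / "go_bp.gmt",
            kegg=d / "kegg.gmt",
            pid=d / "pid.gmt",
            edges=d / "edges.tsv",
            drug_targets=d / "drug_targets.tsv",
            trials=d / "trials.tsv",
            universe=(d / "universe.txt") if (d / "universe.txt").exists() else None,
        )


@dataclass
class RunManifest:
    """Machine-readable account of one pipeline run."""

    config: dict
    inputs: dict[str, str]  # path -> sha256
    counts: dict[str, int] = field(default_factory=dict)
    version: str = __version__
    timestamp: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _vectors_frame(vectors: list[CriterionVector]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": v.gene_id,
                "symbol": v.symbol,
                **{c: getattr(v, c) for c in CRITERIA},
                "score": v.score,
            }
            for v in vectors
        ],
        columns=["gene_id", "symbol", *CRITERIA, "score"],
    )


def run_all(
    paths: PipelinePaths,
    config: PipelineConfig | None = None,
    out_dir: str | Path = "results",
) -> RunManifest:
    """Run all four stages; write result tables and the run manifest."""
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    inputs = {}
    for f in dataclasses.fields(paths):
        p = getattr(paths, f.name)
        if p is None:
            continue
        if not p.exists():
            raise StageError(
                "expand" if f.name in ("associations", "ld", "annotations")
                else "score" if f.name in ("mp", "go_bp", "kegg", "pid", "universe")
                else "network" if f.name == "edges"
                else "drugs",
                FileNotFoundError(p),
            )
        inputs[str(p)] = _sha256(p)

    counts: dict[str, int] = {}

    # ---- stage 1: locus expansion ----------------------------------------
    try:
        logger.info("[expand] reading %s", paths.associations)
        assocs = io.read_associations(paths.associations)
        ld = io.read_ld_table(paths.ld)
        ann = io.read_variant_annotations(paths.annotations)
        leads = locus.filter_associations(assocs, config.p_threshold)
        snps = locus.expand_ld(
            (a.rsid for a in leads), ld, config.r2_min, config.population
        )
        classes = locus.classify_variants(snps, ann)
        genes = locus.map_to_genes(snps, ann)
        counts["leads"] = len(leads)
        counts["risk_snps"] = len(snps.all_snps)
        counts["risk_genes"] = len(genes)
        io.write_tsv(
            pd.DataFrame(
                [
                    {
                        "rsid": r,
                        "is_lead": r in snps.lead_snps,
                        "consequence": classes[r].consequence.value,
                        "eqtl": classes[r].eqtl,
                    }
                    for r in sorted(snps.all_snps)
                ],
                columns=["rsid", "is_lead", "consequence", "eqtl"],
            ),
            out / "risk_snps.tsv",
        )
        io.write_tsv(
            pd.DataFrame(
                [
                    {
                        "gene_id": g.gene_id,
                        "symbol": g.symbol,
                        "supporting_snps": ";".join(sorted(g.supporting_snps)),
                    }
                    for g in genes
                ],
                columns=["gene_id", "symbol", "supporting_snps"],
            ),
            out / "risk_genes.tsv",
        )
    except StageError:
        raise
    except Exception as exc:
        raise StageError("expand", exc) from exc

    # ---- stage 2: annotation scoring -------------------------------------
    try:
        query = {g.symbol for g in genes}
        flag_gene_sets = {}
        enrich_rows = []
        gmt_paths = {"ko_mouse": paths.mp, "go_bp": paths.go_bp,
                     "kegg": paths.kegg, "pid": paths.pid}
        for crit, gmt_path in gmt_paths.items():
            logger.info("[score] enrichment on %s", gmt_path)
            coll = io.read_gmt(gmt_path, universe_path=paths.universe)
            results = scoring.enrich(
                query,
                coll,
                min_term_size=config.min_term_size,
                fdr_threshold=config.fdr_threshold,
                raw_p_selection=(crit == "pid"),
                p_threshold=config.pid_p_threshold,
            )
            flag_gene_sets[crit] = scoring.enriched_genes(coll, results)
            enrich_rows += [
                {
                    "collection": crit,
                    "term_id": r.term_id,
                    "k": r.k,
                    "K": r.K,
                    "n": r.n,
                    "N": r.N,
                    "p": r.p,
                    "q": r.q,
                    "enriched": r.enriched,
                }
                for r in results
            ]
        vectors = scoring.assign_flags(
            genes, classes, flag_gene_sets, eqtl_tissue=config.eqtl_tissue
        )
        biological = scoring.select_biological(vectors, config.biological_score_min)
        counts["biological_genes"] = len(biological)
        io.write_tsv(
            pd.DataFrame(enrich_rows,
                         columns=["collection", "term_id", "k", "K", "n", "N", "p", "q", "enriched"]),
            out / "enrichment.tsv",
            sort_by=["collection", "term_id"],
        )
        io.write_tsv(_vectors_frame(sorted(vectors, key=lambda v: (-v.score, v.symbol, v.gene_id))),
                     out / "scores.tsv")
        io.write_tsv(_vectors_frame(biological), out / "biological_genes.tsv")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("score", exc) from exc

    # ---- stage 3: network expansion --------------------------------------
    try:
        logger.info("[network] reading %s", paths.edges)
        edges = io.read_edges(paths.edges, score_convention=config.score_convention)
        seeds = sorted({v.symbol for v in biological})
        net = network.expand_network(
            seeds, edges, config.max_interactors, config.edge_score_min
        )
        counts["network_members"] = len(net.members)
        counts["induced_pairs"] = network.induced_pairs(net, edges, config.edge_score_min)
        io.write_tsv(
            pd.DataFrame(
                [
                    {
                        "symbol": g,
                        "role": "biological_gene" if g in net.seed_genes else "ppi_gene",
                    }
                    for g in sorted(net.members)
                ],
                columns=["symbol", "role"],
            ),
            out / "network_members.tsv",
        )
        io.write_tsv(
            pd.DataFrame(sorted(net.induced_edges), columns=["gene_a", "gene_b"]),
            out / "pairs.tsv",
        )
    except StageError:
        raise
    except Exception as exc:
        raise StageError("network", exc) from exc

    # ---- stage 4: drug overlap -------------------------------------------
    try:
        logger.info("[drugs] reading %s", paths.drug_targets)
        drug_records = io.read_drug_targets(paths.drug_targets)
        trial_records = io.read_trials(paths.trials)
        cands = drugs_mod.overlap_drugs(
            net.members,
            drug_records,
            seeds=net.seed_genes,
            require_pharm_action=config.require_pharm_action,
            allowed_status=config.allowed_status,
        )
        cands = drugs_mod.classify_status(
            cands, trial_records, config.disease, config.disease_synonyms
        )
        counts["druggable_genes"] = len(drugs_mod.druggable_genes(cands))
        counts["drugs"] = len(cands)
        summary = drugs_mod.summarize(cands)
        io.write_tsv(summary, out / "candidates.tsv")
        (out / "candidates.json").write_text(
            summary.to_json(orient="records", indent=2) + "\n", encoding="utf-8"
        )
        network.export_network(net, out / "network.graphml",
                               drug_links=[r for r in drug_records
                                           if r.target_gene in net.members])
        network.export_network(net, out / "network.dot", fmt="dot")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("drugs", exc) from exc

    cfg = dataclasses.asdict(config)
    cfg["allowed_status"] = sorted(s.value for s in config.allowed_status)
    cfg["disease_synonyms"] = list(config.disease_synonyms)
    manifest = RunManifest(
        config=cfg,
        inputs=inputs,
        counts=counts,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    (out / "run_manifest.json").write_text(manifest.to_json() + "\n", encoding="utf-8")
    return manifest
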
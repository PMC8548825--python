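"""Readers and writers for the pipeline's snapshot-table formats.

All inputs are tab-delimited text with a header row (plus GMT for gene sets).
Every reader is total: a file either parses completely or raises a located
:class:`FormatError` / :class:`ValidationError` naming the offending column,
row or line — there is no partially-loaded state.  Writers emit UTF-8 TSV in
deterministic (primary-key-sorted) row order so that identical inputs produce
byte-identical outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .types import (
    Consequence,
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

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """The file does not conform to the expected table format."""


class ValidationError(ValueError):
    """A well-formed row carries a value violating a domain invariant."""


_TRUE = {"true", "1", "yes", "t", "y"}
_FALSE = {"false", "0", "no", "f", "n", ""}

#: DrugBank/TTD status vocabulary → harmonized 3-value enum. Compound labels
#: such as "approved; investigational" resolve to their strongest component.
STATUS_HARMONIZATION = {
    "approved": DrugStatus.APPROVED,
    "approved; investigational": DrugStatus.APPROVED,
    "approved; withdrawn": DrugStatus.APPROVED,
    "marketed": DrugStatus.APPROVED,
    "clinical": DrugStatus.CLINICAL,
    "clinical trial": DrugStatus.CLINICAL,
    "investigational": DrugStatus.CLINICAL,
    "phase 1": DrugStatus.CLINICAL,
    "phase 2": DrugStatus.CLINICAL,
    "phase 3": DrugStatus.CLINICAL,
    "phase 4": DrugStatus.CLINICAL,
    "experimental": DrugStatus.EXPERIMENTAL,
    "preclinical": DrugStatus.EXPERIMENTAL,
    "investigative": DrugStatus.EXPERIMENTAL,
}


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise FormatError(f"{path}: {exc}") from exc
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df


def _parse_float(value: str, *, path: Path | str, row: int, col: str) -> float:
    try:
        return float(value)
    except ValueError as exc:
        raise ValidationError(
            f"{path}: row {row}: column {col!r}: not a number: {value!r}"
        ) from exc


def _parse_bool(value: str, *, path: Path | str, row: int, col: str) -> bool:
    v = value.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise ValidationError(f"{path}: row {row}: column {col!r}: not a boolean: {value!r}")


def read_associations(path: str | Path) -> list[VariantAssociation]:
    """Read a GWAS-catalog-style association table (rsid, p_value, ...)."""
    df = _read_table(path, required=("rsid", "p_value"))
    records: list[VariantAssociation] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        p = _parse_float(d["p_value"], path=path, row=i, col="p_value")
        if not (0.0 < p <= 1.0):
            raise ValidationError(f"{path}: row {i}: p_value {p} outside (0, 1]")
        rsid = d["rsid"].strip()
        if not rsid:
            raise ValidationError(f"{path}: row {i}: empty rsid")
        trait = d.get("trait", "")
        key = (rsid, trait)
        if key in seen:
            raise ValidationError(f"{path}: row {i}: duplicate (rsid, trait) {key}")
        seen.add(key)
        pos_raw = d.get("pos", "")
        records.append(
            VariantAssociation(
                rsid=rsid,
                p_value=p,
                chrom=d.get("chrom", ""),
                pos=int(pos_raw) if pos_raw else None,
                mapped_gene=d.get("mapped_gene", ""),
                trait=trait,
            )
        )
    return records


def read_ld_table(path: str | Path) -> list[LdProxy]:
    """Read an LD proxy table (lead_rsid, proxy_rsid, r2, population)."""
    df = _read_table(path, required=("lead_rsid", "proxy_rsid", "r2"))
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        r2 = _parse_float(d["r2"], path=path, row=i, col="r2")
        if not (0.0 <= r2 <= 1.0):
            raise ValidationError(f"{path}: row {i}: r2 {r2} outside [0, 1]")
        try:
            records.append(
                LdProxy(
                    lead_rsid=d["lead_rsid"],
                    proxy_rsid=d["proxy_rsid"],
                    r2=r2,
                    population=d.get("population", ""),
                )
            )
        except ValueError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return records


def read_variant_annotations(path: str | Path) -> list[VariantAnnotation]:
    """Read a variant annotation table (rsid, consequence, gene, eQTL flag)."""
    df = _read_table(path, required=("rsid", "consequence"))
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            consequence = Consequence(d["consequence"])
        except ValueError as exc:
            raise ValidationError(
                f"{path}: row {i}: unknown consequence {d['consequence']!r}"
            ) from exc
        eqtl = _parse_bool(d.get("eqtl", ""), path=path, row=i, col="eqtl")
        try:
            records.append(
                VariantAnnotation(
                    rsid=d["rsid"],
                    consequence=consequence,
                    gene_id=d.get("gene_id", ""),
                    gene_symbol=d.get("gene_symbol", ""),
                    eqtl=eqtl,
                    eqtl_tissue=d.get("eqtl_tissue", ""),
                )
            )
        except ValueError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return records


def read_edges(path: str | Path, *, score_convention: str = "auto") -> list[InteractionEdge]:
    """Read a STRING-style scored edge list, normalizing to the unit interval.

    Scores on the 0-1000 integer convention are detected (any score > 1) and
    divided by 1000; ``score_convention`` may force ``"unit"`` or
    ``"string1000"``.  Duplicate unordered pairs collapse keeping the maximum
    score; self-loops are dropped with a logged count.  Normalization is
    idempotent: re-reading a written unit-scale file changes nothing.
    """
    df = _read_table(path, required=("gene_a", "gene_b", "combined_score"))
    raw: list[tuple[str, str, float]] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        score = _parse_float(d["combined_score"], path=path, row=i, col="combined_score")
        if score < 0:
            raise ValidationError(f"{path}: row {i}: negative score {score}")
        raw.append((d["gene_a"], d["gene_b"], score))
    if score_convention == "string1000":
        divide = True
    elif score_convention == "unit":
        divide = False
    else:
        divide = any(s > 1.0 for _, _, s in raw)
    best: dict[tuple[str, str], float] = {}
    self_loops = 0
    for a, b, s in raw:
        if divide:
            s /= 1000.0
        if s > 1.0:
            raise ValidationError(f"{path}: score {s} above 1 after normalization")
        if a == b:
            self_loops += 1
            continue
        pair = (a, b) if a <= b else (b, a)
        if s > best.get(pair, -1.0):
            best[pair] = s
    if self_loops:
        logger.info("%s: dropped %d self-loop edge(s)", path, self_loops)
    return [InteractionEdge(a, b, s) for (a, b), s in sorted(best.items())]


def read_drug_targets(path: str | Path) -> list[DrugTargetRecord]:
    """Read a flattened DrugBank/TTD-style drug-target table.

    Status labels are harmonized to {approved, clinical, experimental};
    unknown labels map to experimental with a warning.
    """
    df = _read_table(path, required=("drug_id", "drug_name", "target_gene", "status"))
    records = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        label = d["status"].strip().lower()
        status = STATUS_HARMONIZATION.get(label)
        if status is None:
            logger.warning(
                "%s: row %d: unknown status %r mapped to experimental", path, i, d["status"]
            )
            status = DrugStatus.EXPERIMENTAL
        key = (d["drug_id"], d["target_gene"])
        if key in seen:
            raise ValidationError(f"{path}: row {i}: duplicate (drug_id, target_gene) {key}")
        seen.add(key)
        records.append(
            DrugTargetRecord(
                drug_id=d["drug_id"],
                drug_name=d["drug_name"],
                target_gene=d["target_gene"],
                pharmacological_action=_parse_bool(
                    d.get("pharmacological_action", ""), path=path, row=i,
                    col="pharmacological_action",
                ),
                status=status,
                indication=d.get("indication", ""),
            )
        )
    return records


def read_trials(path: str | Path) -> list[TrialRecord]:
    """Read a clinical-trial status table (drug_name, condition, phase)."""
    df = _read_table(path, required=("drug_name", "condition", "phase"))
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            phase = TrialPhase(d["phase"])
        except ValueError as exc:
            raise ValidationError(f"{path}: row {i}: unknown phase {d['phase']!r}") from exc
        records.append(
            TrialRecord(
                drug_name=d["drug_name"],
                condition=d["condition"],
                phase=phase,
                registry_id=d.get("registry_id", ""),
            )
        )
    return records


def read_gmt(path: str | Path, universe_path: str | Path | None = None) -> GeneSetCollection:
    """Read a GMT gene-set file: ``term_id TAB description TAB member...``.

    The background universe defaults to the union of all members; pass
    ``universe_path`` (one gene symbol per line) for an explicit background.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sets: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}: line {lineno}: fewer than 3 fields")
        term_id = fields[0]
        if term_id in sets:
            raise FormatError(f"{path}: line {lineno}: duplicate term_id {term_id!r}")
        members = frozenset(g for g in fields[2:] if g)
        if not members:
            raise FormatError(f"{path}: line {lineno}: term {term_id!r} has no members")
        sets[term_id] = members
    universe = None
    if universe_path is not None:
        universe = frozenset(
            g.strip()
            for g in Path(universe_path).read_text(encoding="utf-8").splitlines()
            if g.strip()
        )
    return GeneSetCollection(name=path.stem, sets=sets, universe=universe)


def write_gmt(coll: GeneSetCollection, path: str | Path, descriptions: dict[str, str] | None = None) -> None:
    """Write a collection back to GMT (terms sorted, members sorted)."""
    descriptions = descriptions or {}
    lines = []
    for term_id in sorted(coll.sets):
        desc = descriptions.get(term_id, "na")
        lines.append("\t".join([term_id, desc, *sorted(coll.sets[term_id])]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_universe(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(set(genes))) + "\n", encoding="utf-8")


def write_tsv(df: pd.DataFrame, path: str | Path, sort_by: str | Sequence[str] | None = None) -> None:
    """Write a result table as UTF-8 TSV in deterministic row order."""
    if sort_by is not None:
        df = df.sort_values(list(sort_by) if not isinstance(sort_by, str) else sort_by,
                            kind="mergesort")
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def edges_to_frame(edges: Iterable[InteractionEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"gene_a": e.gene_a, "gene_b": e.gene_b, "combined_score": e.combined_score}
            for e in edges
        ],
        columns=["gene_a", "gene_b", "combined_score"],
    )
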
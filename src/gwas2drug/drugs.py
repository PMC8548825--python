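"""Stage 4 — drug-target overlap and clinical-status prioritization.

The expanded network's members are intersected with a flattened DrugBank/TTD
snapshot.  A drug qualifies when at least one of its targets is a network
member and the record passes the pharmacological-action and status filters
("pharmacological activity, human efficacy, approved / clinical / experimental"
is represented by the pharm-action flag plus status membership — flattened
snapshots carry no separate human-efficacy column).  Each candidate is then
classified by its best clinical-evidence record for the disease of interest,
which is how an already-approved biologic whose sole target is reached only
via expansion is still recovered.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Sequence

import pandas as pd

from .types import (
    DiseaseStatus,
    DrugStatus,
    DrugTargetRecord,
    RepurposingCandidate,
    TrialPhase,
    TrialRecord,
)

_PHASE_TO_STATUS = {
    TrialPhase.APPROVED: DiseaseStatus.APPROVED_FOR_DISEASE,
    TrialPhase.PHASE4: DiseaseStatus.IN_TRIAL_FOR_DISEASE,
    TrialPhase.PHASE3: DiseaseStatus.IN_TRIAL_FOR_DISEASE,
    TrialPhase.PHASE2: DiseaseStatus.IN_TRIAL_FOR_DISEASE,
    TrialPhase.PHASE1: DiseaseStatus.IN_TRIAL_FOR_DISEASE,
    TrialPhase.CASE_REPORT: DiseaseStatus.CASE_REPORT,
    TrialPhase.PRECLINICAL: DiseaseStatus.PRECLINICAL,
}


def overlap_drugs(
    members: Iterable[str],
    drugs: Iterable[DrugTargetRecord],
    *,
    seeds: Iterable[str] = (),
    require_pharm_action: bool = True,
    allowed_status: frozenset[DrugStatus] = frozenset(DrugStatus),
) -> list[RepurposingCandidate]:
    """One candidate per drug with >= 1 filtered target among the members.

    ``direct`` is true when the drug hits at least one biological seed gene;
    false when all its in-network targets were reached via expansion.
    Candidates are sorted by drug name.
    """
    member_set = frozenset(members)
    seed_set = frozenset(seeds)
    hits: dict[str, list[DrugTargetRecord]] = defaultdict(list)
    for rec in drugs:
        if require_pharm_action and not rec.pharmacological_action:
            continue
        if rec.status not in allowed_status:
            continue
        if rec.target_gene in member_set:
            hits[rec.drug_id].append(rec)
    cands = []
    for drug_id in sorted(hits):
        recs = hits[drug_id]
        targets = frozenset(r.target_gene for r in recs)
        indications = sorted({r.indication for r in recs if r.indication})
        cands.append(
            RepurposingCandidate(
                drug_id=drug_id,
                drug_name=recs[0].drug_name,
                target_genes=targets,
                direct=bool(targets & seed_set),
                original_indication="; ".join(indications),
            )
        )
    return sorted(cands, key=lambda c: (c.drug_name.lower(), c.drug_id))


def druggable_genes(cands: Iterable[RepurposingCandidate]) -> frozenset[str]:
    """Union of in-network target genes over all candidates."""
    out: set[str] = set()
    for c in cands:
        out |= c.target_genes
    return frozenset(out)


def classify_status(
    cands: Sequence[RepurposingCandidate],
    trials: Iterable[TrialRecord],
    disease: str,
    synonyms: Sequence[str] = (),
) -> list[RepurposingCandidate]:
    """Set each candidate's disease_status from its best matching trial record.

    Drug-name matching is case-insensitive exact; condition matching is
    case-insensitive exact against the disease name or any synonym.  The best
    record wins: approved > in-trial > case report > preclinical > no evidence.
    """
    accepted = {disease.strip().lower()} | {s.strip().lower() for s in synonyms}
    best: dict[str, DiseaseStatus] = {}
    for t in trials:
        if t.condition.strip().lower() not in accepted:
            continue
        status = _PHASE_TO_STATUS[t.phase]
        key = t.drug_name.strip().lower()
        if key not in best or status.rank() < best[key].rank():
            best[key] = status
    out = []
    for c in cands:
        status = best.get(c.drug_name.strip().lower(), DiseaseStatus.NO_EVIDENCE)
        out.append(
            RepurposingCandidate(
                drug_id=c.drug_id,
                drug_name=c.drug_name,
                target_genes=c.target_genes,
                direct=c.direct,
                original_indication=c.original_indication,
                disease_status=status,
            )
        )
    return out


def summarize(cands: Iterable[RepurposingCandidate]) -> pd.DataFrame:
    """Report table: one row per candidate, strongest disease evidence first,
    then alphabetical by drug name."""
    rows = [
        {
            "drug_id": c.drug_id,
            "drug_name": c.drug_name,
            "target_genes": ";".join(sorted(c.target_genes)),
            "direct": c.direct,
            "original_indication": c.original_indication,
            "disease_status": c.disease_status.value,
        }
        for c in sorted(
            cands, key=lambda c: (c.disease_status.rank(), c.drug_name.lower(), c.drug_id)
        )
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "drug_id",
            "drug_name",
            "target_genes",
            "direct",
            "original_indication",
            "disease_status",
        ],
    )
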
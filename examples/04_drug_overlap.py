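"""Drug-target overlap and clinical prioritization.

Intersects a small expanded network with a drug-target snapshot and ranks the
candidates by their clinical standing for the disease of interest.  The third
drug shows the expansion-recovery pattern: its only target entered the network
as a PPI interactor, not as a biological seed gene.
"""

from gwas2drug import classify_status, overlap_drugs, summarize
from gwas2drug.types import DrugStatus, DrugTargetRecord, TrialPhase, TrialRecord

members = {"IL4", "IL13", "IL4R", "JAK1"}   # seeds IL4/IL13 + 2 added genes
seeds = {"IL4", "IL13"}

drug_table = [
    DrugTargetRecord("D1", "jakinib-a", "JAK1", True, DrugStatus.APPROVED, "myelofibrosis"),
    DrugTargetRecord("D2", "no-action-ib", "IL4", False, DrugStatus.APPROVED, "asthma"),
    DrugTargetRecord("D3", "dupimab-like", "IL4R", True, DrugStatus.APPROVED, "asthma"),
]
trials = [
    TrialRecord("dupimab-like", "atopic dermatitis", TrialPhase.APPROVED, "NCT0001"),
    TrialRecord("jakinib-a", "atopic dermatitis", TrialPhase.PHASE3, "NCT0002"),
]

cands = overlap_drugs(members, drug_table, seeds=seeds)
cands = classify_status(cands, trials, "atopic dermatitis", synonyms=("atopic eczema",))
print(summarize(cands).to_string(index=False))
# no-action-ib fails the pharmacological-action filter. dupimab-like is
# recovered through the expansion-added IL4R (direct=False) and, being
# approved for the disease, sorts above the phase-3 jakinib-a.
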
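"""PPI network expansion under the first-shell interactor limit.

Expands two seed genes through a small scored edge list, keeping the top
interactors ranked by (best seed-edge score, seed-degree, symbol), and counts
the interaction pairs induced among the members.
"""

from gwas2drug import expand_network, induced_pairs
from gwas2drug.types import InteractionEdge

edges = [
    InteractionEdge("IL4", "IL4R", 0.99),
    InteractionEdge("IL13", "IL4R", 0.97),
    InteractionEdge("IL4", "STAT6", 0.80),
    InteractionEdge("IL4", "JAK1", 0.90),
    InteractionEdge("IL13", "JAK1", 0.85),
    InteractionEdge("IL4R", "JAK1", 0.92),
    InteractionEdge("STAT6", "JAK1", 0.60),
]

seeds = {"IL4", "IL13"}
net = expand_network(seeds, edges, max_interactors=2)
print(f"seeds: {sorted(net.seed_genes)}")
print(f"added interactors: {sorted(net.added_genes)}")
print(f"members: {sorted(net.members)}")
print(f"induced interaction pairs: {induced_pairs(net, edges)}")
# IL4R (best seed edge 0.99, touching both seeds) and JAK1 are added; STAT6
# misses the 2-interactor cap. Five of the seven edges connect members to
# members, so five induced pairs are counted.
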
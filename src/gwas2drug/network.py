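"""Stage 3 — PPI network expansion under the 50-interactor criterion.

The biological risk genes (deduplicated by symbol) seed a single expansion
shell: every non-seed gene sharing at least one sufficiently confident edge
with a seed is a candidate, candidates are ranked by (max edge score to any
seed, number of distinct seed neighbours, ascending symbol) and the top
``max_interactors`` are added.  The ranking is the package's own, chosen to
be fully deterministic; STRING-style snapshots give no canonical order.
"""

from __future__ import annotations

from collections import defaultdict
from pathlib import Path
from typing import Iterable

import networkx as nx

from .types import DrugTargetRecord, ExpandedNetwork, InteractionEdge


def expand_network(
    seeds: Iterable[str],
    edges: Iterable[InteractionEdge],
    max_interactors: int = 50,
    edge_score_min: float = 0.0,
) -> ExpandedNetwork:
    """Add up to ``max_interactors`` first-shell interactors to the seeds.

    Seeds with no qualifying edges yield members == seeds.  The induced edge
    set (all qualifying edges with both endpoints among the members) is
    computed on the returned network.
    """
    if max_interactors < 0:
        raise ValueError("max_interactors must be >= 0")
    seed_set = frozenset(seeds)
    edges = [e for e in edges if e.combined_score >= edge_score_min]
    best_score: dict[str, float] = defaultdict(float)
    seed_neighbours: dict[str, set[str]] = defaultdict(set)
    for e in edges:
        for cand, seed in ((e.gene_a, e.gene_b), (e.gene_b, e.gene_a)):
            if seed in seed_set and cand not in seed_set:
                if e.combined_score > best_score[cand]:
                    best_score[cand] = e.combined_score
                seed_neighbours[cand].add(seed)
    ranked = sorted(
        best_score,
        key=lambda g: (-best_score[g], -len(seed_neighbours[g]), g),
    )
    added = frozenset(ranked[:max_interactors])
    members = seed_set | added
    induced = frozenset(
        e.pair for e in edges if e.gene_a in members and e.gene_b in members
    )
    return ExpandedNetwork(seed_genes=seed_set, added_genes=added, induced_edges=induced)


def induced_pairs(
    net: ExpandedNetwork,
    edges: Iterable[InteractionEdge],
    edge_score_min: float = 0.0,
) -> int:
    """Count unordered edges with both endpoints in the network's members."""
    members = net.members
    pairs = {
        e.pair
        for e in edges
        if e.combined_score >= edge_score_min
        and e.gene_a in members
        and e.gene_b in members
    }
    return len(pairs)


def to_graph(
    net: ExpandedNetwork,
    drug_links: Iterable[DrugTargetRecord] | None = None,
) -> nx.Graph:
    """Build the annotated graph: gene nodes with role biological_gene /
    ppi_gene, optional drug and indication nodes linked to their targets."""
    g = nx.Graph()
    for gene in sorted(net.seed_genes):
        g.add_node(gene, role="biological_gene")
    for gene in sorted(net.added_genes):
        g.add_node(gene, role="ppi_gene")
    for a, b in sorted(net.induced_edges):
        g.add_edge(a, b, kind="ppi")
    for rec in drug_links or []:
        if rec.target_gene not in net.members:
            continue
        g.add_node(rec.drug_name, role="drug")
        g.add_edge(rec.drug_name, rec.target_gene, kind="drug_target")
        if rec.indication:
            g.add_node(rec.indication, role="indication")
            g.add_edge(rec.drug_name, rec.indication, kind="indication")
    return g


def export_network(
    net: ExpandedNetwork,
    path: str | Path,
    drug_links: Iterable[DrugTargetRecord] | None = None,
    fmt: str = "graphml",
) -> None:
    """Write the network as GraphML or DOT.

    Node roles mirror the figure-legend colour classes: biological risk genes,
    PPI-added genes, drugs and indications.
    """
    g = to_graph(net, drug_links)
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "dot":
        _write_dot(g, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _quote(s: str) -> str:
    return '"' + s.replace('"', r"\"") + '"'


def _write_dot(g: nx.Graph, path: Path) -> None:
    # minimal undirected DOT dialect; no layout attributes
    lines = ["graph network {"]
    for node, data in sorted(g.nodes(data=True)):
        lines.append(f"  {_quote(node)} [role={_quote(data.get('role', ''))}];")
    for a, b, data in sorted(g.edges(data=True)):
        lines.append(f"  {_quote(a)} -- {_quote(b)} [kind={_quote(data.get('kind', ''))}];")
    lines.append("}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
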
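"""Operon delimitation and protein-cluster cooccurrence networks.

Genes are grouped into operons — maximal runs of same-strand adjacent
genes uninterrupted by a rho-independent terminator on that strand.
Protein clusters that ride in the same operon in at least two genomes
become linked nodes of a cooccurrence network; weak edges (at or below
0.05% of total edge strength) are pruned and the network is summarised
by its connected components.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from itertools import combinations

import networkx as nx

from .types import GeneCall, Operon

logger = logging.getLogger(__name__)


def delimit_operons(
    genes: list[GeneCall],
    terminators: list[tuple[int, str]],
    split_on_opposite_strand: bool = False,
) -> list[Operon]:
    """Partition a genome's genes into operons.

    Scanning genes in genomic order, a new operon starts when the strand
    changes or when a terminator on the current strand lies strictly
    between the previous gene's end and the current gene's start
    (terminators only break operons on their own strand unless
    ``split_on_opposite_strand``). Every gene belongs to exactly one
    operon. Overlapping same-strand genes stay in one operon, with a
    logged warning.
    """
    if not genes:
        return []
    ordered = sorted(genes, key=lambda g: (g.start, g.end))
    genome_id = ordered[0].genome_id
    terms = sorted(terminators)

    def terminator_between(lo: int, hi: int, strand: str) -> bool:
        for pos, tstrand in terms:
            if lo < pos < hi and (split_on_opposite_strand or tstrand == strand):
                return True
        return False

    operons: list[Operon] = []
    current: list[GeneCall] = [ordered[0]]
    for prev, g in zip(ordered, ordered[1:]):
        if g.start < prev.end and g.strand == prev.strand:
            logger.warning(
                "overlapping same-strand genes %s/%s kept in one operon",
                prev.gene_id, g.gene_id,
            )
        if g.strand != prev.strand or terminator_between(prev.end, g.start, g.strand):
            operons.append(_mk_operon(genome_id, len(operons), current))
            current = [g]
        else:
            current.append(g)
    operons.append(_mk_operon(genome_id, len(operons), current))
    return operons


def _mk_operon(genome_id: str, idx: int, genes: list[GeneCall]) -> Operon:
    return Operon(
        operon_id=f"{genome_id}|op{idx:03d}",
        genome_id=genome_id,
        gene_ids=[g.gene_id for g in genes],
        strand=genes[0].strand,
        span=(genes[0].start, max(g.end for g in genes)),
    )


def build_cooccurrence(
    operons: list[Operon],
    pc_assignment: dict[str, str],
    strength_mode: str = "genomes",
) -> nx.Graph:
    """Link protein clusters found in the same operon in >= 2 genomes.

    Let S(a, b) be the set of genomes in which clusters a and b occur
    within one operon. An (undirected, self-loop-free) edge exists when
    |S| >= 2; its strength is |S| (mode "genomes", the default) or
    C(|S|, 2) (mode "genome_pairs"). Genes without a cluster assignment
    are excluded and counted in the graph's ``n_unassigned`` attribute.
    """
    if strength_mode not in ("genomes", "genome_pairs"):
        raise ValueError(f"unknown strength_mode: {strength_mode}")
    genomes_with: dict[tuple[str, str], set[str]] = defaultdict(set)
    nodes: set[str] = set()
    n_unassigned = 0
    for op in operons:
        pcs = set()
        for gid in op.gene_ids:
            pc = pc_assignment.get(gid)
            if pc is None:
                n_unassigned += 1
            else:
                pcs.add(pc)
        nodes.update(pcs)
        for a, b in combinations(sorted(pcs), 2):
            genomes_with[(a, b)].add(op.genome_id)

    g = nx.Graph(n_unassigned=n_unassigned, strength_mode=strength_mode)
    g.add_nodes_from(sorted(nodes))
    for (a, b), gset in sorted(genomes_with.items()):
        n = len(gset)
        if n >= 2:
            strength = n if strength_mode == "genomes" else n * (n - 1) // 2
            g.add_edge(a, b, strength=strength, genomes=sorted(gset))
    return g


def prune_edges(network: nx.Graph, min_fraction: float = 0.0005, strict: bool = False) -> nx.Graph:
    """Remove edges whose strength is <= ``min_fraction`` of the total
    strength (strictly below with ``strict``). Nodes are retained even
    if isolated (flagged with the ``isolated`` attribute). Idempotent:
    pruning lowers the total, which can only raise surviving fractions.
    """
    g = network.copy()
    total = sum(d["strength"] for _, _, d in g.edges(data=True))
    if total == 0:
        return g
    doomed = [
        (a, b)
        for a, b, d in g.edges(data=True)
        if (d["strength"] / total < min_fraction if strict else d["strength"] / total <= min_fraction)
    ]
    g.remove_edges_from(doomed)
    for node in g.nodes:
        g.nodes[node]["isolated"] = g.degree(node) == 0
    return g


def component_clusters(network: nx.Graph) -> dict[str, str]:
    """Connected-component labels per node; each component is labelled by
    its lexicographically smallest member."""
    labels: dict[str, str] = {}
    for comp in nx.connected_components(network):
        rep = min(comp)
        for node in comp:
            labels[node] = rep
    return labels
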
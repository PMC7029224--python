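"""Rule-based cross-assembly of candidate contigs into MAVGs.

Overlapping candidate contigs are merged under three explicit rules:
an overlap qualifies only at >99% nucleotide identity over >1,000
aligned nt with <10 nt of gaps (strict inequalities, as printed); every
junction in a merged layout must be corroborated by at least
``min_support`` contigs; and the contigs of one assembly must be
ecologically coherent (single habitat — freshwater and marine contigs
are never merged). Assembled genomes then pass a final size / GC /
host-protein / tRNA filter.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import edlib
import networkx as nx
import numpy as np

from .align import best_diagonal, cigar_stats, kmer_index, revcomp
from .types import Bin, Contig, HitRecord, MAVG, OverlapEdge

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# deduplication


def dedup_contigs(contigs: list[Contig]) -> tuple[list[Contig], dict[str, str]]:
    """Remove identical and contained sequences, keeping the longer contig.

    A contig that equals, or is an exact substring of, another contig
    (either strand) is dropped; ``removed_map`` records the surviving
    representative for every removal. Idempotent.
    """
    ordered = sorted(contigs, key=lambda c: (-len(c.sequence), c.contig_id))
    retained: list[Contig] = []
    removed: dict[str, str] = {}
    for c in ordered:
        rep = None
        for r in retained:
            if c.sequence in r.sequence or revcomp(c.sequence) in r.sequence:
                rep = r.contig_id
                break
        if rep is None:
            retained.append(c)
        else:
            removed[c.contig_id] = rep
    retained.sort(key=lambda c: c.contig_id)
    return retained, removed


# ---------------------------------------------------------------------------
# all-versus-all overlap computation


def _overlap_for_orientation(
    seq_a: str, seq_b: str, index_a: dict, k: int, min_overlap: int
) -> tuple[float, int, int, tuple[int, int, int, int]] | None:
    """Align the overlap implied by the best seed diagonal.

    Returns (identity, aln_columns, gap_columns, (a0, a1, b0, b1)) or
    None when no seeded overlap of at least ``min_overlap`` nt exists.
    """
    diag = best_diagonal(seq_b, index_a, k, min_seeds=3)
    if diag is None:
        return None
    d, _ = diag  # d = pos_in_a - pos_in_b
    a0, b0 = max(0, d), max(0, -d)
    ov = min(len(seq_a) - a0, len(seq_b) - b0)
    if ov < min_overlap:
        return None
    res = edlib.align(seq_b[b0 : b0 + ov], seq_a[a0 : a0 + ov], mode="NW", task="path")
    stats = cigar_stats(res["cigar"])
    return stats.identity, stats.columns, stats.gap_columns, (a0, a0 + ov, b0, b0 + ov)


def compute_overlaps(
    contigs: list[Contig], min_seed_kmer: int = 21, min_overlap: int = 200
) -> list[OverlapEdge]:
    """All-versus-all overlap detection.

    Exact k-mer seeding locates the shared diagonal of each contig pair
    (both orientations considered); the implied overlap is then aligned
    end-to-end and scored. One edge is reported per unordered pair, for
    the orientation with more matching columns.
    """
    ordered = sorted(contigs, key=lambda c: c.contig_id)
    indexes = {c.contig_id: kmer_index(c.sequence, min_seed_kmer) for c in ordered}
    edges: list[OverlapEdge] = []
    for i, ca in enumerate(ordered):
        for cb in ordered[i + 1 :]:
            best: OverlapEdge | None = None
            for orientation, seq_b in (
                ("forward", cb.sequence),
                ("reverse-complement", revcomp(cb.sequence)),
            ):
                hit = _overlap_for_orientation(
                    ca.sequence, seq_b, indexes[ca.contig_id], min_seed_kmer, min_overlap
                )
                if hit is None:
                    continue
                identity, columns, gaps, (a0, a1, b0, b1) = hit
                edge = OverlapEdge(
                    contig_a=ca.contig_id,
                    contig_b=cb.contig_id,
                    orientation=orientation,
                    identity=identity,
                    aln_len=columns,
                    gap_count=gaps,
                    a_start=a0,
                    a_end=a1,
                    b_start=b0,
                    b_end=b1,
                )
                if best is None or edge.identity * edge.aln_len > best.identity * best.aln_len:
                    best = edge
            if best is not None:
                edges.append(best)
    return edges


def qualify_overlap(
    edge: OverlapEdge,
    min_identity: float = 99.0,
    min_len: int = 1000,
    max_gaps: int = 10,
) -> bool:
    """The three overlap rules, with strict inequalities as printed:
    identity > 99%, alignment length > 1,000 nt, gaps < 10 nt."""
    return (
        edge.identity > min_identity
        and edge.aln_len > min_len
        and edge.gap_count < max_gaps
    )


def bin_contigs(contigs: list[Contig], qualifying_edges: list[OverlapEdge]) -> list[Bin]:
    """Bins = connected components of the qualifying-overlap graph.

    Singleton contigs form their own bins. Output is invariant to input
    order (components are labelled by their smallest member id).
    """
    g = nx.Graph()
    g.add_nodes_from(c.contig_id for c in contigs)
    for e in qualifying_edges:
        g.add_edge(e.contig_a, e.contig_b)
    by_edge: dict[frozenset, list[OverlapEdge]] = defaultdict(list)
    for e in qualifying_edges:
        by_edge[frozenset((e.contig_a, e.contig_b))].append(e)
    bins = []
    for comp in sorted(nx.connected_components(g), key=lambda s: min(s)):
        comp_edges = [
            e
            for pair, lst in by_edge.items()
            if pair <= comp
            for e in lst
        ]
        bins.append(Bin(bin_id=f"bin_{min(comp)}", contig_ids=set(comp), edges=comp_edges))
    return bins


# ---------------------------------------------------------------------------
# layout + consensus


@dataclass
class MergeReport:
    bin_id: str
    excluded_habitat: list[str] = field(default_factory=list)
    junction_supports: list[int] = field(default_factory=list)
    n_splits: int = 0
    conflicts: list[tuple[str, str]] = field(default_factory=list)


_BASE_CODE = {b: i for i, b in enumerate("ACGTN")}


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def _place_contigs(
    members: list[Contig], edges: list[OverlapEdge], report: MergeReport
) -> dict[str, tuple[int, str]]:
    """Assign each contig a layout offset and orientation by BFS from the
    longest contig along qualifying edges. Inconsistent (repeat-induced,
    cyclic) placements are resolved by dropping the weakest conflicting
    edge once; remaining conflicts are reported."""
    lens = {c.contig_id: len(c.sequence) for c in members}
    adjacency: dict[str, list[OverlapEdge]] = defaultdict(list)
    for e in edges:
        adjacency[e.contig_a].append(e)
        adjacency[e.contig_b].append(e)

    def run(active_edges: set[int]) -> tuple[dict[str, tuple[int, str]], list[tuple[int, int]]]:
        placement: dict[str, tuple[int, str]] = {}
        conflicts: list[tuple[int, int]] = []
        order = sorted(members, key=lambda c: (-len(c.sequence), c.contig_id))
        for root in order:
            if root.contig_id in placement:
                continue
            placement[root.contig_id] = (0, "+")
            queue = [root.contig_id]
            while queue:
                cur = queue.pop(0)
                o_cur, s_cur = placement[cur]
                for e in adjacency[cur]:
                    if id(e) not in active_edges:
                        continue
                    if e.contig_a == cur:
                        other, a0, a1, b0, b1 = e.contig_b, e.a_start, e.a_end, e.b_start, e.b_end
                        la, lb = lens[cur], lens[other]
                        fwd = e.orientation == "forward"
                    else:
                        # mirror the edge: treat cur as "a"
                        other = e.contig_a
                        la, lb = lens[cur], lens[other]
                        if e.orientation == "forward":
                            a0, a1, b0, b1 = e.b_start, e.b_end, e.a_start, e.a_end
                            fwd = True
                        else:
                            # cur appears reverse-complemented in the edge frame
                            a0 = lens[cur] - e.b_end
                            a1 = lens[cur] - e.b_start
                            b0 = lens[other] - e.a_end
                            b1 = lens[other] - e.a_start
                            fwd = False
                    if s_cur == "+":
                        off = o_cur + a0 - b0
                        strand = "+" if fwd else "-"
                    else:
                        off = o_cur + (la - a1) - (lb - b1)
                        strand = "-" if fwd else "+"
                    if other in placement:
                        o_e, s_e = placement[other]
                        if s_e != strand or abs(o_e - off) > 50:
                            conflicts.append((id(e), int(e.identity * e.aln_len)))
                        continue
                    placement[other] = (off, strand)
                    queue.append(other)
        return placement, conflicts

    active = {id(e) for e in edges}
    placement, conflicts = run(active)
    if conflicts:
        weakest = min(conflicts, key=lambda t: t[1])[0]
        active.discard(weakest)
        placement, conflicts = run(active)
        if conflicts:
            report.conflicts = [("unresolved", str(len(conflicts)))]
        else:
            report.conflicts = [("dropped_weakest_edge", "1")]
    return placement


def _consensus(
    group: list[tuple[Contig, int, str]]
) -> tuple[str, list[tuple[str, int, int, str]]]:
    """Majority consensus over placed contigs; ties resolved by the base
    of the longest spanning contig."""
    base = min(off for _, off, _ in group)
    group = [(c, off - base, s) for c, off, s in group]
    total = max(off + len(c.sequence) for c, off, _ in group)
    counts = np.zeros((5, total), dtype=np.int32)
    longest = np.zeros(total, dtype=np.uint8)
    path = []
    for c, off, strand in sorted(group, key=lambda t: (len(t[0].sequence), t[0].contig_id)):
        seq = c.sequence if strand == "+" else revcomp(c.sequence)
        codes = np.frombuffer(
            seq.encode().translate(bytes.maketrans(b"ACGTN", bytes(range(5)))), dtype=np.uint8
        )
        idx = np.arange(off, off + len(codes))
        np.add.at(counts, (codes, idx), 1)
        longest[idx] = codes  # later (longer) contigs overwrite
    for c, off, strand in sorted(group, key=lambda t: t[1]):
        path.append((c.contig_id, off, off + len(c.sequence), strand))
    best = counts.max(axis=0)
    consensus = counts.argmax(axis=0).astype(np.uint8)
    tie = (counts == best).sum(axis=0) > 1
    consensus[tie] = longest[tie]
    seq = consensus.tobytes().translate(bytes.maketrans(bytes(range(5)), b"ACGTN")).decode()
    return seq, path


def merge_bin(
    bin_: Bin,
    contigs: dict[str, Contig],
    min_support: int = 3,
    mavg_prefix: str = "MAVG",
) -> tuple[list[MAVG], MergeReport]:
    """Merge one bin of overlapping contigs into one or more MAVGs.

    Contigs whose habitat conflicts with the bin majority are excluded
    before layout. The layout is split wherever fewer than
    ``min_support`` contigs span a junction between consecutive placed
    contigs, so every junction of an emitted MAVG is corroborated by at
    least that many overlapping sequences.
    """
    report = MergeReport(bin_id=bin_.bin_id)
    members = [contigs[cid] for cid in sorted(bin_.contig_ids)]

    habitats = defaultdict(int)
    for c in members:
        habitats[c.habitat] += 1
    majority = max(habitats, key=lambda h: (habitats[h], h))
    report.excluded_habitat = [c.contig_id for c in members if c.habitat != majority]
    members = [c for c in members if c.habitat == majority]
    kept_ids = {c.contig_id for c in members}
    edges = [e for e in bin_.edges if e.contig_a in kept_ids and e.contig_b in kept_ids]

    placement = _place_contigs(members, edges, report)

    # group contigs that landed on the same layout (same BFS tree share a
    # coordinate frame; disconnected sub-layouts get separate frames but
    # identical offsets are possible, so track connectivity explicitly)
    g = nx.Graph()
    g.add_nodes_from(kept_ids)
    for e in edges:
        g.add_edge(e.contig_a, e.contig_b)

    mavgs: list[MAVG] = []
    idx = 0
    for comp in sorted(nx.connected_components(g), key=lambda s: min(s)):
        placed = sorted(
            ((contigs[cid], placement[cid][0], placement[cid][1]) for cid in comp),
            key=lambda t: (t[1], t[0].contig_id),
        )
        # split at under-supported junctions
        groups: list[list[tuple[Contig, int, str]]] = [[placed[0]]]
        cur_end = placed[0][1] + len(placed[0][0].sequence)
        for c, off, strand in placed[1:]:
            end = off + len(c.sequence)
            if off >= cur_end:
                groups.append([(c, off, strand)])
                cur_end = end
                continue
            # junction region = overlap between the incoming contig and the
            # coverage so far; support = distinct contigs intersecting it
            j_start, j_end = off, min(cur_end, end)
            support = sum(
                1
                for cc, oo, _ in placed
                if oo < j_end and oo + len(cc.sequence) > j_start
            )
            report.junction_supports.append(support)
            if support < min_support:
                groups.append([(c, off, strand)])
                report.n_splits += 1
            else:
                groups[-1].append((c, off, strand))
            cur_end = max(cur_end, end)
        for group in groups:
            seq, path = _consensus(group)
            mavgs.append(
                MAVG(
                    mavg_id=f"{mavg_prefix}_{bin_.bin_id}_{idx:02d}",
                    sequence=seq,
                    path=path,
                    habitat=majority,
                )
            )
            idx += 1
    return mavgs, report


# ---------------------------------------------------------------------------
# final MAVG filters


@dataclass
class FilterResult:
    passing: list[MAVG]
    failing: list[tuple[str, str]]  # (mavg_id, first violated rule)
    warnings: list[str] = field(default_factory=list)


def filter_mavgs(
    mavgs: list[MAVG],
    sar11_hits: dict[str, list[HitRecord]] | None = None,
    trna_hits: dict[str, list[HitRecord]] | None = None,
    min_len: int = 100_000,
    gc_range: tuple[float, float] = (30.0, 35.0),
    min_sar11_identity: float = 70.0,
    min_trna_identity: float = 95.0,
    min_sar11_matches: int = 1,
) -> FilterResult:
    """Final genome filters: size (strict >), GC range (inclusive),
    host-protein matches, tRNA matches.

    When no hit tables are supplied, the protein/tRNA criteria are
    reported as not evaluated and the decision rests on size + GC alone.
    The tRNA rule only applies to genomes that have tRNA hits at all.
    """
    result = FilterResult(passing=[], failing=[])
    if sar11_hits is None:
        result.warnings.append("sar11_hits missing: protein criterion not_evaluated")
    if trna_hits is None:
        result.warnings.append("trna_hits missing: tRNA criterion not_evaluated")
    for m in mavgs:
        if not (m.length > min_len):
            result.failing.append((m.mavg_id, "size"))
            continue
        gc = m.gc
        if not (gc_range[0] <= gc <= gc_range[1]):
            result.failing.append((m.mavg_id, "gc"))
            continue
        if sar11_hits is not None:
            n_ok = sum(
                1 for h in sar11_hits.get(m.mavg_id, []) if h.identity > min_sar11_identity
            )
            if n_ok < min_sar11_matches:
                result.failing.append((m.mavg_id, "sar11_proteins"))
                continue
        if trna_hits is not None:
            hits = trna_hits.get(m.mavg_id, [])
            if hits and not any(h.identity > min_trna_identity for h in hits):
                result.failing.append((m.mavg_id, "trna"))
                continue
        result.passing.append(m)
    return result
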
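"""Completeness calls and per-genome descriptive features.

A recovered genome is called complete either by terminal repeats —
identical sequence of more than 10 nt at the 5' and 3' ends, evidence of
a defined-end or circularly permuted genome — or by alignment: sharing
nearly all widely-shared protein clusters of a complete reference
genome, in nearly the same order. The remaining functions compute the
descriptive features reported per genome: length, GC%, mean intergenic
spacer, and host-protein match counts.
"""

from __future__ import annotations

from collections import defaultdict

from .types import CompletenessCall, GeneCall, HitRecord


def gc_content(sequence: str) -> float:
    """GC percentage over non-N bases."""
    s = sequence.upper()
    denom = len(s) - s.count("N")
    if denom == 0:
        raise ValueError("GC content undefined for empty or all-N sequence")
    return 100.0 * (s.count("G") + s.count("C")) / denom


def detect_terminal_repeats(sequence: str, min_repeat: int = 11, max_scan: int = 500) -> int:
    """Longest exact match between the 5' and 3' scan windows.

    Seeds exact ``min_repeat``-mers of the prefix window against the
    suffix window and extends each seed maximally. Matches shorter than
    ``min_repeat`` (i.e. repeats of 10 nt or less at the default) are
    reported as 0. Windows shrink to half the sequence when it is
    shorter than two windows.
    """
    L = len(sequence)
    if L < 2 * max_scan:
        max_scan = L // 2
    if max_scan < min_repeat:
        return 0
    head = sequence[:max_scan]
    tail = sequence[L - max_scan :]
    k = min_repeat
    seeds: dict[str, list[int]] = defaultdict(list)
    for i in range(len(head) - k + 1):
        seeds[head[i : i + k]].append(i)
    best = 0
    for j in range(len(tail) - k + 1):
        for i in seeds.get(tail[j : j + k], ()):
            # extend left within the windows
            li, lj = i, j
            while li > 0 and lj > 0 and head[li - 1] == tail[lj - 1]:
                li -= 1
                lj -= 1
            # extend right
            ri, rj = i + k, j + k
            while ri < len(head) and rj < len(tail) and head[ri] == tail[rj]:
                ri += 1
                rj += 1
            best = max(best, ri - li)
    return best if best >= min_repeat else 0


def completeness_by_terminal_repeats(
    genome_id: str, sequence: str, min_repeat: int = 11, max_scan: int = 500
) -> CompletenessCall:
    rep = detect_terminal_repeats(sequence, min_repeat=min_repeat, max_scan=max_scan)
    if rep >= min_repeat:
        return CompletenessCall(genome_id, "complete", "TR", float(rep))
    return CompletenessCall(genome_id, "partial", "none", float(rep))


def completeness_by_alignment(
    query_genes: list[GeneCall],
    reference_genes: list[GeneCall],
    pc_map: dict[str, str],
    min_core_share: float = 0.9,
    min_synteny: float = 0.8,
) -> CompletenessCall:
    """Complete(Al) if the query shares the reference's widely-shared gene
    content in nearly the same order.

    ``pc_map`` assigns gene ids (of these two genomes and, ideally, of
    additional genomes) to protein clusters. The reference's *shared*
    clusters are those of its clusters that also occur outside the
    reference — hypervariable, reference-private clusters do not count
    against a query. The call is complete when the query contains at
    least ``min_core_share`` of those shared clusters and the longest
    common subsequence of their genome order covers at least
    ``min_synteny`` of them; evidence = min of the two fractions.
    """
    if not query_genes or not reference_genes:
        raise ValueError("both gene lists must be non-empty")
    qid = query_genes[0].genome_id

    genome_of: dict[str, set[str]] = defaultdict(set)
    for g in query_genes + reference_genes:
        if g.gene_id in pc_map:
            genome_of[pc_map[g.gene_id]].add(g.genome_id)
    # pc_map may cover extra genomes beyond these two
    mapped_genes = set(g.gene_id for g in query_genes + reference_genes)
    for gene_id, cluster in pc_map.items():
        if gene_id not in mapped_genes:
            genome_of[cluster].add(gene_id.split("|")[0])

    ref_clusters = {pc_map[g.gene_id] for g in reference_genes if g.gene_id in pc_map}
    shared_ref = {c for c in ref_clusters if len(genome_of[c]) > 1}
    query_clusters = {pc_map[g.gene_id] for g in query_genes if g.gene_id in pc_map}
    common = shared_ref & query_clusters
    if not shared_ref or not common:
        return CompletenessCall(qid, "partial", "none", 0.0)

    share = len(common) / len(shared_ref)

    def order(genes: list[GeneCall]) -> list[str]:
        return [
            pc_map[g.gene_id]
            for g in sorted(genes, key=lambda g: g.start)
            if pc_map.get(g.gene_id) in common
        ]

    q_order, r_order = order(query_genes), order(reference_genes)
    n, m = len(q_order), len(r_order)
    dp = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n):
        for j in range(m):
            dp[i + 1][j + 1] = (
                dp[i][j] + 1 if q_order[i] == r_order[j] else max(dp[i][j + 1], dp[i + 1][j])
            )
    synteny = dp[n][m] / len(common)

    evidence = min(share, synteny)
    if share >= min_core_share and synteny >= min_synteny:
        return CompletenessCall(qid, "complete", "Al", evidence)
    return CompletenessCall(qid, "partial", "none", evidence)


def mean_intergenic_spacer(genes: list[GeneCall]) -> float:
    """Mean gap in bp between consecutive genes (sorted by start,
    strand-agnostic); overlapping genes contribute 0; genome ends are
    excluded. Undefined for fewer than two genes."""
    if len(genes) < 2:
        raise ValueError("mean intergenic spacer requires at least 2 genes")
    ordered = sorted(genes, key=lambda g: (g.start, g.end))
    gaps = [
        max(0, b.start - a.end) for a, b in zip(ordered, ordered[1:])
    ]
    return sum(gaps) / len(gaps)


def count_protein_matches(
    hits: list[HitRecord],
    query_lengths: dict[str, int],
    subject_lengths: dict[str, int],
    min_similarity: float = 70.0,
    len_window: tuple[float, float] = (0.7, 1.3),
) -> int:
    """Count query proteins with a qualifying best hit.

    A hit qualifies at >= ``min_similarity`` percent identity with an
    alignment length between 70% and 130% of the *smaller* protein's
    length. One count per distinct query protein (its best hit by
    bit score, then identity).
    """
    best: dict[str, HitRecord] = {}
    for h in hits:
        if h.query_id not in query_lengths or h.subject_id not in subject_lengths:
            raise KeyError(f"hit references unknown protein: {h.query_id}/{h.subject_id}")
        prev = best.get(h.query_id)
        if prev is None or (h.bitscore, h.identity) > (prev.bitscore, prev.identity):
            best[h.query_id] = h
    n = 0
    for h in best.values():
        smaller = min(query_lengths[h.query_id], subject_lengths[h.subject_id])
        if smaller == 0:
            continue
        ratio = h.aln_len / smaller
        if h.identity >= min_similarity and len_window[0] <= ratio <= len_window[1]:
            n += 1
    return n


def genome_feature_row(
    genome_id: str,
    sequence: str,
    genes: list[GeneCall] | None = None,
    n_trnas: int = 0,
    completeness: CompletenessCall | None = None,
    n_sar11_matches: int | None = None,
    n_core_matches: int | None = None,
) -> dict:
    """One row of the per-genome feature report (length, GC%, gene stats,
    completeness call, match counts)."""
    row = {
        "genome_id": genome_id,
        "length_bp": len(sequence),
        "gc_pct": round(gc_content(sequence), 2),
        "n_trnas": n_trnas,
        "n_genes": len(genes) if genes else 0,
        "mean_igs_bp": round(mean_intergenic_spacer(genes), 2) if genes and len(genes) > 1 else None,
        "completeness": completeness.status if completeness else "partial",
        "method": completeness.method if completeness else "none",
        "n_sar11_matches": n_sar11_matches,
        "n_core_matches": n_core_matches,
    }
    return row
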
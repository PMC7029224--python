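"""Cross-genome analytics.

Core-protein extraction and concatenation prep for phylogenomics,
fragment-based ANI/coverage between genome pairs, consensus functional
annotation across databases, and proteome isoelectric-point (pI)
distributions — the freshwater-vs-marine pI shift is one of the few
proteome-wide signals separating habitat groups.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .align import kmer_index, locate_both_strands
from .types import GeneCall, HitRecord


# ---------------------------------------------------------------------------
# core clusters and concatenation


@dataclass
class CoreSet:
    """Clusters single-copy-present in every genome."""

    cluster_ids: list[str]
    members: dict[str, dict[str, str]]  # cluster_id -> genome_id -> gene_id


def extract_core(pc_assignments: dict[str, list[GeneCall]], genome_ids: list[str]) -> CoreSet:
    """Clusters with exactly one member gene in every listed genome.

    ``pc_assignments`` maps cluster_id -> member genes (across genomes).
    An empty core is a valid result.
    """
    wanted = list(genome_ids)
    cluster_ids = []
    members: dict[str, dict[str, str]] = {}
    for cid in sorted(pc_assignments):
        by_genome: dict[str, list[str]] = defaultdict(list)
        for g in pc_assignments[cid]:
            by_genome[g.genome_id].append(g.gene_id)
        if all(len(by_genome.get(gid, [])) == 1 for gid in wanted):
            cluster_ids.append(cid)
            members[cid] = {gid: by_genome[gid][0] for gid in wanted}
    return CoreSet(cluster_ids=cluster_ids, members=members)


def concatenate_core(
    core: CoreSet, aligned_blocks: dict[str, dict[str, str]]
) -> tuple[dict[str, str], list[tuple[str, int, int]]]:
    """Concatenate per-cluster aligned blocks into a supermatrix.

    ``aligned_blocks`` maps cluster_id -> genome_id -> aligned row
    (equal lengths within a block). Blocks are concatenated in fixed
    cluster-id order; returns (rows per genome, partitions) where
    partitions are (cluster_id, start, end) column spans for external
    tree inference.
    """
    order = sorted(core.cluster_ids)
    genomes = sorted({g for cid in order for g in core.members.get(cid, {})})
    rows = {g: [] for g in genomes}
    partitions: list[tuple[str, int, int]] = []
    pos = 0
    for cid in order:
        block = aligned_blocks[cid]
        widths = {len(s) for s in block.values()}
        if len(widths) != 1:
            raise ValueError(f"block {cid} rows have unequal lengths")
        width = widths.pop()
        for g in genomes:
            if g not in block:
                raise ValueError(f"block {cid} missing genome {g}")
            rows[g].append(block[g])
        partitions.append((cid, pos, pos + width))
        pos += width
    return {g: "".join(parts) for g, parts in rows.items()}, partitions


# ---------------------------------------------------------------------------
# ANI


@dataclass
class ANIResult:
    query_genome: str
    subject_genome: str
    ani: float  # percent; 0 with no_fragments flag when nothing aligns
    coverage: float  # percent of query covered by passing fragments
    n_fragments_used: int
    no_fragments: bool = False


def ani_coverage(
    query: tuple[str, str],
    subject: tuple[str, str],
    frag_len: int = 1020,
    min_frag_identity: float = 30.0,
    min_frag_alncov: float = 0.7,
    k: int = 13,
) -> ANIResult:
    """Fragment-based average nucleotide identity and aligned coverage.

    The query genome is cut into consecutive ``frag_len`` windows (the
    trailing partial window is dropped); each fragment is placed on the
    subject with the built-in seeded aligner, both strands. A fragment
    passes when it aligns at >= ``min_frag_identity`` identity over at
    least ``min_frag_alncov`` of its length. ANI is the mean identity of
    passing fragments; coverage = passing fragments x frag_len / query
    length. Directional: ani(A, B) is reported as queried.
    """
    (q_id, q_seq), (s_id, s_seq) = query, subject
    if len(q_seq) < frag_len or len(s_seq) < frag_len:
        raise ValueError("both genomes must be at least one fragment long")
    index = kmer_index(s_seq, k)
    identities = []
    for start in range(0, len(q_seq) - frag_len + 1, frag_len):
        frag = q_seq[start : start + frag_len]
        hit = locate_both_strands(frag, s_seq, index, k=k, min_seeds=5)
        if hit is None:
            continue
        aligned_q = hit.columns - hit.gap_columns  # columns consuming query or subject
        if hit.identity >= min_frag_identity and aligned_q / frag_len >= min_frag_alncov:
            identities.append(hit.identity)
    n = len(identities)
    if n == 0:
        return ANIResult(q_id, s_id, 0.0, 0.0, 0, no_fragments=True)
    coverage = 100.0 * n * frag_len / len(q_seq)
    return ANIResult(q_id, s_id, float(np.mean(identities)), coverage, n)


# ---------------------------------------------------------------------------
# consensus annotation


@dataclass
class Annotation:
    cluster_id: str
    label: str
    support: int  # votes for the winning label
    evidence: dict[str, list[str]] = field(default_factory=dict)  # db -> labels seen


def _qualifying_hits(
    hits: list[HitRecord], query_lengths: dict[str, int],
    max_evalue: float, len_window: tuple[float, float],
) -> dict[str, list[HitRecord]]:
    """Per query, hits passing E-value and query-length-window rules,
    sorted best first."""
    ok: dict[str, list[HitRecord]] = defaultdict(list)
    for h in hits:
        qlen = query_lengths.get(h.query_id)
        if not qlen:
            continue
        if h.evalue >= max_evalue:
            continue
        if not (len_window[0] <= h.aln_len / qlen <= len_window[1]):
            continue
        ok[h.query_id].append(h)
    for lst in ok.values():
        lst.sort(key=lambda h: (h.evalue, -h.bitscore, h.subject_id))
    return ok


def annotate_consensus(
    hits_per_db: dict[str, list[HitRecord]],
    query_lengths: dict[str, int],
    labels: dict[str, str],
    pc_map: dict[str, str],
    max_evalue: float = 1e-5,
    len_window: tuple[float, float] = (0.7, 1.3),
) -> dict[str, Annotation]:
    """Consensus annotation per protein cluster.

    Per database, each member protein contributes its best qualifying
    hit's label (E < 1e-5, alignment spanning 70-130% of the query
    length). A cluster's annotation is the strict-majority label across
    databases and members; on a tie, second and third best hits join the
    vote; still unresolved clusters become "hypothetical".
    ``labels`` maps subject ids to functional labels.
    """
    qualifying = {
        db: _qualifying_hits(h, query_lengths, max_evalue, len_window)
        for db, h in hits_per_db.items()
    }
    clusters = sorted(set(pc_map.values()))
    out: dict[str, Annotation] = {}
    for cid in clusters:
        members = [q for q, c in pc_map.items() if c == cid]

        def vote(depth: int) -> tuple[Counter, dict[str, list[str]]]:
            votes: Counter = Counter()
            evidence: dict[str, list[str]] = defaultdict(list)
            for db, per_query in qualifying.items():
                for q in members:
                    for h in per_query.get(q, [])[:depth]:
                        lab = labels.get(h.subject_id, "hypothetical")
                        votes[lab] += 1
                        evidence[db].append(lab)
            return votes, dict(evidence)

        votes, evidence = vote(depth=1)
        winner = _strict_majority(votes)
        if winner is None and votes:
            votes, evidence = vote(depth=3)
            winner = _strict_majority(votes) or votes.most_common(1)[0][0]
        if winner is None:
            winner = "hypothetical"
        out[cid] = Annotation(cid, winner, votes.get(winner, 0), evidence)
    return out


def _strict_majority(votes: Counter) -> str | None:
    if not votes:
        return None
    (top, n), *rest = votes.most_common()
    if rest and rest[0][1] == n:
        return None
    return top


# ---------------------------------------------------------------------------
# isoelectric point


#: pKa values as used by EMBOSS pepstats (amino + carboxyl termini and
#: ionizable side chains).
EMBOSS_PKA = {
    "Nterm": 8.6,
    "Cterm": 3.6,
    "C": 8.5,
    "D": 3.9,
    "E": 4.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
    "Y": 10.1,
}

_BASIC = ("K", "R", "H")
_ACIDIC = ("D", "E", "C", "Y")


def net_charge(protein: str, ph: float) -> float:
    """Net charge at a given pH under the Henderson-Hasselbalch model
    with the EMBOSS pKa table. Unknown residues carry no charge."""
    counts = Counter(protein.upper())
    charge = 1.0 / (1.0 + 10 ** (ph - EMBOSS_PKA["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (EMBOSS_PKA["Cterm"] - ph))
    for aa in _BASIC:
        charge += counts[aa] / (1.0 + 10 ** (ph - EMBOSS_PKA[aa]))
    for aa in _ACIDIC:
        charge -= counts[aa] / (1.0 + 10 ** (EMBOSS_PKA[aa] - ph))
    return charge


def isoelectric_point(protein: str, tol: float = 1e-4) -> float:
    """pH at which the net charge vanishes, solved by bisection.

    The termini guarantee a positive charge at pH 0 and a negative
    charge at pH 14, so the bracket is always valid. Converges to well
    under 0.01 pH units.
    """
    if not protein:
        raise ValueError("empty protein sequence")
    lo, hi = 0.0, 14.0
    for _ in range(60):
        mid = (lo + hi) / 2.0
        c = net_charge(protein, mid)
        if abs(c) < tol and hi - lo < 1e-3:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def pi_distribution(proteome: list[str], bin_width: float = 0.2) -> "pd.DataFrame":
    """Binned pI density over pH 0-14; the densities integrate to 1."""
    import pandas as pd

    if not proteome:
        raise ValueError("empty proteome")
    pis = [isoelectric_point(p) for p in proteome]
    edges = np.arange(0.0, 14.0 + bin_width / 2, bin_width)
    dens, _ = np.histogram(pis, bins=edges, density=True)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "density": dens}
    )
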
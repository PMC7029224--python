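"""Built-in pairwise alignment helpers.

The pipeline normally consumes precomputed tabular hit tables, but every
stage can fall back to this self-contained aligner: exact k-mer seeding
to locate a candidate region, then an edit-distance alignment (edlib) to
score it. Identity is computed over alignment columns, with gap columns
counting as mismatches and tallied separately.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass

import edlib

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AlignmentStats:
    matches: int
    columns: int
    gap_columns: int

    @property
    def identity(self) -> float:
        """Percent identity over alignment columns (gaps = mismatches)."""
        return 100.0 * self.matches / self.columns if self.columns else 0.0


def cigar_stats(cigar: str) -> AlignmentStats:
    matches = columns = gaps = 0
    for n, op in _CIGAR_RE.findall(cigar):
        n = int(n)
        columns += n
        if op == "=":
            matches += n
        elif op in "ID":
            gaps += n
    return AlignmentStats(matches, columns, gaps)


def global_identity(a: str, b: str) -> float:
    """Percent identity of a global (Needleman-Wunsch-style) alignment.

    Works for nucleotide and protein sequences alike; characters are
    compared for equality, so ambiguity codes never count as matches.
    """
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, mode="NW", task="path")
    return cigar_stats(res["cigar"]).identity


def global_alignment_stats(a: str, b: str) -> AlignmentStats:
    res = edlib.align(a, b, mode="NW", task="path")
    return cigar_stats(res["cigar"])


def kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        idx[seq[i : i + k]].append(i)
    return idx


def best_diagonal(
    query: str, target_index: dict[str, list[int]], k: int, min_seeds: int = 3, band: int = 100
) -> tuple[int, int] | None:
    """Locate the best seed diagonal of ``query`` against an indexed target.

    Returns ``(diagonal, n_seeds)`` where diagonal = target_pos - query_pos,
    binned into bands of ``band`` nt so that small indels still chain, or
    None when fewer than ``min_seeds`` seeds fall in any band. The seed
    requirement is what gives the aligner BLAST-like locality: unrelated
    sequences essentially never share enough exact k-mers.
    """
    votes: dict[int, int] = defaultdict(int)
    rep: dict[int, int] = {}
    for qpos in range(0, len(query) - k + 1):
        for tpos in target_index.get(query[qpos : qpos + k], ()):
            d = tpos - qpos
            b = d // band
            votes[b] += 1
            rep.setdefault(b, d)
    if not votes:
        return None
    best = max(votes, key=lambda b: (votes[b], -b))
    if votes[best] < min_seeds:
        return None
    return rep[best], votes[best]


@dataclass
class LocalHit:
    """A locally aligned placement of a query on a target sequence."""

    identity: float
    matches: int
    columns: int
    gap_columns: int
    t_start: int
    t_end: int
    strand: str = "+"


def locate(
    query: str,
    target: str,
    target_index: dict[str, list[int]] | None = None,
    k: int = 13,
    min_seeds: int = 3,
    pad: int = 60,
) -> LocalHit | None:
    """Best semi-global placement of ``query`` inside ``target`` (+ strand).

    Seeds with exact k-mers, then aligns the full query against a padded
    window around the seeded diagonal in infix (HW) mode.
    """
    if len(query) < k or len(target) < k:
        return None
    if target_index is None:
        target_index = kmer_index(target, k)
    diag = best_diagonal(query, target_index, k, min_seeds=min_seeds)
    if diag is None:
        return None
    d, _ = diag
    w_start = max(0, d - pad)
    w_end = min(len(target), d + len(query) + pad)
    window = target[w_start:w_end]
    res = edlib.align(query, window, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    stats = cigar_stats(res["cigar"])
    loc0, loc1 = res["locations"][0]
    return LocalHit(
        identity=stats.identity,
        matches=stats.matches,
        columns=stats.columns,
        gap_columns=stats.gap_columns,
        t_start=w_start + loc0,
        t_end=w_start + loc1 + 1,
    )


def locate_both_strands(
    query: str,
    target: str,
    target_index: dict[str, list[int]] | None = None,
    k: int = 13,
    min_seeds: int = 3,
) -> LocalHit | None:
    """Best placement of ``query`` on either strand of ``target``."""
    if target_index is None:
        target_index = kmer_index(target, k)
    fwd = locate(query, target, target_index, k=k, min_seeds=min_seeds)
    rev = locate(revcomp(query), target, target_index, k=k, min_seeds=min_seeds)
    if rev is not None:
        rev.strand = "-"
    hits = [h for h in (fwd, rev) if h is not None]
    if not hits:
        return None
    return max(hits, key=lambda h: h.matches)
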
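"""Read-recruitment abundance profiling.

Reads are recruited to genomes from BLAST-like tabular hits (or the
built-in mapper). Abundance is normalised as RPKG — reads recruited per
kilobase of genome per gigabase of metagenome — so values compare
across genomes and samples of different sizes. A sample is retained
when at least one genome recruits more than 5 RPKG at more than 95%
identity; linear recruitment plots use the permissive 70% identity /
50 nt cutoff so diverged regions remain visible.
"""

from __future__ import annotations

import pandas as pd

from .align import kmer_index, locate_both_strands
from .types import HitRecord, RecruitmentProfile

#: Canonical hit-table columns (BLAST outfmt-6 order, 1-based inclusive
#: subject coordinates as BLAST prints them).
OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

_CANON = ["read_id", "genome_id", "identity", "aln_len", "bitscore", "s_lo", "s_hi", "sample_id"]


def read_outfmt6(path, sample_id: str = "sample") -> pd.DataFrame:
    """Load a BLAST outfmt-6 TSV into the canonical hit frame.

    Subject coordinates are normalised to 0-based half-open with
    s_lo < s_hi regardless of strand.
    """
    df = pd.read_csv(path, sep="\t", names=OUTFMT6_COLUMNS, comment="#")
    return pd.DataFrame(
        {
            "read_id": df.qseqid,
            "genome_id": df.sseqid,
            "identity": df.pident.astype(float),
            "aln_len": df.length.astype(int),
            "bitscore": df.bitscore.astype(float),
            "s_lo": df[["sstart", "send"]].min(axis=1) - 1,
            "s_hi": df[["sstart", "send"]].max(axis=1),
            "sample_id": sample_id,
        }
    )


def hits_frame(records: list[HitRecord], sample_id: str = "sample") -> pd.DataFrame:
    """Canonical hit frame from HitRecord objects (0-based half-open)."""
    return pd.DataFrame(
        {
            "read_id": [h.query_id for h in records],
            "genome_id": [h.subject_id for h in records],
            "identity": [h.identity for h in records],
            "aln_len": [h.aln_len for h in records],
            "bitscore": [h.bitscore for h in records],
            "s_lo": [h.s_start for h in records],
            "s_hi": [h.s_end for h in records],
            "sample_id": sample_id,
        },
        columns=_CANON,
    )


def map_reads(
    reads: list[tuple[str, str]],
    genomes: dict[str, str],
    sample_id: str = "sample",
    k: int = 13,
) -> pd.DataFrame:
    """Built-in fallback mapper: best placement of each read on each
    genome (both strands), emitted as a canonical hit frame."""
    indexes = {gid: kmer_index(seq, k) for gid, seq in genomes.items()}
    rows = []
    for rid, rseq in reads:
        for gid, gseq in genomes.items():
            hit = locate_both_strands(rseq, gseq, indexes[gid], k=k)
            if hit is None:
                continue
            rows.append(
                (rid, gid, hit.identity, hit.columns, float(2 * hit.matches),
                 hit.t_start, hit.t_end, sample_id)
            )
    return pd.DataFrame(rows, columns=_CANON)


def best_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """One row per (sample, read): best bitscore, ties by identity then
    genome id lexicographic."""
    ordered = hits.sort_values(
        ["sample_id", "read_id", "bitscore", "identity", "genome_id"],
        ascending=[True, True, False, False, True],
        kind="mergesort",
    )
    return ordered.drop_duplicates(["sample_id", "read_id"], keep="first")


def count_recruited(
    hits: pd.DataFrame, min_identity: float = 95.0, min_aln_len: int = 50
) -> dict[tuple[str, str], int]:
    """Reads counted per (genome, sample).

    Each read counts once, for its best hit, and only when that hit has
    identity strictly above ``min_identity`` over at least
    ``min_aln_len`` aligned nt.
    """
    bh = best_hits(hits)
    ok = bh[(bh.identity > min_identity) & (bh.aln_len >= min_aln_len)]
    counts = ok.groupby(["genome_id", "sample_id"]).size()
    return {(g, s): int(n) for (g, s), n in counts.items()}


def rpkg(reads_counted: int, genome_len: int, metagenome_bp: float) -> float:
    """Reads per kilobase of genome per gigabase of metagenome."""
    if genome_len <= 0 or metagenome_bp <= 0:
        raise ValueError("genome_len and metagenome_bp must be positive")
    return reads_counted / (genome_len / 1_000.0) / (metagenome_bp / 1e9)


def build_profiles(
    hits: pd.DataFrame,
    genome_lengths: dict[str, int],
    metagenome_bp: dict[str, float],
    min_identity: float = 95.0,
    min_aln_len: int = 50,
    linear_min_identity: float = 70.0,
) -> list[RecruitmentProfile]:
    """Per-(genome, sample) profiles: counts, RPKG and linear points.

    ``metagenome_bp`` is the total bases of each sample's read set
    before any filtering. Profiles are emitted for every
    genome x sample combination present in either table.
    """
    counts = count_recruited(hits, min_identity=min_identity, min_aln_len=min_aln_len)
    points = linear_recruitment(hits, min_identity=linear_min_identity, min_aln_len=min_aln_len)
    profiles = []
    samples = sorted(metagenome_bp)
    for gid in sorted(genome_lengths):
        for sid in samples:
            n = counts.get((gid, sid), 0)
            profiles.append(
                RecruitmentProfile(
                    genome_id=gid,
                    sample_id=sid,
                    reads_counted=n,
                    genome_len=genome_lengths[gid],
                    metagenome_bp=metagenome_bp[sid],
                    rpkg=rpkg(n, genome_lengths[gid], metagenome_bp[sid]),
                    points=points.get((gid, sid), []),
                )
            )
    return profiles


def retain_samples(profiles: list[RecruitmentProfile], threshold: float = 5.0) -> set[str]:
    """Samples where at least one genome recruits strictly more than
    ``threshold`` RPKG."""
    retained = set()
    for p in profiles:
        if p.rpkg > threshold:
            retained.add(p.sample_id)
    return retained


def linear_recruitment(
    hits: pd.DataFrame, min_identity: float = 70.0, min_aln_len: int = 50
) -> dict[tuple[str, str], list[tuple[float, float]]]:
    """(position, identity) points per (genome, sample) for linear
    recruitment plots: one point per qualifying best-hit read at the
    midpoint of its subject interval, sorted by position. The identity
    cutoff is inclusive (a 70% cutoff admits 70.0)."""
    bh = best_hits(hits)
    ok = bh[(bh.identity >= min_identity) & (bh.aln_len >= min_aln_len)]
    out: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for (gid, sid), grp in ok.groupby(["genome_id", "sample_id"]):
        pts = sorted(
            ((float(lo + hi) / 2.0, float(ident)) for lo, hi, ident in
             zip(grp.s_lo, grp.s_hi, grp.identity))
        )
        out[(gid, sid)] = pts
    return out


def recruitment_heatmap_table(profiles: list[RecruitmentProfile]) -> pd.DataFrame:
    """Dense genomes x samples RPKG matrix, rows/columns in first-seen
    input order, zeros where a genome recruited nothing."""
    genomes: list[str] = []
    samples: list[str] = []
    for p in profiles:
        if p.genome_id not in genomes:
            genomes.append(p.genome_id)
        if p.sample_id not in samples:
            samples.append(p.sample_id)
    mat = pd.DataFrame(0.0, index=genomes, columns=samples)
    for p in profiles:
        mat.loc[p.genome_id, p.sample_id] = p.rpkg
    return mat
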
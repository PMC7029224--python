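"""Shared domain types.

Coordinates are 0-based half-open throughout the package; strands are
encoded as ``"+"`` / ``"-"``. Identities are percentages in [0, 100]
unless a field name says ``fraction``.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class Contig:
    """A metagenomic contig with its sample provenance."""

    contig_id: str
    sequence: str
    sample_id: str = "unknown"
    habitat: str = "marine"  # marine | freshwater | brackish
    fraction: str = "cellular"  # cellular | virome

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneCall:
    """One predicted gene on a genome or contig.

    ``protein`` holds the translated product; internal stop codons are
    rendered as ``X`` so the sequence stays within the amino-acid
    alphabet expected by profile searches.
    """

    gene_id: str
    genome_id: str
    start: int
    end: int
    strand: str
    protein: str = ""
    cluster_id: str | None = None


@dataclass
class HitRecord:
    """One pairwise alignment result (BLAST outfmt-6-like).

    The common currency of classification, recruitment, ANI and
    annotation stages.
    """

    query_id: str
    subject_id: str
    identity: float  # percent
    aln_len: int
    evalue: float = 0.0
    q_start: int = 0
    q_end: int = 0
    s_start: int = 0
    s_end: int = 0
    bitscore: float = 0.0


@dataclass
class MarkerHit:
    """A profile (e.g. terL) match on a contig gene."""

    contig_id: str
    gene_id: str
    score: float
    evalue: float
    marker: str = "terL"


@dataclass
class ClusterSet:
    """A collection of protein clusters (PMP-like baits or CMP-like decoys).

    ``clusters`` maps cluster_id -> list of (protein_id, sequence);
    ``representatives`` maps cluster_id -> protein_id of the centroid.
    """

    set_id: str
    clusters: dict[str, list[tuple[str, str]]]
    representatives: dict[str, str]

    def representative_seq(self, cluster_id: str) -> str:
        rep = self.representatives[cluster_id]
        for pid, seq in self.clusters[cluster_id]:
            if pid == rep:
                return seq
        raise KeyError(rep)


@dataclass
class OverlapEdge:
    """A pairwise contig overlap from the all-versus-all comparison."""

    contig_a: str
    contig_b: str
    orientation: str  # forward | reverse-complement
    identity: float  # percent, gap columns count as mismatches
    aln_len: int  # alignment columns
    gap_count: int  # gap columns
    a_start: int
    a_end: int
    b_start: int  # coords in the oriented frame of contig_b
    b_end: int


@dataclass
class Bin:
    """A connected component of the qualifying-overlap graph."""

    bin_id: str
    contig_ids: set[str]
    edges: list[OverlapEdge] = field(default_factory=list)


@dataclass
class MAVG:
    """A cross-assembled candidate phage genome."""

    mavg_id: str
    sequence: str
    path: list[tuple[str, int, int, str]]  # (contig_id, start, end, strand)
    completeness: str = "partial"  # complete | partial
    completeness_method: str = "none"  # Cu | Al | TR | none
    habitat: str = "marine"

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        from .qc import gc_content

        return gc_content(self.sequence)


@dataclass
class CompletenessCall:
    genome_id: str
    status: str  # complete | partial
    method: str  # Cu | Al | TR | none
    evidence: float  # repeat length (TR) or synteny/content score (Al)


@dataclass
class RecruitmentProfile:
    """Per-(genome, sample) read recruitment summary."""

    genome_id: str
    sample_id: str
    reads_counted: int
    genome_len: int
    metagenome_bp: float
    rpkg: float
    points: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class Operon:
    operon_id: str
    genome_id: str
    gene_ids: list[str]
    strand: str
    span: tuple[int, int]


@dataclass
class StageReport:
    """Per-stage funnel accounting (counts in/out with mean lengths)."""

    stage_name: str
    n_in: int
    n_out: int
    mean_len_in: float
    mean_len_out: float
    params_echo: dict = field(default_factory=dict)
    wallclock: float = 0.0
    warnings: list[str] = field(default_factory=list)
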
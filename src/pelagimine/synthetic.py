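"""Ground-truthed synthetic phage communities.

Generates modular ~100-180 kb myophage-like genomes (conserved syntenic
core modules separated by hypervariable regions, including one large
host-recognition cluster, HRC), shreds them into overlapping contigs,
builds bait/decoy reference protein sets, and simulates metagenome read
sets with controlled abundances — so that every downstream stage of the
mining pipeline can be exercised against known truth without any
external data.

All generators take an explicit integer seed and are byte-reproducible:
identical (params, seed) give identical output. Coordinates are 0-based
half-open; strands are "+"/"-".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Seq import Seq

from .types import Contig, GeneCall

NT = np.frombuffer(b"ACGT", dtype="S1")

#: Synthetic terminase-large-subunit-like marker protein. This is a
#: generator-invented sequence (not a natural terL), used so that marker
#: screening, profile construction and clade placement can run
#: self-contained.
MARKER_PROTEIN = (
    "KLWAHIQMSRSMDRETAIYTIPNSATNLKKHKAPVIMLEALLIIPDEIRMLEAAVLESLLAREF"
    "KRCLSGIHADLGVKEYILIFIQTQDPLGLDDKGVRNVYTKCCEHTIKIARMVFCLIQVKCVMAV"
    "LTCSVGESINSADKDVLVPIEILGVGLEGRGRKRIISHEMYSTHGKGPVLGTVRKNSGYNESVE"
    "DSKTLLEADLTEVVNPSKQNHSQIGLADEEIKNSEADKLRVKLLYDIYTLDRILINDGTSIIHA"
    "LQIGSSSLLMISYQLKQHYSKIFKNFARSESEVFLMNIRECYAIADTYDKPAEFYEPEPHEDDD"
    "ENVKEAYEAMLSPSFSGDHGADLLMAGRRQEKDVTPLLIQEVRWDLRPTAELHPARIEFVILND"
)

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

# aa -> synonymous codons (standard table, stops excluded; X maps to a
# pool of non-stop codons so translated-back sequences stay in-frame).
_CODONS: dict[str, list[str]] = {}
for _c in (
    a + b + c
    for a in "TCAG"
    for b in "TCAG"
    for c in "TCAG"
):
    _aa = str(Seq(_c).translate())
    if _aa != "*":
        _CODONS.setdefault(_aa, []).append(_c)
_CODONS["X"] = [c for v in _CODONS.values() for c in v]


# ---------------------------------------------------------------------------
# truth records


@dataclass
class GenomeTruth:
    """Everything known about one simulated genome."""

    genome_id: str
    sequence: str
    module_layout: list[tuple[str, int, int, str]]  # (name, start, end, class)
    gene_truth: list[GeneCall]
    terminators: list[tuple[int, str]]
    terminal_repeat_len: int
    gc_target: float
    habitat: str = "marine"

    def __len__(self) -> int:
        return len(self.sequence)

    def genes_in_class(self, cls: str) -> list[GeneCall]:
        out = []
        for name, start, end, mcls in self.module_layout:
            if mcls != cls:
                continue
            out.extend(g for g in self.gene_truth if start <= g.start and g.end <= end)
        return out


@dataclass
class ShredTruth:
    contig_id: str
    source_genome: str
    source_interval: tuple[int, int]
    mutations_applied: int
    sample_id: str


@dataclass
class ReadTruth:
    read_id: str
    source: str
    start: int
    end: int
    strand: str
    mutations_applied: int


@dataclass
class GenomeParams:
    """Tunable knobs of the genome generator.

    ``module_layout`` gives (name, class, fraction-of-genome) triples;
    classes are core_structural / core_replication / HRC / hypervariable.
    Core modules use a homopolymer-leaning dinucleotide bias, the HRC an
    alternating one, so the two kinds of region are statistically
    distinguishable while the marginal GC stays exactly on target.
    """

    length: int = 140_000
    gc: float = 0.33
    module_layout: tuple[tuple[str, str, float], ...] = (
        ("structural", "core_structural", 0.32),
        ("hrc", "HRC", 0.24),
        ("replication", "core_replication", 0.28),
        ("island", "hypervariable", 0.16),
    )
    gene_len_range: tuple[int, int] = (300, 1200)  # nt, multiples of 3 drawn inside
    igs_range: tuple[int, int] = (5, 45)
    operon_size_range: tuple[int, int] = (2, 7)
    terminator_prob: float = 0.85  # after each same-strand block
    terminal_repeat: int = 0
    marker_protein: str | None = MARKER_PROTEIN
    marker_module: str = "replication"
    cluster_prefix: str = "PC"
    habitat: str = "marine"
    planted_proteins: tuple[tuple[str, str, str], ...] = ()  # (module, cluster_id, protein)

    def validate(self) -> None:
        min_budget = 3000 * len(self.module_layout)
        if self.length < min_budget:
            raise ValueError(
                f"genome length {self.length} below minimum module budget {min_budget}"
            )
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc target must be in (0, 1)")
        if abs(sum(f for _, _, f in self.module_layout) - 1.0) > 1e-6:
            raise ValueError("module fractions must sum to 1")


# ---------------------------------------------------------------------------
# low-level sequence machinery


def _markov_sequence(length: int, gc: float, cls: str, rng: np.random.Generator) -> str:
    """Module sequence with class-specific dinucleotide bias.

    Each position's GC-vs-AT group is drawn i.i.d. at the target GC, so
    the marginal GC is exact in expectation regardless of class; only the
    within-group letter choice depends on the previous letter.
    """
    groups = rng.random(length) < gc  # True -> G/C
    coin = rng.random(length)
    if cls.startswith("core"):
        p_same = 0.72  # homopolymer-leaning
    elif cls == "HRC":
        p_same = 0.28  # alternation-leaning
    else:
        p_same = 0.5
    out = np.empty(length, dtype="S1")
    prev = b"A"
    pairs = {True: (b"G", b"C"), False: (b"A", b"T")}
    for i in range(length):
        first, second = pairs[bool(groups[i])]
        if prev in (first, second):
            same = coin[i] < p_same
            out[i] = prev if same else (second if prev == first else first)
        else:
            out[i] = first if coin[i] < 0.5 else second
        prev = out[i]
    return out.tobytes().decode()


def mutate_sequence(
    seq: str, rate: float, rng: np.random.Generator, gc: float | None = None
) -> tuple[str, int]:
    """Apply i.i.d. substitutions. Returns (sequence, n substitutions).

    With ``gc`` unset, each hit is replaced by one of the other three
    bases uniformly. Given a ``gc`` target, replacements balance the
    GC<->AT fluxes (a G/C base leaves its group with probability 1-gc,
    an A/T base with probability gc), so the base composition stays
    stationary at the target even under heavy mutation.
    """
    if rate <= 0 or not seq:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    sibling = {b"A": b"T", b"T": b"A", b"G": b"C", b"C": b"G"}
    for i in hits:
        cur = arr[i]
        if gc is None:
            choices = NT[NT != cur]
            arr[i] = choices[rng.integers(len(choices))]
            continue
        in_gc = cur in (b"G", b"C")
        p_leave = (1.0 - gc) if in_gc else gc
        if rng.random() < p_leave:
            other = (b"A", b"T") if in_gc else (b"G", b"C")
            arr[i] = other[rng.integers(2)]
        else:
            arr[i] = sibling[bytes(cur)]
    return arr.tobytes().decode(), len(hits)


def mutate_protein(protein: str, rate: float, rng: np.random.Generator) -> str:
    chars = list(protein)
    for i in range(len(chars)):
        if rng.random() < rate:
            alt = _AA20.replace(chars[i], "") if chars[i] in _AA20 else _AA20
            chars[i] = alt[rng.integers(len(alt))]
    return "".join(chars)


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(_CODONS[aa][rng.integers(len(_CODONS[aa]))] if aa in _CODONS else "NNN"
                   for aa in protein)


def translate_region(sequence: str, start: int, end: int, strand: str) -> str:
    """Translated product of a gene interval; internal stops become X."""
    sub = sequence[start:end]
    if strand == "-":
        sub = str(Seq(sub).reverse_complement())
    sub = sub[: len(sub) - len(sub) % 3]
    return str(Seq(sub).translate()).replace("*", "X")


# ---------------------------------------------------------------------------
# genome generation


def generate_phage_genome(
    params: GenomeParams, seed: int, genome_id: str = "genome"
) -> tuple[str, GenomeTruth]:
    """Simulate one modular phage genome.

    The backbone is a module-wise Markov sequence at the target GC; gene
    coordinates are an annotation overlay on that backbone (proteins are
    its translation), except for planted genes — the marker and any
    imported genes — whose reverse-translated coding sequence is written
    into the backbone so profile searches find a real signal.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    L = params.length

    # module boundaries
    bounds = [0]
    for _, _, frac in params.module_layout[:-1]:
        bounds.append(bounds[-1] + int(round(frac * L)))
    bounds.append(L)
    layout = [
        (name, bounds[i], bounds[i + 1], cls)
        for i, (name, cls, _) in enumerate(params.module_layout)
    ]

    seq_parts = [
        _markov_sequence(end - start, params.gc, cls, rng) for (_, start, end, cls) in layout
    ]
    seq = list("".join(seq_parts))

    planted: dict[str, list[tuple[str, str]]] = {}
    if params.marker_protein:
        planted.setdefault(params.marker_module, []).append(
            (f"{params.cluster_prefix}_terL", params.marker_protein)
        )
    for module, cid, prot in params.planted_proteins:
        planted.setdefault(module, []).append((cid, prot))

    genes: list[GeneCall] = []
    terminators: list[tuple[int, str]] = []
    glo, ghi = params.gene_len_range
    ilo, ihi = params.igs_range

    for name, mstart, mend, cls in layout:
        pos = mstart + int(rng.integers(ilo, ihi))
        idx = 0
        # planted genes first, on the forward strand
        for cid, prot in planted.get(name, ()):
            glen = 3 * len(prot)
            if pos + glen >= mend:
                raise ValueError(f"module {name} too small for planted gene {cid}")
            nt = reverse_translate(prot, rng)
            seq[pos : pos + glen] = list(nt)
            genes.append(
                GeneCall(
                    gene_id=f"{genome_id}|g{len(genes):04d}",
                    genome_id=genome_id,
                    start=pos,
                    end=pos + glen,
                    strand="+",
                    cluster_id=cid,
                )
            )
            pos += glen + int(rng.integers(ilo, ihi))
        # random operon blocks
        strand = "+" if rng.random() < 0.5 else "-"
        while True:
            block = int(rng.integers(params.operon_size_range[0], params.operon_size_range[1] + 1))
            placed = 0
            for _ in range(block):
                glen = 3 * int(rng.integers(glo // 3, ghi // 3 + 1))
                if pos + glen > mend:
                    break
                genes.append(
                    GeneCall(
                        gene_id=f"{genome_id}|g{len(genes):04d}",
                        genome_id=genome_id,
                        start=pos,
                        end=pos + glen,
                        strand=strand,
                        cluster_id=f"{params.cluster_prefix}_{name}_{idx:03d}",
                    )
                )
                idx += 1
                placed += 1
                pos += glen + int(rng.integers(ilo, ihi))
            if placed == 0:
                break
            # block boundary: terminator and/or strand flip
            if rng.random() < params.terminator_prob:
                terminators.append((pos - int(rng.integers(1, max(2, ilo))), strand))
            if rng.random() < 0.5:
                strand = "+" if strand == "-" else "-"
            if pos + glo > mend:
                break

    if params.terminal_repeat > 0:
        tr = params.terminal_repeat
        if tr * 4 > L:
            raise ValueError("terminal repeat too long for genome")
        seq[-tr:] = seq[:tr]

    sequence = "".join(seq)
    for g in genes:
        g.protein = translate_region(sequence, g.start, g.end, g.strand)

    truth = GenomeTruth(
        genome_id=genome_id,
        sequence=sequence,
        module_layout=layout,
        gene_truth=genes,
        terminators=sorted(terminators),
        terminal_repeat_len=params.terminal_repeat,
        gc_target=params.gc,
        habitat=params.habitat,
    )
    return sequence, truth


def evolve_member(
    ancestor: GenomeTruth,
    genome_id: str,
    seed: int,
    core_sub: float = 0.02,
    hv_sub: float = 0.15,
    replace_hrc: bool = False,
    private_hv_ids: bool | None = None,
    habitat: str | None = None,
) -> GenomeTruth:
    """Derive a family member from an ancestor genome.

    Core modules are mutated at ``core_sub``; HRC and hypervariable
    modules at ``hv_sub`` (or regenerated wholesale if ``replace_hrc``).
    Gene coordinates are preserved (substitutions only) so orthology
    truth carries over; genes in hypervariable modules receive
    genome-private cluster ids when they have diverged enough that no
    cross-genome clustering should group them (``private_hv_ids``,
    default: automatic at hv_sub >= 0.08 or on replacement).
    """
    rng = np.random.default_rng(seed)
    if private_hv_ids is None:
        private_hv_ids = replace_hrc or hv_sub >= 0.08

    pieces: list[str] = []
    for name, start, end, cls in ancestor.module_layout:
        part = ancestor.sequence[start:end]
        if cls in ("HRC", "hypervariable"):
            if replace_hrc and cls == "HRC":
                part = _markov_sequence(end - start, ancestor.gc_target, cls, rng)
            else:
                part, _ = mutate_sequence(part, hv_sub, rng, gc=ancestor.gc_target)
        else:
            part, _ = mutate_sequence(part, core_sub, rng, gc=ancestor.gc_target)
        pieces.append(part)
    seq = list("".join(pieces))
    if ancestor.terminal_repeat_len > 0:
        tr = ancestor.terminal_repeat_len
        seq[-tr:] = seq[:tr]
    sequence = "".join(seq)

    hv_spans = [
        (start, end)
        for _, start, end, cls in ancestor.module_layout
        if cls in ("HRC", "hypervariable")
    ]

    genes = []
    for g in ancestor.gene_truth:
        cid = g.cluster_id
        in_hv = any(s <= g.start and g.end <= e for s, e in hv_spans)
        if in_hv and private_hv_ids:
            cid = f"{cid}@{genome_id}"
        genes.append(
            GeneCall(
                gene_id=f"{genome_id}|{g.gene_id.split('|')[-1]}",
                genome_id=genome_id,
                start=g.start,
                end=g.end,
                strand=g.strand,
                protein=translate_region(sequence, g.start, g.end, g.strand),
                cluster_id=cid,
            )
        )

    return GenomeTruth(
        genome_id=genome_id,
        sequence=sequence,
        module_layout=list(ancestor.module_layout),
        gene_truth=genes,
        terminators=list(ancestor.terminators),
        terminal_repeat_len=ancestor.terminal_repeat_len,
        gc_target=ancestor.gc_target,
        habitat=habitat or ancestor.habitat,
    )


# ---------------------------------------------------------------------------
# shredding


def shred_genome(
    genome: str,
    n_contigs: int,
    overlap_len: int,
    sub_rate: float,
    seed: int,
    source_genome: str = "genome",
    id_prefix: str | None = None,
    sample_id: str = "sample1",
    habitat: str = "marine",
    fraction: str = "cellular",
) -> tuple[list[Contig], list[ShredTruth]]:
    """Cut a genome into ``n_contigs`` consecutive shreds.

    Consecutive shreds overlap by exactly ``overlap_len`` nt before
    mutation and their union covers the genome. Substitutions are applied
    i.i.d. at ``sub_rate`` independently per shred, so an overlap of
    length c between two shreds carries ~Binomial(c, 2*sub_rate*(1-eps))
    mismatches.
    """
    L = len(genome)
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    if n_contigs > 1 and overlap_len >= L / n_contigs:
        raise ValueError("overlap_len too large for requested tiling")
    rng = np.random.default_rng(seed)
    prefix = id_prefix or f"{source_genome}.ctg"
    bounds = [int(round(i * L / n_contigs)) for i in range(n_contigs + 1)]
    contigs, truths = [], []
    for i in range(n_contigs):
        start = max(0, bounds[i] - (overlap_len if i > 0 else 0))
        end = bounds[i + 1]
        piece, n_mut = mutate_sequence(genome[start:end], sub_rate, rng)
        cid = f"{prefix}{i:02d}"
        contigs.append(
            Contig(contig_id=cid, sequence=piece, sample_id=sample_id, habitat=habitat,
                   fraction=fraction)
        )
        truths.append(ShredTruth(cid, source_genome, (start, end), n_mut, sample_id))
    return contigs, truths


# ---------------------------------------------------------------------------
# reference protein sets


def generate_reference_sets(
    n_pmp_clusters: int,
    n_cmp_clusters: int,
    shared_fraction: float,
    seed: int,
    members_per_cluster: tuple[int, int] = (2, 5),
    member_divergence: float = 0.05,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], dict[str, str]]:
    """Two protein collections with a controlled shared overlap.

    Exactly ``round(shared_fraction * min(n_pmp, n_cmp))`` cluster pairs
    are near-identical across the two sets (1% divergence between their
    base proteins); everything else is independent random protein.
    Returns (pmp_records, cmp_records, truth) where records are
    (protein_id, sequence) and truth maps protein_id -> cluster_id.
    """
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_shared = int(round(shared_fraction * min(n_pmp_clusters, n_cmp_clusters)))

    def random_protein() -> str:
        n = int(rng.integers(150, 450))
        return "".join(_AA20[i] for i in rng.integers(0, 20, size=n))

    truth: dict[str, str] = {}

    def emit(set_id: str, cluster_idx: int, base: str) -> list[tuple[str, str]]:
        cid = f"{set_id}_c{cluster_idx:03d}"
        n_members = int(rng.integers(members_per_cluster[0], members_per_cluster[1] + 1))
        recs = []
        for m in range(n_members):
            prot = base if m == 0 else mutate_protein(base, member_divergence, rng)
            pid = f"{cid}|p{m}"
            truth[pid] = cid
            recs.append((pid, prot))
        return recs

    pmp_bases = [random_protein() for _ in range(n_pmp_clusters)]
    cmp_bases = [
        mutate_protein(pmp_bases[i], 0.01, rng) if i < n_shared else random_protein()
        for i in range(n_cmp_clusters)
    ]
    pmp = [r for i, b in enumerate(pmp_bases) for r in emit("PMP", i, b)]
    cmp_ = [r for i, b in enumerate(cmp_bases) for r in emit("CMP", i, b)]
    return pmp, cmp_, truth


# ---------------------------------------------------------------------------
# reads


def generate_reads(
    genomes_with_abundance: list[tuple[str, float]],
    n_reads: int,
    read_len: int,
    sub_rate: float,
    seed: int,
    labels: list[str] | None = None,
    rc_fraction: float = 0.5,
    id_prefix: str = "read",
) -> tuple[list[tuple[str, str]], list[ReadTruth]]:
    """Simulate a metagenome read set.

    Per-genome read counts are multinomial with probabilities
    proportional to weight x genome length (a fixed sequencing depth
    samples long genomes more often at equal molar abundance).
    """
    seqs = [s for s, _ in genomes_with_abundance]
    weights = np.array([w for _, w in genomes_with_abundance], dtype=float)
    if min(len(s) for s in seqs) < read_len:
        raise ValueError("read_len exceeds shortest genome")
    if labels is None:
        labels = [f"g{i}" for i in range(len(seqs))]
    rng = np.random.default_rng(seed)
    p = weights * np.array([len(s) for s in seqs], dtype=float)
    if p.sum() <= 0:
        raise ValueError("all abundance weights are zero")
    p = p / p.sum()
    counts = rng.multinomial(n_reads, p)

    from .align import revcomp

    reads, truths = [], []
    ridx = 0
    for gi, (seq, cnt) in enumerate(zip(seqs, counts)):
        starts = rng.integers(0, len(seq) - read_len + 1, size=cnt)
        flips = rng.random(cnt) < rc_fraction
        for start, flip in zip(starts, flips):
            start = int(start)
            piece, n_mut = mutate_sequence(seq[start : start + read_len], sub_rate, rng)
            strand = "+"
            if flip:
                piece, strand = revcomp(piece), "-"
            rid = f"{id_prefix}{ridx:06d}"
            reads.append((rid, piece))
            truths.append(ReadTruth(rid, labels[gi], start, start + read_len, strand, n_mut))
            ridx += 1
    return reads, truths


# ---------------------------------------------------------------------------
# full community


@dataclass
class Community:
    """A complete synthetic study: contigs + annotations + references."""

    contigs: list[Contig]
    contig_genes: dict[str, list[GeneCall]]
    shred_truth: list[ShredTruth]
    targets: list[GenomeTruth]  # the PMP-like genomes to be recovered
    decoys: list[GenomeTruth]  # CMP-like genomes that must be excluded
    pmp_refs: list[GenomeTruth]
    cmp_refs: list[GenomeTruth]
    marker_refs_in: list[tuple[str, str]]  # (label, protein) in-group terL
    marker_refs_out: list[tuple[str, str]]
    params: dict = field(default_factory=dict)

    @property
    def pmp_ref_proteins(self) -> list[tuple[str, str]]:
        return [(g.gene_id, g.protein) for t in self.pmp_refs for g in t.gene_truth]

    @property
    def cmp_ref_proteins(self) -> list[tuple[str, str]]:
        return [(g.gene_id, g.protein) for t in self.cmp_refs for g in t.gene_truth]


def _clip_genes(truth: GenomeTruth, contig: Contig, interval: tuple[int, int]) -> list[GeneCall]:
    """Gene calls fully contained in a shred, re-based onto the contig.

    Proteins are translated from the contig sequence itself so that
    shred-level mutations propagate into the predicted proteome.
    """
    start, end = interval
    out = []
    for g in truth.gene_truth:
        if g.start >= start and g.end <= end:
            gs, ge = g.start - start, g.end - start
            out.append(
                GeneCall(
                    gene_id=f"{contig.contig_id}|{g.gene_id.split('|')[-1]}",
                    genome_id=contig.contig_id,
                    start=gs,
                    end=ge,
                    strand=g.strand,
                    protein=translate_region(contig.sequence, gs, ge, g.strand),
                    cluster_id=g.cluster_id,
                )
            )
    return out


def generate_community(
    seed: int,
    n_targets: int = 3,
    n_decoys: int = 3,
    n_background: int = 200,
    n_refs: int = 4,
    genome_len: int = 140_000,
    gc: float = 0.33,
    shred_sub_rate: float = 0.002,
    overlap_len: int = 2000,
    tilings: tuple[int, ...] = (4, 5),
    core_sub: float = 0.02,
    hv_sub: float = 0.15,
    ref_core_sub: float = 0.04,
    ref_hv_sub: float = 0.18,
    n_imported_genes: int = 5,
    decoy_marker_divergence: float = 0.3,
    terminal_repeat: int = 15,
) -> Community:
    """Simulate the full study design.

    Two phage families descend from independent ancestors: a PMP-like
    in-group (targets + bait references) and a CMP-like out-group
    (decoys + decoy references). The out-group carries a diverged copy
    of the marker gene plus a handful of imported in-group core genes,
    so the shared-cluster removal and exclusion classification steps
    have real work to do. Targets and decoys are shredded into two
    staggered overlapping tilings (default 4 + 5 contigs per genome)
    so that every assembly junction is corroborated by a third contig.

    References are drawn at a higher divergence from the family ancestor
    than the targets, so that target markers fall inside the reference
    radiation on the marker tree (the reference clade encloses them),
    mirroring how baits bracket the diversity they are meant to recover.
    """
    rng = np.random.default_rng(seed)

    def sub_seed() -> int:
        return int(rng.integers(2**31 - 1))

    pmp_params = GenomeParams(length=genome_len, gc=gc, terminal_repeat=terminal_repeat)
    _, pmp_anc = generate_phage_genome(pmp_params, sub_seed(), genome_id="pmp_anc")

    # out-group ancestor: distinct gene content except a diverged marker
    # and a few near-identical imported core genes
    cmp_marker = mutate_protein(MARKER_PROTEIN, decoy_marker_divergence, rng)
    core_genes = [
        g for g in pmp_anc.genes_in_class("core_structural") if g.cluster_id != "PC_terL"
    ]
    imported = tuple(
        ("structural", f"CPC_imp_{i:02d}", mutate_protein(core_genes[i].protein, 0.02, rng))
        for i in range(min(n_imported_genes, len(core_genes)))
    )
    cmp_params = replace(
        pmp_params,
        marker_protein=cmp_marker,
        cluster_prefix="CPC",
        planted_proteins=imported,
        terminal_repeat=0,
    )
    _, cmp_anc = generate_phage_genome(cmp_params, sub_seed(), genome_id="cmp_anc")

    pmp_refs = [
        evolve_member(pmp_anc, f"pmp_ref{i}", sub_seed(), ref_core_sub, ref_hv_sub)
        for i in range(n_refs)
    ]
    cmp_refs = [
        evolve_member(cmp_anc, f"cmp_ref{i}", sub_seed(), ref_core_sub, ref_hv_sub)
        for i in range(n_refs)
    ]
    targets = [
        evolve_member(pmp_anc, f"pmp_t{i}", sub_seed(), core_sub, hv_sub)
        for i in range(n_targets)
    ]
    decoys = [
        evolve_member(cmp_anc, f"cmp_d{i}", sub_seed(), core_sub, hv_sub)
        for i in range(n_decoys)
    ]

    contigs: list[Contig] = []
    contig_genes: dict[str, list[GeneCall]] = {}
    shred_truth: list[ShredTruth] = []
    for truth in targets + decoys:
        for t_i, n_c in enumerate(tilings):
            sample = f"samp_{truth.genome_id}_{t_i}"
            shreds, struths = shred_genome(
                truth.sequence,
                n_contigs=n_c,
                overlap_len=overlap_len,
                sub_rate=shred_sub_rate,
                seed=sub_seed(),
                source_genome=truth.genome_id,
                id_prefix=f"{truth.genome_id}.t{t_i}c",
                sample_id=sample,
                habitat=truth.habitat,
            )
            contigs.extend(shreds)
            shred_truth.extend(struths)
            for c, st in zip(shreds, struths):
                contig_genes[c.contig_id] = _clip_genes(truth, c, st.source_interval)

    for b in range(n_background):
        blen = int(rng.integers(1000, 8000))
        bases = rng.integers(0, 4, size=blen)
        contigs.append(
            Contig(
                contig_id=f"bg{b:04d}",
                sequence="".join("ACGT"[i] for i in bases),
                sample_id=f"samp_bg{b % 5}",
                habitat="marine",
            )
        )

    def marker_of(truth: GenomeTruth) -> str:
        for g in truth.gene_truth:
            if g.cluster_id and g.cluster_id.endswith("_terL"):
                return g.protein
        raise RuntimeError("no marker gene in genome")

    return Community(
        contigs=contigs,
        contig_genes=contig_genes,
        shred_truth=shred_truth,
        targets=targets,
        decoys=decoys,
        pmp_refs=pmp_refs,
        cmp_refs=cmp_refs,
        marker_refs_in=[(t.genome_id + "|terL", marker_of(t)) for t in pmp_refs],
        marker_refs_out=[(t.genome_id + "|terL", marker_of(t)) for t in cmp_refs],
        params=dict(
            seed=seed,
            n_targets=n_targets,
            n_decoys=n_decoys,
            n_background=n_background,
            genome_len=genome_len,
            gc=gc,
            shred_sub_rate=shred_sub_rate,
            overlap_len=overlap_len,
            tilings=list(tilings),
        ),
    )
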
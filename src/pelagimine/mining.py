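"""Marker-gene candidate discovery and dual-reference exclusion classification.

The mining stage answers one question per contig: does it come from the
phage group of interest? It proceeds in three steps:

1. screen contigs longer than 5 kb for a terminase (terL) marker with a
   protein profile (HMM);
2. place candidate markers on a distance tree together with labelled
   in-group and out-group reference markers, and keep candidates falling
   in the smallest clade that contains every in-group reference and no
   out-group reference;
3. classify contigs against two reference protein-cluster collections —
   in-group baits and out-group decoys, with shared clusters removed —
   keeping a contig only if it matches at least one bait cluster and no
   decoy cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pyhmmer
from skbio import DistanceMatrix
from skbio.tree import nj

from .align import global_alignment_stats
from .types import ClusterSet, Contig, GeneCall, MarkerHit

logger = logging.getLogger(__name__)

_AMINO = pyhmmer.easel.Alphabet.amino()


def _name(x) -> str:
    return x.decode() if isinstance(x, bytes) else str(x)


def _digital(records: list[tuple[str, str]]) -> list:
    return [
        pyhmmer.easel.TextSequence(name=name.encode(), sequence=seq).digitize(_AMINO)
        for name, seq in records
    ]


def build_marker_profile(records: list[tuple[str, str]], name: str = "terL"):
    """Build a protein profile HMM from marker sequences.

    Sequences of equal length are treated as a trivially aligned MSA
    (the synthetic generator emits substitution-only marker variants);
    otherwise the profile is built from the first sequence alone and a
    pre-aligned input should be preferred.
    """
    if not records:
        raise ValueError("cannot build a profile from an empty sequence set")
    builder = pyhmmer.plan7.Builder(_AMINO)
    background = pyhmmer.plan7.Background(_AMINO)
    lengths = {len(s) for _, s in records}
    if len(lengths) == 1 and len(records) > 1:
        seqs = [
            pyhmmer.easel.TextSequence(name=n.encode(), sequence=s) for n, s in records
        ]
        msa = pyhmmer.easel.TextMSA(name=name.encode(), sequences=seqs).digitize(_AMINO)
        hmm, _, _ = builder.build_msa(msa, background)
    else:
        if len(records) > 1:
            logger.warning(
                "marker sequences have unequal lengths; building profile from %s only",
                records[0][0],
            )
        hmm, _, _ = builder.build(_digital(records[:1])[0], background)
    return hmm


def screen_marker_contigs(
    contigs: list[Contig],
    gene_calls: dict[str, list[GeneCall]],
    marker_profile,
    min_contig_len: int = 5000,
    max_evalue: float = 1e-5,
) -> list[MarkerHit]:
    """Profile-screen genes of contigs longer than ``min_contig_len``.

    Returns one best hit per gene with E <= ``max_evalue``, sorted by
    bit score descending. Contigs without gene calls are skipped with a
    logged warning.
    """
    if marker_profile is None:
        raise ValueError("marker profile is required")
    long_enough = [c for c in contigs if len(c.sequence) > min_contig_len]
    gene_owner: dict[str, str] = {}
    records: list[tuple[str, str]] = []
    for contig in long_enough:
        calls = gene_calls.get(contig.contig_id)
        if not calls:
            logger.warning("contig %s has no gene calls; skipped", contig.contig_id)
            continue
        for g in calls:
            if g.protein:
                gene_owner[g.gene_id] = contig.contig_id
                records.append((g.gene_id, g.protein))
    if not records:
        return []
    hits: list[MarkerHit] = []
    marker_name = _name(marker_profile.name or "marker")
    for tophits in pyhmmer.hmmer.hmmsearch([marker_profile], _digital(records), cpus=1):
        for h in tophits:
            if h.evalue <= max_evalue:
                gid = _name(h.name)
                hits.append(
                    MarkerHit(
                        contig_id=gene_owner[gid],
                        gene_id=gid,
                        score=float(h.score),
                        evalue=float(h.evalue),
                        marker=marker_name,
                    )
                )
    hits.sort(key=lambda m: (-m.score, m.gene_id))
    return hits


# ---------------------------------------------------------------------------
# marker clade selection


def _protein_distance(a: str, b: str) -> float:
    """1 - fraction of identical columns of a global pairwise alignment."""
    stats = global_alignment_stats(a, b)
    return 1.0 - stats.matches / stats.columns if stats.columns else 1.0


@dataclass
class CladeSelection:
    selected: list[str]
    in_group_monophyletic: bool
    intrusions: list[str] = field(default_factory=list)


def select_by_marker_clade(
    candidates: list[tuple[str, str]],
    references_in: list[tuple[str, str]],
    references_out: list[tuple[str, str]],
) -> CladeSelection:
    """Keep candidates in the reference marker clade.

    Builds a neighbor-joining tree from pairwise protein distances and
    searches every bipartition of the (unrooted) tree for the smallest
    side that contains all in-group references and excludes all
    out-group references; candidates on that side are selected. If the
    in-group is not separable, the smallest side containing all
    in-group references is used and out-group intrusions are reported.
    """
    labelled = (
        [(f"cand:{n}", s) for n, s in candidates]
        + [(f"in:{n}", s) for n, s in references_in]
        + [(f"out:{n}", s) for n, s in references_out]
    )
    if len(labelled) < 4:
        raise ValueError("need at least 4 sequences for an unrooted tree")
    if not references_in or not references_out:
        raise ValueError("both in-group and out-group references are required")
    labelled.sort(key=lambda r: r[0])
    names = [n for n, _ in labelled]
    seqs = {n: s for n, s in labelled}
    n = len(names)
    mat = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d = _protein_distance(seqs[names[i]], seqs[names[j]])
            mat[i][j] = mat[j][i] = d
    tree = nj(DistanceMatrix(mat, ids=names))

    all_tips = frozenset(names)
    in_refs = {x for x in names if x.startswith("in:")}
    out_refs = {x for x in names if x.startswith("out:")}

    sides: set[frozenset] = set()
    for node in tree.traverse(include_self=False):
        tips = frozenset(t.name for t in node.tips()) or frozenset([node.name])
        sides.add(tips)
        sides.add(all_tips - tips)

    def pick(require_no_out: bool) -> frozenset | None:
        ok = [
            s
            for s in sides
            if in_refs <= s and (not require_no_out or not (out_refs & s))
        ]
        if not ok:
            return None
        return min(ok, key=lambda s: (len(s), sorted(s)))

    clade = pick(require_no_out=True)
    monophyletic = clade is not None
    if clade is None:
        clade = pick(require_no_out=False) or all_tips
    selected = sorted(x[5:] for x in clade if x.startswith("cand:"))
    intrusions = sorted(x[4:] for x in clade if x.startswith("out:"))
    return CladeSelection(selected, monophyletic, intrusions)


# ---------------------------------------------------------------------------
# protein cluster collections


def _identity_fraction(a: str, b: str) -> float:
    stats = global_alignment_stats(a, b)
    return stats.matches / stats.columns if stats.columns else 0.0


def cluster_proteins(
    records: list[tuple[str, str]],
    set_id: str,
    min_identity: float = 0.35,
    min_coverage: float = 0.7,
) -> ClusterSet:
    """Greedy centroid clustering, longest sequence first.

    A protein joins the first existing cluster whose representative it
    matches at >= ``min_identity`` global identity with a length ratio
    >= ``min_coverage``; otherwise it founds a new cluster and becomes
    its representative. Every protein lands in exactly one cluster.
    """
    if not records:
        raise ValueError(f"empty protein set for {set_id}")
    ordered = sorted(records, key=lambda r: (-len(r[1]), r[0]))
    clusters: dict[str, list[tuple[str, str]]] = {}
    reps: dict[str, str] = {}
    rep_seqs: list[tuple[str, str]] = []  # (cluster_id, seq), insertion order
    for pid, seq in ordered:
        assigned = None
        for cid, rep_seq in rep_seqs:
            short, long_ = sorted((len(seq), len(rep_seq)))
            if long_ == 0 or short / long_ < min_coverage:
                continue
            if _identity_fraction(seq, rep_seq) >= min_identity:
                assigned = cid
                break
        if assigned is None:
            cid = f"{set_id}_{len(rep_seqs):04d}"
            clusters[cid] = [(pid, seq)]
            reps[cid] = pid
            rep_seqs.append((cid, seq))
        else:
            clusters[assigned].append((pid, seq))
    return ClusterSet(set_id=set_id, clusters=clusters, representatives=reps)


def build_cluster_sets(
    pmp_proteins: list[tuple[str, str]],
    cmp_proteins: list[tuple[str, str]],
    min_identity: float = 0.35,
    min_coverage: float = 0.7,
) -> tuple[ClusterSet, ClusterSet]:
    """Cluster the bait (PMP) and decoy (CMP) protein collections."""
    pmp = cluster_proteins(pmp_proteins, "PMP", min_identity, min_coverage)
    cmp_ = cluster_proteins(cmp_proteins, "CMP", min_identity, min_coverage)
    return pmp, cmp_


def remove_shared_clusters(
    pmp: ClusterSet,
    cmp_: ClusterSet,
    share_identity: float = 0.5,
    min_coverage: float = 0.7,
) -> tuple[ClusterSet, ClusterSet, list[tuple[str, str]]]:
    """Drop clusters present in both collections.

    Two clusters are shared when their representatives align globally at
    >= ``share_identity`` identity with a length ratio >= ``min_coverage``.
    Shared clusters are removed from both outputs.
    """
    shared: list[tuple[str, str]] = []
    pmp_shared: set[str] = set()
    cmp_shared: set[str] = set()
    for pc, prew in ((c, pmp.representative_seq(c)) for c in sorted(pmp.clusters)):
        for cc in sorted(cmp_.clusters):
            crew = cmp_.representative_seq(cc)
            short, long_ = sorted((len(prew), len(crew)))
            if long_ == 0 or short / long_ < min_coverage:
                continue
            if _identity_fraction(prew, crew) >= share_identity:
                shared.append((pc, cc))
                pmp_shared.add(pc)
                cmp_shared.add(cc)
    pmp_unique = ClusterSet(
        set_id=pmp.set_id,
        clusters={c: m for c, m in pmp.clusters.items() if c not in pmp_shared},
        representatives={c: r for c, r in pmp.representatives.items() if c not in pmp_shared},
    )
    cmp_unique = ClusterSet(
        set_id=cmp_.set_id,
        clusters={c: m for c, m in cmp_.clusters.items() if c not in cmp_shared},
        representatives={c: r for c, r in cmp_.representatives.items() if c not in cmp_shared},
    )
    return pmp_unique, cmp_unique, shared


# ---------------------------------------------------------------------------
# exclusion classification


@dataclass
class HitRules:
    """What counts as a match to a reference cluster."""

    max_evalue: float = 1e-5
    len_window: tuple[float, float] = (0.7, 1.3)  # aligned fraction of query length


@dataclass
class ClassifyDecision:
    contig_id: str
    decision: str  # keep | discard
    n_pmp_hits: int
    n_cmp_hits: int
    reason: str
    evidence: list[tuple[str, str, str, float]] = field(default_factory=list)
    # evidence rows: (gene_id, set_id, cluster_id, evalue)


def _cluster_matches(
    queries: list[tuple[str, str]], cset: ClusterSet, rules: HitRules
) -> list[tuple[str, str, float]]:
    """Match gene proteins against cluster representatives with phmmer.

    The representatives are used as the profile side of the search (one
    profile per cluster, searched against all gene proteins at once),
    which is much cheaper than profiling every gene. The E-value and
    length-window rules are evaluated per gene protein: the aligned span
    on the gene must cover 70-130% of its length.

    Returns (gene_id, cluster_id, evalue) for each passing pair.
    """
    rep_records = [
        (cid, cset.representative_seq(cid)) for cid in sorted(cset.clusters)
    ]
    if not rep_records or not queries:
        return []
    qlen = {name: len(seq) for name, seq in queries}
    out: list[tuple[str, str, float]] = []
    targets = _digital(queries)
    lo, hi = rules.len_window
    for tophits in pyhmmer.hmmer.phmmer(_digital(rep_records), targets, cpus=1):
        cid = _name(tophits.query.name)
        for h in tophits:
            if h.evalue > rules.max_evalue:
                continue
            d = h.best_domain.alignment
            aln_len = d.target_to - d.target_from + 1  # span on the gene protein
            gene = _name(h.name)
            if not (lo <= aln_len / qlen[gene] <= hi):
                continue
            out.append((gene, cid, float(h.evalue)))
    return out


def classify_candidates(
    contig_proteins: dict[str, list[tuple[str, str]]],
    pmp_unique: ClusterSet,
    cmp_unique: ClusterSet,
    hit_rules: HitRules | None = None,
) -> dict[str, ClassifyDecision]:
    """Keep a contig iff it matches >= 1 bait cluster and 0 decoy clusters."""
    rules = hit_rules or HitRules()
    all_queries: list[tuple[str, str]] = []
    owner: dict[str, str] = {}
    for contig_id, prots in contig_proteins.items():
        for gid, seq in prots:
            owner[gid] = contig_id
            all_queries.append((gid, seq))

    pmp_hits = _cluster_matches(all_queries, pmp_unique, rules) if all_queries else []
    cmp_hits = _cluster_matches(all_queries, cmp_unique, rules) if all_queries else []

    decisions: dict[str, ClassifyDecision] = {}
    per_contig: dict[str, dict[str, list]] = {
        c: {"PMP": [], "CMP": []} for c in contig_proteins
    }
    for gid, cid, ev in pmp_hits:
        per_contig[owner[gid]]["PMP"].append((gid, "PMP", cid, ev))
    for gid, cid, ev in cmp_hits:
        per_contig[owner[gid]]["CMP"].append((gid, "CMP", cid, ev))

    for contig_id, prots in contig_proteins.items():
        if not prots:
            decisions[contig_id] = ClassifyDecision(
                contig_id, "discard", 0, 0, "no_genes"
            )
            continue
        n_pmp = len(per_contig[contig_id]["PMP"])
        n_cmp = len(per_contig[contig_id]["CMP"])
        if n_cmp > 0:
            decision, reason = "discard", "decoy_match"
        elif n_pmp >= 1:
            decision, reason = "keep", "bait_only"
        else:
            decision, reason = "discard", "no_bait_match"
        decisions[contig_id] = ClassifyDecision(
            contig_id,
            decision,
            n_pmp,
            n_cmp,
            reason,
            evidence=sorted(per_contig[contig_id]["PMP"] + per_contig[contig_id]["CMP"]),
        )
    return decisions
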
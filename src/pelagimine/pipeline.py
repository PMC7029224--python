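"""Pipeline orchestration: mine -> assemble -> qc (+ optional stages).

The funnel mirrors the mining workflow: a contig length filter, marker
(terL) screening with clade placement against labelled references, the
dual-reference exclusion classifier, deduplication, rule-based
cross-assembly, and the final genome filters, with per-stage reports of
counts and mean lengths. Marker screening identifies the seed contigs
that anchor each assembly; the exclusion classifier decides which
contigs enter cross-assembly at all, which is what lets whole genomes —
not just their marker-bearing fragments — be reconstructed.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass, field

import pandas as pd

from . import cross_assembly as ca
from . import mining, qc
from .types import Contig, GeneCall, MAVG, StageReport

#: stages whose output count can never exceed their input count
FILTER_STAGES = {"length_filter", "classify", "dedup", "final_filter"}
STAGE_ORDER = ["length_filter", "classify", "dedup", "assemble", "final_filter", "qc"]


@dataclass
class PipelineConfig:
    # mining
    min_contig_len: int = 5000
    marker_max_evalue: float = 1e-5
    cluster_min_identity: float = 0.35
    cluster_min_coverage: float = 0.7
    share_identity: float = 0.5
    hit_max_evalue: float = 1e-5
    hit_len_window: tuple[float, float] = (0.7, 1.3)
    # cross-assembly
    min_seed_kmer: int = 21
    overlap_min_identity: float = 99.0
    overlap_min_len: int = 1000
    overlap_max_gaps: int = 10
    min_support: int = 3
    require_marker_in_mavg: bool = True
    # final filters
    min_mavg_len: int = 100_000
    gc_range: tuple[float, float] = (30.0, 35.0)
    min_sar11_identity: float = 70.0
    min_trna_identity: float = 95.0
    # completeness
    tr_min_repeat: int = 11
    tr_max_scan: int = 500
    # stage toggles
    run_assemble: bool = True
    run_qc: bool = True


@dataclass
class PipelineInputs:
    contigs: list[Contig]
    gene_calls: dict[str, list[GeneCall]]
    marker_refs_in: list[tuple[str, str]]
    marker_refs_out: list[tuple[str, str]] = field(default_factory=list)
    pmp_ref_proteins: list[tuple[str, str]] = field(default_factory=list)
    cmp_ref_proteins: list[tuple[str, str]] = field(default_factory=list)
    sar11_hits: dict | None = None
    trna_hits: dict | None = None


@dataclass
class PipelineResult:
    mavgs: list[MAVG]
    reports: list[StageReport]
    feature_table: pd.DataFrame
    decisions: dict
    marker_hits: list
    clade: object | None
    shared_clusters: list
    merge_reports: list = field(default_factory=list)


def _report(stage: str, items_in, items_out, params: dict, t0: float,
            warnings: list[str] | None = None) -> StageReport:
    def mean_len(items) -> float:
        lens = [len(x.sequence) if hasattr(x, "sequence") else len(x) for x in items]
        return sum(lens) / len(lens) if lens else 0.0

    return StageReport(
        stage_name=stage,
        n_in=len(items_in),
        n_out=len(items_out),
        mean_len_in=mean_len(items_in),
        mean_len_out=mean_len(items_out),
        params_echo=params,
        wallclock=time.monotonic() - t0,
        warnings=warnings or [],
    )


def run_pipeline(inputs: PipelineInputs, config: PipelineConfig | None = None) -> PipelineResult:
    """Execute the mining workflow end to end.

    Re-running with identical inputs and configuration reproduces
    identical outputs: every stage is deterministic.
    """
    cfg = config or PipelineConfig()
    reports: list[StageReport] = []
    cfg_echo = asdict(cfg)

    # -- stage 1: contig length filter ------------------------------------
    t0 = time.monotonic()
    long_contigs = [c for c in inputs.contigs if len(c.sequence) > cfg.min_contig_len]
    reports.append(
        _report("length_filter", inputs.contigs, long_contigs,
                {"min_contig_len": cfg.min_contig_len}, t0)
    )

    # -- marker screen + clade placement (seed discovery) ------------------
    if not inputs.marker_refs_in:
        raise ValueError("stage marker_screen: marker_refs_in input is missing")
    profile = mining.build_marker_profile(inputs.marker_refs_in)
    marker_hits = mining.screen_marker_contigs(
        long_contigs, inputs.gene_calls, profile,
        min_contig_len=cfg.min_contig_len, max_evalue=cfg.marker_max_evalue,
    )
    gene_prot = {
        g.gene_id: g.protein for calls in inputs.gene_calls.values() for g in calls
    }
    clade = None
    marker_contigs: set[str] = {h.contig_id for h in marker_hits}
    if inputs.marker_refs_out and marker_hits:
        candidates = [(h.gene_id, gene_prot[h.gene_id]) for h in marker_hits]
        clade = mining.select_by_marker_clade(
            candidates, inputs.marker_refs_in, inputs.marker_refs_out
        )
        if clade.in_group_monophyletic:
            selected_genes = set(clade.selected)
            marker_contigs = {
                h.contig_id for h in marker_hits if h.gene_id in selected_genes
            }

    # -- stage 2: exclusion classification ---------------------------------
    t0 = time.monotonic()
    if not inputs.pmp_ref_proteins or not inputs.cmp_ref_proteins:
        raise ValueError("stage classify: reference proteome inputs are missing")
    pmp_set, cmp_set = mining.build_cluster_sets(
        inputs.pmp_ref_proteins, inputs.cmp_ref_proteins,
        min_identity=cfg.cluster_min_identity, min_coverage=cfg.cluster_min_coverage,
    )
    pmp_unique, cmp_unique, shared = mining.remove_shared_clusters(
        pmp_set, cmp_set, share_identity=cfg.share_identity
    )
    contig_proteins = {
        c.contig_id: [
            (g.gene_id, g.protein) for g in inputs.gene_calls.get(c.contig_id, [])
        ]
        for c in long_contigs
    }
    rules = mining.HitRules(max_evalue=cfg.hit_max_evalue, len_window=cfg.hit_len_window)
    decisions = mining.classify_candidates(contig_proteins, pmp_unique, cmp_unique, rules)
    kept = [c for c in long_contigs if decisions[c.contig_id].decision == "keep"]
    reports.append(
        _report("classify", long_contigs, kept,
                {"n_shared_clusters_removed": len(shared),
                 "n_marker_contigs": len(marker_contigs),
                 "hit_rules": {"max_evalue": cfg.hit_max_evalue,
                               "len_window": list(cfg.hit_len_window)}},
                t0)
    )

    mavgs: list[MAVG] = []
    merge_reports = []
    if cfg.run_assemble:
        # -- stage 3: dedup -------------------------------------------------
        t0 = time.monotonic()
        retained, removed = ca.dedup_contigs(kept)
        reports.append(_report("dedup", kept, retained, {"n_removed": len(removed)}, t0))

        # -- stage 4: cross-assembly ---------------------------------------
        t0 = time.monotonic()
        edges = ca.compute_overlaps(retained, min_seed_kmer=cfg.min_seed_kmer)
        qualifying = [
            e for e in edges
            if ca.qualify_overlap(e, cfg.overlap_min_identity, cfg.overlap_min_len,
                                  cfg.overlap_max_gaps)
        ]
        bins = ca.bin_contigs(retained, qualifying)
        contig_map = {c.contig_id: c for c in retained}
        for b in bins:
            merged, mrep = ca.merge_bin(b, contig_map, min_support=cfg.min_support)
            merge_reports.append(mrep)
            for m in merged:
                if cfg.require_marker_in_mavg and not (
                    {cid for cid, _, _, _ in m.path} & marker_contigs
                ):
                    continue
                mavgs.append(m)
        reports.append(
            _report("assemble", retained, mavgs,
                    {"n_edges": len(edges), "n_qualifying": len(qualifying),
                     "n_bins": len(bins), "min_support": cfg.min_support}, t0)
        )

        # -- stage 5: final filters ----------------------------------------
        t0 = time.monotonic()
        fres = ca.filter_mavgs(
            mavgs, inputs.sar11_hits, inputs.trna_hits,
            min_len=cfg.min_mavg_len, gc_range=cfg.gc_range,
            min_sar11_identity=cfg.min_sar11_identity,
            min_trna_identity=cfg.min_trna_identity,
        )
        reports.append(
            _report("final_filter", mavgs, fres.passing,
                    {"failing": fres.failing}, t0, warnings=fres.warnings)
        )
        mavgs = fres.passing

    # -- stage 6: qc / feature table ---------------------------------------
    rows = []
    if cfg.run_qc:
        t0 = time.monotonic()
        for m in mavgs:
            call = qc.completeness_by_terminal_repeats(
                m.mavg_id, m.sequence, min_repeat=cfg.tr_min_repeat,
                max_scan=cfg.tr_max_scan,
            )
            m.completeness = call.status
            m.completeness_method = call.method
            rows.append(
                qc.genome_feature_row(m.mavg_id, m.sequence, completeness=call)
                | {"habitat": m.habitat, "n_contigs": len(m.path)}
            )
        reports.append(_report("qc", mavgs, mavgs, {"config": cfg_echo}, t0))
    feature_table = pd.DataFrame(rows)

    return PipelineResult(
        mavgs=mavgs,
        reports=reports,
        feature_table=feature_table,
        decisions=decisions,
        marker_hits=marker_hits,
        clade=clade,
        shared_clusters=shared,
        merge_reports=merge_reports,
    )


def summarize_run(reports: list[StageReport]) -> pd.DataFrame:
    """Funnel table of (stage, n_in, n_out, mean lengths).

    Validates stage order against the canonical workflow and the
    monotone-count invariant of filtering stages.
    """
    positions = [STAGE_ORDER.index(r.stage_name) for r in reports if r.stage_name in STAGE_ORDER]
    if positions != sorted(positions):
        raise ValueError("stage reports are out of workflow order")
    for r in reports:
        if r.stage_name in FILTER_STAGES and r.n_out > r.n_in:
            raise ValueError(
                f"filter stage {r.stage_name} emitted more items than it received"
            )
    return pd.DataFrame(
        [
            (r.stage_name, r.n_in, r.n_out, round(r.mean_len_in, 1), round(r.mean_len_out, 1))
            for r in reports
        ],
        columns=["stage", "n_in", "n_out", "mean_len_in", "mean_len_out"],
    )
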
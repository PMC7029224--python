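"""File-format helpers: FASTA/FASTQ via Biopython, TSV tables via pandas.

The on-disk layout mirrors what the pipeline consumes: contigs FASTA +
metadata TSV (contig_id, sample_id, habitat, fraction), per-contig gene
calls as a TSV with embedded protein sequences, reference protein
FASTAs, and a JSON echo of generator parameters for provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import Contig, GeneCall

GENE_COLUMNS = ["gene_id", "genome_id", "start", "end", "strand", "cluster_id", "protein"]
META_COLUMNS = ["contig_id", "sample_id", "habitat", "fraction"]


def write_fasta(records: list[tuple[str, str]], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def read_fasta(path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


def write_fastq(reads: list[tuple[str, str]], path, quality: int = 30) -> None:
    """Sanger-encoded FASTQ with a constant quality."""
    records = []
    for name, seq in reads:
        rec = SeqRecord(Seq(seq), id=name, description="")
        rec.letter_annotations["phred_quality"] = [quality] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fastq")]


def write_contigs(contigs: list[Contig], fasta_path, meta_path) -> None:
    write_fasta([(c.contig_id, c.sequence) for c in contigs], fasta_path)
    pd.DataFrame(
        [(c.contig_id, c.sample_id, c.habitat, c.fraction) for c in contigs],
        columns=META_COLUMNS,
    ).to_csv(meta_path, sep="\t", index=False)


def read_contigs(fasta_path, meta_path=None) -> list[Contig]:
    meta = {}
    if meta_path is not None:
        df = pd.read_csv(meta_path, sep="\t")
        meta = {r.contig_id: r for r in df.itertuples()}
    out = []
    for name, seq in read_fasta(fasta_path):
        m = meta.get(name)
        out.append(
            Contig(
                contig_id=name,
                sequence=seq,
                sample_id=getattr(m, "sample_id", "unknown"),
                habitat=getattr(m, "habitat", "marine"),
                fraction=getattr(m, "fraction", "cellular"),
            )
        )
    return out


def write_gene_calls(calls: dict[str, list[GeneCall]], path) -> None:
    rows = [
        (g.gene_id, g.genome_id, g.start, g.end, g.strand, g.cluster_id or "", g.protein)
        for genes in calls.values()
        for g in genes
    ]
    pd.DataFrame(rows, columns=GENE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gene_calls(path) -> dict[str, list[GeneCall]]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out: dict[str, list[GeneCall]] = {}
    for r in df.itertuples():
        out.setdefault(r.genome_id, []).append(
            GeneCall(
                gene_id=r.gene_id,
                genome_id=r.genome_id,
                start=int(r.start),
                end=int(r.end),
                strand=r.strand,
                protein=r.protein,
                cluster_id=r.cluster_id or None,
            )
        )
    return out


def write_params_json(params: dict, path) -> None:
    Path(path).write_text(json.dumps(params, indent=2, sort_keys=True) + "\n")


def write_community(community, outdir) -> Path:
    """Materialise a synthetic community as pipeline-ready files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_contigs(community.contigs, outdir / "contigs.fasta", outdir / "contigs.tsv")
    write_gene_calls(community.contig_genes, outdir / "gene_calls.tsv")
    write_fasta(community.marker_refs_in, outdir / "marker_refs_in.faa")
    write_fasta(community.marker_refs_out, outdir / "marker_refs_out.faa")
    write_fasta(community.pmp_ref_proteins, outdir / "pmp_ref_proteins.faa")
    write_fasta(community.cmp_ref_proteins, outdir / "cmp_ref_proteins.faa")
    write_fasta(
        [(t.genome_id, t.sequence) for t in community.targets], outdir / "truth_targets.fasta"
    )
    write_params_json(community.params, outdir / "params.json")
    return outdir
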
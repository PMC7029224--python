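"""Core extraction, concatenation, ANI, consensus annotation and pI."""

import shutil
import subprocess

import numpy as np
import pytest

from pelagimine import comparative as comp
from pelagimine.synthetic import (
    GenomeParams,
    evolve_member,
    generate_phage_genome,
    mutate_sequence,
)
from pelagimine.types import GeneCall, HitRecord


class TestExtractCore:
    def _genes(self, genome_id, clusters):
        return [
            GeneCall(f"{genome_id}|g{i}", genome_id, i * 100, i * 100 + 90, "+",
                     cluster_id=c)
            for i, c in enumerate(clusters)
        ]

    def _assignments(self, *gene_lists):
        out = {}
        for genes in gene_lists:
            for g in genes:
                out.setdefault(g.cluster_id, []).append(g)
        return out

    def test_duplicated_cluster_excluded(self):
        a = self._genes("A", ["X", "Y"])
        b = self._genes("B", ["X", "Y"])
        c = self._genes("C", ["X", "X", "Y"])
        core = comp.extract_core(self._assignments(a, b, c), ["A", "B", "C"])
        assert core.cluster_ids == ["Y"]

    def test_disjoint_proteomes_empty_core(self):
        a = self._genes("A", ["X1", "X2"])
        b = self._genes("B", ["Y1", "Y2"])
        core = comp.extract_core(self._assignments(a, b), ["A", "B"])
        assert core.cluster_ids == []

    def test_family_truth_core_recovered(self, genome30):
        """Core modules of a genome family are single-copy universal;
        hypervariable clusters are genome-private and excluded."""
        _, anc = generate_phage_genome(GenomeParams(length=30_000), seed=41, genome_id="anc")
        members = [evolve_member(anc, f"m{i}", seed=50 + i, hv_sub=0.15) for i in range(3)]
        assignments = self._assignments(*[m.gene_truth for m in members])
        core = comp.extract_core(assignments, [m.genome_id for m in members])
        core_truth = sorted(
            {
                g.cluster_id
                for m in members
                for cls in ("core_structural", "core_replication")
                for g in m.genes_in_class(cls)
            }
        )
        assert core.cluster_ids == core_truth
        assert all(len(core.members[c]) == 3 for c in core.cluster_ids)

    def test_removing_one_core_gene_shrinks_core_by_one(self):
        a = self._genes("A", ["X", "Y", "Z"])
        b = self._genes("B", ["X", "Y", "Z"])
        full = comp.extract_core(self._assignments(a, b), ["A", "B"])
        partial = comp.extract_core(self._assignments(a, b[:2]), ["A", "B"])
        assert set(full.cluster_ids) - set(partial.cluster_ids) == {"Z"}


class TestConcatenateCore:
    def _core(self, clusters, genomes):
        return comp.CoreSet(
            cluster_ids=list(clusters),
            members={c: {g: f"{g}|{c}" for g in genomes} for c in clusters},
        )

    def test_row_widths_are_block_sums(self):
        core = self._core(["c1", "c2"], ["A", "B"])
        blocks = {
            "c1": {"A": "M" * 100, "B": "K" * 100},
            "c2": {"A": "R" * 250, "B": "D" * 250},
        }
        rows, partitions = comp.concatenate_core(core, blocks)
        assert all(len(r) == 350 for r in rows.values())
        assert partitions == [("c1", 0, 100), ("c2", 100, 350)]

    def test_single_block_is_identity(self):
        core = self._core(["c1"], ["A", "B"])
        blocks = {"c1": {"A": "MKR", "B": "MDR"}}
        rows, _ = comp.concatenate_core(core, blocks)
        assert rows == blocks["c1"]

    def test_missing_genome_row_rejected(self):
        core = self._core(["c1"], ["A", "B"])
        with pytest.raises(ValueError, match="missing genome"):
            comp.concatenate_core(core, {"c1": {"A": "MKR"}})

    def test_unequal_block_rows_rejected(self):
        core = self._core(["c1"], ["A", "B"])
        with pytest.raises(ValueError, match="unequal"):
            comp.concatenate_core(core, {"c1": {"A": "MKR", "B": "MK"}})


class TestANI:
    def test_self_comparison_is_100_with_high_coverage(self, genome140):
        seq, _ = genome140
        r = comp.ani_coverage(("g", seq), ("g", seq))
        assert r.ani == 100.0
        assert r.coverage >= 99.0  # trailing partial fragment dropped
        assert r.n_fragments_used == len(seq) // 1020

    def test_one_percent_mutant_near_99(self, genome30):
        seq, _ = genome30
        mut, _ = mutate_sequence(seq, 0.01, np.random.default_rng(3))
        r = comp.ani_coverage(("g", seq), ("m", mut))
        assert r.ani == pytest.approx(99.0, abs=0.2)

    def test_unrelated_genomes_zero_coverage(self, genome30):
        seq, _ = genome30
        rng = np.random.default_rng(9)
        alien = "".join("ACGT"[i] for i in rng.integers(0, 4, 30_000))
        r = comp.ani_coverage(("g", seq), ("r", alien))
        assert r.coverage == 0.0 and r.no_fragments

    @pytest.mark.parametrize("seed", range(5))
    def test_ani_decreases_monotonically_with_divergence(self, genome30, seed):
        seq, _ = genome30
        rng = np.random.default_rng(100 + seed)
        anis = []
        for rate in (0.005, 0.01, 0.02, 0.05):
            mut, _ = mutate_sequence(seq, rate, rng)
            anis.append(comp.ani_coverage(("g", seq), ("m", mut)).ani)
        assert anis == sorted(anis, reverse=True)

    def test_too_short_genome_rejected(self):
        with pytest.raises(ValueError):
            comp.ani_coverage(("a", "ACGT" * 10), ("b", "ACGT" * 1000))

    @pytest.mark.skipif(shutil.which("blastn") is None, reason="blastn not on PATH")
    def test_agrees_with_blastn_fragment_oracle(self, genome30, tmp_path):
        """Independent cross-check: the same fragment protocol driven by
        BLASTN instead of the built-in aligner gives the same ANI."""
        seq, _ = genome30
        mut, _ = mutate_sequence(seq, 0.02, np.random.default_rng(11))
        frag_len = 1020
        frags = [
            (f"f{i}", seq[s : s + frag_len])
            for i, s in enumerate(range(0, len(seq) - frag_len + 1, frag_len))
        ]
        qpath, spath = tmp_path / "frags.fa", tmp_path / "subject.fa"
        qpath.write_text("".join(f">{n}\n{s}\n" for n, s in frags))
        spath.write_text(f">m\n{mut}\n")
        out = subprocess.run(
            ["blastn", "-query", str(qpath), "-subject", str(spath), "-outfmt",
             "6 qseqid pident length", "-max_target_seqs", "1", "-max_hsps", "1"],
            capture_output=True, text=True, check=True,
        ).stdout
        idents = []
        for line in out.strip().splitlines():
            _, pident, length = line.split("\t")
            if float(pident) >= 30.0 and int(length) >= 0.7 * frag_len:
                idents.append(float(pident))
        blast_ani = float(np.mean(idents))
        ours = comp.ani_coverage(("g", seq), ("m", mut)).ani
        assert ours == pytest.approx(blast_ani, abs=0.5)


class TestConsensusAnnotation:
    def _hit(self, q, s, evalue=1e-20, aln=100, bits=100.0):
        return HitRecord(q, s, 90.0, aln, evalue=evalue, bitscore=bits)

    def test_unanimous_label_wins(self):
        hits = {db: [self._hit("p1", "terL_ref")] for db in ("db1", "db2", "db3")}
        ann = comp.annotate_consensus(
            hits, {"p1": 100}, {"terL_ref": "terminase"}, {"p1": "pc1"}
        )
        assert ann["pc1"].label == "terminase"

    def test_weak_evalue_hit_rejected(self):
        hits = {"db1": [self._hit("p1", "terL_ref", evalue=1e-4)]}
        ann = comp.annotate_consensus(
            hits, {"p1": 100}, {"terL_ref": "terminase"}, {"p1": "pc1"}
        )
        assert ann["pc1"].label == "hypothetical"

    def test_length_window_enforced(self):
        hits = {"db1": [self._hit("p1", "terL_ref", aln=60)]}  # 60% of query
        ann = comp.annotate_consensus(
            hits, {"p1": 100}, {"terL_ref": "terminase"}, {"p1": "pc1"}
        )
        assert ann["pc1"].label == "hypothetical"

    def test_majority_across_databases(self):
        labels = {"a": "tail fiber", "b": "tail fiber", "c": "hypothetical"}
        hits = {
            "db1": [self._hit("p1", "a")],
            "db2": [self._hit("p1", "b")],
            "db3": [self._hit("p1", "c")],
        }
        ann = comp.annotate_consensus(hits, {"p1": 100}, labels, {"p1": "pc1"})
        assert ann["pc1"].label == "tail fiber"

    def test_tie_resolved_by_deeper_hits(self):
        labels = {"a": "portal", "b": "sheath", "a2": "portal"}
        hits = {
            "db1": [self._hit("p1", "a", bits=100), self._hit("p1", "a2", bits=90)],
            "db2": [self._hit("p1", "b")],
        }
        ann = comp.annotate_consensus(hits, {"p1": 100}, labels, {"p1": "pc1"})
        assert ann["pc1"].label == "portal"


class TestIsoelectricPoint:
    def test_basic_residues_raise_pi_acidic_lower_it(self):
        assert comp.isoelectric_point("KKKK") > comp.isoelectric_point("DDDD")

    def test_charge_bracket_valid_for_any_protein(self):
        for pep in ("G", "ACDEFGHIKLMNPQRSTVWY", "PPPPP"):
            assert comp.net_charge(pep, 0.0) > 0
            assert comp.net_charge(pep, 14.0) < 0

    def test_matches_grid_search_oracle(self):
        """Bisection agrees with a brute-force 0.001-pH grid search."""
        rng = np.random.default_rng(17)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        grid = np.arange(0.0, 14.0, 0.001)
        for _ in range(30):
            pep = "".join(aas[i] for i in rng.integers(0, 20, rng.integers(20, 200)))
            charges = np.array([comp.net_charge(pep, ph) for ph in grid])
            oracle = grid[np.argmin(np.abs(charges))]
            assert comp.isoelectric_point(pep) == pytest.approx(oracle, abs=0.01)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            comp.isoelectric_point("")


class TestPiDistribution:
    def test_density_integrates_to_one(self):
        df = comp.pi_distribution(["KKKKAAAA", "DDEEAA", "ACDEFGHIKL"])
        assert float((df.density * 0.2).sum()) == pytest.approx(1.0, abs=1e-9)

    def test_single_protein_unit_mass_in_one_bin(self):
        df = comp.pi_distribution(["KKKKKK"])
        occupied = df[df.density > 0]
        assert len(occupied) == 1
        assert float((occupied.density * 0.2).sum()) == pytest.approx(1.0)

    def test_base_rich_proteome_shifts_basic(self):
        acid = ["DDEEDDEEAA" * 3] * 5
        base = ["KKRRKKRRAA" * 3] * 5
        mode = lambda df: float(df.loc[df.density.idxmax(), "bin_left"])
        assert mode(comp.pi_distribution(base)) > mode(comp.pi_distribution(acid))

    def test_empty_proteome_rejected(self):
        with pytest.raises(ValueError):
            comp.pi_distribution([])
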
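"""Cross-assembly rules: dedup, overlaps, qualification, binning,
consensus merging and the final MAVG filters."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pelagimine import cross_assembly as ca
from pelagimine.align import global_identity, revcomp
from pelagimine.synthetic import GenomeParams, generate_phage_genome, shred_genome
from pelagimine.types import Contig, HitRecord, MAVG, OverlapEdge


def _contigs(*seqs, habitat="marine"):
    return [Contig(f"c{i}", s, f"s{i}", habitat=habitat) for i, s in enumerate(seqs)]


def _staggered_shreds(seq, rate, seeds=(1, 2)):
    c1, _ = shred_genome(seq, 4, 2000, rate, seeds[0], id_prefix="a")
    c2, _ = shred_genome(seq, 5, 2000, rate, seeds[1], id_prefix="b")
    return c1 + c2


class TestDedup:
    def test_identical_pair_collapses(self, genome30):
        seq, _ = genome30
        retained, removed = ca.dedup_contigs(_contigs(seq, seq))
        assert len(retained) == 1
        assert removed == {"c1": "c0"}

    def test_substring_removed_longer_kept(self, genome30):
        seq, _ = genome30
        retained, removed = ca.dedup_contigs(_contigs(seq, seq[5000:15000]))
        assert [c.contig_id for c in retained] == ["c0"]
        assert removed["c1"] == "c0"

    def test_reverse_complement_duplicate_removed(self, genome30):
        seq, _ = genome30
        retained, removed = ca.dedup_contigs(_contigs(seq, revcomp(seq[2000:9000])))
        assert [c.contig_id for c in retained] == ["c0"]

    def test_distinct_set_unchanged_and_idempotent(self, genome30):
        seq, _ = genome30
        contigs = _contigs(seq[:10000], seq[15000:25000])
        retained, removed = ca.dedup_contigs(contigs)
        assert removed == {}
        retained2, removed2 = ca.dedup_contigs(retained)
        assert removed2 == {} and len(retained2) == len(retained)


class TestOverlaps:
    def test_exact_shared_block_detected(self, genome30):
        seq, _ = genome30
        contigs = _contigs(seq[:12000], seq[10000:22000])
        edges = ca.compute_overlaps(contigs)
        assert len(edges) == 1
        e = edges[0]
        assert e.identity == 100.0 and e.aln_len == 2000 and e.gap_count == 0
        assert (e.a_start, e.a_end, e.b_start, e.b_end) == (10000, 12000, 0, 2000)

    def test_reverse_complement_overlap_same_edge(self, genome30):
        seq, _ = genome30
        contigs = _contigs(seq[:12000], revcomp(seq[10000:22000]))
        edges = ca.compute_overlaps(contigs)
        assert len(edges) == 1
        e = edges[0]
        assert e.orientation == "reverse-complement"
        assert e.identity == 100.0 and e.aln_len == 2000

    @pytest.mark.parametrize("seed", range(10))
    def test_adjacent_shreds_qualify_at_low_sub_rate(self, genome30, seed):
        """At sub_rate 0.002 the expected overlap identity is ~99.6%,
        comfortably above the >99% rule (binomial tail on 2,000 nt)."""
        seq, _ = genome30
        contigs, _ = shred_genome(seq, 4, 2000, 0.002, seed=100 + seed)
        edges = ca.compute_overlaps(contigs)
        adjacent = [
            e for e in edges
            if abs(int(e.contig_a[-2:]) - int(e.contig_b[-2:])) == 1
        ]
        assert len(adjacent) == 3
        assert all(e.identity > 99.0 for e in adjacent)


class TestQualifyOverlap:
    @pytest.mark.parametrize(
        "identity,aln_len,gaps,expected",
        [
            (99.5, 1500, 2, True),
            (99.0, 1500, 2, False),  # strict >99
            (99.5, 1000, 2, False),  # strict >1000
            (99.5, 1500, 10, False),  # strict <10
            (99.01, 1001, 9, True),
            (100.0, 999, 0, False),
        ],
    )
    def test_boundary_table(self, identity, aln_len, gaps, expected):
        e = OverlapEdge("a", "b", "forward", identity, aln_len, gaps, 0, aln_len, 0, aln_len)
        assert ca.qualify_overlap(e) is expected

    @settings(max_examples=200, deadline=None)
    @given(
        identity=st.floats(90.0, 100.0),
        aln_len=st.integers(1, 5000),
        gaps=st.integers(0, 50),
    )
    def test_matches_three_inequalities(self, identity, aln_len, gaps):
        e = OverlapEdge("a", "b", "forward", identity, aln_len, gaps, 0, 1, 0, 1)
        assert ca.qualify_overlap(e) == (identity > 99.0 and aln_len > 1000 and gaps < 10)


class TestBinning:
    def test_chain_forms_one_bin(self):
        edges = [
            OverlapEdge("a", "b", "forward", 99.5, 1500, 0, 0, 1, 0, 1),
            OverlapEdge("b", "c", "forward", 99.5, 1500, 0, 0, 1, 0, 1),
        ]
        contigs = [Contig(x, "ACGT" * 300, "s") for x in "abc"]
        bins = ca.bin_contigs(contigs, edges)
        assert len(bins) == 1 and bins[0].contig_ids == {"a", "b", "c"}

    def test_no_edges_all_singletons(self):
        contigs = [Contig(x, "ACGT" * 300, "s") for x in "abc"]
        bins = ca.bin_contigs(contigs, [])
        assert len(bins) == 3

    def test_two_genomes_two_bins_matching_truth(self, genome30):
        seq, _ = genome30
        other, _ = generate_phage_genome(GenomeParams(length=30_000), seed=99)
        contigs = []
        for prefix, g in (("x", seq), ("y", other)):
            cs, _ = shred_genome(g, 4, 2000, 0.0, seed=1, id_prefix=prefix)
            contigs.extend(cs)
        qualifying = [e for e in ca.compute_overlaps(contigs) if ca.qualify_overlap(e)]
        bins = ca.bin_contigs(contigs, qualifying)
        multi = [b for b in bins if len(b.contig_ids) > 1]
        assert len(multi) == 2
        sources = [{cid[0] for cid in b.contig_ids} for b in multi]
        assert sources == [{"x"}, {"y"}] or sources == [{"y"}, {"x"}]

    def test_order_invariance(self, genome30):
        seq, _ = genome30
        contigs, _ = shred_genome(seq, 4, 2000, 0.0, seed=1)
        qualifying = [e for e in ca.compute_overlaps(contigs) if ca.qualify_overlap(e)]
        a = ca.bin_contigs(contigs, qualifying)
        b = ca.bin_contigs(contigs[::-1], qualifying[::-1])
        assert [x.contig_ids for x in a] == [x.contig_ids for x in b]


class TestMerge:
    def _merge(self, contigs, min_support=3):
        qualifying = [e for e in ca.compute_overlaps(contigs) if ca.qualify_overlap(e)]
        bins = ca.bin_contigs(contigs, qualifying)
        big = max(bins, key=lambda b: len(b.contig_ids))
        return ca.merge_bin(big, {c.contig_id: c for c in contigs}, min_support=min_support)

    def test_exact_reconstruction_from_error_free_shreds(self, genome30):
        seq, _ = genome30
        mavgs, report = self._merge(_staggered_shreds(seq, 0.0))
        assert len(mavgs) == 1
        assert mavgs[0].sequence == seq
        assert report.n_splits == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_reconstruction_across_seeds(self, seed):
        params = GenomeParams(length=24_000, gc=0.33)
        seq, _ = generate_phage_genome(params, seed=200 + seed)
        c1, _ = shred_genome(seq, 3, 1500, 0.0, seed=1, id_prefix="a")
        c2, _ = shred_genome(seq, 4, 1500, 0.0, seed=2, id_prefix="b")
        qualifying = [e for e in ca.compute_overlaps(c1 + c2) if ca.qualify_overlap(e)]
        bins = ca.bin_contigs(c1 + c2, qualifying)
        mavgs, _ = ca.merge_bin(bins[0], {c.contig_id: c for c in c1 + c2}, min_support=3)
        assert len(mavgs) == 1 and mavgs[0].sequence == seq

    def test_mutated_shreds_reconstruct_within_tolerance(self, genome30):
        seq, _ = genome30
        mavgs, _ = self._merge(_staggered_shreds(seq, 0.002))
        assert len(mavgs) == 1
        assert global_identity(mavgs[0].sequence, seq) >= 99.5

    def test_single_tiling_splits_at_min_support_three(self, genome30):
        seq, _ = genome30
        contigs, _ = shred_genome(seq, 4, 2000, 0.0, seed=1)
        mavgs, report = self._merge(contigs, min_support=3)
        assert len(mavgs) == 4  # every junction has support 2 only
        assert all(s < 3 for s in report.junction_supports)

    def test_single_tiling_merges_at_min_support_two(self, genome30):
        seq, _ = genome30
        contigs, _ = shred_genome(seq, 4, 2000, 0.0, seed=1)
        mavgs, _ = self._merge(contigs, min_support=2)
        assert len(mavgs) == 1 and mavgs[0].sequence == seq

    def test_freshwater_contig_excluded_from_marine_bin(self, genome30):
        seq, _ = genome30
        contigs = _staggered_shreds(seq, 0.0)
        contigs[3] = Contig(
            contigs[3].contig_id, contigs[3].sequence, "lake1", habitat="freshwater"
        )
        qualifying = [e for e in ca.compute_overlaps(contigs) if ca.qualify_overlap(e)]
        bins = ca.bin_contigs(contigs, qualifying)
        mavgs, report = ca.merge_bin(
            bins[0], {c.contig_id: c for c in contigs}, min_support=2
        )
        assert report.excluded_habitat == [contigs[3].contig_id]
        assert all(contigs[3].contig_id not in {p[0] for p in m.path} for m in mavgs)

    def test_reverse_complement_contig_merges_correctly(self, genome30):
        seq, _ = genome30
        contigs, _ = shred_genome(seq, 3, 2000, 0.0, seed=1)
        flipped = Contig(
            contigs[1].contig_id, revcomp(contigs[1].sequence), contigs[1].sample_id
        )
        contigs = [contigs[0], flipped, contigs[2]]
        mavgs, _ = self._merge(contigs, min_support=2)
        assert len(mavgs) == 1 and mavgs[0].sequence in (seq, revcomp(seq))

    def test_every_contig_accounted_for(self, genome30):
        """Conservation: each bin member lands in a MAVG path or an
        exclusion report."""
        seq, _ = genome30
        contigs = _staggered_shreds(seq, 0.0)
        qualifying = [e for e in ca.compute_overlaps(contigs) if ca.qualify_overlap(e)]
        bins = ca.bin_contigs(contigs, qualifying)
        mavgs, report = ca.merge_bin(bins[0], {c.contig_id: c for c in contigs})
        in_paths = {cid for m in mavgs for cid, _, _, _ in m.path}
        assert in_paths | set(report.excluded_habitat) == {c.contig_id for c in contigs}


class TestFilterMavgs:
    def _mavg(self, length=150_000, gc=0.33, mavg_id="m1"):
        # deterministic sequence at the requested GC
        n_gc = int(round(length * gc))
        seq = ("GC" * length)[: n_gc] + ("AT" * length)[: length - n_gc]
        return MAVG(mavg_id=mavg_id, sequence=seq, path=[])

    def _hit(self, mavg_id, identity):
        return HitRecord(query_id="p", subject_id=mavg_id, identity=identity, aln_len=100)

    def test_short_genome_fails_size(self):
        res = ca.filter_mavgs([self._mavg(length=99_000)], {}, {})
        assert res.failing == [("m1", "size")]

    def test_gc_out_of_range_fails(self):
        res = ca.filter_mavgs([self._mavg(gc=0.36)], {}, {})
        assert res.failing == [("m1", "gc")]

    def test_all_rules_met_passes(self):
        m = self._mavg()
        res = ca.filter_mavgs([m], {"m1": [self._hit("m1", 85.0)] * 5}, {})
        assert res.passing == [m]

    def test_sar11_identity_boundary_strict(self):
        m = self._mavg()
        res = ca.filter_mavgs([m], {"m1": [self._hit("m1", 70.0)]}, {})
        assert res.failing == [("m1", "sar11_proteins")]

    def test_trna_rule_only_when_trnas_present(self):
        m = self._mavg()
        ok = ca.filter_mavgs([m], {"m1": [self._hit("m1", 85.0)]}, {"m1": []})
        assert ok.passing == [m]
        bad = ca.filter_mavgs(
            [m], {"m1": [self._hit("m1", 85.0)]}, {"m1": [self._hit("m1", 94.0)]}
        )
        assert bad.failing == [("m1", "trna")]

    def test_missing_tables_pass_on_size_and_gc_with_warning(self):
        res = ca.filter_mavgs([self._mavg()], None, None)
        assert len(res.passing) == 1
        assert any("not_evaluated" in w for w in res.warnings)
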
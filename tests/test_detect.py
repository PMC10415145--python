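import random

import pytest
from hypothesis import given, settings, strategies as st

from longsv import (Breakpoint, cluster_signals, filter_by_control,
                    parse_sv_signals)
from longsv.model import AlignmentRecord, BreakpointSignal


def _rec(chrom="chr1", start=1000, strand="+", cigar="50M", read_id="r1",
         seq=None, sa=(), supplementary=False):
    from longsv.io import parse_cigar_string
    ops = parse_cigar_string(cigar)
    qlen = sum(n for op, n in ops if op in "MIS=X")
    reflen = sum(n for op, n in ops if op in "MD=XN")
    return AlignmentRecord(
        read_id=read_id, chrom=chrom, start=start, end=start + reflen,
        strand=strand, cigar=ops, seq=seq or "A" * qlen,
        sa_segments=list(sa), is_supplementary=supplementary)


class TestCigarSignals:
    def test_deletion_op_breakpoints(self):
        """50M200D50M at chr1:1000 gives bp1=(1049,+), bp2=(1250,-)."""
        (sig,) = parse_sv_signals([_rec(cigar="50M200D50M")], 50)
        assert sig.bp1 == Breakpoint("chr1", 1049, "+")
        assert sig.bp2 == Breakpoint("chr1", 1250, "-")
        assert sig.insert_len_estimate == 0
        assert sig.source == "cigar_indel"

    def test_insertion_op_breakpoints(self):
        (sig,) = parse_sv_signals([_rec(cigar="50M150I50M")], 50)
        assert sig.insert_len_estimate == 150
        assert sig.bp1.pos + 1 == sig.bp2.pos
        assert (sig.bp1.dir, sig.bp2.dir) == ("+", "-")

    def test_small_indels_ignored(self):
        assert parse_sv_signals([_rec(cigar="50M49D50M")], 50) == []
        assert parse_sv_signals([_rec(cigar="50M49D50M")], 25) != []

    def test_one_signal_per_read_per_junction(self):
        # same junction seen in two records of one read is deduplicated
        recs = [_rec(cigar="50M200D50M"), _rec(cigar="50M200D50M",
                                               supplementary=True)]
        assert len(parse_sv_signals(recs, 50)) == 1


class TestSplitSignals:
    """Direction pairs for all four strand combinations of a split read.

    For a read leaving segment A and entering segment B, the junction
    breakend on A is at its reference end (dir +) when A is forward and at
    its reference start (dir -) when reverse; mirrored for B.
    """

    @pytest.mark.parametrize("strand_a,strand_b,dir_a,dir_b", [
        ("+", "+", "+", "-"),
        ("+", "-", "+", "+"),
        ("-", "+", "-", "-"),
        ("-", "-", "-", "+"),
    ])
    def test_strand_combinations(self, strand_a, strand_b, dir_a, dir_b):
        # primary covers read[0:100] on chr1, partner covers read[100:200]
        # on chr2; query spans arranged per strand so A precedes B
        cig_a = "100M100S" if strand_a == "+" else "100S100M"
        cig_b = "100S100M" if strand_b == "+" else "100M100S"
        rec_a = _rec(chrom="chr1", start=1000, strand=strand_a, cigar=cig_a,
                     seq="A" * 200)
        rec_b = _rec(chrom="chr2", start=5000, strand=strand_b, cigar=cig_b,
                     seq="A" * 200, supplementary=True)
        sigs = parse_sv_signals([rec_a, rec_b], 50)
        assert len(sigs) == 1
        sig = sigs[0]
        bps = {("chr1", sig.bp1.dir) if sig.bp1.chrom == "chr1"
               else ("chr2", sig.bp1.dir),
               ("chr2", sig.bp2.dir) if sig.bp2.chrom == "chr2"
               else ("chr1", sig.bp2.dir)}
        assert bps == {("chr1", dir_a), ("chr2", dir_b)}
        a_bp = sig.bp1 if sig.bp1.chrom == "chr1" else sig.bp2
        assert a_bp.pos == (1099 if strand_a == "+" else 1000)

    def test_sa_tag_substitutes_for_missing_record(self):
        rec = _rec(chrom="chr1", start=1000, strand="+", cigar="100M100S",
                   seq="A" * 200, sa=[("chr2", 5000, "+", "100S100M")])
        sigs = parse_sv_signals([rec], 50)
        assert len(sigs) == 1
        assert {sigs[0].bp1.chrom, sigs[0].bp2.chrom} == {"chr1", "chr2"}

    def test_unknown_chrom_sa_segment_skipped(self):
        rec = _rec(chrom="chr1", start=1000, strand="+", cigar="100M100S",
                   seq="A" * 200, sa=[("chrUn", 5000, "+", "100S100M")])
        assert parse_sv_signals([rec], 50,
                                known_chroms={"chr1", "chr2"}) == []


def _sig(read_id, p1, p2, d1="+", d2="-", c1="chr1", c2="chr1"):
    return BreakpointSignal(read_id, Breakpoint(c1, p1, d1),
                            Breakpoint(c2, p2, d2), 0, "cigar_indel", (0, 0))


class TestClustering:
    def test_nearby_signals_form_one_cluster(self):
        sigs = [_sig(f"r{i}", 1000 + 10 * i, 5000) for i in range(3)]
        (cl,) = cluster_signals(sigs, 200, 3)
        assert len(cl.supporting_read_ids) == 3
        assert cl.bp1_range == (1000, 1020)

    def test_opposite_direction_pairs_split(self):
        sigs = ([_sig(f"r{i}", 1000, 5000, "+", "-") for i in range(3)]
                + [_sig(f"q{i}", 1000, 5000, "-", "+") for i in range(3)])
        assert len(cluster_signals(sigs, 200, 3)) == 2

    def test_transitive_chain_single_linkage(self):
        """A chain 0,150,300,450 with margin 200 is one cluster even though
        its ends are farther apart than the margin."""
        sigs = [_sig(f"r{i}", p, 5000) for i, p in
                enumerate([0, 150, 300, 450])]
        clusters = cluster_signals(sigs, 200, 3)
        assert len(clusters) == 1
        assert clusters[0].bp1_range == (0, 450)

    def test_matches_brute_force_single_linkage(self):
        rng = random.Random(17)
        sigs = [_sig(f"r{i}", rng.randrange(0, 3000),
                     rng.randrange(5000, 8000)) for i in range(40)]
        margin = 200
        # brute-force transitive closure
        n = len(sigs)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i in range(n):
            for j in range(n):
                if (abs(sigs[i].bp1.pos - sigs[j].bp1.pos) <= margin
                        and abs(sigs[i].bp2.pos - sigs[j].bp2.pos) <= margin):
                    parent[find(i)] = find(j)
        expected = {}
        for i in range(n):
            expected.setdefault(find(i), set()).add(sigs[i].read_id)
        expected_sets = {frozenset(v) for v in expected.values()
                         if len(v) >= 3}
        got = {frozenset(c.supporting_read_ids)
               for c in cluster_signals(sigs, margin, 3)}
        assert got == expected_sets

    @settings(max_examples=25, deadline=None)
    @given(st.permutations(list(range(12))))
    def test_order_invariance(self, perm):
        base = [_sig(f"r{i}", 100 * i, 5000) for i in range(12)]
        shuffled = [base[i] for i in perm]
        a = {frozenset(c.supporting_read_ids)
             for c in cluster_signals(base, 200, 3)}
        b = {frozenset(c.supporting_read_ids)
             for c in cluster_signals(shuffled, 200, 3)}
        assert a == b


class TestControlFilter:
    def _clusters(self):
        sigs = [_sig(f"r{i}", 1000, 5000) for i in range(3)]
        return cluster_signals(sigs, 200, 3)

    def test_matching_control_signal_removes_cluster(self):
        clusters = self._clusters()
        ctrl = [_sig("c1", 1050, 5080)]
        assert filter_by_control(clusters, ctrl, (), 200) == []

    def test_distant_control_signal_keeps_cluster(self):
        clusters = self._clusters()
        ctrl = [_sig("c1", 1500, 5000)]
        assert len(filter_by_control(clusters, ctrl, (), 200)) == 1

    def test_panel_only_match_removes_cluster(self):
        clusters = self._clusters()
        panel = [_sig("p1", 980, 4990)]
        assert filter_by_control(clusters, (), panel, 200) == []

    def test_direction_mismatch_does_not_match(self):
        clusters = self._clusters()
        ctrl = [_sig("c1", 1000, 5000, "-", "+")]
        assert len(filter_by_control(clusters, ctrl, (), 200)) == 1
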
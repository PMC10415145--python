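import random

import edlib
import numpy as np
import pytest

from longsv import (Breakpoint, build_consensus, jump_sw_align,
                    extract_junction_segments)
from longsv.model import BreakpointSignal, SVCandidateCluster
from longsv.refine import (canonicalize_junction, refine_candidate,
                           RefineFailure)
from longsv.seqs import revcomp
from longsv.library import random_seq

from .conftest import noisy_copy
from .oracles import jump_oracle


class TestJumpAlignment:
    def test_exact_concatenation(self):
        """A query that is exactly ref1-end + ref2-start aligns with an
        empty insert and full score."""
        q = "ACGTTTTT" + "GGGGCATG"
        a = jump_sw_align(q, "TTACGTTTTT", "GGGGCATGAA")
        assert a.score == 2 * 16
        assert (a.q_end1, a.q_start2) == (8, 8)
        assert a.r1_end == 9 and a.r2_start == 0
        assert q[a.q_end1:a.q_start2] == ""

    def test_inserted_sequence_between_pieces(self):
        q = "ACGTTTTT" + "AAACCC" + "GGGGCATG"
        a = jump_sw_align(q, "TTACGTTTTT", "GGGGCATGAA")
        assert q[a.q_end1:a.q_start2] == "AAACCC"
        assert a.score == 2 * 16

    def test_matches_exhaustive_split_enumeration(self):
        """DP score equals brute-force max over all (end, start) splits of
        anchored two-piece Smith-Waterman on random small instances."""
        rng = random.Random(42)
        for _ in range(250):
            q = "".join(rng.choice("ACGT")
                        for _ in range(rng.randint(1, 30)))
            r1 = "".join(rng.choice("ACGT")
                         for _ in range(rng.randint(1, 50)))
            r2 = "".join(rng.choice("ACGT")
                         for _ in range(rng.randint(1, 50)))
            got = jump_sw_align(q, r1, r2).score
            want = jump_oracle(q, r1, r2)
            assert got == pytest.approx(want), (q, r1, r2)

    def test_jump_never_worse_than_single_region(self):
        rng = random.Random(7)
        for _ in range(60):
            q = "".join(rng.choice("ACGT") for _ in range(25))
            r1 = "".join(rng.choice("ACGT") for _ in range(40))
            r2 = "".join(rng.choice("ACGT") for _ in range(40))
            a = jump_sw_align(q, r1, r2)
            assert a.score >= jump_sw_align(q, r1, "T").score - 1e-9
            assert a.score >= jump_sw_align(q, "T", r2).score - 1e-9


class TestConsensus:
    def test_identical_segments_pass_through(self):
        seg = "ACGT" * 50
        c = build_consensus([seg] * 5)
        assert c.seq == seg
        assert c.n_inputs == 5 and not c.flags

    def test_noisy_segments_polish_to_truth(self):
        """Five 5%-noise copies of a 400 bp sequence polish back to >=99%
        identity."""
        rng = np.random.default_rng(11)
        truth = random_seq(rng, 400)
        segs = [noisy_copy(truth, 0.05, rng) for _ in range(5)]
        c = build_consensus(segs)
        ed = edlib.align(c.seq, truth, mode="NW")["editDistance"]
        assert 1 - ed / len(truth) >= 0.99

    def test_discordant_mixture_flagged(self):
        rng = np.random.default_rng(3)
        a, b = random_seq(rng, 400), random_seq(rng, 400)
        c = build_consensus([a, a, b, b, a[:200] + b[200:]])
        assert "high_discordance" in c.flags

    def test_single_segment_unpolished(self):
        c = build_consensus(["ACGTACGT"])
        assert c.flags == ["unpolished"]


def _cluster(read_offsets, bp1, bp2, read_ids=None, bp1_first=True):
    sigs = []
    for i, off in enumerate(read_offsets):
        rid = read_ids[i] if read_ids else f"r{i}"
        sigs.append(BreakpointSignal(rid, bp1, bp2, 0, "cigar_indel", off,
                                     bp1_first))
    return SVCandidateCluster(signals=sigs, bp1_range=(bp1.pos, bp1.pos),
                              bp2_range=(bp2.pos, bp2.pos))


class TestSegmentExtraction:
    def test_minus_strand_segment_is_revcomp_of_plus(self):
        rng = np.random.default_rng(1)
        read = random_seq(rng, 1000)
        bp1, bp2 = Breakpoint("chr1", 10, "+"), Breakpoint("chr1", 20, "-")
        fwd = _cluster([(500, 500)], bp1, bp2, ["a"])
        rev = _cluster([(500, 500)], bp1, bp2, ["a"], bp1_first=False)
        seg_f = extract_junction_segments(fwd, {"a": read}, flank=300)
        seg_r = extract_junction_segments(rev, {"a": read}, flank=300)
        assert seg_r == [revcomp(seg_f[0])]

    def test_short_context_reads_excluded(self):
        bp1, bp2 = Breakpoint("chr1", 10, "+"), Breakpoint("chr1", 20, "-")
        cl = _cluster([(30, 30)], bp1, bp2, ["a"])
        assert extract_junction_segments(cl, {"a": "A" * 200}, flank=300,
                                         min_flank=50) == []


class TestRefineCandidate:
    def _deletion_case(self, seed=0, err=0.0, n_reads=6):
        """Toy genome with a 500 bp deletion; reads are allele copies."""
        rng = np.random.default_rng(seed)
        genome = {"chr1": random_seq(rng, 8000)}
        s, e = 3000, 3500
        allele = genome["chr1"][:s] + genome["chr1"][e:]
        bp1, bp2 = Breakpoint("chr1", s - 1, "+"), Breakpoint("chr1", e, "-")
        reads = {}
        offsets = []
        for i in range(n_reads):
            lo = 2000 + 37 * i
            read = allele[lo:lo + 2000]
            reads[f"r{i}"] = noisy_copy(read, err, rng) if err else read
            q = s - lo
            offsets.append((q, q))
        cl = _cluster(offsets, bp1, bp2,
                      read_ids=[f"r{i}" for i in range(n_reads)])
        return genome, cl, (s, e)

    def test_exact_deletion_recovered(self, config):
        genome, cl, (s, e) = self._deletion_case()
        res = refine_candidate(cl, genome,
                               self._reads_for(cl, genome, s, e), config)
        assert not isinstance(res, RefineFailure)
        b1, b2, _ = canonicalize_junction(
            Breakpoint("chr1", s - 1, "+"), Breakpoint("chr1", e, "-"), "",
            genome)
        assert (res.bp1.pos, res.bp2.pos) == (b1.pos, b2.pos)
        assert res.inserted_seq == ""

    def _reads_for(self, cluster, genome, s, e, err=0.0, seed=0):
        rng = np.random.default_rng(seed)
        allele = genome["chr1"][:s] + genome["chr1"][e:]
        reads = {}
        for i, sig in enumerate(cluster.signals):
            lo = sig.read_offsets[0]
            start = s - lo
            read = allele[start:start + 2000]
            reads[sig.read_id] = noisy_copy(read, err, rng) if err else read
        return reads

    def test_noisy_deletion_recovered_exactly(self, config):
        genome, cl, (s, e) = self._deletion_case(seed=2, err=0.10, n_reads=10)
        res = refine_candidate(cl, genome,
                               self._reads_for(cl, genome, s, e, 0.10, 5),
                               config)
        assert not isinstance(res, RefineFailure)
        b1, b2, ins = canonicalize_junction(
            Breakpoint("chr1", s - 1, "+"), Breakpoint("chr1", e, "-"), "",
            genome)
        assert abs(res.bp1.pos - b1.pos) <= 2
        assert abs(res.bp2.pos - b2.pos) <= 2

    def test_inversion_junction_searches_revcomp(self, config):
        """A (+,+) junction aligns its second piece against the reverse
        complement and recovers the constructed truth."""
        rng = np.random.default_rng(9)
        genome = {"chr1": random_seq(rng, 9000)}
        s, e = 3000, 6000
        allele = genome["chr1"][:s] + revcomp(genome["chr1"][s:e]) \
            + genome["chr1"][e:]
        bp1 = Breakpoint("chr1", s - 1, "+")
        bp2 = Breakpoint("chr1", e - 1, "+")
        reads = {}
        offsets = []
        ids = []
        for i in range(5):
            lo = 2200 + 53 * i
            reads[f"r{i}"] = allele[lo:lo + 1600]
            offsets.append((s - lo, s - lo))
            ids.append(f"r{i}")
        cl = _cluster(offsets, bp1, bp2, ids)
        res = refine_candidate(cl, genome, reads, config)
        assert not isinstance(res, RefineFailure)
        assert (res.bp1.pos, res.bp2.pos) == (s - 1, e - 1)
        assert (res.bp1.dir, res.bp2.dir) == ("+", "+")

    def test_unalignable_consensus_fails_with_reason(self, config):
        rng = np.random.default_rng(4)
        genome = {"chr1": random_seq(rng, 5000)}
        bp1, bp2 = Breakpoint("chr1", 2000, "+"), Breakpoint("chr1", 2500, "-")
        cl = _cluster([(400, 400)] * 3, bp1, bp2, ["a", "b", "c"])
        junk = random_seq(rng, 800)
        res = refine_candidate(cl, genome,
                               {"a": junk, "b": junk, "c": junk}, config)
        assert isinstance(res, RefineFailure)


class TestCanonicalization:
    def test_exact_homology_absorbed_into_bp1(self):
        rng = np.random.default_rng(0)
        genome = {"chr1": random_seq(rng, 2000)}
        # engineer 4 bp homology: ref after bp1 equals allele continuation
        s, e = 800, 1200
        g = list(genome["chr1"])
        g[s:s + 4] = g[e:e + 4]
        genome["chr1"] = "".join(g)
        b1, b2, ins = canonicalize_junction(
            Breakpoint("chr1", s - 1, "+"), Breakpoint("chr1", e, "-"), "",
            genome)
        assert b1.pos - (s - 1) == b2.pos - e
        assert b1.pos >= s - 1 + 4

    def test_blunt_junction_unchanged(self):
        rng = np.random.default_rng(1)
        genome = {"chr1": random_seq(rng, 2000)}
        ins = "CCCCC" if genome["chr1"][801] != "C" else "GGGGG"
        b1, b2, out = canonicalize_junction(
            Breakpoint("chr1", 800, "+"), Breakpoint("chr1", 801, "-"),
            ins, genome)
        if genome["chr1"][801:806] != ins and \
                genome["chr1"][796:801] != ins:
            assert (b1.pos, b2.pos, out) == (800, 801, ins)
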
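import numpy as np
import pytest
from intervaltree import Interval, IntervalTree

from longsv import (Breakpoint, build_segment_pair, classify_read,
                    final_filters, validate_candidate)
from longsv.model import CanonicalSVRecord, ConsensusContig
from longsv.refine import RefinedCandidate
from longsv.library import random_seq
from longsv.seqs import revcomp

from .conftest import noisy_copy


def _refined(bp1, bp2, ins=""):
    return RefinedCandidate(bp1=bp1, bp2=bp2, inserted_seq=ins,
                            consensus=ConsensusContig("N", 2), score=0.0)


@pytest.fixture(scope="module")
def genome():
    rng = np.random.default_rng(8)
    return {"chr1": random_seq(rng, 20_000), "chr2": random_seq(rng, 20_000)}


class TestSegmentPair:
    def test_deletion_segment_concatenates_flanks(self, genome, config):
        sv = _refined(Breakpoint("chr1", 4999, "+"),
                      Breakpoint("chr1", 7000, "-"))
        pair = build_segment_pair(sv, genome, flank=300)
        assert pair.sv_segment == genome["chr1"][4700:5000] \
            + genome["chr1"][7000:7300]
        assert len(pair.sv_segment) == 600
        assert pair.junctions == (300, 300)

    def test_insertion_segment_includes_insert(self, genome):
        ins = "ACGT" * 250
        sv = _refined(Breakpoint("chr1", 4999, "+"),
                      Breakpoint("chr1", 5000, "-"), ins)
        pair = build_segment_pair(sv, genome, flank=300)
        assert len(pair.sv_segment) == 1600
        assert pair.sv_segment[300:1300] == ins

    def test_inversion_junction_flank_revcomped(self, genome):
        """A (+,+) adjacency takes the bp2-side flank reverse-complemented."""
        sv = _refined(Breakpoint("chr1", 4999, "+"),
                      Breakpoint("chr1", 7999, "+"))
        pair = build_segment_pair(sv, genome, flank=300)
        assert pair.sv_segment == genome["chr1"][4700:5000] \
            + revcomp(genome["chr1"][7700:8000])

    def test_chromosome_end_truncation_flagged(self, genome):
        sv = _refined(Breakpoint("chr1", 100, "+"),
                      Breakpoint("chr1", 7000, "-"))
        pair = build_segment_pair(sv, genome, flank=300)
        assert "flank_truncated" in pair.flags


class TestClassifyRead:
    @pytest.fixture()
    def pair(self, genome):
        sv = _refined(Breakpoint("chr1", 4999, "+"),
                      Breakpoint("chr1", 7000, "-"))
        return build_segment_pair(sv, genome, flank=300)

    def test_sv_allele_read_is_variant(self, pair, config):
        assert classify_read(pair.sv_segment, pair, config) == "variant"

    def test_reference_read_is_reference(self, pair, config):
        assert classify_read(pair.ref_segment1, pair, config) == "reference"
        assert classify_read(pair.ref_segment2, pair, config) == "reference"

    def test_strand_symmetry(self, pair, config):
        for read in (pair.sv_segment, pair.ref_segment1):
            assert classify_read(read, pair, config) == \
                classify_read(revcomp(read), pair, config)

    def test_noisy_variant_reads_still_variant(self, pair, config):
        rng = np.random.default_rng(2)
        for _ in range(5):
            read = noisy_copy(pair.sv_segment, 0.10, rng)
            assert classify_read(read, pair, config) == "variant"

    def test_junction_avoiding_read_not_variant(self, pair, genome, config):
        # matches only the left flank: no junction span, must not count
        read = genome["chr1"][4700:4960]
        assert classify_read(read, pair, config) != "variant"


class TestValidateCandidate:
    def _case(self, genome, config, n_tumor_var, n_control_var):
        sv = _refined(Breakpoint("chr1", 4999, "+"),
                      Breakpoint("chr1", 7000, "-"))
        pair = build_segment_pair(sv, genome, flank=config.validate_flank)
        tumor = [(f"tv{i}", pair.sv_segment) for i in range(n_tumor_var)]
        tumor += [(f"tr{i}", pair.ref_segment1) for i in range(4)]
        control = [(f"cv{i}", pair.sv_segment) for i in range(n_control_var)]
        control += [(f"cr{i}", pair.ref_segment1) for i in range(4)]
        return validate_candidate(sv, tumor, control, genome, config)

    def test_three_tumor_zero_control_kept(self, genome, config):
        rec = self._case(genome, config, 3, 0)
        assert isinstance(rec, CanonicalSVRecord)
        assert (rec.tumor_support, rec.control_support) == (3, 0)
        assert rec.tumor_vaf == pytest.approx(3 / 7)

    def test_two_tumor_rejected(self, genome, config):
        assert self._case(genome, config, 2, 0) == \
            "insufficient_tumor_support"

    def test_any_control_support_rejected(self, genome, config):
        assert self._case(genome, config, 5, 1) == "control_support"

    def test_uncovered_control_flagged(self, genome, config):
        sv = _refined(Breakpoint("chr1", 4999, "+"),
                      Breakpoint("chr1", 7000, "-"))
        pair = build_segment_pair(sv, genome, flank=config.validate_flank)
        tumor = [(f"t{i}", pair.sv_segment) for i in range(3)]
        rec = validate_candidate(sv, tumor, [], genome, config)
        assert "control_uncovered" in rec.flags

    def test_counting_idempotent(self, genome, config):
        sv = _refined(Breakpoint("chr1", 4999, "+"),
                      Breakpoint("chr1", 7000, "-"))
        pair = build_segment_pair(sv, genome, flank=config.validate_flank)
        tumor = [(f"t{i}", pair.sv_segment) for i in range(5)] \
            + [(f"n{i}", pair.ref_segment1) for i in range(5)]
        r1 = validate_candidate(sv, tumor, [], genome, config)
        r2 = validate_candidate(sv, tumor, [], genome, config)
        assert (r1.tumor_support, r1.tumor_vaf) == \
            (r2.tumor_support, r2.tumor_vaf)


def _rec(svtype, bp1pos, bp2pos, ins="", chrom="chr1"):
    return CanonicalSVRecord(
        Breakpoint(chrom, bp1pos, "+"), Breakpoint(chrom, bp2pos, "-"),
        ins, svtype, tumor_support=5)


class TestFinalFilters:
    def test_size_boundary_on_deletions(self):
        """A 99 bp deletion is removed, a 100 bp deletion kept."""
        short = _rec("DEL", 999, 1099)   # deleted span 99
        exact = _rec("DEL", 999, 1100)   # deleted span 100
        kept = final_filters([short, exact], None, 100)
        assert kept == [exact]

    def test_size_boundary_on_insertions(self):
        small = _rec("INS", 999, 1000, "A" * 99)
        ok = _rec("INS", 999, 1000, "A" * 100)
        assert final_filters([small, ok], None, 100) == [ok]

    def test_deletion_confined_in_simple_repeat_removed(self):
        trees = {"chr1": IntervalTree([Interval(900, 4000, "rep")])}
        confined = _rec("DEL", 1000, 3000)
        outside = _rec("DEL", 5000, 7005)
        straddling = _rec("DEL", 3900, 6000)
        kept = final_filters([confined, outside, straddling], trees, 100)
        assert kept == [outside, straddling]

    def test_translocations_not_size_filtered(self):
        tra = CanonicalSVRecord(Breakpoint("chr1", 100, "+"),
                                Breakpoint("chr2", 200, "-"), "", "TRA")
        assert final_filters([tra], None, 100) == [tra]
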
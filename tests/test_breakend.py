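import numpy as np
import pytest

from longsv import (Breakpoint, CanonicalSVRecord, annotate_contig,
                    build_breakend_contig, classify_breakend,
                    cluster_breakends, parse_softclips)
from longsv.breakend import (BreakendCluster, family_coverage,
                             filter_breakends_by_control, telomere_fraction)
from longsv.model import AlignmentRecord, SoftclipSignal
from longsv.library import TELOMERE_MOTIF, random_seq
from longsv.seqs import revcomp

from .conftest import noisy_copy


def _rec(read_id, chrom, start, strand, cigar, seq):
    from longsv.io import parse_cigar_string
    ops = parse_cigar_string(cigar)
    reflen = sum(n for op, n in ops if op in "MD=XN")
    return AlignmentRecord(read_id=read_id, chrom=chrom, start=start,
                           end=start + reflen, strand=strand, cigar=ops,
                           seq=seq)


class TestParseSoftclips:
    def test_right_clip_orientation_and_breakpoint(self):
        seq = "A" * 100 + "C" * 600
        (sig,) = parse_softclips(
            [_rec("r", "chr1", 5000, "+", "100M600S", seq)], min_clip=500)
        assert sig.bp == Breakpoint("chr1", 5099, "+")
        assert sig.clip_seq == "C" * 600
        assert sig.clip_side == "right"

    def test_left_clip_revcomped_junction_outward(self):
        seq = "C" * 600 + "A" * 100
        (sig,) = parse_softclips(
            [_rec("r", "chr1", 5000, "+", "600S100M", seq)], min_clip=500)
        assert sig.bp == Breakpoint("chr1", 5000, "-")
        assert sig.clip_seq == revcomp("C" * 600) == "G" * 600

    def test_short_clips_ignored(self):
        seq = "C" * 100 + "A" * 100
        assert parse_softclips(
            [_rec("r", "chr1", 5000, "+", "100S100M", seq)],
            min_clip=500) == []

    def test_split_alignment_clips_not_breakend_evidence(self):
        # the clipped half is aligned elsewhere by a supplementary record
        seq = "A" * 600 + "C" * 600
        prim = _rec("r", "chr1", 1000, "+", "600M600S", seq)
        supp = _rec("r", "chr2", 9000, "+", "600S600M", seq)
        supp.is_supplementary = True
        assert parse_softclips([prim, supp], min_clip=500) == []


def _clip_sig(read_id, pos, d="+", chrom="chr1"):
    return SoftclipSignal(read_id=read_id, bp=Breakpoint(chrom, pos, d),
                          clip_side="right" if d == "+" else "left",
                          clip_seq="A" * 600, clip_len=600)


class TestBreakendClustering:
    def test_nearby_same_direction_clips_cluster(self):
        sigs = [_clip_sig(f"r{i}", 1000 + 7 * i) for i in range(3)]
        (cl,) = cluster_breakends(sigs, margin=50, min_reads=3)
        assert len(cl.supporting_read_ids) == 3

    def test_opposite_directions_separate(self):
        sigs = [_clip_sig(f"r{i}", 1000) for i in range(3)] \
            + [_clip_sig(f"q{i}", 1000, "-") for i in range(3)]
        assert len(cluster_breakends(sigs, 50, 3)) == 2

    def test_control_clip_removes_cluster(self):
        clusters = cluster_breakends(
            [_clip_sig(f"r{i}", 1000) for i in range(3)], 50, 3)
        ctrl = [_clip_sig("c", 1030)]
        assert filter_breakends_by_control(clusters, ctrl, margin=200) == []
        far = [_clip_sig("c", 1900)]
        assert len(filter_breakends_by_control(clusters, far, 200)) == 1


class TestBreakendContig:
    def test_noisy_clips_polish_to_truth(self):
        rng = np.random.default_rng(6)
        inner = random_seq(rng, 100)
        truth = random_seq(rng, 1500)
        sigs = []
        for i in range(5):
            sigs.append(SoftclipSignal(
                read_id=f"r{i}", bp=Breakpoint("chr1", 1000, "+"),
                clip_side="right",
                clip_seq=noisy_copy(truth, 0.05, rng),
                clip_len=1500,
                inner_seq=noisy_copy(inner, 0.05, rng)))
        contig = build_breakend_contig(BreakendCluster(sigs))
        import edlib
        full = inner + truth
        ed = edlib.align(contig.seq, full, mode="NW")["editDistance"]
        assert 1 - ed / len(full) >= 0.99

    def test_two_clips_low_support_flag(self):
        sigs = [_clip_sig("a", 1000), _clip_sig("b", 1000)]
        contig = build_breakend_contig(BreakendCluster(sigs))
        assert "low_support" in contig.flags


@pytest.fixture(scope="module")
def breakend_genome():
    genome, _ = __import__("longsv").simulate.make_genome(
        length=80_000, n_chroms=2, seed=33)
    return genome


def _record(contig, chrom="chr1", pos=30_000):
    from longsv.model import SingleBreakendRecord
    return SingleBreakendRecord(bp=Breakpoint(chrom, pos, "+"),
                                contig=contig, tumor_support=5)


class TestClassification:
    def test_satellite_contig(self, breakend_genome, repeat_library,
                              monomer_set, config):
        hor = monomer_set.hors[0]
        contig = "".join(monomer_set.monomers[m]
                         for m in hor.monomer_order) * 2
        cls, ev, _ = classify_breakend(_record(contig), breakend_genome,
                                       repeat_library, (), config)
        assert cls == "Satellite"

    def test_telomere_contig(self, breakend_genome, repeat_library, config):
        contig = TELOMERE_MOTIF * 300
        cls, _, _ = classify_breakend(_record(contig), breakend_genome,
                                      repeat_library, (), config)
        assert cls == "Telomere"
        assert telomere_fraction(contig) == pytest.approx(1.0)

    def test_l1_unique_locus_chimera(self, breakend_genome, repeat_library,
                                     config):
        l1 = repeat_library.seqs["L1HS"]
        distant = breakend_genome["chr2"][40_000:42_000]
        contig = l1[-1000:] + distant
        cls, ev, _ = classify_breakend(_record(contig), breakend_genome,
                                       repeat_library, (), config)
        assert cls == "L1Mediated"

    def test_virus_chimera(self, breakend_genome, repeat_library, config):
        rng = np.random.default_rng(0)
        hbv = repeat_library.seqs["HBV"]
        contig = hbv[500:2000] + random_seq(rng, 500)
        cls, _, _ = classify_breakend(_record(contig), breakend_genome,
                                      repeat_library, (), config)
        assert cls == "VirusMediated"

    def test_unique_contig_rescued_as_canonical(self, breakend_genome,
                                                repeat_library, config):
        contig = breakend_genome["chr2"][40_000:43_000]
        cls, ev, rescued = classify_breakend(
            _record(contig), breakend_genome, repeat_library, (), config)
        assert cls == "RescuedCanonical"
        assert rescued is not None
        partner = rescued.bp2 if rescued.bp1.chrom == "chr1" else rescued.bp1
        assert (partner.chrom, partner.pos, partner.dir) == \
            ("chr2", 40_000, "-")

    def test_duplicate_of_canonical_dropped(self, breakend_genome,
                                            repeat_library, config):
        canon = CanonicalSVRecord(Breakpoint("chr1", 29_950, "+"),
                                  Breakpoint("chr2", 50_000, "-"), "", "TRA")
        contig = TELOMERE_MOTIF * 300
        cls, _, _ = classify_breakend(_record(contig), breakend_genome,
                                      repeat_library, [canon], config)
        assert cls is None

    def test_random_contig_unclassified(self, breakend_genome,
                                        repeat_library, config):
        rng = np.random.default_rng(5)
        contig = random_seq(rng, 2000)
        cls, _, _ = classify_breakend(_record(contig), breakend_genome,
                                      repeat_library, (), config)
        assert cls == "Unclassified"

    def test_classification_deterministic(self, breakend_genome,
                                          repeat_library, config):
        l1 = repeat_library.seqs["L1HS"]
        contig = l1[-800:] + breakend_genome["chr2"][40_000:41_500]
        results = {classify_breakend(_record(contig), breakend_genome,
                                     repeat_library, (), config)[0]
                   for _ in range(3)}
        assert len(results) == 1


def test_family_coverage_and_annotation(repeat_library):
    alu = repeat_library.seqs["AluY"]
    rng = np.random.default_rng(1)
    contig = alu + random_seq(rng, 300)
    anns = annotate_contig(contig, repeat_library)
    alu_hits = [a for a in anns if a.label == "AluY"]
    assert alu_hits and alu_hits[0].start < 20
    assert 0.4 < family_coverage(contig, anns, "SINE") < 0.6
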
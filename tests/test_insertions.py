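import numpy as np
import pytest

from longsv import (Breakpoint, CanonicalSVRecord, classify_insertion,
                    detect_5prime_inversion, detect_polya, detect_tsd,
                    infer_transduction_sources)
from longsv.model import LINE1SourceElement
from longsv.library import random_seq
from longsv.seqs import revcomp

from .oracles import polya_oracle


class TestPolyA:
    @pytest.mark.parametrize("seq,expected", [
        ("G" * 100 + "GG" + "A" * 25, (25, "3'")),
        ("G" * 100 + "A" * 9, None),                     # below min length
        ("G" * 100 + "AAAAAGAAAAA", (11, "3'")),         # merged across one G
        ("T" * 20 + "G" * 100, (20, "5'")),              # antisense tail
        ("G" * 120, None),
    ])
    def test_examples(self, seq, expected):
        assert detect_polya(seq) == expected

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(12)
        for _ in range(300):
            n = int(rng.integers(10, 100))
            seq = "".join(rng.choice(list("ACGTAA"))
                          for _ in range(n))
            assert detect_polya(seq) == polya_oracle(seq), seq


@pytest.fixture(scope="module")
def tsd_genome():
    rng = np.random.default_rng(3)
    return {"chr1": random_seq(rng, 5000)}


class TestTSD:
    def _rec(self, bp1pos, bp2pos, genome):
        return CanonicalSVRecord(Breakpoint("chr1", bp1pos, "+"),
                                 Breakpoint("chr1", bp2pos, "-"),
                                 "G" * 200, "INS")

    def test_overlapping_breakpoints_give_tsd(self, tsd_genome):
        length, seq = detect_tsd(self._rec(1014, 1000, tsd_genome), tsd_genome)
        assert length == 15
        assert seq == tsd_genome["chr1"][1000:1015]

    def test_blunt_insertion_no_tsd(self, tsd_genome):
        assert detect_tsd(self._rec(999, 1000, tsd_genome), tsd_genome) is None

    def test_tsd_bounds(self, tsd_genome):
        assert detect_tsd(self._rec(1003, 1000, tsd_genome), tsd_genome) is None
        assert detect_tsd(self._rec(1060, 1000, tsd_genome), tsd_genome) is None


class TestFivePrimeInversion:
    def test_sense_only_truncated_insert(self, repeat_library):
        l1 = repeat_library.seqs["L1HS"]
        segs, inv = detect_5prime_inversion(l1[3000:], l1)
        assert not inv

    def test_twin_priming_geometry_detected(self, repeat_library):
        l1 = repeat_library.seqs["L1HS"]
        insert = revcomp(l1[2000:2600]) + l1[2600:5500]
        segs, inv = detect_5prime_inversion(insert, l1)
        assert inv
        orients = [s.orientation for s in segs]
        assert orients[0] == "-" and "+" in orients

    def test_fully_antisense_insert_not_twin_priming(self, repeat_library):
        l1 = repeat_library.seqs["L1HS"]
        segs, inv = detect_5prime_inversion(revcomp(l1[2000:4500]), l1)
        assert not inv
        assert all(s.orientation == "-" for s in segs if s.length() > 100)


@pytest.fixture(scope="module")
def transduction_setup(repeat_library):
    rng = np.random.default_rng(21)
    genome = {"chr1": random_seq(rng, 120_000),
              "chr2": random_seq(rng, 120_000)}
    l1 = repeat_library.seqs["L1HS"]
    genome["chr1"] = genome["chr1"][:50_000] + l1 \
        + genome["chr1"][50_000 + len(l1):]
    sources = [LINE1SourceElement("chr1", 50_000, 50_000 + len(l1), "+",
                                  "src1", "reference")]
    downstream = genome["chr1"][50_000 + len(l1):50_000 + len(l1) + 1200]
    return genome, sources, downstream, l1


class TestClassifyInsertion:
    def test_panel_of_constructed_inserts(self, transduction_setup,
                                          repeat_library, transcripts,
                                          config):
        genome, sources, downstream, l1 = transduction_setup
        alu = repeat_library.seqs["AluY"]
        sva = repeat_library.seqs["SVA"]
        site = ("chr2", 80_000)
        panel = {
            "SoloLINE1": (l1[2500:] + "A" * 25, "SoloLINE1"),
            "SoloAlu": (alu + "A" * 15, "SoloAlu"),
            "SoloSVA": (sva + "A" * 12, "SoloSVA"),
            "PartneredTransduction": (l1[-800:] + downstream + "A" * 20,
                                      "PartneredTransduction"),
            "OrphanTransduction": (downstream + "A" * 18,
                                   "OrphanTransduction"),
            "ProcessedPseudogene": (transcripts[0].seq + "A" * 22,
                                    "ProcessedPseudogene"),
            "TandemDup": (genome["chr2"][80_000 - 900:80_000], "TandemDup"),
        }
        for name, (ins, want) in panel.items():
            ann = classify_insertion(ins, transcripts, repeat_library,
                                     genome, sources, site=site,
                                     config=config)
            assert ann.insertion_class == want, name

    def test_transduction_source_interval_reported(self, transduction_setup,
                                                   repeat_library,
                                                   transcripts, config):
        genome, sources, downstream, l1 = transduction_setup
        ann = classify_insertion(downstream + "A" * 18, transcripts,
                                 repeat_library, genome, sources,
                                 config=config)
        assert ann.transduction_source[:2] == ("chr1", 50_000)
        # run-merging may extend the tail into adjacent A-rich sequence
        assert ann.polya is not None
        assert ann.polya[0] >= 18 and ann.polya[1] == "3'"

    def test_uninformative_insert_is_other(self, transduction_setup,
                                           repeat_library, transcripts,
                                           config):
        genome, sources, _, _ = transduction_setup
        rng = np.random.default_rng(77)
        ann = classify_insertion(random_seq(rng, 400), transcripts,
                                 repeat_library, genome, sources,
                                 config=config)
        assert ann.insertion_class == "Other"

    def test_short_inserts_not_classified(self, transduction_setup,
                                          repeat_library, transcripts):
        genome, sources, _, _ = transduction_setup
        ann = classify_insertion("ACGT" * 10, transcripts, repeat_library,
                                 genome, sources)
        assert ann.insertion_class == "Other"
        assert ann.evidence.get("reason") == "too_short"


class TestTransductionSources:
    def test_grouping_and_window(self, transduction_setup, repeat_library,
                                 transcripts, config):
        genome, sources, downstream, l1 = transduction_setup
        anns = []
        for k in range(3):
            ins = downstream[200 * k:] + "A" * 15
            anns.append(classify_insertion(ins, transcripts, repeat_library,
                                           genome, sources, config=config))
        groups = infer_transduction_sources(anns, sources)
        assert set(groups) == {"src1"}
        assert len(groups["src1"]["events"]) == 3
        assert not groups["src1"]["nested"]

    def test_nested_source_flagged(self, transduction_setup, repeat_library,
                                   transcripts, config):
        genome, sources, downstream, _ = transduction_setup
        somatic_src = [LINE1SourceElement("chr1", 50_000, 56_000, "+",
                                          "som1", "somatic")]
        ann = classify_insertion(downstream + "A" * 15, transcripts,
                                 repeat_library, genome, somatic_src,
                                 config=config)
        groups = infer_transduction_sources([ann], somatic_src)
        assert groups["som1"]["nested"]
        assert ann.nested

    def test_far_downstream_not_attributed(self, transduction_setup,
                                           repeat_library, transcripts,
                                           config):
        genome, sources, _, _ = transduction_setup
        far = genome["chr1"][80_000:81_200]  # ~24 kb downstream of source
        ann = classify_insertion(far + "A" * 15, transcripts, repeat_library,
                                 genome, sources, config=config)
        assert ann.insertion_class == "Other"
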
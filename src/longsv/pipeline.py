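"""End-to-end orchestration of the two detection modules.

``call_canonical`` runs parsing, clustering, control subtraction,
consensus/jump-alignment refinement, read-level validation and the final
filters; ``call_breakends`` runs the soft-clip module and classification,
rescuing canonical SVs where the contig places uniquely.  ``run`` wires
both together from file paths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from intervaltree import IntervalTree

from . import breakend as be
from . import detect, refine, validate
from .config import Config
from .io import read_alignments, write_clusters_tsv
from .library import RepeatLibrary
from .model import AlignmentRecord, Breakpoint, CanonicalSVRecord
from .seqs import revcomp

log = logging.getLogger(__name__)


@dataclass
class Sample:
    """In-memory alignments of one sample plus lookup structures."""

    name: str
    records: list[AlignmentRecord]
    read_seqs: dict[str, str] = field(default_factory=dict)
    trees: dict[str, IntervalTree] = field(default_factory=dict)

    @classmethod
    def load(cls, path, name: str = "sample") -> "Sample":
        records = list(read_alignments(path, sample=name))
        return cls.from_records(records, name)

    @classmethod
    def from_records(cls, records: Sequence[AlignmentRecord],
                     name: str = "sample") -> "Sample":
        s = cls(name=name, records=list(records))
        for i, rec in enumerate(s.records):
            if rec.seq and rec.read_id not in s.read_seqs:
                s.read_seqs[rec.read_id] = (
                    rec.seq if rec.strand == "+" else revcomp(rec.seq))
            tree = s.trees.setdefault(rec.chrom, IntervalTree())
            if rec.end > rec.start:
                tree.addi(rec.start, rec.end, i)
        return s

    def window_reads(self, bp: Breakpoint, flank: int, half: int
                     ) -> list[tuple[str, str]]:
        """(read_id, window sequence) for reads overlapping bp ± flank;
        the window is the read subsequence around the breakpoint."""
        tree = self.trees.get(bp.chrom)
        if tree is None:
            return []
        out = []
        for iv in sorted(tree.overlap(bp.pos - flank, bp.pos + flank),
                         key=lambda iv: iv.data):
            rec = self.records[iv.data]
            if not rec.seq:
                continue
            q = _ref2query(rec, min(max(bp.pos, rec.start), rec.end - 1))
            if q is None:
                continue
            seq = rec.seq[max(0, q - half):q + half]
            if len(seq) >= 100:
                out.append((rec.read_id, seq))
        return out


def _ref2query(rec: AlignmentRecord, refpos: int) -> Optional[int]:
    """Query index (stored orientation) aligned at reference ``refpos``."""
    ref = rec.start
    q = 0
    for op, n in rec.cigar:
        if op in "M=X":
            if ref + n > refpos:
                return q + (refpos - ref)
            ref += n
            q += n
        elif op in "DN":
            if ref + n > refpos:
                return q
            ref += n
        elif op in "SI":
            q += n
    return q if ref >= refpos else None


# ---------------------------------------------------------------------------
# canonical module
# ---------------------------------------------------------------------------

def call_canonical(tumor: Sample, control: Sample,
                   reference: dict[str, str],
                   config: Optional[Config] = None,
                   panel: Sequence[Sample] = (),
                   simple_repeats=None,
                   clusters_tsv=None
                   ) -> tuple[list[CanonicalSVRecord], list[dict]]:
    """Full canonical SV module; returns (records, audit trail)."""
    cfg = config or Config()
    known = set(reference)
    audit: list[dict] = []

    t_signals = detect.parse_sv_signals(tumor.records, cfg.min_indel_size,
                                        known)
    clusters = detect.cluster_signals(t_signals, cfg.cluster_margin,
                                      cfg.min_tumor_read_pre)
    c_signals = detect.parse_sv_signals(control.records,
                                        cfg.control_min_indel_size, known)
    p_signals = []
    for p in panel:
        p_signals.extend(detect.parse_sv_signals(
            p.records, cfg.control_min_indel_size, known))
    n_before = len(clusters)
    clusters = detect.filter_by_control(clusters, c_signals, p_signals,
                                        cfg.control_margin)
    log.info("clusters: %d tumor, %d after control subtraction",
             n_before, len(clusters))
    if clusters_tsv:
        write_clusters_tsv(clusters, clusters_tsv)

    records: list[CanonicalSVRecord] = []
    seen_keys: set[tuple] = set()
    for cluster in clusters:
        desc = (f"{cluster.chrom1}:{cluster.bp1_range}{cluster.dirs[0]}-"
                f"{cluster.chrom2}:{cluster.bp2_range}{cluster.dirs[1]}")
        refined = refine.refine_candidate(cluster, reference,
                                          tumor.read_seqs, cfg)
        if isinstance(refined, refine.RefineFailure):
            audit.append({"cluster": desc, "stage": "refine",
                          "reason": refined.reason})
            continue
        key = (refined.bp1.chrom, refined.bp1.pos, refined.bp1.dir,
               refined.bp2.chrom, refined.bp2.pos, refined.bp2.dir)
        if key in seen_keys:
            audit.append({"cluster": desc, "stage": "refine",
                          "reason": "duplicate_junction"})
            continue
        seen_keys.add(key)

        half = cfg.validate_flank - 50
        t_reads, c_reads = [], []
        for bp in (refined.bp1, refined.bp2):
            t_reads.extend(tumor.window_reads(bp, cfg.validate_flank, half))
            c_reads.extend(control.window_reads(bp, cfg.validate_flank, half))
        result = validate.validate_candidate(refined, t_reads, c_reads,
                                             reference, cfg)
        if isinstance(result, str):
            audit.append({"cluster": desc, "stage": "validate",
                          "reason": result})
            continue
        records.append(result)

    records = validate.final_filters(records, simple_repeats,
                                     cfg.min_sv_size, cfg.simple_repeat_pad)
    records.sort(key=lambda r: (r.bp1.sort_key(), r.bp2.sort_key()))
    return records, audit


# ---------------------------------------------------------------------------
# single breakend module
# ---------------------------------------------------------------------------

def call_breakends(tumor: Sample, control: Sample,
                   reference: dict[str, str],
                   repeat_library: RepeatLibrary,
                   canonical_records: Sequence[CanonicalSVRecord] = (),
                   config: Optional[Config] = None,
                   panel: Sequence[Sample] = ()
                   ) -> tuple[list, list[CanonicalSVRecord], list[dict]]:
    """Single breakend module; returns (breakend records, rescued
    canonical records, audit trail)."""
    cfg = config or Config()
    audit: list[dict] = []

    t_clips = be.parse_softclips(tumor.records, cfg.min_clip,
                                 cfg.breakend_inner_margin)
    c_clips = be.parse_softclips(control.records, cfg.control_min_clip,
                                 cfg.breakend_inner_margin)
    for p in panel:
        c_clips.extend(be.parse_softclips(p.records, cfg.control_min_clip,
                                          cfg.breakend_inner_margin))
    clusters = be.cluster_breakends(t_clips, cfg.breakend_margin,
                                    cfg.min_tumor_read_pre)
    clusters = be.filter_breakends_by_control(clusters, c_clips,
                                              cfg.control_margin)

    breakends = []
    rescued_records: list[CanonicalSVRecord] = []
    for cluster in clusters:
        desc = f"{cluster.chrom}:{cluster.pos_range}{cluster.dir}"
        contig = be.build_breakend_contig(cluster, cfg.max_contig,
                                          cfg.breakend_inner_margin,
                                          cfg.max_consensus_inputs)
        half = cfg.validate_flank - 50
        t_reads = tumor.window_reads(cluster.bp, cfg.validate_flank, half)
        c_reads = control.window_reads(cluster.bp, cfg.validate_flank, half)
        result = be.refine_and_validate_breakend(cluster, contig, reference,
                                                 t_reads, c_reads, cfg)
        if isinstance(result, str):
            audit.append({"cluster": desc, "stage": "validate",
                          "reason": result})
            continue
        cls, evidence, rescued = be.classify_breakend(
            result, reference, repeat_library, canonical_records, cfg)
        if cls is None:
            audit.append({"cluster": desc, "stage": "classify",
                          "reason": "duplicate_of_canonical"})
            continue
        if cls == "RescuedCanonical" and rescued is not None:
            half2 = cfg.validate_flank - 50
            t2, c2 = [], []
            for bp in (rescued.bp1, rescued.bp2):
                t2.extend(tumor.window_reads(bp, cfg.validate_flank, half2))
                c2.extend(control.window_reads(bp, cfg.validate_flank, half2))
            vres = validate.validate_candidate(rescued, t2, c2, reference,
                                               cfg)
            if isinstance(vres, str):
                audit.append({"cluster": desc, "stage": "rescue",
                              "reason": vres})
                result.classification = "Unclassified"
                result.evidence = evidence
                breakends.append(result)
                continue
            kept = validate.final_filters([vres], None, cfg.min_sv_size,
                                          cfg.simple_repeat_pad)
            if kept:
                rescued_records.extend(kept)
            result.classification = "RescuedCanonical"
            result.evidence = evidence
            breakends.append(result)
            continue
        result.classification = cls
        result.evidence = evidence
        breakends.append(result)
    return breakends, rescued_records, audit


# ---------------------------------------------------------------------------
# file-level convenience
# ---------------------------------------------------------------------------

def run(tumor_path, control_path, reference: dict[str, str],
        config: Optional[Config] = None,
        panel_paths: Sequence = (),
        simple_repeats=None,
        repeat_library: Optional[RepeatLibrary] = None,
        with_breakends: bool = False):
    """Run the caller on SAM/BAM paths; returns a result dict."""
    cfg = config or Config()
    tumor = Sample.load(tumor_path, "tumor")
    control = Sample.load(control_path, "control")
    panel = [Sample.load(p, f"panel{i}") for i, p in enumerate(panel_paths)]
    canonical, audit = call_canonical(tumor, control, reference, cfg,
                                      panel, simple_repeats)
    out = {"canonical": canonical, "audit": audit, "breakends": [],
           "rescued": []}
    if with_breakends and repeat_library is not None:
        bnds, rescued, b_audit = call_breakends(
            tumor, control, reference, repeat_library, canonical, cfg, panel)
        out["breakends"] = bnds
        out["rescued"] = rescued
        out["audit"] = audit + b_audit
        out["canonical"] = sorted(
            canonical + rescued,
            key=lambda r: (r.bp1.sort_key(), r.bp2.sort_key()))
    return out
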
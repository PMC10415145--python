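"""Stage 4 of the canonical SV module: in-silico re-genotyping.

For each refined candidate the putative SV allele ("SV segment") and the
two reference-allele segments are rebuilt from the reference, every read
near either breakpoint in tumor and control is aligned against all three,
and the final ≥3 tumor / 0 control supporting-read rule plus the size and
simple-repeat filters are applied.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

import edlib
from intervaltree import IntervalTree

from .config import Config
from .model import CanonicalSVRecord, SegmentPair, svtype_of
from .refine import RefinedCandidate
from .seqs import revcomp

log = logging.getLogger(__name__)


def build_segment_pair(sv: RefinedCandidate, reference: dict[str, str],
                       flank: int = 300) -> SegmentPair:
    """Assemble the putative SV segment (flank1 + insert + flank2, each
    flank orientation-correct per breakpoint direction) and the two
    reference segments spanning each breakpoint."""
    flags: list[str] = []

    def clamp(chrom: str, lo: int, hi: int) -> str:
        seq = reference[chrom]
        lo2, hi2 = max(0, lo), min(len(seq), hi)
        if lo2 != lo or hi2 != hi:
            flags.append("flank_truncated")
        return seq[lo2:hi2]

    bp1, bp2 = sv.bp1, sv.bp2
    if bp1.dir == "+":
        flank1 = clamp(bp1.chrom, bp1.pos - flank + 1, bp1.pos + 1)
    else:
        flank1 = revcomp(clamp(bp1.chrom, bp1.pos, bp1.pos + flank))
    if bp2.dir == "-":
        flank2 = clamp(bp2.chrom, bp2.pos, bp2.pos + flank)
    else:
        flank2 = revcomp(clamp(bp2.chrom, bp2.pos - flank + 1, bp2.pos + 1))

    sv_segment = flank1 + sv.inserted_seq + flank2
    # reference segments get extra margin so read windows never overhang
    pad = flank + 60
    ref1 = clamp(bp1.chrom, bp1.pos - pad, bp1.pos + pad)
    ref2 = clamp(bp2.chrom, bp2.pos - pad, bp2.pos + pad)
    return SegmentPair(
        sv_segment=sv_segment, ref_segment1=ref1, ref_segment2=ref2,
        junctions=(len(flank1), len(flank1) + len(sv.inserted_seq)),
        flags=flags)


def _dissim(a: str, b: str) -> tuple[float, Optional[tuple[int, int]], bool]:
    """Normalized infix dissimilarity between two sequences.

    The shorter sequence is aligned inside the longer (free ends on the
    longer); returns (edit distance / shorter length, location within b
    when b was the longer, flag whether b was the longer)."""
    if not a or not b:
        return 1.0, None, False
    q, t = (a, b) if len(a) <= len(b) else (b, a)
    res = edlib.align(q, t, mode="HW", task="locations")
    d = res["editDistance"] / len(q)
    loc = None
    if t is b and res["locations"]:
        ts, te = res["locations"][0]
        loc = (int(ts), int(te) + 1)
    return d, loc, t is b


def classify_read(read_seq: str, pair: SegmentPair,
                  config: Optional[Config] = None) -> str:
    """Label one read 'variant', 'reference' or 'ambiguous'.

    The read window is aligned (both orientations, free-end infix mode)
    against the SV segment and against each reference segment.  It
    supports the variant when its SV-segment dissimilarity undercuts the
    best reference dissimilarity by the configured margin AND the
    alignment crosses a junction with at least ``min_span`` bases on each
    side; the symmetric condition gives 'reference'; anything else is
    ambiguous and counted neither way.
    """
    cfg = config or Config()
    if not read_seq:
        return "ambiguous"
    rc = revcomp(read_seq)
    sv_hits = [_dissim(s, pair.sv_segment) for s in (read_seq, rc)]
    d_sv, loc, in_seg = min(sv_hits, key=lambda h: h[0])
    d_ref = min(_dissim(s, seg)[0]
                for s in (read_seq, rc)
                for seg in (pair.ref_segment1, pair.ref_segment2) if seg)
    if d_ref - d_sv > cfg.score_margin:
        if _spans_junction(loc if in_seg else None, pair, cfg):
            return "variant"
        return "ambiguous"
    if d_sv - d_ref > cfg.score_margin:
        return "reference"
    return "ambiguous"


def _spans_junction(loc: Optional[tuple[int, int]], pair: SegmentPair,
                    cfg: Config) -> bool:
    if loc is None:
        # the read contains the whole SV segment, junctions included
        return True
    ts, te = loc
    seg_len = len(pair.sv_segment)
    for j in pair.junctions:
        lo = max(0, j - cfg.min_span)
        hi = min(seg_len, j + cfg.min_span)
        if ts <= lo and te >= hi:
            return True
    return False


def validate_candidate(sv: RefinedCandidate,
                       tumor_reads: Iterable[tuple[str, str]],
                       control_reads: Iterable[tuple[str, str]],
                       reference: dict[str, str],
                       config: Optional[Config] = None):
    """Re-genotype every nearby read and apply the support-count rule.

    ``tumor_reads``/``control_reads`` are (read_id, window_sequence) pairs
    for reads overlapping either breakpoint (one entry per read per
    breakpoint window; entries for the same read are merged, variant
    taking precedence).  Returns a :class:`CanonicalSVRecord` or a
    rejection reason string.
    """
    cfg = config or Config()
    pair = build_segment_pair(sv, reference, flank=cfg.validate_flank)

    def count(reads) -> tuple[dict[str, str], int, int]:
        label: dict[str, str] = {}
        rank = {"ambiguous": 0, "reference": 1, "variant": 2}
        for read_id, seq in reads:
            cls = classify_read(seq, pair, cfg)
            if rank[cls] > rank.get(label.get(read_id, "ambiguous"), 0):
                label[read_id] = cls
            label.setdefault(read_id, cls)
        var = sum(1 for v in label.values() if v == "variant")
        ref = sum(1 for v in label.values() if v == "reference")
        return label, var, ref

    t_label, t_var, t_ref = count(tumor_reads)
    c_label, c_var, _ = count(control_reads)

    flags = list(sv.flags) + list(pair.flags)
    if not c_label:
        flags.append("control_uncovered")
    if t_var < cfg.min_tumor_support:
        return "insufficient_tumor_support"
    if c_var > cfg.max_control_support:
        return "control_support"

    vaf = t_var / (t_var + t_ref) if (t_var + t_ref) else 0.0
    supporting = sorted(r for r, v in t_label.items() if v == "variant")
    return CanonicalSVRecord(
        bp1=sv.bp1, bp2=sv.bp2, inserted_seq=sv.inserted_seq,
        svtype=svtype_of(sv.bp1, sv.bp2, sv.inserted_seq),
        tumor_support=t_var, control_support=c_var, tumor_vaf=vaf,
        supporting_read_ids=supporting,
        homology_len=sv.homology_len, flags=flags)


def final_filters(records: Iterable[CanonicalSVRecord],
                  simple_repeats: Optional[dict[str, IntervalTree]] = None,
                  min_size: int = 100,
                  pad: int = 10) -> list[CanonicalSVRecord]:
    """Final reporting filters: DEL/INS below ``min_size`` and DEL/INS
    confined within one (padded) simple-repeat interval are removed."""
    out: list[CanonicalSVRecord] = []
    for r in records:
        if r.svtype == "DEL" and r.deleted_span < min_size:
            continue
        if r.svtype == "INS" and len(r.inserted_seq) < min_size:
            continue
        if r.svtype in ("DEL", "INS") and simple_repeats:
            tree = simple_repeats.get(r.bp1.chrom)
            if tree is not None and _confined(tree, r, pad):
                continue
        out.append(r)
    return out


def _confined(tree: IntervalTree, r: CanonicalSVRecord, pad: int) -> bool:
    for iv in tree.at(r.bp1.pos):
        if iv.begin - pad <= r.bp1.pos and iv.begin - pad <= r.bp2.pos \
                and r.bp1.pos < iv.end + pad and r.bp2.pos < iv.end + pad:
            return True
    # bp1 just left of the interval start can still be confined given the pad
    for iv in tree.overlap(r.bp1.pos - pad, r.bp1.pos + pad + 1):
        if iv.begin - pad <= r.bp1.pos < iv.end + pad \
                and iv.begin - pad <= r.bp2.pos < iv.end + pad:
            return True
    return False
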
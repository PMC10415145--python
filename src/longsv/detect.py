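"""Stage 1-2 of the canonical SV module.

Per-read junction signals are pulled out of CIGAR indels and split
(primary/supplementary) alignments, clustered by single-linkage within a
positional margin, and candidates with apparent support in the matched
control or a panel of normals are removed.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Optional, Sequence

from .io import parse_cigar_string
from .model import (AlignmentRecord, Breakpoint, BreakpointSignal,
                    SVCandidateCluster)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# per-read segment geometry
# ---------------------------------------------------------------------------

def _cigar_ref_len(cigar) -> int:
    return sum(n for op, n in cigar if op in "MDN=X")


def _cigar_query_len(cigar) -> int:
    return sum(n for op, n in cigar if op in "MIS=XH")


def _segment_from_cigar(chrom: str, pos: int, strand: str, cigar) -> dict:
    """Describe one aligned segment: reference span + query span in
    original-read orientation."""
    left = cigar[0][1] if cigar[0][0] in "SH" else 0
    right = cigar[-1][1] if cigar[-1][0] in "SH" else 0
    qlen = _cigar_query_len(cigar)
    qs, qe = left, qlen - right
    if strand == "-":
        qs, qe = qlen - qe, qlen - qs
    return {"chrom": chrom, "start": pos, "end": pos + _cigar_ref_len(cigar),
            "strand": strand, "qs": qs, "qe": qe}


def read_segments(records: Sequence[AlignmentRecord],
                  known_chroms: Optional[set[str]] = None) -> list[dict]:
    """All aligned segments of one read, ordered along the original read.

    Segments come from the actual primary/supplementary records; SA-tag
    entries fill in partners that have no record of their own.
    """
    segs: list[dict] = []
    seen: set[tuple] = set()
    unknown = 0
    for rec in records:
        key = (rec.chrom, rec.start, rec.strand)
        if key in seen:
            continue
        seen.add(key)
        segs.append(_segment_from_cigar(rec.chrom, rec.start, rec.strand,
                                        rec.cigar))
    for rec in records:
        for chrom, pos, strand, cigstr in rec.sa_segments:
            if known_chroms is not None and chrom not in known_chroms:
                unknown += 1
                continue
            key = (chrom, pos, strand)
            if key in seen:
                continue
            seen.add(key)
            segs.append(_segment_from_cigar(chrom, pos, strand,
                                            parse_cigar_string(cigstr)))
    if unknown:
        log.debug("skipped %d SA segments on unknown chromosomes", unknown)
    segs.sort(key=lambda s: s["qs"])
    return segs


# ---------------------------------------------------------------------------
# signal parsing
# ---------------------------------------------------------------------------

def _ordered_signal(read_id: str, bpa: Breakpoint, bpb: Breakpoint,
                    insert_len: int, source: str,
                    offsets: tuple[int, int]) -> BreakpointSignal:
    """Canonically order the breakend pair by genome position."""
    if bpb.sort_key() < bpa.sort_key():
        return BreakpointSignal(read_id, bpb, bpa, insert_len, source,
                                offsets, bp1_first=False)
    return BreakpointSignal(read_id, bpa, bpb, insert_len, source,
                            offsets, bp1_first=True)


def _cigar_indel_signals(rec: AlignmentRecord, min_size: int
                         ) -> list[BreakpointSignal]:
    out: list[BreakpointSignal] = []
    qlen = rec.query_length()
    ref = rec.start
    q = 0
    for op, n in rec.cigar:
        if op in "M=X":
            ref += n
            q += n
        elif op in "SH":
            q += n
        elif op == "I":
            if n >= min_size and ref > rec.start:
                bp1 = Breakpoint(rec.chrom, ref - 1, "+")
                bp2 = Breakpoint(rec.chrom, ref, "-")
                if rec.strand == "+":
                    offsets, first = (q, q + n), True
                else:
                    offsets, first = (qlen - q - n, qlen - q), False
                out.append(BreakpointSignal(rec.read_id, bp1, bp2, n,
                                            "cigar_indel", offsets, first))
            q += n
        elif op in "DN":
            if n >= min_size:
                bp1 = Breakpoint(rec.chrom, ref - 1, "+")
                bp2 = Breakpoint(rec.chrom, ref + n, "-")
                if rec.strand == "+":
                    offsets, first = (q, q), True
                else:
                    offsets, first = (qlen - q, qlen - q), False
                out.append(BreakpointSignal(rec.read_id, bp1, bp2, 0,
                                            "cigar_indel", offsets, first))
            ref += n
    return out


def _split_signals(read_id: str, segs: list[dict]) -> list[BreakpointSignal]:
    """One signal per adjacent pair of aligned segments along the read.

    Junction orientation follows from each segment's strand: the read
    leaves segment A at its reference end when A is forward (dir '+') or at
    its reference start when reverse (dir '-'); it enters segment B at the
    mirrored side.
    """
    out: list[BreakpointSignal] = []
    for a, b in zip(segs, segs[1:]):
        if min(a["qe"], b["qe"]) - max(a["qs"], b["qs"]) > 0.5 * min(
                a["qe"] - a["qs"], b["qe"] - b["qs"]):
            continue  # mostly-overlapping query spans: not a junction
        if a["strand"] == "+":
            bpa = Breakpoint(a["chrom"], a["end"] - 1, "+")
        else:
            bpa = Breakpoint(a["chrom"], a["start"], "-")
        if b["strand"] == "+":
            bpb = Breakpoint(b["chrom"], b["start"], "-")
        else:
            bpb = Breakpoint(b["chrom"], b["end"] - 1, "+")
        insert = max(0, b["qs"] - a["qe"])
        sig = _ordered_signal(read_id, bpa, bpb, insert, "split_alignment",
                              (a["qe"], b["qs"]))
        out.append(sig)
    return out


def parse_sv_signals(alignments: Iterable[AlignmentRecord],
                     min_indel_size: int = 50,
                     known_chroms: Optional[set[str]] = None
                     ) -> list[BreakpointSignal]:
    """Extract junction signals from one sample's alignments.

    One signal per sufficiently large D/I CIGAR operation and one per
    adjacent primary/supplementary segment pair, deduplicated per read and
    junction.
    """
    by_read: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for rec in alignments:
        if rec.is_secondary:
            continue
        by_read[rec.read_id].append(rec)

    signals: list[BreakpointSignal] = []
    seen: set[tuple] = set()
    for read_id, recs in by_read.items():
        cand: list[BreakpointSignal] = []
        for rec in recs:
            cand.extend(_cigar_indel_signals(rec, min_indel_size))
        segs = read_segments(recs, known_chroms)
        if len(segs) > 1:
            cand.extend(_split_signals(read_id, segs))
        for sig in cand:
            key = (read_id, sig.bp1.chrom, sig.bp1.pos, sig.bp1.dir,
                   sig.bp2.chrom, sig.bp2.pos, sig.bp2.dir)
            if key in seen:
                continue
            seen.add(key)
            signals.append(sig)
    return signals


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def cluster_signals(signals: Sequence[BreakpointSignal],
                    cluster_margin: int = 200,
                    min_reads: int = 3) -> list[SVCandidateCluster]:
    """Single-linkage clustering of signals sharing chromosome/direction
    pairs, joining two signals when both breakpoints lie within the margin
    (transitive closure).  Clusters with fewer distinct reads than
    ``min_reads`` are discarded early."""
    by_key: dict[tuple, list[int]] = defaultdict(list)
    for i, s in enumerate(signals):
        by_key[s.key()].append(i)

    uf = _UnionFind(len(signals))
    for idxs in by_key.values():
        idxs.sort(key=lambda i: signals[i].bp1.pos)
        for ai in range(len(idxs)):
            a = signals[idxs[ai]]
            for bi in range(ai + 1, len(idxs)):
                b = signals[idxs[bi]]
                if b.bp1.pos - a.bp1.pos > cluster_margin:
                    break
                if abs(a.bp2.pos - b.bp2.pos) <= cluster_margin:
                    uf.union(idxs[ai], idxs[bi])

    groups: dict[int, list[BreakpointSignal]] = defaultdict(list)
    for i, s in enumerate(signals):
        groups[uf.find(i)].append(s)

    clusters: list[SVCandidateCluster] = []
    for members in groups.values():
        if len({m.read_id for m in members}) < min_reads:
            continue
        bp1s = [m.bp1.pos for m in members]
        bp2s = [m.bp2.pos for m in members]
        clusters.append(SVCandidateCluster(
            signals=sorted(members, key=lambda m: (m.bp1.pos, m.read_id)),
            bp1_range=(min(bp1s), max(bp1s)),
            bp2_range=(min(bp2s), max(bp2s)),
        ))
    clusters.sort(key=lambda c: (c.signals[0].bp1.sort_key(),
                                 c.signals[0].bp2.sort_key()))
    return clusters


def filter_by_control(clusters: Sequence[SVCandidateCluster],
                      control_signals: Sequence[BreakpointSignal],
                      panel_signals: Sequence[BreakpointSignal] = (),
                      control_margin: int = 200) -> list[SVCandidateCluster]:
    """Drop clusters with any matching control/panel signal.

    A signal matches when chromosome and direction pairs agree and both of
    its breakpoints fall within ``control_margin`` of the cluster's
    breakpoint ranges.  Control evidence is deliberately asymmetric: a
    single permissively-parsed control read suffices for removal.
    """
    by_key: dict[tuple, list[BreakpointSignal]] = defaultdict(list)
    for s in list(control_signals) + list(panel_signals):
        by_key[s.key()].append(s)

    kept: list[SVCandidateCluster] = []
    for c in clusters:
        key = (c.chrom1, c.chrom2, c.dirs[0], c.dirs[1])
        lo1, hi1 = c.bp1_range[0] - control_margin, c.bp1_range[1] + control_margin
        lo2, hi2 = c.bp2_range[0] - control_margin, c.bp2_range[1] + control_margin
        matched = any(lo1 <= s.bp1.pos <= hi1 and lo2 <= s.bp2.pos <= hi2
                      for s in by_key.get(key, ()))
        if not matched:
            kept.append(c)
    return kept
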
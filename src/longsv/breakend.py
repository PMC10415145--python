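"""Single breakend SV module.

Detects tumor-specific breakpoints whose partner sequence cannot be placed
on the reference: long soft-clips are clustered, the clipped sequence is
polished into a breakend contig, the breakpoint is fixed at single-base
resolution, the candidate is re-genotyped against tumor and control reads,
and the contig is classified (satellite / simple repeat / telomere /
LINE1- or Alu-mediated / virus-mediated) or rescued into a canonical SV
when its partner locus is unambiguous after all.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Optional, Sequence

from .config import Config
from .library import RepeatLibrary, TELOMERE_MOTIF
from .model import (AlignmentRecord, AnnotationInterval, Breakpoint,
                    CanonicalSVRecord, ConsensusContig, SingleBreakendRecord)
from .refine import RefinedCandidate, build_consensus
from .seqs import best_local, revcomp, unique_genome_hit
from .validate import SegmentPair, classify_read

log = logging.getLogger(__name__)

from .model import SoftclipSignal


# ---------------------------------------------------------------------------
# parsing / clustering
# ---------------------------------------------------------------------------

def parse_softclips(alignments: Iterable[AlignmentRecord],
                    min_clip: int = 500,
                    inner_margin: int = 100) -> list[SoftclipSignal]:
    """One signal per soft clip of at least ``min_clip`` bases.

    ``clip_seq`` is normalized so position 0 is adjacent to the junction
    (left clips are reverse-complemented).  Clips whose bases are aligned
    by another segment of the same read are skipped — those are split
    alignments, i.e. canonical-SV evidence, not breakends."""
    by_read: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for rec in alignments:
        if not rec.is_secondary and rec.seq:
            by_read[rec.read_id].append(rec)

    out: list[SoftclipSignal] = []
    for read_id, recs in by_read.items():
        spans = [r.query_span() for r in recs]
        for rec in recs:
            L = len(rec.seq)
            for side in ("left", "right"):
                clip = rec.left_clip if side == "left" else rec.right_clip
                if clip < min_clip:
                    continue
                # clip span: stored orientation, then original-read coords
                span = (0, clip) if side == "left" else (L - clip, L)
                if rec.strand == "-":
                    span = (L - span[1], L - span[0])
                covered = sum(max(0, min(span[1], qe) - max(span[0], qs))
                              for qs, qe in spans
                              if (qs, qe) != rec.query_span())
                if covered > 0.5 * clip:
                    continue
                if side == "right":
                    bp = Breakpoint(rec.chrom, rec.end - 1, "+")
                    clip_seq = rec.seq[L - clip:]
                    inner = rec.seq[max(0, L - clip - inner_margin):L - clip]
                else:
                    bp = Breakpoint(rec.chrom, rec.start, "-")
                    clip_seq = revcomp(rec.seq[:clip])
                    inner = revcomp(rec.seq[clip:clip + inner_margin])
                out.append(SoftclipSignal(
                    read_id=read_id, bp=bp, clip_side=side,
                    clip_seq=clip_seq, clip_len=clip, inner_seq=inner))
    return out


class BreakendCluster:
    def __init__(self, signals: list[SoftclipSignal]):
        self.signals = sorted(signals, key=lambda s: (s.bp.pos, s.read_id))
        poss = [s.bp.pos for s in self.signals]
        self.pos_range = (min(poss), max(poss))

    @property
    def chrom(self) -> str:
        return self.signals[0].bp.chrom

    @property
    def dir(self) -> str:
        return self.signals[0].bp.dir

    @property
    def supporting_read_ids(self) -> list[str]:
        return sorted({s.read_id for s in self.signals})

    @property
    def bp(self) -> Breakpoint:
        poss = sorted(s.bp.pos for s in self.signals)
        return Breakpoint(self.chrom, poss[len(poss) // 2], self.dir)


def cluster_breakends(signals: Sequence[SoftclipSignal], margin: int = 50,
                      min_reads: int = 3) -> list[BreakendCluster]:
    """Single-linkage clustering of clip signals on (chrom, dir, pos)."""
    by_key: dict[tuple, list[SoftclipSignal]] = defaultdict(list)
    for s in signals:
        by_key[(s.bp.chrom, s.bp.dir)].append(s)
    clusters = []
    for sigs in by_key.values():
        sigs.sort(key=lambda s: s.bp.pos)
        cur: list[SoftclipSignal] = []
        for s in sigs:
            if cur and s.bp.pos - cur[-1].bp.pos > margin:
                clusters.append(cur)
                cur = []
            cur.append(s)
        if cur:
            clusters.append(cur)
    out = [BreakendCluster(c) for c in clusters
           if len({s.read_id for s in c}) >= min_reads]
    out.sort(key=lambda c: (c.bp.sort_key(), c.dir))
    return out


def filter_breakends_by_control(clusters: Sequence[BreakendCluster],
                                control_signals: Sequence[SoftclipSignal],
                                margin: int = 200) -> list[BreakendCluster]:
    """Remove clusters with any control clip at the same oriented position."""
    by_key: dict[tuple, list[int]] = defaultdict(list)
    for s in control_signals:
        by_key[(s.bp.chrom, s.bp.dir)].append(s.bp.pos)
    kept = []
    for c in clusters:
        poss = by_key.get((c.chrom, c.dir), ())
        lo, hi = c.pos_range[0] - margin, c.pos_range[1] + margin
        if not any(lo <= p <= hi for p in poss):
            kept.append(c)
    return kept


# ---------------------------------------------------------------------------
# contig building + validation
# ---------------------------------------------------------------------------

def build_breakend_contig(cluster: BreakendCluster,
                          max_contig: int = 5000,
                          inner_margin: int = 100,
                          max_inputs: int = 12) -> ConsensusContig:
    """Polish the clipped sequences (each prefixed by ``inner_margin``
    aligned bases inside the breakpoint) into a consensus contig."""
    inputs = []
    used = set()
    for s in sorted(cluster.signals, key=lambda s: (-s.clip_len, s.read_id)):
        if s.read_id in used:
            continue
        used.add(s.read_id)
        inputs.append((s.inner_seq + s.clip_seq)[:max_contig + inner_margin])
        if len(inputs) >= max_inputs:
            break
    if len(inputs) == 1:
        return ConsensusContig(seq=inputs[0], n_inputs=1,
                               flags=["low_support"])
    contig = build_consensus(inputs)
    if contig.n_inputs == 2:
        contig.flags.append("low_support")
    contig.seq = contig.seq[:max_contig + inner_margin]
    return contig


def refine_and_validate_breakend(cluster: BreakendCluster,
                                 contig: ConsensusContig,
                                 reference: dict[str, str],
                                 tumor_reads: Iterable[tuple[str, str]],
                                 control_reads: Iterable[tuple[str, str]],
                                 config: Optional[Config] = None):
    """Fix the breakpoint at single-base resolution and re-genotype.

    Returns a :class:`SingleBreakendRecord` (contig = polished sequence
    *beyond* the breakpoint) or a rejection reason string."""
    cfg = config or Config()
    W = cfg.refine_window
    chrom_seq = reference[cluster.chrom]
    lo = max(0, cluster.pos_range[0] - W - cfg.breakend_inner_margin)
    hi = min(len(chrom_seq), cluster.pos_range[1] + W + cfg.breakend_inner_margin)
    window = chrom_seq[lo:hi]
    head = contig.seq[:cfg.breakend_inner_margin + 50]
    probe = head if cluster.dir == "+" else revcomp(head)
    hit = best_local(probe, window)
    if hit is None:
        return "breakpoint_unalignable"
    _, (qs, qe), (ts, te) = hit
    if cluster.dir == "+":
        pos = lo + te - 1
        consumed = qe  # contig bases accounted for by the aligned side
    else:
        pos = lo + ts
        consumed = len(probe) - qs
    bp = Breakpoint(cluster.chrom, pos, cluster.dir)
    beyond = contig.seq[consumed:]
    if not beyond:
        return "no_sequence_beyond_breakpoint"

    flank = cfg.validate_flank
    if bp.dir == "+":
        fl = chrom_seq[max(0, bp.pos - flank + 1):bp.pos + 1]
    else:
        fl = revcomp(chrom_seq[bp.pos:bp.pos + flank])
    ref_seg = chrom_seq[max(0, bp.pos - flank - 60):bp.pos + flank + 60]
    pair = SegmentPair(sv_segment=fl + beyond, ref_segment1=ref_seg,
                       ref_segment2=ref_seg,
                       junctions=(len(fl), len(fl)))

    def count(reads):
        label = {}
        rank = {"ambiguous": 0, "reference": 1, "variant": 2}
        for read_id, seq in reads:
            cls = classify_read(seq, pair, cfg)
            if rank[cls] > rank.get(label.get(read_id, "ambiguous"), 0):
                label[read_id] = cls
            label.setdefault(read_id, cls)
        return (sum(1 for v in label.values() if v == "variant"),
                sum(1 for v in label.values() if v == "reference"), label)

    t_var, _, _ = count(tumor_reads)
    c_var, _, c_label = count(control_reads)
    if t_var < cfg.min_tumor_support:
        return "insufficient_tumor_support"
    if c_var > cfg.max_control_support:
        return "control_support"
    flags = list(contig.flags)
    if not c_label:
        flags.append("control_uncovered")
    return SingleBreakendRecord(bp=bp, contig=beyond, tumor_support=t_var,
                                control_support=c_var, flags=flags)


# ---------------------------------------------------------------------------
# annotation + classification
# ---------------------------------------------------------------------------

def annotate_contig(contig: str, library: RepeatLibrary,
                    min_len: int = 50, max_hits_per_elem: int = 6
                    ) -> list[AnnotationInterval]:
    """Iterative masked local alignment of each consensus against the
    contig; non-overlapping hits become annotation intervals."""
    out: list[AnnotationInterval] = []
    for name, cons in sorted(library.seqs.items()):
        fam = library.families.get(name, "Unknown")
        for orient in ("+", "-"):
            target = contig
            masked = list(contig)
            query = cons if orient == "+" else revcomp(cons)
            for _ in range(max_hits_per_elem):
                hit = best_local(query, "".join(masked))
                if hit is None:
                    break
                score, (qs, qe), (ts, te) = hit
                if te - ts < min_len:
                    break
                ident = min(1.0, score / (2.0 * (te - ts)))
                out.append(AnnotationInterval(
                    start=ts, end=te, label=name, identity=ident,
                    orientation=orient, family=fam))
                for k in range(ts, te):
                    masked[k] = "N"
    out.sort(key=lambda a: (a.start, -a.length()))
    return _prune_overlaps(out)


def _prune_overlaps(intervals: list[AnnotationInterval]
                    ) -> list[AnnotationInterval]:
    kept: list[AnnotationInterval] = []
    for iv in sorted(intervals, key=lambda a: (-(a.length() * a.identity),
                                               a.start)):
        if all(min(iv.end, k.end) - max(iv.start, k.start) < 0.5 * iv.length()
               for k in kept):
            kept.append(iv)
    kept.sort(key=lambda a: a.start)
    return kept


def family_coverage(contig: str, annotations: list[AnnotationInterval],
                    *families: str) -> float:
    if not contig:
        return 0.0
    mask = [False] * len(contig)
    for a in annotations:
        if a.family in families:
            for k in range(a.start, min(a.end, len(contig))):
                mask[k] = True
    return sum(mask) / len(contig)


def telomere_fraction(contig: str, motif: str = TELOMERE_MOTIF) -> float:
    if len(contig) < len(motif):
        return 0.0
    n = 0
    for m in (motif, revcomp(motif)):
        n += contig.count(m)
    return min(1.0, n * len(motif) / len(contig))


def classify_breakend(record: SingleBreakendRecord,
                      reference: dict[str, str],
                      repeat_library: RepeatLibrary,
                      canonical_records: Sequence[CanonicalSVRecord] = (),
                      config: Optional[Config] = None,
                      validate_reads: Optional[tuple] = None):
    """Assign the breakend category following the fixed decision order.

    Returns (classification, evidence, rescued_candidate_or_None);
    classification None means the breakend duplicates an already-called
    canonical SV and should be dropped.  ``validate_reads`` — a
    (tumor_reads, control_reads) pair — enables full re-validation of
    rescued canonical candidates by the caller.
    """
    cfg = config or Config()
    contig = record.contig

    # (1) duplicate of an existing canonical record
    for c in canonical_records:
        for bp in (c.bp1, c.bp2):
            if bp.chrom == record.bp.chrom \
                    and abs(bp.pos - record.bp.pos) <= cfg.duplicate_margin:
                return None, [], None

    evidence = annotate_contig(contig, repeat_library)

    # (2) whole-contig unique placement -> rescued canonical SV; contigs
    # are polished, so the whole-length identity must be high too
    hit = unique_genome_hit(contig, reference, max_div=0.15)
    if hit is not None:
        ed, chrom, ts, te, orient = hit
        if (te - ts) >= cfg.rescue_cov * len(contig) \
                and ed <= 0.15 * len(contig):
            partner = (Breakpoint(chrom, ts, "-") if orient == "+"
                       else Breakpoint(chrom, te - 1, "+"))
            bp1, bp2 = record.bp, partner
            swapped = bp2.sort_key() < bp1.sort_key()
            if swapped:
                bp1, bp2 = bp2, bp1
            rescued = RefinedCandidate(
                bp1=bp1, bp2=bp2, inserted_seq="",
                consensus=ConsensusContig(seq=contig, n_inputs=1),
                score=0.0, flags=["rescued_from_breakend"])
            evidence.append(AnnotationInterval(
                start=0, end=te - ts, label=f"{chrom}:{ts}-{te}",
                identity=1.0 - ed / max(1, te - ts), orientation=orient,
                family="Genome"))
            return "RescuedCanonical", evidence, rescued

    # (3) repeat-dominated contigs
    if family_coverage(contig, evidence, "Satellite") >= cfg.repeat_cov \
            and telomere_fraction(contig) < cfg.repeat_cov:
        return "Satellite", evidence, None
    if telomere_fraction(contig) >= cfg.repeat_cov:
        return "Telomere", evidence, None
    if family_coverage(contig, evidence, "Simple_repeat") >= cfg.repeat_cov:
        return "SimpleRepeat", evidence, None

    # (4) mobile-element-mediated: element prefix + distant unique remainder
    for fam, label in (("LINE", "L1Mediated"), ("SINE", "AluMediated")):
        pre = [a for a in evidence
               if a.family == fam and a.start < 6000
               and a.length() >= cfg.min_element_match]
        if not pre:
            continue
        elem_end = max(a.end for a in pre)
        remainder = contig[elem_end:]
        if len(remainder) < cfg.min_element_match:
            continue
        rhit = unique_genome_hit(remainder, reference)
        if rhit is None:
            continue
        _, chrom, ts, te, orient = rhit
        distant = (chrom != record.bp.chrom
                   or abs(ts - record.bp.pos) > cfg.distant_min)
        if distant and (te - ts) >= 0.8 * len(remainder):
            evidence.append(AnnotationInterval(
                start=elem_end, end=elem_end + (te - ts),
                label=f"{chrom}:{ts}-{te}", identity=1.0,
                orientation=orient, family="Genome"))
            return label, evidence, None

    # (5) viral sequence
    for a in evidence:
        if a.family == "Virus" and a.length() >= cfg.min_element_match:
            return "VirusMediated", evidence, None

    return "Unclassified", evidence, None
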
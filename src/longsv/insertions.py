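"""Classification and structural annotation of inserted sequences.

Full-length inserts from canonical insertion calls are classified as
processed pseudogene, solo LINE1/Alu/SVA, partnered or orphan 3'
transduction, tandem duplication or other, and their hallmark features are
extracted: 5' inversion (twin priming), target-site duplication, polyA
tail, and the LINE1 source element behind each transduction.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

from .breakend import annotate_contig, family_coverage
from .config import Config
from .library import RepeatLibrary, Transcript
from .model import (AnnotationInterval, CanonicalSVRecord,
                    InsertionAnnotation, LINE1SourceElement)
from .seqs import best_local, revcomp, unique_genome_hit

log = logging.getLogger(__name__)

_FAMILY_CLASS = {"LINE": "SoloLINE1", "SINE": "SoloAlu",
                 "Retroposon": "SoloSVA"}


def detect_polya(inserted_seq: str, window: int = 30, min_len: int = 10,
                 min_frac: float = 0.8) -> Optional[tuple[int, str]]:
    """Longest A-run (3' end) or T-run (5' end, antisense inserts) in the
    terminal window with at least ``min_frac`` purity.

    Runs may absorb isolated other bases as long as the purity holds; the
    reported run is the longest terminal stretch that starts and ends on
    the tail base.  Returns (length, side), side in {"3'", "5'"}, or None.
    """
    best: Optional[tuple[int, str]] = None
    for side, termseq, base in (("3'", inserted_seq[-window:][::-1], "A"),
                                ("5'", inserted_seq[:window], "T")):
        if not termseq or termseq[0] != base:
            continue
        cnt = 0
        best_k = 0
        for k, ch in enumerate(termseq, 1):
            if ch == base:
                cnt += 1
                if cnt / k >= min_frac:
                    best_k = k
        if best_k >= min_len and (best is None or best_k > best[0]):
            best = (best_k, side)
    return best


def detect_tsd(sv: CanonicalSVRecord, reference: dict[str, str],
               max_tsd: int = 50, min_tsd: int = 5
               ) -> Optional[tuple[int, str]]:
    """Target-site duplication of an insertion call.

    With breakpoints at the last retained base (bp1, dir +) and the first
    retained base (bp2, dir −), a TSD shows as overlapping breakpoints;
    its length is ``bp1.pos − bp2.pos + 1`` and its sequence is the
    duplicated reference span."""
    if sv.bp1.chrom != sv.bp2.chrom or (sv.bp1.dir, sv.bp2.dir) != ("+", "-"):
        return None
    length = sv.bp1.pos - sv.bp2.pos + 1
    if not (min_tsd <= length <= max_tsd):
        return None
    seq = reference[sv.bp1.chrom][sv.bp2.pos:sv.bp1.pos + 1]
    return length, seq


def detect_5prime_inversion(inserted_seq: str, element_consensus: str,
                            min_seg: int = 50
                            ) -> tuple[list[AnnotationInterval], bool]:
    """Twin-priming geometry: an antisense 5' segment followed by a sense
    3' segment of the same element, with compatible consensus coordinates
    (the antisense piece maps upstream-adjacent to or overlapping the
    sense piece start).  Pure antisense inserts are reported as segments
    but not flagged."""
    segs: list[AnnotationInterval] = []
    for orient, query in (("+", element_consensus),
                          ("-", revcomp(element_consensus))):
        masked = inserted_seq
        for _ in range(3):
            hit = best_local(query, masked)
            if hit is None:
                break
            score, (qs, qe), (ts, te) = hit
            if te - ts < min_seg:
                break
            if orient == "+":
                c_start, c_end = qs, qe
            else:
                c_start = len(element_consensus) - qe
                c_end = len(element_consensus) - qs
            segs.append(AnnotationInterval(
                start=ts, end=te, label="element", orientation=orient,
                identity=min(1.0, score / (2.0 * (te - ts))),
                family=f"{c_start}-{c_end}"))
            masked = masked[:ts] + "N" * (te - ts) + masked[te:]
    segs.sort(key=lambda a: a.start)
    anti = [s for s in segs if s.orientation == "-"]
    sense = [s for s in segs if s.orientation == "+"]
    if not anti or not sense:
        return segs, False
    first_anti = anti[0]
    first_sense = min(sense, key=lambda s: s.start)
    if first_anti.start > first_sense.start:
        return segs, False
    a_lo, a_hi = (int(x) for x in first_anti.family.split("-"))
    s_lo, s_hi = (int(x) for x in first_sense.family.split("-"))
    # antisense piece must come from at or upstream of the sense piece
    compatible = a_lo <= s_lo + 50 and a_hi <= s_hi
    return segs, bool(compatible)


def classify_insertion(inserted_seq: str,
                       transcripts: Sequence[Transcript],
                       repeat_library: RepeatLibrary,
                       reference: dict[str, str],
                       sources: Sequence[LINE1SourceElement] = (),
                       site: Optional[tuple[str, int]] = None,
                       config: Optional[Config] = None
                       ) -> InsertionAnnotation:
    """Classify one inserted sequence following the fixed decision order:
    processed pseudogene, then solo mobile element (family covering
    >=80%), then realignment of the repeat-free residue to the reference
    (adjacent -> tandem duplication; downstream of a LINE1 source ->
    partnered/orphan transduction), else Other."""
    cfg = config or Config()
    ann = InsertionAnnotation(insertion_class="Other")
    if len(inserted_seq) < 100:
        ann.evidence["reason"] = "too_short"
        return ann

    polya = detect_polya(inserted_seq, cfg.polya_window, cfg.polya_min_len,
                         cfg.polya_min_frac)
    if polya:
        ann.polya = polya
    core = inserted_seq
    if polya and polya[1] == "3'":
        core = inserted_seq[:len(inserted_seq) - polya[0]]
    elif polya and polya[1] == "5'":
        core = inserted_seq[polya[0]:]

    # (1) transcriptome match: processed pseudogene
    for tr in transcripts:
        cov, junctions = _transcript_match(core, tr)
        if cov >= cfg.insert_cov and junctions >= cfg.min_exon_junctions:
            ann.insertion_class = "ProcessedPseudogene"
            ann.evidence["transcript"] = tr.name
            ann.evidence["exon_junctions_spanned"] = junctions
            return ann

    # (2) solo mobile element
    annotations = annotate_contig(core, repeat_library)
    ann.repeat_segments = annotations
    for fam, label in _FAMILY_CLASS.items():
        if family_coverage(core, annotations, fam) >= cfg.insert_cov:
            ann.insertion_class = label
            if fam == "LINE":
                cons = next(iter(repeat_library.of_family("LINE").values()),
                            None)
                if cons:
                    segs, inv = detect_5prime_inversion(core, cons)
                    ann.has_5prime_inversion = inv
                    ann.evidence["element_segments"] = segs
            return ann

    # (3) residue realignment: tandem dup / transduction
    residue = _longest_unannotated(core, annotations)
    if residue and len(residue[1]) >= 100:
        _, res_seq = residue
        hit = unique_genome_hit(res_seq, reference)
        if hit is not None:
            _, chrom, ts, te, orient = hit
            if site and chrom == site[0] \
                    and min(abs(ts - site[1]), abs(te - site[1])) <= \
                    max(cfg.tandem_window, len(res_seq) + cfg.tandem_window):
                ann.insertion_class = "TandemDup"
                ann.evidence["hit"] = (chrom, ts, te, orient)
                return ann
            src = _downstream_source(chrom, ts, te, sources,
                                     cfg.source_window)
            if src is not None:
                has_l1 = any(a.family == "LINE"
                             and a.length() >= cfg.min_element_match
                             for a in annotations)
                ann.insertion_class = ("PartneredTransduction" if has_l1
                                       else "OrphanTransduction")
                ann.transduction_source = (src.chrom, src.start, src.end,
                                           src.element_id)
                ann.evidence["hit"] = (chrom, ts, te, orient)
                if src.provenance == "somatic":
                    ann.nested = True
                return ann
            ann.evidence["hit"] = (chrom, ts, te, orient)
    return ann


def _transcript_match(seq: str, tr: Transcript) -> tuple[float, int]:
    """Coverage of the insert by the transcript plus the number of exon
    junctions the alignment spans (both orientations)."""
    best_cov, best_j = 0.0, 0
    for query in (tr.seq, revcomp(tr.seq)):
        hit = best_local(query, seq)
        if hit is None:
            continue
        _, (qs, qe), (ts, te) = hit
        cov = (te - ts) / len(seq)
        if query is tr.seq:
            lo, hi = qs, qe
        else:
            lo, hi = len(tr.seq) - qe, len(tr.seq) - qs
        j = sum(1 for x in tr.exon_junctions if lo + 20 <= x <= hi - 20)
        if cov > best_cov:
            best_cov, best_j = cov, j
    return best_cov, best_j


def _longest_unannotated(seq: str, annotations: list[AnnotationInterval]
                         ) -> Optional[tuple[int, str]]:
    mask = [False] * len(seq)
    for a in annotations:
        for k in range(a.start, min(a.end, len(seq))):
            mask[k] = True
    best = None
    start = None
    for i in range(len(seq) + 1):
        free = i < len(seq) and not mask[i]
        if free and start is None:
            start = i
        elif not free and start is not None:
            if best is None or i - start > len(best[1]):
                best = (start, seq[start:i])
            start = None
    return best


def _downstream_source(chrom: str, ts: int, te: int,
                       sources: Sequence[LINE1SourceElement],
                       window: int) -> Optional[LINE1SourceElement]:
    """The LINE1 source immediately upstream of the aligned residue, if
    any lies within the attribution window (strand-aware: downstream of a
    '+' element means to its right)."""
    best = None
    best_d = None
    for src in sources:
        if src.chrom != chrom:
            continue
        if src.strand == "+":
            d = ts - src.end
        else:
            d = src.start - te
        if -200 <= d <= window and (best_d is None or d < best_d):
            best, best_d = src, d
    return best


def infer_transduction_sources(annotations: Sequence[InsertionAnnotation],
                               sources: Sequence[LINE1SourceElement],
                               somatic_l1_sites: Sequence[tuple[str, int]] = ()
                               ) -> dict[str, dict]:
    """Group transduction events per source element and flag nested events
    (source is itself a somatic LINE1 insertion locus)."""
    groups: dict[str, dict] = {}
    by_id = {s.element_id: s for s in sources}
    for ann in annotations:
        if ann.insertion_class not in ("PartneredTransduction",
                                       "OrphanTransduction"):
            continue
        chrom, start, end, sid = ann.transduction_source
        g = groups.setdefault(sid, {"source": by_id.get(sid),
                                    "events": [], "nested": False})
        g["events"].append(ann)
        src = by_id.get(sid)
        nested = (src is not None and src.provenance == "somatic") or any(
            c == chrom and abs(p - start) <= 1000
            for c, p in somatic_l1_sites)
        if nested:
            g["nested"] = True
            ann.nested = True
    return groups
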
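"""Centromeric higher-order repeat (HOR) analysis.

Satellite-bound breakend contigs are decomposed into ~171 bp alpha-satellite
monomers by a chained dynamic program (each block is the best end-anchored
alignment of one monomer consensus, both orientations), and scored against
each chromosome's canonical HOR order: every monomer block whose
predecessor relationship is consistent with the HOR's successor map
contributes (end − start) · identity / 100, and the sum divided by the
contig length is the HOR match score in [0, 1].
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import edlib

from .model import HORDefinition, MonomerMatch, SingleBreakendRecord
from .seqs import revcomp

log = logging.getLogger(__name__)


def _end_anchored(query: str, target_window: str) -> tuple[int, int]:
    """Best alignment of the full query ending exactly at the window end.

    Returns (edit_distance, consumed_window_bases)."""
    res = edlib.align(query[::-1], target_window[::-1], mode="SHW",
                      task="locations")
    ed = res["editDistance"]
    span = res["locations"][0][1] + 1 if res["locations"] else len(query)
    return ed, span


def decompose_monomers(contig: str, monomers: dict[str, str],
                       min_identity: float = 50.0,
                       len_slack: int = 35) -> list[MonomerMatch]:
    """Partition the contig into non-overlapping monomer blocks.

    A DP over contig positions chooses, at each end position, either a gap
    base (contributing nothing) or the best-scoring monomer block ending
    there (local alignment of the monomer, both orientations), maximizing
    the summed identity-weighted length.  Blocks below ``min_identity``
    percent are left as gaps."""
    n = len(contig)
    if not monomers or n < min(len(m) for m in monomers.values()):
        return []
    variants = []
    for mid, seq in sorted(monomers.items()):
        variants.append((mid, "+", seq))
        variants.append((mid, "-", revcomp(seq)))

    score = [0.0] * (n + 1)
    back: list[Optional[tuple]] = [None] * (n + 1)
    for i in range(1, n + 1):
        score[i] = score[i - 1]
        back[i] = None
        for mid, orient, mseq in variants:
            L = len(mseq)
            if i < L - len_slack:
                continue
            lo = max(0, i - L - len_slack)
            ed, span = _end_anchored(mseq, contig[lo:i])
            if span <= 0 or span > i:
                continue
            identity = max(0.0, 100.0 * (1.0 - ed / L))
            if identity < min_identity:
                continue
            cand = score[i - span] + span * identity / 100.0
            if cand > score[i] + 1e-9:
                score[i] = cand
                back[i] = (mid, orient, span, identity)

    matches: list[MonomerMatch] = []
    i = n
    while i > 0:
        if back[i] is None:
            i -= 1
            continue
        mid, orient, span, identity = back[i]
        matches.append(MonomerMatch(monomer_id=mid, start_pos=i - span,
                                    end_pos=i, identity=identity,
                                    orientation=orient))
        i -= span
    matches.reverse()
    return matches


def hor_match_score(matches: Sequence[MonomerMatch], hor: HORDefinition,
                    contig_len: int, gap_tolerance: int = 5) -> float:
    """Identity-weighted fraction of the contig consistent with the HOR.

    The first monomer block is always consistent; later blocks are
    consistent when the previous block's monomer lists them as a successor
    in the HOR order (orientation-aware) and no gap separates the blocks.
    Consistent blocks add (end − start) · identity / 100; the total is
    divided by the contig length."""
    if contig_len <= 0 or not matches:
        return 0.0
    total = 0.0
    prev: Optional[MonomerMatch] = None
    for m in matches:
        if prev is None:
            consistent = True
        elif m.start_pos - prev.end_pos > gap_tolerance:
            consistent = False  # gap blocks break adjacency
        elif m.orientation != prev.orientation:
            consistent = False
        elif m.orientation == "+":
            consistent = hor.allows(prev.monomer_id, m.monomer_id)
        else:
            consistent = hor.allows(m.monomer_id, prev.monomer_id)
        if consistent:
            total += (m.end_pos - m.start_pos) * m.identity / 100.0
        prev = m
    return min(1.0, total / contig_len)


def hor_profile(record: SingleBreakendRecord | str,
                monomers: dict[str, str],
                hors: Sequence[HORDefinition],
                breakend_chrom: Optional[str] = None,
                min_identity: float = 50.0) -> dict:
    """Score a breakend contig against every chromosome's HOR.

    Each chromosome is scored with its own monomer subset (as with
    per-chromosome monomer FASTAs).  Returns per-chromosome scores, the
    argmax chromosome, and an ``interchromosomal`` flag when the best
    centromere does not belong to the breakend's own chromosome."""
    if isinstance(record, SingleBreakendRecord):
        contig = record.contig
        breakend_chrom = breakend_chrom or record.bp.chrom
    else:
        contig = record
    scores: dict[str, float] = {}
    decompositions: dict[str, list[MonomerMatch]] = {}
    for hor in hors:
        subset = {mid: monomers[mid] for mid in set(hor.monomer_order)
                  if mid in monomers}
        matches = decompose_monomers(contig, subset,
                                     min_identity=min_identity)
        decompositions[hor.chromosome] = matches
        scores[hor.chromosome] = hor_match_score(matches, hor, len(contig))
    best = max(scores, key=lambda c: scores[c]) if scores else None
    return {
        "scores": scores,
        "best_chrom": best,
        "interchromosomal": (best is not None and breakend_chrom is not None
                             and best != breakend_chrom),
        "decompositions": decompositions,
    }
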
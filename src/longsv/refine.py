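"""Stage 3 of the canonical SV module: consensus building and breakpoint
refinement.

The junction-spanning portions of the supporting reads are extracted in a
common orientation, error-corrected by centroid selection plus iterated
per-column majority vote, and the polished sequence is aligned to the two
candidate reference regions with a Smith-Waterman variant that allows a
one-time jump between regions.  The jump cell yields single-base breakpoint
coordinates and the inserted sequence between them.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import edlib
import numpy as np

from .config import Config
from .model import (Breakpoint, ConsensusContig, JumpAlignment,
                    SVCandidateCluster)
from .seqs import revcomp

log = logging.getLogger(__name__)

NEG = -1e9


# ---------------------------------------------------------------------------
# junction segment extraction
# ---------------------------------------------------------------------------

def extract_junction_segments(cluster: SVCandidateCluster,
                              read_seqs: dict[str, str],
                              flank: int = 300,
                              min_flank: int = 50,
                              max_inputs: int = 0) -> list[str]:
    """Per supporting read, the subsequence from ``flank`` bases before the
    junction to ``flank`` after, reverse-complemented into a common
    (bp1-side-first) orientation.  Reads with less than ``min_flank``
    context on either side are excluded."""
    segments: list[tuple[int, str, str]] = []
    used: set[str] = set()
    for sig in cluster.signals:
        if sig.read_id in used or sig.read_id not in read_seqs:
            continue
        used.add(sig.read_id)
        seq = read_seqs[sig.read_id]
        q1, q2 = sorted(sig.read_offsets)
        lo = max(0, q1 - flank)
        hi = min(len(seq), q2 + flank)
        if q1 - lo < min_flank or hi - q2 < min_flank:
            continue
        seg = seq[lo:hi]
        if not sig.bp1_first:
            seg = revcomp(seg)
        segments.append((min(q1 - lo, hi - q2), sig.read_id, seg))
    # prefer reads with the most context on both sides, deterministically
    segments.sort(key=lambda t: (-t[0], t[1]))
    if max_inputs:
        segments = segments[:max_inputs]
    return [s for _, _, s in segments]


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def _vote_round(template: str, segments: Sequence[str]) -> tuple[str, float]:
    """Align every segment to the template and take per-column majority
    vote (gaps included).  End gaps of each alignment are trimmed so reads
    truncated at one side do not vote deletions at template ends."""
    L = len(template)
    base_votes: list[Counter] = [Counter() for _ in range(L)]
    ins_votes: list[Counter] = [Counter() for _ in range(L + 1)]
    covered = np.zeros(L + 1, dtype=np.int32)
    identities = []

    for seg in segments:
        res = edlib.align(seg, template, mode="NW", task="path")
        identities.append(max(0.0, 1.0 - res["editDistance"] / max(len(seg), L)))
        ops = _parse_edlib_cigar(res["cigar"])
        # trim end gap runs: reads truncated on one side must not vote
        # deletions at template ends
        q = t = 0
        while ops and ops[0][0] in "ID":
            op, n = ops.pop(0)
            if op == "I":
                q += n
            else:
                t += n
        while ops and ops[-1][0] in "ID":
            ops.pop()
        t_begin = t
        for op, n in ops:
            if op in "=XM":
                for x in range(n):
                    base_votes[t + x][seg[q + x]] += 1
                q += n
                t += n
            elif op == "I":  # bases present in segment, absent in template
                ins_votes[t][seg[q:q + n]] += 1
                q += n
            elif op == "D":  # template bases absent in segment
                for x in range(n):
                    base_votes[t + x]["-"] += 1
                t += n
        covered[t_begin:t + 1] += 1

    out: list[str] = []
    for pos in range(L + 1):
        if ins_votes[pos]:
            ins, cnt = ins_votes[pos].most_common(1)[0]
            # ties go to insertion: alignment ambiguity splits insertion
            # votes across neighbouring columns, biasing strict majority
            # toward deletions
            if cnt * 2 >= covered[pos]:
                out.append(ins)
        if pos == L:
            break
        votes = base_votes[pos]
        if not votes:
            out.append(template[pos])
            continue
        base, _ = max(votes.items(), key=lambda kv: (kv[1], kv[0]))
        if base != "-":
            out.append(base)
    consensus = "".join(out)
    mean_id = float(np.mean(identities)) if identities else 0.0
    return consensus, mean_id


def _parse_edlib_cigar(cigar: str) -> list[tuple[str, int]]:
    ops: list[tuple[str, int]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((ch, int(num)))
            num = ""
    return ops


def build_consensus(segments: Sequence[str], rounds: int = 2) -> ConsensusContig:
    """Error-correct junction segments: pick the centroid segment (smallest
    summed edit distance to the others), then iterate alignment + majority
    vote ``rounds`` times.

    With a single segment the sequence passes through unpolished, flagged
    ``unpolished``.  A mixture of discordant junctions is flagged
    ``high_discordance`` (mean identity to the consensus < 0.8)."""
    segments = [s for s in segments if s]
    if not segments:
        raise ValueError("no segments to polish")
    if len(segments) == 1:
        return ConsensusContig(seq=segments[0], n_inputs=1,
                               flags=["unpolished"])

    n = len(segments)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _edit_distance(segments[i], segments[j])
            dist[i, j] = dist[j, i] = d
    centroid = int(np.argmin(dist.sum(axis=1)))
    template = segments[centroid]

    mean_id = 1.0
    for _ in range(rounds):
        template, mean_id = _vote_round(template, segments)

    flags = []
    if mean_id < 0.8:
        flags.append("high_discordance")
    return ConsensusContig(seq=template, n_inputs=n, mean_identity=mean_id,
                           flags=flags)


# ---------------------------------------------------------------------------
# jump-enabled Smith-Waterman
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _sw_layer(query: np.ndarray, ref: np.ndarray, match: float,
              mismatch: float, open_cost: float, ext: float,
              floor: Optional[np.ndarray] = None) -> np.ndarray:
    """Affine-gap local DP of query (rows) vs ref (cols).

    ``floor`` gives, per query row i (0..n), the value at which a fresh
    alignment may start before consuming query base i+1 (0 for standard
    local alignment; the jump budget A(i) for the second layer).  Returns H
    with shape (n+1, m+1); H[i, j] is the best alignment ending exactly at
    query i / ref j.
    """
    n, m = len(query), len(ref)
    H = np.full((n + 1, m + 1), NEG, dtype=np.float64)
    H[0, :] = NEG
    F = np.full(m + 1, NEG, dtype=np.float64)
    if floor is None:
        floor = np.zeros(n + 1)
    js = np.arange(m + 1, dtype=np.float64)
    for i in range(1, n + 1):
        sub = np.where(ref == query[i - 1], match, mismatch)
        F = np.maximum(H[i - 1] + open_cost, F + ext)
        diag = np.maximum(H[i - 1, :-1], floor[i - 1]) + sub
        H0 = np.full(m + 1, NEG)
        H0[1:] = diag
        H0 = np.maximum(H0, F)
        # horizontal gap runs via prefix max: E[j] = max_{k<j} H0[k]+open+ext*(j-1-k)
        T = H0 - ext * js
        E = np.full(m + 1, NEG)
        run = np.maximum.accumulate(T[:-1])
        E[1:] = run + open_cost + ext * js[1:] - ext
        H[i] = np.maximum(H0, E)
    return H


def jump_sw_align(query: str, ref1: str, ref2: str,
                  match: int = 2, mismatch: int = -4,
                  gap_open: int = -4, gap_extend: int = -2,
                  jump_penalty: float = 0.0,
                  per_inserted_base: float = 0.0) -> JumpAlignment:
    """Two-region local alignment with a one-time jump.

    The query is aligned locally against ``ref1``; at any query position
    the DP may jump once into ``ref2``, optionally paying ``jump_penalty``
    plus ``per_inserted_base`` for every query base skipped between the two
    pieces.  The optimum equals, over all query split points
    ``q_end1 <= q_start2``, the best end-anchored local alignment of
    ``query[:q_end1]`` vs ref1 plus the best start-anchored local alignment
    of ``query[q_start2:]`` vs ref2 plus the jump terms.

    Co-optimal splits (junction micro-homology) are broken toward the
    rightmost ``q_end1``/``q_start2`` — maximal attribution to the bp1
    side.
    """
    q = _encode(query)
    r1 = _encode(ref1)
    r2 = _encode(ref2)
    n = len(q)
    open_cost = gap_open + gap_extend

    H1 = _sw_layer(q, r1, match, mismatch, open_cost, gap_extend)
    with np.errstate(invalid="ignore"):
        E1 = H1.max(axis=1)  # best layer-1 score ending exactly at query i
    E1 = np.maximum(E1, NEG)
    E1[0] = 0.0

    idx = np.arange(n + 1, dtype=np.float64)
    shifted = E1 - per_inserted_base * idx
    prefix = np.maximum.accumulate(shifted)
    A = prefix + per_inserted_base * idx + jump_penalty
    A = np.maximum(A, 0.0)  # fresh start in ref2 without any ref1 piece

    H2 = _sw_layer(q, r2, match, mismatch, open_cost, gap_extend, floor=A)

    best1 = float(np.max(E1))
    best2 = float(np.max(H2)) if H2.size else NEG
    score = max(0.0, best1, best2)

    if best2 < score - 1e-9 or best2 <= 0:
        # no useful jump: report the layer-1 (or empty) optimum
        i1 = int(np.argmax(E1))
        j1 = int(np.argmax(H1[i1])) if best1 > 0 else -1
        return JumpAlignment(score=score, q_end1=i1, q_start2=n,
                             r1_end=j1 - 1 if j1 > 0 else -1, r2_start=-1,
                             piece1_len=i1, piece2_len=0, jumped=False)

    ie, je = np.unravel_index(int(np.argmax(H2)), H2.shape)
    ie, je = int(ie), int(je)
    i0, j0 = _traceback(q, r2, H2, A, match, mismatch, open_cost, gap_extend,
                        ie, je)
    q_start2 = i0 - 1
    r2_start = j0 - 1

    # choose the ref1 piece feeding the jump: rightmost co-optimal end
    target = A[q_start2]
    i_end1 = 0
    cand = (E1[:q_start2 + 1] + per_inserted_base
            * (q_start2 - idx[:q_start2 + 1]) + jump_penalty)
    hits = np.nonzero(np.abs(cand - target) < 1e-9)[0]
    piece1_empty = target <= 0 and (len(hits) == 0 or E1[hits[-1]] <= 0)
    if len(hits) and not piece1_empty:
        # co-optimal ends arise only from net-zero gapped extensions
        # (exact-match extension always gains score): take the shortest
        # piece so the junction is not dragged into the inserted sequence
        i_end1 = int(hits[0])
    r1_end = -1
    piece1_len = 0
    if i_end1 > 0:
        j_end1 = int(np.argmax(H1[i_end1]))
        i_start1, _ = _traceback(q, r1, H1, np.zeros(n + 1), match, mismatch,
                                 open_cost, gap_extend, i_end1, j_end1)
        r1_end = j_end1 - 1
        piece1_len = i_end1 - (i_start1 - 1)

    return JumpAlignment(score=score, q_end1=i_end1, q_start2=q_start2,
                         r1_end=r1_end, r2_start=r2_start,
                         piece1_len=piece1_len,
                         piece2_len=ie - q_start2,
                         jumped=i_end1 > 0 or piece1_len > 0)


def _traceback(q: np.ndarray, ref: np.ndarray, H: np.ndarray,
               floor: np.ndarray, match: float, mismatch: float,
               open_cost: float, ext: float, i: int, j: int
               ) -> tuple[int, int]:
    """Walk one optimal path back from (i, j); return the (i0, j0) cell
    where the alignment starts (first aligned pair is query[i0-1]/ref[j0-1]).

    The start check runs first so, tracing backwards, the path terminates
    at the latest possible query position (rightmost-split tie-break)."""
    v = H[i, j]
    eps = 1e-9
    while True:
        s = match if q[i - 1] == ref[j - 1] else mismatch
        if abs(floor[i - 1] + s - v) < eps:
            return i, j
        if i > 1 and j > 1 and abs(H[i - 1, j - 1] + s - v) < eps:
            i, j = i - 1, j - 1
            v = H[i, j]
            continue
        moved = False
        for k in range(j - 1, 0, -1):  # horizontal gap run
            if abs(H[i, k] + open_cost + ext * (j - k - 1) - v) < eps:
                j, v = k, H[i, k]
                moved = True
                break
        if moved:
            continue
        for l in range(i - 1, 0, -1):  # vertical gap run
            if abs(H[l, j] + open_cost + ext * (i - l - 1) - v) < eps:
                i, v = l, H[l, j]
                moved = True
                break
        if not moved:
            return i, j


def _trim_junction(query: str, ref1: str, ref2: str, aln: JumpAlignment,
                   window: int = 10, max_mismatch: int = 1) -> None:
    """Pull back mismatch-rich terminal extensions at the junction.

    Because the jump is free, the local alignment happily extends a few
    net-positive but error-rich bases of the inserted sequence onto the
    reference side of the junction, displacing the breakpoint.  Each piece
    end is walked back (ungapped) until its terminal ``window`` bases
    carry at most ``max_mismatch`` mismatches.  A gapped junction
    neighbourhood would make the ungapped walk run away, so trims larger
    than ``max_trim`` are reverted."""
    max_trim = 30
    q1, r1 = aln.q_end1, aln.r1_end
    while q1 > 0 and r1 >= 0 and aln.q_end1 - q1 < max_trim:
        k = min(window, q1, r1 + 1)
        mism = sum(query[q1 - 1 - x] != ref1[r1 - x] for x in range(k))
        if mism <= max_mismatch or k < 4:
            break
        q1 -= 1
        r1 -= 1
    if 0 < aln.q_end1 - q1 < max_trim:
        aln.q_end1, aln.r1_end = q1, r1

    q2, r2 = aln.q_start2, aln.r2_start
    n, m = len(query), len(ref2)
    while q2 < n and r2 < m and q2 - aln.q_start2 < max_trim:
        k = min(window, n - q2, m - r2)
        mism = sum(query[q2 + x] != ref2[r2 + x] for x in range(k))
        if mism <= max_mismatch or k < 4:
            break
        q2 += 1
        r2 += 1
    if 0 < q2 - aln.q_start2 < max_trim:
        aln.q_start2, aln.r2_start = q2, r2


def canonicalize_junction(bp1: Breakpoint, bp2: Breakpoint, inserted: str,
                          reference: dict[str, str], cap: int = 100
                          ) -> tuple[Breakpoint, Breakpoint, str]:
    """Normalize a junction to its maximal-reference-attribution form.

    A junction with inserted sequence admits many equivalent coordinate
    representations (the allele string is unchanged when bases slide
    between the insert and either reference side).  The canonical form
    absorbs exactly-matching bases into the bp1 side first, then into the
    bp2 side — the same representation the jump alignment's scoring and
    tie-break produce — so calls and simulated truth are comparable."""
    c1, c2 = reference[bp1.chrom], reference[bp2.chrom]
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    a, b = bp1.pos, bp2.pos
    ins = inserted

    def ref1_next(x):  # reference continuing junction-ward through bp1
        p = a + 1 + x if bp1.dir == "+" else a - 1 - x
        if 0 <= p < len(c1):
            return c1[p] if bp1.dir == "+" else comp.get(c1[p], "N")
        return None

    def allele_right(x):  # allele content after the junction
        if x < len(ins):
            return ins[x]
        y = x - len(ins)
        p = b + y if bp2.dir == "-" else b - y
        if 0 <= p < len(c2):
            return c2[p] if bp2.dir == "-" else comp.get(c2[p], "N")
        return None

    k1 = 0
    while k1 < cap:
        q = allele_right(k1)
        r = ref1_next(k1)
        if q is None or r is None or q != r:
            break
        k1 += 1
    i1 = min(k1, len(ins))
    a = a + k1 if bp1.dir == "+" else a - k1
    shift2 = k1 - i1
    b = b + shift2 if bp2.dir == "-" else b - shift2
    ins = ins[i1:]

    def ref2_prev(x):  # reference continuing junction-ward through bp2
        p = b - 1 - x if bp2.dir == "-" else b + 1 + x
        if 0 <= p < len(c2):
            return c2[p] if bp2.dir == "-" else comp.get(c2[p], "N")
        return None

    def allele_left(x):  # allele content before the junction, backwards
        if x < len(ins):
            return ins[len(ins) - 1 - x]
        y = x - len(ins)
        p = a - y if bp1.dir == "+" else a + y
        if 0 <= p < len(c1):
            return c1[p] if bp1.dir == "+" else comp.get(c1[p], "N")
        return None

    # bp2-side absorption takes only insert bases: once the insert is
    # exhausted, further sliding is pure micro-homology, which the
    # tie-break attributes to the bp1 side
    k2 = 0
    while k2 < min(cap, len(ins)):
        q = allele_left(k2)
        r = ref2_prev(k2)
        if q is None or r is None or q != r:
            break
        k2 += 1
    b = b - k2 if bp2.dir == "-" else b + k2
    ins = ins[:len(ins) - k2]

    return (Breakpoint(bp1.chrom, a, bp1.dir),
            Breakpoint(bp2.chrom, b, bp2.dir), ins)


# ---------------------------------------------------------------------------
# candidate refinement
# ---------------------------------------------------------------------------

@dataclass
class RefineFailure:
    reason: str


@dataclass
class RefinedCandidate:
    bp1: Breakpoint
    bp2: Breakpoint
    inserted_seq: str
    consensus: ConsensusContig
    score: float
    homology_len: int = 0
    flags: list = None

    def __post_init__(self):
        if self.flags is None:
            self.flags = []


def _window(genome: dict[str, str], chrom: str, lo: int, hi: int
            ) -> tuple[str, int, int]:
    seq = genome[chrom]
    lo = max(0, lo)
    hi = min(len(seq), hi)
    return seq[lo:hi], lo, hi


def refine_candidate(cluster: SVCandidateCluster,
                     reference: dict[str, str],
                     read_seqs: dict[str, str],
                     config: Optional[Config] = None):
    """Compose extraction, consensus and jump alignment into single-base
    breakpoints plus the polished inserted sequence.

    Returns a :class:`RefinedCandidate` or a :class:`RefineFailure` with a
    reason string."""
    cfg = config or Config()
    segments = extract_junction_segments(
        cluster, read_seqs, flank=cfg.junction_flank, min_flank=cfg.min_flank,
        max_inputs=cfg.max_consensus_inputs)
    if not segments:
        return RefineFailure("no_junction_segments")
    if len(segments) >= 2:
        consensus = build_consensus(segments)
    else:
        consensus = ConsensusContig(seq=segments[0], n_inputs=1,
                                    flags=["unpolished"])
    query = consensus.seq
    if not query:
        return RefineFailure("empty_consensus")

    dir1, dir2 = cluster.dirs
    W = cfg.refine_window
    ref1_seq, w1s, w1e = _window(reference, cluster.chrom1,
                                 cluster.bp1_range[0] - W,
                                 cluster.bp1_range[1] + 1 + W)
    ref2_seq, w2s, w2e = _window(reference, cluster.chrom2,
                                 cluster.bp2_range[0] - W,
                                 cluster.bp2_range[1] + 1 + W)
    if dir1 == "-":
        ref1_seq = revcomp(ref1_seq)
    if dir2 == "+":
        ref2_seq = revcomp(ref2_seq)

    aln = jump_sw_align(query, ref1_seq, ref2_seq,
                        match=cfg.match, mismatch=cfg.mismatch,
                        gap_open=cfg.gap_open, gap_extend=cfg.gap_extend,
                        jump_penalty=cfg.jump_penalty,
                        per_inserted_base=cfg.per_inserted_base)
    if not aln.jumped or aln.piece1_len == 0 or aln.piece2_len == 0:
        return RefineFailure("no_jump_alignment")
    _trim_junction(query, ref1_seq, ref2_seq, aln)
    aligned = aln.piece1_len + aln.piece2_len
    if aln.piece1_len < cfg.min_span or aln.piece2_len < cfg.min_span \
            or aln.score < cfg.min_jump_frac * cfg.match * aligned:
        return RefineFailure("low_consensus_score")

    if dir1 == "+":
        pos1 = w1s + aln.r1_end
    else:
        pos1 = w1e - 1 - aln.r1_end
    if dir2 == "-":
        pos2 = w2s + aln.r2_start
    else:
        pos2 = w2e - 1 - aln.r2_start

    # micro-homology: bases just left of the junction that match ref2 just
    # before the landing site equally well (tie-broken onto the bp1 side)
    hom = 0
    while (aln.q_end1 - hom > 0 and aln.r2_start - hom > 0
           and query[aln.q_end1 - hom - 1] == ref2_seq[aln.r2_start - hom - 1]
           and hom < 100):
        hom += 1

    inserted = query[aln.q_end1:aln.q_start2]
    bp1 = Breakpoint(cluster.chrom1, pos1, dir1)
    bp2 = Breakpoint(cluster.chrom2, pos2, dir2)
    bp1, bp2, inserted = canonicalize_junction(bp1, bp2, inserted, reference)
    flags = list(consensus.flags)
    tsd_overlap = (bp1.chrom == bp2.chrom and (dir1, dir2) == ("+", "-")
                   and 0 <= bp1.pos - bp2.pos <= 200)
    if bp2.sort_key() < bp1.sort_key() and not tsd_overlap:
        bp1, bp2 = bp2, bp1
        inserted = revcomp(inserted) if dir1 == dir2 else inserted
        flags.append("swapped")
    return RefinedCandidate(bp1=bp1, bp2=bp2, inserted_seq=inserted,
                            consensus=consensus, score=aln.score,
                            homology_len=hom, flags=flags)
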
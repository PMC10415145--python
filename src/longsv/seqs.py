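"""Small sequence utilities shared across modules.

Plain local alignments go through Bio.Align.PairwiseAligner (C
implementation); fast approximate placement of long sequences on a genome
uses edlib.  The jump-enabled two-region DP lives in :mod:`longsv.refine`.
"""

from __future__ import annotations

from functools import lru_cache

import edlib
from Bio import Align

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@lru_cache(maxsize=8)
def local_aligner(match: int = 2, mismatch: int = -4,
                  gap_open: int = -4, gap_extend: int = -2) -> Align.PairwiseAligner:
    aln = Align.PairwiseAligner()
    aln.mode = "local"
    aln.match_score = match
    aln.mismatch_score = mismatch
    aln.open_gap_score = gap_open + gap_extend
    aln.extend_gap_score = gap_extend
    return aln


def local_score(a: str, b: str, **scores) -> float:
    if not a or not b:
        return 0.0
    return local_aligner(**scores).score(a, b)


def best_local(a: str, b: str, **scores):
    """Best local alignment of a (query) vs b (target).

    Returns (score, (a_start, a_end), (b_start, b_end)) or None when no
    positive-scoring alignment exists.
    """
    if not a or not b:
        return None
    aligner = local_aligner(**scores)
    if aligner.score(a, b) <= 0:
        return None
    aln = aligner.align(a, b)[0]
    qb, tb = aln.aligned
    return (
        aln.score,
        (int(qb[0][0]), int(qb[-1][1])),
        (int(tb[0][0]), int(tb[-1][1])),
    )


def alignment_identity(a: str, b: str) -> float:
    """Global identity of two sequences in [0, 1] from edit distance."""
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, mode="NW", task="distance")
    return max(0.0, 1.0 - res["editDistance"] / max(len(a), len(b)))


def locate(query: str, target: str, max_div: float = 0.3):
    """Best infix placement of ``query`` inside ``target`` via edit distance.

    Returns (edit_distance, t_start, t_end) or None when the best placement
    diverges more than ``max_div`` of the query length.
    """
    if not query or not target:
        return None
    k = int(max_div * len(query))
    res = edlib.align(query, target, mode="HW", task="locations", k=k)
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    ts, te = res["locations"][0]
    return res["editDistance"], int(ts), int(te) + 1


def locate_in_genome(query: str, genome: dict[str, str], max_div: float = 0.25):
    """Place ``query`` on a genome, both orientations.

    Returns a list of hits sorted best-first:
    (edit_distance, chrom, t_start, t_end, orientation).
    """
    hits = []
    for orient, seq in (("+", query), ("-", revcomp(query))):
        k = int(max_div * len(seq))
        for chrom, target in genome.items():
            res = edlib.align(seq, target, mode="HW", task="locations", k=k)
            if res["editDistance"] < 0 or not res["locations"]:
                continue
            # co-optimal placements count separately unless they overlap
            kept: list[tuple[int, int]] = []
            for ts, te in res["locations"]:
                if any(abs(ts - ks) < len(seq) // 2 for ks, _ in kept):
                    continue
                kept.append((int(ts), int(te) + 1))
                if len(kept) >= 4:
                    break
            for ts, te in kept:
                hits.append((res["editDistance"], chrom, ts, te, orient))
    hits.sort(key=lambda h: (h[0], h[1], h[2]))
    return hits


def unique_genome_hit(query: str, genome: dict[str, str], max_div: float = 0.25,
                      min_gap_frac: float = 0.1):
    """Best genome placement when it is clearly better than any alternative.

    The best hit must beat the runner-up (outside its own locus) by at least
    ``min_gap_frac * len(query)`` edit operations.  Returns the winning hit
    tuple or None when ambiguous/absent.
    """
    hits = locate_in_genome(query, genome, max_div=max_div)
    if not hits:
        return None
    best = hits[0]
    for h in hits[1:]:
        same_locus = (
            h[1] == best[1]
            and min(h[3], best[3]) - max(h[2], best[2]) > 0
        )
        if same_locus:
            continue
        if h[0] - best[0] < min_gap_frac * len(query):
            return None
        break
    return best
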
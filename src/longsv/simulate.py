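"""Synthetic data with exact truth: toy genomes, injected germline and
somatic SVs, and noisy long reads emitted directly as alignment records.

Alignments are emitted from the known read origins instead of running an
aligner: every read's CIGAR (soft clips at novel junctions, SA tags for
split reads, D/I operations for contained indels) reflects its true origin,
with sequencing errors injected consistently into both sequence and CIGAR.
The error model splits the total error rate 40:30:30 into substitutions,
insertions and deletions.  Realism knobs — ±``clip_jitter`` bp of junction
slop and a per-segment mapping ``dropout`` rate — stress the caller the way
imperfect alignment does.

Donor (rearranged) genomes are piece lists over the reference, so truth
breakpoints are exact by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pysam

from .library import BASES, random_seq
from .model import Breakpoint
from .seqs import revcomp

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------

def make_genome(length: int = 500_000, n_chroms: int = 2, gc: float = 0.42,
                seed: int = 0,
                features: Optional[Sequence[dict]] = None
                ) -> tuple[dict[str, str], list[dict]]:
    """Random toy genome, optionally with embedded repeat arrays.

    ``features`` entries: ``{"chrom", "pos", "seq"}`` — the given sequence
    replaces the reference at that locus (length preserved overall only if
    the feature fits).  Returns (genome, realized feature intervals).
    """
    rng = np.random.default_rng(seed)
    genome = {f"chr{i + 1}": random_seq(rng, length, gc)
              for i in range(n_chroms)}
    realized = []
    for feat in features or []:
        chrom, pos, seq = feat["chrom"], feat["pos"], feat["seq"].upper()
        ref = genome[chrom]
        if pos + len(seq) > len(ref):
            raise ValueError("feature does not fit in chromosome")
        genome[chrom] = ref[:pos] + seq + ref[pos + len(seq):]
        realized.append({"chrom": chrom, "start": pos,
                         "end": pos + len(seq),
                         "label": feat.get("label", "feature")})
    return genome, realized


# ---------------------------------------------------------------------------
# donor genomes and truth
# ---------------------------------------------------------------------------

# donor piece: ("ref", chrom, start, end, strand) or ("novel", seq, label)
Piece = tuple


@dataclass
class TruthSV:
    svtype: str
    junctions: list[tuple[Breakpoint, Breakpoint, str]]
    size: int = 0
    insert_class: str = ""
    tsd: int = 0
    polya: int = 0
    meta: dict = field(default_factory=dict)

    def matches_call(self, bp1: Breakpoint, bp2: Breakpoint,
                     margin: int = 200) -> bool:
        for tb1, tb2, _ in self.junctions:
            if (tb1.chrom == bp1.chrom and tb2.chrom == bp2.chrom
                    and abs(tb1.pos - bp1.pos) <= margin
                    and abs(tb2.pos - bp2.pos) <= margin
                    and tb1.dir == bp1.dir and tb2.dir == bp2.dir):
                return True
        return False


@dataclass
class TruthSet:
    germline: list[TruthSV] = field(default_factory=list)
    somatic: list[TruthSV] = field(default_factory=list)
    seed: int = 0
    read_origins: dict[str, tuple] = field(default_factory=dict)


class Donor:
    """A rearranged haplotype as piece lists over the reference."""

    def __init__(self, genome: dict[str, str]):
        self.reference = genome
        self.chroms: dict[str, list[Piece]] = {
            c: [("ref", c, 0, len(s), "+")] for c, s in genome.items()}

    def length(self, dchrom: str) -> int:
        return sum(self._piece_len(p) for p in self.chroms[dchrom])

    def _piece_len(self, p: Piece) -> int:
        return p[3] - p[2] if p[0] == "ref" else len(p[1])

    def piece_seq(self, p: Piece) -> str:
        if p[0] == "novel":
            return p[1]
        seq = self.reference[p[1]][p[2]:p[3]]
        return seq if p[4] == "+" else revcomp(seq)

    def sequence(self, dchrom: str) -> str:
        return "".join(self.piece_seq(p) for p in self.chroms[dchrom])

    def _locate(self, chrom: str, pos: int) -> tuple[str, int, int]:
        """Find the forward reference piece containing reference pos."""
        for dchrom, pieces in self.chroms.items():
            for i, p in enumerate(pieces):
                if p[0] == "ref" and p[1] == chrom and p[4] == "+" \
                        and p[2] <= pos < p[3]:
                    return dchrom, i, pos - p[2]
        raise ValueError(f"position {chrom}:{pos} not in any forward piece")

    def _split(self, chrom: str, pos: int) -> tuple[str, int]:
        """Split so that reference pos starts a piece; return its index."""
        dchrom, i, off = self._locate(chrom, pos)
        p = self.chroms[dchrom][i]
        if off == 0:
            return dchrom, i
        left = ("ref", p[1], p[2], p[2] + off, "+")
        right = ("ref", p[1], p[2] + off, p[3], "+")
        self.chroms[dchrom][i:i + 1] = [left, right]
        return dchrom, i + 1

    # --- edits -------------------------------------------------------------

    def delete(self, chrom: str, start: int, end: int) -> None:
        dc, i = self._split(chrom, start)
        dc2, j = self._split(chrom, end)
        assert dc == dc2
        del self.chroms[dc][i:j]

    def insert(self, chrom: str, pos: int, seq: str, tsd: int = 0,
               label: str = "insertion") -> None:
        dc, i = self._split(chrom, pos)
        pieces = [("novel", seq, label)]
        if tsd:
            pieces.append(("ref", chrom, pos - tsd, pos, "+"))
        self.chroms[dc][i:i] = pieces

    def invert(self, chrom: str, start: int, end: int) -> None:
        dc, i = self._split(chrom, start)
        _, j = self._split(chrom, end)
        self.chroms[dc][i:j] = [("ref", chrom, start, end, "-")]

    def duplicate(self, chrom: str, start: int, end: int) -> None:
        dc, i = self._split(chrom, start)
        _, j = self._split(chrom, end)
        self.chroms[dc][j:j] = [("ref", chrom, start, end, "+")]

    def translocate(self, chrom_a: str, pos_a: int,
                    chrom_b: str, pos_b: int) -> None:
        """Balanced reciprocal translocation: exchange tails."""
        dca, i = self._split(chrom_a, pos_a)
        dcb, j = self._split(chrom_b, pos_b)
        if dca == dcb:
            raise ValueError("translocation endpoints on the same donor chromosome")
        tail_a = self.chroms[dca][i:]
        tail_b = self.chroms[dcb][j:]
        self.chroms[dca][i:] = tail_b
        self.chroms[dcb][j:] = tail_a

    def breakend(self, chrom: str, pos: int, foreign: str,
                 label: str = "foreign") -> None:
        """One-sided junction: donor continues into unalignable sequence;
        the remainder of the chromosome survives as a separate fragment."""
        dc, i = self._split(chrom, pos)
        rest = self.chroms[dc][i:]
        self.chroms[dc][i:] = [("novel", foreign, label)]
        if rest:
            self.chroms[f"{dc}_frag{pos}"] = rest


# ---------------------------------------------------------------------------
# SV planning / injection
# ---------------------------------------------------------------------------

def _place_intervals(genome: dict[str, str], n: int, sizes, rng,
                     taken: list[tuple[str, int, int]], min_gap: int
                     ) -> list[tuple[str, int, int]]:
    chroms = sorted(genome)
    lens = np.array([len(genome[c]) for c in chroms], dtype=float)
    out = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 20_000:
            raise RuntimeError("could not place non-overlapping SVs")
        c = chroms[int(rng.choice(len(chroms), p=lens / lens.sum()))]
        size = int(sizes[len(out) % len(sizes)]) if hasattr(sizes, "__len__") \
            else int(sizes)
        edge = min(10_000, len(genome[c]) // 10)
        if len(genome[c]) - size - 2 * edge <= 0:
            continue
        start = int(rng.integers(edge, len(genome[c]) - size - edge))
        iv = (c, start, start + size)
        if all(ivc != c or s - min_gap > iv[2] or e + min_gap < iv[1]
               for ivc, s, e in taken):
            taken.append(iv)
            out.append(iv)
    return out


def inject_svs(genome: dict[str, str], spec: dict[str, int],
               seed: int = 0, size_range: tuple[int, int] = (150, 5000),
               min_gap: int = 1000,
               avoid: Optional[list[tuple[str, int, int]]] = None,
               mei_library: Optional[dict] = None
               ) -> tuple[Donor, list[TruthSV]]:
    """Inject non-overlapping SVs of the requested counts into a fresh
    donor built over ``genome``.

    ``spec`` maps SV type (DEL/INS/DUP/INV/TRA/MEI/BND) to a count.  Sizes
    are spread evenly over ``size_range``.  MEI entries need
    ``mei_library`` with keys ``consensus`` (element sequence) and
    optionally ``tsd``/``polya``/``inversion``.  Truth breakpoints are in
    reference coordinates.
    """
    rng = np.random.default_rng(seed)
    donor = Donor(genome)
    truth: list[TruthSV] = []
    taken: list[tuple[str, int, int]] = list(avoid or [])

    def spread(n):
        lo, hi = size_range
        if n == 1:
            return [int((lo + hi) / 2)]
        return [int(lo + (hi - lo) * k / (n - 1)) for k in range(n)]

    order = ["DEL", "INS", "MEI", "DUP", "INV", "TRA", "BND"]
    for svtype in order:
        n = spec.get(svtype, 0)
        if not n:
            continue
        if svtype == "TRA":
            done = 0
            tries = 0
            while done < n and tries < 200:
                tries += 1
                (ca, pa, _), = _place_intervals(genome, 1, [1], rng, taken,
                                                min_gap)
                (cb, pb, _), = _place_intervals(genome, 1, [1], rng, taken,
                                                min_gap)
                try:
                    donor.translocate(ca, pa, cb, pb)
                except ValueError:
                    continue  # endpoints collapsed onto one donor chromosome
                j1 = _ordered(Breakpoint(ca, pa - 1, "+"),
                              Breakpoint(cb, pb, "-"), "")
                j2 = _ordered(Breakpoint(cb, pb - 1, "+"),
                              Breakpoint(ca, pa, "-"), "")
                truth.append(TruthSV("TRA", [j1, j2]))
                done += 1
            if done < n:
                raise RuntimeError("could not place requested translocations")
            continue
        sizes = spread(n)
        spots = _place_intervals(genome, n, sizes, rng, taken, min_gap)
        for k, (c, s, e) in enumerate(spots):
            size = e - s
            if svtype == "DEL":
                donor.delete(c, s, e)
                truth.append(TruthSV("DEL", [(Breakpoint(c, s - 1, "+"),
                                              Breakpoint(c, e, "-"), "")],
                                     size=size))
            elif svtype == "INS":
                ins = random_seq(rng, size)
                donor.insert(c, s, ins)
                truth.append(TruthSV("INS", [(Breakpoint(c, s - 1, "+"),
                                              Breakpoint(c, s, "-"), ins)],
                                     size=size))
            elif svtype == "MEI":
                lib = mei_library or {}
                cons = lib.get("consensus", random_seq(rng, 3000))
                tsd = int(lib.get("tsd", 12))
                polya = int(lib.get("polya", 20))
                frag = cons[max(0, len(cons) - size):]
                ins = frag + "A" * polya
                donor.insert(c, s, ins, tsd=tsd, label="MEI")
                truth.append(TruthSV(
                    "INS", [(Breakpoint(c, s - 1, "+"),
                             Breakpoint(c, s - tsd, "-"), ins)],
                    size=len(ins), insert_class=lib.get("class", "SoloLINE1"),
                    tsd=tsd, polya=polya))
            elif svtype == "DUP":
                donor.duplicate(c, s, e)
                truth.append(TruthSV("DUP", [(Breakpoint(c, s, "-"),
                                              Breakpoint(c, e - 1, "+"), "")],
                                     size=size))
            elif svtype == "INV":
                donor.invert(c, s, e)
                truth.append(TruthSV(
                    "INV", [(Breakpoint(c, s - 1, "+"),
                             Breakpoint(c, e - 1, "+"), ""),
                            (Breakpoint(c, s, "-"),
                             Breakpoint(c, e, "-"), "")],
                    size=size))
            elif svtype == "BND":
                lib = mei_library or {}
                foreign = lib.get("foreign", random_seq(rng, 8000))
                donor.breakend(c, s, foreign)
                truth.append(TruthSV(
                    "BND", [(Breakpoint(c, s - 1, "+"),
                             Breakpoint(c, s - 1, "+"), "")],
                    size=len(foreign), meta={"foreign": foreign}))
    return donor, truth


def _ordered(bpa: Breakpoint, bpb: Breakpoint, ins: str):
    if bpb.sort_key() < bpa.sort_key():
        return (bpb, bpa, ins)
    return (bpa, bpb, ins)


# ---------------------------------------------------------------------------
# error model
# ---------------------------------------------------------------------------

def _inject_errors(seq: str, error_rate: float, rng: np.random.Generator
                   ) -> tuple[str, list[tuple[str, int]]]:
    """Return (noisy sequence, ops) where ops align the noisy sequence to
    the clean one: M advances both, I is an extra read base, D a missing
    one.  Error budget 40:30:30 substitution:insertion:deletion."""
    L = len(seq)
    if L == 0 or error_rate <= 0:
        return seq, ([("M", L)] if L else [])
    k = rng.binomial(L, error_rate)
    if k == 0:
        return seq, [("M", L)]
    pos = np.sort(rng.choice(L, size=k, replace=False))
    types = rng.choice(3, size=k, p=[0.4, 0.3, 0.3])  # 0 sub, 1 ins, 2 del

    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    subs = pos[types == 0]
    if len(subs):
        cur = np.searchsorted(BASES, arr[subs])
        cur[cur > 3] = 0  # N or odd bases -> treat as A
        arr[subs] = BASES[(cur + rng.integers(1, 4, size=len(subs))) % 4]

    ins_pos = pos[types == 1]
    del_pos = pos[types == 2]
    if len(ins_pos):
        ins_bases = BASES[rng.integers(0, 4, size=len(ins_pos))]
        arr = np.insert(arr, ins_pos, ins_bases)
    if len(del_pos):
        adj = del_pos + np.searchsorted(ins_pos, del_pos, side="right") \
            if len(ins_pos) else del_pos
        arr = np.delete(arr, adj)

    events = sorted([(int(p), "I") for p in ins_pos]
                    + [(int(p), "D") for p in del_pos])
    ops: list[tuple[str, int]] = []
    prev = 0
    for p, t in events:
        if p > prev:
            _push(ops, "M", p - prev)
        _push(ops, t, 1)
        prev = p + (1 if t == "D" else 0)
    if L > prev:
        _push(ops, "M", L - prev)
    return bytes(arr).decode(), ops


def _push(ops: list, op: str, n: int) -> None:
    if n <= 0:
        return
    if ops and ops[-1][0] == op:
        ops[-1] = (op, ops[-1][1] + n)
    else:
        ops.append((op, n))


def _ops_query_len(ops) -> int:
    return sum(n for op, n in ops if op in "MI")


def _ops_ref_len(ops) -> int:
    return sum(n for op, n in ops if op in "MD")


def _trim_query(ops: list, nq: int, side: str) -> tuple[list, int, int]:
    """Trim exactly ``nq`` query bases from one end of an op list.

    Returns (ops, query_trimmed, ref_trimmed); trailing/leading D runs are
    dropped too."""
    ops = list(ops)
    q_tr = r_tr = 0
    idx = 0 if side == "left" else -1
    while ops and q_tr < nq:
        op, n = ops[idx]
        take = min(n, nq - q_tr) if op in "MI" else n
        if op in "MI":
            q_tr += take
        if op in "MD":
            r_tr += take if op == "M" else n
        if take == n:
            ops.pop(idx)
        else:
            ops[idx] = (op, n - take)
    while ops and ops[idx][0] == "D":
        r_tr += ops[idx][1]
        ops.pop(idx)
    return ops, q_tr, r_tr


# ---------------------------------------------------------------------------
# read simulation + alignment emission
# ---------------------------------------------------------------------------

@dataclass
class SamSegment:
    chrom: str
    ref_start: int
    ref_end: int
    strand: str
    ops: list  # reference-order (ascending coordinate) M/I/D ops
    q_start: int  # query span in original-read orientation
    q_end: int


@dataclass
class SimRead:
    read_id: str
    seq: str
    hap: str
    dchrom: str
    dstart: int
    dend: int
    strand: str
    segments: list = field(default_factory=list)


def _read_pieces(donor: Donor, dchrom: str, dstart: int, dend: int) -> list:
    """Donor pieces overlapped by [dstart, dend), clipped, in donor order.

    Each entry: ("ref", chrom, rs, re, strand) or ("novel", seq, label),
    where for "-" pieces the clipped reference interval accounts for donor
    orientation."""
    out = []
    off = 0
    for p in donor.chroms[dchrom]:
        ln = donor._piece_len(p)
        lo, hi = max(dstart, off), min(dend, off + ln)
        if lo < hi:
            a, b = lo - off, hi - off  # within-piece donor offsets
            if p[0] == "novel":
                out.append(("novel", p[1][a:b], p[2]))
            elif p[4] == "+":
                out.append(("ref", p[1], p[2] + a, p[2] + b, "+"))
            else:
                out.append(("ref", p[1], p[3] - b, p[3] - a, "-"))
        off += ln
        if off >= dend:
            break
    return out


def _build_segments(donor: Donor, pieces: list, error_rate: float,
                    rng: np.random.Generator, max_del: int = 100_000,
                    min_anchor: int = 100
                    ) -> tuple[str, list[SamSegment]]:
    """Turn a read's donor pieces into its noisy sequence plus SAM
    segments with reference-order CIGAR ops."""
    # 1. noisy sequence + per-piece read-order ops
    noisy = []
    for p in pieces:
        clean = donor.piece_seq(p)
        err_seq, ops = _inject_errors(clean, error_rate, rng)
        noisy.append({"piece": p, "seq": err_seq, "ops": ops})

    # 2. group into colinear runs
    groups: list[list[dict]] = []
    cur: list[dict] = []
    last_ref: Optional[dict] = None
    pending_novel: list[dict] = []

    for item in noisy:
        p = item["piece"]
        if p[0] == "novel":
            if cur:
                pending_novel.append(item)
            # novel with no aligned context yet -> leading clip
            continue
        if not cur or last_ref is None:
            pending_novel.clear()
            cur = [item]
            last_ref = item
            groups.append(cur)
            continue
        prev = last_ref["piece"]
        same = (p[1] == prev[1] and p[4] == prev[4])
        if p[4] == "+":
            gap = p[2] - prev[3]
        else:
            gap = prev[2] - p[3]
        tsd_absorb = bool(pending_novel) and -100 <= gap < 0
        if same and (0 <= gap <= max_del or tsd_absorb):
            if tsd_absorb:
                # an aligner folds the re-covered reference bases into the
                # insertion; move them out of the next piece into the novel
                t = -gap
                ops2, q_tr = _trim_ref_left(item["ops"], t)
                moved = item["seq"][:q_tr]
                item["piece"] = (("ref", p[1], p[2] + t, p[3], "+")
                                 if p[4] == "+" else
                                 ("ref", p[1], p[2], p[3] - t, "-"))
                item["seq"] = item["seq"][q_tr:]
                item["ops"] = ops2
                pending_novel[-1]["seq"] += moved
                gap = 0
            for nv in pending_novel:
                cur.append(nv)
            pending_novel.clear()
            if gap > 0:
                cur.append({"piece": ("gap", prev[1], gap), "seq": "",
                            "ops": [("D", gap)]})
            cur.append(item)
            last_ref = item
        else:
            pending_novel.clear()
            cur = [item]
            last_ref = item
            groups.append(cur)

    read_seq = "".join(item["seq"] for item in noisy)

    # 3. per group, assemble a SamSegment
    segments: list[SamSegment] = []
    # query offsets of each noisy item
    offsets = {}
    q = 0
    for item in noisy:
        offsets[id(item)] = q
        q += len(item["seq"])
    novel_q = {id(item): (offsets[id(item)], offsets[id(item)] + len(item["seq"]))
               for item in noisy}

    for grp in groups:
        ref_items = [g for g in grp if g["piece"][0] == "ref"]
        if not ref_items:
            continue
        strand = ref_items[0]["piece"][4]
        chrom = ref_items[0]["piece"][1]
        rs = min(g["piece"][2] for g in ref_items)
        re_ = max(g["piece"][3] for g in ref_items)
        q_start = min(offsets[id(g)] for g in grp if g["piece"][0] != "gap")
        q_end = max(offsets[id(g)] + len(g["seq"])
                    for g in grp if g["piece"][0] != "gap")
        # reference-order ops: for '+' groups read order == ref order;
        # for '-' groups reverse item order and each op list
        items = grp if strand == "+" else list(reversed(grp))
        ops: list[tuple[str, int]] = []
        for g in items:
            glist = g["ops"] if (strand == "+" or g["piece"][0] == "gap") \
                else list(reversed(g["ops"]))
            if g["piece"][0] == "novel":
                glist = [("I", len(g["seq"]))]
            for op, n in glist:
                _push(ops, op, n)
        # trim end D ops
        while ops and ops[0][0] == "D":
            rs += ops.pop(0)[1]
        while ops and ops[-1][0] == "D":
            re_ -= ops.pop()[1]
        while ops and ops[0][0] == "I":
            n = ops.pop(0)[1]
            if strand == "+":
                q_start += n
            else:
                q_end -= n
        while ops and ops[-1][0] == "I":
            n = ops.pop()[1]
            if strand == "+":
                q_end -= n
            else:
                q_start += n
        if _ops_query_len(ops) < min_anchor:
            continue
        segments.append(SamSegment(chrom=chrom, ref_start=rs, ref_end=re_,
                                   strand=strand, ops=ops,
                                   q_start=q_start, q_end=q_end))
    segments.sort(key=lambda s: s.q_start)
    return read_seq, segments


def _trim_ref_left(ops: list, nr: int) -> tuple[list, int]:
    """Trim ``nr`` reference bases from the left of a read-order op list;
    returns (ops, query bases consumed)."""
    ops = list(ops)
    q_tr = r_tr = 0
    while ops and r_tr < nr:
        op, n = ops[0]
        if op == "I":
            q_tr += n
            ops.pop(0)
            continue
        take = min(n, nr - r_tr)
        r_tr += take
        if op == "M":
            q_tr += take
        if take == n:
            ops.pop(0)
        else:
            ops[0] = (op, n - take)
    return ops, q_tr


def _flip_read(seq: str, segments: list[SamSegment]) -> tuple[str, list]:
    L = len(seq)
    flipped = []
    for s in segments:
        flipped.append(SamSegment(
            chrom=s.chrom, ref_start=s.ref_start, ref_end=s.ref_end,
            strand="-" if s.strand == "+" else "+", ops=s.ops,
            q_start=L - s.q_end, q_end=L - s.q_start))
    flipped.sort(key=lambda s: s.q_start)
    return revcomp(seq), flipped


def _apply_jitter(read_len: int, segments: list[SamSegment], jitter: int,
                  rng: np.random.Generator) -> None:
    """Move up to ``jitter`` aligned bases at each inter-segment junction
    into the soft clip, emulating alignment slop at breakpoints."""
    if jitter <= 0 or len(segments) < 2:
        return
    for k, seg in enumerate(segments):
        for side_is_left in (True, False):
            if side_is_left and k == 0:
                continue
            if not side_is_left and k == len(segments) - 1:
                continue
            j = int(rng.integers(0, jitter + 1))
            if j <= 0:
                continue
            # side in query space -> side in reference-order op space
            ref_side = "left" if (side_is_left == (seg.strand == "+")) \
                else "right"
            ops, q_tr, r_tr = _trim_query(seg.ops, j, ref_side)
            if _ops_query_len(ops) < 50:
                continue
            seg.ops = ops
            if ref_side == "left":
                seg.ref_start += r_tr
            else:
                seg.ref_end -= r_tr
            if side_is_left:
                seg.q_start += q_tr
            else:
                seg.q_end -= q_tr


def simulate_reads(donors: dict[str, Donor], reference: dict[str, str],
                   depth: float = 30.0, mean_len: float = 8000.0,
                   sd_log: float = 0.45, error_rate: float = 0.10,
                   seed: int = 0, clip_jitter: int = 3,
                   dropout: float = 0.02, read_prefix: str = "r"
                   ) -> list[SimRead]:
    """Sample noisy reads from the donor haplotypes.

    ``depth`` is the total sample depth over the reference (split across
    haplotypes by donor length).  Lengths are log-normal with the given
    mean; reads are truncated at donor chromosome ends.
    """
    rng = np.random.default_rng(seed)
    ref_len = sum(len(s) for s in reference.values())
    target = depth * ref_len
    entries = []
    for hap in sorted(donors):
        for dchrom in sorted(donors[hap].chroms):
            entries.append((hap, dchrom, donors[hap].length(dchrom)))
    lens = np.array([e[2] for e in entries], dtype=float)
    probs = lens / lens.sum()
    mu = np.log(mean_len) - sd_log ** 2 / 2

    reads: list[SimRead] = []
    emitted_bases = 0
    idx = 0
    while emitted_bases < target:
        hap, dchrom, dlen = entries[int(rng.choice(len(entries), p=probs))]
        rl = int(np.clip(rng.lognormal(mu, sd_log), 500, 80_000))
        start = int(rng.integers(0, max(1, dlen - 200)))
        end = min(dlen, start + rl)
        if end - start < 500:
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        donor = donors[hap]
        pieces = _read_pieces(donor, dchrom, start, end)
        seq, segments = _build_segments(donor, pieces, error_rate, rng)
        if strand == "-":
            seq, segments = _flip_read(seq, segments)
        _apply_jitter(len(seq), segments, clip_jitter, rng)
        if dropout > 0 and segments:
            segments = [s for s in segments if rng.random() >= dropout]
        read = SimRead(read_id=f"{read_prefix}{idx:06d}", seq=seq, hap=hap,
                       dchrom=dchrom, dstart=start, dend=end, strand=strand,
                       segments=segments)
        idx += 1
        emitted_bases += len(seq)
        reads.append(read)
    return reads


def emit_alignments(reads: list[SimRead], reference: dict[str, str],
                    path, sample: str = "tumor") -> int:
    """Write the reads' alignment records as a coordinate-sorted SAM file.

    The longest segment of each read is primary; the rest are
    supplementary with cross-referencing SA tags.  Reads with no mappable
    segment are omitted (returned count is written records)."""
    chroms = sorted(reference)
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(reference[c])} for c in chroms],
        "PG": [{"ID": "longsv-simulate", "PN": "longsv simulate"}],
        "RG": [{"ID": sample, "SM": sample}],
    })
    tid = {c: i for i, c in enumerate(chroms)}

    rows = []
    for read in reads:
        if not read.segments:
            continue
        primary = max(read.segments,
                      key=lambda s: _ops_query_len(s.ops))
        for seg in read.segments:
            rows.append((read, seg, seg is primary))

    def sam_cigar(read, seg) -> list[tuple[int, int]]:
        L = len(read.seq)
        if seg.strand == "+":
            left, right = seg.q_start, L - seg.q_end
        else:
            left, right = L - seg.q_end, seg.q_start
        ct = []
        if left:
            ct.append((4, left))
        opcode = {"M": 0, "I": 1, "D": 2}
        ct.extend((opcode[o], n) for o, n in seg.ops)
        if right:
            ct.append((4, right))
        return ct

    def cigar_str(read, seg) -> str:
        names = "MIDNSHP=X"
        return "".join(f"{n}{names[o]}" for o, n in sam_cigar(read, seg))

    rows.sort(key=lambda r: (tid[r[1].chrom], r[1].ref_start))
    n = 0
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read, seg, is_primary in rows:
            a = pysam.AlignedSegment(header)
            a.query_name = read.read_id
            a.reference_id = tid[seg.chrom]
            a.reference_start = seg.ref_start
            a.mapping_quality = 60
            flag = 0
            if seg.strand == "-":
                flag |= 16
            if not is_primary:
                flag |= 2048
            a.flag = flag
            a.cigartuples = sam_cigar(read, seg)
            a.query_sequence = read.seq if seg.strand == "+" \
                else revcomp(read.seq)
            others = [s for s in read.segments if s is not seg]
            tags = [("RG", sample), ("XH", read.hap), ("NM", 0)]
            if others:
                sa = "".join(
                    f"{s.chrom},{s.ref_start + 1},{s.strand},"
                    f"{cigar_str(read, s)},60,0;"
                    for s in others)
                tags.append(("SA", sa))
            a.set_tags(tags)
            out.write(a)
            n += 1
    return n


# ---------------------------------------------------------------------------
# whole-sample convenience + truth evaluation
# ---------------------------------------------------------------------------

def simulate_pair(reference: dict[str, str],
                  somatic_spec: Optional[dict[str, int]] = None,
                  germline_spec: Optional[dict[str, int]] = None,
                  depth: float = 30.0, error_rate: float = 0.10,
                  mean_len: float = 8000.0, seed: int = 0,
                  tumor_sam="tumor.sam", control_sam="control.sam",
                  size_range: tuple[int, int] = (150, 5000),
                  **read_kwargs) -> TruthSet:
    """Build a diploid tumor/control pair and write both SAM files.

    Haplotype 1 of the tumor carries the somatic SVs; haplotype 2 of both
    samples carries the germline SVs (heterozygous), so somatic VAF is
    ~50% and the control filter sees every germline junction.
    """
    rng = np.random.default_rng(seed)
    germ_donor, germ_truth = inject_svs(
        reference, germline_spec or {}, seed=int(rng.integers(2**31)),
        size_range=size_range)
    avoid = [(bp1.chrom, min(bp1.pos, bp2.pos) - 1,
              max(bp1.pos, bp2.pos) + 1)
             for t in germ_truth for bp1, bp2, _ in t.junctions]
    som_donor, som_truth = inject_svs(
        reference, somatic_spec or {}, seed=int(rng.integers(2**31)),
        size_range=size_range, avoid=avoid)

    truth = TruthSet(germline=germ_truth, somatic=som_truth, seed=seed)
    tumor_reads = simulate_reads(
        {"hap1": som_donor, "hap2": germ_donor}, reference, depth=depth,
        mean_len=mean_len, error_rate=error_rate,
        seed=int(rng.integers(2**31)), read_prefix="t", **read_kwargs)
    control_reads = simulate_reads(
        {"hap1": Donor(reference), "hap2": germ_donor}, reference,
        depth=depth, mean_len=mean_len, error_rate=error_rate,
        seed=int(rng.integers(2**31)), read_prefix="c", **read_kwargs)
    for r in tumor_reads:
        truth.read_origins[r.read_id] = (r.hap, r.dchrom, r.dstart, r.dend,
                                         r.strand)
    emit_alignments(tumor_reads, reference, tumor_sam, sample="tumor")
    emit_alignments(control_reads, reference, control_sam, sample="control")
    return truth


def evaluate_calls(truth_svs: list[TruthSV], records, margin: int = 200,
                   reference: Optional[dict[str, str]] = None) -> dict:
    """Event-level recall/precision plus breakpoint accuracy.

    A truth SV is recovered when any call matches one of its junctions
    within ``margin``; a call is a true positive when it matches any truth
    junction.  Breakpoint error is the largest coordinate deviation of a
    matched call from its truth junction.  When ``reference`` is given,
    truth junctions are first normalized to the caller's canonical
    representation (junctions with micro-homology or accidental
    insert/reference identity admit several equivalent coordinate
    representations of the same allele)."""
    records = list(records)
    if reference is not None:
        from .refine import canonicalize_junction
        truth_svs = [
            TruthSV(t.svtype,
                    [canonicalize_junction(b1, b2, ins, reference)
                     for b1, b2, ins in t.junctions],
                    size=t.size, insert_class=t.insert_class, tsd=t.tsd,
                    polya=t.polya, meta=t.meta)
            for t in truth_svs]
    matched_truth = set()
    tp = 0
    bp_errors = []
    for rec in records:
        hit = None
        for i, t in enumerate(truth_svs):
            if t.matches_call(rec.bp1, rec.bp2, margin):
                hit = (i, t)
                break
        if hit is None:
            continue
        tp += 1
        matched_truth.add(hit[0])
        errs = [max(abs(b1.pos - rec.bp1.pos), abs(b2.pos - rec.bp2.pos))
                for b1, b2, _ in hit[1].junctions
                if b1.chrom == rec.bp1.chrom and b2.chrom == rec.bp2.chrom
                and b1.dir == rec.bp1.dir and b2.dir == rec.bp2.dir]
        if errs:
            bp_errors.append(min(errs))
    n_calls = len(list(records))
    recall = len(matched_truth) / len(truth_svs) if truth_svs else 1.0
    precision = tp / n_calls if n_calls else 1.0
    within2 = (sum(1 for e in bp_errors if e <= 2) / len(bp_errors)
               if bp_errors else 0.0)
    return {"recall": recall, "precision": precision,
            "n_calls": n_calls, "n_truth": len(truth_svs),
            "breakpoint_within_2bp": within2,
            "bp_errors": bp_errors}
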
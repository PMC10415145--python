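"""Domain types shared across the caller.

Coordinate conventions
----------------------
All internal coordinates are 0-based, half-open.  1-based coordinates appear
only at the SAM/VCF boundary.

A :class:`Breakpoint` is an oriented reference position:

* ``dir == "+"``  — the SV adjacency leaves the reference moving *right*:
  the reference sequence up to and including ``pos`` is retained on this
  side of the junction.
* ``dir == "-"`` — the adjacency leaves moving *left*: the reference
  sequence from ``pos`` onward is retained (``pos`` is the first retained
  base).

Under this convention a blunt insertion before reference base ``p`` has
``bp1 = (chrom, p-1, "+")`` and ``bp2 = (chrom, p, "-")``; a deletion of
``[s, e)`` has ``bp1 = (chrom, s-1, "+")`` and ``bp2 = (chrom, e, "-")``.
A target-site duplication shows up as overlapping breakpoints
(``bp2.pos <= bp1.pos``) with TSD length ``bp1.pos - bp2.pos + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

CigarOp = tuple[str, int]

_CHROM_ORDER_CACHE: dict[str, tuple[int, str]] = {}


def _chrom_key(chrom: str) -> tuple[int, str]:
    """Sort key placing numeric chromosome names numerically."""
    key = _CHROM_ORDER_CACHE.get(chrom)
    if key is None:
        name = chrom[3:] if chrom.startswith("chr") else chrom
        key = (int(name), chrom) if name.isdigit() else (10**6, chrom)
        _CHROM_ORDER_CACHE[chrom] = key
    return key


@dataclass(frozen=True, order=False)
class Breakpoint:
    chrom: str
    pos: int
    dir: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.dir not in ("+", "-"):
            raise ValueError(f"breakpoint dir must be '+' or '-', got {self.dir!r}")
        if self.pos < 0:
            raise ValueError(f"negative breakpoint position {self.pos}")

    def sort_key(self) -> tuple[tuple[int, str], int]:
        return (_chrom_key(self.chrom), self.pos)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}({self.dir})"


@dataclass
class AlignmentRecord:
    """One aligned segment of one read, as parsed from SAM/BAM."""

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    cigar: list[CigarOp]
    seq: Optional[str]
    sa_segments: list[tuple[str, int, str, str]] = field(default_factory=list)
    is_secondary: bool = False
    is_supplementary: bool = False
    sample: str = "tumor"
    mapq: int = 60

    @property
    def left_clip(self) -> int:
        if self.cigar and self.cigar[0][0] in "SH":
            return self.cigar[0][1]
        return 0

    @property
    def right_clip(self) -> int:
        if self.cigar and self.cigar[-1][0] in "SH":
            return self.cigar[-1][1]
        return 0

    def query_length(self) -> int:
        """Full read length implied by the CIGAR (clips included)."""
        return sum(n for op, n in self.cigar if op in "M=XISH")

    def query_span(self) -> tuple[int, int]:
        """Aligned query interval in *original read* orientation."""
        qs = self.left_clip
        qe = self.query_length() - self.right_clip
        if self.strand == "-":
            total = self.query_length()
            qs, qe = total - qe, total - qs
        return qs, qe


def svtype_of(bp1: Breakpoint, bp2: Breakpoint, inserted_seq: str) -> str:
    """Derive the reported SV type from the oriented breakpoint pair."""
    if bp1.chrom != bp2.chrom:
        return "TRA"
    dirs = (bp1.dir, bp2.dir)
    if dirs == ("+", "-"):
        deleted = bp2.pos - bp1.pos - 1
        return "INS" if len(inserted_seq) > max(deleted, 0) else "DEL"
    if dirs == ("-", "+"):
        return "DUP"
    return "INV"


@dataclass
class CanonicalSVRecord:
    """A final two-breakpoint SV with its polished inserted sequence."""

    bp1: Breakpoint
    bp2: Breakpoint
    inserted_seq: str
    svtype: str
    tumor_support: int = 0
    control_support: int = 0
    tumor_vaf: float = 0.0
    supporting_read_ids: list[str] = field(default_factory=list)
    homology_len: int = 0
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        # bp1 precedes bp2 in genome order, except that insertion junctions
        # with a target-site duplication legitimately overlap (bp2 lands up
        # to ~max_tsd bases left of bp1)
        if self.bp2.sort_key() < self.bp1.sort_key():
            overlap_ok = (self.bp1.chrom == self.bp2.chrom
                          and (self.bp1.dir, self.bp2.dir) == ("+", "-")
                          and self.bp1.pos - self.bp2.pos <= 200)
            if not overlap_ok:
                raise ValueError("bp1 must not follow bp2 in genome order")

    @property
    def deleted_span(self) -> int:
        if self.bp1.chrom != self.bp2.chrom:
            return 0
        return max(0, self.bp2.pos - self.bp1.pos - 1)

    def key(self) -> tuple:
        return (
            self.bp1.chrom, self.bp1.pos, self.bp1.dir,
            self.bp2.chrom, self.bp2.pos, self.bp2.dir,
        )


@dataclass
class SingleBreakendRecord:
    """A one-sided SV: an oriented breakpoint plus the contig beyond it."""

    bp: Breakpoint
    contig: str
    tumor_support: int = 0
    control_support: int = 0
    classification: str = "Unclassified"
    evidence: list["AnnotationInterval"] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)


@dataclass
class BreakpointSignal:
    """One read's evidence for one junction."""

    read_id: str
    bp1: Breakpoint
    bp2: Breakpoint
    insert_len_estimate: int
    source: str  # "cigar_indel" | "split_alignment"
    read_offsets: tuple[int, int]  # query coords bracketing the junction,
    # in original-read orientation
    bp1_first: bool = True  # original read traverses bp1 side before bp2 side

    def key(self) -> tuple:
        return (
            self.bp1.chrom, self.bp2.chrom, self.bp1.dir, self.bp2.dir,
        )


@dataclass
class SVCandidateCluster:
    signals: list[BreakpointSignal]
    bp1_range: tuple[int, int]
    bp2_range: tuple[int, int]

    @property
    def chrom1(self) -> str:
        return self.signals[0].bp1.chrom

    @property
    def chrom2(self) -> str:
        return self.signals[0].bp2.chrom

    @property
    def dirs(self) -> tuple[str, str]:
        return (self.signals[0].bp1.dir, self.signals[0].bp2.dir)

    @property
    def median_insert_len(self) -> int:
        vals = sorted(s.insert_len_estimate for s in self.signals)
        return vals[len(vals) // 2]

    @property
    def supporting_read_ids(self) -> list[str]:
        return sorted({s.read_id for s in self.signals})

    @property
    def bp1_median(self) -> int:
        vals = sorted(s.bp1.pos for s in self.signals)
        return vals[len(vals) // 2]

    @property
    def bp2_median(self) -> int:
        vals = sorted(s.bp2.pos for s in self.signals)
        return vals[len(vals) // 2]


@dataclass
class ConsensusContig:
    seq: str
    n_inputs: int
    support: list[int] = field(default_factory=list)
    mean_identity: float = 1.0
    flags: list[str] = field(default_factory=list)


@dataclass
class JumpAlignment:
    """Result of the one-time-jump two-region local alignment.

    Query indices are 0-based; ``inserted_seq = query[q_end1:q_start2]``.
    ``r1_end``/``r2_start`` are coordinates *within the supplied reference
    windows* (window-local); callers translate them to genome coordinates.
    """

    score: float
    q_end1: int
    q_start2: int
    r1_end: int
    r2_start: int
    piece1_len: int = 0
    piece2_len: int = 0
    jumped: bool = True


@dataclass
class SegmentPair:
    sv_segment: str
    ref_segment1: str
    ref_segment2: str
    junctions: tuple[int, int]  # positions of bp1/bp2 junctions inside sv_segment
    flags: list[str] = field(default_factory=list)


@dataclass
class SoftclipSignal:
    read_id: str
    bp: Breakpoint
    clip_side: str  # "left" | "right"
    clip_seq: str   # junction-proximal base first
    clip_len: int
    inner_seq: str = ""  # aligned read bases just inside the breakpoint


@dataclass
class AnnotationInterval:
    start: int
    end: int
    label: str
    identity: float = 1.0
    orientation: str = "+"
    family: str = ""

    def length(self) -> int:
        return self.end - self.start


@dataclass
class InsertionAnnotation:
    insertion_class: str
    repeat_segments: list[AnnotationInterval] = field(default_factory=list)
    has_5prime_inversion: bool = False
    tsd: Optional[tuple[int, str]] = None
    polya: Optional[tuple[int, str]] = None
    transduction_source: Optional[tuple[str, int, int, str]] = None
    nested: bool = False
    evidence: dict = field(default_factory=dict)


@dataclass(frozen=True)
class LINE1SourceElement:
    chrom: str
    start: int
    end: int
    strand: str
    element_id: str
    provenance: str = "reference"  # reference | population_catalog | curated | somatic


@dataclass
class MonomerMatch:
    monomer_id: str
    start_pos: int
    end_pos: int
    identity: float  # percent, 0..100
    orientation: str = "+"

    def length(self) -> int:
        return self.end_pos - self.start_pos


@dataclass
class HORDefinition:
    chromosome: str
    monomer_order: list[str]
    successors: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.successors:
            order = self.monomer_order
            succ: dict[str, set[str]] = {m: set() for m in order}
            for i, m in enumerate(order):
                succ[m].add(order[(i + 1) % len(order)])
            self.successors = succ

    def allows(self, prev: str, cur: str) -> bool:
        return cur in self.successors.get(prev, set())
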
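"""Readers and writers for every on-disk format the caller touches.

SAM/BAM goes through pysam; FASTA through Bio.SeqIO; BED files become
intervaltree sets.  Results are written both as a fixed-column TSV (the
round-trip format) and as VCF 4.2 with paired BND records.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Iterator, Optional

import pysam
from Bio import SeqIO
from intervaltree import Interval, IntervalTree

from .model import (AlignmentRecord, AnnotationInterval, Breakpoint,
                    CanonicalSVRecord, LINE1SourceElement,
                    SingleBreakendRecord)

log = logging.getLogger(__name__)

_CIGAR_OPS = "MIDNSHP=X"


def _cigartuples_to_ops(cigartuples) -> list[tuple[str, int]]:
    return [(_CIGAR_OPS[op], ln) for op, ln in cigartuples]


def parse_sa_tag(sa: str) -> list[tuple[str, int, str, str]]:
    """Parse an SA tag into (chrom, 0-based pos, strand, cigar) tuples."""
    segments = []
    for part in sa.rstrip(";").split(";"):
        if not part:
            continue
        f = part.split(",")
        segments.append((f[0], int(f[1]) - 1, f[2], f[3]))
    return segments


def parse_cigar_string(cigar: str) -> list[tuple[str, int]]:
    ops: list[tuple[str, int]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((ch, int(num)))
            num = ""
    return ops


def read_alignments(path, region: Optional[tuple[str, int, int]] = None,
                    sample: str = "tumor") -> Iterator[AlignmentRecord]:
    """Stream alignment records from a SAM/BAM file.

    Secondary alignments are dropped; supplementary alignments are kept and
    flagged (they carry the split-read evidence).  Coordinates are 0-based
    half-open.  Records with malformed CIGARs are skipped and counted in a
    warning.
    """
    skipped = 0
    emitted = 0
    save = pysam.set_verbosity(0)
    try:
        with pysam.AlignmentFile(str(path), require_index=False) as fh:
            if region is not None:
                try:
                    it = fh.fetch(region[0], region[1], region[2])
                except ValueError:
                    it = (r for r in fh.fetch(until_eof=True)
                          if r.reference_name == region[0]
                          and not r.is_unmapped
                          and r.reference_start < region[2]
                          and r.reference_end > region[1])
            else:
                it = fh.fetch(until_eof=True)
            for rec in it:
                if rec.is_unmapped or rec.is_secondary:
                    continue
                if not rec.cigartuples:
                    skipped += 1
                    continue
                cigar = _cigartuples_to_ops(rec.cigartuples)
                seq = rec.query_sequence
                if seq is not None:
                    qlen = sum(n for op, n in cigar if op in "MIS=X")
                    if qlen != len(seq):
                        skipped += 1
                        continue
                sa = []
                if rec.has_tag("SA"):
                    sa = parse_sa_tag(rec.get_tag("SA"))
                emitted += 1
                yield AlignmentRecord(
                    read_id=rec.query_name,
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    cigar=cigar,
                    seq=seq,
                    sa_segments=sa,
                    is_supplementary=rec.is_supplementary,
                    sample=sample,
                    mapq=rec.mapping_quality,
                )
    finally:
        pysam.set_verbosity(save)
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} records with malformed CIGAR/SEQ")
    if emitted == 0:
        warnings.warn(f"{path}: no mapped alignments found")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into a name -> uppercase-sequence mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate sequence name {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_bed(path) -> dict[str, IntervalTree]:
    """Read a BED file (0-based half-open) into per-chromosome interval trees."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            chrom, start, end = f[0], int(f[1]), int(f[2])
            if end <= start:
                continue
            trees.setdefault(chrom, IntervalTree()).add(
                Interval(start, end, f[3] if len(f) > 3 else None))
    return trees


def read_line1_sources(path) -> list[LINE1SourceElement]:
    """BED + strand + provenance columns: chrom start end id strand provenance."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            out.append(LINE1SourceElement(
                chrom=f[0], start=int(f[1]), end=int(f[2]),
                element_id=f[3] if len(f) > 3 else f"{f[0]}:{f[1]}",
                strand=f[4] if len(f) > 4 else "+",
                provenance=f[5] if len(f) > 5 else "reference",
            ))
    return out


def read_repeatmasker_out(path) -> list[AnnotationInterval]:
    """Parse a RepeatMasker ``.out`` annotation table (standard layout).

    Query coordinates are converted to 0-based half-open intervals; the
    percent divergence column becomes an identity in [0, 1].
    """
    out: list[AnnotationInterval] = []
    with open(path) as fh:
        for line in fh:
            f = line.split()
            if not f or not f[0].replace(".", "").isdigit():
                continue  # header/blank lines
            div = float(f[1])
            q_start, q_end = int(f[5]) - 1, int(f[6])
            orient = "-" if f[8] in ("C", "-") else "+"
            label = f[9]
            family = f[10] if len(f) > 10 else ""
            out.append(AnnotationInterval(
                start=q_start, end=q_end, label=label,
                identity=max(0.0, 1.0 - div / 100.0),
                orientation=orient, family=family))
    return out


# ---------------------------------------------------------------------------
# result TSV + VCF
# ---------------------------------------------------------------------------

TSV_COLUMNS = ["chr1", "pos1", "dir1", "chr2", "pos2", "dir2", "inserted_seq",
               "svtype", "tumor_support", "control_support", "vaf",
               "homology_len", "flags"]


def write_results(records: Iterable[CanonicalSVRecord], out_prefix,
                  reference: Optional[dict[str, str]] = None) -> tuple[str, str]:
    """Write the final SV set as ``<prefix>.sv.tsv`` and ``<prefix>.sv.vcf``.

    The TSV is the authoritative round-trip format; the VCF encodes each SV
    as a pair of cross-referenced BND records (positions 1-based).
    """
    records = list(records)
    tsv_path = f"{out_prefix}.sv.tsv"
    vcf_path = f"{out_prefix}.sv.vcf"
    with open(tsv_path, "w") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for r in records:
            fh.write("\t".join(map(str, [
                r.bp1.chrom, r.bp1.pos, r.bp1.dir,
                r.bp2.chrom, r.bp2.pos, r.bp2.dir,
                r.inserted_seq if r.inserted_seq else ".",
                r.svtype, r.tumor_support, r.control_support,
                f"{r.tumor_vaf:.4f}", r.homology_len,
                ",".join(r.flags) if r.flags else ".",
            ])) + "\n")
    _write_vcf(records, vcf_path, reference)
    return tsv_path, vcf_path


def read_results(tsv_path) -> list[CanonicalSVRecord]:
    from .model import svtype_of  # local import to avoid cycle noise
    out: list[CanonicalSVRecord] = []
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:6] != TSV_COLUMNS[:6]:
            raise ValueError(f"unexpected result TSV header in {tsv_path}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            ins = "" if f[6] == "." else f[6]
            rec = CanonicalSVRecord(
                bp1=Breakpoint(f[0], int(f[1]), f[2]),
                bp2=Breakpoint(f[3], int(f[4]), f[5]),
                inserted_seq=ins,
                svtype=f[7],
                tumor_support=int(f[8]),
                control_support=int(f[9]),
                tumor_vaf=float(f[10]),
                homology_len=int(f[11]),
                flags=[] if f[12] == "." else f[12].split(","),
            )
            if rec.svtype != svtype_of(rec.bp1, rec.bp2, ins):
                rec.flags.append("svtype_override")
            out.append(rec)
    return out


def _ref_base(reference, chrom: str, pos: int) -> str:
    if reference and chrom in reference and 0 <= pos < len(reference[chrom]):
        return reference[chrom][pos]
    return "N"


def _bnd_alt(ref_base: str, ins: str, here_dir: str, mate: Breakpoint) -> str:
    from .seqs import revcomp
    p = f"{mate.chrom}:{mate.pos + 1}"
    if here_dir == "+":
        t = ref_base + ins
        return f"{t}[{p}[" if mate.dir == "-" else f"{t}]{p}]"
    t = ins + ref_base
    return f"]{p}]{t}" if mate.dir == "+" else f"[{p}[{t}"


def _write_vcf(records: list[CanonicalSVRecord], path,
               reference: Optional[dict[str, str]]) -> None:
    from .seqs import revcomp
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##ALT=<ID=BND,Description="Breakend">\n')
        for key, desc in [
            ("SVTYPE", "Type of structural variant"),
            ("MATEID", "ID of mate breakend"),
            ("SVINSLEN", "Length of the inserted sequence"),
            ("TUMOR_SUPPORT", "Variant supporting reads in tumor"),
            ("CONTROL_SUPPORT", "Variant supporting reads in control"),
            ("VAF", "Tumor variant allele fraction"),
            ("HOMLEN", "Micro-homology length at the junction"),
        ]:
            num = "1"
            typ = "Float" if key == "VAF" else ("String" if key in ("SVTYPE", "MATEID") else "Integer")
            fh.write(f'##INFO=<ID={key},Number={num},Type={typ},Description="{desc}">\n')
        if reference:
            for chrom, seq in reference.items():
                fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, r in enumerate(records):
            ids = (f"longsv_{i}_1", f"longsv_{i}_2")
            ins1 = r.inserted_seq
            # from bp2's viewpoint the insert is read in the opposite allele
            # direction for inversion-type adjacencies
            ins2 = revcomp(ins1) if r.bp1.dir == r.bp2.dir else ins1
            for bp, mate, ident, mate_id, ins in (
                    (r.bp1, r.bp2, ids[0], ids[1], ins1),
                    (r.bp2, r.bp1, ids[1], ids[0], ins2)):
                base = _ref_base(reference, bp.chrom, bp.pos)
                alt = _bnd_alt(base, ins, bp.dir, mate)
                info = (f"SVTYPE=BND;MATEID={mate_id};SVINSLEN={len(r.inserted_seq)};"
                        f"TUMOR_SUPPORT={r.tumor_support};"
                        f"CONTROL_SUPPORT={r.control_support};"
                        f"VAF={r.tumor_vaf:.4f};HOMLEN={r.homology_len}")
                fh.write(f"{bp.chrom}\t{bp.pos + 1}\t{ident}\t{base}\t{alt}"
                         f"\t.\tPASS\t{info}\n")


BREAKEND_TSV_COLUMNS = ["chrom", "pos", "dir", "tumor_support",
                        "control_support", "classification", "contig",
                        "evidence", "flags"]


def write_breakend_results(records: Iterable[SingleBreakendRecord],
                           out_prefix) -> str:
    path = f"{out_prefix}.breakend.tsv"
    with open(path, "w") as fh:
        fh.write("\t".join(BREAKEND_TSV_COLUMNS) + "\n")
        for r in records:
            ev = ";".join(
                f"{a.label}:{a.start}-{a.end}:{a.orientation}:{a.identity:.2f}"
                for a in r.evidence) or "."
            fh.write("\t".join(map(str, [
                r.bp.chrom, r.bp.pos, r.bp.dir, r.tumor_support,
                r.control_support, r.classification, r.contig, ev,
                ",".join(r.flags) if r.flags else ".",
            ])) + "\n")
    return path


def write_clusters_tsv(clusters, path) -> None:
    """Debug dump of intermediate candidate clusters."""
    cols = ["chrom1", "bp1_lo", "bp1_hi", "dir1", "chrom2", "bp2_lo", "bp2_hi",
            "dir2", "median_insert_len", "n_reads", "read_ids"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in clusters:
            fh.write("\t".join(map(str, [
                c.chrom1, c.bp1_range[0], c.bp1_range[1], c.dirs[0],
                c.chrom2, c.bp2_range[0], c.bp2_range[1], c.dirs[1],
                c.median_insert_len, len(c.supporting_read_ids),
                ",".join(c.supporting_read_ids),
            ])) + "\n")
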
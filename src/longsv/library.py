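"""Repeat-consensus, transcript and centromere-monomer resources.

Real analyses supply their own consensus FASTAs (RepeatMasker-style
``NAME#family`` identifiers), transcript FASTAs and HORmon-style monomer /
HOR-order tables.  For tests and examples, :func:`synthetic_library`
deterministically generates a *synthetic* stand-in library with realistic
element lengths (the sequences are random, not biological consensi) — a
LINE1-like 6 kb element with a polyA 3' end, an Alu-like 300 bp element, an
SVA-like fragment, an HBV-like viral genome fragment, simple-repeat units
and two chromosomes' worth of 171 bp alpha-satellite monomers with a
canonical higher-order repeat (HOR) order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import HORDefinition

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

TELOMERE_MOTIF = "TTAGGG"


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.42) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return bytes(BASES[rng.choice(4, size=length, p=p)]).decode()


@dataclass
class Transcript:
    name: str
    seq: str
    exon_junctions: list[int] = field(default_factory=list)


@dataclass
class RepeatLibrary:
    """Consensus sequences keyed by element name, with repeat families."""

    seqs: dict[str, str]
    families: dict[str, str]

    def of_family(self, *families: str) -> dict[str, str]:
        return {n: s for n, s in self.seqs.items()
                if self.families.get(n) in families}

    @classmethod
    def from_fasta_dict(cls, seqs: dict[str, str]) -> "RepeatLibrary":
        """Build from FASTA records named ``NAME#family`` (RepeatMasker
        convention); records without '#' get family 'Unknown'."""
        out_seqs, fams = {}, {}
        for name, seq in seqs.items():
            base, _, fam = name.partition("#")
            out_seqs[base] = seq.upper()
            fams[base] = fam.split("/")[0] if fam else "Unknown"
        return cls(out_seqs, fams)


@dataclass
class MonomerSet:
    monomers: dict[str, str]          # monomer id -> consensus
    hors: list[HORDefinition]


def synthetic_library(seed: int = 20231,
                      include_monomers: bool = True) -> RepeatLibrary:
    """Deterministic synthetic stand-in repeat/virus consensus library."""
    rng = np.random.default_rng(seed)
    seqs = {
        "L1HS#LINE/L1": random_seq(rng, 5970) + "A" * 30,
        "AluY#SINE/Alu": random_seq(rng, 281) + "A" * 19,
        "SVA#Retroposon/SVA": random_seq(rng, 1300),
        "HBV#Virus": random_seq(rng, 3215),
        "(AT)n#Simple_repeat": "AT" * 60,
        "(CAGG)n#Simple_repeat": "CAGG" * 30,
        "TEL#Satellite/telo": TELOMERE_MOTIF * 20,
    }
    if include_monomers:
        for mid, mono in synthetic_monomers().monomers.items():
            seqs[f"{mid}#Satellite/centr"] = mono
    return RepeatLibrary.from_fasta_dict(seqs)


def synthetic_monomers(seed: int = 20232, n_chroms: int = 2,
                       monomer_len: int = 171,
                       hor_len: int = 12) -> MonomerSet:
    """Two synthetic centromeres: per chromosome, ``hor_len`` divergent
    monomers in a fixed canonical order.  Monomers within a chromosome are
    mutations of a common ancestor (~20% divergence), mirroring real
    alpha-satellite monomer families."""
    rng = np.random.default_rng(seed)
    letters = "ABCDEFGHIJKLMNOPQRSTUVWX"
    monomers: dict[str, str] = {}
    hors: list[HORDefinition] = []
    for c in range(n_chroms):
        chrom = f"chr{c + 1}" if c else "chrX"
        ancestor = np.frombuffer(random_seq(rng, monomer_len).encode(),
                                 dtype=np.uint8)
        order = []
        for k in range(hor_len):
            mono = ancestor.copy()
            n_mut = int(0.2 * monomer_len)
            pos = rng.choice(monomer_len, size=n_mut, replace=False)
            mono[pos] = BASES[(np.searchsorted(BASES, mono[pos])
                               + rng.integers(1, 4, size=n_mut)) % 4]
            mid = f"{chrom}_{letters[k]}"
            monomers[mid] = bytes(mono).decode()
            order.append(mid)
        hors.append(HORDefinition(chromosome=chrom, monomer_order=order))
    return MonomerSet(monomers=monomers, hors=hors)


def synthetic_transcripts(seed: int = 20233) -> list[Transcript]:
    rng = np.random.default_rng(seed)
    out = []
    for name, exons in [("IBTK-like", (420, 510, 390)),
                        ("CARNMT1-like", (350, 610, 280, 450))]:
        parts = [random_seq(rng, n) for n in exons]
        junctions = list(np.cumsum([len(p) for p in parts[:-1]]))
        out.append(Transcript(name=name, seq="".join(parts),
                              exon_junctions=[int(j) for j in junctions]))
    return out


def read_transcripts(fasta: dict[str, str],
                     descriptions: dict[str, str] | None = None
                     ) -> list[Transcript]:
    """Transcripts from a FASTA mapping; exon junction offsets may be given
    in the description as ``junctions=120,340``."""
    out = []
    for name, seq in fasta.items():
        junctions: list[int] = []
        desc = (descriptions or {}).get(name, "")
        for tok in desc.split():
            if tok.startswith("junctions="):
                junctions = [int(x) for x in tok.split("=", 1)[1].split(",") if x]
        out.append(Transcript(name=name, seq=seq.upper(),
                              exon_junctions=junctions))
    return out


def read_hor_table(path) -> list[HORDefinition]:
    """HOR order file: ``chromosome<TAB>comma-separated monomer ids``."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, order = line.split("\t")
            out.append(HORDefinition(chromosome=chrom,
                                     monomer_order=order.split(",")))
    return out
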
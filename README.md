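# longsv

Somatic structural-variant (SV) discovery from **tumor / matched-control
paired long-read alignments**, at single-base resolution, with
error-corrected inserted sequences.

Long reads span repeats that defeat short-read SV callers, but naive
"call each sample separately and subtract" workflows leak germline SVs
that narrowly miss thresholds in the control. `longsv` instead analyses
tumor and control jointly, in two modules:

* **Canonical SV module** — SVs defined by two breakpoints plus any
  sequence inserted between them (DEL, DUP, INS, INV, TRA). Four stages:
  1. *Parsing*: junction signals from CIGAR indels (internal threshold
     50 bp) and split primary/supplementary alignments (SA tags);
  2. *Clustering*: single-linkage within 200 bp on both breakpoints,
     with removal of candidates that have **any** supporting read in the
     matched control or a panel of normals (control parsed permissively —
     the asymmetry is deliberate);
  3. *Refinement*: the junction-spanning read portions are polished into
     a consensus (centroid selection + two rounds of per-column majority
     vote), then aligned to the two candidate reference windows with a
     **Smith–Waterman variant that allows a one-time jump** between
     regions. The jump cell gives the two breakpoints exactly and the
     query bases skipped between the pieces are the inserted sequence;
  4. *Validation*: the putative SV-allele segment and both
     reference-allele segments are rebuilt and every read near either
     breakpoint is re-genotyped against them; kept iff ≥3 tumor variant
     reads and 0 control variant reads, then DEL/INS < 100 bp and
     DEL/INS confined to simple repeats are dropped.

* **Single breakend SV module** — junctions whose partner sequence
  (satellite arrays, telomere, viral genomes, mobile elements) cannot be
  placed uniquely. Long soft-clips (≥500 bp) are clustered, polished into
  a breakend contig, validated with the same ≥3/0 rule, and classified:
  `RescuedCanonical` (contig places uniquely after all → re-emitted as a
  canonical SV), `Satellite`, `SimpleRepeat`, `Telomere`, `L1Mediated`,
  `AluMediated`, `VirusMediated`, or `Unclassified`.

Companion workflows annotate full-length **mobile-element insertions**
(solo LINE1/Alu/SVA, processed pseudogene, partnered/orphan 3′
transduction with source-element inference, 5′ inversion / twin priming,
target-site duplication, polyA tail) and score satellite breakend contigs
against chromosome-specific centromeric **higher-order repeats**: each
monomer block consistent with the HOR successor order contributes
`(end − start) · identity / 100`, and the sum divided by the contig
length is the HOR match score in [0, 1].

A first-class **synthetic-data module** (`longsv.simulate`) builds toy
diploid genomes, injects germline + somatic SVs (including MEI-style
insertions with TSDs and polyA tails, and one-sided junctions into
foreign sequence), and emits noisy long reads *directly as alignment
records* with correct CIGARs, soft clips and SA tags — no external
aligner needed, and the truth is exact by construction.

## Worked example

`examples/01_call_somatic_svs.py` simulates a 2 × 200 kb tumor/control
pair (30×, 10 % read error, ten somatic and four germline SVs) and runs
the canonical module:

```
10 somatic SVs injected, 11 junctions called:
  INS chr1:126793(+) -> chr1:126793(-)  insert=1074bp  support=16/0  VAF=0.64
  DEL chr1:140089(+) -> chr1:141165(-)  insert=0bp  support=18/0  VAF=0.46
  TRA chr1:156448(+) -> chr2:38356(-)  insert=0bp  support=13/0  VAF=0.19
  ...
recall 1.00, precision 1.00, breakpoints within 2 bp: 1.00
```

Each line is one junction: oriented breakpoints (`+` = reference retained
to the left of the position, `-` = retained from the position rightward),
the polished insert length, tumor/control variant-supporting read counts
from the validation stage, and the tumor variant-allele fraction
(≈0.5 for heterozygous events; lower where extra copies exist, e.g.
around a reciprocal translocation). Inversions and reciprocal
translocations surface as two junction records each. Results are written
as a fixed-column TSV (round-trip format) and a VCF 4.2 file with paired
BND records.

The other examples demonstrate single-breakend classification and
canonical rescue (`02`), insertion annotation with transduction-source
inference (`03`), and HOR match scores with interchromosomal centromere
detection (`04`).

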
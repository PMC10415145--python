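# Methods

This note records the models, numerical choices and known limitations
behind `longsv`, in the spirit of a methods supplement.

## Coordinates and breakpoint convention

All internal coordinates are 0-based half-open; 1-based appears only at
the SAM/VCF boundary. A breakpoint is an oriented position: with
`dir = "+"` the reference up to and including `pos` is retained on that
side of the junction; with `dir = "-"` the reference from `pos` onward is
retained (`pos` is the first retained base). Under this convention a
blunt insertion before base *p* is `(p−1, +) / (p, −)`; a deletion of
`[s, e)` is `(s−1, +) / (e, −)`; a target-site duplication (TSD) shows as
overlapping breakpoints with length `bp1.pos − bp2.pos + 1`. Record pairs
are ordered by genome position, except that TSD-overlapping insertion
junctions keep the `(+, −)` orientation.

### Junction representation is not unique

A junction with inserted sequence admits many coordinate representations
of the same allele: bases can slide between the insert and either
reference side wherever they match exactly (micro-homology and accidental
insert/reference identity). The caller reports the
**maximal-reference-attribution** form, bp1 side first — the same form
its jump alignment's scoring and tie-breaks produce — implemented in
`refine.canonicalize_junction`. The simulator's truth is mapped through
the same normalizer before comparison; this is a change of coordinates,
not of tolerance.

## Canonical SV module

**Parsing.** One signal per D/I CIGAR operation ≥ `min_indel_size`
(default 50 bp — deliberately below the 100 bp reporting filter so
consensus refinement can recover true sizes near the boundary) and one
per adjacent pair of aligned segments of a split read. Junction
orientations follow from segment strands: a read leaves a forward segment
at its reference end (`+`) and a reverse segment at its reference start
(`-`), mirrored on entry. Control and panel samples are parsed with a
permissive threshold (`control_min_indel_size` = 25 bp, any single read
suffices for subtraction): the main failure mode of subtraction designs
is a germline SV that narrowly misses thresholds in the control, so
stringency must be asymmetric.

**Clustering.** Single-linkage within `cluster_margin` (200 bp, matching
the margin used for control subtraction) on both breakpoints, same
chromosome and direction pair; clusters with < 3 distinct reads are
dropped early. Transitive chains can make a cluster's breakpoint range
wider than twice the margin; ranges truthfully cover all members.

**Consensus.** Per supporting read, the junction-spanning portion
(±`junction_flank` = 300 bp around the junction's query interval, ≥50 bp
context required per side) is extracted and oriented bp1-side-first. The
centroid segment (minimal summed edit distance) seeds two rounds of
align-and-vote polishing: every segment is globally aligned to the
template (edit-distance alignments; end gap runs trimmed so truncated
reads do not vote deletions at template ends) and each template column
takes the majority base, including deletion; insertion votes are keyed to
the column they precede. **Ties go to insertion**: alignment ambiguity
splits insertion votes across neighbouring columns, so a strict majority
systematically shortens consensi (measured ≈ −0.3 % length bias at 10 %
read error; the tie rule removes most of it). Up to
`max_consensus_inputs` = 16 segments are used, preferring reads with the
most junction context; at 10 % read error the resulting consensus
identity is ≈ 99.8 %.

**Jump alignment.** The polished query is aligned against the two
candidate reference windows (breakpoint ranges padded by `refine_window`
= 200 bp, orientation per breakpoint direction) by an affine-gap local DP
in two layers: layer 1 is standard Smith–Waterman against window 1; a
layer-2 cell may additionally start from the best layer-1 score at any
earlier query position, paying `jump_penalty` (default 0) plus
`per_inserted_base` (default 0) per skipped query base. The optimum
equals brute-force enumeration over all query split points of
end-anchored + start-anchored two-piece alignment (property-tested
against an independent Gotoh oracle). The skipped query bases are the
inserted sequence. Scoring defaults for the operation are
match 2 / mismatch −4 / gap open −4 / gap extend −2; the *pipeline*
refines with mismatch −6 (config `mismatch`), because its queries are
polished consensi: at 2/−4 the break-even identity for extending an
alignment is 2/3, low enough that near-matching insert bases get absorbed
onto the reference side of the junction and displace the breakpoint by a
few bases.

Three further placement rules, all motivated by measured failure modes on
simulated data: (i) co-optimal split ties take the **shortest** ref1
piece — co-optimal ends can only arise from net-zero gapped extensions,
since exact-match extension always gains score, and such extensions drag
the junction into the insert (micro-homology is then re-attributed
deterministically by the canonicalizer); (ii) each piece end is walked
back while its terminal 10 aligned bases carry ≥2 mismatches (ungapped
walk, reverted beyond 30 bp — a gapped neighbourhood would make it run
away); (iii) refinement fails unless both pieces align ≥ `min_span` =
50 bp with score ≥ 0.6 · match · (aligned length of both pieces). The
reported micro-homology length is the maximal exact backward identity
between query and the second window at the junction.

**Validation.** The putative SV segment is rebuilt from the reference
(300 bp orientation-correct flank on each side of the polished insert)
along with reference segments spanning each breakpoint (±360 bp, slightly
wider than the read windows so they never overhang). Every read
overlapping a breakpoint ±300 bp contributes a ±250 bp window around the
junction's position in the read; windows are compared to the three
segments in both orientations by free-end infix edit distance, normalized
by window length. A read is *variant* when its SV-segment dissimilarity
undercuts the best reference dissimilarity by `score_margin` = 0.05 and
its placement crosses a junction with ≥ `min_span` = 50 bp on each side;
the symmetric condition gives *reference*; everything else is *ambiguous*
and counted neither way (the ambiguous class avoids mis-counting reads
that barely overlap the junction). Final rule: keep iff ≥3 tumor variant
reads and 0 control variant reads; VAF = variant/(variant+reference) in
tumor; then DEL with deleted span <100 bp or INS with insert <100 bp are
dropped, as are DEL/INS with both breakpoints inside one simple-repeat
interval padded by 10 bp. Candidates with no overlapping control reads
are kept but flagged `control_uncovered`.

## Single breakend module

Soft clips ≥ `min_clip` = 500 bp (control: 250 bp) whose bases are *not*
aligned by another segment of the same read (those are split alignments,
i.e. canonical evidence) become signals at the clip's oriented reference
position; left clips are reverse-complemented so every clip sequence
reads junction-outward. Clustering margin 50 bp; control subtraction on
(chrom, dir, pos) within 200 bp. Contigs are built from the clips
prefixed by 100 bp of aligned sequence inside the breakpoint, polished by
the same consensus machinery, and capped at `max_contig` = 5000 bp. The
inner margin re-aligned to the reference window fixes the breakpoint at
single-base resolution; the validation logic above is reused with the
same ≥3/0 rule, the putative segment being flank + contig.

Classification order (first match wins): duplicate of an already-called
canonical breakpoint (±200 bp) → dropped; whole contig places uniquely on
the reference (≥80 % span, ≥85 % identity, runner-up placement worse by
≥10 % of the contig length) → `RescuedCanonical`, re-emitted through full
validation; ≥60 % coverage by satellite / simple-repeat annotation, or
≥60 % telomere-motif content → `Satellite` / `SimpleRepeat` / `Telomere`;
a LINE1 (resp. Alu) match ≥200 bp in the contig prefix whose remainder
places uniquely ≥10 kb away or on another chromosome → `L1Mediated` /
`AluMediated`; any ≥200 bp viral-library match → `VirusMediated`; else
`Unclassified`. The annotation provider is either the built-in
local-alignment annotator over a consensus library or a parsed
RepeatMasker `.out` table. All cutoffs are config-exposed
operationalizations of a qualitative decision chart.

## Insertion annotation

Inserts ≥100 bp are classified in fixed order: transcript match covering
≥80 % and spanning ≥2 exon junctions (so retained-intron fragments do not
qualify) → processed pseudogene; a single mobile-element family covering
≥80 % → solo LINE1/Alu/SVA; otherwise the longest repeat-free residue is
re-aligned to the genome — a unique hit adjacent to the insertion site
(within 100 bp plus the residue length) → tandem duplication; a hit
within `source_window` = 10 kb downstream (strand-aware) of a catalogued
LINE1 source element → partnered transduction if the insert also carries
≥200 bp of LINE1 sequence, else orphan transduction; else `Other`.
Sources whose provenance is a previous somatic LINE1 call mark their
events as nested transductions.

Structure fields: a 5′ inversion (twin priming) is called when the insert
decomposes into an antisense segment followed by a sense segment of the
same consensus with compatible element coordinates (antisense from at or
upstream of the sense start); a purely antisense insert is not twin
priming. PolyA tails are the longest terminal run (A at 3′, T at 5′) with
purity ≥0.8 within a 30 bp window, ≥10 bp, starting and ending on the
tail base — runs may absorb isolated other bases, and the terminal-anchor
definition is what the brute-force property oracle mirrors. TSDs come
directly from the overlap of refined insertion breakpoints (5–50 bp).

## HOR match score

Satellite contigs are partitioned by a DP over contig positions: each end
position either extends a gap (contributing nothing) or closes the
best end-anchored alignment of one monomer consensus (both orientations,
length slack ±35 bp); blocks below 50 % identity stay gaps; the tiling
maximizes summed identity-weighted length. Scoring against a chromosome's
HOR: the first block is always consistent; a later block is consistent
when the previous block's monomer lists it as successor (orientation
aware) and no gap >5 bp separates them. Consistent blocks add
`(end − start) · identity / 100`; the sum over the contig length is the
score — exactly 1.0 for a perfect canonical array, and computed per
chromosome with that chromosome's own monomer set, as with per-chromosome
monomer FASTAs. The first monomer's term is counted. The per-chromosome
profile flags an event interchromosomal when the best-scoring centromere
is not the breakend's own chromosome.

## Synthetic data

The generator emits alignments directly from known read origins instead
of running an aligner: donor haplotypes are piece lists over the
reference (so truth breakpoints are exact), reads are sampled with
log-normal lengths (default mean 8 kb), and each read's CIGAR is
constructed jointly with its sequence — D/I operations for contained
indels, soft clips plus SA tags for split reads, soft clips for junctions
into unalignable (foreign) sequence, and the TSD of an insertion folded
into the I operation the way an aligner would. Errors are injected
consistently into sequence and CIGAR at the stated rate, split
40:30:30 substitution:insertion:deletion. Realism knobs default to
±3 bp of clip jitter at junctions and a 2 % per-segment mapping dropout.
Reciprocal translocations exchange chromosome tails, so each event
contributes two truth junctions, as do inversions.

Defaults mirror the validation conditions used throughout: 30× depth per
sample, 10 % read error, heterozygous somatic SVs (tumor haplotype 1) and
heterozygous germline SVs shared with the control (haplotype 2). The
end-to-end benchmark (`benchmark.run_somatic_benchmark`) uses a 2 × 1 Mb
genome with 40 somatic SVs (10 each DEL/INS/INV/TRA, 150–5000 bp) and 8
germline SVs; across seeds it measures recall ≥ 0.97, precision 1.0,
95–100 % of breakpoints within ±2 bp, and zero calls when the tumor is
used as its own control. Problem sizes were chosen so the whole suite
runs in minutes on one CPU.

**What passing these tests does not show:** the synthetic genomes are
uniform-random sequence (plus explicitly embedded repeat arrays), so the
mapping ambiguity, segmental duplication structure and coverage biases of
real genomes are absent; error profiles are position-independent, without
homopolymer bias; the read emitter is not an aligner, so aligner-specific
artifacts (multi-mapping, clipped-anchor placement) are only
approximated by the jitter/dropout knobs. Accuracy numbers on synthetic
data are therefore upper bounds on real-data behaviour.

The packaged repeat/virus consensus library and centromere monomer sets
are deterministic *synthetic stand-ins* with realistic lengths (LINE1-like
6 kb with polyA end, Alu-like 300 bp, SVA-like 1.3 kb, HBV-like 3.2 kb,
171 bp alpha-satellite monomers with a 12-mer HOR per chromosome); real
runs accept user-supplied FASTAs in RepeatMasker `NAME#family`
convention.

## Degenerate inputs and edge behaviour

Secondary alignments are dropped at ingest; supplementary kept (they
carry split-read evidence). Malformed CIGARs skip the record with a
counted warning; an unmapped-only file yields an empty stream with a
warning. Breakpoints within a flank of a chromosome end truncate the
flank and flag the record. Candidates with a single usable segment pass
through unpolished (`unpolished` flag); mixtures of discordant junctions
are flagged `high_discordance` (mean identity to the consensus < 0.8).
Empty monomer sets or contigs shorter than the shortest monomer decompose
to nothing and score 0.

## Known limitations

No phasing and no multi-sample joint calling beyond tumor + control +
panel; no CRAM; no assembly across the unalignable side of a breakend; no
base-quality-aware consensus; the monomer DP is a block-chaining
approximation of full repeat-decomposition automata (the contract is the
scored tiling); germline SVs are deliberately not genotyped — the control
exists only to establish somatic specificity.
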
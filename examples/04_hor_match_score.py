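"""Score a centromeric breakend contig against chromosome-specific
higher-order repeat (HOR) structures.

A contig built from chrX-like alpha-satellite monomers in canonical order
scores 1.0 against the chrX HOR and much lower against another
chromosome's; attached to a breakend on chr2, the profile flags the event
as interchromosomal.
"""

from longsv import Breakpoint, decompose_monomers, hor_match_score, hor_profile
from longsv.library import synthetic_monomers
from longsv.model import SingleBreakendRecord

monomers = synthetic_monomers()
chrx = [h for h in monomers.hors if h.chromosome == "chrX"][0]
contig = "".join(monomers.monomers[m] for m in chrx.monomer_order) * 2

matches = decompose_monomers(
    contig, {m: monomers.monomers[m] for m in chrx.monomer_order})
print(f"decomposition: {len(matches)} monomer blocks, e.g. "
      f"{matches[0].monomer_id} [{matches[0].start_pos}:{matches[0].end_pos}]"
      f" id={matches[0].identity:.1f}%")
print(f"chrX HOR match score: "
      f"{hor_match_score(matches, chrx, len(contig)):.3f}")

record = SingleBreakendRecord(bp=Breakpoint("chr2", 11_000, "+"),
                              contig=contig)
profile = hor_profile(record, monomers.monomers, monomers.hors)
for chrom, score in profile["scores"].items():
    print(f"  {chrom}: {score:.3f}")
print(f"best centromere: {profile['best_chrom']}, "
      f"interchromosomal: {profile['interchromosomal']}")
print("\nEach consistent monomer block adds (end-start)*identity/100; the "
      "sum over the contig length is the HOR match score, 1.0 for a "
      "perfect canonical array.")
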
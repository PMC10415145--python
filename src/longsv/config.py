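"""Caller configuration: every tunable threshold with its default.

Configs round-trip through a flat ``key=value`` text file so a whole run is
reproducible from one small artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, fields


@dataclass
class Config:
    # --- canonical detection -------------------------------------------------
    min_indel_size: int = 50          # internal CIGAR indel parse threshold (bp)
    control_min_indel_size: int = 25  # permissive threshold for control/panel parsing
    cluster_margin: int = 200         # single-linkage join distance (bp)
    min_tumor_read_pre: int = 3       # distinct reads required before refinement
    control_margin: int = 200         # control/panel subtraction margin (bp)

    # --- refinement ----------------------------------------------------------
    junction_flank: int = 300         # read bases taken each side of the junction
    min_flank: int = 50               # minimum read context to use a segment
    max_consensus_inputs: int = 16    # segments fed to the consensus builder
    refine_window: int = 200          # padding around breakpoint ranges (bp)
    match: int = 2
    mismatch: int = -6                # strict: queries are polished consensi
    gap_open: int = -4
    gap_extend: int = -2
    jump_penalty: float = 0.0
    per_inserted_base: float = 0.0
    min_jump_frac: float = 0.6        # min score as fraction of match*aligned bases

    # --- validation ----------------------------------------------------------
    validate_flank: int = 300
    score_margin: float = 0.05        # delta for variant-vs-reference calls
    min_span: int = 50                # aligned bases required either side of junction
    min_tumor_support: int = 3
    max_control_support: int = 0
    min_sv_size: int = 100            # final DEL/INS size filter (bp)
    simple_repeat_pad: int = 10

    # --- single breakend -----------------------------------------------------
    min_clip: int = 500
    control_min_clip: int = 250       # permissive clip threshold for control
    breakend_margin: int = 50
    breakend_inner_margin: int = 100
    max_contig: int = 5000
    rescue_cov: float = 0.80          # unique genome coverage for canonical rescue
    repeat_cov: float = 0.60          # satellite/simple-repeat/telomere coverage
    min_element_match: int = 200      # bp of L1/Alu/virus match required
    duplicate_margin: int = 200       # vs already-called canonical records
    distant_min: int = 10000          # bp separating "distant" partner loci

    # --- insertion annotation ------------------------------------------------
    insert_cov: float = 0.80          # mobile-element / transcript coverage rule
    min_exon_junctions: int = 2
    source_window: int = 10000        # transduction attribution window (bp)
    tandem_window: int = 100          # adjacency window for tandem duplications
    polya_window: int = 30
    polya_min_len: int = 10
    polya_min_frac: float = 0.8
    min_tsd: int = 5
    max_tsd: int = 50

    # --- HOR -----------------------------------------------------------------
    monomer_min_identity: float = 50.0  # percent; below → gap block
    monomer_len_slack: int = 35         # block length tolerance around monomer length

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")

    @classmethod
    def load(cls, path) -> "Config":
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("=")
                key = key.strip()
                if key not in types:
                    raise KeyError(f"unknown config key: {key}")
                t = types[key]
                if t in ("int", int):
                    kwargs[key] = int(val)
                elif t in ("float", float):
                    kwargs[key] = float(val)
                else:
                    kwargs[key] = val.strip()
        return cls(**kwargs)
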
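"""Self-contained benchmark experiments used for validation and
reproduction: simulate a tumor/control pair at study conditions, run the
caller, and score against the exact truth."""

from __future__ import annotations

import tempfile
from pathlib import Path
from typing import Optional

from . import pipeline, simulate
from .config import Config


def run_somatic_benchmark(seed: int,
                          genome_length: int = 1_000_000,
                          n_chroms: int = 2,
                          somatic_spec: Optional[dict] = None,
                          germline_spec: Optional[dict] = None,
                          depth: float = 30.0,
                          error_rate: float = 0.10,
                          mean_len: float = 8000.0,
                          size_range: tuple[int, int] = (150, 5000),
                          config: Optional[Config] = None,
                          workdir=None,
                          with_self_control: bool = True) -> dict:
    """End-to-end somatic recovery experiment.

    Simulates a diploid tumor/control pair (40 somatic SVs by default: 10
    each of deletion, insertion, inversion, translocation; heterozygous
    germline SVs shared with the control), runs the canonical module, and
    returns recall, precision, breakpoint accuracy and the number of calls
    from a tumor-vs-itself run (specificity control).
    """
    cfg = config or Config()
    somatic = somatic_spec or {"DEL": 10, "INS": 10, "INV": 10, "TRA": 10}
    germline = germline_spec or {"DEL": 4, "INS": 4}
    if workdir is None:
        workdir = tempfile.mkdtemp(prefix="longsv_bench_")
    workdir = Path(workdir)

    genome, _ = simulate.make_genome(genome_length, n_chroms, seed=seed)
    truth = simulate.simulate_pair(
        genome, somatic, germline, depth=depth, error_rate=error_rate,
        mean_len=mean_len, seed=seed,
        tumor_sam=workdir / "tumor.sam",
        control_sam=workdir / "control.sam",
        size_range=size_range)
    tumor = pipeline.Sample.load(workdir / "tumor.sam", "tumor")
    control = pipeline.Sample.load(workdir / "control.sam", "control")
    records, audit = pipeline.call_canonical(tumor, control, genome, cfg)
    ev = simulate.evaluate_calls(truth.somatic, records, reference=genome)
    out = {
        "n_truth": ev["n_truth"],
        "n_calls": ev["n_calls"],
        "recall": ev["recall"],
        "precision": ev["precision"],
        "breakpoint_within_2bp": ev["breakpoint_within_2bp"],
        "records": records,
        "truth": truth,
        "genome": genome,
        "audit": audit,
    }
    if with_self_control:
        self_records, _ = pipeline.call_canonical(tumor, tumor, genome, cfg)
        out["self_control_calls"] = len(self_records)
    return out
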
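import numpy as np
import pytest

from longsv import Config, simulate
from longsv.library import (synthetic_library, synthetic_monomers,
                            synthetic_transcripts)


@pytest.fixture(scope="session")
def repeat_library():
    return synthetic_library()


@pytest.fixture(scope="session")
def monomer_set():
    return synthetic_monomers()


@pytest.fixture(scope="session")
def transcripts():
    return synthetic_transcripts()


@pytest.fixture(scope="session")
def toy_genome():
    genome, _ = simulate.make_genome(length=60_000, n_chroms=2, seed=42)
    return genome


@pytest.fixture()
def config():
    return Config()


def noisy_copy(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    """Independent per-base substitution/insertion/deletion noise (40:30:30)."""
    out = []
    for ch in seq:
        r = rng.random()
        if r < error_rate * 0.4:
            out.append("ACGT"[rng.integers(4)])
        elif r < error_rate * 0.7:
            out.append(ch + "ACGT"[rng.integers(4)])
        elif r < error_rate:
            continue
        else:
            out.append(ch)
    return "".join(out)


@pytest.fixture(scope="session")
def sim_pair(tmp_path_factory):
    """A small tumor/control pair with known somatic and germline SVs."""
    d = tmp_path_factory.mktemp("sim")
    genome, _ = simulate.make_genome(120_000, 2, seed=5)
    truth = simulate.simulate_pair(
        genome, {"DEL": 3, "INS": 3, "INV": 1, "TRA": 1, "DUP": 1},
        {"DEL": 2},
        depth=30, error_rate=0.10, mean_len=6000, seed=5,
        tumor_sam=d / "tumor.sam", control_sam=d / "control.sam",
        size_range=(150, 2000))
    return {"genome": genome, "truth": truth,
            "tumor": d / "tumor.sam", "control": d / "control.sam"}
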
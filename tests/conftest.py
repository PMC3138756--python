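"""Shared fixtures: a small simulated study and the full noiseless study.

Also hosts the quadratic local-alignment oracle used to cross-check the
seed-based presence caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from isrna.config import SimConfig
from isrna.pipeline import PipelineConfig, run_all
from isrna.simulate import simulate_study, write_fixture


def tiny_config(**overrides) -> SimConfig:
    """A fast, small study used by unit tests."""
    base = dict(
        seed=11,
        genome_length=600_000,
        n_chromosomes=3,
        n_genes=60,
        n_known_ncrna={"rRNA": 3, "tRNA": 3, "snoRNA": 10, "snRNA": 5, "misc": 5},
        n_novel=12,
        novel_context_mix={"intergenic": 4 / 12, "sense_intronic": 6 / 12,
                           "antisense_intronic": 2 / 12},
        n_sno_cd=1, n_sno_haca=1, n_sno_scarna=1,
        track_noise_sd=0.0, noise_sd_log2=0.0, dye_offset_sd=0.0,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def tiny_study():
    return simulate_study(tiny_config())


@pytest.fixture(scope="session")
def study_run(tmp_path_factory):
    """The full noiseless study (300 is-ncRNA loci) run end-to-end once."""
    cfg = SimConfig(seed=1, track_noise_sd=0.0, noise_sd_log2=0.0,
                    dye_offset_sd=0.0)
    study = simulate_study(cfg)
    fixture_dir = tmp_path_factory.mktemp("study_fixture")
    write_fixture(study, fixture_dir)
    outdir = fixture_dir / "out"
    report = run_all(PipelineConfig.from_fixture(fixture_dir, outdir))
    return study, fixture_dir, outdir, report


# ---------------------------------------------------------------------------
# Quadratic Smith-Waterman oracle (match +1, mismatch -1, gap -2, linear)
# ---------------------------------------------------------------------------

@dataclass
class OracleAlignment:
    score: float
    identity: float
    coverage: float


def sw_local_oracle(query: str, target: str) -> OracleAlignment:
    """Full dynamic-programming local alignment with traceback.

    Independent of the package's aligner: plain O(n*m) DP over the scoring
    scheme match +1 / mismatch -1 / gap -2 (linear).
    """
    n, m = len(target), len(query)
    H = np.zeros((n + 1, m + 1))
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 stop, 1 diag, 2 up, 3 left
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = H[i - 1, j - 1] + (1 if target[i - 1] == query[j - 1] else -1)
            up = H[i - 1, j] - 2
            left = H[i, j - 1] - 2
            h = max(0.0, diag, up, left)
            H[i, j] = h
            if h == 0:
                ptr[i, j] = 0
            elif h == diag:
                ptr[i, j] = 1
            elif h == up:
                ptr[i, j] = 2
            else:
                ptr[i, j] = 3
            if h > best:
                best, bi, bj = h, i, j
    if best <= 0:
        return OracleAlignment(0.0, 0.0, 0.0)
    i, j = bi, bj
    identities = columns = 0
    j_end = j
    while ptr[i, j] != 0:
        if ptr[i, j] == 1:
            identities += int(target[i - 1] == query[j - 1])
            i, j = i - 1, j - 1
        elif ptr[i, j] == 2:
            i -= 1
        else:
            j -= 1
        columns += 1
    j_start = j
    return OracleAlignment(best, identities / columns, (j_end - j_start) / m)
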
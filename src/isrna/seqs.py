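"""Small nucleotide-sequence utilities shared across the pipeline."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

VALID_ALPHABET = frozenset("ACGTUN")


def revcomp(seq: str) -> str:
    """Reverse complement (U treated as A's partner, N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_rna(seq: str) -> str:
    """Uppercase and convert U to T so mapping works in DNA space."""
    return seq.upper().replace("U", "T")


def random_seq(rng: np.random.Generator, n: int) -> str:
    """Uniform random DNA string of length ``n``."""
    return bytes(_BASES[rng.integers(0, 4, size=n)]).decode("ascii")


def diverge(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Copy ``seq`` substituting each base with probability ``rate``.

    Substitutions always change the base (no silent substitutions), which
    makes the realized divergence equal to the hit rate.
    """
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    idx = np.nonzero(hit)[0]
    for i in idx:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))
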
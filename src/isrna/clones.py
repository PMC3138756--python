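"""Clone-read processing: adapter trimming, size selection, deduplication.

Raw library reads are adapter-flanked cDNA inserts.  The processing chain is
``trim_adapters`` -> ``size_filter`` -> ``deduplicate``, producing unique
insert sequences with clone counts — the unit of everything downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .seqs import VALID_ALPHABET, normalize_rna


@dataclass(frozen=True)
class CloneRead:
    """One sequenced library clone.

    ``sequence`` is validated against the A/C/G/T/U/N alphabet and stored
    with U normalized to T so all later stages operate in DNA space.
    """

    read_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r} has an empty sequence")
        seq = normalize_rna(self.sequence)
        bad = set(seq) - VALID_ALPHABET
        if bad:
            raise ValueError(
                f"read {self.read_id!r} contains invalid characters: {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)


@dataclass
class UniqueTranscript:
    """A deduplicated insert with its clone count and member reads."""

    transcript_id: str
    sequence: str
    member_read_ids: List[str]

    @property
    def clone_count(self) -> int:
        return len(self.member_read_ids)


@dataclass
class TrimResult:
    read_id: str
    insert: Optional[str]
    reason: Optional[str] = None

    @property
    def accepted(self) -> bool:
        return self.insert is not None


def _best_match(seq: str, adapter: str, max_mismatch: int) -> Optional[int]:
    """Start of the adapter occurrence with fewest mismatches (earliest tie)."""
    m = len(adapter)
    best = None
    best_mm = max_mismatch + 1
    for i in range(len(seq) - m + 1):
        mm = 0
        window = seq[i:i + m]
        for a, b in zip(window, adapter):
            if a != b:
                mm += 1
                if mm >= best_mm:
                    break
        if mm < best_mm:
            best, best_mm = i, mm
            if mm == 0:
                break
    return best


def trim_adapters(
    read: CloneRead, adapter_5: str, adapter_3: str, max_mismatch: int = 1
) -> TrimResult:
    """Excise the insert between the 5' and 3' adapters.

    The 5' adapter is located by its best (fewest-mismatch, earliest)
    occurrence, the 3' adapter by its best occurrence downstream of it.
    Reads lacking either adapter, or whose insert is empty, are rejected
    with a reason code.
    """
    if not adapter_5 or not adapter_3:
        raise ValueError("adapters must be non-empty")
    a5 = normalize_rna(adapter_5)
    a3 = normalize_rna(adapter_3)
    seq = read.sequence
    p5 = _best_match(seq, a5, max_mismatch)
    if p5 is None:
        return TrimResult(read.read_id, None, "no_5prime_adapter")
    insert_start = p5 + len(a5)
    downstream = seq[insert_start:]
    p3 = _best_match(downstream, a3, max_mismatch)
    if p3 is None:
        return TrimResult(read.read_id, None, "no_3prime_adapter")
    insert = downstream[:p3]
    if not insert:
        return TrimResult(read.read_id, None, "empty_insert")
    return TrimResult(read.read_id, insert)


def size_filter(insert: str, min_len: int = 50, max_len: int = 500) -> bool:
    """Keep inserts with ``min_len <= length <= max_len`` (both inclusive)."""
    if min_len <= 0 or max_len <= 0 or min_len > max_len:
        raise ValueError("size bounds must be positive with min <= max")
    return min_len <= len(insert) <= max_len


def deduplicate(inserts: Sequence[Tuple[str, str]]) -> List[UniqueTranscript]:
    """Group exact-identical insert sequences into unique transcripts.

    Transcript ids are assigned in first-occurrence order so the result is a
    pure function of the input ordering; the (sequence, count) multiset is
    invariant under input permutation.
    """
    groups: Dict[str, List[str]] = {}
    for read_id, seq in inserts:
        groups.setdefault(seq, []).append(read_id)
    return [
        UniqueTranscript(transcript_id=f"t{i:04d}", sequence=seq, member_read_ids=ids)
        for i, (seq, ids) in enumerate(groups.items(), start=1)
    ]


@dataclass
class CloneProcessingResult:
    """Outcome of the full read-processing chain with per-stage counts."""

    uniques: List[UniqueTranscript]
    rejections: pd.DataFrame  # columns: read_id, reason
    n_input: int = 0
    n_trimmed: int = 0
    n_size_kept: int = 0

    @property
    def n_unique(self) -> int:
        return len(self.uniques)


def process_reads(
    reads: Iterable[Tuple[str, str]],
    adapter_5: str,
    adapter_3: str,
    min_len: int = 50,
    max_len: int = 500,
    max_mismatch: int = 1,
) -> CloneProcessingResult:
    """Run trim -> size-filter -> deduplicate over raw reads."""
    kept: List[Tuple[str, str]] = []
    rejected: List[Tuple[str, str]] = []
    n_input = n_trimmed = 0
    for read_id, seq in reads:
        n_input += 1
        res = trim_adapters(CloneRead(read_id, seq), adapter_5, adapter_3, max_mismatch)
        if not res.accepted:
            rejected.append((read_id, res.reason))
            continue
        n_trimmed += 1
        if not size_filter(res.insert, min_len, max_len):
            rejected.append((read_id, "size_out_of_range"))
            continue
        kept.append((read_id, res.insert))
    uniques = deduplicate(kept)
    rej = pd.DataFrame(rejected, columns=["read_id", "reason"])
    return CloneProcessingResult(
        uniques=uniques, rejections=rej,
        n_input=n_input, n_trimmed=n_trimmed, n_size_kept=len(kept),
    )


def uniques_to_fasta_records(uniques: Iterable[UniqueTranscript]):
    """FASTA records with ``transcript_id|count=N`` headers."""
    for u in uniques:
        yield f"{u.transcript_id}|count={u.clone_count}", u.sequence
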
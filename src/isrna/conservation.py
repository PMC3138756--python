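"""Per-species conservation scoring, grouping, and primate presence calls.

Each locus gets the arithmetic mean of a per-base conservation score track
(a PhastCons-style probability in [0, 1]) per species; bases without track
coverage score 0, since absence from an alignment is itself evidence of
non-conservation.  The mean-score vector is then reduced to a conservation
group by clade-level rules:

* ``beyond_eutherian`` — conserved in at least one non-mammal species;
* ``eutherian`` — conserved in at least one rodent and one other eutherian;
* ``non_rodent_mammal`` — conserved in some non-rodent eutherian but in no
  rodent;
* ``primate_only`` — conserved only within the (non-human) primates;
* ``other`` — anything else (e.g. a rodent-only pattern).

"Conserved" means mean score >= ``tau_present`` (default 0.5, bisecting the
conventional strong/weak anchors of 0.8 and 0.6).  Human is excluded from
the calls: self-conservation is uninformative.

Presence/absence of a locus in another genome is decided by best local
alignment (Smith-Waterman via Biopython's PairwiseAligner) against identity
and query-coverage thresholds.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import Align

from .loci import GenomicLocus

GROUP_ORDER = ("other", "primate_only", "non_rodent_mammal", "eutherian",
               "beyond_eutherian")


class ScoreTrack:
    """Sparse per-base score track over one genome (bedGraph semantics).

    Intervals are half-open, non-overlapping within a chromosome; positions
    not covered by any interval score 0.
    """

    def __init__(self, intervals: Sequence[Tuple[str, int, int, float]]):
        self._by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        per_chrom: Dict[str, List[Tuple[int, int, float]]] = {}
        for chrom, start, end, score in intervals:
            per_chrom.setdefault(chrom, []).append((start, end, score))
        for chrom, ivs in per_chrom.items():
            ivs.sort()
            starts = np.array([s for s, _, _ in ivs], dtype=np.int64)
            ends = np.array([e for _, e, _ in ivs], dtype=np.int64)
            scores = np.array([x for _, _, x in ivs], dtype=float)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping track intervals on {chrom}")
            self._by_chrom[chrom] = (starts, ends, scores)

    @classmethod
    def from_bedgraph(cls, path) -> "ScoreTrack":
        from .io import read_bedgraph
        return cls(read_bedgraph(path))

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Mean score over [start, end); uncovered bases contribute 0."""
        if end <= start:
            raise ValueError("zero-length interval")
        if chrom not in self._by_chrom:
            return 0.0
        starts, ends, scores = self._by_chrom[chrom]
        lo = bisect.bisect_right(ends.tolist(), start)
        total = 0.0
        for i in range(lo, len(starts)):
            if starts[i] >= end:
                break
            ov = min(end, ends[i]) - max(start, starts[i])
            if ov > 0:
                total += ov * scores[i]
        return total / (end - start)


def mean_score(locus: GenomicLocus, track: ScoreTrack) -> float:
    """Mean per-base conservation score of ``locus`` under ``track``."""
    return track.mean(locus.chrom, locus.start, locus.end)


@dataclass
class ConservationProfile:
    transcript_id: str
    species: Tuple[str, ...]
    means: np.ndarray  # aligned with species
    group: str = ""

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        if self.means.shape != (len(self.species),):
            raise ValueError("one mean score per species required")
        if np.any(self.means < -1e-9) or np.any(self.means > 1 + 1e-9):
            raise ValueError("mean scores must lie in [0, 1]")


def assign_group(
    means: Mapping[str, float],
    clades: Mapping[str, str],
    tau_present: float = 0.5,
    human: str = "human",
) -> str:
    """Reduce a per-species mean-score map to a conservation group label."""
    conserved_clades = set()
    for sp, score in means.items():
        if sp == human:
            continue
        if sp not in clades:
            raise ValueError(f"unknown species {sp!r} (no clade label)")
        if score >= tau_present:
            conserved_clades.add(clades[sp])
    if "non_mammal" in conserved_clades:
        return "beyond_eutherian"
    if "rodent" in conserved_clades and "other_eutherian" in conserved_clades:
        return "eutherian"
    if "rodent" not in conserved_clades and "other_eutherian" in conserved_clades:
        return "non_rodent_mammal"
    if "primate" in conserved_clades:
        return "primate_only"
    return "other"


def build_profiles(
    loci: Mapping[str, GenomicLocus],
    tracks: Mapping[str, ScoreTrack],
    species_list: Sequence[str],
    clades: Mapping[str, str],
    tau_present: float = 0.5,
) -> List[ConservationProfile]:
    """Score every locus against every species track and assign groups."""
    missing = [sp for sp in species_list if sp not in tracks]
    if missing:
        raise ValueError(f"missing tracks for species: {missing}")
    profiles = []
    for tid in sorted(loci):
        locus = loci[tid]
        means = np.array(
            [mean_score(locus, tracks[sp]) for sp in species_list], dtype=float
        )
        group = assign_group(dict(zip(species_list, means)), clades, tau_present)
        profiles.append(ConservationProfile(tid, tuple(species_list), means, group))
    return profiles


def profiles_to_frame(profiles: Sequence[ConservationProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"transcript_id": p.transcript_id, "group": p.group}
        row.update(dict(zip(p.species, p.means)))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Presence/absence by local alignment
# ---------------------------------------------------------------------------

@dataclass
class PresenceCall:
    present: bool
    identity: float
    coverage: float
    score: float


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2  # linear gap cost
    return aligner


def presence_call(
    query: str,
    target: str,
    min_identity: float = 0.8,
    min_coverage: float = 0.5,
) -> PresenceCall:
    """Call a query present in a target sequence by best local alignment.

    identity = identities / aligned columns (gaps count against identity);
    coverage = query span of the alignment / query length.  Both thresholds
    must be met.
    """
    if len(query) < 20:
        raise ValueError("query must be at least 20 nt")
    if not target:
        raise ValueError("empty target sequence")
    aligner = _aligner()
    score = aligner.score(target, query)
    if score <= 0:
        return PresenceCall(False, 0.0, 0.0, float(score))
    aln = next(iter(aligner.align(target, query)))
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / columns if columns else 0.0
    qblocks = aln.aligned[1]
    coverage = (qblocks[-1][1] - qblocks[0][0]) / len(query) if len(qblocks) else 0.0
    present = bool(identity >= min_identity and coverage >= min_coverage)
    return PresenceCall(present, float(identity), float(coverage), float(score))


def build_presence_matrix(
    queries: Mapping[str, str],
    targets: Mapping[str, Mapping[str, str]],
    min_identity: float = 0.8,
    min_coverage: float = 0.5,
    human: str = "human",
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Presence/absence matrix of query transcripts across target genomes.

    ``targets`` maps species -> {query_id: candidate region sequence}.  The
    human column is all-True by construction (a transcript is present in the
    genome it was cloned from).  Returns (boolean matrix, per-call stats).
    """
    species = [human] + [sp for sp in targets if sp != human]
    calls = {}
    stats_rows = []
    for tid in sorted(queries):
        row = {human: True}
        for sp in targets:
            region = targets[sp].get(tid)
            if region is None:
                row[sp] = False
                continue
            call = presence_call(queries[tid], region, min_identity, min_coverage)
            row[sp] = call.present
            stats_rows.append({
                "transcript_id": tid, "species": sp, "present": call.present,
                "identity": call.identity, "coverage": call.coverage,
            })
        calls[tid] = row
    matrix = pd.DataFrame.from_dict(calls, orient="index").reindex(columns=species)
    matrix.index.name = "transcript_id"
    return matrix, pd.DataFrame(stats_rows)


def load_clades_tsv(path) -> Dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["species"], df["clade"]))


def load_tracks_dir(directory, species_list: Sequence[str]) -> Dict[str, ScoreTrack]:
    directory = Path(directory)
    return {
        sp: ScoreTrack.from_bedgraph(directory / f"{sp}.bedGraph")
        for sp in species_list
    }
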
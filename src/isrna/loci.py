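"""Genomic mapping and annotation-cascade classification of unique transcripts.

Mapping is exact-seed / mismatch-extension: disjoint k-mer seeds from the
query are looked up in a hash index of the genome and each candidate
placement is verified by full-length Hamming comparison.  With at least
``max_mismatch + 1`` disjoint seeds per query the search is exhaustive
(pigeonhole), so it agrees with a naive both-strand sliding-window scan.
Indels are not modeled: library clones are genome-derived.

Classification applies a fixed precedence cascade (rRNA -> tRNA -> known
ncRNA -> mRNA exon -> novel) and assigns novel loci a genomic context:
intergenic, sense-intronic or antisense-intronic relative to protein-coding
gene models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .io import BedRecord, GeneModel
from .seqs import revcomp

#: classes resolved before the known-ncRNA rule
_REMOVAL_CLASSES = ("rRNA", "tRNA")


@dataclass(frozen=True, order=True)
class GenomicLocus:
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Mapping
# ---------------------------------------------------------------------------

class GenomeIndex:
    """Hash index of all k-mers of a genome, plus the raw sequences."""

    def __init__(self, genome: Dict[str, str], k: int = 16):
        if k < 1:
            raise ValueError("k must be positive")
        self.k = k
        self.genome = {c: s.upper() for c, s in genome.items()}
        self.chrom_lengths = {c: len(s) for c, s in self.genome.items()}
        self._index: Dict[str, List[Tuple[str, int]]] = {}
        for chrom, seq in self.genome.items():
            for i in range(len(seq) - k + 1):
                self._index.setdefault(seq[i:i + k], []).append((chrom, i))

    def seed_hits(self, kmer: str) -> List[Tuple[str, int]]:
        return self._index.get(kmer, [])


def _mismatches_at(genome_seq: str, pos: int, query: str, limit: int) -> Optional[int]:
    """Hamming distance of ``query`` vs genome at ``pos``, or None if > limit."""
    if pos < 0 or pos + len(query) > len(genome_seq):
        return None
    mm = 0
    for a, b in zip(genome_seq[pos:pos + len(query)], query):
        if a != b:
            mm += 1
            if mm > limit:
                return None
    return mm


def _naive_scan_strand(genome_seq: str, query: str, max_mismatch: int) -> List[int]:
    """Vectorized sliding-window scan; exact but O(n*m)."""
    n, m = len(genome_seq), len(query)
    if m > n:
        return []
    g = np.frombuffer(genome_seq.encode("ascii"), dtype=np.uint8)
    q = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
    mism = np.zeros(n - m + 1, dtype=np.int32)
    for j in range(m):
        mism += g[j:n - m + 1 + j] != q[j]
    return np.nonzero(mism <= max_mismatch)[0].tolist()


def map_to_genome(
    query: str, index: GenomeIndex, max_mismatch: int = 2
) -> List[GenomicLocus]:
    """All genomic placements of ``query`` within ``max_mismatch`` substitutions.

    Reverse-complement matches are reported on strand '-'.  Queries too short
    to carry ``max_mismatch + 1`` disjoint seeds fall back to the exhaustive
    scan so the result is exact for every query length.  Loci are sorted by
    (chrom, start, strand); an unmapped query yields an empty list.
    """
    query = query.upper()
    m = len(query)
    loci = set()
    use_seeds = m >= (max_mismatch + 1) * index.k
    for strand, q in (("+", query), ("-", revcomp(query))):
        if use_seeds:
            candidates = set()
            n_seeds = max_mismatch + 1
            # disjoint seeds spread across the query (pigeonhole guarantee)
            offsets = sorted({
                round(i * (m - index.k) / max(n_seeds - 1, 1)) for i in range(n_seeds)
            })
            for off in offsets:
                for chrom, pos in index.seed_hits(q[off:off + index.k]):
                    candidates.add((chrom, pos - off))
            for chrom, start in candidates:
                mm = _mismatches_at(index.genome[chrom], start, q, max_mismatch)
                if mm is not None:
                    loci.add(GenomicLocus(chrom, start, start + m, strand))
        else:
            for chrom, seq in index.genome.items():
                for start in _naive_scan_strand(seq, q, max_mismatch):
                    loci.add(GenomicLocus(chrom, start, start + m, strand))
    return sorted(loci, key=lambda l: (l.chrom, l.start, l.strand))


def naive_map_oracle(
    query: str, genome: Dict[str, str], max_mismatch: int = 2
) -> List[GenomicLocus]:
    """Reference both-strand sliding-window mapper (no index, no seeds)."""
    query = query.upper()
    loci = set()
    for strand, q in (("+", query), ("-", revcomp(query))):
        for chrom, seq in genome.items():
            for start in _naive_scan_strand(seq.upper(), q, max_mismatch):
                loci.add(GenomicLocus(chrom, start, start + len(q), strand))
    return sorted(loci, key=lambda l: (l.chrom, l.start, l.strand))


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@dataclass
class ClassifiedLocus:
    locus: GenomicLocus
    transcript_id: str
    category: str  # mRNA | rRNA | tRNA | known_ncRNA:<class> | novel
    context: Optional[str] = None  # set only when category == novel
    host_gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category != "novel" and self.context is not None:
            raise ValueError("context is only defined for novel loci")
        intronic = self.context in ("sense_intronic", "antisense_intronic")
        if intronic != (self.host_gene_id is not None):
            raise ValueError("host_gene_id present iff the context is intronic")


class AnnotationIndex:
    """Interval indices over gene models and known-ncRNA records."""

    def __init__(
        self,
        genes: Sequence[GeneModel],
        known_ncrna: Sequence[BedRecord],
        chrom_lengths: Dict[str, int],
    ):
        self.chrom_lengths = dict(chrom_lengths)
        self.genes = {g.gene_id: g for g in genes}
        chroms = set(chrom_lengths)
        self.exon_tree = {c: IntervalTree() for c in chroms}
        self.gene_tree = {c: IntervalTree() for c in chroms}
        self.intron_tree = {c: IntervalTree() for c in chroms}
        self.ncrna_tree = {c: IntervalTree() for c in chroms}
        for g in genes:
            self.gene_tree[g.chrom][g.start:g.end] = g
            for s, e in g.exons:
                self.exon_tree[g.chrom][s:e] = g
            for s, e in g.introns():
                self.intron_tree[g.chrom][s:e] = g
        for r in known_ncrna:
            # BED name field carries "<class>:<id>" or bare class
            cls = r.name.split(":", 1)[0]
            self.ncrna_tree[r.chrom][r.start:r.end] = (cls, r.name)

    def check_chrom(self, chrom: str) -> None:
        if chrom not in self.chrom_lengths:
            raise ValueError(f"chromosome {chrom!r} absent from annotation")


def overlap_required(
    locus: GenomicLocus,
    feature: Tuple[int, int],
    min_fraction: float = 0.5,
) -> bool:
    """True iff the overlap covers at least ``min_fraction`` of the locus."""
    s, e = feature
    ov = min(locus.end, e) - max(locus.start, s)
    return ov >= min_fraction * len(locus)


def classify_locus(
    locus: GenomicLocus,
    annotation: AnnotationIndex,
    transcript_id: str = "",
    min_overlap: float = 0.5,
) -> ClassifiedLocus:
    """Classify one mapped locus against the annotation cascade.

    Precedence: rRNA, tRNA, known ncRNA class, mRNA exon (any strand), then
    novel.  A novel locus contained in an intron is sense- or
    antisense-intronic depending on strand agreement with the host gene; one
    overlapping no gene span is intergenic; any other geometry is 'other'.
    """
    annotation.check_chrom(locus.chrom)
    iv = slice(locus.start, locus.end)

    nc_hits = [
        (h.data[0], h.data[1], (h.begin, h.end))
        for h in annotation.ncrna_tree[locus.chrom][iv]
        if overlap_required(locus, (h.begin, h.end), min_overlap)
    ]
    for removal in _REMOVAL_CLASSES:
        if any(cls == removal for cls, _, _ in nc_hits):
            return ClassifiedLocus(locus, transcript_id, removal)
    if nc_hits:
        cls = sorted(nc_hits)[0][0]
        return ClassifiedLocus(locus, transcript_id, f"known_ncRNA:{cls}")

    for h in annotation.exon_tree[locus.chrom][iv]:
        if overlap_required(locus, (h.begin, h.end), min_overlap):
            return ClassifiedLocus(locus, transcript_id, "mRNA")

    # novel: derive the genomic context
    containing = sorted(
        (
            h for h in annotation.intron_tree[locus.chrom][iv]
            if h.begin <= locus.start and locus.end <= h.end
        ),
        key=lambda h: h.data.gene_id,
    )
    if containing:
        host = containing[0].data
        context = "sense_intronic" if locus.strand == host.strand else "antisense_intronic"
        return ClassifiedLocus(locus, transcript_id, "novel", context, host.gene_id)
    if not annotation.gene_tree[locus.chrom][iv]:
        return ClassifiedLocus(locus, transcript_id, "novel", "intergenic")
    return ClassifiedLocus(locus, transcript_id, "novel", "other")


# ---------------------------------------------------------------------------
# Chromosome-distribution randomness check
# ---------------------------------------------------------------------------

@dataclass
class ChromDistTest:
    observed: Dict[str, int]
    expected: Dict[str, float]
    statistic: float
    df: int
    p_value: float


def chromosome_distribution_test(
    loci: Sequence[GenomicLocus], chrom_lengths: Dict[str, int]
) -> ChromDistTest:
    """Chi-square test of locus counts against length-proportional expectation."""
    if len(chrom_lengths) < 2:
        raise ValueError("need at least two chromosomes")
    if not loci:
        raise ValueError("need at least one locus")
    chroms = list(chrom_lengths)
    total_len = sum(chrom_lengths.values())
    n = len(loci)
    observed = {c: 0 for c in chroms}
    for loc in loci:
        if loc.chrom not in observed:
            raise ValueError(f"locus chromosome {loc.chrom!r} not in chrom_lengths")
        observed[loc.chrom] += 1
    expected = {c: n * chrom_lengths[c] / total_len for c in chroms}
    if any(e == 0 for e in expected.values()):
        raise ValueError(
            "expected count of 0 for some chromosome; pool short chromosomes "
            "before testing"
        )
    stat = sum((observed[c] - expected[c]) ** 2 / expected[c] for c in chroms)
    df = len(chroms) - 1
    p = float(stats.chi2.sf(stat, df))
    return ChromDistTest(observed, expected, float(stat), df, p)
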
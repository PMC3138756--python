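"""Host-gene set enrichment and a simplified snoRNA box-motif screen.

Enrichment is the exact upper-tail hypergeometric test: with N background
genes, K in the set, n query genes and k in the overlap, p = P(X >= k),
Benjamini-Hochberg adjusted across the tested sets.

The motif screen is a deliberately simple positional box detector — it looks
for the canonical C (RUGAUGA) / D (CUGA) boxes of 2'-O-methylation guides
and the H (ANANNA) / ACA boxes of pseudouridylation guides at their
characteristic positions.  It does not fold terminal stems or score target
duplexes, so it is a coarse candidate filter, not a replacement for
structure-aware snoRNA gene finders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from scipy import stats
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# Hypergeometric gene-set enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    set_name: str
    N: int  # background size
    K: int  # set size within background
    n: int  # query size
    k: int  # overlap
    p_value: float
    adjusted_p: float = float("nan")
    overlap_genes: Tuple[str, ...] = ()


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("require 0 <= K <= N and 0 <= n <= N")
    if k <= max(0, n + K - N):
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeometric_enrichment(
    query_genes: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
    background: Sequence[str],
) -> List[EnrichmentResult]:
    """Test every gene set for overrepresentation in the query.

    Query genes must be drawn from the background universe; set members
    outside the background are ignored.  Results are BH-adjusted over all
    tested sets and sorted by raw p.
    """
    bg: Set[str] = set(background)
    query = set(query_genes)
    missing = sorted(query - bg)
    if missing:
        raise ValueError(f"query genes absent from background: {missing[:10]}")
    N, n = len(bg), len(query)
    results = []
    for name in gene_sets:
        members = set(gene_sets[name]) & bg
        overlap = sorted(query & members)
        K, k = len(members), len(overlap)
        p = hypergeom_upper_tail(N, K, n, k)
        results.append(EnrichmentResult(name, N, K, n, k, p, overlap_genes=tuple(overlap)))
    if results:
        _, adj, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
        for r, a in zip(results, adj):
            r.adjusted_p = float(a)
    return sorted(results, key=lambda r: (r.p_value, r.set_name))


# ---------------------------------------------------------------------------
# snoRNA / scaRNA box-motif screen
# ---------------------------------------------------------------------------

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "AG", "N": "ACGU",
}


@dataclass
class SnoMotifCall:
    transcript_id: str
    call: str  # CD | HACA | scaRNA_like | none
    boxes: Dict[str, int] = field(default_factory=dict)  # box -> start position

    def __post_init__(self) -> None:
        need = {
            "CD": {"C", "D"},
            "HACA": {"H", "ACA"},
            "scaRNA_like": {"C", "D", "H", "ACA"},
            "none": set(),
        }[self.call]
        if not need <= set(self.boxes):
            raise ValueError(f"call {self.call} requires boxes {sorted(need)}")


def _match(seq: str, pattern: str, start: int, max_mismatch: int = 0) -> bool:
    window = seq[start:start + len(pattern)]
    if len(window) < len(pattern):
        return False
    mm = sum(base not in _IUPAC[p] for base, p in zip(window, pattern))
    return mm <= max_mismatch


def _find(seq: str, pattern: str, lo: int, hi: int, max_mismatch: int = 0) -> Optional[int]:
    """First start in [lo, hi) where pattern matches within the mismatch budget."""
    for start in range(max(lo, 0), min(hi, len(seq) - len(pattern) + 1)):
        if _match(seq, pattern, start, max_mismatch):
            return start
    return None


def sno_motif_screen(sequence: str, transcript_id: str = "") -> SnoMotifCall:
    """Screen one transcript for C/D and H/ACA box arrangements.

    Positional rules: C box RUGAUGA (<= 1 mismatch) within the 5' 20 nt;
    D box CUGA (exact) starting within the 3' 10 nt; H box ANANNA inside the
    single-stranded hinge (40-70% of the length); ACA exactly 3 nt from the
    3' end.  A transcript with both a C/D and an H/ACA pair is a scaRNA
    candidate.
    """
    seq = sequence.upper().replace("T", "U")
    L = len(seq)
    if L < 50:
        raise ValueError("sequence must be at least 50 nt")
    boxes: Dict[str, int] = {}
    c = _find(seq, "RUGAUGA", 0, 20 - 7 + 1, max_mismatch=1)
    if c is not None:
        boxes["C"] = c
    d = _find(seq, "CUGA", L - 10, L)
    if d is not None:
        boxes["D"] = d
    hinge_lo, hinge_hi = int(0.4 * L), int(0.7 * L)
    h = _find(seq, "ANANNA", hinge_lo, hinge_hi - 6 + 1)
    if h is not None:
        boxes["H"] = h
    if seq[L - 6:L - 3] == "ACA":
        boxes["ACA"] = L - 6
    has_cd = "C" in boxes and "D" in boxes
    has_haca = "H" in boxes and "ACA" in boxes
    if has_cd and has_haca:
        call = "scaRNA_like"
    elif has_cd:
        call = "CD"
    elif has_haca:
        call = "HACA"
    else:
        call = "none"
    return SnoMotifCall(transcript_id, call, boxes)
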
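"""Seeded synthetic-study generator with ground-truth annotation.

The generator builds every input the analysis pipeline consumes — a random
genome with protein-coding gene models, known-ncRNA loci, novel is-ncRNA
loci placed by genomic context, an adapter-flanked clone library with a
skewed clone-count law, per-species conservation score tracks realizing
group archetypes, primate ortholog regions, loop-design two-channel array
intensities with planted expression effects, and host-gene pathway sets —
together with a :class:`GroundTruth` sidecar that records the planted answer
for every locus and read.  One integer seed determines all outputs.

Archetype score targets (per-species mean): conserved-in-primates 0.9,
weakly conserved elsewhere 0.55-0.6, not conserved 0.05, human 0.98
(self-scores carry no sampling noise).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .config import SimConfig, DEFAULT_PRIMATE_DIVERGENCE, largest_remainder
from .io import (BedRecord, GeneModel, write_bed6, write_bedgraph, write_fasta,
                 write_gff3, write_gmt, write_tsv)
from .seqs import diverge, random_seq, revcomp


class SimulationError(ValueError):
    """Raised when the requested features cannot be placed."""


#: target mean conservation score per (group, clade)
_GROUP_TARGETS: Dict[str, Dict[str, float]] = {
    "eutherian": {"primate": 0.9, "rodent": 0.55, "other_eutherian": 0.55,
                  "non_mammal": 0.05},
    "non_rodent_mammal": {"primate": 0.9, "rodent": 0.05,
                          "other_eutherian": 0.55, "non_mammal": 0.05},
    "primate_only": {"primate": 0.9, "rodent": 0.05,
                     "other_eutherian": 0.05, "non_mammal": 0.05},
    "beyond_eutherian": {"primate": 0.9, "rodent": 0.55,
                         "other_eutherian": 0.6, "non_mammal": 0.6},
    # a rodent-only pattern: falls outside the three broad groups
    "other": {"primate": 0.05, "rodent": 0.7, "other_eutherian": 0.05,
              "non_mammal": 0.05},
}

_HUMAN_SCORE = 0.98


def locus_coord_key(chrom: str, start: int, end: int, strand: str) -> str:
    """Canonical coordinate id used to join loci across file boundaries."""
    return f"{chrom}:{start}-{end}({strand})"


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class LocusTruth:
    locus_id: str
    chrom: str
    start: int
    end: int
    strand: str
    category: str  # novel | known_ncRNA:<class> | rRNA | tRNA | mRNA
    context: Optional[str] = None  # novel loci only
    host_gene: Optional[str] = None
    conservation_group: Optional[str] = None
    sno_class: str = "none"  # none | CD | HACA | scaRNA
    primate_presence: Optional[Dict[str, bool]] = None
    tissue_effects: Optional[List[float]] = None
    stage_effects: Optional[List[float]] = None
    sequence: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GroundTruth:
    loci: List[LocusTruth] = field(default_factory=list)
    reads: Dict[str, str] = field(default_factory=dict)  # read_id -> locus_id
    chrom_lengths: Dict[str, int] = field(default_factory=dict)

    def by_id(self) -> Dict[str, LocusTruth]:
        return {l.locus_id: l for l in self.loci}

    def novel(self) -> List[LocusTruth]:
        return [l for l in self.loci if l.category == "novel"]

    def array_targets(self) -> List[LocusTruth]:
        """Loci the microarray is designed against (novel + known is-ncRNA)."""
        return [l for l in self.loci
                if l.category == "novel" or l.category.startswith("known_ncRNA:")]

    def to_json(self, path) -> None:
        payload = {
            "chrom_lengths": self.chrom_lengths,
            "reads": self.reads,
            "loci": [asdict(l) for l in self.loci],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True, indent=0)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            loci=[LocusTruth(**d) for d in payload["loci"]],
            reads=payload["reads"],
            chrom_lengths=payload["chrom_lengths"],
        )


# ---------------------------------------------------------------------------
# snoRNA motif planting (DNA space, transcript orientation)
# ---------------------------------------------------------------------------

def _scrub_cbox(s: List[str]) -> None:
    """Destroy any <=1-mismatch [AG]TGATGA occurrence in the 5' 20 nt."""
    pattern = "RTGATGA"
    allowed = {"R": "AG", "T": "T", "G": "G", "A": "A"}
    changed = True
    while changed:
        changed = False
        for i in range(0, min(20, len(s)) - 7 + 1):
            mm = sum(s[i + j] not in allowed[p] for j, p in enumerate(pattern))
            if mm <= 1:
                # C never occurs in the pattern, so two Cs kill the window
                s[i + 1] = "C"
                s[i + 4] = "C"
                changed = True


def _scrub_dbox(s: List[str]) -> None:
    """Destroy CTGA occurrences starting in the 3' 10 nt (ACA box protected)."""
    L = len(s)
    for i in range(max(L - 10, 0), L - 4 + 1):
        if "".join(s[i:i + 4]) == "CTGA" and i <= L - 7:
            s[i] = "A"


def _scrub_hbox(s: List[str]) -> None:
    """Destroy ANANNA occurrences in the hinge region (40-70% of length)."""
    L = len(s)
    lo, hi = int(0.4 * L), int(0.7 * L) - 6 + 1
    for i in range(lo, max(hi, lo)):
        if s[i] == "A" and s[i + 2] == "A" and s[i + 5] == "A":
            s[i] = "C"


def plant_sno_motifs(seq: str, kind: str) -> str:
    """Overwrite box motifs into a transcript sequence (DNA alphabet).

    ``kind`` is CD, HACA or scaRNA.  Competing box arrangements that would
    change the planted call are scrubbed.
    """
    if len(seq) < 50:
        raise SimulationError("motif planting needs >= 50 nt")
    s = list(seq)
    L = len(s)
    if kind in ("CD", "scaRNA"):
        s[3:10] = list("ATGATGA")  # C box, 1-mismatch tolerant form is RTGATGA
        dpos = L - 8 if kind == "CD" else L - 10
        s[dpos:dpos + 4] = list("CTGA")  # D box
    if kind in ("HACA", "scaRNA"):
        h = min(int(0.55 * L), int(0.7 * L) - 6)
        s[h:h + 6] = list("ACAGTA")  # H box (ANANNA)
        s[L - 6:L - 3] = list("ACA")
    if kind == "CD":
        # D box at L-8 occupies L-6 with G, so no ACA box can coexist;
        # remove chance H boxes so the call stays CD
        _scrub_hbox(s)
    elif kind == "HACA":
        _scrub_cbox(s)
        _scrub_dbox(s)
    return "".join(s)


# ---------------------------------------------------------------------------
# Genome, annotation and locus placement
# ---------------------------------------------------------------------------

def _split_counts(total: int, parts: int) -> List[int]:
    return largest_remainder([1.0 / parts] * parts, total)


def _place_genes(cfg: SimConfig, rng: np.random.Generator,
                 chrom_lengths: Dict[str, int]) -> List[GeneModel]:
    genes: List[GeneModel] = []
    per_chrom = _split_counts(cfg.n_genes, cfg.n_chromosomes)
    gid = 0
    for chrom, n_here in zip(chrom_lengths, per_chrom):
        cursor = 100
        limit = chrom_lengths[chrom] - 100
        for _ in range(n_here):
            gap = int(rng.integers(400, 1201))
            exon_lens = rng.integers(150, 301, size=cfg.exons_per_gene)
            intron_lens = rng.integers(1200, 1801, size=cfg.exons_per_gene - 1)
            start = cursor + gap
            exons = []
            pos = start
            for i, el in enumerate(exon_lens):
                exons.append((pos, pos + int(el)))
                pos += int(el)
                if i < len(intron_lens):
                    pos += int(intron_lens[i])
            end = pos
            if end > limit:
                raise SimulationError(
                    f"genome too small: gene placement exceeded {chrom} "
                    f"({end} > {limit}); increase genome_length or reduce n_genes"
                )
            gid += 1
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"g{gid:04d}", chrom, start, end, strand,
                                   tuple(exons)))
            cursor = end
    return genes


def _free_segments(chrom_lengths: Dict[str, int],
                   genes: Sequence[GeneModel]) -> List[Tuple[str, int, int]]:
    segs = []
    by_chrom: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chrom_lengths}
    for g in genes:
        by_chrom[g.chrom].append((g.start, g.end))
    for chrom, spans in by_chrom.items():
        spans.sort()
        prev = 100
        for s, e in spans:
            if s - prev > 0:
                segs.append((chrom, prev, s))
            prev = e
        tail = chrom_lengths[chrom] - 100
        if tail - prev > 0:
            segs.append((chrom, prev, tail))
    return segs


def _carve(free: List[Tuple[str, int, int]], length: int,
           rng: np.random.Generator, margin: int = 10) -> Tuple[str, int]:
    eligible = [i for i, (_c, s, e) in enumerate(free) if e - s >= length + 2 * margin]
    if not eligible:
        raise SimulationError(
            f"genome too small: no intergenic segment can hold a {length} nt locus"
        )
    i = eligible[int(rng.integers(len(eligible)))]
    chrom, s, e = free.pop(i)
    start = int(rng.integers(s + margin, e - margin - length + 1))
    if start - s > 2 * margin:
        free.append((chrom, s, start))
    if e - (start + length) > 2 * margin:
        free.append((chrom, start + length, e))
    return chrom, start


_KNOWN_LENGTHS = {
    "rRNA": (100, 160), "tRNA": (70, 90), "snoRNA": (70, 200),
    "snRNA": (80, 190), "misc": (60, 400),
}


def _effect_vector(n: int, size: float, rng: np.random.Generator) -> List[float]:
    v = np.zeros(n)
    focal = int(rng.integers(n))
    sign = 1.0 if rng.random() < 0.5 else -1.0
    v[focal] = sign * size
    v -= v.mean()
    return [float(x) for x in v]


def make_genome_and_annotation(
    cfg: SimConfig,
) -> Tuple[Dict[str, str], List[GeneModel], List[BedRecord], GroundTruth]:
    """Build the genome, gene models, known-ncRNA BED and ground truth."""
    rng = np.random.default_rng([cfg.seed, 0])
    per_chrom = _split_counts(cfg.genome_length, cfg.n_chromosomes)
    chrom_lengths = {f"chr{i + 1}": n for i, n in enumerate(per_chrom)}
    genome = {c: bytearray(random_seq(rng, n), "ascii")
              for c, n in chrom_lengths.items()}

    genes = _place_genes(cfg, rng, chrom_lengths)
    free = _free_segments(chrom_lengths, genes)
    truth = GroundTruth(chrom_lengths=dict(chrom_lengths))

    # --- known ncRNA loci (intergenic) ---------------------------------
    known_bed: List[BedRecord] = []
    for cls in cfg.n_known_ncrna:
        lo, hi = _KNOWN_LENGTHS.get(cls, (60, 400))
        for i in range(cfg.n_known_ncrna[cls]):
            length = int(rng.integers(lo, hi + 1))
            chrom, start = _carve(free, length, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            locus_id = f"{cls}{i + 1:03d}"
            known_bed.append(BedRecord(chrom, start, start + length,
                                       f"{cls}:{locus_id}", 0, strand))
            category = cls if cls in ("rRNA", "tRNA") else f"known_ncRNA:{cls}"
            truth.loci.append(LocusTruth(locus_id, chrom, start, start + length,
                                         strand, category))

    # --- novel loci per context mix -------------------------------------
    ctx_counts = cfg.novel_context_counts()
    lo, hi = cfg.insert_length_range
    intronic_total = ctx_counts.get("sense_intronic", 0) + \
        ctx_counts.get("antisense_intronic", 0)
    eligible_genes = [g for g in genes
                      if any(e - s >= hi + 4 for s, e in g.introns())]
    if len(eligible_genes) < intronic_total:
        raise SimulationError(
            f"genome too small: {intronic_total} intronic loci requested but only "
            f"{len(eligible_genes)} genes have introns of at least {hi + 4} nt"
        )
    gene_pool = [eligible_genes[i] for i in rng.permutation(len(eligible_genes))]
    novel: List[LocusTruth] = []
    idx = 0
    for context in ("intergenic", "sense_intronic", "antisense_intronic"):
        for _ in range(ctx_counts.get(context, 0)):
            idx += 1
            locus_id = f"nc{idx:03d}"
            length = int(rng.integers(lo, min(hi, 500) + 1))
            if context == "intergenic":
                chrom, start = _carve(free, length, rng)
                strand = "+" if rng.random() < 0.5 else "-"
                novel.append(LocusTruth(locus_id, chrom, start, start + length,
                                        strand, "novel", context))
            else:
                host = gene_pool.pop()
                introns = [iv for iv in host.introns() if iv[1] - iv[0] >= length + 4]
                i_s, i_e = introns[int(rng.integers(len(introns)))]
                start = int(rng.integers(i_s + 2, i_e - length - 1))
                strand = host.strand if context == "sense_intronic" else \
                    ("-" if host.strand == "+" else "+")
                novel.append(LocusTruth(locus_id, host.chrom, start, start + length,
                                        strand, "novel", context,
                                        host_gene=host.gene_id))

    # --- conservation groups, sno motifs, primate presence ---------------
    group_counts = cfg.conservation_group_counts()
    group_labels = [g for g, c in group_counts.items() for _ in range(c)]
    for locus, gi in zip(novel, rng.permutation(len(novel))):
        locus.conservation_group = group_labels[gi]

    sno_labels = (["CD"] * cfg.n_sno_cd + ["HACA"] * cfg.n_sno_haca +
                  ["scaRNA"] * cfg.n_sno_scarna)
    order = rng.permutation(len(novel))
    for label, oi in zip(sno_labels, order):
        novel[oi].sno_class = label

    primates = list(DEFAULT_PRIMATE_DIVERGENCE)
    primate_only = [l for l in novel if l.conservation_group == "primate_only"]
    marmoset_absent = {l.locus_id for l in primate_only[:len(primate_only) // 2]}
    for locus in novel:
        if locus.conservation_group == "other":
            locus.primate_presence = {sp: False for sp in primates}
        else:
            locus.primate_presence = {
                sp: not (sp == "marmoset" and locus.locus_id in marmoset_absent)
                for sp in primates
            }

    # --- planted expression effects --------------------------------------
    truth.loci.extend(novel)
    known_targets = [l for l in truth.loci if l.category.startswith("known_ncRNA:")]
    for pool, frac_t, frac_s in (
        (novel, cfg.effect_fraction, cfg.stage_effect_fraction),
        (known_targets, cfg.effect_fraction_known, cfg.stage_effect_fraction_known),
    ):
        for locus in pool:
            locus.tissue_effects = [0.0] * len(cfg.tissues)
            locus.stage_effects = [0.0] * len(cfg.stages)
        n_t = int(round(frac_t * len(pool)))
        for i in rng.permutation(len(pool))[:n_t]:
            pool[i].tissue_effects = _effect_vector(
                len(cfg.tissues), cfg.effect_size_log2, rng)
        n_s = int(round(frac_s * len(pool)))
        for i in rng.permutation(len(pool))[:n_s]:
            pool[i].stage_effects = _effect_vector(
                len(cfg.stages), cfg.effect_size_log2, rng)

    # --- write sno motifs into the genome, then freeze sequences ----------
    for locus in novel:
        if locus.sno_class != "none":
            raw = genome[locus.chrom][locus.start:locus.end].decode("ascii")
            tx = raw if locus.strand == "+" else revcomp(raw)
            planted = plant_sno_motifs(tx, locus.sno_class)
            back = planted if locus.strand == "+" else revcomp(planted)
            genome[locus.chrom][locus.start:locus.end] = back.encode("ascii")
    genome_str = {c: bytes(b).decode("ascii") for c, b in genome.items()}
    for locus in truth.loci:
        raw = genome_str[locus.chrom][locus.start:locus.end]
        locus.sequence = raw if locus.strand == "+" else revcomp(raw)
    return genome_str, genes, known_bed, truth


# ---------------------------------------------------------------------------
# Clone library
# ---------------------------------------------------------------------------

def make_clone_library(
    cfg: SimConfig,
    truth: GroundTruth,
    genes: Sequence[GeneModel],
    genome: Dict[str, str],
) -> List[Tuple[str, str]]:
    """Emit adapter-flanked reads; fills ``truth.reads`` and mRNA decoy loci.

    Clone counts follow a zero-truncated geometric law: parameter
    ``clone_count_p`` for novel loci (most single-clone) and
    ``clone_count_p_known`` for known is-ncRNAs (multi-clone).  A
    ``decoy_fraction`` of all reads derives from mRNA exon fragments and
    rRNA/tRNA loci, exercising the removal cascade.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    targets = truth.array_targets()
    if not targets:
        raise SimulationError("no loci to draw clones from")
    entries: List[Tuple[str, str]] = []  # (locus_id, insert)
    for locus in targets:
        p = cfg.clone_count_p if locus.category == "novel" else cfg.clone_count_p_known
        count = int(rng.geometric(p))
        entries.extend([(locus.locus_id, locus.sequence)] * count)

    n_main = len(entries)
    n_decoy = int(round(cfg.decoy_fraction / (1 - cfg.decoy_fraction) * n_main))
    removal = {cls: [l for l in truth.loci if l.category == cls]
               for cls in ("rRNA", "tRNA")}
    mrna_decoys: List[LocusTruth] = []
    lo, _hi = cfg.insert_length_range
    for i in range(n_decoy):
        dtype = ["mRNA", "rRNA", "tRNA"][
            int(rng.choice(3, p=[0.6, 0.25, 0.15]))]
        if dtype == "mRNA":
            gene = genes[int(rng.integers(len(genes)))]
            exons = [e for e in gene.exons if e[1] - e[0] >= lo]
            ex_s, ex_e = exons[int(rng.integers(len(exons)))]
            length = int(rng.integers(lo, min(500, ex_e - ex_s) + 1))
            start = int(rng.integers(ex_s, ex_e - length + 1))
            raw = genome[gene.chrom][start:start + length]
            seq = raw if gene.strand == "+" else revcomp(raw)
            decoy = LocusTruth(f"mx{i + 1:04d}", gene.chrom, start, start + length,
                               gene.strand, "mRNA", sequence=seq)
            mrna_decoys.append(decoy)
            entries.append((decoy.locus_id, seq))
        else:
            pool = removal[dtype]
            locus = pool[int(rng.integers(len(pool)))]
            entries.append((locus.locus_id, locus.sequence))
    truth.loci.extend(mrna_decoys)

    reads: List[Tuple[str, str]] = []
    for i, j in enumerate(rng.permutation(len(entries)), start=1):
        locus_id, insert = entries[j]
        read_id = f"r{i:05d}"
        truth.reads[read_id] = locus_id
        reads.append((read_id, cfg.adapter_5 + insert + cfg.adapter_3))
    return reads


# ---------------------------------------------------------------------------
# Conservation tracks and primate orthologs
# ---------------------------------------------------------------------------

def make_conservation_tracks(
    cfg: SimConfig, truth: GroundTruth
) -> Dict[str, List[Tuple[str, int, int, float]]]:
    """Per-species bedGraph-style intervals realizing each locus's archetype.

    Tracks cover the novel loci (the set whose conservation is analyzed).
    Human scores are deterministic; other species get optional per-base
    Gaussian noise (sd ``track_noise_sd``), clipped to [0, 1].
    """
    rng = np.random.default_rng([cfg.seed, 2])
    tracks: Dict[str, List[Tuple[str, int, int, float]]] = {
        sp: [] for sp in cfg.species_list
    }
    loci = sorted(truth.novel(), key=lambda l: (l.chrom, l.start))
    for locus in loci:
        targets = _GROUP_TARGETS[locus.conservation_group]
        for sp in cfg.species_list:
            if sp == "human":
                tracks[sp].append((locus.chrom, locus.start, locus.end, _HUMAN_SCORE))
                continue
            t = targets[cfg.clades[sp]]
            if cfg.track_noise_sd == 0:
                tracks[sp].append((locus.chrom, locus.start, locus.end, t))
            else:
                vals = np.clip(
                    t + rng.normal(0, cfg.track_noise_sd, size=locus.length), 0, 1)
                tracks[sp].extend(
                    (locus.chrom, locus.start + k, locus.start + k + 1, float(v))
                    for k, v in enumerate(vals)
                )
    return tracks


def make_primate_orthologs(
    cfg: SimConfig, truth: GroundTruth, flank: int = 80
) -> Dict[str, Dict[str, str]]:
    """Candidate ortholog regions of each novel locus in primate genomes.

    A present ortholog is the locus sequence copied with the species'
    substitution divergence; an absent one is unrelated random sequence of
    the same length.  Both are embedded in random flanks, emulating the
    syntenic region a genome search would return.  Records are keyed by the
    human locus coordinates so consumers can join on mapped positions.
    """
    rng = np.random.default_rng([cfg.seed, 3])
    out: Dict[str, Dict[str, str]] = {sp: {} for sp in DEFAULT_PRIMATE_DIVERGENCE}
    for locus in truth.novel():
        presence = locus.primate_presence or {}
        key = locus_coord_key(locus.chrom, locus.start, locus.end, locus.strand)
        for sp, rate in DEFAULT_PRIMATE_DIVERGENCE.items():
            core = (diverge(locus.sequence, rate, rng) if presence.get(sp, True)
                    else random_seq(rng, locus.length))
            out[sp][key] = random_seq(rng, flank) + core + random_seq(rng, flank)
    return out


# ---------------------------------------------------------------------------
# Loop-design microarray
# ---------------------------------------------------------------------------

def make_probe_table(cfg: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """Probe annotation: two probes per target longer than 200 nt, else one.

    Probes are exact 50-mer subsequences of the transcript (or the whole
    transcript when shorter).
    """
    rows = []
    for locus in truth.array_targets():
        seq = locus.sequence
        probes = [seq[:50]] if len(seq) <= 200 else [seq[:50], seq[-50:]]
        for k, pseq in enumerate(probes, start=1):
            rows.append({
                "probe_id": f"{locus.locus_id}_p{k}",
                "target_id": locus.locus_id,
                "chrom": locus.chrom, "start": locus.start, "end": locus.end,
                "strand": locus.strand, "probe_seq": pseq,
            })
    return pd.DataFrame(rows)


def simulate_loop_design(
    cfg: SimConfig,
    truth: GroundTruth,
    which: str = "tissues",
    probes: Optional[pd.DataFrame] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Design and intensity tables for one loop experiment.

    Samples form a cycle; array *i* hybridizes Cy5 = sample[i+1] against
    Cy3 = sample[i].  Each probe is printed in triplicate; each replicate's
    log-ratio is contrast + array offset (Normal(0, dye_offset_sd)) +
    Normal(0, noise_sd_log2) noise, converted to two positive channel
    intensities around a per-probe baseline.
    """
    if which not in ("tissues", "stages"):
        raise ValueError("which must be 'tissues' or 'stages'")
    samples = list(cfg.tissues if which == "tissues" else cfg.stages)
    if len(samples) < 2:
        raise SimulationError("a loop needs at least two samples")
    rng = np.random.default_rng([cfg.seed, 4 if which == "tissues" else 5])
    if probes is None:
        probes = make_probe_table(cfg, truth)
    mu = {
        l.locus_id: (l.tissue_effects if which == "tissues" else l.stage_effects)
        or [0.0] * len(samples)
        for l in truth.array_targets()
    }
    n = len(samples)
    design_rows = []
    arrays = []
    for i in range(n):
        aid = f"{which}_a{i + 1}"
        cy5, cy3 = samples[(i + 1) % n], samples[i]
        design_rows.append({"array_id": aid, "cy5_sample": cy5, "cy3_sample": cy3})
        arrays.append((aid, samples.index(cy5), samples.index(cy3)))

    probe_ids = probes["probe_id"].tolist()
    target_ids = probes["target_id"].tolist()
    baseline = rng.normal(10.0, 1.0, size=len(probe_ids))
    rows = []
    for aid, i5, i3 in arrays:
        delta = rng.normal(0, cfg.dye_offset_sd) if cfg.dye_offset_sd > 0 else 0.0
        contrast = np.array([mu[t][i5] - mu[t][i3] for t in target_ids])
        for rep in range(1, cfg.n_replicates + 1):
            eps = (rng.normal(0, cfg.noise_sd_log2, size=len(probe_ids))
                   if cfg.noise_sd_log2 > 0 else np.zeros(len(probe_ids)))
            m = contrast + delta + eps
            cy5 = np.power(2.0, baseline + m / 2)
            cy3 = np.power(2.0, baseline - m / 2)
            rows.extend({
                "array_id": aid, "probe_id": pid, "replicate": rep,
                "cy5": float(c5), "cy3": float(c3),
            } for pid, c5, c3 in zip(probe_ids, cy5, cy3))
    return pd.DataFrame(design_rows), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

def make_gene_sets(
    cfg: SimConfig, truth: GroundTruth, genes: Sequence[GeneModel]
) -> Tuple[Dict[str, List[str]], List[str]]:
    """A planted enriched pathway among sense-intronic host genes + decoys."""
    rng = np.random.default_rng([cfg.seed, 6])
    background = [g.gene_id for g in genes]
    hosts = sorted({l.host_gene for l in truth.novel()
                    if l.context == "sense_intronic"})
    non_hosts = [g for g in background if g not in set(hosts)]
    n_hit = min(cfg.enriched_hosts, len(hosts))
    hits = [hosts[i] for i in rng.permutation(len(hosts))[:n_hit]]
    pad = [non_hosts[i] for i in
           rng.permutation(len(non_hosts))[:cfg.enriched_set_size - n_hit]]
    sets: Dict[str, List[str]] = {"axon_guidance": sorted(hits + pad)}
    for i in range(cfg.n_decoy_sets):
        size = int(rng.integers(8, 16))
        members = [background[j] for j in rng.permutation(len(background))[:size]]
        sets[f"pathway_{i + 1:02d}"] = sorted(members)
    return sets, background


# ---------------------------------------------------------------------------
# Whole-study assembly and fixture writing
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    cfg: SimConfig
    genome: Dict[str, str]
    genes: List[GeneModel]
    known_bed: List[BedRecord]
    truth: GroundTruth
    reads: List[Tuple[str, str]]
    tracks: Dict[str, List[Tuple[str, int, int, float]]]
    orthologs: Dict[str, Dict[str, str]]
    probes: pd.DataFrame
    tissue_design: pd.DataFrame
    tissue_intensities: pd.DataFrame
    stage_design: pd.DataFrame
    stage_intensities: pd.DataFrame
    gene_sets: Dict[str, List[str]]
    background: List[str]


def simulate_study(cfg: SimConfig) -> SimulatedStudy:
    """Generate every input of one study from the seed in ``cfg``."""
    genome, genes, known_bed, truth = make_genome_and_annotation(cfg)
    reads = make_clone_library(cfg, truth, genes, genome)
    tracks = make_conservation_tracks(cfg, truth)
    orthologs = make_primate_orthologs(cfg, truth)
    probes = make_probe_table(cfg, truth)
    t_design, t_int = simulate_loop_design(cfg, truth, "tissues", probes)
    s_design, s_int = simulate_loop_design(cfg, truth, "stages", probes)
    gene_sets, background = make_gene_sets(cfg, truth, genes)
    return SimulatedStudy(cfg, genome, genes, known_bed, truth, reads, tracks,
                          orthologs, probes, t_design, t_int, s_design, s_int,
                          gene_sets, background)


def write_fixture(study: SimulatedStudy, outdir) -> Dict[str, str]:
    """Write a complete on-disk fixture; returns the path manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "tracks").mkdir(exist_ok=True)
    (outdir / "orthologs").mkdir(exist_ok=True)
    cfg = study.cfg

    paths = {
        "genome": str(outdir / "genome.fasta"),
        "annotation": str(outdir / "annotation.gff3"),
        "known_ncrna": str(outdir / "known_ncrna.bed"),
        "reads": str(outdir / "reads.fasta"),
        "tracks_dir": str(outdir / "tracks"),
        "clades": str(outdir / "clades.tsv"),
        "orthologs_dir": str(outdir / "orthologs"),
        "probes": str(outdir / "probes.tsv"),
        "tissue_design": str(outdir / "design_tissues.tsv"),
        "tissue_intensities": str(outdir / "intensities_tissues.tsv"),
        "stage_design": str(outdir / "design_stages.tsv"),
        "stage_intensities": str(outdir / "intensities_stages.tsv"),
        "gene_sets": str(outdir / "gene_sets.gmt"),
        "background": str(outdir / "background_genes.txt"),
        "truth": str(outdir / "truth.json"),
        "config": str(outdir / "sim_config.yaml"),
    }
    write_fasta(paths["genome"], sorted(study.genome.items()))
    write_gff3(paths["annotation"], study.genes, study.truth.chrom_lengths)
    write_bed6(paths["known_ncrna"], study.known_bed)
    write_fasta(paths["reads"], study.reads)
    for sp in cfg.species_list:
        write_bedgraph(Path(paths["tracks_dir"]) / f"{sp}.bedGraph",
                       study.tracks[sp])
    pd.DataFrame(
        {"species": list(cfg.species_list),
         "clade": [cfg.clades[sp] for sp in cfg.species_list]}
    ).to_csv(paths["clades"], sep="\t", index=False)
    for sp, seqs in study.orthologs.items():
        write_fasta(Path(paths["orthologs_dir"]) / f"{sp}.fasta",
                    sorted(seqs.items()))
    write_tsv(paths["probes"], study.probes)
    write_tsv(paths["tissue_design"], study.tissue_design)
    write_tsv(paths["tissue_intensities"], study.tissue_intensities)
    write_tsv(paths["stage_design"], study.stage_design)
    write_tsv(paths["stage_intensities"], study.stage_intensities)
    write_gmt(paths["gene_sets"], study.gene_sets)
    with open(paths["background"], "w") as fh:
        fh.write("\n".join(study.background) + "\n")
    study.truth.to_json(paths["truth"])
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    return paths
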
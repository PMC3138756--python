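"""Readers and writers for the flat-file formats the pipeline consumes.

Coordinates are 0-based half-open everywhere in memory (BED convention);
GFF3 is written and read 1-based inclusive, with the conversion confined to
this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records: Iterable[Tuple[str, str]]) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")


def read_reads(path) -> List[Tuple[str, str]]:
    """Read clone reads from FASTA or FASTQ, ordered as in the file."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), fmt)]


# ---------------------------------------------------------------------------
# Gene models / GFF3
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene with its exons (0-based half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: Tuple[Tuple[int, int], ...]

    def introns(self) -> List[Tuple[int, int]]:
        ex = sorted(self.exons)
        return [(a_end, b_start) for (_, a_end), (b_start, _) in zip(ex, ex[1:])
                if b_start > a_end]


def write_gff3(path, genes: Iterable[GeneModel], chrom_lengths: Dict[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tisrna_sim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};biotype=protein_coding\n"
            )
            for i, (s, e) in enumerate(sorted(g.exons), start=1):
                fh.write(
                    f"{g.chrom}\tisrna_sim\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


def _gff_attributes(field: str) -> Dict[str, str]:
    out = {}
    for item in field.strip().split(";"):
        if item and "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
    return out


def read_gff3(path) -> Tuple[List[GeneModel], Dict[str, int]]:
    """Parse the gene/exon subset of GFF3 used by this pipeline."""
    chrom_lengths: Dict[str, int] = {}
    genes: Dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                _, chrom, _one, length = line.split()
                chrom_lengths[chrom] = int(length)
                continue
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = (
                line.rstrip("\n").split("\t")
            )
            a = _gff_attributes(attrs)
            s, e = int(start) - 1, int(end)
            if ftype == "gene":
                genes[a["ID"]] = {
                    "chrom": chrom, "start": s, "end": e, "strand": strand,
                    "exons": [],
                }
            elif ftype == "exon":
                genes[a["Parent"]]["exons"].append((s, e))
    models = [
        GeneModel(gene_id=gid, chrom=g["chrom"], start=g["start"], end=g["end"],
                  strand=g["strand"], exons=tuple(sorted(g["exons"])))
        for gid, g in genes.items()
    ]
    return models, chrom_lengths


# ---------------------------------------------------------------------------
# BED6 / bedGraph
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BedRecord:
    chrom: str
    start: int
    end: int
    name: str
    score: float
    strand: str


def write_bed6(path, records: Iterable[BedRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.score:g}\t{r.strand}\n")


def read_bed6(path) -> List[BedRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, score, strand = line.rstrip("\n").split("\t")[:6]
            out.append(BedRecord(chrom, int(start), int(end), name, float(score), strand))
    return out


def write_bedgraph(path, intervals: Iterable[Tuple[str, int, int, float]]) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, score in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{score:.6g}\n")


def read_bedgraph(path) -> List[Tuple[str, int, int, float]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, score = line.split()[:4]
            out.append((chrom, int(start), int(end), float(score)))
    return out


# ---------------------------------------------------------------------------
# GMT gene sets / TSV helpers
# ---------------------------------------------------------------------------

def write_gmt(path, gene_sets: Dict[str, List[str]]) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_gmt(path) -> Dict[str, List[str]]:
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = parts[2:]
    return sets


def write_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
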
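"""End-to-end orchestration: trim -> size -> dedup -> map -> classify ->
conserve -> express -> enrich -> snoscreen, with a machine-readable report.

All stage outputs are written under one output directory with a manifest;
given fixed inputs and parameters the run is byte-deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
import yaml

from . import __version__, clones, conservation, expression, loci, screens
from .io import (read_bed6, read_fasta, read_gff3, read_reads, read_gmt,
                 read_tsv, write_fasta, write_tsv)
from .simulate import locus_coord_key

logger = logging.getLogger("isrna")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    # input paths
    reads: str
    genome: str
    annotation: str
    known_ncrna: str
    tracks_dir: str
    clades: str
    probes: str
    tissue_design: str
    tissue_intensities: str
    stage_design: str
    stage_intensities: str
    gene_sets: str
    background: str
    outdir: str
    orthologs_dir: Optional[str] = None
    species_list: Optional[List[str]] = None  # default: clades file order

    # stage parameters
    adapter_5: str = "ATCGTAGGCACCTGAAATCG"
    adapter_3: str = "TGGAATTCTCGGGTGCCAAG"
    adapter_max_mismatch: int = 1
    min_len: int = 50
    max_len: int = 500
    map_max_mismatch: int = 2
    seed_k: int = 16
    min_overlap: float = 0.5
    tau_present: float = 0.5
    min_identity: float = 0.8
    min_coverage: float = 0.5
    tau_fold: float = 1.0
    margin: float = 1.0
    reference_tissue: str = "brain"
    reference_stage: str = "13w"
    seed: int = 1

    def validate(self) -> None:
        for name in ("reads", "genome", "annotation", "known_ncrna", "clades",
                     "probes", "tissue_design", "tissue_intensities",
                     "stage_design", "stage_intensities", "gene_sets",
                     "background"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise FileNotFoundError(f"input {name!r} missing: {path}")
        if not Path(self.tracks_dir).is_dir():
            raise FileNotFoundError(f"tracks_dir missing: {self.tracks_dir}")
        if not (0 < self.min_overlap <= 1):
            raise ValueError("min_overlap must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    @classmethod
    def from_fixture(cls, fixture_dir, outdir, **overrides) -> "PipelineConfig":
        """Point every input at a directory written by ``write_fixture``."""
        d = Path(fixture_dir)
        sim = yaml.safe_load(open(d / "sim_config.yaml")) if (
            d / "sim_config.yaml").exists() else {}
        defaults = dict(
            reads=str(d / "reads.fasta"),
            genome=str(d / "genome.fasta"),
            annotation=str(d / "annotation.gff3"),
            known_ncrna=str(d / "known_ncrna.bed"),
            tracks_dir=str(d / "tracks"),
            clades=str(d / "clades.tsv"),
            orthologs_dir=str(d / "orthologs"),
            probes=str(d / "probes.tsv"),
            tissue_design=str(d / "design_tissues.tsv"),
            tissue_intensities=str(d / "intensities_tissues.tsv"),
            stage_design=str(d / "design_stages.tsv"),
            stage_intensities=str(d / "intensities_stages.tsv"),
            gene_sets=str(d / "gene_sets.gmt"),
            background=str(d / "background_genes.txt"),
            outdir=str(outdir),
        )
        if sim:
            defaults["adapter_5"] = sim["adapter_5"]
            defaults["adapter_3"] = sim["adapter_3"]
            defaults["min_len"], defaults["max_len"] = sim["insert_length_range"]
            defaults["reference_tissue"] = sim["tissues"][0]
            defaults["reference_stage"] = sim["stages"][0]
        defaults.update(overrides)
        return cls(**defaults)


def format_count_pct(k: int, n: int) -> str:
    """Render 'count (percent)' with whole-percent rounding; em-dash for n=0."""
    if n == 0:
        return "0 (–)"
    return f"{k} ({round(100 * k / n)}%)"


@dataclass
class RunReport:
    status: str = "ok"
    version: str = __version__
    parameters: Dict = field(default_factory=dict)
    cascade: Dict[str, int] = field(default_factory=dict)
    category_counts: Dict[str, int] = field(default_factory=dict)
    novel_context_counts: Dict[str, int] = field(default_factory=dict)
    chromosome_test: Dict = field(default_factory=dict)
    conservation_groups: Dict[str, int] = field(default_factory=dict)
    primate_presence: Dict[str, int] = field(default_factory=dict)
    expression: Dict = field(default_factory=dict)
    enrichment: List[Dict] = field(default_factory=list)
    sno_calls: Dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def write_report(report: RunReport, outdir) -> Tuple[str, str]:
    """Emit the JSON report and a human-readable text summary."""
    outdir = Path(outdir)
    json_path = outdir / "report.json"
    with open(json_path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    lines = [
        f"isrna run report (v{report.version}) — status: {report.status}",
        "",
        "Clone cascade: " + ", ".join(
            f"{k}={v}" for k, v in report.cascade.items()),
        "Categories:    " + ", ".join(
            f"{k}={v}" for k, v in sorted(report.category_counts.items())),
        "Novel contexts: " + ", ".join(
            f"{k}={v}" for k, v in sorted(report.novel_context_counts.items())),
    ]
    if report.chromosome_test:
        ct = report.chromosome_test
        lines.append(
            f"Chromosome distribution: chi2={ct['statistic']:.3f} "
            f"df={ct['df']} p={ct['p_value']:.3g}"
        )
    if report.conservation_groups:
        lines.append("Conservation groups: " + ", ".join(
            f"{k}={v}" for k, v in sorted(report.conservation_groups.items())))
    for exp_name, block in report.expression.items():
        for subset, d in block.get("distinct", {}).items():
            lines.append(
                f"Distinct (>2-fold) {exp_name}/{subset}: "
                + format_count_pct(d["distinct"], d["n"])
            )
    if report.enrichment:
        top = report.enrichment[0]
        lines.append(
            f"Top enriched set: {top['set_name']} "
            f"(k={top['k']}/{top['n']}, p={top['p_value']:.3g}, "
            f"BH q={top['adjusted_p']:.3g})"
        )
    if report.sno_calls:
        lines.append("snoRNA motif calls: " + ", ".join(
            f"{k}={v}" for k, v in sorted(report.sno_calls.items())))
    text = "\n".join(lines) + "\n"
    txt_path = outdir / "report.txt"
    txt_path.write_text(text)
    return str(json_path), str(txt_path)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _classify_all(uniques, genome, annotation_path, known_path, cfg):
    genes, chrom_lengths = read_gff3(annotation_path)
    # chromosome lengths may be stated in the FASTA only
    for chrom, seq in genome.items():
        chrom_lengths.setdefault(chrom, len(seq))
    known = read_bed6(known_path)
    ann = loci.AnnotationIndex(genes, known, chrom_lengths)
    index = loci.GenomeIndex(genome, k=cfg.seed_k)
    classified: List[loci.ClassifiedLocus] = []
    unmapped: List[str] = []
    mapped_transcripts = 0
    for u in uniques:
        hits = loci.map_to_genome(u.sequence, index, cfg.map_max_mismatch)
        if not hits:
            unmapped.append(u.transcript_id)
            continue
        mapped_transcripts += 1
        for hit in hits:
            classified.append(
                loci.classify_locus(hit, ann, u.transcript_id, cfg.min_overlap))
    return classified, unmapped, mapped_transcripts, chrom_lengths, ann


def _expression_stage(cfg, which, categories_by_coord, outdir):
    prefix = "tissue" if which == "tissues" else "stage"
    design = read_tsv(getattr(cfg, f"{prefix}_design"))
    intens = read_tsv(getattr(cfg, f"{prefix}_intensities"))
    probes = read_tsv(cfg.probes)
    exp = expression.build_experiment(design, intens)
    exp = expression.normalize_experiment(exp)
    probe_mat = expression.estimate_effects(exp)
    groups = {t: g["probe_id"].tolist()
              for t, g in probes.groupby("target_id", sort=True)}
    mat = expression.aggregate_probes(probe_mat, groups)

    coord_by_target = {
        r.target_id: locus_coord_key(r.chrom, r.start, r.end, r.strand)
        for r in probes.itertuples()
    }
    category = {
        t: categories_by_coord.get(coord_by_target[t], ("unmatched", None))[0]
        for t in mat.effects.index
    }
    reference = cfg.reference_tissue if which == "tissues" else cfg.reference_stage
    calls = expression.make_call_table(
        mat, focal_sample=reference if which == "tissues" else None,
        tau_fold=cfg.tau_fold, margin=cfg.margin)
    table = calls.table.copy()
    table.insert(0, "category", pd.Series(category))

    block = {"n_targets": int(len(mat.effects)), "distinct": {}}
    for subset, mask in (
        ("novel", table["category"] == "novel"),
        ("known", table["category"].str.startswith("known_ncRNA")),
    ):
        n = int(mask.sum())
        k = int((table["distinct"] & mask).sum())
        block["distinct"][subset] = {
            "n": n, "distinct": k,
            "fraction": (k / n) if n else None,
            "rendered": format_count_pct(k, n),
        }
    if which == "tissues":
        spec_counts = table.loc[table["category"] == "novel", "specificity"] \
            .value_counts().to_dict()
        block["novel_specificity"] = {k: int(v) for k, v in sorted(spec_counts.items())}

    t1, t2 = expression.relative_expression_tables(mat, reference)
    write_tsv(outdir / f"expression_{which}.tsv",
              mat.effects.rename_axis("target_id").reset_index())
    write_tsv(outdir / f"relative_{which}_reference.tsv",
              t1.rename_axis("target_id").reset_index())
    write_tsv(outdir / f"relative_{which}_vs_{reference}.tsv",
              t2.rename_axis("target_id").reset_index())
    write_tsv(outdir / f"calls_{which}.tsv",
              table.rename_axis("target_id").reset_index())

    # cluster the distinct-called transcripts (constant rows carry no pattern)
    distinct_ids = table.index[table["distinct"]].tolist()
    if which == "tissues" and len(distinct_ids) >= 2:
        sub = expression.ExpressionMatrix(mat.effects.loc[distinct_ids],
                                          mat.se.loc[distinct_ids])
        try:
            clust = expression.hierarchical_cluster(sub)
        except ValueError:
            clust = None
        if clust is not None:
            (outdir / "cluster_tissues.nwk").write_text(clust.newick + "\n")
            write_tsv(outdir / "cluster_tissues_leaf_order.tsv",
                      mat.effects.loc[clust.leaf_order]
                      .rename_axis("target_id").reset_index())
            block["cluster_leaves"] = len(clust.leaf_order)
    return block


def run_all(cfg: PipelineConfig) -> RunReport:
    """Execute every stage; returns the run report (also written to disk)."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # parameter echo: scalars only; outdir excluded so identical inputs give
    # byte-identical reports regardless of where they are written
    report = RunReport(parameters={
        k: v for k, v in asdict(cfg).items()
        if k != "outdir" and not isinstance(v, (list, dict))
    })
    manifest: Dict[str, str] = {}

    def _stage(name):
        logger.info("stage %s", name)
        return name

    # --- clone processing ------------------------------------------------
    stage = _stage("trim/size/dedup")
    try:
        raw_reads = read_reads(cfg.reads)
        result = clones.process_reads(
            raw_reads, cfg.adapter_5, cfg.adapter_3,
            cfg.min_len, cfg.max_len, cfg.adapter_max_mismatch)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc
    report.cascade = {
        "reads_in": result.n_input,
        "trimmed": result.n_trimmed,
        "size_kept": result.n_size_kept,
        "unique": result.n_unique,
    }
    write_fasta(outdir / "unique_transcripts.fasta",
                clones.uniques_to_fasta_records(result.uniques))
    write_tsv(outdir / "rejections.tsv", result.rejections)
    manifest["unique_transcripts"] = "unique_transcripts.fasta"
    manifest["rejections"] = "rejections.tsv"
    if result.n_input == 0:
        report.status = "no_input"
        write_report(report, outdir)
        _write_manifest(manifest, outdir)
        return report

    # --- mapping & classification ----------------------------------------
    stage = _stage("map/classify")
    try:
        genome = read_fasta(cfg.genome)
        classified, unmapped, mapped_transcripts, chrom_lengths, _ann = \
            _classify_all(result.uniques, genome, cfg.annotation,
                          cfg.known_ncrna, cfg)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc
    counts_by_tid = {u.transcript_id: u.clone_count for u in result.uniques}
    rows = [{
        "chrom": c.locus.chrom, "start": c.locus.start, "end": c.locus.end,
        "strand": c.locus.strand, "transcript_id": c.transcript_id,
        "clone_count": counts_by_tid[c.transcript_id],
        "category": c.category, "context": c.context or "",
        "host_gene": c.host_gene_id or "",
    } for c in classified]
    class_df = pd.DataFrame(rows).sort_values(
        ["chrom", "start", "end", "transcript_id"]).reset_index(drop=True)
    write_tsv(outdir / "classified_loci.tsv", class_df)
    manifest["classified_loci"] = "classified_loci.tsv"
    report.cascade.update({
        "mapped_transcripts": mapped_transcripts,
        "unmapped_transcripts": len(unmapped),
        "mapped_loci": len(classified),
    })
    cat_counts: Dict[str, int] = {}
    for c in classified:
        cat_counts[c.category] = cat_counts.get(c.category, 0) + 1
    report.category_counts = cat_counts
    novel = [c for c in classified if c.category == "novel"]
    ctx_counts: Dict[str, int] = {}
    for c in novel:
        ctx_counts[c.context] = ctx_counts.get(c.context, 0) + 1
    report.novel_context_counts = ctx_counts

    if novel and len(chrom_lengths) >= 2:
        test = loci.chromosome_distribution_test(
            [c.locus for c in novel], chrom_lengths)
        report.chromosome_test = {
            "statistic": test.statistic, "df": test.df, "p_value": test.p_value,
            "observed": test.observed,
        }

    # --- conservation -----------------------------------------------------
    stage = _stage("conserve")
    try:
        clades = conservation.load_clades_tsv(cfg.clades)
        species = cfg.species_list or list(clades)
        tracks = conservation.load_tracks_dir(cfg.tracks_dir, species)
        novel_by_key = {}
        for c in novel:
            key = locus_coord_key(c.locus.chrom, c.locus.start, c.locus.end,
                                  c.locus.strand)
            novel_by_key[key] = c.locus
        profiles = conservation.build_profiles(
            novel_by_key, tracks, species, clades, cfg.tau_present)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc
    prof_df = conservation.profiles_to_frame(profiles)
    write_tsv(outdir / "conservation_profiles.tsv", prof_df)
    manifest["conservation_profiles"] = "conservation_profiles.tsv"
    grp_counts: Dict[str, int] = {}
    for p in profiles:
        grp_counts[p.group] = grp_counts.get(p.group, 0) + 1
    report.conservation_groups = grp_counts

    if cfg.orthologs_dir and Path(cfg.orthologs_dir).is_dir():
        stage = _stage("presence")
        try:
            ortho_files = sorted(Path(cfg.orthologs_dir).glob("*.fasta"))
            targets = {f.stem: read_fasta(f) for f in ortho_files}
            seq_by_tid = {u.transcript_id: u.sequence for u in result.uniques}
            queries, per_tid_targets = {}, {sp: {} for sp in targets}
            for c in novel:
                key = locus_coord_key(c.locus.chrom, c.locus.start,
                                      c.locus.end, c.locus.strand)
                queries[key] = seq_by_tid[c.transcript_id]
                for sp in targets:
                    if key in targets[sp]:
                        per_tid_targets[sp][key] = targets[sp][key]
            matrix, stats = conservation.build_presence_matrix(
                queries, per_tid_targets, cfg.min_identity, cfg.min_coverage)
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, str(exc)) from exc
        write_tsv(outdir / "presence_matrix.tsv", matrix.reset_index())
        write_tsv(outdir / "presence_stats.tsv", stats)
        manifest["presence_matrix"] = "presence_matrix.tsv"
        report.primate_presence = {
            sp: int(matrix[sp].sum()) for sp in matrix.columns
        }

    # --- expression --------------------------------------------------------
    stage = _stage("express")
    categories_by_coord = {}
    for c in classified:
        key = locus_coord_key(c.locus.chrom, c.locus.start, c.locus.end,
                              c.locus.strand)
        categories_by_coord[key] = (c.category, c.context)
    try:
        for which in ("tissues", "stages"):
            report.expression[which] = _expression_stage(
                cfg, which, categories_by_coord, outdir)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc
    manifest["expression_tissues"] = "expression_tissues.tsv"
    manifest["expression_stages"] = "expression_stages.tsv"

    # --- enrichment ---------------------------------------------------------
    stage = _stage("enrich")
    try:
        gene_sets = read_gmt(cfg.gene_sets)
        background = [l.strip() for l in open(cfg.background) if l.strip()]
        hosts = sorted({c.host_gene_id for c in novel
                        if c.context == "sense_intronic"})
        results = screens.hypergeometric_enrichment(hosts, gene_sets, background) \
            if hosts else []
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc
    enr_df = pd.DataFrame([{
        "set_name": r.set_name, "N": r.N, "K": r.K, "n": r.n, "k": r.k,
        "p_value": r.p_value, "adjusted_p": r.adjusted_p,
        "overlap": ",".join(r.overlap_genes),
    } for r in results])
    write_tsv(outdir / "enrichment.tsv", enr_df)
    manifest["enrichment"] = "enrichment.tsv"
    report.enrichment = enr_df.drop(columns=["overlap"]).to_dict("records") \
        if len(enr_df) else []

    # --- snoRNA motif screen -------------------------------------------------
    stage = _stage("snoscreen")
    try:
        seq_by_tid = {u.transcript_id: u.sequence for u in result.uniques}
        novel_tids = sorted({c.transcript_id for c in novel})
        sno_rows = []
        for tid in novel_tids:
            call = screens.sno_motif_screen(seq_by_tid[tid], tid)
            sno_rows.append({"transcript_id": tid, "call": call.call,
                             "boxes": ",".join(sorted(call.boxes))})
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc
    sno_df = pd.DataFrame(sno_rows)
    write_tsv(outdir / "sno_calls.tsv", sno_df)
    manifest["sno_calls"] = "sno_calls.tsv"
    counts = sno_df["call"].value_counts().to_dict() if len(sno_df) else {}
    report.sno_calls = {k: int(v) for k, v in sorted(counts.items())}

    write_report(report, outdir)
    _write_manifest(manifest, outdir)
    return report


def _write_manifest(manifest: Dict[str, str], outdir: Path) -> None:
    with open(Path(outdir) / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
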
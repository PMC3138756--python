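"""Synthetic-study generator: determinism, placement, library and arrays."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from conftest import tiny_config
from isrna.config import ConfigError, SimConfig, largest_remainder
from isrna.seqs import revcomp
from isrna.simulate import (GroundTruth, LocusTruth, SimulationError,
                            make_clone_library, make_conservation_tracks,
                            make_genome_and_annotation, simulate_loop_design,
                            simulate_study, write_fixture)


class TestConfig:
    def test_largest_remainder_reproduces_exact_rationals(self):
        assert largest_remainder([27 / 82, 44 / 82, 11 / 82], 82) == [27, 44, 11]
        assert sum(largest_remainder([0.3, 0.3, 0.4], 7)) == 7

    def test_invalid_mix_rejected(self):
        with pytest.raises(ConfigError, match="sums to"):
            SimConfig(novel_context_mix={"intergenic": 0.5, "sense_intronic": 0.4,
                                         "antisense_intronic": 0.2})

    def test_species_must_start_with_human(self):
        with pytest.raises(ConfigError, match="human first"):
            SimConfig(species_list=("chimp", "human"))


class TestGenomeAndAnnotation:
    def test_seeded_determinism_is_byte_identical(self, tmp_path):
        cfg = tiny_config()
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_fixture(simulate_study(cfg), d1)
        write_fixture(simulate_study(cfg), d2)
        files1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
        assert files1 == files2
        for rel in files1:
            h1 = hashlib.sha256((d1 / rel).read_bytes()).hexdigest()
            h2 = hashlib.sha256((d2 / rel).read_bytes()).hexdigest()
            assert h1 == h2, f"{rel} differs between identically seeded runs"

    def test_context_counts_exact(self, tiny_study):
        ctx = {}
        for l in tiny_study.truth.novel():
            ctx[l.context] = ctx.get(l.context, 0) + 1
        assert ctx == {"intergenic": 4, "sense_intronic": 6,
                       "antisense_intronic": 2}

    def test_pure_sense_intronic_mix_is_contained_in_introns(self):
        cfg = tiny_config(n_novel=8, novel_context_mix={
            "intergenic": 0.0, "sense_intronic": 1.0, "antisense_intronic": 0.0})
        genome, genes, _bed, truth = make_genome_and_annotation(cfg)
        by_gene = {g.gene_id: g for g in genes}
        for l in truth.novel():
            host = by_gene[l.host_gene]
            assert l.strand == host.strand
            assert any(s < l.start and l.end < e for s, e in host.introns())

    def test_novel_loci_avoid_exons_and_known_ncrna(self, tiny_study):
        study = tiny_study
        exons = [(g.chrom, s, e) for g in study.genes for s, e in g.exons]
        known = [(b.chrom, b.start, b.end) for b in study.known_bed]
        for l in study.truth.novel():
            for chrom, s, e in exons + known:
                if chrom == l.chrom:
                    assert min(l.end, e) - max(l.start, s) <= 0

    def test_infeasible_placement_raises_sizing_error(self):
        with pytest.raises((SimulationError, ConfigError)):
            cfg = tiny_config(genome_length=30_000, n_genes=60)
            make_genome_and_annotation(cfg)

    def test_transcript_sequence_is_strand_aware_genome_slice(self, tiny_study):
        study = tiny_study
        for l in study.truth.loci[:20]:
            raw = study.genome[l.chrom][l.start:l.end]
            assert l.sequence == (raw if l.strand == "+" else revcomp(raw))


class TestCloneLibrary:
    def test_reads_are_adapter_flanked_truth_inserts(self, tiny_study):
        study = tiny_study
        cfg, truth = study.cfg, study.truth
        by_id = truth.by_id()
        assert len(study.reads) == len(truth.reads)
        for read_id, seq in study.reads[:50]:
            locus = by_id[truth.reads[read_id]]
            assert seq == cfg.adapter_5 + locus.sequence + cfg.adapter_3

    def test_insert_maps_to_its_source_locus_by_substring_scan(self, tiny_study):
        study = tiny_study
        by_id = study.truth.by_id()
        for read_id, seq in study.reads[:10]:
            insert = seq[len(study.cfg.adapter_5):-len(study.cfg.adapter_3)]
            locus = by_id[study.truth.reads[read_id]]
            chrom = study.genome[locus.chrom]
            fwd = chrom.find(insert)
            rev = chrom.find(revcomp(insert))
            pos = fwd if locus.strand == "+" else rev
            assert pos == locus.start

    def test_read_count_equals_sum_of_clone_counts(self, tiny_study):
        per_locus = {}
        for rid, lid in tiny_study.truth.reads.items():
            per_locus[lid] = per_locus.get(lid, 0) + 1
        assert sum(per_locus.values()) == len(tiny_study.reads)

    def test_single_clone_no_decoys_yields_one_read_per_locus(self):
        cfg = tiny_config(clone_count_p=1.0, clone_count_p_known=1.0,
                          decoy_fraction=0.0)
        genome, genes, _bed, truth = make_genome_and_annotation(cfg)
        reads = make_clone_library(cfg, truth, genes, genome)
        assert len(reads) == len(truth.array_targets())

    def test_empty_locus_set_is_an_error(self):
        cfg = tiny_config()
        truth = GroundTruth(chrom_lengths={"chr1": 1000})
        with pytest.raises(SimulationError, match="no loci"):
            make_clone_library(cfg, truth, [], {"chr1": "A" * 1000})


class TestConservationTracks:
    def test_archetype_means_by_construction(self, tiny_study):
        from isrna.conservation import ScoreTrack, mean_score
        from isrna.loci import GenomicLocus
        study = tiny_study
        tracks = {sp: ScoreTrack(iv) for sp, iv in study.tracks.items()}
        clades = study.cfg.clades
        for l in study.truth.novel():
            locus = GenomicLocus(l.chrom, l.start, l.end, l.strand)
            assert mean_score(locus, tracks["human"]) >= 0.95
            if l.conservation_group == "eutherian":
                for sp in study.cfg.species_list:
                    if clades[sp] == "non_mammal":
                        assert mean_score(locus, tracks[sp]) < 0.2

    def test_noisy_tracks_are_in_unit_interval(self):
        cfg = tiny_config(track_noise_sd=0.15)
        _g, _genes, _bed, truth = make_genome_and_annotation(cfg)
        tracks = make_conservation_tracks(cfg, truth)
        for sp, ivs in tracks.items():
            assert all(0.0 <= s <= 1.0 for _c, _s, _e, s in ivs)


class TestLoopDesign:
    def _one_locus_truth(self, effects):
        locus = LocusTruth("nc001", "chr1", 0, 100, "+", "novel",
                           context="intergenic", sequence="A" * 100,
                           tissue_effects=effects)
        return GroundTruth(loci=[locus], chrom_lengths={"chr1": 1000})

    def test_noiseless_three_cycle_m_values(self):
        cfg = tiny_config(tissues=("s1", "s2", "s3"))
        truth = self._one_locus_truth([-1.0, 0.0, 1.0])
        design, intens = simulate_loop_design(cfg, truth, "tissues")
        m = np.log2(intens["cy5"] / intens["cy3"])
        got = intens.assign(m=m).groupby("array_id")["m"].mean()
        # arrays (s2|s1), (s3|s2), (s1|s3) => M = (1, 1, -2)
        assert got["tissues_a1"] == pytest.approx(1.0, abs=1e-9)
        assert got["tissues_a2"] == pytest.approx(1.0, abs=1e-9)
        assert got["tissues_a3"] == pytest.approx(-2.0, abs=1e-9)

    def test_zero_effects_give_pure_array_offset(self):
        cfg = tiny_config(tissues=("s1", "s2", "s3"), dye_offset_sd=0.3)
        truth = self._one_locus_truth([0.0, 0.0, 0.0])
        _design, intens = simulate_loop_design(cfg, truth, "tissues")
        m = intens.assign(m=np.log2(intens["cy5"] / intens["cy3"]))
        per_array = m.groupby("array_id")["m"]
        assert (per_array.max() - per_array.min()).max() < 1e-9

    def test_each_probe_printed_in_triplicate(self, tiny_study):
        counts = tiny_study.tissue_intensities.groupby(
            ["array_id", "probe_id"]).size()
        assert (counts == 3).all()

    def test_long_transcripts_get_two_probes(self, tiny_study):
        probes = tiny_study.probes
        by_target = probes.groupby("target_id").size()
        lengths = {l.locus_id: l.length for l in tiny_study.truth.array_targets()}
        for target, n in by_target.items():
            assert n == (2 if lengths[target] > 200 else 1)
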
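"""Genomic mapping, annotation-cascade classification, chromosome test."""

import numpy as np
import pytest
from scipy import stats

from isrna.io import BedRecord, GeneModel
from isrna.loci import (AnnotationIndex, GenomeIndex, GenomicLocus,
                        chromosome_distribution_test, classify_locus,
                        map_to_genome, naive_map_oracle, overlap_required)
from isrna.seqs import random_seq, revcomp


class TestMapping:
    def test_forward_hits(self):
        # CGTA occurs forward at [1,5) and [5,9); its reverse complement
        # TACG also occurs at [3,7), reported on the minus strand
        index = GenomeIndex({"chr1": "ACGTACGTAA"})
        hits = map_to_genome("CGTA", index, max_mismatch=0)
        assert [(h.start, h.end, h.strand) for h in hits] == \
            [(1, 5, "+"), (3, 7, "-"), (5, 9, "+")]
        assert hits == naive_map_oracle("CGTA", {"chr1": "ACGTACGTAA"}, 0)

    def test_reverse_complement_hits(self):
        # TACG's reverse complement CGTA sits at [1,5) and [5,9)
        index = GenomeIndex({"chr1": "ACGTACGTAA"})
        hits = map_to_genome("TACG", index, max_mismatch=0)
        assert [(h.start, h.end, h.strand) for h in hits] == \
            [(1, 5, "-"), (3, 7, "+"), (5, 9, "-")]
        assert hits == naive_map_oracle("TACG", {"chr1": "ACGTACGTAA"}, 0)

    def test_whole_chromosome_identity(self):
        rng = np.random.default_rng(0)
        chrom = random_seq(rng, 200)
        index = GenomeIndex({"chr1": chrom})
        hits = map_to_genome(chrom, index, max_mismatch=0)
        assert any(
            (h.chrom, h.start, h.end, h.strand) == ("chr1", 0, 200, "+")
            for h in hits
        )

    def test_unmapped_returns_empty(self):
        index = GenomeIndex({"chr1": "A" * 100})
        assert map_to_genome("C" * 50, index) == []

    def test_seed_path_agrees_with_naive_oracle(self):
        rng = np.random.default_rng(5)
        genome = {"chr1": random_seq(rng, 8000), "chr2": random_seq(rng, 4000)}
        index = GenomeIndex(genome)
        for _ in range(200):
            L = int(rng.integers(50, 121))
            if rng.random() < 0.1:
                q = random_seq(rng, L)
            else:
                chrom = "chr1" if rng.random() < 0.7 else "chr2"
                s = int(rng.integers(0, len(genome[chrom]) - L))
                q = list(genome[chrom][s:s + L])
                for _ in range(int(rng.integers(0, 3))):
                    q[int(rng.integers(L))] = "ACGT"[int(rng.integers(4))]
                q = "".join(q)
                if rng.random() < 0.5:
                    q = revcomp(q)
            assert map_to_genome(q, index, 2) == naive_map_oracle(q, genome, 2)


@pytest.fixture()
def annotation():
    # one + strand gene with 2 exons / 1 intron, and known ncRNAs
    gene = GeneModel("g1", "chr1", 1000, 2000, "+",
                     exons=((1000, 1200), (1800, 2000)))
    gene2 = GeneModel("g2", "chr1", 5000, 6000, "-",
                      exons=((5000, 5200), (5800, 6000)))
    known = [
        BedRecord("chr1", 3000, 3100, "rRNA:rr1", 0, "+"),
        BedRecord("chr1", 3200, 3280, "tRNA:tr1", 0, "+"),
        BedRecord("chr1", 3400, 3500, "snoRNA:sno1", 0, "-"),
    ]
    return AnnotationIndex([gene, gene2], known, {"chr1": 10000, "chr2": 5000})


class TestClassification:
    def test_intergenic_novel(self, annotation):
        c = classify_locus(GenomicLocus("chr1", 8000, 8100, "+"), annotation)
        assert (c.category, c.context, c.host_gene_id) == \
            ("novel", "intergenic", None)

    def test_sense_and_antisense_intronic(self, annotation):
        sense = classify_locus(GenomicLocus("chr1", 1300, 1400, "+"), annotation)
        anti = classify_locus(GenomicLocus("chr1", 1300, 1400, "-"), annotation)
        assert (sense.context, sense.host_gene_id) == ("sense_intronic", "g1")
        assert (anti.context, anti.host_gene_id) == ("antisense_intronic", "g1")

    def test_strand_flip_swaps_only_the_context(self, annotation):
        a = classify_locus(GenomicLocus("chr1", 5300, 5400, "-"), annotation)
        b = classify_locus(GenomicLocus("chr1", 5300, 5400, "+"), annotation)
        assert a.context == "sense_intronic" and b.context == "antisense_intronic"
        assert a.category == b.category == "novel"
        assert a.host_gene_id == b.host_gene_id == "g2"

    def test_precedence_rrna_trna_known_mrna(self, annotation):
        assert classify_locus(
            GenomicLocus("chr1", 3000, 3100, "+"), annotation).category == "rRNA"
        assert classify_locus(
            GenomicLocus("chr1", 3200, 3280, "-"), annotation).category == "tRNA"
        assert classify_locus(
            GenomicLocus("chr1", 3400, 3500, "+"), annotation
        ).category == "known_ncRNA:snoRNA"
        # exon overlap on either strand is mRNA
        assert classify_locus(
            GenomicLocus("chr1", 1000, 1100, "-"), annotation).category == "mRNA"

    def test_partial_gene_overlap_is_other(self, annotation):
        c = classify_locus(GenomicLocus("chr1", 1790, 1810, "+"), annotation,
                           min_overlap=0.9)
        assert (c.category, c.context) == ("novel", "other")

    def test_unknown_chromosome_raises(self, annotation):
        with pytest.raises(ValueError, match="absent"):
            classify_locus(GenomicLocus("chrX", 0, 100, "+"), annotation)


class TestOverlapRequired:
    def test_identical_intervals(self):
        loc = GenomicLocus("chr1", 10, 20, "+")
        assert overlap_required(loc, (10, 20), 1.0)

    def test_fractional_threshold(self):
        loc = GenomicLocus("chr1", 0, 10, "+")
        assert not overlap_required(loc, (6, 20), 0.5)  # 4 bp overlap
        assert overlap_required(loc, (5, 20), 0.5)      # 5 bp overlap

    def test_disjoint(self):
        assert not overlap_required(GenomicLocus("chr1", 0, 10, "+"), (50, 60), 0.1)


class TestChromosomeDistribution:
    def _loci(self, counts):
        return [GenomicLocus(c, 0, 10, "+") for c, n in counts.items()
                for _ in range(n)]

    def test_perfect_fit(self):
        t = chromosome_distribution_test(
            self._loci({"c1": 3, "c2": 1}), {"c1": 75, "c2": 25})
        assert t.statistic == pytest.approx(0.0)
        assert t.p_value == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        t = chromosome_distribution_test(
            self._loci({"c2": 4}), {"c1": 75, "c2": 25})
        # expected (3, 1): (0-3)^2/3 + (4-1)^2/1 = 12
        assert t.statistic == pytest.approx(12.0)
        assert t.df == 1
        assert t.p_value == pytest.approx(float(stats.chi2.sf(12, 1)))

    def test_single_locus_equal_lengths(self):
        t = chromosome_distribution_test(
            self._loci({"c1": 1}), {"c1": 100, "c2": 100})
        assert t.statistic == pytest.approx(1.0)
        assert t.df == 1

    def test_zero_expected_instructs_pooling(self):
        with pytest.raises(ValueError, match="pool"):
            chromosome_distribution_test(
                self._loci({"c1": 1}), {"c1": 100, "c2": 0})

    def test_needs_two_chromosomes_and_a_locus(self):
        with pytest.raises(ValueError):
            chromosome_distribution_test(self._loci({"c1": 1}), {"c1": 100})
        with pytest.raises(ValueError):
            chromosome_distribution_test([], {"c1": 100, "c2": 100})
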
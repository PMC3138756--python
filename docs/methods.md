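# Methods

`isrna` re-creates, at desk scale, the dry-lab half of a cloning-based
survey of intermediate-size noncoding RNAs (is-ncRNAs, 50–500 nt): clone
reads are reduced to unique transcripts, mapped to a genome, classified
against an annotation cascade, scored for cross-species conservation, and
profiled on a two-color loop-design microarray, with host-gene pathway
enrichment and a snoRNA box-motif screen on the side.  Because the package
is exercised on simulated data, this note describes both the analysis models
and what the simulator does and does not emulate.

## Clone processing

A library read is modeled as `5'-adapter + insert + 3'-adapter`.  Trimming
locates each adapter by its best (fewest-mismatch, earliest) occurrence with
a configurable mismatch budget (default 1, because real ligation junctions
are heterogeneous); reads missing either adapter, or whose insert is empty,
are rejected with a reason code that ends up in a rejection log.  Size
selection keeps inserts with 50 ≤ length ≤ 500 inclusive.  Deduplication is
exact-sequence grouping — unique transcripts are not fuzzy clusters;
near-duplicates are left for genomic mapping to resolve.  U is normalized to
T at ingest so everything downstream operates in DNA space.  Clone counts
are conserved by construction: the counts of the unique transcripts always
sum to the number of retained reads.

## Genomic mapping

Mapping is exact-seed / mismatch-extension: `max_mismatch + 1` disjoint
k-mers (k = 16) from the query are looked up in a hash index of the genome
and every candidate placement is verified by full-length Hamming comparison
on both strands.  By pigeonhole, a query carrying at most `max_mismatch`
substitutions must have one clean seed, so the search is exhaustive;
queries too short for that guarantee fall back to a vectorized
sliding-window scan.  Indels are not modeled — clones are genome-derived
fragments.  The default mismatch budget is 2.  Every qualifying placement is
reported (one transcript may map to several loci) and classified
independently.

## Classification cascade

Categories are assigned by first-match precedence: rRNA → tRNA → known
ncRNA class → mRNA exon (either strand) → novel.  Overlap calls require
≥ 50% of the transcript locus to be covered by the feature
(`--min-overlap`, a declared default: any fraction in (0, 1] is accepted).
A novel locus strictly contained in an intron is sense- or
antisense-intronic according to strand agreement with the host gene, which
is recorded; a novel locus overlapping no gene span is intergenic; any other
geometry is `other`.  Chromosome-distribution randomness is checked with a
chi-square test against length-proportional expected counts
(df = #chromosomes − 1); a zero expected count raises an error instructing
the caller to pool short chromosomes.

## Conservation

Each novel locus receives the arithmetic mean of a per-base conservation
score (a PhastCons-style probability) per species; bases without track
coverage score 0, treating absence from the alignment as evidence of
non-conservation.  A species counts as "conserved" when its mean is at
least τ_present = 0.5 — chosen to bisect the conventional strong (0.8) and
weak (0.6) anchors — and the vector is reduced to a group:

* `beyond_eutherian`: ≥ 1 non-mammal conserved;
* `eutherian`: ≥ 1 rodent and ≥ 1 other eutherian conserved ("most
  eutherians" is deliberately relaxed to this one-of-each rule, since no
  quantitative definition exists; the rule is configurable);
* `non_rodent_mammal`: no rodent but ≥ 1 other eutherian conserved;
* `primate_only`: only non-human primates conserved;
* `other`: anything else (e.g. rodent-only patterns).

Human is excluded from the calls.  Raising τ_present can only narrow the
assigned group (monotonicity is property-tested).  Presence/absence of a
transcript in another genome is decided by the best local alignment
(Smith–Waterman, match +1 / mismatch −1 / linear gap −2, via Biopython)
against declared thresholds of 80% identity and 50% query coverage; at
those thresholds a clean copy and a 10%-diverged copy call present while a
30%-diverged copy does not.

## Loop-design expression analysis

Each array co-hybridizes two samples (Cy5/Cy3) and the samples form a
cycle, so all pairwise contrasts are estimable from n arrays for n samples.
Replicate spots (printed in triplicate) are averaged into one
M = log2(Cy5/Cy3) per (array, probe); a robust median alternative sits
behind a flag.  Global median normalization subtracts each array's median M,
absorbing dye/offset effects instead of modeling them as parameters — exact
as long as most probes are unaffected on any one array.  Per-sample effects
µ solve the least-squares problem min Σ_a (M_a − (µ_cy5(a) − µ_cy3(a)))²
subject to Σµ = 0; on a connected design the null space of the incidence
matrix is exactly the constant vector, so the Moore–Penrose solution
enforces the constraint.  Standard errors come from the residual variance
(dof = arrays − (samples − 1)) and diag(pinv(XᵀX)).  Disconnected or
underdetermined designs raise errors naming the problem.  Probe effects are
averaged per transcript (two probes for transcripts > 200 nt).

Calls: a transcript is *distinct* when its maximal pairwise |Δµ| strictly
exceeds τ_fold = 1 log2 unit (>2-fold); *predominant*/*depleted* in a focal
sample when the focal effect beats/trails every other sample by a margin
defaulting to the same 1 log2 unit (no published numeric definition exists;
both knobs are config-exposed).  Display tables mirror the usual
reference-anchored layout: one column of reference-sample effects centered
over transcripts, plus per-sample effects relative to each transcript's own
reference value.  Expression patterns are clustered with average linkage on
1 − Pearson correlation; rows are pre-sorted by transcript id for
deterministic tie-breaking, and zero-variance rows are an error (the
correlation is undefined).  The pipeline therefore clusters only the
distinct-called transcripts — on noiseless fixtures every unaffected
transcript has an exactly constant row.

## Enrichment and motif screen

Host genes of sense-intronic novel loci are tested against gene sets with
the exact upper-tail hypergeometric probability P(X ≥ k), one-sided,
Benjamini–Hochberg adjusted across sets.  The snoRNA screen is a simple
positional box detector: C box RUGAUGA (≤ 1 mismatch) in the 5′ 20 nt,
D box CUGA (exact) starting in the 3′ 10 nt, H box ANANNA in the 40–70%
hinge, ACA exactly 3 nt from the 3′ end; C+D ⇒ CD, H+ACA ⇒ H/ACA, all four
⇒ scaRNA-like.  It deliberately omits terminal-stem folding and target-
duplex scoring, so it is a coarse candidate filter whose false-positive
rate on random sequence is measured, not asserted.

## The simulator

The generator emits a complete study from one seed: a random multi-
chromosome genome (default 2.4 Mb over 4 chromosomes — large enough to
place 400 three-exon genes plus all loci without overlap, small enough to
index in seconds); 218 known is-ncRNA loci (snoRNA/snRNA/misc) plus rRNA
and tRNA removal-class loci; and 82 novel loci split exactly 27 intergenic /
44 sense-intronic / 11 antisense-intronic by largest-remainder
apportionment.  Intronic loci sit strictly inside introns of distinct host
genes; nothing overlaps an exon or a known ncRNA.

Clone counts follow a zero-truncated geometric law, p = 0.7 for novel loci
(most single-clone) and p = 0.12 for known loci (multi-clone,
high-expression); 14% of reads are decoys from mRNA exon fragments and
rRNA/tRNA loci, matching the removal fraction a cascade of this kind is
expected to absorb.  Conservation tracks realize group archetypes with
per-species target means (0.9 conserved-primate, 0.55–0.6 weakly conserved,
0.05 absent, human fixed at 0.98 with no sampling noise) plus optional
per-base Gaussian noise (default sd 0.1, clipped to [0, 1]).  Array
intensities follow M = Δµ + δ_array + ε with ε ~ N(0, 0.3) per replicate
spot and δ ~ N(0, 0.2) per array, converted to two positive channels around
a per-probe baseline; planted >2-fold effects (1.5 log2 on one sample,
centered) are given to 34/82 novel and 46/244-scaled known transcripts for
tissues, and 7/82 and 1/244-scaled for gestation stages.  Four C/D, nine
H/ACA and one scaRNA box arrangement are written into novel locus sequences
(with competing boxes scrubbed), and a six-gene pathway containing four
sense-intronic host genes is planted among 19 random decoy sets.

Not emulated: sequencing errors, chimeric clones, cross-hybridization,
splicing, repeat structure, and real phylogenetic correlation between
species scores.  Passing tests on this generator therefore demonstrate the
correctness of the analysis logic under its stated model, not robustness to
every artifact of real libraries.

## Numerical and scale choices

Coordinates are 0-based half-open internally (BED convention), converted at
the GFF3 boundary.  Determinism: all randomness flows from
`numpy.random.default_rng([seed, stage])`; identical configurations produce
byte-identical files.  The acceptance checks run on deliberately desk-scale
problems — a 300-locus study for end-to-end recovery, a 50 kb genome with
1,000 queries for mapping-oracle equivalence, 200 transcripts × 100
replicates for estimator calibration — sizes at which the independent
oracles (exhaustive scans, integer-rational enumeration, quadratic
alignment) are themselves cheap to run.
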
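# Methods

## References and read classification

Quantifying mature tRNAs from small RNA-seq is hard because a read can
come from a mature tRNA, from an unprocessed (premature) transcript that
still carries flanking genomic sequence, or from anywhere else in the
transcriptome, and because mature tRNAs differ from their genomic loci:
introns are spliced out and a non-templated 3′ `CCA` is added.
`trnaquant` resolves this with two purpose-built references.

**Artificial genome.** Every annotated tRNA gene span is masked to `N`
in the input genome (only the gene body; the flanks stay genomic).
For each gene, one decoy chromosome named `preTRNA::<gene>` is appended:
the unspliced gene oriented 5′→3′ with up to `flank_len = 50` nt of
upstream and downstream flank (truncated at chromosome edges). The
decoy records the upstream flank length and gene length so the pure
gene-body interval is recoverable.

**Mature genome.** One record per gene: the oriented gene span with
introns removed and `CCA` appended. All predicted genes are kept here —
pseudogenes and organellar genes included — so that their reads are
absorbed by their own records instead of contaminating neighbours;
restriction to the cytosolic, high-confidence, non-pseudogene set
happens at counting time.

Round-one hits are classified by reference role: masked chromosome →
*non-tRNA*; decoy with the read fully inside
`[upstream_flank, upstream_flank + gene_len)` → *mature*; decoy with any
flank overlap → *premature*; no hit → *unmapped*. Round two re-aligns
the mature reads plus non-tRNA reads strictly shorter than 30 nt against
the mature genome and tallies best hits per countable gene.

A structural consequence worth knowing: an error-free 3′ fragment that
carries the `CCA` necessarily best-hits the decoy with the `CCA` falling
in the downstream flank (≤ 3 mismatches), is classified premature, and
is dropped — likewise fragments spanning a splice junction of an
intron-bearing gene cannot map contiguously to the intron-retaining
decoy. Both losses are properties of the two-round contract itself, not
of this implementation; the test suite demonstrates them explicitly
(`test_simulate.py::TestRecovery`). They depress absolute counts roughly
uniformly across genes, which is why rank-level recovery stays high.

## Aligner

An internal end-to-end, ungapped, up-to-`k`-mismatch (`k = 3`) best-hit
aligner over both strands. Candidates come from pigeonhole seeding: the
read is split into `k + 1` near-equal segments, at least one of which
must match the reference exactly for any placement with ≤ `k`
mismatches; exact segment lookups in a lazily built q-mer index
enumerate a superset of valid placements, each verified by a full
Hamming count. `N` never matches on either side. Among placements tied
at the minimum mismatch count, one is drawn uniformly using a generator
keyed by `(seed, crc32(read_id))`, so results are independent of batch
order and sequence-identical gene copies receive near-binomial splits
instead of collapsing onto the first reference. The tie-break seed is a
recorded pipeline parameter (default 1715). Unit tests assert exact
agreement with an exhaustive Hamming-scan oracle on randomized reference
sets.

## Annotation parsing and naming

Input annotations use the tRNAscan-SE tabular dialect (1-based inclusive
coordinates, `begin > end` on the minus strand, genomic intron
coordinates, bit score, optional note column). Internally all
coordinates are 0-based half-open; introns are stored gene-local on the
oriented gene. Flags: `pseudo` iff the note contains "pseudo";
`high_confidence` iff the note contains "high confidence" (when no note
column exists, all non-pseudo genes are treated as high-confidence,
matching annotations pre-filtered to the high-confidence set);
non-cytosolic iff the chromosome matches `^(chrM|chrMT|MT|mito)` (case
insensitive) or the sequence name contains `mt-` — chromosome naming is
the only organelle signal such annotations carry.

Names follow the GtRNAdb convention `tRNA-{isotype}-{anticodon}-{group}-{copy}`:
loci with identical (isotype, anticodon, spliced mature sequence) share
a group; groups are numbered per anticodon family by descending maximum
bit score (ties by lexicographic sequence) and copies by (chromosome,
start). The score-then-sequence ordering is this package's documented
convention; the database's own numbering order is not specified anywhere
authoritative.

## Preprocessing

Adapter trimming finds the leftmost position where the adapter (or an
end-anchored prefix of it) matches the read suffix with at most
`floor(0.1 × overlap)` mismatches and overlap ≥ 3; leftmost-match-wins
keeps the shortest insert, which is the safe choice for read-through
libraries. Reads are then discarded whole if shorter than `min_len`
(default 15 nt — shorter reads cannot place uniquely under three
mismatches) or if their mean Phred score falls below the threshold
(25 or 30). The preset adapter sequences (Illumina small RNA 3′
`TGGAATTCTCGGTGGTCGCCGTATCATT`, Illumina universal `AGATCGGAAGAGC`,
SOLiD `CGCCTTGGCCGT`) are conventional defaults and overridable; SOLiD
is treated as a literal sequence, not color space. The QC report
maintains `passed + too_short + low_quality == total` exactly.

## Differential expression

The statistics path mirrors the classic exact-test workflow for count
data, implemented natively and cross-checked against Bioconductor edgeR
on fixed small matrices (TMM factors agree to 1e-8; exact-test p-values
to 1e-9 against `rejection.region = "smallp"`):

- **CPM / prevalence filter:** keep an entity iff CPM ≥ `min_cpm`
  (default 1) in at least `ceil(min_fraction × n_samples)` samples
  (default 0.9 — with 10 samples, 9 passes and 8 fails).
- **TMM:** reference sample = closest upper-quartile to the mean; per
  sample, over genes positive in both columns, trim 30 % two-sided on
  M-values and 5 % on A-values (rank-based), weight retained M by
  inverse delta-method variances `(N−y)/(Ny)` summed over the two
  samples, factor = 2^weighted-mean; factors rescaled to geometric
  mean 1.
- **Common dispersion:** counts are equalized to the geometric-mean
  effective library size (pseudo-counts); conditioning each group on its
  total removes the mean parameter, leaving a dispersion-only
  conditional likelihood summed over genes and groups, maximized
  numerically (bounded Brent over φ ∈ [1e-6, 4]; the lower bound is
  returned when the likelihood is monotone, i.e. no overdispersion
  signal). One shared φ is appropriate at tRNA scale, where few hundred
  entities give per-gene estimates little support.
- **Exact test:** group sums of rounded pseudo-counts are NB with sizes
  `n_g/φ` under the null of a common per-sample mean; conditioning on
  the total `t`, the two-sided p-value sums the probabilities of all
  splits `(a, t−a)` whose probability does not exceed the observed
  split's (the "small-p" rejection region). At φ → 0 the NB convolution
  degenerates to the exact binomial split test, which the tests verify
  by direct enumeration.
- **Adjustment:** Bonferroni and Benjamini–Hochberg (the BH column is
  the FDR); `significant` ⇔ |log2FC| > log2(1.5) and adjusted p < 0.05
  by default. Fold changes use prior-smoothed CPMs (prior count 0.125,
  scaled per sample by relative library size) so zero counts stay
  finite; the control group is the alphabetically first label unless set
  explicitly. No F-statistic is reported: the exact-test path has none,
  and GLM/quasi-likelihood machinery is out of scope.

## Visualization data

MDS uses the leading-log-fold-change distance (root-mean-square of the
`top_k = 500` largest per-gene |log-CPM| differences per sample pair)
followed by classical Torgerson scaling; the top-2 eigenvectors are
scaled by √eigenvalue with the first nonzero loading forced positive for
a deterministic sign. Volcano, anticodon-bar and amino-acid-pyramid
tables are groupings of the DE tables; rendering is a thin matplotlib
layer over those tables, which are the tested surface.

## Synthetic data generator

`simulate_genome` plants non-overlapping tRNA genes (length 70–90 nt,
optional intron of 8–20 nt at ~5 % of genes by default, both strands,
~10 % pseudogenes, ~10 % organellar genes on a `chrM` chromosome) in
uniform-random background and emits the annotation in the exact dialect
the parser consumes. `simulate_reads` draws read origins
mature / premature / non-tRNA (default 0.7 / 0.15 / 0.15); mature reads
are per-gene lognormal-abundance fragments, half 3′-anchored on the
`CCA` by default and otherwise interior to the spliced gene body;
premature reads straddle a flank/gene junction; background reads come
from regions ≥ 1 kb from any gene. Substitution errors (default 0.5 %),
optional adapter read-through and Gaussian quality strings complete the
model. Every read carries its origin, source reference and position, so
recovery is scored exactly. All randomness flows from the mandatory
seed; outputs are byte-identical per config.

What the generator does **not** model — reverse-transcription stops at
modified bases, tRF biogenesis, ligation bias, CCA-vs-CC ends — bounds
what passing tests show: they demonstrate correctness of the mapping,
classification, counting and testing machinery under the stated read
model, not performance on the full complexity of real libraries.

## Benchmark problem sizes and numerical choices

The recovery benchmarks use 50,000 reads over 30 genes (mixed origins)
and 10,000 reads over 20 genes (exact-recovery conditions:
zero error, mature-only, interior fragments, intron-free unique genes —
the regime where count identity is mathematically implied). The
mixed-origin benchmark is run intron-free because junction-read loss is
a documented property of the classification contract (shown separately)
and would otherwise measure the gene composition rather than the
pipeline. Aligner-oracle checks use 20 random two-reference sets of
2 kb × 200 reads of 30 nt. The null-calibration simulation uses 500
genes, 5 vs 5 samples, φ = 0.2. Ties in the aligner are resolved by the
seeded read-keyed RNG; rounding of pseudo-counts is banker's rounding;
the exact test normalizes the NB convolution numerically in log space.

## Limitations

- tRNA-derived fragments are not identified or separated; sub-30 nt tRF
  reads that map inside a gene body are counted as mature signal.
- 3′ `CCA`-carrying fragments and splice-junction fragments are lost to
  the premature/unmapped classes by construction (see above).
- Only single-end reads, two-group designs, and the exact-test path are
  supported; no batch covariates or GLM framework.
- The aligner is strictly ungapped with uniform mismatch costs; no
  quality-aware scoring or indel handling.
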
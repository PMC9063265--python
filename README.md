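# trnaquant

Quantification of **mature tRNA expression from single-end small RNA-seq**,
with two-group differential expression and plot-ready summaries — as a
scriptable Python library and CLI.

Small RNA-seq libraries contain a mixture of reads derived from mature
tRNAs (processed: flanks removed, introns spliced, 3′ `CCA` added),
premature tRNA transcripts (still carrying flanking sequence), and
everything else in the transcriptome. Naive mapping conflates these.
`trnaquant` separates them with a two-round mapping strategy built on
purpose-made references:

1. **Artificial genome** — the input genome with every annotated tRNA gene
   masked to `N`, plus one decoy chromosome per gene carrying the
   unspliced gene with ≤ 50 nt of 5′ and 3′ flank.
2. **Mature tRNA genome** — one record per gene: the spliced gene sequence
   with `CCA` appended.

Round one aligns reads end-to-end, ungapped, with up to three mismatches
and a single best hit (ties broken uniformly at random with a seeded,
read-keyed generator). Reads are classified by where they land:
*non-tRNA* (masked genome), *premature* (any overlap with a decoy flank),
or *mature* (fully inside the pure gene body). Mature reads — plus
non-tRNA reads shorter than 30 nt — are re-aligned against the mature
genome and counted over the cytosolic, high-confidence, non-pseudogene
set. Counts are reported at three levels:

- **individual tRNA** (`tRNA-Ala-AGC-2-1`; loci with identical mature
  sequence share a group index and differ in the final copy index),
- **isodecoder** (`tRNA-Ala-AGC-2` — copy counts merged),
- **isoacceptor** (`tRNA-Ala-AGC` — groups merged).

Differential expression between two groups uses the classic count-based
recipe implemented natively: CPM prevalence filtering (default CPM ≥ 1 in
≥ 90 % of samples), TMM normalization, a common negative-binomial
dispersion estimated by conditional maximum likelihood, a two-sided
exact test on group sums conditioned on the total, and Bonferroni /
Benjamini–Hochberg adjustment. Entities with |fold change| > 1.5 and
adjusted p < 0.05 are flagged significant, and plot-ready tables are
produced for MDS, volcano, per-anticodon bar and per-amino-acid pyramid
views.

A synthetic-data generator (`trnaquant simulate` / `trnaquant.simulate`)
produces toy genomes, tRNAscan-SE-style annotations and labelled read
sets with known ground truth, so the full pipeline is testable without
any download.

## Worked example

```bash
# 1. simulate a toy dataset with known truth
trnaquant simulate --seed 3 --outdir demo --n-genes 8 --n-reads 200

# 2. build the artificial + mature genomes
trnaquant build-genome --genome demo/genome.fa \
    --annotation demo/annotation.tsv --outdir demo/build
# -> "8 premature decoys, 8 mature records -> demo/build"

# 3. preprocess and quantify
trnaquant preprocess --fastq demo/reads.fastq --outdir demo/prep \
    --adapter-preset none
trnaquant quantify --fastq s1 demo/prep/reads.clean.fastq \
    --build-dir demo/build --outdir demo/quant --seed 9
# -> "counted 63 reads -> demo/quant"
```

`demo/quant/counts_individual.tsv` then holds the per-gene counts:

```
# trnaquant v0.1.0 k=3 seed=9 len_threshold=30
name	s1
tRNA-Ala-AGC-1-1	6
tRNA-Arg-CCG-1-1	1
tRNA-Glu-TTC-1-1	30
tRNA-Gly-GCC-1-1	8
...
```

and `class_tally.tsv` shows where the 200 input reads went: 37 non-tRNA,
91 premature, 67 mature in round one (5 unmapped), with 85 reads
selected for round two and 63 counted. Reads overlapping a decoy flank —
including 3′ fragments carrying the `CCA` tail — are classified
premature and excluded; that separation is exactly what the two-round
design exists to make. Aggregated
tables (`counts_isodecoder.tsv`, `counts_isoacceptor.tsv`) always sum to
the same total. The same isodecoder merge is what turns two
sequence-identical gene copies with, say, 551 and 560 reads into an
isodecoder count of 1,111.

For a multi-sample comparison, list samples in a tab-separated sheet
(`sample  group  fastq`) and run `trnaquant run-all --config config.yaml`;
the stages write filtered counts, DE tables (`de_<level>.tsv` with
log2FC, average log2-CPM, raw/Bonferroni/BH p-values and a significance
flag) and the four plot data files.

## Layout

| module | role |
|---|---|
| `trnaquant.annotation` | tRNAscan-SE parsing, GtRNAdb-style naming, mature sequences |
| `trnaquant.genome` | masking, premature decoys, bundle + registry I/O |
| `trnaquant.preprocess` | adapter trimming, quality/length filters, QC report |
| `trnaquant.align` | ungapped k-mismatch best-hit aligner (pigeonhole-seeded) |
| `trnaquant.quantify` | two-round classification, counting, level aggregation |
| `trnaquant.destats` | CPM, prevalence filter, TMM, exact NB test, adjustment |
| `trnaquant.viz` | MDS / volcano / bar / pyramid data and thin renderers |
| `trnaquant.simulate` | synthetic genomes, annotations and labelled reads |
| `trnaquant.pipeline`, `trnaquant.cli` | stage orchestration and CLI |

See `docs/methods.md` for the model details, parameter defaults and known
limitations.
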
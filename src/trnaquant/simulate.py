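"""Synthetic genomes, tRNA annotations and small RNA-seq reads with truth labels.

The generator emulates the read structure a small RNA-seq library shows
around tRNA loci: fragments of mature tRNAs (optionally 3'-anchored so a
fraction carries the CCA tail), premature reads straddling a flank/gene
junction, and background reads from genomic regions far from any tRNA
gene.  Every read carries a truth label (origin and source gene), so
pipeline recovery can be scored exactly.  All randomness flows from the
mandatory seed; identical configs produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import TrnaGene, reverse_complement
from .genome import GenomeBundle

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: (isotype, anticodon) pool used for planted genes
ISOTYPE_POOL = [
    ("Ala", "AGC"), ("Gly", "GCC"), ("Glu", "TTC"), ("Lys", "CTT"),
    ("Arg", "CCG"), ("Val", "AAC"), ("Leu", "CAA"), ("Ser", "AGA"),
    ("Pro", "AGG"), ("Thr", "AGT"), ("Asp", "GTC"), ("Ile", "AAT"),
]


@dataclass(frozen=True)
class SimConfig:
    seed: int
    n_chroms: int = 2
    chrom_len: int = 20_000
    n_genes: int = 30
    gene_len_range: tuple[int, int] = (70, 90)
    intron_prob: float = 0.15
    intron_len_range: tuple[int, int] = (8, 20)
    frac_minus: float = 0.5
    frac_pseudo: float = 0.1
    frac_non_cytosolic: float = 0.1
    identical_copies: int = 0          # genes duplicated with identical sequence
    # read simulation
    n_reads: int = 50_000
    origin_fractions: tuple[float, float, float] = (0.7, 0.15, 0.15)  # mature/premature/non-tRNA
    abundance_log_mu: float = 0.0
    abundance_log_sigma: float = 1.0
    read_len_range: tuple[int, int] = (18, 45)
    three_prime_frac: float = 0.5      # mature fragments anchored at the CCA end
    error_rate: float = 0.005
    adapter: str = "TGGAATTCTCGGTGGTCGCCGTATCATT"
    read_through_prob: float = 0.0
    machine_len: int = 50
    mean_quality: int = 36
    quality_sd: float = 3.0
    background_margin: int = 1000      # min distance of background reads from genes

    def __post_init__(self) -> None:
        if abs(sum(self.origin_fractions) - 1.0) > 1e-9:
            raise ValueError("origin fractions must sum to 1")
        for f in (self.intron_prob, self.frac_minus, self.frac_pseudo,
                  self.frac_non_cytosolic, self.three_prime_frac,
                  self.read_through_prob, *self.origin_fractions):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass
class SimTruth:
    reads: pd.DataFrame        # read_id, origin, gene, source_ref, source_pos
    abundances: pd.Series      # per-gene sampling weight (mature origin)

    def true_counts(self) -> pd.Series:
        """Per-gene mature-origin read counts (sums to n mature reads)."""
        mature = self.reads[self.reads["origin"] == "mature"]
        return mature.groupby("gene").size().reindex(
            self.abundances.index, fill_value=0
        )


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode("ascii")


def simulate_genome(cfg: SimConfig) -> tuple[dict[str, str], str]:
    """Random genome with planted tRNA genes + tRNAscan-SE-style annotation.

    Returns the genome mapping and the annotation text (1-based inclusive
    coordinates, begin > end on the minus strand, genomic intron
    coordinates, bit score, and a note column with pseudo / high
    confidence flags).
    """
    rng = np.random.default_rng(cfg.seed)
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    n_mito = int(round(cfg.frac_non_cytosolic * cfg.n_genes))
    if n_mito:
        chrom_names.append("chrM")
    genome = {name: _random_seq(rng, cfg.chrom_len) for name in chrom_names}

    # place genes in evenly spaced slots per chromosome
    n_nuclear = cfg.n_genes - n_mito
    gene_rows = []
    gi = 0
    nuclear_assigned = 0
    for ci, name in enumerate(chrom_names):
        if name == "chrM":
            n_here = n_mito
        else:
            left = cfg.n_chroms - ci
            n_here = (n_nuclear - nuclear_assigned + left - 1) // left
            nuclear_assigned += n_here
        if n_here == 0:
            continue
        slot = cfg.chrom_len // n_here
        for j in range(n_here):
            glen = int(rng.integers(cfg.gene_len_range[0], cfg.gene_len_range[1] + 1))
            intron: tuple[int, int] | None = None
            if rng.random() < cfg.intron_prob:
                ilen = int(rng.integers(*cfg.intron_len_range))
                ipos = int(rng.integers(30, min(45, glen - ilen - 10)))
                intron = (ipos, ipos + ilen)
                glen += ilen
            lo = j * slot + 60
            hi = (j + 1) * slot - glen - 60
            if hi <= lo:
                raise ValueError("infeasible packing: chromosome too short for genes")
            start = int(rng.integers(lo, hi))
            strand = "-" if rng.random() < cfg.frac_minus else "+"
            iso, ac = ISOTYPE_POOL[gi % len(ISOTYPE_POOL)]
            pseudo = rng.random() < cfg.frac_pseudo
            score = float(np.round(rng.uniform(20, 40) if pseudo else rng.uniform(50, 90), 1))
            gene_rows.append(
                dict(chrom=name, start=start, glen=glen, strand=strand,
                     isotype=iso, anticodon=ac, intron=intron,
                     score=score, pseudo=pseudo)
            )
            gi += 1

    # identical copies: overwrite the genomic span of the copy with the
    # original's span so spliced mature sequences match exactly
    arrays = {n: bytearray(s, "ascii") for n, s in genome.items()}
    n_copies = min(cfg.identical_copies, len(gene_rows) // 2)
    for c in range(n_copies):
        src, dst = gene_rows[2 * c], gene_rows[2 * c + 1]
        if src["chrom"] == "chrM" or dst["chrom"] == "chrM":
            continue
        span = arrays[src["chrom"]][src["start"] : src["start"] + src["glen"]]
        if src["strand"] != dst["strand"]:
            span = bytearray(
                reverse_complement(span.decode("ascii")).encode("ascii")
            )
        dst.update(glen=src["glen"], intron=src["intron"],
                   isotype=src["isotype"], anticodon=src["anticodon"],
                   pseudo=src["pseudo"])
        if dst["strand"] == "-" and src["strand"] == "+":
            pass  # span already reverse-complemented above
        arrays[dst["chrom"]][dst["start"] : dst["start"] + dst["glen"]] = span
    genome = {n: a.decode("ascii") for n, a in arrays.items()}

    lines = []
    for i, g in enumerate(gene_rows, start=1):
        start, glen = g["start"], g["glen"]
        if g["strand"] == "+":
            begin, end = start + 1, start + glen
        else:
            begin, end = start + glen, start + 1
        ib = ie = 0
        if g["intron"] is not None:
            ilo, ihi = g["intron"]  # local to oriented gene, half-open
            if g["strand"] == "+":
                ib, ie = start + ilo + 1, start + ihi
            else:
                ib, ie = start + glen - ilo, start + glen - ihi + 1
        note = "pseudo" if g["pseudo"] else "high confidence set"
        lines.append(
            f"{g['chrom']}\t{i}\t{begin}\t{end}\t{g['isotype']}\t"
            f"{g['anticodon']}\t{ib}\t{ie}\t{g['score']}\t{note}"
        )
    header = (
        "Sequence\ttRNA#\tBegin\tEnd\tType\tCodon\tIntron-Begin\tIntron-End\tScore\tNote\n"
        "--------\t-----\t-----\t---\t----\t-----\t------------\t----------\t-----\t----\n"
    )
    return genome, header + "\n".join(lines) + ("\n" if lines else "")


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def _quality_string(rng: np.random.Generator, n: int, mean: int, sd: float) -> str:
    q = np.clip(np.round(rng.normal(mean, sd, size=n)), 2, 40).astype(int)
    return "".join(chr(v + 33) for v in q)


def _background_windows(
    genome: Mapping[str, str], genes: list[TrnaGene], margin: int, min_len: int
) -> list[tuple[str, int, int]]:
    windows = []
    for chrom, seq in genome.items():
        spans = sorted(
            (g.start - margin, g.end + margin) for g in genes if g.chrom == chrom
        )
        cursor = 0
        for lo, hi in spans + [(len(seq), len(seq))]:
            if lo - cursor >= min_len:
                windows.append((chrom, cursor, lo))
            cursor = max(cursor, hi)
    return windows


def simulate_reads(
    bundle: GenomeBundle,
    genome: Mapping[str, str],
    genes: list[TrnaGene],
    cfg: SimConfig,
    abundances: pd.Series | None = None,
) -> tuple[str, SimTruth]:
    """Simulate a FASTQ (returned as text) plus per-read truth labels.

    Mature reads are fragments of mature reference sequences (a
    configurable fraction anchored at the 3' end so they cover the CCA);
    premature reads straddle a flank/gene junction of a decoy record;
    background reads come from genomic windows at least
    ``background_margin`` away from every gene.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    mature = dict(bundle.mature_records)
    gene_names = [g.name for g in genes]
    if abundances is None:
        weights = rng.lognormal(cfg.abundance_log_mu, cfg.abundance_log_sigma,
                                size=len(gene_names))
        abundances = pd.Series(weights, index=gene_names)
    probs = (abundances / abundances.sum()).to_numpy()
    premature = {r.name: r for r in bundle.premature_records}
    pre_names = [r.name for r in bundle.premature_records]
    backgrounds = _background_windows(
        genome, genes, cfg.background_margin, cfg.read_len_range[1] + 1
    )
    f_mat, f_pre, f_bg = cfg.origin_fractions
    if f_bg > 0 and not backgrounds:
        raise ValueError("no background window far enough from genes")
    origins = rng.choice(
        ["mature", "premature", "non_trna"], size=cfg.n_reads, p=[f_mat, f_pre, f_bg]
    )
    lo_len, hi_len = cfg.read_len_range
    fastq_parts: list[str] = []
    rows = []
    for i in range(cfg.n_reads):
        origin = origins[i]
        read_len = int(rng.integers(lo_len, hi_len + 1))
        if origin == "mature":
            gene = gene_names[int(rng.choice(len(gene_names), p=probs))]
            src = mature[gene]
            read_len = min(read_len, len(src))
            if rng.random() < cfg.three_prime_frac:
                # 3'-anchored fragment carrying the CCA tail
                pos = len(src) - read_len
            else:
                # interior fragment of the spliced gene body (never the CCA)
                body = len(src) - 3
                pos = int(rng.integers(0, max(1, body - read_len + 1)))
            insert = src[pos : pos + read_len]
            source_ref = gene
        elif origin == "premature":
            ref = pre_names[int(rng.integers(len(pre_names)))]
            rec = premature[ref]
            junctions = []
            if rec.upstream_flank_len > 0:
                junctions.append(rec.upstream_flank_len)
            if rec.downstream_flank_len > 0:
                junctions.append(rec.upstream_flank_len + rec.gene_len)
            if not junctions:
                junctions = [0]
            junction = int(junctions[int(rng.integers(len(junctions)))])
            read_len = min(read_len, len(rec.seq))
            # window must cover bases on both sides of the junction
            lo = max(0, junction - read_len + 1)
            hi = min(junction - 1, len(rec.seq) - read_len)
            pos = int(rng.integers(lo, hi + 1)) if hi >= lo else lo
            insert = rec.seq[pos : pos + read_len]
            gene = rec.name.split("::", 1)[1]
            source_ref = ref
        else:
            chrom, wlo, whi = backgrounds[int(rng.integers(len(backgrounds)))]
            pos = int(rng.integers(wlo, whi - read_len))
            insert = genome[chrom][pos : pos + read_len]
            if rng.random() < 0.5:
                insert = reverse_complement(insert)
            gene = ""
            source_ref = chrom
        insert = _apply_errors(rng, insert, cfg.error_rate)
        if cfg.read_through_prob > 0 and rng.random() < cfg.read_through_prob:
            insert = (insert + cfg.adapter)[: cfg.machine_len]
        read_id = f"read{i:06d}"
        qual = _quality_string(rng, len(insert), cfg.mean_quality, cfg.quality_sd)
        fastq_parts.append(f"@{read_id}\n{insert}\n+\n{qual}\n")
        rows.append(
            dict(read_id=read_id, origin=origin, gene=gene,
                 source_ref=source_ref, source_pos=pos)
        )
    truth = SimTruth(
        reads=pd.DataFrame(rows, columns=["read_id", "origin", "gene",
                                          "source_ref", "source_pos"]),
        abundances=abundances,
    )
    return "".join(fastq_parts), truth
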
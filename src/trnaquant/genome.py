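"""Artificial-genome construction for mature tRNA quantification.

The artificial genome is the input genome with every annotated tRNA gene
span masked to ``N``, plus one additional decoy chromosome per gene
carrying the unspliced (premature) gene sequence with up to 50 nt of 5'
and 3' flanking sequence, oriented to the gene strand.  The mature tRNA
genome holds one record per gene: the spliced gene sequence with a 3'
``CCA`` tail.  A registry maps every reference name to its role
(genomic / premature / mature) and owning gene, so downstream read
classification can key on reference names alone.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import TrnaGene, extract_mature_sequence, reverse_complement

#: reserved prefix for premature decoy chromosome names
PREMATURE_PREFIX = "preTRNA::"

ROLE_GENOMIC = "genomic"
ROLE_PREMATURE = "premature"
ROLE_MATURE = "mature"


@dataclass(frozen=True)
class FlankParams:
    """Flank length (nt) added on each side of the gene in the decoy record."""

    flank_len: int = 50

    def __post_init__(self) -> None:
        if self.flank_len < 0:
            raise ValueError("flank_len must be >= 0")


@dataclass(frozen=True)
class PrematureRecord:
    name: str
    seq: str
    upstream_flank_len: int
    gene_len: int

    @property
    def downstream_flank_len(self) -> int:
        return len(self.seq) - self.upstream_flank_len - self.gene_len


@dataclass(frozen=True)
class RegistryEntry:
    role: str
    gene_name: str = ""
    upstream_flank_len: int = 0
    gene_len: int = 0
    isotype: str = ""
    anticodon: str = ""
    high_confidence: bool = True
    cytosolic: bool = True
    pseudo: bool = False


@dataclass
class GenomeBundle:
    """Masked genome + premature decoys + mature reference + name registry."""

    masked_chroms: dict[str, str]
    premature_records: list[PrematureRecord]
    mature_records: list[tuple[str, str]]
    registry: dict[str, RegistryEntry]

    @property
    def artificial_references(self) -> list[tuple[str, str]]:
        refs = [(name, seq) for name, seq in self.masked_chroms.items()]
        refs += [(r.name, r.seq) for r in self.premature_records]
        return refs


def mask_genome(
    genome: Mapping[str, str], genes: Iterable[TrnaGene]
) -> dict[str, str]:
    """Replace every annotated gene span with N; everything else untouched."""
    arrays = {name: bytearray(seq, "ascii") for name, seq in genome.items()}
    for g in genes:
        if g.end > len(arrays[g.chrom]):
            raise ValueError(f"gene {g.name or g.chrom} extends beyond chromosome")
        arrays[g.chrom][g.start : g.end] = b"N" * (g.end - g.start)
    return {name: arr.decode("ascii") for name, arr in arrays.items()}


def build_premature_library(
    genes: Iterable[TrnaGene],
    genome: Mapping[str, str],
    params: FlankParams = FlankParams(),
) -> list[PrematureRecord]:
    """One decoy record per gene: 5' flank + unspliced gene + 3' flank.

    Flanks are truncated at chromosome edges; the record is oriented to the
    gene strand, so ``upstream_flank_len`` is always the 5' (leading) flank.
    """
    records = []
    f = params.flank_len
    for g in genes:
        chrom = genome[g.chrom]
        left = min(f, g.start)
        right = min(f, len(chrom) - g.end)
        seq = chrom[g.start - left : g.end + right].upper()
        if g.strand == "-":
            seq = reverse_complement(seq)
            upstream = right
        else:
            upstream = left
        records.append(
            PrematureRecord(
                name=PREMATURE_PREFIX + g.name,
                seq=seq,
                upstream_flank_len=upstream,
                gene_len=g.length,
            )
        )
    return records


def build_bundle(
    genome: Mapping[str, str],
    genes: list[TrnaGene],
    params: FlankParams = FlankParams(),
) -> GenomeBundle:
    """Assemble the artificial genome, mature genome and registry.

    The mature reference keeps every predicted gene (pseudo and organellar
    included); restriction to the cytosolic high-confidence set happens at
    counting time so that excluded genes still absorb their own reads.
    """
    for g in genes:
        if not g.name:
            raise ValueError("genes must be named before bundling")
    masked = mask_genome(genome, genes)
    premature = build_premature_library(genes, genome, params)
    registry: dict[str, RegistryEntry] = {
        name: RegistryEntry(role=ROLE_GENOMIC) for name in genome
    }
    for rec, g in zip(premature, genes):
        if rec.name in genome:
            raise ValueError(f"premature record name collides with chromosome: {rec.name}")
        registry[rec.name] = RegistryEntry(
            role=ROLE_PREMATURE, gene_name=g.name,
            upstream_flank_len=rec.upstream_flank_len, gene_len=rec.gene_len,
            isotype=g.isotype, anticodon=g.anticodon,
            high_confidence=g.high_confidence, cytosolic=g.cytosolic, pseudo=g.pseudo,
        )
    mature = []
    for g in genes:
        seq = extract_mature_sequence(g, genome)
        mature.append((g.name, seq))
        registry[g.name] = RegistryEntry(
            role=ROLE_MATURE, gene_name=g.name, gene_len=len(seq),
            isotype=g.isotype, anticodon=g.anticodon,
            high_confidence=g.high_confidence, cytosolic=g.cytosolic, pseudo=g.pseudo,
        )
    return GenomeBundle(
        masked_chroms=masked,
        premature_records=premature,
        mature_records=mature,
        registry=registry,
    )


# ---------------------------------------------------------------------------
# I/O

def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


_REGISTRY_COLS = [
    "ref_name", "role", "gene_name", "upstream_flank_len", "gene_len",
    "isotype", "anticodon", "high_confidence", "cytosolic", "pseudo",
]


def write_registry(registry: Mapping[str, RegistryEntry], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_REGISTRY_COLS)
        for name, e in registry.items():
            w.writerow([
                name, e.role, e.gene_name, e.upstream_flank_len, e.gene_len,
                e.isotype, e.anticodon, int(e.high_confidence),
                int(e.cytosolic), int(e.pseudo),
            ])


def read_registry(path: str | Path) -> dict[str, RegistryEntry]:
    registry = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            registry[row["ref_name"]] = RegistryEntry(
                role=row["role"], gene_name=row["gene_name"],
                upstream_flank_len=int(row["upstream_flank_len"]),
                gene_len=int(row["gene_len"]),
                isotype=row["isotype"], anticodon=row["anticodon"],
                high_confidence=bool(int(row["high_confidence"])),
                cytosolic=bool(int(row["cytosolic"])),
                pseudo=bool(int(row["pseudo"])),
            )
    return registry


def write_genes_table(genes: Iterable[TrnaGene], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow([
            "name", "chrom", "start", "end", "strand", "isotype", "anticodon",
            "introns", "score", "pseudo", "high_confidence", "cytosolic",
        ])
        for g in genes:
            w.writerow([
                g.name, g.chrom, g.start, g.end, g.strand, g.isotype, g.anticodon,
                ";".join(f"{s}-{e}" for s, e in g.introns), g.score,
                int(g.pseudo), int(g.high_confidence), int(g.cytosolic),
            ])
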
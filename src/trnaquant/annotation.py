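"""tRNA gene annotation: parsing, naming, and mature-sequence extraction.

Annotations arrive in the tabular dialect emitted by tRNAscan-SE: one row
per predicted gene with 1-based inclusive coordinates, ``begin > end``
encoding the minus strand, intron coordinates in the same genomic frame
(0 when absent), a covariance-model bit score, and an optional free-text
note column carrying "pseudo" / "high confidence" flags.

Internally everything is 0-based half-open on the + reference frame;
intron coordinates are stored gene-local on the oriented (5'->3') gene.

Genes are named GtRNAdb-style, ``tRNA-{isotype}-{anticodon}-{group}-{copy}``:
loci sharing an isotype, anticodon and spliced mature sequence share a
group index, and the trailing copy index distinguishes genomic locations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: chromosome names treated as organellar (non-cytosolic)
_MITO_CHROM = re.compile(r"^(chrM|chrMT|MT|mito)", re.IGNORECASE)

_NAME_RE = re.compile(
    r"^tRNA-(?P<isotype>[A-Za-z]{3}|iMet|fMet)-(?P<anticodon>[A-Z]{3})"
    r"-(?P<group>\d+)-(?P<copy>\d+)$"
)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TrnaGene:
    """One annotated tRNA locus.

    Coordinates are 0-based half-open on the + strand of ``chrom``;
    ``introns`` are half-open intervals local to the oriented gene.
    """

    chrom: str
    start: int
    end: int
    strand: str
    isotype: str
    anticodon: str
    introns: tuple[tuple[int, int], ...] = ()
    score: float = 0.0
    pseudo: bool = False
    high_confidence: bool = True
    cytosolic: bool = True
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid gene span [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        glen = self.end - self.start
        prev_end = -1
        for istart, iend in self.introns:
            if not (0 <= istart < iend <= glen):
                raise ValueError(f"intron ({istart}, {iend}) outside gene of length {glen}")
            if istart <= prev_end:
                raise ValueError("introns must be sorted and pairwise disjoint")
            prev_end = iend

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def mature_length(self) -> int:
        return self.length - sum(e - s for s, e in self.introns) + 3


def parse_gene_name(name: str) -> tuple[str, str, int, int]:
    """Split ``tRNA-Ala-AGC-2-1`` into (isotype, anticodon, group, copy)."""
    m = _NAME_RE.match(name)
    if m is None:
        raise ValueError(f"unparseable tRNA gene name: {name!r}")
    return (m["isotype"], m["anticodon"], int(m["group"]), int(m["copy"]))


def isodecoder_key(name: str) -> str:
    """Drop the copy field: tRNA-Ala-AGC-2-1 -> tRNA-Ala-AGC-2."""
    iso, ac, group, _ = parse_gene_name(name)
    return f"tRNA-{iso}-{ac}-{group}"


def isoacceptor_key(name: str) -> str:
    """Drop group and copy: tRNA-Ala-AGC-2-1 -> tRNA-Ala-AGC."""
    iso, ac, _, _ = parse_gene_name(name)
    return f"tRNA-{iso}-{ac}"


class AnnotationError(ValueError):
    """Raised for a malformed annotation row, carrying the line number."""


def _to_local(pos_1based: int, gene_start: int, gene_end: int, strand: str) -> int:
    """Map a 1-based genomic coordinate to a 0-based oriented gene-local offset."""
    g = pos_1based - 1
    if strand == "+":
        return g - gene_start
    return gene_end - 1 - g


def parse_trna_annotation(
    lines: Iterable[str], genome: Mapping[str, str]
) -> list[TrnaGene]:
    """Parse tRNAscan-SE tabular annotation rows into :class:`TrnaGene` records.

    Header lines beginning with ``Sequence``, ``Name`` or ``----`` are
    skipped.  Rows with a non-numeric coordinate, ``begin == end``, an
    unknown chromosome or a malformed anticodon raise
    :class:`AnnotationError` naming the offending line.
    """
    genes: list[TrnaGene] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.lstrip().startswith(("Sequence", "Name", "----")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 9:
            raise AnnotationError(f"line {lineno}: expected >=9 columns, got {len(fields)}")
        chrom = fields[0].strip()
        try:
            begin, end = int(fields[2]), int(fields[3])
            ibegin, iend = int(fields[6]), int(fields[7])
            score = float(fields[8])
        except ValueError as exc:
            raise AnnotationError(f"line {lineno}: non-numeric field ({exc})") from None
        if chrom not in genome:
            raise AnnotationError(f"line {lineno}: chromosome {chrom!r} absent from genome")
        if begin == end:
            raise AnnotationError(f"line {lineno}: begin == end ({begin})")
        isotype = fields[4].strip()
        anticodon = fields[5].strip().upper()
        if len(anticodon) != 3:
            raise AnnotationError(f"line {lineno}: anticodon {anticodon!r} not length 3")
        strand = "+" if begin < end else "-"
        start = begin - 1 if strand == "+" else end - 1
        gend = end if strand == "+" else begin
        if gend > len(genome[chrom]):
            raise AnnotationError(f"line {lineno}: gene end {gend} beyond {chrom} length")
        introns: tuple[tuple[int, int], ...] = ()
        if ibegin != 0 and iend != 0:
            lo = _to_local(ibegin, start, gend, strand)
            hi = _to_local(iend, start, gend, strand)
            if lo > hi:
                lo, hi = hi, lo
            introns = ((lo, hi + 1),)
        note = " ".join(fields[9:]).lower() if len(fields) > 9 else ""
        has_note = len(fields) > 9
        pseudo = "pseudo" in note
        high_conf = ("high confidence" in note) if has_note else not pseudo
        cytosolic = not (_MITO_CHROM.match(chrom) or "mt-" in fields[0].lower())
        try:
            genes.append(
                TrnaGene(
                    chrom=chrom, start=start, end=gend, strand=strand,
                    isotype=isotype, anticodon=anticodon, introns=introns,
                    score=score, pseudo=pseudo, high_confidence=high_conf,
                    cytosolic=cytosolic,
                )
            )
        except ValueError as exc:
            raise AnnotationError(f"line {lineno}: {exc}") from None
    return genes


def extract_mature_sequence(gene: TrnaGene, genome: Mapping[str, str]) -> str:
    """Mature sequence: oriented gene span, introns spliced out, 3' CCA appended."""
    span = genome[gene.chrom][gene.start : gene.end].upper()
    if gene.strand == "-":
        span = reverse_complement(span)
    pieces, cursor = [], 0
    for istart, iend in gene.introns:
        pieces.append(span[cursor:istart])
        cursor = iend
    pieces.append(span[cursor:])
    return "".join(pieces) + "CCA"


def assign_gtrnadb_names(
    genes: list[TrnaGene], genome: Mapping[str, str]
) -> list[TrnaGene]:
    """Assign GtRNAdb-style names; pre-existing names are preserved verbatim.

    Groups (loci with identical isotype, anticodon and spliced mature
    sequence) are numbered per (isotype, anticodon) by descending max bit
    score, ties broken by lexicographic mature sequence; copies within a
    group are numbered by (chrom, start).
    """
    mature = {id(g): extract_mature_sequence(g, genome) for g in genes}
    by_family: dict[tuple[str, str], dict[str, list[TrnaGene]]] = {}
    for g in genes:
        by_family.setdefault((g.isotype, g.anticodon), {}).setdefault(
            mature[id(g)], []
        ).append(g)

    named: dict[int, str] = {}
    for (iso, ac), groups in by_family.items():
        ordered = sorted(
            groups.items(), key=lambda kv: (-max(g.score for g in kv[1]), kv[0])
        )
        for gi, (_, members) in enumerate(ordered, start=1):
            for ci, g in enumerate(sorted(members, key=lambda g: (g.chrom, g.start)), start=1):
                named[id(g)] = f"tRNA-{iso}-{ac}-{gi}-{ci}"
    return [g if g.name else replace(g, name=named[id(g)]) for g in genes]
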
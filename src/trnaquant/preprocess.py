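"""Adapter trimming and quality/length filtering of single-end small RNA-seq.

Small RNA inserts are shorter than the sequencing read, so the 3' adapter
is usually read through; trimming removes the adapter suffix.  Reads are
then discarded whole if they fall below a minimum length or a minimum
mean Phred quality.  The QC report keeps the four quantities users need
to judge a library: total reads, adapter-matched reads, too-short reads,
and reads passing all filters (low-quality is reported as well, and
passed + too_short + low_quality == total always holds).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, TextIO

#: Conventional default adapter sequences per preset (overridable).
ADAPTER_PRESETS = {
    "illumina_small_rna_3p": "TGGAATTCTCGGTGGTCGCCGTATCATT",
    "illumina_universal": "AGATCGGAAGAGC",
    "solid": "CGCCTTGGCCGT",
    "none": "",
}


@dataclass(frozen=True)
class RawRead:
    read_id: str
    seq: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.quals):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")


@dataclass
class QcReport:
    total: int = 0
    adapter_matched: int = 0
    too_short: int = 0
    low_quality: int = 0
    passed: int = 0

    def check(self) -> None:
        assert self.passed + self.too_short + self.low_quality == self.total

    def to_tsv(self) -> str:
        rows = [
            ("total", self.total),
            ("adapter_matched", self.adapter_matched),
            ("too_short", self.too_short),
            ("low_quality", self.low_quality),
            ("passed", self.passed),
        ]
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


@dataclass(frozen=True)
class PreprocessParams:
    adapter_preset: str = "illumina_small_rna_3p"
    adapter_seq: str | None = None   # overrides the preset when given
    min_quality: int = 25            # mean Phred threshold (25 or 30)
    min_len: int = 15
    min_overlap: int = 3
    max_mismatch_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if self.adapter_preset not in ADAPTER_PRESETS:
            raise ValueError(f"unknown adapter preset {self.adapter_preset!r}")

    @property
    def adapter(self) -> str:
        if self.adapter_seq is not None:
            return self.adapter_seq
        return ADAPTER_PRESETS[self.adapter_preset]


def trim_adapter(
    read: RawRead,
    adapter: str,
    min_overlap: int = 3,
    max_mismatch_rate: float = 0.1,
) -> tuple[RawRead, bool]:
    """Trim a 3' adapter occurrence from ``read``.

    Scans left to right for the first position ``i`` at which the adapter
    (or an end-anchored prefix of it, for adapters running off the read
    end) matches ``read.seq[i:]`` with at most
    ``floor(max_mismatch_rate * overlap)`` mismatches and overlap >=
    ``min_overlap``.  The leftmost match wins, which keeps the shortest
    insert and is robust to adapter read-through.
    """
    seq = read.seq
    n, m = len(seq), len(adapter)
    if m == 0:
        return read, False
    for i in range(0, n - min_overlap + 1):
        overlap = min(m, n - i)
        allowed = int(max_mismatch_rate * overlap)
        mismatches = 0
        for a, b in zip(seq[i : i + overlap], adapter[:overlap]):
            if a != b:
                mismatches += 1
                if mismatches > allowed:
                    break
        else:
            return RawRead(read.read_id, seq[:i], read.quals[:i]), True
    return read, False


def passes_quality(read: RawRead, min_quality: int) -> bool:
    """Whole-read filter: mean Phred score >= threshold (empty reads fail)."""
    if not read.quals:
        return False
    return sum(read.quals) / len(read.quals) >= min_quality


# ---------------------------------------------------------------------------
# FASTQ I/O (Phred+33, gzip-transparent)

class FastqError(ValueError):
    pass


def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def parse_fastq(handle: TextIO) -> Iterator[RawRead]:
    record_idx = 0
    while True:
        header = handle.readline()
        if not header:
            return
        if not header.startswith("@"):
            raise FastqError(f"record {record_idx}: header does not start with '@'")
        seq = handle.readline().rstrip("\n")
        plus = handle.readline()
        qual = handle.readline().rstrip("\n")
        if not qual and not plus:
            raise FastqError(f"record {record_idx}: truncated record")
        if not plus.startswith("+"):
            raise FastqError(f"record {record_idx}: missing '+' separator")
        if len(seq) != len(qual):
            raise FastqError(f"record {record_idx}: sequence/quality length mismatch")
        yield RawRead(
            read_id=header[1:].split()[0] if len(header) > 1 else "",
            seq=seq.upper(),
            quals=tuple(ord(c) - 33 for c in qual),
        )
        record_idx += 1


def format_fastq(read: RawRead) -> str:
    quals = "".join(chr(q + 33) for q in read.quals)
    return f"@{read.read_id}\n{read.seq}\n+\n{quals}\n"


def preprocess_reads(
    reads: Iterable[RawRead], params: PreprocessParams
) -> tuple[list[RawRead], QcReport]:
    """Trim + filter an in-memory read iterable; returns passed reads + QC."""
    report = QcReport()
    adapter = params.adapter
    passed: list[RawRead] = []
    for read in reads:
        report.total += 1
        if adapter:
            read, matched = trim_adapter(
                read, adapter, params.min_overlap, params.max_mismatch_rate
            )
            if matched:
                report.adapter_matched += 1
        if len(read.seq) < params.min_len:
            report.too_short += 1
        elif not passes_quality(read, params.min_quality):
            report.low_quality += 1
        else:
            report.passed += 1
            passed.append(read)
    report.check()
    return passed, report


def preprocess_fastq(
    in_path: str | Path,
    out_path: str | Path,
    params: PreprocessParams = PreprocessParams(),
) -> QcReport:
    """File-to-file preprocessing driver; writes passed reads as FASTQ."""
    with _open_text(in_path) as fin:
        passed, report = preprocess_reads(parse_fastq(fin), params)
    with _open_text(out_path, "wt") as fout:
        for read in passed:
            fout.write(format_fastq(read))
    return report
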
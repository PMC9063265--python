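"""Ungapped end-to-end best-hit aligner with up to k mismatches.

The contract mirrors a bowtie ``-v 3 --best`` run: every end-to-end
ungapped placement of the read on either strand of every reference is a
candidate; the hit with the fewest mismatches (Hamming distance) wins,
provided it has at most ``k`` mismatches; ties within the best stratum
are broken uniformly at random with a generator keyed per read id, so
batch order never changes a read's placement.  ``N`` never matches:
reference ``N`` mismatches every read base, and read ``N`` mismatches
every reference base.

Candidates are found by pigeonhole seeding: a read with at most ``k``
mismatches must contain at least one of ``k + 1`` contiguous segments
matching the reference exactly, so exact lookups of the segments in a
q-mer index enumerate a superset of all valid placements, each of which
is then verified by a full Hamming count.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .annotation import reverse_complement

# Encoding: reference N -> 1, read N -> 2 so N never equals anything it
# is compared against; ACGT map to distinct codes shared by both sides.
_REF_CODE = np.zeros(256, dtype=np.uint8)
_READ_CODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _REF_CODE[_b] = _i + 3
    _READ_CODE[_b] = _i + 3
_REF_CODE[ord("N")] = 1
_READ_CODE[ord("N")] = 2


def _encode(seq: str, table: np.ndarray) -> np.ndarray:
    return table[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class AlignmentHit:
    read_id: str
    ref_name: str
    pos: int          # 0-based leftmost base of the read on the + strand
    strand: str       # '+' or '-'
    mismatches: int
    read_len: int


class RefIndex:
    """Concatenated reference sequences with lazy per-q exact q-mer lookup."""

    def __init__(self, references: Iterable[tuple[str, str]]):
        refs = list(references)
        if not refs:
            raise ValueError("empty reference set")
        self.names = [name for name, _ in refs]
        self.lengths = np.array([len(seq) for _, seq in refs], dtype=np.int64)
        # reference starts within the concatenation
        self.starts = np.concatenate([[0], np.cumsum(self.lengths)])
        self.seq = _encode("".join(seq for _, seq in refs), _REF_CODE)
        self._qmer_cache: dict[int, dict[bytes, np.ndarray]] = {}

    @property
    def total_length(self) -> int:
        return int(self.starts[-1])

    def _qmer_index(self, q: int) -> dict[bytes, np.ndarray]:
        idx = self._qmer_cache.get(q)
        if idx is None:
            buckets: dict[bytes, list[int]] = {}
            data = self.seq.tobytes()
            n = len(data)
            for p in range(n - q + 1):
                kmer = data[p : p + q]
                if 1 in kmer or 2 in kmer:  # skip q-mers containing N
                    continue
                buckets.setdefault(kmer, []).append(p)
            idx = {k: np.array(v, dtype=np.int64) for k, v in buckets.items()}
            self._qmer_cache[q] = idx
        return idx

    def locate(self, concat_pos: int) -> tuple[int, int]:
        """Map a concatenation offset to (reference index, local offset)."""
        ri = int(np.searchsorted(self.starts, concat_pos, side="right")) - 1
        return ri, concat_pos - int(self.starts[ri])


def build_index(references: Iterable[tuple[str, str]]) -> RefIndex:
    return RefIndex(references)


def _segment_bounds(read_len: int, k: int) -> list[tuple[int, int]]:
    """Split [0, read_len) into k+1 near-equal contiguous segments."""
    n_seg = k + 1
    base, extra = divmod(read_len, n_seg)
    bounds, pos = [], 0
    for i in range(n_seg):
        size = base + (1 if i < extra else 0)
        bounds.append((pos, pos + size))
        pos += size
    return bounds


def _candidate_starts(index: RefIndex, encoded: np.ndarray, k: int) -> np.ndarray:
    """Pigeonhole candidate window starts (concatenation frame)."""
    L = len(encoded)
    data = encoded.tobytes()
    starts: list[np.ndarray] = []
    for seg_start, seg_end in _segment_bounds(L, k):
        q = seg_end - seg_start
        if q == 0:
            continue
        kmer = data[seg_start:seg_end]
        if 2 in kmer:  # read N in segment: cannot match exactly anywhere
            continue
        hits = index._qmer_index(q).get(kmer)
        if hits is not None:
            starts.append(hits - seg_start)
    if not starts:
        return np.empty(0, dtype=np.int64)
    cand = np.unique(np.concatenate(starts))
    # window must lie fully within one reference
    cand = cand[(cand >= 0) & (cand + L <= index.total_length)]
    if cand.size:
        ref_of_start = np.searchsorted(index.starts, cand, side="right")
        ref_of_end = np.searchsorted(index.starts, cand + L - 1, side="right")
        cand = cand[ref_of_start == ref_of_end]
    return cand


def _verify(index: RefIndex, encoded: np.ndarray, cand: np.ndarray) -> np.ndarray:
    """Hamming distance of the read against each candidate window."""
    L = len(encoded)
    windows = index.seq[cand[:, None] + np.arange(L)]
    return (windows != encoded).sum(axis=1)


def align_read(
    index: RefIndex,
    read: str,
    k: int = 3,
    rng: np.random.Generator | None = None,
    read_id: str = "",
) -> AlignmentHit | None:
    """Best ungapped placement of ``read`` on either strand, or None.

    Among placements tied at the minimum mismatch count, one is chosen
    uniformly at random using ``rng`` (a fresh default generator when not
    supplied, which makes single calls non-deterministic on ties).
    """
    if len(read) < k + 1:
        raise ValueError(f"read shorter than k+1 ({len(read)} < {k + 1})")
    if rng is None:
        rng = np.random.default_rng()
    best: list[tuple[int, str]] = []  # (concat_start, strand) in best stratum
    best_mm = k + 1
    for strand, seq in (("+", read), ("-", reverse_complement(read))):
        encoded = _encode(seq, _READ_CODE)
        cand = _candidate_starts(index, encoded, k)
        if cand.size == 0:
            continue
        mm = _verify(index, encoded, cand)
        strand_min = int(mm.min())
        if strand_min > min(best_mm, k):
            continue
        if strand_min < best_mm:
            best_mm = strand_min
            best = []
        best.extend((int(s), strand) for s in cand[mm == strand_min])
    if not best:
        return None
    m = best_mm
    s, strand = best[int(rng.integers(len(best)))] if len(best) > 1 else best[0]
    ri, local = index.locate(s)
    return AlignmentHit(
        read_id=read_id, ref_name=index.names[ri], pos=local,
        strand=strand, mismatches=m, read_len=len(read),
    )


def _read_rng(seed: int, read_id: str) -> np.random.Generator:
    """Generator keyed by (seed, read_id): batch-order invariant tie-breaks."""
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(read_id.encode())])
    )


def align_batch(
    index: RefIndex,
    reads: Iterable[tuple[str, str]],
    k: int = 3,
    seed: int = 1715,
) -> dict[str, AlignmentHit | None]:
    """Align (read_id, sequence) pairs; duplicate read ids are rejected."""
    out: dict[str, AlignmentHit | None] = {}
    for read_id, seq in reads:
        if read_id in out:
            raise ValueError(f"duplicate read id: {read_id}")
        out[read_id] = align_read(
            index, seq, k=k, rng=_read_rng(seed, read_id), read_id=read_id
        )
    return out


# ---------------------------------------------------------------------------
# Output formats

def hits_to_tsv(hits: Mapping[str, AlignmentHit | None]) -> str:
    lines = ["read_id\tref_name\tpos\tstrand\tmismatches"]
    for read_id, hit in hits.items():
        if hit is None:
            lines.append(f"{read_id}\t*\t-1\t*\t-1")
        else:
            lines.append(
                f"{read_id}\t{hit.ref_name}\t{hit.pos}\t{hit.strand}\t{hit.mismatches}"
            )
    return "\n".join(lines) + "\n"


def hits_to_sam(
    hits: Mapping[str, AlignmentHit | None],
    index: RefIndex,
    reads: Mapping[str, str],
) -> str:
    """Minimal unsorted SAM: @SQ header, FLAG 0/16/4, NM tag."""
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name, length in zip(index.names, index.lengths):
        lines.append(f"@SQ\tSN:{name}\tLN:{int(length)}")
    for read_id, hit in hits.items():
        seq = reads[read_id]
        if hit is None:
            lines.append(f"{read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*")
            continue
        flag = 0 if hit.strand == "+" else 16
        out_seq = seq if hit.strand == "+" else reverse_complement(seq)
        lines.append(
            f"{read_id}\t{flag}\t{hit.ref_name}\t{hit.pos + 1}\t255\t"
            f"{hit.read_len}M\t*\t0\t0\t{out_seq}\t*\tNM:i:{hit.mismatches}"
        )
    return "\n".join(lines) + "\n"
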
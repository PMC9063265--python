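"""Two-round read classification and multi-level mature tRNA counting.

Round one aligns preprocessed reads against the artificial genome and
classifies each read by where its best hit lands: the masked genomic
background (non-tRNA), a premature decoy chromosome with any overlap of
the 50 nt flanks (premature), or fully inside the pure gene body of a
decoy (mature).  Mature reads — plus non-tRNA reads shorter than 30 nt,
which may be tRNA fragments failing round one only because of the CCA
tail — go to round two against the mature tRNA genome, where counting is
restricted to cytosolic, high-confidence, non-pseudo genes.  Counts
aggregate from individual tRNAs to isodecoders (drop the copy index) to
isoacceptors (drop group and copy).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .align import AlignmentHit, align_batch, build_index
from .annotation import isoacceptor_key, isodecoder_key
from .genome import (
    GenomeBundle,
    RegistryEntry,
    ROLE_GENOMIC,
    ROLE_MATURE,
    ROLE_PREMATURE,
)


class ReadClass(enum.Enum):
    NON_TRNA = "non_trna"
    PREMATURE = "premature"
    MATURE = "mature"
    UNMAPPED = "unmapped"


LEVELS = ("individual", "isodecoder", "isoacceptor")


@dataclass
class CountTable:
    """Non-negative integer counts, entities x samples, at one level."""

    level: str
    counts: pd.DataFrame  # index: entity names; columns: sample names

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def entities(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


def classify_first_round(
    hit: AlignmentHit | None,
    registry: Mapping[str, RegistryEntry],
    read_len: int,
) -> ReadClass:
    """Classify a round-one hit by reference role and decoy position."""
    if hit is None:
        return ReadClass.UNMAPPED
    entry = registry.get(hit.ref_name)
    if entry is None:
        raise KeyError(f"hit on unknown reference {hit.ref_name!r}")
    if entry.role == ROLE_GENOMIC:
        return ReadClass.NON_TRNA
    if entry.role != ROLE_PREMATURE:
        raise ValueError(
            f"round-one hit on {entry.role} reference {hit.ref_name!r}"
        )
    gene_lo = entry.upstream_flank_len
    gene_hi = entry.upstream_flank_len + entry.gene_len
    if hit.pos >= gene_lo and hit.pos + read_len <= gene_hi:
        return ReadClass.MATURE
    return ReadClass.PREMATURE


def select_second_round(
    records: Iterable[tuple[str, ReadClass, int]],
    len_threshold: int = 30,
) -> list[str]:
    """Read ids for round two: all mature + non-tRNA strictly below threshold."""
    selected = []
    for read_id, cls, read_len in records:
        if cls is ReadClass.MATURE:
            selected.append(read_id)
        elif cls is ReadClass.NON_TRNA and read_len < len_threshold:
            selected.append(read_id)
    return selected


@dataclass
class DropReport:
    """Round-two reads landing on genes excluded from counting."""

    dropped: dict[str, int] = field(default_factory=dict)  # gene -> n reads

    def total(self) -> int:
        return sum(self.dropped.values())


def _countable(entry: RegistryEntry) -> bool:
    return entry.cytosolic and entry.high_confidence and not entry.pseudo


def count_individual(
    round2_hits: Mapping[str, AlignmentHit | None],
    registry: Mapping[str, RegistryEntry],
    sample: str = "sample",
) -> tuple[CountTable, DropReport]:
    """Tally round-two best hits per countable mature gene.

    The counted universe is the cytosolic, high-confidence, non-pseudo
    subset; reads best-hitting excluded genes are dropped and reported.
    """
    universe = sorted(
        name for name, e in registry.items()
        if e.role == ROLE_MATURE and _countable(e)
    )
    counts = dict.fromkeys(universe, 0)
    drop = DropReport()
    for hit in round2_hits.values():
        if hit is None:
            continue
        entry = registry.get(hit.ref_name)
        if entry is None or entry.role != ROLE_MATURE:
            raise KeyError(f"round-two hit on non-mature reference {hit.ref_name!r}")
        if _countable(entry):
            counts[hit.ref_name] += 1
        else:
            drop.dropped[hit.ref_name] = drop.dropped.get(hit.ref_name, 0) + 1
    frame = pd.DataFrame({sample: pd.Series(counts, dtype=int)})
    return CountTable(level="individual", counts=frame), drop


def aggregate_counts(table: CountTable, level: str) -> CountTable:
    """Merge individual counts to isodecoder or isoacceptor level."""
    if level == table.level:
        return table
    if table.level != "individual":
        raise ValueError("aggregation starts from the individual level")
    if level == "isodecoder":
        keyfn = isodecoder_key
    elif level == "isoacceptor":
        keyfn = isoacceptor_key
    else:
        raise ValueError(f"unknown level {level!r}")
    if table.counts.empty:
        return CountTable(level=level, counts=table.counts.copy())
    keys = [keyfn(name) for name in table.counts.index]
    merged = table.counts.groupby(pd.Index(keys, name=level)).sum().sort_index()
    return CountTable(level=level, counts=merged)


@dataclass
class ClassTally:
    n_input: int = 0
    n_unmapped: int = 0
    n_non_trna: int = 0
    n_premature: int = 0
    n_mature_r1: int = 0
    n_selected_r2: int = 0
    n_counted_r2: int = 0
    n_dropped_r2: int = 0

    def check(self) -> None:
        assert (
            self.n_unmapped + self.n_non_trna + self.n_premature + self.n_mature_r1
            == self.n_input
        )


def quantify_reads(
    reads: list[tuple[str, str]],
    bundle: GenomeBundle,
    k: int = 3,
    seed: int = 1715,
    len_threshold: int = 30,
    sample: str = "sample",
) -> tuple[CountTable, ClassTally, DropReport]:
    """End-to-end single-sample driver over in-memory (id, seq) reads."""
    tally = ClassTally(n_input=len(reads))
    art_index = build_index(bundle.artificial_references)
    r1_hits = align_batch(art_index, reads, k=k, seed=seed)
    seqs = dict(reads)
    classes: list[tuple[str, ReadClass, int]] = []
    for read_id, seq in reads:
        cls = classify_first_round(r1_hits[read_id], bundle.registry, len(seq))
        classes.append((read_id, cls, len(seq)))
        if cls is ReadClass.UNMAPPED:
            tally.n_unmapped += 1
        elif cls is ReadClass.NON_TRNA:
            tally.n_non_trna += 1
        elif cls is ReadClass.PREMATURE:
            tally.n_premature += 1
        else:
            tally.n_mature_r1 += 1
    selected = select_second_round(classes, len_threshold)
    tally.n_selected_r2 = len(selected)
    if selected and bundle.mature_records:
        mat_index = build_index(bundle.mature_records)
        r2_hits = align_batch(
            mat_index, [(rid, seqs[rid]) for rid in selected], k=k, seed=seed
        )
    else:
        r2_hits = {}
    table, drop = count_individual(r2_hits, bundle.registry, sample=sample)
    tally.n_counted_r2 = table.total()
    tally.n_dropped_r2 = drop.total()
    tally.check()
    return table, tally, drop


def combine_samples(tables: list[CountTable]) -> CountTable:
    """Join single-sample individual tables into one entities x samples table."""
    if not tables:
        raise ValueError("no tables to combine")
    level = tables[0].level
    frames = [t.counts for t in tables]
    joined = pd.concat(frames, axis=1).fillna(0).astype(int)
    return CountTable(level=level, counts=joined)
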
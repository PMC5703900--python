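"""Genomic interval primitives.

All coordinates are 0-based half-open ``[start, end)``, the BED convention.
GTF output is converted to 1-based inclusive at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware genomic interval, 0-based half-open.

    Sorting order is (chrom, start, end), which downstream region logic
    (run extraction, merging, stitching) relies on.
    """

    chrom: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Any-length overlap on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def merge_intervals(
    intervals: Iterable[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose gap (next.start - prev.end) is <= ``gap``.

    gap=0 merges touching/overlapping intervals; output is sorted and
    disjoint (strand is dropped: merged regions are unstranded).
    """
    ivs = sort_intervals(intervals)
    if not ivs:
        return []
    merged: list[GenomicInterval] = []
    cur_chrom, cur_start, cur_end = ivs[0].chrom, ivs[0].start, ivs[0].end
    for iv in ivs[1:]:
        if iv.chrom == cur_chrom and iv.start - cur_end <= gap:
            cur_end = max(cur_end, iv.end)
        else:
            merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return merged


def overlaps_any(query: GenomicInterval, targets: Sequence[GenomicInterval]) -> bool:
    """True iff ``query`` overlaps (any length) at least one target."""
    return any(query.overlaps(t) for t in targets)


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(iv.length for iv in intervals)


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def covered_fraction(
    queries: Sequence[GenomicInterval], targets: Sequence[GenomicInterval]
) -> float:
    """Fraction of query bp covered by the (merged) target set."""
    merged = merge_intervals(targets)
    tot = total_length(queries)
    if tot == 0:
        return float("nan")
    cov = sum(overlap_length(q, t) for q in queries for t in merged)
    return cov / tot


def complement(
    intervals: Sequence[GenomicInterval], chrom_sizes: dict[str, int]
) -> list[GenomicInterval]:
    """Intervals covering everything in ``chrom_sizes`` not covered by input."""
    merged = merge_intervals(intervals)
    by_chrom: dict[str, list[GenomicInterval]] = {c: [] for c in chrom_sizes}
    for iv in merged:
        if iv.chrom in by_chrom:
            by_chrom[iv.chrom].append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        pos = 0
        for iv in by_chrom[chrom]:
            if iv.start > pos:
                out.append(GenomicInterval(chrom, pos, min(iv.start, size)))
            pos = max(pos, iv.end)
        if pos < size:
            out.append(GenomicInterval(chrom, pos, size))
    return out


def intervals_to_arrays(
    intervals: Sequence[GenomicInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome (starts, ends) arrays for vectorized overlap queries."""
    out: dict[str, tuple[list[int], list[int]]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, ([], []))
        out[iv.chrom][0].append(iv.start)
        out[iv.chrom][1].append(iv.end)
    return {
        c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
        for c, (s, e) in out.items()
    }
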
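"""Genomic interval primitives.

All coordinates are 0-based, half-open ``[start, end)``.  The only 1-based
surface in the package is the DNM position column, which is converted at the
IO boundary (see :mod:`regburden.io_formats`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "sort_intervals",
    "merge_intervals",
    "total_span",
    "IntervalIndex",
]


@dataclass(order=True)
class GenomicInterval:
    """A half-open genomic interval with optional name and score."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos0: int) -> bool:
        return chrom == self.chrom and self.start <= pos0 < self.end


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def merge_intervals(
    intervals: Iterable[GenomicInterval], *, merge_abutting: bool = True
) -> list[GenomicInterval]:
    """Coalesce overlapping (and, by default, abutting) intervals.

    Names and scores are dropped from coalesced records.
    """
    ivs = sort_intervals(intervals)
    if not ivs:
        return []
    out: list[GenomicInterval] = []
    cur = GenomicInterval(ivs[0].chrom, ivs[0].start, ivs[0].end)
    for iv in ivs[1:]:
        joined = iv.start <= cur.end if merge_abutting else iv.start < cur.end
        if iv.chrom == cur.chrom and joined:
            cur.end = max(cur.end, iv.end)
        else:
            out.append(cur)
            cur = GenomicInterval(iv.chrom, iv.start, iv.end)
    out.append(cur)
    return out


def total_span(intervals: Iterable[GenomicInterval]) -> int:
    """Total base pairs covered after merging."""
    return sum(iv.length for iv in merge_intervals(intervals))


class IntervalIndex:
    """Fast point/interval queries against a merged, sorted interval set."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        merged = merge_intervals(intervals)
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self.intervals = merged
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in merged:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            self._starts[chrom] = np.array([iv.start for iv in ivs], dtype=np.int64)
            self._ends[chrom] = np.array([iv.end for iv in ivs], dtype=np.int64)

    def contains_point(self, chrom: str, pos0: int) -> bool:
        starts = self._starts.get(chrom)
        if starts is None or len(starts) == 0:
            return False
        i = int(np.searchsorted(starts, pos0, side="right")) - 1
        return i >= 0 and pos0 < self._ends[chrom][i]

    def contains_points(self, chrom: str, positions0: Sequence[int]) -> np.ndarray:
        """Vectorized point containment; returns a boolean array."""
        pos = np.asarray(positions0, dtype=np.int64)
        starts = self._starts.get(chrom)
        if starts is None or len(starts) == 0:
            return np.zeros(pos.shape, dtype=bool)
        i = np.searchsorted(starts, pos, side="right") - 1
        ok = i >= 0
        hit = np.zeros(pos.shape, dtype=bool)
        hit[ok] = pos[ok] < self._ends[chrom][i[ok]]
        return hit

    def overlaps_interval(self, chrom: str, start: int, end: int) -> bool:
        starts = self._starts.get(chrom)
        if starts is None or len(starts) == 0:
            return False
        i = int(np.searchsorted(starts, end, side="left")) - 1
        return i >= 0 and self._ends[chrom][i] > start
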
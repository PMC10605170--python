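"""Genomic intervals, bin grids, and interval-overlap primitives.

All coordinates are 0-based half-open (BED convention) throughout the
package; a bin ``[start, end)`` and a peak overlap iff they share at least
one base under half-open arithmetic.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GenomicInterval",
    "BinGrid",
    "make_bins",
    "merge_intervals",
    "overlaps_any",
    "count_bins_overlapped",
]

_REGION_RE = re.compile(r"^([\w.]+):([\d,]+)-([\d,]+)$")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self.start}")
        if self.start >= self.end:
            raise ValueError(f"empty or inverted interval: {self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @classmethod
    def parse(cls, region: str) -> "GenomicInterval":
        """Parse a ``chrom:start-end`` region string (commas allowed)."""
        m = _REGION_RE.match(region)
        if m is None:
            raise ValueError(f"cannot parse region string {region!r}")
        chrom, start, end = m.groups()
        return cls(chrom, int(start.replace(",", "")), int(end.replace(",", "")))

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class BinGrid:
    """Contiguous equal-width tiling of a window into half-open bins."""

    window: GenomicInterval
    bin_size: int

    @property
    def n_bins(self) -> int:
        return self.window.length // self.bin_size

    @property
    def starts(self) -> np.ndarray:
        return self.window.start + self.bin_size * np.arange(self.n_bins)

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.bin_size

    def bin(self, index: int) -> GenomicInterval:
        if not 0 <= index < self.n_bins:
            raise IndexError(f"bin index {index} outside grid of {self.n_bins} bins")
        start = self.window.start + index * self.bin_size
        return GenomicInterval(self.window.chrom, start, start + self.bin_size)

    def intervals(self) -> list[GenomicInterval]:
        return [self.bin(i) for i in range(self.n_bins)]


def make_bins(window: GenomicInterval, bin_size: int) -> BinGrid:
    """Tile ``window`` into contiguous ``bin_size``-bp half-open bins.

    A trailing partial bin (when ``bin_size`` does not divide the window
    length) is truncated with a warning; a window shorter than one bin is an
    error.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if window.length < bin_size:
        raise ValueError(
            f"window length {window.length} shorter than bin size {bin_size}"
        )
    remainder = window.length % bin_size
    if remainder:
        warnings.warn(
            f"window length {window.length} not divisible by bin size {bin_size}; "
            f"dropping final {remainder} bp",
            stacklevel=2,
        )
    return BinGrid(window, bin_size)


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge possibly-overlapping half-open intervals into disjoint sorted ones."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    merged_s = [starts[0]]
    merged_e = [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s < merged_e[-1]:
            merged_e[-1] = max(merged_e[-1], e)
        else:
            merged_s.append(s)
            merged_e.append(e)
    return np.asarray(merged_s), np.asarray(merged_e)


def overlaps_any(
    query_starts: np.ndarray,
    query_ends: np.ndarray,
    subject_starts: np.ndarray,
    subject_ends: np.ndarray,
) -> np.ndarray:
    """Boolean flag per query: does it overlap any subject interval?

    Subjects may overlap each other; they are merged internally. Overlap is
    ≥1 bp under half-open arithmetic.
    """
    query_starts = np.asarray(query_starts, dtype=np.int64)
    query_ends = np.asarray(query_ends, dtype=np.int64)
    ms, me = merge_intervals(subject_starts, subject_ends)
    if ms.size == 0:
        return np.zeros(query_starts.shape, dtype=bool)
    # the only merged interval that can overlap [qs, qe) is the last one
    # starting strictly before qe
    idx = np.searchsorted(ms, query_ends, side="left") - 1
    hit = idx >= 0
    hit[hit] = me[idx[hit]] > query_starts[hit]
    return hit


def count_bins_overlapped(
    bin_starts: np.ndarray,
    bin_ends: np.ndarray,
    peak_starts: np.ndarray,
    peak_ends: np.ndarray,
) -> int:
    """Number of query bins intersected by at least one peak."""
    return int(overlaps_any(bin_starts, bin_ends, peak_starts, peak_ends).sum())
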
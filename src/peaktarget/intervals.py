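"""Genomic interval primitives.

All coordinates in this package are 0-based half-open ``[start, end)``.
External formats are converted at the I/O boundary: GTF and MACS14 tables
(1-based inclusive) in :mod:`peaktarget.genome` and :mod:`peaktarget.peaks`,
BED/narrowPeak (already 0-based half-open) pass through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, position: int) -> bool:
        """True if ``position`` falls inside the interval (half-open)."""
        return self.start <= position < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        """>=1 bp overlap; touching half-open intervals do not overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or touching intervals on the same chromosome.

    Input may be unsorted; output is sorted by (chrom, start).
    """
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(iv)
    return merged
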
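"""Peak-call I/O and artifact-blacklist filtering.

Readers for ENCODE narrowPeak, plain BED3/BED4 and the MACS14 ``.xls`` table
dialect, all normalised to 0-based half-open intervals with a single summit
position. Peaks lacking a summit (BED input, narrowPeak offset ``-1``) get a
midpoint summit and are flagged ``summit_imputed``.

The blacklist filter removes a peak when its interval overlaps any blacklist
interval by at least 1 bp (``mode="interval"``), or when the summit itself
falls in a blacklist interval (``mode="summit"``).
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import Iterable

from intervaltree import IntervalTree

from .intervals import GenomicInterval, merge_intervals


@dataclass(frozen=True)
class PeakCall:
    """One called peak: an interval plus a single summit position."""

    peak_id: str
    interval: GenomicInterval
    summit: int
    score: float = 0.0
    enrichment: float | None = None
    summit_imputed: bool = False

    def __post_init__(self) -> None:
        if not self.interval.contains(self.summit):
            raise ValueError(
                f"{self.peak_id}: summit {self.summit} outside "
                f"[{self.interval.start}, {self.interval.end})"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass
class BlacklistSet:
    """Per-chromosome merged intervals of known artifactual signal."""

    intervals: dict[str, list[GenomicInterval]] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval]) -> "BlacklistSet":
        merged = merge_intervals(list(intervals))
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in merged:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        return cls(by_chrom)

    @classmethod
    def from_bed(cls, path: str) -> "BlacklistSet":
        ivs = []
        with open(path) as handle:
            for line in handle:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                cols = line.split("\t")
                ivs.append(GenomicInterval(cols[0], int(cols[1]), int(cols[2])))
        return cls.from_intervals(ivs)


def _midpoint(start: int, end: int) -> int:
    return (start + end) // 2


def read_narrowpeak(path: str) -> list[PeakCall]:
    """Read ENCODE narrowPeak (BED6+4); falls back to BED3/4 parsing.

    Column 10 is the summit offset from ``start``; ``-1`` means no summit
    was called and the floor midpoint is imputed. Rows with fewer than 10
    columns are parsed as plain BED with a midpoint summit (logged once).
    """
    peaks = []
    n_bed_fallback = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            name = cols[3] if len(cols) > 3 and cols[3] not in (".", "") \
                else f"peak_{lineno}"
            iv = GenomicInterval(chrom, start, end)
            if len(cols) >= 10:
                offset = int(cols[9])
                # narrowPeak: col 7 signalValue (enrichment), col 8 -log10 p
                enrich = float(cols[6]) if cols[6] not in (".", "-1") else None
                score = float(cols[7]) if cols[7] != "." else 0.0
                if offset == -1:
                    summit, imputed = _midpoint(start, end), True
                else:
                    summit, imputed = start + offset, False
                    if summit >= end:
                        raise ValueError(
                            f"{path}:{lineno}: summit offset {offset} >= "
                            f"peak length {end - start}"
                        )
            else:
                n_bed_fallback += 1
                score, enrich = 0.0, None
                summit, imputed = _midpoint(start, end), True
            peaks.append(PeakCall(name, iv, summit, score, enrich, imputed))
    if n_bed_fallback:
        print(f"read_narrowpeak: {n_bed_fallback} row(s) had <10 columns; "
              "parsed as BED with midpoint summits", file=sys.stderr)
    return peaks


def read_macs_xls(path: str) -> list[PeakCall]:
    """Read a MACS14 ``.xls`` peak table.

    MACS14 tables are tab-separated with ``#`` comment lines and a header
    row; coordinates are 1-based inclusive and the summit column is an
    absolute 1-based position. Both are converted to the internal 0-based
    convention. A missing summit column triggers midpoint imputation.
    """
    peaks = []
    header: list[str] | None = None
    n_comments = 0
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                n_comments += 1
                continue
            cols = line.split("\t")
            if header is None:
                header = [c.strip().lower() for c in cols]
                if "summit" not in header:
                    print(f"read_macs_xls: {path} has no summit column; "
                          "imputing midpoints", file=sys.stderr)
                continue
            row = dict(zip(header, cols))
            start = int(row["start"]) - 1  # 1-based inclusive -> 0-based
            end = int(row["end"])
            iv = GenomicInterval(row["chr"], start, end)
            if "summit" in row:
                summit, imputed = int(row["summit"]) - 1, False
            else:
                summit, imputed = _midpoint(start, end), True
            name = row.get("name", f"macs_peak_{len(peaks) + 1}")
            score = float(row.get("-10*log10(pvalue)", 0.0))
            enrich = float(row["fold_enrichment"]) \
                if "fold_enrichment" in row else None
            peaks.append(PeakCall(name, iv, summit, score, enrich, imputed))
    if n_comments:
        print(f"read_macs_xls: skipped {n_comments} comment/blank line(s)",
              file=sys.stderr)
    return peaks


def read_peaks(path: str, fmt: str = "narrowpeak") -> list[PeakCall]:
    if fmt in ("narrowpeak", "bed"):
        return read_narrowpeak(path)
    if fmt == "macs14":
        return read_macs_xls(path)
    raise ValueError(f"unknown peak format {fmt!r}")


def write_narrowpeak(peaks: Iterable[PeakCall], path: str) -> None:
    with open(path, "w") as out:
        for p in peaks:
            offset = -1 if p.summit_imputed else p.summit - p.interval.start
            enrich = p.enrichment if p.enrichment is not None else -1
            out.write(
                f"{p.chrom}\t{p.interval.start}\t{p.interval.end}\t{p.peak_id}"
                f"\t0\t.\t{enrich:g}\t{p.score:g}\t-1\t{offset}\n"
            )


def write_macs_xls(peaks: Iterable[PeakCall], path: str) -> None:
    with open(path, "w") as out:
        out.write("# This file is generated by the peaktarget simulator "
                  "in the MACS14 table dialect\n")
        out.write("chr\tstart\tend\tlength\tsummit\ttags"
                  "\t-10*log10(pvalue)\tfold_enrichment\tFDR(%)\tname\n")
        for p in peaks:
            start1 = p.interval.start + 1  # 0-based -> 1-based inclusive
            out.write(
                f"{p.chrom}\t{start1}\t{p.interval.end}\t{len(p.interval)}"
                f"\t{p.summit + 1}\t0\t{p.score:g}"
                f"\t{p.enrichment if p.enrichment is not None else 1:g}"
                f"\t0\t{p.peak_id}\n"
            )


def filter_blacklist(
    peaks: list[PeakCall],
    blacklist: BlacklistSet,
    mode: str = "interval",
) -> tuple[list[PeakCall], list[PeakCall]]:
    """Partition peaks into (kept, removed) against a blacklist.

    ``mode="interval"``: removed iff the peak interval overlaps a blacklist
    interval by >=1 bp. ``mode="summit"``: removed iff the summit base lies
    in a blacklist interval. Order is preserved; kept + removed == input.
    """
    if mode not in ("interval", "summit"):
        raise ValueError(f"unknown blacklist mode {mode!r}")
    trees = {
        chrom: IntervalTree.from_tuples((iv.start, iv.end) for iv in ivs)
        for chrom, ivs in blacklist.intervals.items()
    }
    kept, removed = [], []
    for p in peaks:
        tree = trees.get(p.chrom)
        if tree is None:
            hit = False
        elif mode == "interval":
            hit = bool(tree.overlap(p.interval.start, p.interval.end))
        else:
            hit = bool(tree.at(p.summit))
        (removed if hit else kept).append(p)
    return kept, removed
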
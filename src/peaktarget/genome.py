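"""Gene models: GTF parsing, transcript/exon structures and TSS derivation.

Transcript models are assembled from Ensembl-dialect GTF. Internally every
coordinate is 0-based half-open; the GTF's 1-based inclusive coordinates are
converted on read (``start - 1``) and back on write. The transcription start
site (TSS) is the first transcribed base: ``locus.start`` on the ``+`` strand
and ``locus.end - 1`` on the ``-`` strand.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass
from typing import Iterable

from gffutils.feature import feature_from_line

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")


class GtfParseError(ValueError):
    """A structurally malformed GTF line (names the line number)."""


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded transcript locus with its ordered, non-overlapping exons."""

    transcript_id: str
    gene_id: str
    gene_name: str
    locus: GenomicInterval
    strand: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >=1 exon")
        prev_end = None
        for exon in self.exons:
            if exon.chrom != self.locus.chrom:
                raise ValueError(f"{self.transcript_id}: exon off-chromosome")
            if exon.start < self.locus.start or exon.end > self.locus.end:
                raise ValueError(f"{self.transcript_id}: exon outside locus")
            if prev_end is not None and exon.start < prev_end:
                raise ValueError(
                    f"{self.transcript_id}: exons unsorted or overlapping"
                )
            prev_end = exon.end


@dataclass(frozen=True)
class TSS:
    """The transcription start site of one transcript."""

    transcript_id: str
    chrom: str
    position: int
    strand: str


def derive_tss(model: TranscriptModel) -> TSS:
    """First transcribed base: locus start (+) or locus end - 1 (-)."""
    if model.strand == "+":
        position = model.locus.start
    elif model.strand == "-":
        position = model.locus.end - 1
    else:  # pragma: no cover - TranscriptModel validates strand
        raise ValueError(f"invalid strand {model.strand!r}")
    return TSS(model.transcript_id, model.locus.chrom, position, model.strand)


def point_in_exon(model: TranscriptModel, position: int) -> str:
    """Classify a position against one transcript.

    Returns ``"exonic"`` if the position falls inside any exon,
    ``"intronic"`` if it is inside the locus but in no exon, and
    ``"outside"`` otherwise. The chromosome is not checked here; callers
    compare positions on the model's own chromosome.
    """
    if not model.locus.contains(position):
        return "outside"
    for exon in model.exons:
        if exon.contains(position):
            return "exonic"
    return "intronic"


def _attr(feature, key: str) -> str | None:
    values = feature.attributes.get(key)
    return values[0] if values else None


def parse_gtf(
    path: str,
    feature_filter: Iterable[str] = ("transcript", "exon"),
) -> list[TranscriptModel]:
    """Parse an Ensembl-dialect GTF into transcript models.

    One :class:`TranscriptModel` is returned per ``transcript_id``. If a
    ``transcript`` feature line exists it defines the locus; otherwise the
    locus is the envelope of the transcript's exons. Exon records missing a
    ``transcript_id`` are skipped with a logged warning; structurally
    malformed lines raise :class:`GtfParseError` naming the line number.
    A duplicate ``transcript_id`` spanning two chromosomes (or strands) is a
    hard error: silently merging would corrupt TSS distances.
    """
    wanted = set(feature_filter)
    exons: dict[str, list[GenomicInterval]] = {}
    loci: dict[str, GenomicInterval] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene_id, gene_name, strand)
    n_skipped = 0

    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise GtfParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns"
                )
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise GtfParseError(f"{path}:{lineno}: {exc}") from exc
            if feat.featuretype not in wanted:
                continue
            tid = _attr(feat, "transcript_id")
            if tid is None:
                logger.warning(
                    "%s:%d: %s record missing transcript_id, skipped",
                    path, lineno, feat.featuretype,
                )
                n_skipped += 1
                continue
            if feat.strand not in STRANDS:
                raise GtfParseError(
                    f"{path}:{lineno}: strand must be + or -, got {feat.strand!r}"
                )
            # GTF is 1-based inclusive -> 0-based half-open
            iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end)
            known = meta.get(tid)
            this = (
                _attr(feat, "gene_id") or "",
                _attr(feat, "gene_name") or "",
                feat.strand,
            )
            if known is None:
                meta[tid] = this
            elif known[2] != feat.strand:
                raise GtfParseError(
                    f"{path}:{lineno}: transcript {tid} on conflicting strands"
                )
            ref = loci.get(tid) or (exons[tid][0] if exons.get(tid) else None)
            if ref is not None and ref.chrom != iv.chrom:
                raise GtfParseError(
                    f"{path}:{lineno}: duplicate transcript_id {tid} "
                    f"on chromosomes {ref.chrom} and {iv.chrom}"
                )
            if feat.featuretype == "transcript":
                loci[tid] = iv
            else:
                exons.setdefault(tid, []).append(iv)

    if n_skipped:
        print(f"parse_gtf: skipped {n_skipped} record(s) without transcript_id",
              file=sys.stderr)

    models = []
    for tid, (gene_id, gene_name, strand) in meta.items():
        exon_list = sorted(exons.get(tid, []))
        if not exon_list:
            # transcript line without exon lines: treat as single-exon
            exon_list = [loci[tid]]
        locus = loci.get(tid)
        if locus is None:
            locus = GenomicInterval(
                exon_list[0].chrom,
                min(e.start for e in exon_list),
                max(e.end for e in exon_list),
            )
        models.append(
            TranscriptModel(tid, gene_id, gene_name, locus, strand,
                            tuple(exon_list))
        )
    models.sort(key=lambda m: (m.locus.chrom, m.locus.start, m.transcript_id))
    return models


def write_gtf(models: Iterable[TranscriptModel], path: str,
              source: str = "peaktarget") -> None:
    """Write transcript models as Ensembl-dialect GTF (transcript + exon lines)."""
    with open(path, "w") as out:
        for m in models:
            attrs = (
                f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                f'gene_name "{m.gene_name}";'
            )
            rows = [(m.locus, "transcript")] + [(e, "exon") for e in m.exons]
            for iv, ftype in rows:
                out.write(
                    f"{iv.chrom}\t{source}\t{ftype}\t{iv.start + 1}\t{iv.end}"
                    f"\t.\t{m.strand}\t.\t{attrs}\n"
                )
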
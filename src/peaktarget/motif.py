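"""Exact fixed-motif scanning and cluster calling.

Scans DNA sequences for every exact occurrence of a motif word on both
strands (minus-strand hits are occurrences of the reverse complement,
reported at their plus-strand offset) and chains nearby hits into clusters:
maximal runs in which consecutive hit starts are no more than ``window_bp``
apart, reported when the run holds at least ``min_hits`` hits. This mirrors
the GC-rich GGCCGG element whose promoter clusters mark direct
transcription-factor binding.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import reverse_complement

from .annotate import TranscriptIndex  # noqa: F401  (re-export convenience)
from .genome import TranscriptModel, derive_tss
from .intervals import GenomicInterval

_VALID_SEQ = set("ACGTN")
_VALID_MOTIF = set("ACGT")


@dataclass(frozen=True)
class MotifHit:
    """One exact motif occurrence (minus-strand hits at + strand offsets)."""

    seq_id: str
    position: int
    strand: str
    motif: str


@dataclass(frozen=True)
class MotifCluster:
    """A chained run of >= min_hits motif hits within one sequence."""

    seq_id: str
    window: GenomicInterval
    n_hits: int
    hits: tuple[MotifHit, ...]


@dataclass(frozen=True)
class PromoterSequence:
    """A strand-aware promoter window; position 0 is most upstream."""

    transcript_id: str
    gene_id: str
    sequence: str
    genomic: GenomicInterval
    strand: str
    truncated: bool = False


def _find_all(haystack: str, needle: str) -> list[int]:
    out, start = [], 0
    while True:
        i = haystack.find(needle, start)
        if i == -1:
            return out
        out.append(i)
        start = i + 1  # overlapping occurrences all reported


def scan_motif(sequence: str, motif: str, seq_id: str = "seq",
               both_strands: bool = True) -> list[MotifHit]:
    """All exact occurrences of ``motif`` (and its reverse complement).

    ``N`` never matches. Hits are sorted by position; a minus-strand hit is
    an occurrence of the reverse complement reported at its plus-strand
    offset with strand ``-``.
    """
    sequence = sequence.upper()
    motif = motif.upper()
    if len(motif) < 4 or set(motif) - _VALID_MOTIF:
        raise ValueError(f"motif must be ACGT-only, length >= 4: {motif!r}")
    if set(sequence) - _VALID_SEQ:
        bad = sorted(set(sequence) - _VALID_SEQ)
        raise ValueError(f"sequence contains invalid characters {bad}")
    if len(motif) > len(sequence):
        return []
    hits = [MotifHit(seq_id, i, "+", motif)
            for i in _find_all(sequence, motif)]
    if both_strands:
        rc = reverse_complement(motif)
        hits += [MotifHit(seq_id, i, "-", motif)
                 for i in _find_all(sequence, rc)]
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def call_clusters(hits: list[MotifHit], window_bp: int = 200,
                  min_hits: int = 2) -> list[MotifCluster]:
    """Chain hits into clusters per sequence.

    A cluster is a maximal run of hits (sorted by position) in which
    consecutive hit starts differ by at most ``window_bp``; runs with fewer
    than ``min_hits`` hits are dropped.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if min_hits < 2:
        raise ValueError("min_hits must be >= 2")
    by_seq: dict[str, list[MotifHit]] = {}
    for h in hits:
        by_seq.setdefault(h.seq_id, []).append(h)
    clusters = []
    for seq_id in sorted(by_seq):
        run: list[MotifHit] = []
        seq_hits = sorted(by_seq[seq_id], key=lambda h: (h.position, h.strand))
        for h in seq_hits + [None]:
            if run and (h is None or h.position - run[-1].position > window_bp):
                if len(run) >= min_hits:
                    clusters.append(MotifCluster(
                        seq_id,
                        GenomicInterval(seq_id, run[0].position,
                                        run[-1].position + len(run[-1].motif)),
                        len(run),
                        tuple(run),
                    ))
                run = []
            if h is not None:
                run.append(h)
    return clusters


def extract_promoter_sequences(
    models: list[TranscriptModel],
    fasta,
    upstream_bp: int = 3000,
    downstream_bp: int = 0,
) -> list[PromoterSequence]:
    """Strand-aware promoter windows around each TSS.

    ``fasta`` is any mapping from chromosome name to sequence string
    (e.g. a ``pyfaidx.Fasta``; records are coerced with ``str``). The
    window covers ``upstream_bp`` bases 5' of the TSS through
    ``downstream_bp`` bases 3' of it (TSS base included on the downstream
    side); minus-strand windows are reverse-complemented so that position 0
    is always the most upstream base. Windows are truncated at contig edges
    and flagged.
    """
    out = []
    for m in models:
        tss = derive_tss(m)
        try:
            record = fasta[m.locus.chrom]
        except KeyError as exc:
            raise KeyError(
                f"{m.transcript_id}: chromosome {m.locus.chrom!r} "
                "absent from FASTA"
            ) from exc
        chrom_seq = str(record)
        chrom_len = len(chrom_seq)
        if m.strand == "+":
            start, end = tss.position - upstream_bp, tss.position + downstream_bp
        else:
            start, end = tss.position + 1 - downstream_bp, tss.position + 1 + upstream_bp
        truncated = start < 0 or end > chrom_len
        start_c, end_c = max(0, start), min(chrom_len, end)
        if end_c <= start_c:
            continue
        seq = chrom_seq[start_c:end_c].upper()
        if m.strand == "-":
            seq = reverse_complement(seq)
        out.append(PromoterSequence(
            m.transcript_id, m.gene_id, seq,
            GenomicInterval(m.locus.chrom, start_c, end_c),
            m.strand, truncated,
        ))
    return out
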
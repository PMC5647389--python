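"""Strand-aware classification of peak summits relative to transcript models.

Each peak is represented by its summit — the single base of maximal signal —
and compared against every transcript's TSS and exon structure:

* **proximal promoter**: the summit lies on the upstream (5') side of a TSS
  at a distance ``0 <= d <= proximal_max`` (default 2 kb), measured along the
  transcript's direction of transcription. The boundary is inclusive on both
  ends: a summit exactly at the TSS (``d = 0``) and one exactly 2 kb upstream
  both count as proximal.
* **distal promoter**: upstream with ``proximal_max < d <= distal_max``
  (default 2-50 kb).
* **exonic / intronic**: the summit falls inside a transcript locus, in an
  exon or an intron respectively. A summit downstream of the TSS (``d < 0``)
  is never a promoter hit.
* **intergenic**: no relation of any kind — no TSS within ``distal_max``
  upstream-wise and the summit inside no locus.

A summit may relate to several transcripts at once (e.g. intronic in one
gene and promoter-adjacent to another); the peak's single class is the
highest-precedence relation present under

    proximal_promoter > distal_promoter > exonic > intronic,

with all contributing associations retained for gene-level integration.

:class:`SummitClassifier` packages this as a scikit-learn style estimator:
``fit`` indexes the transcript models, ``annotate`` returns full
:class:`PeakAnnotation` records and ``predict`` just the class labels.
"""

from __future__ import annotations

import bisect
from collections import Counter
from dataclasses import dataclass, field

from intervaltree import IntervalTree
from sklearn.base import BaseEstimator

from .genome import TSS, TranscriptModel, derive_tss, point_in_exon
from .peaks import PeakCall

PEAK_CLASSES = (
    "proximal_promoter",
    "distal_promoter",
    "exonic",
    "intronic",
    "intergenic",
)

# larger = higher precedence when several relations coexist
_PRECEDENCE = {"proximal": 4, "distal": 3, "exonic": 2, "intronic": 1}
_RELATION_TO_CLASS = {
    "proximal": "proximal_promoter",
    "distal": "distal_promoter",
    "exonic": "exonic",
    "intronic": "intronic",
}


@dataclass(frozen=True)
class ClassifierConfig:
    """Distance thresholds for promoter classification (bp, inclusive)."""

    proximal_max: int = 2000
    distal_max: int = 50000

    def __post_init__(self) -> None:
        if not 0 < self.proximal_max < self.distal_max:
            raise ValueError(
                f"need 0 < proximal_max < distal_max, got "
                f"{self.proximal_max}, {self.distal_max}"
            )


@dataclass(frozen=True)
class Association:
    """One (peak, transcript) relation with its signed TSS distance.

    ``signed_distance`` is the upstream offset of the summit from the TSS
    along the direction of transcription: >= 0 for promoter relations,
    <= 0 when the summit lies at or past the TSS inside the gene body.
    """

    transcript_id: str
    gene_id: str
    relation: str
    signed_distance: int


@dataclass(frozen=True)
class PeakAnnotation:
    """A peak's class label plus every transcript association behind it."""

    peak_id: str
    chrom: str
    summit: int
    peak_class: str
    associations: tuple[Association, ...] = ()
    summit_imputed: bool = False

    @property
    def gene_ids(self) -> set[str]:
        return {a.gene_id for a in self.associations}

    @property
    def best(self) -> Association | None:
        """Highest-precedence association (smallest |distance| tiebreak)."""
        if not self.associations:
            return None
        return max(
            self.associations,
            key=lambda a: (_PRECEDENCE[a.relation], -abs(a.signed_distance)),
        )


def upstream_distance(summit: int, tss: TSS) -> int:
    """Signed summit->TSS distance along the direction of transcription.

    Positive when the summit is upstream (5') of the TSS, negative when it
    is at the TSS's downstream side (inside the gene body direction).
    """
    if tss.strand == "+":
        return tss.position - summit
    return summit - tss.position


def summit_tss_relation(
    summit: int,
    chrom: str,
    tss: TSS,
    config: ClassifierConfig = ClassifierConfig(),
) -> str:
    """Relate one summit to one TSS: ``proximal``, ``distal`` or ``none``.

    A chromosome mismatch yields ``none`` (not an error); so does a summit
    downstream of the TSS (``d < 0``).
    """
    if chrom != tss.chrom:
        return "none"
    d = upstream_distance(summit, tss)
    if 0 <= d <= config.proximal_max:
        return "proximal"
    if config.proximal_max < d <= config.distal_max:
        return "distal"
    return "none"


class TranscriptIndex:
    """Window-query index over transcript models.

    TSS positions are kept in per-chromosome sorted arrays (binary search
    for the +/- distal windows); loci live in per-chromosome interval trees
    for point containment queries.
    """

    def __init__(self, models: list[TranscriptModel]):
        self.models = list(models)
        seen: dict[str, str] = {}
        for m in self.models:
            prev = seen.get(m.transcript_id)
            if prev is not None and prev != m.locus.chrom:
                raise ValueError(
                    f"duplicate transcript_id {m.transcript_id} on "
                    f"chromosomes {prev} and {m.locus.chrom}"
                )
            seen[m.transcript_id] = m.locus.chrom
        self.tss = [derive_tss(m) for m in self.models]
        self._tss_by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        tmp: dict[str, list[tuple[int, int]]] = {}
        for i, t in enumerate(self.tss):
            tmp.setdefault(t.chrom, []).append((t.position, i))
        for chrom, pairs in tmp.items():
            pairs.sort()
            self._tss_by_chrom[chrom] = (
                [p for p, _ in pairs],
                [i for _, i in pairs],
            )
        self._locus_trees: dict[str, IntervalTree] = {}
        for i, m in enumerate(self.models):
            tree = self._locus_trees.setdefault(m.locus.chrom, IntervalTree())
            tree.addi(m.locus.start, m.locus.end, i)

    def tss_in_window(self, chrom: str, lo: int, hi: int) -> list[int]:
        """Indices of transcripts whose TSS position lies in [lo, hi]."""
        entry = self._tss_by_chrom.get(chrom)
        if entry is None:
            return []
        positions, idx = entry
        a = bisect.bisect_left(positions, lo)
        b = bisect.bisect_right(positions, hi)
        return idx[a:b]

    def loci_containing(self, chrom: str, position: int) -> list[int]:
        tree = self._locus_trees.get(chrom)
        if tree is None:
            return []
        return sorted(hit.data for hit in tree.at(position))

    def nearest_tss(self, chrom: str, position: int,
                    max_dist: int) -> int | None:
        """Index of the absolutely nearest TSS within ``max_dist`` bp."""
        hits = self.tss_in_window(chrom, position - max_dist,
                                  position + max_dist)
        if not hits:
            return None
        return min(hits, key=lambda i: (abs(self.tss[i].position - position),
                                        self.models[i].transcript_id))


class SummitClassifier(BaseEstimator):
    """Rule-based peak-summit classifier over a fitted transcript reference.

    Parameters
    ----------
    proximal_max : int, default 2000
        Inclusive upstream distance (bp) for the proximal promoter call.
    distal_max : int, default 50000
        Inclusive upstream distance (bp) for the distal promoter call.

    Attributes
    ----------
    index_ : TranscriptIndex
        Window-query index built by :meth:`fit`.
    n_transcripts_ : int
    """

    def __init__(self, proximal_max: int = 2000, distal_max: int = 50000):
        self.proximal_max = proximal_max
        self.distal_max = distal_max

    @property
    def config(self) -> ClassifierConfig:
        return ClassifierConfig(self.proximal_max, self.distal_max)

    def fit(self, transcripts: list[TranscriptModel], y=None):
        self.config  # validates thresholds
        self.index_ = TranscriptIndex(transcripts)
        self.n_transcripts_ = len(self.index_.models)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "index_"):
            raise RuntimeError("SummitClassifier is not fitted; call fit() "
                               "with transcript models first")

    def annotate_summit(self, chrom: str, summit: int,
                        peak_id: str = "peak",
                        summit_imputed: bool = False) -> PeakAnnotation:
        self._check_fitted()
        cfg, index = self.config, self.index_
        associations: list[Association] = []
        # promoter relations: any TSS whose upstream window covers the summit
        window = index.tss_in_window(
            chrom, summit - cfg.distal_max, summit + cfg.distal_max
        )
        for i in window:
            tss = index.tss[i]
            relation = summit_tss_relation(summit, chrom, tss, cfg)
            if relation != "none":
                associations.append(Association(
                    tss.transcript_id, index.models[i].gene_id, relation,
                    upstream_distance(summit, tss),
                ))
        # genic relations: every locus containing the summit
        for i in index.loci_containing(chrom, summit):
            model = index.models[i]
            label = point_in_exon(model, summit)
            if label in ("exonic", "intronic"):
                associations.append(Association(
                    model.transcript_id, model.gene_id, label,
                    upstream_distance(summit, index.tss[i]),
                ))
        associations.sort(
            key=lambda a: (-_PRECEDENCE[a.relation], abs(a.signed_distance),
                           a.transcript_id)
        )
        if associations:
            peak_class = _RELATION_TO_CLASS[associations[0].relation]
        else:
            peak_class = "intergenic"
        return PeakAnnotation(peak_id, chrom, summit, peak_class,
                              tuple(associations), summit_imputed)

    def annotate(self, peaks: list[PeakCall]) -> list[PeakAnnotation]:
        """Full annotation records for a list of peak calls."""
        return [
            self.annotate_summit(p.chrom, p.summit, p.peak_id,
                                 p.summit_imputed)
            for p in peaks
        ]

    def predict(self, peaks: list[PeakCall]) -> list[str]:
        """Class labels only, aligned with ``peaks``."""
        return [a.peak_class for a in self.annotate(peaks)]


def classify_summit(
    peak: PeakCall,
    index: TranscriptIndex | list[TranscriptModel],
    config: ClassifierConfig = ClassifierConfig(),
) -> PeakAnnotation:
    """Functional wrapper around :class:`SummitClassifier` for one peak."""
    clf = SummitClassifier(config.proximal_max, config.distal_max)
    if isinstance(index, TranscriptIndex):
        clf.index_ = index
        clf.n_transcripts_ = len(index.models)
    else:
        clf.fit(index)
    return clf.annotate_summit(peak.chrom, peak.summit, peak.peak_id,
                               peak.summit_imputed)


@dataclass(frozen=True)
class DistributionSummary:
    """Per-class peak counts and percentages (the genomic-distribution plot)."""

    counts: dict[str, int]
    percentages: dict[str, float]
    promoter_total_percent: float
    n_peaks: int


def summarize_distribution(
    annotations: list[PeakAnnotation],
) -> DistributionSummary:
    """Count peaks per class and express each as a percentage of the total."""
    if not annotations:
        raise ValueError("cannot summarize an empty annotation list")
    counter = Counter(a.peak_class for a in annotations)
    unknown = set(counter) - set(PEAK_CLASSES)
    if unknown:
        raise ValueError(f"unknown peak classes {sorted(unknown)}")
    n = len(annotations)
    counts = {cls: counter.get(cls, 0) for cls in PEAK_CLASSES}
    percentages = {cls: 100.0 * c / n for cls, c in counts.items()}
    promoter_total = (percentages["proximal_promoter"]
                      + percentages["distal_promoter"])
    return DistributionSummary(counts, percentages, promoter_total, n)
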
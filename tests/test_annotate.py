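"""Summit classification rules, precedence, and distribution summaries."""

import numpy as np
import pytest

from peaktarget import (
    ClassifierConfig,
    GenomicInterval,
    PeakAnnotation,
    PeakCall,
    SummitClassifier,
    TranscriptModel,
    classify_summit,
    summarize_distribution,
    summit_tss_relation,
)
from peaktarget.genome import TSS, derive_tss

CFG = ClassifierConfig()


@pytest.mark.parametrize("strand,tss_pos,summit,expected", [
    ("+", 10000, 8500, "proximal"),   # d = 1500
    ("+", 10000, 8000, "proximal"),   # d = 2000, inclusive boundary
    ("+", 10000, 10000, "proximal"),  # d = 0, summit exactly at TSS
    ("+", 10000, 7999, "distal"),     # d = 2001
    ("+", 10000, 5000, "distal"),     # d = 5000
    ("+", 60000, 10000, "distal"),    # d = 50000, inclusive distal bound
    ("+", 60001, 10000, "none"),      # d = 50001, past distal_max
    ("+", 10000, 10050, "none"),      # summit downstream of TSS, d < 0
    ("-", 19999, 21499, "proximal"),  # strand mirror, d = 1500
    ("-", 19999, 21999, "proximal"),  # d = 2000 on the minus strand
    ("-", 19999, 22000, "distal"),
    ("-", 19999, 19000, "none"),      # downstream of a minus-strand TSS
])
def test_summit_tss_relation_boundaries(strand, tss_pos, summit, expected):
    tss = TSS("t", "chr1", tss_pos, strand)
    assert summit_tss_relation(summit, "chr1", tss, CFG) == expected


def test_distal_boundary_is_inclusive():
    tss = TSS("t", "chr1", 60000, "+")
    assert summit_tss_relation(10000, "chr1", tss, CFG) == "distal"


def test_chromosome_mismatch_is_none_not_error():
    tss = TSS("t", "chr2", 10000, "+")
    assert summit_tss_relation(9000, "chr1", tss, CFG) == "none"


def test_sign_convention_matches_enumeration():
    """Exhaustive scan of summit positions around a toy TSS: the relation
    label must equal the direct definition at every offset."""
    for strand in "+-":
        tss = TSS("t", "chr1", 100_000, strand)
        for summit in range(100_000 - 52_000, 100_000 + 52_000, 37):
            d = (tss.position - summit) if strand == "+" \
                else (summit - tss.position)
            expected = ("proximal" if 0 <= d <= 2000
                        else "distal" if 2000 < d <= 50_000 else "none")
            assert summit_tss_relation(summit, "chr1", tss, CFG) == expected


def _model(tid, gid, chrom, start, end, strand, exons=None):
    exons = exons or [(start, end)]
    return TranscriptModel(
        tid, gid, gid.upper(), GenomicInterval(chrom, start, end), strand,
        tuple(GenomicInterval(chrom, a, b) for a, b in exons),
    )


def test_precedence_promoter_beats_intronic():
    """A summit intronic in gene A and 1 kb upstream of gene B's TSS is
    proximal_promoter with both associations retained."""
    gene_a = _model("tA", "gA", "chr1", 1000, 11000, "+",
                    exons=[(1000, 2000), (10000, 11000)])
    # gene C's TSS at 6000 is 1 kb downstream of the summit at 5000
    gene_c = _model("tC", "gC", "chr1", 6000, 9000, "+",
                    exons=[(6000, 9000)])
    peak = PeakCall("p", GenomicInterval("chr1", 4900, 5100), 5000)
    ann = classify_summit(peak, [gene_a, gene_c])
    assert ann.peak_class == "proximal_promoter"
    relations = {(a.gene_id, a.relation) for a in ann.associations}
    assert ("gC", "proximal") in relations
    assert ("gA", "intronic") in relations


def test_distal_peak_outside_all_loci():
    gene = _model("t", "g", "chr1", 10000, 20000, "+")
    peak = PeakCall("p", GenomicInterval("chr1", 7400, 7600), 7500)
    assert classify_summit(peak, [gene]).peak_class == "distal_promoter"


def test_far_peak_is_intergenic():
    gene = _model("t", "g", "chr1", 10000, 20000, "+")
    peak = PeakCall("p", GenomicInterval("chr1", 79000, 79200), 79100)
    ann = classify_summit(peak, [gene])
    assert ann.peak_class == "intergenic" and ann.associations == ()


def test_classifier_is_order_invariant(models, peaks_and_truth):
    peaks, _ = peaks_and_truth
    fwd = SummitClassifier().fit(models).predict(peaks)
    rev = SummitClassifier().fit(models[::-1]).predict(peaks)
    assert fwd == rev


def test_strand_mirror_symmetry(models, peaks_and_truth):
    """Reflecting all coordinates and flipping all strands leaves every
    peak class unchanged."""
    peaks, _ = peaks_and_truth
    origin = 200_000_000
    mirrored_models = []
    for m in models:
        locus = GenomicInterval(m.locus.chrom, origin - m.locus.end,
                                origin - m.locus.start)
        exons = tuple(
            GenomicInterval(e.chrom, origin - e.end, origin - e.start)
            for e in reversed(m.exons))
        mirrored_models.append(TranscriptModel(
            m.transcript_id, m.gene_id, m.gene_name, locus,
            "-" if m.strand == "+" else "+", exons))
    mirrored_peaks = [
        PeakCall(p.peak_id,
                 GenomicInterval(p.chrom, origin - p.interval.end,
                                 origin - p.interval.start),
                 origin - 1 - p.summit)
        for p in peaks
    ]
    base = SummitClassifier().fit(models).predict(peaks)
    mirror = SummitClassifier().fit(mirrored_models).predict(mirrored_peaks)
    assert base == mirror


def test_classifier_equals_brute_force_scan(models, peaks_and_truth,
                                            fitted_classifier):
    """Oracle equivalence: the indexed classifier equals a direct scan over
    every (peak, transcript) pair."""
    peaks, _ = peaks_and_truth
    precedence = {"proximal": 4, "distal": 3, "exonic": 2, "intronic": 1}
    to_class = {"proximal": "proximal_promoter", "distal": "distal_promoter",
                "exonic": "exonic", "intronic": "intronic"}
    predicted = fitted_classifier.predict(peaks)
    for peak, label in zip(peaks, predicted):
        relations = []
        for m in models:
            if m.locus.chrom != peak.chrom:
                continue
            tss = derive_tss(m)
            rel = summit_tss_relation(peak.summit, peak.chrom, tss, CFG)
            if rel != "none":
                relations.append(rel)
            if m.locus.contains(peak.summit):
                in_exon = any(e.contains(peak.summit) for e in m.exons)
                relations.append("exonic" if in_exon else "intronic")
        expected = (to_class[max(relations, key=precedence.get)]
                    if relations else "intergenic")
        assert label == expected


def test_sklearn_params_roundtrip():
    clf = SummitClassifier(proximal_max=1000, distal_max=10000)
    assert clf.get_params() == {"proximal_max": 1000, "distal_max": 10000}
    clf.set_params(proximal_max=500)
    assert clf.config.proximal_max == 500


def test_unfitted_classifier_raises():
    with pytest.raises(RuntimeError, match="not fitted"):
        SummitClassifier().predict(
            [PeakCall("p", GenomicInterval("chr1", 0, 10), 5)])


def _annotation(cls, i=0):
    return PeakAnnotation(f"p{i}", "chr1", 100, cls)


def test_distribution_uniform_four_classes():
    anns = [_annotation(c, i) for i, c in enumerate(
        ["proximal_promoter", "distal_promoter", "exonic", "intergenic"])]
    summary = summarize_distribution(anns)
    assert all(v == 25.0 for k, v in summary.percentages.items()
               if k != "intronic")
    assert summary.promoter_total_percent == 50.0


def test_distribution_reproduces_reported_shape():
    """Counts [43, 297, 9, 179, 472] of 1000 give the study's published
    genomic distribution: 4.3 / 29.7 / 0.9 / 17.9 / 47.2 percent with a
    34.0 percent promoter total."""
    counts = {"proximal_promoter": 43, "distal_promoter": 297,
              "exonic": 9, "intronic": 179, "intergenic": 472}
    anns = []
    i = 0
    for cls, n in counts.items():
        for _ in range(n):
            anns.append(_annotation(cls, i))
            i += 1
    summary = summarize_distribution(anns)
    assert summary.n_peaks == 1000
    assert summary.percentages == {
        "proximal_promoter": 4.3, "distal_promoter": 29.7,
        "exonic": 0.9, "intronic": 17.9, "intergenic": 47.2,
    }
    assert summary.promoter_total_percent == pytest.approx(34.0)
    assert sum(summary.counts.values()) == summary.n_peaks


def test_distribution_percentages_sum_to_100(peaks_and_truth,
                                             fitted_classifier):
    peaks, _ = peaks_and_truth
    summary = summarize_distribution(fitted_classifier.annotate(peaks))
    assert sum(summary.percentages.values()) == pytest.approx(100.0, abs=0.05)
    assert sum(summary.counts.values()) == summary.n_peaks


def test_distribution_empty_input_is_error():
    with pytest.raises(ValueError, match="empty"):
        summarize_distribution([])


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        ClassifierConfig(proximal_max=5000, distal_max=2000)
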
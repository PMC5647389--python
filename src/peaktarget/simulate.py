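"""Seeded generators for every input the pipeline consumes.

Every generator is deterministic given ``SimConfig.seed`` and emits files in
the exact dialects the pipeline's readers parse (Ensembl GTF, ENCODE
narrowPeak, MACS14 tables, Cuffdiff ``gene_exp.diff``, BED blacklists,
FASTA, flat gene->term tables), together with a :class:`GroundTruth` that is
consistent with the files *by construction* — re-deriving labels from the
emitted files with the pipeline's own operators reproduces it exactly.

The construction is geometric, not sampled:

* genes are packed into isolated slots wide enough that a peak planted
  relative to one gene can relate to no other gene (slot width =
  2 x distal_max + maximum locus length);
* per-class peak counts follow largest-remainder rounding of the class mix
  (defaults mirror the study's genomic distribution, 4.3 / 29.7 / 0.9 /
  17.9 / 47.2 percent), so distribution summaries are exact, not
  approximate;
* each peak's summit is placed to realise its assigned class under the
  classifier's precedence rules — proximal peaks cover the inclusive
  0 and proximal_max distance boundaries explicitly, intergenic peaks sit
  beyond distal_max (in absolute distance) from every TSS and outside every
  locus;
* the differential-expression table is built to exact significant /
  up / down totals (defaults 2233 down + 2206 up of 38,052 genes) with the
  peak-associated DEG count fixed by ``frac_deg_with_peak``;
* term mappings carry planted over-represented terms with exact study
  overlaps (3x the background rate by default) against null terms at the
  background rate;
* promoter sequences carry exact-word motif plants in an otherwise
  motif-free background (rejection sampling), recorded strand-aware.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genome import TranscriptModel, derive_tss, write_gtf
from .intervals import GenomicInterval
from .peaks import PeakCall, write_narrowpeak
from .integrate import DEGRecord, write_cuffdiff

MOTIF_COMPLEMENT = str.maketrans("ACGT", "TGCA")

STUDY_CLASS_MIX = {
    "proximal_promoter": 0.043,
    "distal_promoter": 0.297,
    "exonic": 0.009,
    "intronic": 0.179,
    "intergenic": 0.472,
}


@dataclass
class SimConfig:
    """Knobs for the synthetic study; defaults mirror the emulated study."""

    seed: int = 0
    # genome
    n_chroms: int = 4
    chrom_length_bp: int | None = None  # None -> computed from packing needs
    n_genes: int = 1000
    exons_per_gene: tuple[int, int] = (2, 5)
    locus_length_range: tuple[int, int] = (5000, 20000)
    # classifier geometry the construction must respect
    proximal_max: int = 2000
    distal_max: int = 50000
    # peaks
    n_peaks: int = 1000
    class_mix: dict[str, float] = field(
        default_factory=lambda: dict(STUDY_CLASS_MIX))
    peak_width_range: tuple[int, int] = (200, 400)
    # differential expression
    n_deg_down: int = 2233
    n_deg_up: int = 2206
    n_nonsig: int = 33613
    frac_deg_with_peak: float = 344 / 4439
    # replicate QC
    n_replicates: int = 5
    n_qc_genes: int = 500
    n_qc_outliers: int = 2
    qc_noise_sd: float = 4.0
    # motif planting
    motif: str = "GGCCGG"
    motif_copies: int = 3
    motif_spacing_bp: int = 60
    motif_upstream_bp: int = 1500

    def __post_init__(self) -> None:
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix must sum to 1, got {total}")
        if any(v < 0 for v in self.class_mix.values()):
            raise ValueError("class_mix proportions must be non-negative")
        if self.exons_per_gene[0] < 2:
            raise ValueError("need >= 2 exons per gene so introns exist")

    @property
    def max_locus_len(self) -> int:
        return self.locus_length_range[1]

    @property
    def slot_width(self) -> int:
        # isolates each gene: nothing planted for one gene can fall within
        # distal_max of another gene's TSS
        return 2 * self.distal_max + self.max_locus_len + 5000

    @property
    def genes_per_chrom(self) -> int:
        return math.ceil(self.n_genes / self.n_chroms)

    def required_chrom_length(self) -> int:
        intergenic_reserve = (
            math.ceil(self.n_peaks / self.n_chroms) * 500 + 10000
        )
        return (self.genes_per_chrom * self.slot_width
                + self.distal_max + intergenic_reserve)

    def resolved_chrom_length(self) -> int:
        needed = self.required_chrom_length()
        if self.chrom_length_bp is None:
            return needed
        if self.chrom_length_bp < needed:
            raise ValueError(
                f"chrom_length_bp={self.chrom_length_bp} cannot pack "
                f"{self.n_genes} genes with {self.distal_max} bp isolation; "
                f"need >= {needed}"
            )
        return self.chrom_length_bp

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


@dataclass
class GroundTruth:
    """What the generators planted, keyed the way the pipeline reports."""

    true_class: dict[str, str] = field(default_factory=dict)
    target_gene: dict[str, str | None] = field(default_factory=dict)
    deg_direction: dict[str, str] = field(default_factory=dict)  # sig only
    deg_with_peak: set[str] = field(default_factory=set)
    peak_gene_ids: set[str] = field(default_factory=set)
    blacklisted_peaks: set[str] = field(default_factory=set)
    motif_plants: list[dict] = field(default_factory=list)
    planted_terms: list[str] = field(default_factory=list)
    qc_outliers: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "true_class": self.true_class,
            "target_gene": self.target_gene,
            "deg_direction": self.deg_direction,
            "deg_with_peak": sorted(self.deg_with_peak),
            "peak_gene_ids": sorted(self.peak_gene_ids),
            "blacklisted_peaks": sorted(self.blacklisted_peaks),
            "motif_plants": self.motif_plants,
            "planted_terms": self.planted_terms,
            "qc_outliers": self.qc_outliers,
        }


def largest_remainder_counts(proportions: dict[str, float],
                             total: int) -> dict[str, int]:
    """Integer class counts summing to ``total`` (largest-remainder)."""
    raw = {cls: p * total for cls, p in proportions.items()}
    counts = {cls: int(math.floor(v)) for cls, v in raw.items()}
    short = total - sum(counts.values())
    leftovers = sorted(raw, key=lambda c: (raw[c] - counts[c], c),
                       reverse=True)
    for cls in leftovers[:short]:
        counts[cls] += 1
    return counts


def _partition(rng: np.random.Generator, length: int, n_parts: int,
               min_len: int) -> list[int]:
    """Split ``length`` into ``n_parts`` integers, each >= min_len."""
    free = length - min_len * n_parts
    if free < 0:
        raise ValueError("locus too short for requested exon count")
    extra = rng.multinomial(free, [1.0 / n_parts] * n_parts)
    return [min_len + int(e) for e in extra]


def simulate_annotation(config: SimConfig, path: str | None = None,
                        ) -> list[TranscriptModel]:
    """Place non-overlapping, strand-alternating multi-exon transcripts.

    Genes occupy isolated slots (see module docstring); writing the GTF is
    optional. Raises if the configured chromosome length cannot hold the
    packing.
    """
    rng = np.random.default_rng(config.seed)
    chrom_len = config.resolved_chrom_length()
    chroms = config.chrom_names()
    lo_exons, hi_exons = config.exons_per_gene
    lo_len, hi_len = config.locus_length_range
    models = []
    for i in range(config.n_genes):
        chrom = chroms[i % config.n_chroms]
        slot = i // config.n_chroms
        slot_start = slot * config.slot_width
        locus_start = slot_start + config.distal_max
        locus_len = int(rng.integers(lo_len, hi_len + 1))
        n_exons = int(rng.integers(lo_exons, hi_exons + 1))
        # alternating exon/intron segments spanning the locus exactly
        segments = _partition(rng, locus_len, 2 * n_exons - 1, 200)
        exons, pos = [], locus_start
        for j, seg in enumerate(segments):
            if j % 2 == 0:
                exons.append(GenomicInterval(chrom, pos, pos + seg))
            pos += seg
        strand = "+" if i % 2 == 0 else "-"
        gid = f"g{i + 1:05d}"
        models.append(TranscriptModel(
            transcript_id=f"t{i + 1:05d}",
            gene_id=gid,
            gene_name=gid.upper(),
            locus=GenomicInterval(chrom, locus_start, locus_start + locus_len),
            strand=strand,
            exons=tuple(exons),
        ))
        if locus_start + locus_len + config.distal_max > chrom_len:
            raise ValueError(
                "infeasible packing; increase chrom_length_bp to "
                f">= {config.required_chrom_length()}"
            )
    # same ordering as parse_gtf, so write->parse is the identity
    models.sort(key=lambda m: (m.locus.chrom, m.locus.start, m.transcript_id))
    if path is not None:
        write_gtf(models, path)
    return models


def _plant_summit(rng: np.random.Generator, cls: str, model: TranscriptModel,
                  config: SimConfig, forced_d: int | None = None) -> int:
    """Summit position realising ``cls`` relative to ``model``."""
    tss = derive_tss(model)
    sign = -1 if model.strand == "+" else 1  # upstream direction
    if cls == "proximal_promoter":
        d = int(rng.integers(0, config.proximal_max + 1)) \
            if forced_d is None else forced_d
        return tss.position + sign * d
    if cls == "distal_promoter":
        d = int(rng.integers(config.proximal_max + 1, config.distal_max + 1))
        return tss.position + sign * d
    if cls == "exonic":
        while True:
            exon = model.exons[int(rng.integers(0, len(model.exons)))]
            pos = int(rng.integers(exon.start, exon.end))
            if pos != tss.position:  # the TSS base itself would be proximal
                return pos
    if cls == "intronic":
        introns = [
            (a.end, b.start)
            for a, b in zip(model.exons, model.exons[1:])
        ]
        start, end = introns[int(rng.integers(0, len(introns)))]
        return int(rng.integers(start, end))
    raise ValueError(f"unknown class {cls!r}")


def simulate_peaks(config: SimConfig, models: list[TranscriptModel],
                   path: str | None = None,
                   truth: GroundTruth | None = None,
                   ) -> tuple[list[PeakCall], GroundTruth]:
    """Plant peaks realising the configured class mix exactly.

    Non-intergenic peaks cycle round-robin over a permutation of the genes
    so distinct genes accumulate peaks first; intergenic summits go to
    gene-free chromosome tails, > distal_max (absolute) from every TSS.
    """
    rng = np.random.default_rng(config.seed + 1)
    truth = truth or GroundTruth()
    counts = largest_remainder_counts(config.class_mix, config.n_peaks)
    chrom_len = config.resolved_chrom_length()
    chroms = config.chrom_names()
    tail_start = config.genes_per_chrom * config.slot_width \
        + config.distal_max + 1
    perm = rng.permutation(len(models))
    lo_w, hi_w = config.peak_width_range

    classes = []
    for cls in ("proximal_promoter", "distal_promoter", "exonic",
                "intronic", "intergenic"):
        classes += [cls] * counts.get(cls, 0)
    order = rng.permutation(len(classes))

    peaks = []
    genic_i = 0
    tail_counter = dict.fromkeys(chroms, 0)
    n_proximal_seen = 0
    for peak_no, ci in enumerate(order):
        cls = classes[ci]
        pid = f"peak{peak_no + 1:05d}"
        if cls == "intergenic":
            chrom = chroms[peak_no % config.n_chroms]
            summit = tail_start + 500 * tail_counter[chrom]
            tail_counter[chrom] += 1
            if summit >= chrom_len:
                raise ValueError("intergenic class unrealizable: chromosome "
                                 "tail exhausted; increase chrom_length_bp")
            gene = None
        else:
            model = models[perm[genic_i % len(models)]]
            genic_i += 1
            forced = None
            if cls == "proximal_promoter":
                # cover both inclusive distance boundaries explicitly
                if n_proximal_seen == 0:
                    forced = 0
                elif n_proximal_seen == 1:
                    forced = config.proximal_max
                n_proximal_seen += 1
            summit = _plant_summit(rng, cls, model, config, forced)
            gene = model.gene_id
            truth.peak_gene_ids.add(gene)
        width = int(rng.integers(lo_w, hi_w + 1))
        offset = int(rng.integers(0, width))
        start = max(0, summit - offset)
        iv = GenomicInterval(chrom if cls == "intergenic" else model.locus.chrom,
                             start, start + width)
        peaks.append(PeakCall(
            pid, iv, summit,
            score=round(float(rng.uniform(20, 200)), 2),
            enrichment=round(float(rng.uniform(2, 50)), 2),
        ))
        truth.true_class[pid] = cls
        truth.target_gene[pid] = gene
    if path is not None:
        write_narrowpeak(peaks, path)
    return peaks, truth


def simulate_blacklist(config: SimConfig, peaks: list[PeakCall],
                       path: str | None = None,
                       frac_blacklisted: float = 0.05,
                       truth: GroundTruth | None = None,
                       ) -> tuple[list[GenomicInterval], GroundTruth]:
    """Blacklist intervals planted inside a fraction of the peaks.

    Each planted interval sits strictly within its peak; the ground-truth
    removed set is computed by pairwise overlap during construction (a
    planted interval may graze a second peak).
    """
    rng = np.random.default_rng(config.seed + 2)
    truth = truth or GroundTruth()
    n_bl = int(round(frac_blacklisted * len(peaks)))
    chosen = rng.choice(len(peaks), size=n_bl, replace=False) if n_bl else []
    intervals = []
    for i in sorted(int(c) for c in chosen):
        p = peaks[i]
        mid = (p.interval.start + p.interval.end) // 2
        intervals.append(GenomicInterval(p.chrom, max(p.interval.start, mid - 50),
                                         min(p.interval.end, mid + 50)))
    for p in peaks:  # construction-time pairwise overlap = ground truth
        if any(p.interval.overlaps(iv) for iv in intervals):
            truth.blacklisted_peaks.add(p.peak_id)
    if path is not None:
        with open(path, "w") as out:
            for iv in sorted(intervals):
                out.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    return intervals, truth


def simulate_de_table(config: SimConfig, models: list[TranscriptModel],
                      path: str | None = None,
                      truth: GroundTruth | None = None,
                      ) -> tuple[list[DEGRecord], GroundTruth]:
    """DE table with exact significant / up / down / peak-overlap totals.

    The gene universe is the simulated genome padded with extra gene ids up
    to ``n_deg_down + n_deg_up + n_nonsig`` rows. Exactly
    ``round(frac_deg_with_peak * n_deg)`` significant genes are drawn from
    the peak-bearing genes recorded in ``truth`` (when available), the rest
    from peak-free genes, so the DEG-with-peak intersection is fixed by
    construction.
    """
    rng = np.random.default_rng(config.seed + 3)
    truth = truth or GroundTruth()
    n_deg = config.n_deg_down + config.n_deg_up
    n_total = n_deg + config.n_nonsig
    universe = [m.gene_id for m in models]
    names = {m.gene_id: m.gene_name for m in models}
    for i in range(len(universe), n_total):
        universe.append(f"pad{i + 1:05d}")
    universe = universe[:n_total]

    peak_genes = sorted(truth.peak_gene_ids & set(universe))
    n_with_peak = int(round(config.frac_deg_with_peak * n_deg))
    n_with_peak = min(n_with_peak, len(peak_genes), n_deg)
    with_peak = [peak_genes[int(i)] for i in
                 rng.choice(len(peak_genes), size=n_with_peak, replace=False)] \
        if n_with_peak else []
    excluded = set(with_peak) | truth.peak_gene_ids
    free_pool = [g for g in universe if g not in excluded]
    n_rest = n_deg - n_with_peak
    if n_rest > len(free_pool):
        raise ValueError("not enough peak-free genes to reach the DEG total")
    rest = [free_pool[int(i)] for i in
            rng.choice(len(free_pool), size=n_rest, replace=False)]
    deg_genes = with_peak + rest
    directions = (["down"] * config.n_deg_down + ["up"] * config.n_deg_up)
    dir_order = rng.permutation(n_deg)

    deg_map = {g: directions[dir_order[i]] for i, g in enumerate(deg_genes)}
    truth.deg_direction.update(deg_map)
    truth.deg_with_peak.update(with_peak)

    records = []
    for gene in universe:
        direction = deg_map.get(gene)
        if direction is not None:
            magnitude = round(float(rng.lognormal(0.5, 0.5)) + 0.05, 4)
            log2fc = magnitude if direction == "up" else -magnitude
            q = round(float(rng.uniform(1e-6, 0.0499)), 6)
            significant = True
        else:
            log2fc = round(float(rng.normal(0.0, 0.1)), 4)
            q = round(float(rng.uniform(0.05, 1.0)), 6)
            significant = False
        value_1 = round(float(rng.lognormal(3.0, 1.0)), 4)
        value_2 = round(value_1 * 2.0 ** log2fc, 4)
        records.append(DEGRecord(
            gene_id=gene,
            gene_name=names.get(gene, gene.upper()),
            log2fc=log2fc,
            q_value=q,
            significant=significant,
            direction=direction or "none",
            fpkm_by_condition=(value_1, value_2),
        ))
    if path is not None:
        write_cuffdiff(records, path)
    return records, truth


def simulate_replicate_matrix(config: SimConfig,
                              truth: GroundTruth | None = None):
    """FPKM matrix with planted low-correlation outlier replicates.

    ``n_replicates`` per condition (WT, MUT); gene baselines are log-normal
    with small per-replicate noise, and ``n_qc_outliers`` WT replicates get
    independent heavy noise (sd ``qc_noise_sd`` on the log2 scale) that
    destroys their correlation with clean peers.
    """
    import pandas as pd

    from .integrate import ReplicateMatrix

    rng = np.random.default_rng(config.seed + 4)
    truth = truth or GroundTruth()
    n_genes = config.n_qc_genes
    base = rng.normal(3.0, 2.0, size=n_genes)  # log2 scale
    effect = rng.normal(0.0, 0.5, size=n_genes)  # MUT condition shift
    cols, data = [], {}
    outliers = [f"WT_rep{i + 1}" for i in range(config.n_qc_outliers)]
    for cond in ("WT", "MUT"):
        for r in range(config.n_replicates):
            name = f"{cond}_rep{r + 1}"
            mean = base + (effect if cond == "MUT" else 0.0)
            sd = config.qc_noise_sd if name in outliers else 0.15
            log2fpkm = mean + rng.normal(0.0, sd, size=n_genes)
            data[name] = np.maximum(2.0 ** log2fpkm - 1.0, 0.0)
            cols.append(name)
    values = pd.DataFrame(data, index=[f"g{i + 1:05d}" for i in range(n_genes)],
                          columns=cols)
    conditions = pd.Series({c: c.split("_")[0] for c in cols})
    truth.qc_outliers = outliers
    return ReplicateMatrix(values, conditions), truth


def simulate_term_mapping(config: SimConfig, study: set[str],
                          background: set[str],
                          n_terms: int = 50, n_planted: int = 5,
                          enrichment_fold: float = 3.0,
                          term_size_range: tuple[int, int] = (60, 140),
                          path: str | None = None, slim_path: str | None = None,
                          truth: GroundTruth | None = None):
    """Flat gene->term mapping with exactly-constructed over-representation.

    Planted terms contain ``round(fold * K * n / N)`` study genes; null
    terms contain the background-rate count ``round(K * n / N)``. Exact
    construction (not sampling) keeps the rank assertions sharp. One
    planted term plus a handful of null terms form the slim subset, so a
    slim-restricted run yields a single significant term.
    """
    from .enrich import TermMapping

    rng = np.random.default_rng(config.seed + 5)
    truth = truth or GroundTruth()
    study_l = sorted(study)
    non_study = sorted(background - study)
    n, N = len(study_l), len(background)
    if not 0 < n < N:
        raise ValueError("need a non-empty study strictly inside background")
    terms = []
    slim_ids = []
    for t in range(n_terms):
        planted = t < n_planted
        K = int(rng.integers(*term_size_range))
        target = enrichment_fold if planted else 1.0
        k = int(round(target * K * n / N))
        k = min(k, n, K)
        picks_study = rng.choice(len(study_l), size=k, replace=False)
        picks_bg = rng.choice(len(non_study), size=K - k, replace=False)
        genes = frozenset(
            [study_l[int(i)] for i in picks_study]
            + [non_study[int(i)] for i in picks_bg]
        )
        # planted ids sort before null ids: deterministic tie-breaking
        term_id = f"T{'A' if planted else 'N'}{t + 1:03d}"
        is_slim = (planted and t == 0) or (not planted and t < n_planted + 5)
        if is_slim:
            slim_ids.append(term_id)
        terms.append(TermMapping(term_id, f"synthetic process {t + 1}",
                                 genes, is_slim))
        if planted:
            truth.planted_terms.append(term_id)
    if path is not None:
        with open(path, "w") as out:
            out.write("gene_id\tterm_id\tterm_name\n")
            for term in terms:
                for gene in sorted(term.genes):
                    out.write(f"{gene}\t{term.term_id}\t{term.term_name}\n")
    if slim_path is not None:
        with open(slim_path, "w") as out:
            for tid in slim_ids:
                out.write(tid + "\n")
    return terms, truth


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


_BASE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)


def _to_str(arr: np.ndarray) -> str:
    return _BASE_LUT[arr].tobytes().decode("ascii")


def _scrub_motif(rng: np.random.Generator, arr: np.ndarray, words: list[str],
                 protected: set[int], max_rounds: int = 200) -> None:
    """Mutate bases until no word occurs outside protected positions."""
    seq = _to_str(arr)
    for _ in range(max_rounds):
        dirty = []
        for word in words:
            start = 0
            while True:
                i = seq.find(word, start)
                if i == -1:
                    break
                span = set(range(i, i + len(word)))
                if not span <= protected:
                    dirty.append((i, len(word), span))
                start = i + 1
        if not dirty:
            return
        for i, m, span in dirty:
            free = sorted(span - protected)
            j = free[int(rng.integers(0, len(free)))]
            arr[j] = (arr[j] + int(rng.integers(1, 4))) % 4
        seq = _to_str(arr)
    raise RuntimeError("failed to scrub accidental motif occurrences")


def simulate_sequences(config: SimConfig, models: list[TranscriptModel],
                       path: str | None = None,
                       plant_genes: list[str] | None = None,
                       truth: GroundTruth | None = None,
                       ) -> tuple[dict[str, str], GroundTruth]:
    """Chromosome sequences with motif clusters planted upstream of TSSs.

    The background is guaranteed free of accidental exact occurrences of
    the motif and its reverse complement (rejection scrubbing). For each
    planted gene, ``motif_copies`` exact words are placed with
    ``motif_spacing_bp`` between starts; the most upstream copy begins
    ``motif_upstream_bp`` upstream of the TSS. Minus-strand genes receive
    the reverse-complement word so the plant reads as the motif in
    TSS-oriented promoter coordinates.
    """
    rng = np.random.default_rng(config.seed + 6)
    truth = truth or GroundTruth()
    motif = config.motif.upper()
    rc = motif.translate(MOTIF_COMPLEMENT)[::-1]
    chrom_len = config.resolved_chrom_length()
    if plant_genes is None:
        plant_genes = [m.gene_id for m in models]
    plant_set = set(plant_genes)

    arrays = {c: _random_sequence(rng, chrom_len)
              for c in config.chrom_names()}
    protected: dict[str, set[int]] = {c: set() for c in arrays}
    plants: list[dict] = []
    for m in models:
        if m.gene_id not in plant_set:
            continue
        tss = derive_tss(m)
        for c in range(config.motif_copies):
            d = config.motif_upstream_bp - c * config.motif_spacing_bp
            if m.strand == "+":
                g_start, word, g_strand = tss.position - d, motif, "+"
            else:
                g_start, word, g_strand = tss.position + d - len(motif) + 1, \
                    rc, "-"
            if g_start < 0 or g_start + len(motif) > chrom_len:
                raise ValueError("motif plant outside chromosome")
            arr = arrays[m.locus.chrom]
            for j, b in enumerate(word):
                arr[g_start + j] = "ACGT".index(b)
            protected[m.locus.chrom].update(
                range(g_start, g_start + len(motif)))
            plants.append({
                "gene_id": m.gene_id, "transcript_id": m.transcript_id,
                "chrom": m.locus.chrom, "genomic_start": int(g_start),
                "strand": g_strand, "upstream_distance": int(d),
            })
    for chrom, arr in arrays.items():
        _scrub_motif(rng, arr, [motif, rc], protected[chrom])
    sequences = {c: _to_str(a) for c, a in arrays.items()}
    truth.motif_plants = plants
    if path is not None:
        with open(path, "w") as out:
            for chrom in config.chrom_names():
                out.write(f">{chrom}\n")
                seq = sequences[chrom]
                for i in range(0, len(seq), 60):
                    out.write(seq[i:i + 60] + "\n")
    return sequences, truth
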
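"""ChIP/RNA-seq integration: DEG tables, peak-gene intersection, replicate QC.

The differential-expression table is consumed, not modelled: significance is
the upstream caller's FDR decision (the ``significant`` column of a Cuffdiff
``gene_exp.diff``), direction the sign of the log2 fold change. Intersection
with peak annotations is pure set algebra at the gene level: a DEG is
peak-associated iff at least one annotated peak lists its gene_id in any
association (promoter, exonic or intronic — intergenic peaks carry no gene).

Replicate QC mirrors the standard expression-correlation screen: Pearson r
on log2(FPKM + 1) for every replicate pair; a replicate whose median
correlation with its same-condition peers falls below ``min_corr`` is
discarded.
"""

from __future__ import annotations

import math
import sys
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotate import PeakAnnotation, TranscriptIndex

CUFFDIFF_COLUMNS = [
    "test_id", "gene_id", "gene", "locus", "sample_1", "sample_2",
    "status", "value_1", "value_2", "log2(fold_change)", "test_stat",
    "p_value", "q_value", "significant",
]


@dataclass(frozen=True)
class DEGRecord:
    """One gene's differential-expression outcome."""

    gene_id: str
    gene_name: str
    log2fc: float
    q_value: float
    significant: bool
    direction: str  # up / down / none
    fpkm_by_condition: tuple[float, float] = (0.0, 0.0)


@dataclass(frozen=True)
class IntegrationResult:
    """The DEG-with-peak intersection and its Venn decomposition."""

    n_deg: int
    n_deg_with_peak: int
    genes: tuple[tuple[str, str, tuple[str, ...]], ...]  # (gene, direction, classes)
    venn: tuple[int, int, int]  # (deg_only, peak_genes_only, intersection)

    @property
    def fraction_deg_with_peak(self) -> float:
        return self.n_deg_with_peak / self.n_deg if self.n_deg else 0.0


def _direction(log2fc: float, significant: bool) -> str:
    if not significant:
        return "none"
    return "up" if log2fc > 0 else "down"


def read_cuffdiff(
    path: str,
    columns: dict[str, str] | None = None,
    q_threshold: float | None = None,
) -> list[DEGRecord]:
    """Read a Cuffdiff ``gene_exp.diff`` (or generic DE TSV) into records.

    Parameters
    ----------
    columns
        Optional mapping from required field names
        (``gene_id, gene_name, value_1, value_2, log2fc, q_value,
        significant``) to the file's column names, for non-Cuffdiff TSVs.
    q_threshold
        If given, overrides the table's own ``significant`` decision with
        ``q_value < q_threshold``.
    """
    names = {
        "gene_id": "gene_id", "gene_name": "gene",
        "value_1": "value_1", "value_2": "value_2",
        "log2fc": "log2(fold_change)", "q_value": "q_value",
        "significant": "significant",
    }
    if columns:
        names.update(columns)
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in (names["gene_id"], names["log2fc"],
                           names["q_value"], names["significant"])
               if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")

    records = []
    for row in table.itertuples(index=False):
        row = dict(zip(table.columns, row))
        q_raw = row[names["q_value"]]
        try:
            q = float(q_raw)
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"{path}: non-numeric q_value {q_raw!r} for gene "
                f"{row[names['gene_id']]}"
            ) from exc
        log2fc = float(row[names["log2fc"]])  # inf/-inf sentinels survive
        if q_threshold is None:
            significant = str(row[names["significant"]]).strip().lower() == "yes"
        else:
            significant = q < q_threshold
        fpkm = (
            float(row.get(names["value_1"], 0.0)),
            float(row.get(names["value_2"], 0.0)),
        )
        records.append(DEGRecord(
            gene_id=str(row[names["gene_id"]]),
            gene_name=str(row.get(names["gene_name"], "")),
            log2fc=log2fc,
            q_value=q,
            significant=significant,
            direction=_direction(log2fc, significant),
            fpkm_by_condition=fpkm,
        ))
    return records


def write_cuffdiff(records: list[DEGRecord], path: str,
                   sample_1: str = "WT", sample_2: str = "MUT") -> None:
    """Write records in the Cuffdiff ``gene_exp.diff`` column layout."""
    rows = []
    for r in records:
        rows.append({
            "test_id": r.gene_id, "gene_id": r.gene_id, "gene": r.gene_name,
            "locus": "-", "sample_1": sample_1, "sample_2": sample_2,
            "status": "OK",
            "value_1": r.fpkm_by_condition[0],
            "value_2": r.fpkm_by_condition[1],
            "log2(fold_change)": r.log2fc,
            "test_stat": 0.0,
            "p_value": r.q_value,
            "q_value": r.q_value,
            "significant": "yes" if r.significant else "no",
        })
    pd.DataFrame(rows, columns=CUFFDIFF_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def intersect_deg_peaks(
    degs: list[DEGRecord],
    annotations: list[PeakAnnotation],
    include_intergenic_nearest: bool = False,
    index: TranscriptIndex | None = None,
    nearest_max_dist: int = 50000,
) -> IntegrationResult:
    """Intersect significant DEGs with peak-associated genes.

    Peak-associated genes are the union of gene_ids over every annotation's
    associations; intergenic peaks contribute none unless
    ``include_intergenic_nearest`` is set, in which case each intergenic
    summit is assigned the absolutely nearest TSS within
    ``nearest_max_dist`` bp (requires ``index``).
    """
    deg_map: dict[str, DEGRecord] = {}
    for r in degs:
        if r.significant:
            deg_map.setdefault(r.gene_id, r)

    peak_genes: dict[str, set[str]] = {}  # gene_id -> peak classes seen
    for a in annotations:
        for gene in a.gene_ids:
            peak_genes.setdefault(gene, set()).add(a.peak_class)
        if include_intergenic_nearest and not a.associations:
            if index is None:
                raise ValueError(
                    "include_intergenic_nearest requires a TranscriptIndex"
                )
            i = index.nearest_tss(a.chrom, a.summit, nearest_max_dist)
            if i is not None:
                gene = index.models[i].gene_id
                peak_genes.setdefault(gene, set()).add(a.peak_class)

    inter = sorted(set(deg_map) & set(peak_genes))
    genes = tuple(
        (g, deg_map[g].direction, tuple(sorted(peak_genes[g])))
        for g in inter
    )
    n_deg = len(deg_map)
    venn = (n_deg - len(inter), len(set(peak_genes) - set(deg_map)),
            len(inter))
    return IntegrationResult(n_deg, len(inter), genes, venn)


@dataclass
class ReplicateMatrix:
    """FPKM expression matrix (genes x replicates) with condition labels."""

    values: pd.DataFrame  # genes x replicates, non-negative
    conditions: pd.Series  # replicate -> condition label

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.conditions.index):
            self.conditions = self.conditions.reindex(self.values.columns)
        if self.conditions.isna().any():
            raise ValueError("every replicate needs a condition label")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("FPKM values must be non-negative")


def replicate_qc(
    matrix: ReplicateMatrix,
    min_corr: float = 0.9,
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Screen replicates by within-condition Pearson correlation.

    Returns (kept replicate ids, discarded replicate ids, full pairwise
    correlation table on log2(FPKM + 1)). Discarding is a greedy fixed
    point: while any replicate's median correlation with the *retained*
    same-condition peers is below ``min_corr``, the worst such replicate is
    removed and medians are recomputed. At convergence a replicate is
    discarded iff its median correlation with the retained peers of its
    condition is below threshold — robust when several outliers would
    otherwise drag down their clean peers' medians. Zero-variance
    replicates (undefined r) are auto-discarded first with a warning.
    """
    if not -1 < min_corr < 1:
        raise ValueError(f"min_corr must be in (-1, 1), got {min_corr}")
    if matrix.values.shape[1] < 2:
        raise ValueError("replicate QC needs >= 2 replicates")
    log = np.log2(matrix.values + 1.0)
    corr = log.corr(method="pearson")
    discarded: list[str] = []
    retained = list(matrix.values.columns)
    for rep in list(retained):
        if float(log[rep].std()) == 0.0:
            print(f"replicate_qc: {rep} has zero variance (undefined r); "
                  "discarded", file=sys.stderr)
            discarded.append(rep)
            retained.remove(rep)
    while True:
        medians: dict[str, float] = {}
        for rep in retained:
            condition = matrix.conditions[rep]
            peers = [c for c in retained
                     if c != rep and matrix.conditions[c] == condition]
            if not peers:
                continue
            with_peers = corr.loc[rep, peers].dropna()
            if len(with_peers):
                medians[rep] = float(with_peers.median())
        failing = {r: m for r, m in medians.items() if m < min_corr}
        if not failing:
            break
        worst = min(sorted(failing), key=failing.get)
        discarded.append(worst)
        retained.remove(worst)
    return retained, discarded, corr
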
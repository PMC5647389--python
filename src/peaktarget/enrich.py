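"""Hypergeometric term over-representation with BH-FDR.

For a study set of n genes drawn from a background universe of N genes, a
term annotating K background genes and k study genes is scored with the
upper-tail hypergeometric probability

    p = P(X >= k),  X ~ Hypergeometric(N, K, n)

and the fold enrichment (k/n) / (K/N). Multiple testing is controlled with
Benjamini-Hochberg step-up FDR by default (Bonferroni and no correction are
available). Two rankings are produced: ascending p and descending fold;
an optional slim restriction tests only terms flagged ``is_slim``.

Term mappings are flat gene <-> term tables, expected pre-propagated up the
ontology graph; no OBO parsing happens here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class TermMapping:
    """One term and the genes annotated to it."""

    term_id: str
    term_name: str
    genes: frozenset[str]
    is_slim: bool = False

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"{self.term_id}: term has no genes")


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's over-representation test."""

    term_id: str
    term_name: str
    k: int  # study genes in term
    n: int  # study size
    K: int  # background genes in term
    N: int  # background size
    p_value: float
    fold: float
    q_value: float = float("nan")


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise ValueError(
            f"impossible configuration k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    # scipy's survival function is P(X > k-1) = P(X >= k), log-space inside
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def read_term_mapping(path: str, slim_path: str | None = None) -> list[TermMapping]:
    """Read a flat gene->term TSV (gene_id, term_id[, term_name]).

    ``slim_path`` optionally names a file with one term_id per line; listed
    terms get ``is_slim=True``.
    """
    genes_by_term: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path) as handle:
        first = True
        for line in handle:
            cols = line.rstrip("\n").split("\t")
            if first and cols[0].lower() in ("gene_id", "gene"):
                first = False
                continue
            first = False
            if len(cols) < 2 or not cols[0]:
                continue
            gene, term = cols[0], cols[1]
            genes_by_term.setdefault(term, set()).add(gene)
            if len(cols) > 2 and cols[2]:
                names.setdefault(term, cols[2])
    slim: set[str] = set()
    if slim_path:
        with open(slim_path) as handle:
            slim = {l.strip() for l in handle if l.strip()}
    return [
        TermMapping(term, names.get(term, term), frozenset(genes),
                    term in slim)
        for term, genes in sorted(genes_by_term.items())
    ]


def run_enrichment(
    study: set[str],
    background: set[str],
    mapping: list[TermMapping],
    slim_only: bool = False,
    alpha: float = 0.05,
    correction: str = "bh",
) -> tuple[list[EnrichmentResult], list[EnrichmentResult]]:
    """Test every term and return (ranked by p asc, ranked by fold desc).

    Term gene sets are intersected with the background before testing;
    terms with no study gene (k = 0) are not reported. ``significant``
    means q_value < alpha under the chosen correction.
    """
    study = set(study)
    background = set(background)
    if not study:
        raise ValueError("study set is empty")
    if not study <= background:
        raise ValueError("study set must be a subset of the background")
    N, n = len(background), len(study)
    results = []
    for term in mapping:
        if slim_only and not term.is_slim:
            continue
        term_genes = term.genes & background
        K = len(term_genes)
        k = len(term_genes & study)
        if k == 0:
            continue
        p = hypergeom_upper(k, K, n, N)
        fold = (k / n) / (K / N)
        results.append(EnrichmentResult(term.term_id, term.term_name,
                                        k, n, K, N, p, fold))
    if results:
        pvals = [r.p_value for r in results]
        if correction == "bh":
            qvals = bh_fdr(pvals)
        elif correction == "bonferroni":
            qvals = np.minimum(np.asarray(pvals) * len(pvals), 1.0).tolist()
        elif correction == "none":
            qvals = pvals
        else:
            raise ValueError(f"unknown correction {correction!r}")
        results = [replace(r, q_value=q) for r, q in zip(results, qvals)]
    by_p = sorted(results, key=lambda r: (r.p_value, -r.fold, r.term_id))
    by_fold = sorted(results, key=lambda r: (-r.fold, r.p_value, r.term_id))
    return by_p, by_fold


def significant_terms(results: list[EnrichmentResult],
                      alpha: float = 0.05) -> list[EnrichmentResult]:
    return [r for r in results if r.q_value < alpha]
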
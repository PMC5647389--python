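# Methods

## Coordinate conventions

Everything internal is 0-based half-open `[start, end)`. GTF (1-based
inclusive) and MACS14 tables (1-based start, absolute 1-based summit) are
converted at the I/O boundary; BED/narrowPeak pass through unchanged. The
TSS is the first transcribed base: `locus.start` on `+`, `locus.end - 1`
on `-`. Keeping a single convention internally confines every off-by-one
risk to two reader/writer pairs, both covered by round-trip and
hand-constructed boundary tests.

## Summit classification

A peak is represented by its summit alone; peak edges never enter the
distance computation. For a summit s and a TSS t the upstream distance
along the direction of transcription is d = t − s on `+` and d = s − t on
`-`. The relation is *proximal* iff 0 ≤ d ≤ 2000 (both boundaries
inclusive, so a summit exactly at the TSS is proximal), *distal* iff
2000 < d ≤ 50000, and *none* otherwise — in particular for any summit on
the downstream side of the TSS (d < 0). Exon/intron labels come from
point containment in each transcript locus; a position exonic in any
containing transcript is exonic.

When several relations coexist the peak class is the highest-precedence
relation under **proximal > distal > exonic > intronic**, with every
contributing (transcript, relation, signed distance) association retained
for gene-level work; *intergenic* means no relation of any kind. The
precedence order is a genuine design choice: the five classes must be
mutually exclusive for a distribution summary to sum to 100%, and
promoter relations are tested before genic containment, so a summit
intronic in one gene but promoter-adjacent to another is a promoter peak.
All transcripts are used (no one-representative-per-gene reduction);
deduplication to genes happens only at the integration step.

The classifier is exposed as a scikit-learn-style estimator
(`SummitClassifier.fit(models)` builds per-chromosome sorted TSS arrays
for binary-searched ±50 kb windows and interval trees for locus
containment; `predict`/`annotate` query them). Classification is
deterministic and invariant to transcript input order; associations are
sorted by (precedence, |distance|, transcript id).

## Blacklist filtering

The artifact blacklist is applied to called peak intervals: ≥ 1 bp of
overlap with any blacklist interval removes the peak (half-open
semantics, so touching intervals never overlap). A summit-only mode is
available. Filtering reads before peak calling would be the upstream
alternative; this package consumes peaks, so interval-level filtering is
the post-hoc equivalent, and the run log states the number removed.

## Integration with differential expression

Significance is the upstream caller's FDR decision (the `significant`
column of `gene_exp.diff`); a `q_threshold` override exists but is off by
default — the package consumes the DE caller's decision rather than
re-thresholding. Direction is the sign of log2 fold change; infinite
fold changes survive as ±inf sentinels. A DEG is peak-associated iff at
least one annotation lists its gene id in any association; intergenic
peaks contribute no gene. An escape hatch
(`include_intergenic_nearest`) assigns intergenic summits to the
absolutely nearest TSS within 50 kb for sensitivity analyses; it is off
by default because an intergenic peak has, by definition, no gene within
the promoter window.

## Replicate QC

Pearson r is computed on log2(FPKM + 1) for every replicate pair.
Discarding is a greedy fixed point: while any replicate's **median
correlation with the currently retained same-condition peers** is below
`min_corr` (default 0.9), the worst such replicate is removed and medians
are recomputed. A single-pass rule ("median with all peers < threshold")
is not robust when several outliers are present at once — each outlier
drags down the medians of its clean peers — whereas the fixed-point rule
removes outliers worst-first and leaves clean replicates untouched; at
convergence every discarded replicate does fail the median rule against
the retained set. Zero-variance replicates (undefined r) are discarded
up front with a warning. The default threshold 0.9 is a conventional
choice for expression replicates; no canonical value exists, so it is
exposed as a parameter.

## Enrichment

Upper-tail hypergeometric p = P(X ≥ k) with X ~ Hypergeom(N, K, n),
computed via `scipy.stats.hypergeom.sf` (log-space internally; an
exhaustive draw-enumeration oracle in the tests verifies it to 1e-12 for
every configuration with N ≤ 12). Fold enrichment is (k/n)/(K/N). The
background universe defaults to the genes in the DE table — the tested
universe — not the genes in the mapping. Terms with k = 0 are not
reported. Benjamini–Hochberg is the default correction (the FDR language
of the emulated analysis; Bonferroni and none are available). Mappings
are flat, pre-propagated gene↔term tables; ontology-graph propagation is
out of scope. Ties in the p ranking break by fold then term id.

## Motif scanning

Exact-word matching only, both strands: minus-strand hits are
occurrences of the reverse complement reported at their plus-strand
offset; overlapping occurrences are all reported and `N` never matches.
A cluster is a maximal run of hits in which consecutive starts differ by
≤ 200 bp, reported at ≥ 2 hits; both parameters are exposed since no
field-standard definition of a promoter motif cluster exists. Promoter
windows are strand-aware (position 0 is the most upstream base; minus
strand windows are reverse-complemented) and truncated at contig edges
with a flag.

## Synthetic data

The generators emit the exact file dialects the readers parse, and their
ground truth is correct by construction rather than by re-measurement:

* **Genome packing.** Each gene occupies an isolated slot of width
  2 × distal_max + max locus length + 5 kb, so nothing placed for one
  gene can fall within 50 kb of another gene's TSS; strands alternate,
  loci are 5–20 kb with 2–5 exons (alternating exon/intron segments
  ≥ 200 bp, multinomially partitioned). Intergenic summits go to a
  gene-free chromosome tail > 50 kb (absolute distance) from every TSS —
  a conservative superset of the classifier's strand-aware rule, so the
  planted label is unambiguous.
* **Peak classes** follow largest-remainder rounding of the class mix —
  default 4.3 / 29.7 / 0.9 / 17.9 / 47.2 percent (proximal, distal,
  exonic, intronic, intergenic) — so summaries hit the target
  percentages exactly rather than in expectation. The first two proximal
  peaks pin the inclusive d = 0 and d = 2000 boundaries. Non-intergenic
  peaks cycle a permutation of the genes round-robin.
* **The DE cohort** defaults to 2233 down + 2206 up significant genes
  among 38,052 (the genome's genes padded with extra ids), with exactly
  `round(frac_deg_with_peak × n_deg)` significant genes drawn from the
  peak-bearing set (default fraction 344/4439). Effect sizes are
  log-normal for DEGs and Normal(0, 0.1) for the rest; q-values land on
  the correct side of 0.05 by construction.
* **Replicate matrices** are log-normal (gene baselines N(3, 2) on log2,
  per-replicate noise sd 0.15) with 2 of 5 wild-type replicates given
  independent heavy noise (sd 4.0 on log2), destroying their pairwise
  correlations.
* **Term mappings** plant over-represented terms with exact study
  overlap `round(3 × K n / N)` against null terms at the background rate
  `round(K n / N)` — constructed, not sampled, so rank assertions hold
  for every seed. One planted term plus five null terms form the slim
  subset, making the slim-restricted run yield exactly one significant
  term.
* **Sequences** are uniform-random ACGT scrubbed free of accidental
  exact motif occurrences (bounded rejection), with 3 motif copies
  planted 60 bp apart starting 1.5 kb upstream of each TSS,
  reverse-complemented for minus-strand genes so the plant reads as the
  motif in promoter-oriented coordinates.

What the generator does **not** emulate: read-level noise, peak-shape or
signal strength, realistic base composition, correlated expression
structure, isoform complexity (one transcript per gene), or ambiguity
between overlapping genes (slots forbid it). Passing tests therefore
demonstrate the correctness of the classification/integration logic
under unambiguous geometry, not robustness to the messiness of real
annotation (nested genes, bidirectional promoters, many isoforms) —
those cases are governed by the precedence rules above but have no
unambiguous ground truth to test against.

## Problem sizes and determinism

The study-scale checks use 1000 transcripts over 4 chromosomes, 5000
peaks, a 38,052-gene DE cohort, 10 replicates × 500 genes for QC, 50
terms over a 5000-gene background, and 10 genes × 2 chromosomes for
sequence simulation — sizes at which every stage runs in seconds while
keeping the published count arithmetic exact. All randomness flows from
`numpy.random.default_rng(seed)` with fixed draw order; a fixed seed
yields byte-identical output files.
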
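# Methods

## Scope and data model

markercov characterizes clusters of an scRNA-seq UMI-count matrix. The
in-memory container is `anndata.AnnData` in the cells × genes orientation;
on disk the 10x triplet layout (Matrix Market `matrix.mtx` in genes × cells,
`features.tsv`, `barcodes.tsv`) and dense TSV are supported. Gene families
are recognized by identifier prefix: `MT-` marks mitochondrial genes and
`HB` hemoglobin genes; the QC rules and the nuclear/mitochondrial split key
on these flags.

The public surface is a set of scikit-learn-style estimators (`QCFilter`,
`LogNormalizer`, `DispersionHVG`, `ScaledPCA`, `GraphClusterer`,
`ClusterSignature`, `MarkerSelector`) with `get_params`/`set_params`,
fitted attributes with trailing underscores, and thin functional wrappers
(`qc_filter`, `normalize_log`, `select_hvg`, …) for script use.

## Quality control

Four rules are applied in one fixed pass (genes → cell count rule → cell
fraction rules → doublet hook), deliberately not iterated to a fixed point:

| rule | default | boundary |
|---|---|---|
| gene detected in < `min_cells_per_gene` cells | 3 | strict `<` |
| cell with < `min_genes_per_cell` detected genes | 200 | strict `<` |
| mitochondrial UMI fraction > `max_mito_fraction` | 0.30 | strict `>` |
| hemoglobin UMI fraction > `max_hemoglobin_fraction` | 0.05 | strict `>` |

"Detected" means UMI count > 0 throughout. The per-cell fractions are
computed on the full pre-filter matrix over all genes (whether the
denominator should instead be nuclear-only is ambiguous in the source
protocol; all-genes was chosen and recorded here). The per-cell detected-
gene count is taken after the gene rule. Removing cells can newly strand
genes below the gene threshold; because the pass is single, such genes
survive — callers wanting a fixed point can re-apply the filter. Each
removed cell is tallied under the first rule it fails, in rule order.
Doublet removal is a pluggable hook (a barcode list or a callable); the
package does not implement doublet detection itself, and the default hook
removes nothing. Removing every cell raises an error rather than returning
an empty matrix.

## Normalization, HVG, PCA, clustering

Normalization is the standard log-CP10k transform: each cell's counts are
divided by the cell total, multiplied by a scale factor (default 10,000)
and mapped through ln(1 + x). The transform is invertible given the stored
per-cell totals (round-trip verified to 1e-10 relative).

Highly variable genes use mean-binned standardized dispersion: per-gene
mean and var/mean dispersion are computed on the de-logged (per-10k)
values, genes are cut into 20 equal-frequency mean bins, dispersion is
z-scored within each bin, and the top-n genes (default 2,000) by
standardized dispersion are kept. Exactly constant genes are never
selected; if fewer varying genes exist than requested, all are returned
with a warning. Within-bin standardization implies a known caveat: when a
mean bin consists almost entirely of genuinely variable genes (as happens
in simulations with a flat baseline mean), their advantage cancels within
the bin. The synthetic generator therefore offers a per-gene baseline-mean
spread (below) to emulate the broad mean distribution of real data.

PCA standardizes each gene (mean 0, unit sd, sd 0 guarded) and clips
standardized values at ±10 before decomposition so single outlier cells
cannot dominate a component. `n_compute` components (default 100) are
computed and the first `n_use` (default 50) used; component signs are fixed
by making each loading vector's largest-magnitude entry positive, making
embeddings reproducible. `n_compute` above the matrix rank limit is reduced
with a warning.

Clustering builds a k-nearest-neighbour graph (k = 20, Euclidean, on the
embedding) and runs Leiden community detection with the RBConfiguration
quality at a given resolution (default 0.4), seeded. The backend is
pluggable and externally supplied labels are first class: a two-column
(barcode, label) TSV can replace clustering entirely, which also expresses
manual cluster merges. Unknown or missing barcodes in a label file are hard
errors naming the offenders.

## Inside/outside statistics and signatures

For one cluster versus all other cells (both groups must be non-empty):

- `avg_in`/`avg_out`: arithmetic means of per-10k normalized (non-log)
  values. The non-log scale was chosen because published per-gene averages
  span 0.4–211, inconsistent with a natural-log scale.
- `lfcio = log2((avg_in + ε)/(avg_out + ε))`, ε = 1e-9, capped at ±25 so a
  zero denominator yields a large finite, order-preserving value.
- `pct_in`/`pct_out`: percent of cells with raw count > 0, computed as
  integer detection counts divided last, so values are exact k/n.
- `ratio = pct_in/pct_out`; +∞ when `pct_out = 0` and `pct_in > 0`; 0 when
  both are 0.

The expression prefilter keeps a gene iff `pct_in ≥ 10` or `pct_out ≥ 10`
("below 10% in both groups" is dropped; the boundary is strict as printed).
Only prefiltered genes are tested; Benjamini–Hochberg adjustment runs over
the tested genes of that comparison. The default test is a two-sided
Wilcoxon rank-sum on normalized values; genes identical across both groups
get p = 1 by convention. The test is pluggable (`test=` accepts any
callable mapping two dense group matrices to per-gene p-values) because the
protocol this package operationalizes used a negative-binomial
likelihood-ratio test (DESeq2 with scran sum factors) whose re-implementation
is out of scope — consequently p/padj values are not comparable across
engines, while the deterministic columns (means, percentages, ratios) are.

A signature keeps rows with `padj ≤ 0.01` and `lfcio ≥ 2` (both boundaries
inclusive as written, so `lfcio = 1.99` is excluded no matter how small the
p-value), sorted by ratio descending with ties broken by higher lfcio, then
lexicographic gene id. An empty signature is valid output.

### Expression bands

Band classification of a gene's LFCio relative to the mean μ and sd σ of
the LFCio distribution of the evaluated genes (sample sd, per comparison):
`barely_detected` (`avg_in ≤ 0.05`) is checked before everything; then, in
order, `very_low` (LFCio ≤ μ−σ, clamping values below μ−2σ), `low`
(μ−σ < LFCio ≤ −0.5), `similar` (|LFCio−μ| ≤ 0.5), `high`
(0.5 < LFCio ≤ μ+σ), `very_high` (LFCio > μ+σ). σ ≤ 0.5 is rejected because
the similar band would overlap its neighbours. The printed source form of
the very-low band ("μ−2σ < LFCio ≤ −μ−σ") is not an interval for μ > 0 and
is treated as a typo for μ−2σ < LFCio ≤ μ−σ. For μ far from 0 the literal
rules leave uncovered points; these fall back to `low` below μ and `high`
above, so the scheme is a total partition for any σ > 0.5. Whether μ/σ
should be per-cluster or global is unspecified in the source; they are
computed per cluster comparison and recorded in the run metadata.

## Marker combinations and coverage

Candidates come from the cluster's signature with `pct_in > 60` (strict);
the k = 5 with the largest ratio are selected (ties: higher lfcio, then
gene id; +∞ ratios sort first). Fewer than k candidates returns them all
with a warning. Coverage of a panel over the in-cluster cells uses raw
count > 0 as "expressed": UCC is the fraction expressing at least one panel
gene, ICC the fraction expressing all, UICC = UCC × ICC. UCC never
decreases and ICC never increases as genes are added; for a single gene
UCC = ICC = pct_in/100 and UICC = (pct_in/100)².

Rough identification ranks reference cell types (a type → gene-set map read
from a two-column TSV; no database is bundled) by the hypergeometric upper
tail P(X ≥ overlap) of the overlap between signature and reference genes in
a stated gene universe, ascending, ties broken by larger overlap; zero
overlap gives p = 1 by the tail convention. The scoring scheme is this
package's own operationalization of a manual comparison step; the final
("exact") assignment of cell types relies on curation and is out of scope.

## Synthetic data generator

The generator emulates the structure of a cell-called droplet experiment:
counts are gamma-Poisson (negative binomial) with a single global
dispersion φ (variance m + φ·m², φ → 0 recovers Poisson), default φ = 0.5 —
typical droplet-data overdispersion. Defaults mirror the structure of the
study the statistics operationalize: 16 clusters with unequal sizes
(the published 16-type composition scaled down 5×, ~2,155 cells), 2,000
genes, 5 planted markers per cluster with fold change 8 applied inside
their own cluster, baseline mean 1 UMI/gene/cell, 13 mitochondrial and 10
hemoglobin genes by prefix, 50 low-quality cells and 20 doublets.

Per-cell library-size factors are log-normal(0, 0.3) so normalization is
non-trivial. Per-gene baseline means are optionally spread log-normally
(`gene_mean_sigma`, default 0: every gene's expected count is exactly
`baseline_mean`, which keeps the count-law checks closed-form; σ ≈ 1
emulates the broad mean distribution of real transcriptomes and is what
makes bin-standardized HVG selection meaningful, see above). Low-quality
cells are a normal draw plus extra mitochondrial UMIs equal to the cell
total, forcing a mitochondrial fraction ≥ 1/2 > 30% by construction.
Doublets are unscaled sums of two random genuine cells — the simplest
defensible model, present only to exercise the removal hook. Marker sets
are disjoint across clusters and drawn from the non-mito/non-hemoglobin
genes; overlapping explicit assignments are rejected. Everything derives
from one integer seed (bitwise reproducible).

What the generator does **not** emulate: transcriptome-wide co-expression
structure, batch effects, ambient RNA, per-gene dispersion variation, or
realistic doublet expression profiles. Tests passing on this generator
therefore demonstrate correctness of the statistics and selection rules
under a clean negative-binomial world, not performance on real tissue.

## Problem sizes and numerical choices

Simulation-backed tests use desk-scale problems chosen to make the checked
properties hold with margin under the stated conditions: count-law checks
at 1,000–2,000 cells; signature/marker recovery at 200-cell clusters,
5 fold-8 markers, 20 seeds; clustering recovery at 3 × 80 cells with 20
fold-8 markers and a 150-gene HVG set (minimum ARI 0.987 over 10 seeds);
type-I-error checks at 500 + 500 cells × 1,000 null genes. Percent-style
exports round half-up at 2 dp, matching printed-table conventions; full
precision is kept in parallel JSON. Exports are byte-identical across
repeated runs on identical inputs, and the run-metadata JSON records all
thresholds, seeds and per-cluster μ/σ needed to re-run identically.

## Known limitations

- p-values from the default rank-sum engine are not comparable to
  count-model GLM engines; published p-dependent quantities (and published
  UICC values, which depend on the underlying matrix and a stochastic
  clustering) are not reproducible from the shipped tables alone.
- Two published composition figures (21.73% for DCs + macrophages, 1.27%
  for B + plasma cells) are not derivable from the shipped per-type counts
  under any grouping found; they are excluded from the worked examples.
- The QC pass is single-shot by design; gene/cell rules do not interact
  iteratively.
- `rough_identify` scores set overlap only; expression-weighted variants
  are possible extensions.
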
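# Methods

This note documents the models, parameter choices and numerical conventions
behind `allosc`, and what the synthetic-data generator does and does not
emulate.

## Data model and assumptions

The pipeline consumes (a) a raw integer gene × cell count matrix with
per-cell study metadata (patient, pre/post-transplant timepoint, donor vs
third-party stimulus, chip), (b) an AIRR-style TCR rearrangement table (one
row per detected chain: locus, V/D/J calls, CDR3 nucleotide and amino-acid
sequence, read count, productivity flag) as produced by an upstream
IgBLAST-class aligner, and (c) gene-set annotation plus gene lengths for
enrichment analysis. Read alignment, CDR3 calling and sequencing chemistry
are out of scope; the pipeline starts from tabular outputs.

Cross-chip batch integration is deliberately not implemented; an optional
per-chip gene-wise centering switch (`per_chip_centering`, off by default)
is provided instead. Synthetic fixtures control batch structure directly, so
anchor-style integration would add complexity without testable benefit here.

## Quality control

A cell is removed when it has fewer than `min_genes` (500) expressed genes,
more than `max_genes` (5000) expressed genes (a doublet signature), or when
more than `max_pct_mito` (5) percent of its counts fall on genes whose
symbol starts with `MT-` (dying cells leak cytoplasmic RNA and retain
mitochondrial transcripts). All three removal inequalities are strict, so
cells at exactly 500/5000 genes or exactly 5.0% mito are retained; the suite
pins this convention on boundary fixtures (499/500/5000/5001 genes,
4.9/5.0/5.1% mito). A zero-count cell has pct_mito defined as 0 and is
always removed. The mito prefix is configurable because the gene set is an
annotation convention, not a biological constant.

## Normalization, HVG, PCA

Normalized expression is `ln(1 + count/cell_total × scale_factor)` with
scale factor 10,000. This makes the normalized profile invariant to
sequencing depth, and exponentiating and rescaling recovers count
proportions exactly (a tested round-trip property).

Highly variable genes are ranked by the variance of standardized counts
under a fitted mean–variance trend: a quadratic fit of log10 variance on
log10 mean, refitted once after dropping the most overdispersed decile so
that strong markers do not inflate the trend at their own means;
standardized residuals are clipped at √n_cells. A plain log-normalized
variance ranking is available (`hvg_method="lognorm_variance"`). Only
protein-coding genes are eligible by default (requires a `biotype` column).
Ties break by gene id, and a constant gene never outranks a variable one.

Before PCA, HVG rows are centered and unit-scaled with values clipped at
±10 (outlier cells would otherwise dominate components). PCA uses the full
SVD; each component's sign is fixed so its largest-magnitude gene loading is
positive, making coordinates reproducible. Default 16 dimensions.

## Graph clustering

Cells are connected to their k = 20 nearest Euclidean neighbors in PCA
space; an edge's weight is the Jaccard overlap of the two cells' neighbor
sets (shared-nearest-neighbor weighting), and zero-overlap edges are
dropped. Louvain modularity optimization with a resolution parameter
(default 0.4) partitions the graph. Determinism: the node order fed to the
optimizer is the barcode sort order shuffled by the seed, so the result is
independent of input cell order and reproducible per seed. Labels are
canonicalized as consecutive integers by decreasing cluster size (ties by
smallest member barcode), so label 0 is always the largest cluster. k and
the resolution are configuration parameters; 20 is an ecosystem-standard
neighborhood size at a few hundred to a few thousand cells.

Cluster annotation assigns each cluster the marker set (e.g. CD4 vs
CD8A/CD8B) with the highest mean in-minus-out expression margin. A cluster
is flagged for exclusion as a non-T contaminant when a configured
contaminant marker (CD14, CD19, NCAM1) is significantly upregulated
one-vs-rest (adjusted p < 0.01 and log2FC > 1, both configurable) — the
analogue of discarding a small monocyte-like cluster from sorted T cells.

## Differential expression

The default test is the two-sided Wilcoxon rank-sum. For groups of at most
10 cells each, the p-value is computed by exact enumeration of the rank-sum
null distribution via dynamic programming over the tied pooled ranks
(doubled to integers); the reported value is min(1, 2·min(P(W≤w), P(W≥w))).
Larger groups use the tie-corrected normal approximation with a 0.5
continuity correction. The exact path is validated against an independent
full-permutation oracle for all group sizes ≤ 8 (agreement to 1e-10) and the
null type-I error is calibrated (raw p < 0.05 fraction in [0.03, 0.07] over
2000 null genes × 10 seeds). A logistic-regression likelihood-ratio test
(expression predicting group membership, deviance vs chi²(1)) is provided as
an alternative method.

Fold change is `log2((mean(expm1(x_in)) + 1)/(mean(expm1(x_out)) + 1))` —
computed on de-logged normalized expression with a pseudocount of one, so it
is finite and exactly antisymmetric under group swap. Genes expressed in
less than `min_pct` (5%) of cells in **both** groups are skipped; the
one-sided reading ("at least one group") is used because a gene expressed
only in the in-group is precisely a marker candidate. Adjustment is
Bonferroni by default (Benjamini–Hochberg selectable) over the tested genes.
Marker ranking keeps genes with adjusted p strictly below 1e-5 and sorts by
|log2FC| (ties by gene id). Pre/post contrasts take post as the in-group, so
negative fold changes mean downregulation after transplantation; both
timepoints must have ≥3 cells in the cluster or the contrast is skipped with
a warning. Cells are pooled across patients within a cluster; a per-patient
covariate is a possible extension, not implemented.

## GO over-representation with length bias correction

Longer genes yield more reads and are more likely to be called DE, biasing
naive enrichment toward categories of long genes. The probability weighting
function P(DE | length) is estimated by sorting genes into up to 20
equal-count length bins, taking per-bin DE proportions at the bin median
length, and smoothing with isotonic regression (monotone nondecreasing),
interpolated back to genes; genes without length get the mean weight, and at
least 90% of tested genes must have lengths. All-DE or no-DE inputs yield a
flat function with a warning; weights are floored at 1e-6.

Each category of size m with k DE genes (of D DE genes in a universe of M)
gets the upper-tail probability P(X ≥ k) under the Wallenius noncentral
hypergeometric distribution with odds = mean weight inside / mean weight
outside the category. With uniform weights the code branches to the exact
central hypergeometric tail. The Wallenius path is validated against a
100,000-draw weighted-urn simulation (exponential-race sampling without
replacement, which realizes the Wallenius scheme exactly). Up- and
downregulated DE genes are tested separately on the sign of avg_log2FC; the
DE threshold feeding GO is adjusted p < 0.01 for cluster markers and < 0.1
for pre/post contrasts, both configurable.

## TCR chain filter cascade

Applied per cell, in order:

1. **Productivity / read depth** — keep chains that are productive and have
   ≥25 reads (inclusive). Productivity uses the record's flag when present,
   otherwise it is computed: CDR3 nucleotide length divisible by 3 and no
   stop codon in the translation. Chains that cannot be assessed (empty or
   non-ACGT CDR3, no flag) are dropped with a logged reason.
2. **Primary-chain selection (r = 1)** — within each (cell, locus), keep the
   highest-read surviving chain; ties break lexicographically by CDR3
   sequence.
3. **Dominance (`top`)** — the selected chain must carry strictly more than
   0.8 of all reads observed for that (cell, locus). The denominator
   includes reads of chains already removed as unproductive: this is the
   conservative reading, because an unproductive chain with a large read
   share still signals an ambiguous well.
4. **Locus fraction (`flocus`)** — among a cell's selected chains, a locus
   is kept only if its reads exceed strictly 0.1 of the cell's
   selected-chain total. Computing flocus on post-selection reads (rather
   than all raw reads) is required for the cascade to be idempotent — with
   raw-read denominators, re-running the cascade on its own output could
   drop a previously retained locus — and idempotence is a tested property.

Boundary conventions: "minimum of 25" is inclusive (≥25); the dominance and
fraction rules are strict (>0.8, >0.1). All four rules are pinned on both
sides of their thresholds in the suite (reads 24/25, top 0.79/0.81, flocus
0.09/0.11).

Clonotype keys are `locus:V:J:CDR3nt`. The D segment is excluded from the
key because TRA has no D and D calls are unreliable; the V(D)J usage table
still reports the full triple. TRD chains pass the cascade and appear in the
filtered chain table but never form clonotypes or enter diversity. A paired
clonotype exists only when both TRA and TRB survive in the same cell.

## Shannon diversity

Per sample and level (TRA, TRB, TRA∧TRB): counts nᵢ per unique clonotype
over the N cells carrying a clonotype at that level, pᵢ = nᵢ/N,
H = −Σ pᵢ ln pᵢ, EH = H/ln S. For S = 1 the formula is 0/0; EH is defined
as 0, matching the verbal meaning (every cell the same clonotype). EH is
invariant under clonotype relabeling and under duplicating every cell, and
weakly decreases when one clonotype's count grows at another's expense at
fixed S (majorization monotonicity) — all property-tested, with H checked
against a brute-force loop. V/J segments in the usage table are ordered by a
bundled genomic-position table; unknown segment names sort last with a
logged notice.

## Synthetic-data generator

The generator emulates the statistical structure of a sorted alloreactive
T-cell study so that every stage has ground truth:

- **Design** — `n_patients` (default 5) × {pre, post} × {donor, third-party}
  samples of `n_cells_per_sample` (default 200) cells, one chip per sample.
  The defaults mirror a cohort with five pre- and five post-transplant
  donor-stimulated samples and a few hundred sorted cells deposited per
  chip.
- **Counts** — negative binomial with variance μ + dispersion·μ² (default
  dispersion 0.5); per-gene baseline means lognormal around `baseline_mean`
  (default 0.5, giving ~600 expressed genes per cell at the 2000-gene desk
  scale). Four clusters by default with decreasing proportions, the last a
  5% monocyte-like contaminant (CD14/CD19/NCAM1 up, CD3D/TNFRSF9 down,
  broader marker program). Each T cluster carries 20 planted marker genes at
  log2FC 2 on well-expressed protein-coding genes; ~10% of genes are labeled
  non-coding to exercise the protein-coding filter.
- **Artifacts** — per-cell mito fraction from Beta(2, 80) (mean ≈2.4%, ~8%
  of healthy cells above the 5% cutoff); dead cells (5%) draw their fraction
  from Uniform(0.08, 0.35); doublets (3%) are exact sums of two freshly
  drawn parent profiles (the parents are stored in the ground truth, and
  conservation is tested).
- **Pre/post effect** — `prepost_gene_count` (5) abundant non-marker genes
  shifted by `prepost_log2fc` (−0.6) in post-transplant cells of one cluster,
  donor-stimulated samples only by default, so the third-party contrast acts
  as a negative control.
- **Repertoire** — per-sample clonotype pools of size
  `unique_clonotype_fraction × n` (0.9) with power-law frequencies
  k^(−clonality_alpha) (α = 0.5); a fraction of exactly 1 assigns every cell
  its own clonotype and α→large concentrates the repertoire (EH→0). CDR3s
  are random in-frame codon strings starting with the canonical cysteine
  codon and no stops, so productivity is computable from sequence, not just
  read from a flag; unproductive chains (5%) get a frameshift or an internal
  stop. Chain reads are negative binomial around `reads_per_chain_mean`
  (150) with shape equal to the mean (Fano factor 2), truncated at 1;
  secondary same-locus chains (10%) get Uniform{1..0.3·primary} reads, which
  exercises the 25-read, dominance and locus-fraction rules on both sides.
  Pools of the same patient and stimulus can share `shared_clonotypes`
  identities across timepoints to create known repertoire overlap.

At these defaults the matched TRA∧TRB equitability per sample comes out
around 0.95–0.97 — the highly polyclonal regime reported for donor-reactive
repertoires.

What the generator does **not** emulate: ambient RNA and barcode swapping,
UMI structure (counts are read-like), patient-level biological variability
beyond sample labels, chip batch effects (unless `chip_shift` > 0, a
per-chip lognormal gene factor), allelic inclusion (secondary chains are
noise, not real second alleles), and realistic V(D)J recombination biases
(segments are drawn uniformly). Passing tests therefore demonstrate
correctness of the pipeline's computations under a controlled model, not
robustness to every artifact of real chips.

## Problem sizes and determinism

The test suite and examples run at a deliberate desk scale — 2000 genes,
200 cells per sample, up to ~4000 cells per study — chosen so the full suite
completes in a couple of minutes while keeping every filter and test
statistically exercised. All randomness flows from explicit seeds
(`rng_seed` for the generator, `seed` for clustering and the pipeline);
equal seeds give bit-identical matrices, chain tables and reports, and this
is tested end to end.

## Known limitations

- At 2000 simulated genes the 5000-expressed-genes doublet filter cannot
  trigger, so simulated doublets survive QC and typically form a small extra
  cluster rather than being removed; on real data (~20k genes) the gene-count
  filter is the intended doublet guard.
- The Louvain implementation optimizes modularity greedily; micro-scale
  partitions can differ between seeds on weakly structured graphs (cluster
  *count* stability across seeds is tested on well-separated synthetic data).
- The logistic-regression DE test falls back to p = 1 when the fit fails
  (e.g. perfect separation with no converged deviance), which is
  conservative.
- Pre/post contrasts pool cells across patients; patient identity is not a
  model covariate.
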
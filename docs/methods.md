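# Methods

This note documents the statistical models, parameter choices and numerical
conventions behind `scbmm`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Quality control and normalization

Genes are retained when detected (raw count > 0) in at least `min_cells = 3`
cells; the boundary is inclusive (a gene in exactly 3 cells stays). The
mitochondrial filter computes each cell's proportion of counts on `mt-`-prefixed
genes and removes cells above `median + nmads * 1.4826 * MAD` with
`nmads = 3`. Two conventions are deliberate and exposed as configuration:
the MAD is the *median* absolute deviation with the 1.4826 normal-consistency
factor (the convention of standard scRNA-seq QC tooling), and rejection is
one-sided — low mitochondrial content is never a reason to drop a cell.
The filter is applied per sample: samples can differ in ambient mitochondrial
content, and a pooled threshold would let a high-mito sample drag the cutoff.

Log-normalization is `ln(1 + scale * x_cg / N_c)` with `scale = 10,000` and
`N_c` the cell's total count; zeros map to zeros, so sparsity is preserved,
and the transform is exactly invertible given `N_c`. Regression of
confounders (detected-molecule count, mitochondrial percentage) during
scaling is intentionally not implemented; downstream stages consume the
log-normalized layer or raw counts only.

"Expressed" everywhere in this package means raw count > 0. Percent-expressed
filters computed on normalized values would be identical (log-normalization
introduces no new zeros), but raw counts make the convention unambiguous.

## Label curation

Curation mirrors the manual steps an analyst applies after clustering and
automated annotation, as explicit operations with a replayable log:

- `merge_labels` renames classes (pure relabeling; cell count invariant).
- `drop_small_types` removes a type entirely when it has fewer than 5 cells
  in any sample ("any" is the default policy; "all" is available). A type
  absent from a sample counts as zero cells there.
- `drop_discordant` removes cells whose label is not their cluster's majority
  label *and* has in-cluster frequency below 10%. The qualitative rule
  ("monocytes sitting in the neutrophil cluster") needs a quantitative
  threshold; 10% is this package's choice, exposed as configuration, and
  should not be attributed to any upstream source.
- `flag_low_complexity_clusters` flags clusters whose median
  detected-genes-per-cell falls below `median − 3 * 1.4826 * MAD` across
  cluster medians. Flagging is separated from exclusion on purpose: dropping
  a whole cluster is an analyst decision, so the package reports and the
  caller subsets.

All curation operations are idempotent, and the union of log entries equals
the set difference between input and output cells.

The reference-centroid annotator is a single-pass simplification: Spearman
correlation of each cell's log-normalized profile against reference type
centroids on the 1,000 highest-variance shared genes, argmax label, ties
broken by reference order, constant profiles labelled `unassigned`.
Iterative fine-tuning among top candidates is omitted; externally produced
labels supplied via `cell_meta` are the primary supported path.

## Differential expression

For cell type *t* at day *d* versus day 0, the cascade is: skip the
comparison when either group has under 5 cells (an empty table with a recorded
reason, not an error); test only genes expressed in ≥ 10% of either group
*and* with linear fold change ≥ 1.5; Wilcoxon rank-sum on log-normalized
values; Bonferroni with multiplier m = total genes in the dataset (not genes
tested — the convention of the common single-cell toolkits, recorded in the
output metadata and configurable); significant = adjusted p < 0.05 and
|logFC| ≥ ln(1.5).

logFC is the natural-log fold change of linear-scale group means:
`ln(mean(expm1(v₁)) + 1) − ln(mean(expm1(v₂)) + 1)`. The +1 terms shrink
fold changes of weakly expressed genes toward zero; this is intentional (it
damps ratios estimated from a handful of counts) and matches how the
widely used toolkits report logFC.

The rank-sum test uses midranks for ties. For pooled sizes n₁+n₂ ≤ 24 the
two-sided p is exact: the permutation distribution of the rank sum over all
C(n, n₁) subsets is computed by generating-function convolution over doubled
midranks (identical to literal enumeration, polynomial time), and p is twice
the smaller tail, capped at 1. The cutoff is set at 24 because the normal
approximation is demonstrably poor for small unbalanced groups under the
heavy ties typical of sparse counts (deviations above 0.1 are easy to
construct at sizes like 2 vs 11), while the exact distribution is cheap
there. Above the cutoff, a normal approximation with tie-corrected variance
and a 0.5 continuity correction is used; at 20 vs 20 it agrees with the
exact p within ~0.005. When every value is tied across both groups, p = 1.

Conserved markers for a cluster require, against *every* other cluster on
pooled timepoints (day 12 excluded by default — most types are depleted
there): ≥ 5 cells per group, ≥ 75% expressing in either group, a ≥ 50-point
difference in percent expressing, and positive logFC ≥ ln 2. The combined
p-value is the maximum over comparisons — the most conservative, order-free
combination; a minimum-p mode exists for compatibility with meta-analytic
toolkit defaults but is not the default here. Comparisons against clusters
below the cell minimum are skipped rather than failing the gene.

## Communication networks

The 20% expression rule is computed per (cell type × timepoint) on raw
counts, never pooling days, and the threshold is inclusive (exactly 20%
qualifies — the boundary is otherwise ambiguous, and inclusiveness is the
choice here, configurable). Links are presence/absence: no expression-level
weighting, no permutation p-values, no receptor complexes — the pair table is
strictly gene-to-gene. Ligand-receptor pairs naming genes absent from the
measured universe are counted in a coverage report instead of raising,
since curated pair lists routinely contain unmeasured genes. Edge weights
are link counts per ordered (sender, receiver) pair including self-loops, so
summed weights equal the number of links; day-versus-day-0 comparisons are
elementwise signed weight differences on the zero-filled node union.

## Over-representation

For a term of size K (restricted to the universe), query of size N and
overlap k, the p-value is the inclusive hypergeometric upper tail
P(X ≥ k) — identical to a one-sided Fisher exact test on the 2×2 table.
The universe is the measured gene set of the filtered matrix, not the union
of the collection: the question is enrichment relative to what could have
been detected. Benjamini–Hochberg runs across all terms of the collection.
Queries under 20 genes are not tested (`enrich_min_genes_gate`); the
rank-based combined scores of web enrichment services are deliberately not
reproduced — raw p + BH is the contract.

## RNA velocity

The steady-state model treats each gene's unspliced abundance as γ·spliced at
equilibrium; velocity is the residual v = u − γs. The estimator: (1) pool
each cell with its k = 25 nearest neighbors (mean) in the space of the first
20 principal components of log1p spliced counts; (2) per gene, select the
top and bottom 2% of cells by pooled spliced expression and fit γ by least
squares through the origin, γ = Σus / Σs²; (3) evaluate v for all cells and
report per-cell magnitudes as the L2 norm over fitted genes. Both tails
enter the fit by default (a top-only mode exists). There is no intercept
term. Genes whose selected spliced values are all zero are dropped from the
fit — never NaN-filled. Pooling operates on raw spliced/unspliced counts;
normalizing before pooling is a defensible alternative but is not what this
estimator does. Determinism: PCA uses a full SVD, and neighbor ties in
distance are broken by cell index via a stable argsort, so results are
reproducible bit-for-bit given input order. Embedding-grid visualization of
velocity arrows is out of scope; the per-cell vectors and magnitudes are the
product.

## Synthetic data generator

Counts are Gamma–Poisson: per-gene baseline rates are lognormal (normalized
to sum to 1), multiplied by planted fold factors, scaled by a lognormal
per-cell depth (default mean ln 3000, sd 0.25), with a global dispersion of
0.3 mixing into the Poisson rate. Dispersion is global, not per-gene — a
simplification exposed in the config. Default sizes mirror the profiled
course: five days (D0–D12), per-day cell counts 6,079 / 4,405 / 5,137 /
6,561 / 4,378, 14,000 genes, ~10 cell types with most types collapsing at the
final day. Tests and the acceptance script run deliberately smaller
configurations (hundreds of cells, hundreds to 2,000 genes) chosen to match
the group sizes the recovery claims are stated at.

Planted structure and its rationale:

- *Markers* get a low baseline (mean count 0.15 outside the type) multiplied
  by 20 inside the type, so they genuinely satisfy percent-expressed
  difference filters the way biological markers do.
- *DE genes* multiply the mean by exp(logFC) in one (type, day) slot and are
  drawn from baseline rates above the 60th percentile: with the ln(mean+1)
  logFC convention, effects planted on near-silent genes shrink below the
  1.5-fold prefilter, and recovery would measure detectability rather than
  the cascade's behavior.
- *Ligand-receptor channels* are planted by controlling the expressed
  fraction directly (Bernoulli presence at 0.70 when active, 0.005 when
  inactive), because the fraction is exactly the statistic the network stage
  thresholds; with ≥ 50 cells per type the realized fractions respect the
  ≥ 0.5 / ≤ 0.05 bounds with probability ≥ 0.99.
- *Velocity genes* take a high baseline (98th percentile) and unspliced
  counts Poisson-distributed around γ·s with lognormal rate jitter
  (sd 0.1); at `noise_sd = 0` the layers are exact expectations, making
  zero-noise recovery a float-tolerance test.

Everything is drawn from a single seeded `numpy` Generator in a fixed order,
so outputs are bit-identical across runs and platforms.

What the generator does *not* emulate — and what passing tests therefore do
not show about real data: ambient RNA and empty droplets, doublets, batch
effects, per-gene dispersion structure, gene–gene correlation, UMI
collisions, or annotation error in the reference. Recovery results certify
the pipeline's statistical machinery under its own model assumptions, not
performance on any particular tissue.

## Pipeline conventions

Per-sample gene filtering is logged per sample, but the merged matrix keeps
the union of per-sample surviving gene sets: intersecting would silently
delete genes expressed only at some timepoints (stage-specific ligands being
the canonical example), blinding cross-timepoint DE and network deltas to
exactly the signal of interest. All outputs are plain TSV/JSON without
timestamps; two runs from the same inputs and configuration are
byte-identical. The resolved configuration is snapshotted to `config.json`
in every output directory, and a JSON-lines log records each filter's
before/after counts.

## Known limitations

- No pseudobulk or mixed-model DE: cells are treated as exchangeable within
  groups, so biological replicate structure is not modelled.
- The Bonferroni-with-all-genes convention is conservative; the
  genes-tested multiplier is available but changes the family definition.
- The communication stage counts qualitative links; two cell types with very
  different expression magnitudes can have equal weights.
- The steady-state velocity model assumes shared kinetics across cells of a
  gene and no time-dependent transcriptional bursts; the dynamical model is
  out of scope.
- The centroid annotator is intentionally minimal and should not replace a
  full reference-based annotation tool on real data.
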
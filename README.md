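# scbmm

A time-course single-cell RNA-seq toolkit for characterizing the bone-marrow
microenvironment (BMM) during leukemia progression. It packages, as tested
reusable components, the computation chain used to follow the *normal* cells of
the marrow — neutrophils, monocytes, B-lineage cells, and hematopoietic
stem/progenitor populations such as GMP, MDP and ST-HSC & MLP — across a
transplant time course (days 0, 3, 6, 9, 12), when most cell types become
depleted by advancing disease at the final day.

It is aimed at computational biologists who have per-timepoint count matrices
(with cluster and cell-type annotations from any upstream pipeline) and want
the downstream statistics with explicit, inspectable filter cascades rather
than a monolithic framework.

## What it computes

**QC and normalization** (`core_io`) — genes detected in < 3 cells are
removed; cells whose mitochondrial read proportion exceeds
median + 3 · 1.4826 · MAD (one-sided) are removed; counts are log-normalized,
`ln(1 + 10,000 · x_cg / Σ_g x_cg)`.

**Label curation** (`annotation_curation`) — explicit, logged, idempotent
rules: merge near-identical classes (e.g. pro-B + pre-B → "pro- and pre-B",
STSL + MLP → "ST-HSC & MLP"), drop types with < 5 cells in any sample, remove
cells whose label is rare (< 10%) and non-majority within their cluster, and
flag clusters with outlying low detected-genes-per-cell. A single-pass
Spearman reference-centroid annotator is included for synthetic tests.

**Differential expression** (`differential_expression`) — per cell type,
each later day versus day 0, Wilcoxon rank-sum on log-normalized values with
the filter cascade: ≥ 5 cells per group, gene expressed in ≥ 10% of either
group, linear fold change ≥ 1.5. P-values are Bonferroni-corrected with the
multiplier equal to the total gene count; fold changes are natural-log fold
changes of linear-scale group means, `logFC = ln(mean₁+1) − ln(mean₂+1)`.
For small samples (n₁+n₂ ≤ 24) the p-value is exact under the tie-aware
permutation distribution; beyond that, a tie-corrected normal approximation
with continuity correction is used. Conserved cluster markers use the
stricter cascade (5 cells / 75% expressed / 50-point percent difference /
two-fold), against every other cluster, with the final day excluded.

**Intercellular communication** (`communication_network`) — a cell type
*expresses* a gene at a timepoint when ≥ 20% of its cells (inclusive) have a
nonzero count. For each ligand→receptor pair in a curated table, a directed
link sender→receiver forms when the sender expresses the ligand and the
receiver the receptor (autocrine links included). Per-timepoint networks
weight each ordered type pair by its link count; networks are compared by
signed weight differences against day 0.

**Over-representation** (`enrichment`) — one-sided hypergeometric tail for
query gene lists (DE genes, expressed ligands/receptors of a type) against a
GMT collection, universe restricted to measured genes, Benjamini–Hochberg
across terms; queries under 20 genes are gated out.

**RNA velocity** (`velocity`) — steady-state model `v = u − γs` on
spliced/unspliced UMI layers: counts pooled over 25 nearest neighbors in PCA
space of the log spliced matrix, γ fit per gene by least squares through the
origin on the top and bottom 2% expression quantiles, per-cell velocity
magnitude as the L2 norm across fitted genes.

**Synthetic time courses** (`synthetic_data`) — a Gamma–Poisson (negative
binomial) generator that plants known cell types, marker genes, DE genes with
chosen log-fold changes, ligand-receptor channels active only in chosen
(sender, receiver, timepoint) slots, and spliced/unspliced layers with known
per-gene γ — so every stage above can be scored against ground truth.

## Worked example

Simulate a 5-day course shaped like a leukemia transplant experiment (six
cell types, ~1,200 cells, 500 genes, most types collapsing at day 12), with a
planted monocyte→ST-HSC & MLP channel active from day 3 and eight genes
doubled in pro- and pre-B cells at day 3, then run the full chain:

```bash
scbmm pipeline --simulate-config sim.json --lr-pairs lr.tsv --seed 1 --out run
```

The run prints its recovery report (abridged):

```
"channel_recovery": { "sensitivity": 1.0, "inactive_link_rate": 0.0,
                      "n_active_channels": 4, "n_inactive_channels": 16 },
"de_recovery":      { "n_planted": 8, "n_recovered": 4, "recall": 0.5,
                      "n_false_positives_in_planted_slots": 0 },
"gamma_recovery":   { "median_relative_error": 0.016, "n_recovered": 15 },
"n_cells_final": 1153, "n_genes_final": 500
```

The planted communication channel is recovered at every active day with no
spurious links, and the per-gene velocity slopes come back within ~2% of
truth. DE recall is 0.5 here because this small course has only ~35
pro- and pre-B cells per day — at that group size a doubling survives the
Bonferroni cut only for well-expressed genes (the acceptance run below, with
300 cells per group, recovers ≥ 95%). Stage artifacts land under `run/`:

```
run/de_counts.tsv                      # per (type, day): n over / n under
pro- and pre-B  D3   4  0              # the planted day-3 response
run/networks/network_D3.tsv            # edge list: D3 Monocytes ST-HSC & MLP 1
run/networks/delta_vs_reference.tsv    # signed change vs day 0 per day
run/gamma.tsv                          # gene  gamma  n_extreme_cells
run/velocity_magnitude.tsv             # per-cell velocity L2 norm
run/curation_log.json, run/log.jsonl   # every filter's before/after counts
```

Every subcommand (`simulate`, `qc`, `annotate`, `de`, `markers`, `commnet`,
`enrich`, `velocity`, `pipeline`) is a thin wrapper over the library; see
`scbmm --help`.

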
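"""Cell-type label curation and a simple reference-centroid annotator.

After clustering and automated annotation, single-cell atlases are
routinely curated by hand: near-identical classes are merged, types with
too few cells per sample are dropped, cells whose label disagrees with
their cluster's consensus are removed, and clusters with anomalously low
transcriptional complexity (few detected genes per cell) are flagged for
exclusion.  This module makes each of those steps an explicit, logged,
idempotent operation.

The annotator here correlates each cell's log-normalized profile against
reference centroids (Spearman, on a shared variable-gene set) in a
single pass; externally produced labels can always be supplied directly
through ``cell_meta`` instead.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core_io import CountMatrix, detected_genes_per_cell, MAD_CONSISTENCY

__all__ = [
    "ReferenceProfiles",
    "CurationLog",
    "annotate_by_centroid",
    "merge_labels",
    "drop_small_types",
    "drop_discordant",
    "flag_low_complexity_clusters",
]

UNASSIGNED = "unassigned"


@dataclass
class ReferenceProfiles:
    """Mean log-expression profiles of pure reference cell types."""

    profiles: pd.DataFrame  # types x genes

    def __post_init__(self) -> None:
        if self.profiles.index.has_duplicates:
            raise ValueError("duplicate reference type names")

    @property
    def type_names(self) -> list[str]:
        return self.profiles.index.tolist()

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReferenceProfiles":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path: str | Path) -> None:
        self.profiles.to_csv(path, sep="\t")


@dataclass
class CurationLog:
    """Ordered record of curation actions; replaying it reproduces the output."""

    actions: list[dict] = field(default_factory=list)

    def record(self, rule: str, **details) -> None:
        self.actions.append({"rule": rule, **details})

    def removed_cell_ids(self) -> set[str]:
        out: set[str] = set()
        for a in self.actions:
            out.update(a.get("removed_cells", []))
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.actions, indent=2, default=str))


def annotate_by_centroid(
    cm: CountMatrix, ref: ReferenceProfiles, top_var_genes: int = 1000
) -> pd.DataFrame:
    """Label each cell by its best-correlated reference centroid.

    Uses Spearman correlation between the cell's ``lognorm`` profile and
    each reference centroid over the shared variable-gene set (the
    ``top_var_genes`` highest-variance genes across centroids).  Ties
    are broken by reference order; constant cell profiles (zero rank
    variance) are labelled ``unassigned``.

    Returns a DataFrame indexed by cell id with columns ``label`` and
    ``score`` (the winning correlation).
    """
    if "lognorm" not in cm.layers:
        raise ValueError("run lognormalize() first: no 'lognorm' layer")

    shared = ref.profiles.columns.intersection(cm.gene_ids)
    if len(shared) == 0:
        raise ValueError("no shared genes between query and reference")
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared genes; need >= 10")

    ref_shared = ref.profiles[shared]
    n_var = min(top_var_genes, len(shared))
    var_order = ref_shared.var(axis=0).to_numpy()
    # stable selection of the highest-variance genes
    top_idx = np.argsort(-var_order, kind="stable")[:n_var]
    genes = shared[top_idx]

    q = cm.layers["lognorm"][:, cm.gene_ids.get_indexer(genes)].toarray()
    r = ref_shared[genes].to_numpy()

    # Spearman = Pearson on midranks
    q_rank = np.apply_along_axis(rankdata, 1, q)
    r_rank = np.apply_along_axis(rankdata, 1, r)

    qc = q_rank - q_rank.mean(axis=1, keepdims=True)
    rc = r_rank - r_rank.mean(axis=1, keepdims=True)
    q_norm = np.linalg.norm(qc, axis=1)
    r_norm = np.linalg.norm(rc, axis=1)

    valid = q_norm > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (qc @ rc.T) / np.outer(np.maximum(q_norm, 1e-300), np.maximum(r_norm, 1e-300))

    best = np.argmax(corr, axis=1)  # argmax takes the first maximum: reference order
    labels = np.where(valid, np.array(ref.type_names, dtype=object)[best], UNASSIGNED)
    scores = np.where(valid, corr[np.arange(len(best)), best], np.nan)

    return pd.DataFrame({"label": labels, "score": scores}, index=cm.cell_ids)


def merge_labels(
    labels: pd.Series, mapping: dict[str, str], ignore_unknown: bool = True
) -> pd.Series:
    """Relabel classes (e.g. pro-B + pre-B -> 'pro- and pre-B').

    Pure renaming: the number of cells is unchanged.  Mapping keys not
    present among the labels warn (or raise when ``ignore_unknown`` is
    False).
    """
    present = set(labels.dropna().unique())
    unknown = [k for k in mapping if k not in present]
    if unknown:
        msg = f"merge_labels: mapping keys not present in labels: {unknown}"
        if ignore_unknown:
            warnings.warn(msg)
        else:
            raise KeyError(msg)
    return labels.map(lambda v: mapping.get(v, v))


def drop_small_types(
    cm: CountMatrix,
    min_cells_per_sample: int = 5,
    policy: str = "any",
    log: CurationLog | None = None,
) -> tuple[CountMatrix, CurationLog]:
    """Remove every cell of a type that is too rare per sample.

    A type is dropped when its cell count is below
    ``min_cells_per_sample`` in *any* sample (timepoint) under the
    default policy, or in *all* samples under ``policy="all"``.  A type
    absent from a sample counts as 0 there.
    """
    if policy not in ("any", "all"):
        raise ValueError("policy must be 'any' or 'all'")
    log = log if log is not None else CurationLog()
    if min_cells_per_sample <= 0:
        return cm, log

    meta = cm.cell_meta
    tab = (
        meta.groupby(["cell_type", "timepoint"], dropna=False, observed=False)
        .size()
        .unstack(fill_value=0)
    )
    if tab.empty:
        return cm, log

    below = tab < min_cells_per_sample
    dropped_types = (
        below.any(axis=1) if policy == "any" else below.all(axis=1)
    )
    dropped_types = dropped_types[dropped_types].index.tolist()
    if not dropped_types:
        return cm, log

    mask_remove = meta["cell_type"].isin(dropped_types).to_numpy()
    removed = cm.cell_ids[mask_remove].tolist()
    out = cm.subset(cells=~mask_remove)
    log.record(
        "drop_small_types",
        min_cells_per_sample=min_cells_per_sample,
        policy=policy,
        dropped_types=[str(t) for t in dropped_types],
        removed_cells=removed,
    )
    return out, log


def drop_discordant(
    cm: CountMatrix,
    min_label_frac_in_cluster: float = 0.10,
    log: CurationLog | None = None,
) -> tuple[CountMatrix, CurationLog]:
    """Remove cells whose label is rare within their cluster.

    Within each cluster, a cell is discordant when its label is not the
    cluster's majority label and that label's in-cluster frequency is
    below ``min_label_frac_in_cluster`` — e.g. a handful of
    monocyte-labelled cells sitting inside the neutrophil cluster.
    """
    log = log if log is not None else CurationLog()
    if min_label_frac_in_cluster <= 0:
        return cm, log

    meta = cm.cell_meta
    remove_mask = np.zeros(cm.n_cells, dtype=bool)
    for cluster, sub in meta.groupby("cluster", dropna=False, observed=False):
        freqs = sub["cell_type"].value_counts(normalize=True)
        if freqs.empty:
            continue
        majority = freqs.index[0]
        bad_labels = freqs[(freqs.index != majority) & (freqs < min_label_frac_in_cluster)].index
        if len(bad_labels):
            bad_cells = sub.index[sub["cell_type"].isin(bad_labels)]
            remove_mask[cm.cell_ids.get_indexer(bad_cells)] = True

    if not remove_mask.any():
        return cm, log
    removed = cm.cell_ids[remove_mask].tolist()
    out = cm.subset(cells=~remove_mask)
    log.record(
        "drop_discordant",
        min_label_frac_in_cluster=min_label_frac_in_cluster,
        removed_cells=removed,
    )
    return out, log


def flag_low_complexity_clusters(cm: CountMatrix, nmads: float = 3.0) -> list[str]:
    """Flag clusters whose median detected-genes-per-cell is an outlier.

    Per cluster, the median number of genes detected per cell is
    computed; clusters whose median lies below
    ``median - nmads * 1.4826 * MAD`` across cluster medians are
    flagged.  Exclusion is left to an explicit ``subset`` call: flagging
    mirrors a manual review step, it does not remove anything.
    """
    clusters = cm.cell_meta["cluster"]
    uniq = clusters.dropna().unique()
    if len(uniq) < 3:
        warnings.warn("flag_low_complexity_clusters: fewer than 3 clusters; nothing flagged")
        return []

    detected = detected_genes_per_cell(cm)
    medians = {}
    for cl in uniq:
        mask = (clusters == cl).to_numpy()
        medians[cl] = float(np.median(detected[mask]))

    vals = np.array(list(medians.values()))
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med))) * MAD_CONSISTENCY
    cutoff = med - nmads * mad
    return [str(cl) for cl, m in medians.items() if m < cutoff]
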
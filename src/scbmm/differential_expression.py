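"""Per-cell-type time-course differential expression and conserved markers.

Expression differences between a timepoint and the day-0 baseline are
tested per cell type with the Wilcoxon rank-sum test on log-normalized
values, after a filter cascade: at least 5 cells per group, at least 10%
of cells expressing the gene in either group, and a linear-scale fold
change of at least 1.5.  P-values are Bonferroni-adjusted with the
multiplier equal to the total number of genes in the dataset, and fold
changes are reported as natural-log fold changes (logFC) of linear-scale
group means.

Conserved markers for a cluster are genes that beat *every* other
cluster under a stricter cascade — 5 cells per group, 75% expressing in
either group, a 50-point difference in percent expressing, and a
two-fold increase — with the last timepoint excluded (cell types are
depleted there).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from pathlib import Path
import json

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .core_io import CountMatrix

__all__ = [
    "DETable",
    "MarkerTable",
    "wilcoxon_rank_sum",
    "log_fold_change",
    "de_by_timepoint",
    "count_de_by_direction",
    "conserved_markers",
]

EXACT_MAX_N = 24  # exact-distribution cutoff for the rank-sum test


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum test
# ---------------------------------------------------------------------------

def _rank_sum_u(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mann-Whitney U for x (midranks for ties) and the pooled ranks."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1 = len(x)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u), ranks


def _exact_p(ranks: np.ndarray, n1: int, u_obs: float) -> float:
    """Two-sided exact p under the permutation distribution with ties.

    The null distribution of the rank sum over all C(n, n1) subsets of
    the pooled midranks is computed by generating-function convolution
    (doubled midranks are integers), which is identical to literal
    enumeration but polynomial-time.  Two-sided p is twice the smaller
    tail, capped at 1.
    """
    n = len(ranks)
    doubled = np.rint(2.0 * ranks).astype(np.int64)
    max_sum = int(doubled.sum())
    # dp[k, s] = number of size-k subsets with doubled rank sum s
    dp = np.zeros((n1 + 1, max_sum + 1))
    dp[0, 0] = 1.0
    for val in doubled:
        for k in range(min(n1, n), 0, -1):
            dp[k, val:] += dp[k - 1, : max_sum + 1 - val]
    counts = dp[n1]
    total = comb(n, n1)
    s_obs = int(round(2.0 * (u_obs + n1 * (n1 + 1) / 2.0)))
    le = counts[: s_obs + 1].sum()
    ge = counts[s_obs:].sum()
    p = 2.0 * min(le, ge) / total
    return min(1.0, float(p))


def _normal_approx_p(ranks: np.ndarray, n1: int, u_obs: float) -> float:
    """Two-sided normal approximation with tie correction and continuity."""
    n = len(ranks)
    n2 = n - n1
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0  # every value tied across both groups
    z = (abs(u_obs - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * norm.sf(z)))


def wilcoxon_rank_sum(x, y, force_approx: bool = False) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) test, two-sided.

    Returns ``(U, p)`` where U is the Mann-Whitney statistic for ``x``.
    For small samples (n1 + n2 <= 24) the p-value is exact under the
    tie-aware permutation distribution (the normal approximation is
    unreliable there, especially with the heavy ties of sparse counts);
    otherwise a normal approximation with tie-corrected variance and
    continuity correction is used.  All values identical across both
    groups gives p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both groups must be non-empty")
    u, ranks = _rank_sum_u(x, y)
    if len(x) + len(y) <= EXACT_MAX_N and not force_approx:
        p = _exact_p(ranks, len(x), u)
    else:
        p = _normal_approx_p(ranks, len(x), u)
    return u, p


# ---------------------------------------------------------------------------
# Fold changes
# ---------------------------------------------------------------------------

def log_fold_change(lognorm1, lognorm2) -> float:
    """Natural-log fold change of linear-scale group means.

    Values are log-normalized expression; the groups are un-logged
    (expm1), averaged, re-shifted by 1 and re-logged:
    ``ln(mean(expm1(v1)) + 1) - ln(mean(expm1(v2)) + 1)``.
    """
    m1 = float(np.mean(np.expm1(np.asarray(lognorm1, dtype=float))))
    m2 = float(np.mean(np.expm1(np.asarray(lognorm2, dtype=float))))
    return float(np.log1p(m1) - np.log1p(m2))


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class DETable:
    """Differential-expression results plus the parameters that produced them."""

    table: pd.DataFrame
    meta: dict = field(default_factory=dict)
    reason: str | None = None  # set when the comparison was skipped

    COLUMNS = (
        "gene", "logFC", "p_raw", "p_adj", "pct_group1", "pct_group2",
        "n1", "n2", "direction", "significant",
    )

    @classmethod
    def empty(cls, reason: str, meta: dict | None = None) -> "DETable":
        return cls(pd.DataFrame(columns=list(cls.COLUMNS)), meta=meta or {}, reason=reason)

    def significant_rows(self) -> pd.DataFrame:
        if self.table.empty:
            return self.table
        return self.table[self.table["significant"]]

    def write(self, path: str | Path) -> None:
        path = Path(path)
        self.table.to_csv(path, sep="\t", index=False)
        sidecar = dict(self.meta)
        if self.reason:
            sidecar["skipped_reason"] = self.reason
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


@dataclass
class MarkerTable:
    """Conserved-marker results for one cluster."""

    table: pd.DataFrame
    meta: dict = field(default_factory=dict)
    reason: str | None = None

    COLUMNS = ("gene", "cluster", "combined_p", "min_logFC", "pct_in", "pct_out_max")

    @classmethod
    def empty(cls, reason: str, meta: dict | None = None) -> "MarkerTable":
        return cls(pd.DataFrame(columns=list(cls.COLUMNS)), meta=meta or {}, reason=reason)

    def write(self, path: str | Path) -> None:
        path = Path(path)
        self.table.to_csv(path, sep="\t", index=False)
        sidecar = dict(self.meta)
        if self.reason:
            sidecar["skipped_reason"] = self.reason
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


# ---------------------------------------------------------------------------
# Group statistics helpers
# ---------------------------------------------------------------------------

def _group_stats(cm: CountMatrix, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(percent expressed, linear-scale mean of expm1(lognorm)) per gene."""
    counts = cm.counts[idx]
    pct = counts.getnnz(axis=0) / len(idx)
    ln = cm.layers["lognorm"][idx]
    lin = ln.copy()
    lin.data = np.expm1(lin.data)
    mean_lin = np.asarray(lin.sum(axis=0)).ravel() / len(idx)
    return pct, mean_lin


def de_by_timepoint(
    cm: CountMatrix,
    cell_type: str,
    timepoint: str,
    reference_timepoint: str = "D0",
    min_cells: int = 5,
    min_pct: float = 0.10,
    min_fold: float = 1.5,
    alpha: float = 0.05,
    bonferroni_all_genes: bool = True,
) -> DETable:
    """Test one cell type at ``timepoint`` against the reference day.

    Groups below ``min_cells`` skip the comparison (empty table with a
    reason).  Genes must be expressed in >= ``min_pct`` of cells in
    either group and show a linear fold change >= ``min_fold`` (either
    direction) to be tested.  The Bonferroni multiplier is the total
    number of genes in the dataset (the toolkit convention), recorded in
    the metadata; set ``bonferroni_all_genes=False`` to use the number
    of genes actually tested.
    """
    if "lognorm" not in cm.layers:
        raise ValueError("run lognormalize() first: no 'lognorm' layer")
    known_types = set(cm.cell_meta["cell_type"].dropna().unique())
    if cell_type not in known_types:
        raise KeyError(f"unknown cell type: {cell_type}")
    known_tps = set(cm.cell_meta["timepoint"].dropna().unique())
    for tp in (timepoint, reference_timepoint):
        if tp not in known_tps:
            raise KeyError(f"unknown timepoint: {tp}")

    meta_common = {
        "cell_type": cell_type,
        "timepoint": timepoint,
        "reference_timepoint": reference_timepoint,
        "min_cells": min_cells,
        "min_pct": min_pct,
        "min_fold": min_fold,
        "alpha": alpha,
        "logFC_convention": "ln(mean(expm1(lognorm))+1) difference",
    }

    in_type = cm.cells_where(cell_type=cell_type)
    g1 = np.flatnonzero(in_type & (cm.cell_meta["timepoint"] == timepoint).to_numpy())
    g2 = np.flatnonzero(in_type & (cm.cell_meta["timepoint"] == reference_timepoint).to_numpy())
    n1, n2 = len(g1), len(g2)
    meta_common.update(n1=n1, n2=n2)

    if n1 < min_cells or n2 < min_cells:
        return DETable.empty("min_cells", meta_common)

    pct1, mean1 = _group_stats(cm, g1)
    pct2, mean2 = _group_stats(cm, g2)
    logfc = np.log1p(mean1) - np.log1p(mean2)

    candidates = np.flatnonzero(
        ((pct1 >= min_pct) | (pct2 >= min_pct)) & (np.abs(logfc) >= np.log(min_fold))
    )

    m = cm.n_genes if bonferroni_all_genes else max(len(candidates), 1)
    meta_common["bonferroni_m"] = int(m)

    ln1 = cm.layers["lognorm"][g1]
    ln2 = cm.layers["lognorm"][g2]

    rows = []
    for gi in candidates:
        x = np.asarray(ln1[:, gi].todense()).ravel()
        y = np.asarray(ln2[:, gi].todense()).ravel()
        _, p = wilcoxon_rank_sum(x, y)
        p_adj = min(1.0, p * m)
        lf = float(logfc[gi])
        rows.append(
            {
                "gene": cm.gene_ids[gi],
                "logFC": lf,
                "p_raw": p,
                "p_adj": p_adj,
                "pct_group1": float(pct1[gi]),
                "pct_group2": float(pct2[gi]),
                "n1": n1,
                "n2": n2,
                "direction": "over" if lf > 0 else "under",
                "significant": bool(p_adj < alpha and abs(lf) >= np.log(min_fold)),
            }
        )

    table = pd.DataFrame(rows, columns=list(DETable.COLUMNS))
    return DETable(table, meta=meta_common)


def count_de_by_direction(de: DETable) -> dict[str, int]:
    """Count significant genes by direction of change."""
    sig = de.significant_rows()
    if sig.empty:
        return {"n_over": 0, "n_under": 0}
    return {
        "n_over": int((sig["direction"] == "over").sum()),
        "n_under": int((sig["direction"] == "under").sum()),
    }


def conserved_markers(
    cm: CountMatrix,
    cluster: str,
    min_cells: int = 5,
    min_pct: float = 0.75,
    min_pct_diff: float = 0.50,
    min_fold: float = 2.0,
    exclude_timepoints: tuple[str, ...] = ("D12",),
    combine: str = "max",
    group_col: str = "cell_type",
) -> MarkerTable:
    """Genes consistently up in ``cluster`` against every other cluster.

    Pairwise Wilcoxon tests of the cluster against each other cluster on
    pooled non-excluded timepoints.  A gene is a marker only if every
    comparison passes all four filters: 5 cells per group, >= 75%
    expressing in either group, a >= 50-point difference in percent
    expressing, and a positive logFC of at least ln(2).  The combined
    p-value is the maximum over comparisons (most conservative;
    ``combine="min"`` gives the anti-conservative alternative).
    """
    if combine not in ("max", "min"):
        raise ValueError("combine must be 'max' or 'min'")
    if "lognorm" not in cm.layers:
        raise ValueError("run lognormalize() first: no 'lognorm' layer")

    keep = ~cm.cell_meta["timepoint"].isin(exclude_timepoints).to_numpy()
    labels = cm.cell_meta[group_col].to_numpy(dtype=object)
    groups = [g for g in pd.unique(labels[keep]) if not pd.isna(g)]
    if len(groups) < 2:
        raise ValueError("need at least 2 clusters for conserved markers")
    if cluster not in groups:
        raise KeyError(f"unknown cluster: {cluster}")

    meta = {
        "cluster": cluster,
        "min_cells": min_cells,
        "min_pct": min_pct,
        "min_pct_diff": min_pct_diff,
        "min_fold": min_fold,
        "exclude_timepoints": list(exclude_timepoints),
        "combine": combine,
    }

    g_in = np.flatnonzero(keep & (labels == cluster))
    if len(g_in) < min_cells:
        return MarkerTable.empty("min_cells", meta)
    pct_in, mean_in = _group_stats(cm, g_in)
    ln_in = cm.layers["lognorm"][g_in]

    others = [g for g in groups if g != cluster]
    surviving = np.arange(cm.n_genes)
    per_cmp: list[tuple[str, np.ndarray, np.ndarray, np.ndarray]] = []
    pct_out_all = []
    for other in others:
        g_out = np.flatnonzero(keep & (labels == other))
        if len(g_out) < min_cells:
            continue  # comparison not evaluable; conservative choice: skip it
        pct_out, mean_out = _group_stats(cm, g_out)
        logfc = np.log1p(mean_in) - np.log1p(mean_out)
        ok = (
            ((pct_in >= min_pct) | (pct_out >= min_pct))
            & ((pct_in - pct_out) >= min_pct_diff)
            & (logfc >= np.log(min_fold))
        )
        surviving = surviving[ok[surviving]]
        per_cmp.append((other, g_out, logfc, pct_out))
        pct_out_all.append(pct_out)
        if len(surviving) == 0:
            break

    if not per_cmp:
        return MarkerTable.empty("no_evaluable_comparisons", meta)

    rows = []
    for gi in surviving:
        x = np.asarray(ln_in[:, gi].todense()).ravel()
        ps, lfs = [], []
        for other, g_out, logfc, _pct_out in per_cmp:
            y = np.asarray(cm.layers["lognorm"][g_out][:, gi].todense()).ravel()
            _, p = wilcoxon_rank_sum(x, y)
            ps.append(p)
            lfs.append(float(logfc[gi]))
        combined = max(ps) if combine == "max" else min(ps)
        rows.append(
            {
                "gene": cm.gene_ids[gi],
                "cluster": cluster,
                "combined_p": combined,
                "min_logFC": min(lfs),
                "pct_in": float(pct_in[gi]),
                "pct_out_max": float(max(p[gi] for p in pct_out_all)),
            }
        )

    return MarkerTable(pd.DataFrame(rows, columns=list(MarkerTable.COLUMNS)), meta=meta)
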
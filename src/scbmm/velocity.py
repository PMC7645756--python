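"""Steady-state RNA velocity from spliced/unspliced UMI layers.

Under the steady-state model, each gene's unspliced abundance is
proportional to its spliced abundance, u = gamma * s, with gamma the
steady-state (degradation/transcription) ratio.  Velocity is the
residual v = u - gamma * s: positive where transcription is being
induced (excess pre-mRNA), negative under repression.

The estimator follows the classic recipe: counts are pooled over each
cell's k nearest neighbors (k = 25) in PCA space of the log spliced
matrix to tame sparsity, gamma is fit per gene by least squares through
the origin on the expression extremes (top and bottom 2% quantiles of
pooled spliced), and velocity is evaluated for every cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .core_io import CountMatrix

__all__ = ["VelocityFit", "knn_pool", "fit_gamma", "compute_velocity", "estimate_velocity"]


@dataclass
class VelocityFit:
    """Per-gene gamma, pooled layers, and the velocity residuals."""

    gamma: dict[str, float]
    fitted_genes: list[str]
    pooled_s: np.ndarray  # cells x fitted genes
    pooled_u: np.ndarray
    velocity: np.ndarray = field(default=None)  # type: ignore[assignment]
    cell_ids: list[str] = field(default_factory=list)
    n_extreme: dict[str, int] = field(default_factory=dict)

    def magnitudes(self) -> np.ndarray:
        """Per-cell L2 norm of the velocity vector over fitted genes."""
        return np.linalg.norm(self.velocity, axis=1)

    def write_gamma(self, path: str | Path) -> None:
        rows = [
            {
                "gene": g,
                "gamma": self.gamma[g],
                "n_extreme_cells": self.n_extreme.get(g, ""),
            }
            for g in self.fitted_genes
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def write_magnitudes(self, path: str | Path) -> None:
        pd.DataFrame(
            {"cell_id": self.cell_ids, "velocity_magnitude": self.magnitudes()}
        ).to_csv(path, sep="\t", index=False)


def _dense(mat) -> np.ndarray:
    return mat.toarray() if sp.issparse(mat) else np.asarray(mat, dtype=float)


def knn_pool(
    s, u, k: int = 25, n_pcs: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Average each cell with its k nearest neighbors in PCA space.

    Neighbors are computed on log1p(spliced) projected to ``n_pcs``
    principal components; each pooled value is the mean over the cell
    and its k neighbors.  Distance ties are broken by cell index
    (stable sort), so the result is deterministic given input order.
    ``k = 0`` returns the inputs unchanged.
    """
    s = _dense(s)
    u = _dense(u)
    if s.shape != u.shape:
        raise ValueError("spliced and unspliced shapes differ")
    n_cells = s.shape[0]
    if k == 0:
        return s.copy(), u.copy()
    if k >= n_cells:
        raise ValueError(f"k={k} must be < number of cells ({n_cells})")

    logs = np.log1p(s)
    n_comp = min(n_pcs, min(logs.shape) - 1)
    if n_comp < 1:
        coords = logs
    else:
        coords = PCA(n_components=n_comp, svd_solver="full", random_state=0).fit_transform(logs)

    pooled_s = np.empty_like(s, dtype=float)
    pooled_u = np.empty_like(u, dtype=float)
    # brute-force chunked distances with stable argsort => index tie-break
    chunk = max(1, int(2e7) // max(n_cells, 1))
    sq = (coords**2).sum(axis=1)
    for lo in range(0, n_cells, chunk):
        hi = min(lo + chunk, n_cells)
        d2 = sq[lo:hi, None] - 2 * coords[lo:hi] @ coords.T + sq[None, :]
        order = np.argsort(d2, axis=1, kind="stable")[:, : k + 1]
        for row, nbrs in enumerate(order):
            pooled_s[lo + row] = s[nbrs].mean(axis=0)
            pooled_u[lo + row] = u[nbrs].mean(axis=0)
    return pooled_s, pooled_u


def fit_gamma(
    pooled_s: np.ndarray,
    pooled_u: np.ndarray,
    extreme_quantile: float = 0.02,
    tails: str = "both",
) -> tuple[dict[int, float], dict[int, int]]:
    """Per-gene steady-state slope on the expression extremes.

    For each gene, the cells in the top (and, by default, bottom)
    ``extreme_quantile`` of pooled spliced expression are selected and
    gamma is the least-squares slope through the origin,
    ``sum(u*s) / sum(s^2)``.  Genes whose selected spliced values are
    all zero are dropped (absent from the result, never NaN).

    Returns ``(gamma_by_column, n_extreme_by_column)`` keyed by gene
    column index.
    """
    if tails not in ("both", "top"):
        raise ValueError("tails must be 'both' or 'top'")
    n_cells, n_genes = pooled_s.shape
    n_ext = max(1, int(np.ceil(extreme_quantile * n_cells)))
    if 2 * n_ext > n_cells:
        raise ValueError("extreme_quantile too large for the number of cells")

    gammas: dict[int, float] = {}
    n_extreme: dict[int, int] = {}
    for g in range(n_genes):
        s_col = pooled_s[:, g]
        order = np.argsort(s_col, kind="stable")
        sel = order[-n_ext:] if tails == "top" else np.concatenate([order[:n_ext], order[-n_ext:]])
        s_sel = s_col[sel]
        denom = float((s_sel**2).sum())
        if denom == 0.0:
            continue  # spliced signal absent on the extremes: not fittable
        u_sel = pooled_u[sel, g]
        gammas[g] = float((u_sel * s_sel).sum() / denom)
        n_extreme[g] = len(sel)
    return gammas, n_extreme


def compute_velocity(pooled_s, pooled_u, gamma: np.ndarray) -> np.ndarray:
    """Residual velocity v[c, g] = pooled_u - gamma[g] * pooled_s."""
    return pooled_u - gamma[None, :] * pooled_s


def estimate_velocity(
    cm: CountMatrix,
    k: int = 25,
    n_pcs: int = 20,
    extreme_quantile: float = 0.02,
    tails: str = "both",
    genes=None,
) -> VelocityFit:
    """End-to-end velocity estimate from a CountMatrix with velocity layers.

    ``genes`` restricts the fit (e.g. to genes with unspliced signal);
    by default all genes with any nonzero unspliced count are fit.
    """
    for lname in ("spliced", "unspliced"):
        if lname not in cm.layers:
            raise ValueError(f"missing layer: {lname!r}")
    s_all = cm.layers["spliced"]
    u_all = cm.layers["unspliced"]

    if genes is None:
        has_u = np.asarray((u_all != 0).sum(axis=0)).ravel() > 0
        gene_idx = np.flatnonzero(has_u)
    else:
        gene_idx = cm.gene_ids.get_indexer(list(genes))
        if (gene_idx < 0).any():
            missing = [g for g, i in zip(genes, gene_idx) if i < 0]
            raise KeyError(f"unknown genes: {missing[:5]}")
    if len(gene_idx) == 0:
        raise ValueError("no genes with unspliced signal to fit")

    s = _dense(s_all[:, gene_idx])
    u = _dense(u_all[:, gene_idx])
    pooled_s, pooled_u = knn_pool(s, u, k=k, n_pcs=n_pcs)
    gamma_by_col, n_ext = fit_gamma(pooled_s, pooled_u, extreme_quantile, tails)

    fitted_cols = sorted(gamma_by_col)
    fitted_genes = [str(cm.gene_ids[gene_idx[c]]) for c in fitted_cols]
    gamma_vec = np.array([gamma_by_col[c] for c in fitted_cols])
    ps = pooled_s[:, fitted_cols]
    pu = pooled_u[:, fitted_cols]
    v = compute_velocity(ps, pu, gamma_vec)

    return VelocityFit(
        gamma={g: float(gm) for g, gm in zip(fitted_genes, gamma_vec)},
        fitted_genes=fitted_genes,
        pooled_s=ps,
        pooled_u=pu,
        velocity=v,
        cell_ids=list(cm.cell_ids),
        n_extreme={g: n_ext[c] for g, c in zip(fitted_genes, fitted_cols)},
    )
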
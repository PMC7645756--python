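"""Count-matrix container, 10x-style bundle I/O, QC filters and normalization.

The central object is :class:`CountMatrix`, a cells x genes sparse count
matrix with per-cell and per-gene metadata and optional named layers
(e.g. ``lognorm``, ``spliced``, ``unspliced``).  On disk, matrices live in
MatrixMarket coordinate format with the 10x convention of genes x rows /
cells x columns; they are transposed to cells x genes on read.

QC follows the standard droplet-RNA-seq recipe: genes detected in fewer
than 3 cells are removed, cells whose mitochondrial read proportion lies
more than 3 scaled median absolute deviations above the median are
removed (one-sided), and counts are log-normalized per cell with a scale
factor of 10,000 (natural log).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "QCReport",
    "read_mtx_bundle",
    "write_mtx_bundle",
    "filter_genes_min_cells",
    "filter_cells_mito",
    "lognormalize",
    "expressed_fraction",
    "flag_mito_genes",
]

#: column order expected in cell_meta.tsv
CELL_META_COLUMNS = ("cell_id", "timepoint", "cell_type", "cluster")

#: consistency constant making the MAD an estimator of the normal sigma
MAD_CONSISTENCY = 1.4826


def _timepoint_categories(values: pd.Series) -> list[str]:
    """Order timepoint labels naturally: D0 < D3 < D12, else lexical."""
    uniq = [v for v in pd.unique(values.dropna())]

    def key(v: str):
        s = str(v)
        digits = "".join(ch for ch in s if ch.isdigit())
        return (0, int(digits)) if digits else (1, s)

    return sorted(uniq, key=key)


@dataclass
class QCReport:
    """Before/after bookkeeping for a single filtering step."""

    step: str
    n_cells_before: int
    n_cells_after: int
    n_genes_before: int
    n_genes_after: int
    removed_cell_ids: list[str] = field(default_factory=list)
    removed_gene_ids: list[str] = field(default_factory=list)
    mito_threshold: float | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_cells_after != self.n_cells_before - len(self.removed_cell_ids):
            raise ValueError("inconsistent cell counts in QCReport")
        if self.n_genes_after != self.n_genes_before - len(self.removed_gene_ids):
            raise ValueError("inconsistent gene counts in QCReport")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))


@dataclass
class CountMatrix:
    """Sparse cells x genes count matrix with metadata and named layers.

    Parameters
    ----------
    counts
        Non-negative integer-valued sparse matrix, cells in rows.
    cell_meta
        Indexed by unique cell id; carries at least ``timepoint``,
        ``cell_type`` and ``cluster`` columns (missing allowed).
    gene_meta
        Indexed by unique gene id (symbol, de-duplicated); carries
        ``is_mito``.
    layers
        Named matrices with the same shape as ``counts``.
    """

    counts: sp.csr_matrix
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame
    layers: dict[str, sp.csr_matrix] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.counts.eliminate_zeros()
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def cell_ids(self) -> pd.Index:
        return self.cell_meta.index

    @property
    def gene_ids(self) -> pd.Index:
        return self.gene_meta.index

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def validate(self) -> None:
        if self.counts.shape != (len(self.cell_meta), len(self.gene_meta)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match metadata "
                f"({len(self.cell_meta)} cells, {len(self.gene_meta)} genes)"
            )
        if self.cell_meta.index.has_duplicates:
            raise ValueError("duplicate cell ids")
        if self.gene_meta.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.counts.nnz:
            data = self.counts.data
            if data.min() < 0:
                raise ValueError("negative values in counts")
            if not np.allclose(data, np.round(data)):
                raise ValueError("non-integer values in counts")
        for name, layer in self.layers.items():
            if layer.shape != self.counts.shape:
                raise ValueError(f"layer {name!r} shape {layer.shape} != counts shape")

    # -- manipulation ----------------------------------------------------
    def subset(self, cells=None, genes=None) -> "CountMatrix":
        """Return a new CountMatrix restricted to the given cells/genes.

        ``cells``/``genes`` may be boolean masks, integer positions, or
        lists of ids.  Layers are subset identically.
        """
        ci = self._as_positions(cells, self.cell_meta.index)
        gi = self._as_positions(genes, self.gene_meta.index)
        counts = self.counts[ci][:, gi]
        layers = {k: sp.csr_matrix(v)[ci][:, gi] for k, v in self.layers.items()}
        return CountMatrix(
            counts=counts,
            cell_meta=self.cell_meta.iloc[ci].copy(),
            gene_meta=self.gene_meta.iloc[gi].copy(),
            layers=layers,
        )

    @staticmethod
    def _as_positions(sel, index: pd.Index) -> np.ndarray:
        if sel is None:
            return np.arange(len(index))
        sel = np.asarray(sel)
        if sel.dtype == bool:
            if sel.shape[0] != len(index):
                raise ValueError("boolean selector has wrong length")
            return np.flatnonzero(sel)
        if sel.dtype.kind in "iu":
            return sel
        return index.get_indexer(sel)

    def copy(self) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts.copy(),
            cell_meta=self.cell_meta.copy(),
            gene_meta=self.gene_meta.copy(),
            layers={k: v.copy() for k, v in self.layers.items()},
        )

    def cells_where(self, **conditions) -> np.ndarray:
        """Boolean mask of cells matching metadata equality conditions."""
        mask = np.ones(self.n_cells, dtype=bool)
        for col, val in conditions.items():
            mask &= (self.cell_meta[col] == val).to_numpy()
        return mask


def flag_mito_genes(gene_ids, prefixes: tuple[str, ...] = ("mt-",)) -> np.ndarray:
    """Mitochondrial flag by symbol prefix (mouse convention ``mt-``)."""
    lowered = [g.lower() for g in gene_ids]
    return np.array([any(g.startswith(p.lower()) for p in prefixes) for g in lowered])


def _dedup_symbols(symbols: list[str]) -> list[str]:
    """Make symbols unique by appending .1, .2 ... in file order."""
    seen: dict[str, int] = {}
    out = []
    for s in symbols:
        if s in seen:
            seen[s] += 1
            out.append(f"{s}.{seen[s]}")
        else:
            seen[s] = 0
            out.append(s)
    return out


def read_mtx_bundle(directory: str | Path, mito_prefixes: tuple[str, ...] = ("mt-",)) -> CountMatrix:
    """Read a 10x-style bundle (matrix.mtx + barcodes.tsv + genes.tsv).

    The on-disk matrix is genes x cells; it is transposed to cells x
    genes.  Optional ``spliced.mtx``/``unspliced.mtx`` (same orientation
    and ordering) become layers; an optional ``cell_meta.tsv`` supplies
    timepoint / cell_type / cluster annotations keyed by barcode.
    """
    directory = Path(directory)
    for fname in ("matrix.mtx", "barcodes.tsv", "genes.tsv"):
        if not (directory / fname).exists():
            raise FileNotFoundError(f"missing required file: {directory / fname}")

    mat = sp.csr_matrix(scipy.io.mmread(directory / "matrix.mtx")).T.tocsr()

    barcodes = (directory / "barcodes.tsv").read_text().split()
    if len(set(barcodes)) != len(barcodes):
        dupes = sorted({b for b in barcodes if barcodes.count(b) > 1})
        raise ValueError(f"duplicate barcodes in barcodes.tsv: {dupes[:5]}")

    genes = pd.read_csv(directory / "genes.tsv", sep="\t", header=None)
    if genes.shape[1] < 2:
        raise ValueError("genes.tsv must have two columns: id, symbol")

    n_cells, n_genes = mat.shape
    if n_cells != len(barcodes):
        raise ValueError(
            f"matrix.mtx has {n_cells} cells but barcodes.tsv has {len(barcodes)} lines"
        )
    if n_genes != len(genes):
        raise ValueError(
            f"matrix.mtx has {n_genes} genes but genes.tsv has {len(genes)} lines"
        )

    gene_ids = _dedup_symbols(genes.iloc[:, 1].astype(str).tolist())
    gene_meta = pd.DataFrame(
        {"accession": genes.iloc[:, 0].astype(str).to_numpy()},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    gene_meta["is_mito"] = flag_mito_genes(gene_ids, mito_prefixes)

    cell_meta = pd.DataFrame(index=pd.Index(barcodes, name="cell_id"))
    meta_path = directory / "cell_meta.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", dtype=str).set_index("cell_id")
        cell_meta = cell_meta.join(meta)
    for col in ("timepoint", "cell_type", "cluster"):
        if col not in cell_meta.columns:
            cell_meta[col] = pd.NA
    if cell_meta["timepoint"].notna().any():
        cell_meta["timepoint"] = pd.Categorical(
            cell_meta["timepoint"],
            categories=_timepoint_categories(cell_meta["timepoint"]),
            ordered=True,
        )

    layers = {}
    for lname in ("spliced", "unspliced"):
        lpath = directory / f"{lname}.mtx"
        if lpath.exists():
            layer = sp.csr_matrix(scipy.io.mmread(lpath)).T.tocsr()
            if layer.shape != mat.shape:
                raise ValueError(f"{lname}.mtx shape {layer.shape} != matrix shape")
            layers[lname] = layer

    return CountMatrix(counts=mat, cell_meta=cell_meta, gene_meta=gene_meta, layers=layers)


def write_mtx_bundle(cm: CountMatrix, directory: str | Path) -> None:
    """Write a bundle readable by :func:`read_mtx_bundle`.

    Counts (and spliced/unspliced layers, when present) are written
    genes x cells; derived layers such as ``lognorm`` are not persisted
    (they are recomputable).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    def _write(name: str, mat: sp.spmatrix) -> None:
        m = sp.coo_matrix(mat.T)
        if np.allclose(m.data, np.round(m.data)):
            m = m.astype(np.int64)
            scipy.io.mmwrite(directory / name, m, field="integer")
        else:
            scipy.io.mmwrite(directory / name, m, precision=17)

    _write("matrix.mtx", cm.counts)
    for lname in ("spliced", "unspliced"):
        if lname in cm.layers:
            _write(f"{lname}.mtx", cm.layers[lname])

    (directory / "barcodes.tsv").write_text("\n".join(cm.cell_ids) + "\n")
    accession = (
        cm.gene_meta["accession"]
        if "accession" in cm.gene_meta.columns
        else pd.Series(cm.gene_ids, index=cm.gene_ids)
    )
    pd.DataFrame({"accession": accession.to_numpy(), "symbol": cm.gene_ids}).to_csv(
        directory / "genes.tsv", sep="\t", header=False, index=False
    )

    meta = cm.cell_meta.reset_index()[["cell_id", "timepoint", "cell_type", "cluster"]]
    if meta[["timepoint", "cell_type", "cluster"]].notna().any().any():
        meta.to_csv(directory / "cell_meta.tsv", sep="\t", index=False)


def filter_genes_min_cells(cm: CountMatrix, min_cells: int = 3) -> tuple[CountMatrix, QCReport]:
    """Remove genes detected (count > 0) in fewer than ``min_cells`` cells.

    All-zero genes are removed for any ``min_cells >= 1``.
    """
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    n_detected = cm.counts.getnnz(axis=0)
    keep = n_detected >= min_cells
    removed = cm.gene_ids[~keep].tolist()
    out = cm.subset(genes=keep)
    report = QCReport(
        step="filter_genes_min_cells",
        n_cells_before=cm.n_cells,
        n_cells_after=cm.n_cells,
        n_genes_before=cm.n_genes,
        n_genes_after=out.n_genes,
        removed_gene_ids=removed,
        params={"min_cells": min_cells},
    )
    return out, report


def mito_fraction(cm: CountMatrix) -> np.ndarray:
    """Per-cell proportion of counts on mitochondrial genes (0 for empty cells)."""
    if "is_mito" not in cm.gene_meta.columns:
        raise ValueError("gene_meta lacks an is_mito column")
    total = np.asarray(cm.counts.sum(axis=1)).ravel()
    mito = np.asarray(cm.counts[:, cm.gene_meta["is_mito"].to_numpy(bool)].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    return frac


def filter_cells_mito(cm: CountMatrix, nmads: float = 3.0) -> tuple[CountMatrix, QCReport]:
    """Drop cells whose mitochondrial proportion is a high outlier.

    A cell is removed when its proportion exceeds
    ``median + nmads * 1.4826 * MAD`` (median absolute deviation; the
    1.4826 factor makes the MAD consistent for a normal sigma).  The
    rejection is one-sided: only the high tail is removed.
    """
    if cm.n_cells < 2:
        raise ValueError("filter_cells_mito needs at least 2 cells")
    frac = mito_fraction(cm)
    med = float(np.median(frac))
    mad = float(np.median(np.abs(frac - med))) * MAD_CONSISTENCY
    threshold = med + nmads * mad
    keep = frac <= threshold
    if not keep.any():
        raise ValueError("mitochondrial filter removed every cell; degenerate input")
    removed = cm.cell_ids[~keep].tolist()
    out = cm.subset(cells=keep)
    report = QCReport(
        step="filter_cells_mito",
        n_cells_before=cm.n_cells,
        n_cells_after=out.n_cells,
        n_genes_before=cm.n_genes,
        n_genes_after=cm.n_genes,
        removed_cell_ids=removed,
        mito_threshold=threshold,
        params={"nmads": nmads, "median": med, "mad_scaled": mad},
    )
    return out, report


def lognormalize(cm: CountMatrix, scale: float = 10_000.0) -> CountMatrix:
    """Add a ``lognorm`` layer: ln(1 + scale * count / cell_total).

    Sparse zeros stay zeros.  Cells with zero total counts are an error
    (they cannot be normalized).
    """
    totals = np.asarray(cm.counts.sum(axis=1)).ravel()
    if (totals == 0).any():
        bad = cm.cell_ids[totals == 0][0]
        raise ValueError(f"cell {bad!r} has zero total counts; cannot normalize")
    norm = sp.diags(scale / totals) @ cm.counts.astype(np.float64)
    norm = norm.tocsr()
    norm.data = np.log1p(norm.data)
    cm.layers["lognorm"] = norm
    return cm


def expressed_fraction(cm: CountMatrix, cells, gene: str) -> float:
    """Fraction of the selected cells with a nonzero raw count for ``gene``."""
    gi = cm.gene_ids.get_indexer([gene])
    if gi[0] < 0:
        raise KeyError(f"unknown gene: {gene}")
    ci = cm._as_positions(cells, cm.cell_meta.index)
    if len(ci) == 0:
        raise ValueError("empty cell selection")
    col = cm.counts[ci, gi[0]]
    return float((np.asarray(col.todense()).ravel() > 0).mean())


def detected_genes_per_cell(cm: CountMatrix) -> np.ndarray:
    """Number of genes with nonzero count in each cell."""
    return cm.counts.getnnz(axis=1)


def warn_if_empty(cm: CountMatrix, context: str) -> None:
    if cm.n_cells == 0 or cm.n_genes == 0:
        warnings.warn(f"{context}: empty matrix ({cm.n_cells} cells, {cm.n_genes} genes)")
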
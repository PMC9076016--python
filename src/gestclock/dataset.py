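"""Cell x gene expression container and on-disk layout.

:class:`ExpressionDataset` is the carrier object threaded through QC,
signature scoring and the clock.  It is deliberately light: a (sparse or
dense) cells x genes matrix, a gene-name index, a per-cell metadata frame,
and a ``layer_tag`` recording which processing stage the values represent
(``counts`` -> ``lognorm`` -> ``imputed`` -> ``scaled``).

On disk a dataset is a directory with ``matrix.mtx`` (cells as rows),
``genes.tsv`` (one symbol per line) and ``cells.tsv`` (tab-separated cell
metadata) -- the plain-text layout produced by the synthetic-cohort
generator and accepted by every pipeline entry point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

__all__ = [
    "ExpressionDataset",
    "read_dataset",
    "write_dataset",
    "stage_from_weeks",
    "period_from_weeks",
    "STAGES",
    "PERIODS",
]

Matrix = Union[np.ndarray, sparse.spmatrix]

#: canonical pregnancy-stage labels in chronological order
STAGES = ("non-pregnant", "first", "second", "third")
#: coarse pregnancy periods used to stratify the clock's train/test split
PERIODS = ("early", "middle", "late")

REQUIRED_META = ("cell_id", "subject_id", "cell_type", "ga_days", "ga_weeks", "stage")


def stage_from_weeks(ga_weeks: int, early_substage: bool = False) -> str:
    """Map gestational weeks to a pregnancy stage label.

    Non-pregnant samples carry gestational age 0.  Trimester cutoffs follow
    the clinical convention: first = weeks 1-13, second = 14-27, third >= 28.
    With ``early_substage=True`` the first trimester is further split into
    ``first-early`` (GW6-9 and any week <= 9) and ``first-late`` (GW10-13),
    the finer sub-staging used when dissecting early-pregnancy interferon
    dynamics.
    """
    if ga_weeks <= 0:
        return "non-pregnant"
    if ga_weeks <= 13:
        if early_substage:
            return "first-early" if ga_weeks <= 9 else "first-late"
        return "first"
    if ga_weeks <= 27:
        return "second"
    return "third"


def period_from_weeks(ga_weeks: int) -> str:
    """Map gestational weeks to the early/middle/late period (pregnant only)."""
    if ga_weeks <= 0:
        raise ValueError("period is defined for pregnant samples only (ga_weeks >= 1)")
    if ga_weeks <= 13:
        return "early"
    if ga_weeks <= 27:
        return "middle"
    return "late"


@dataclass
class ExpressionDataset:
    """Cells x genes expression values plus per-cell metadata.

    Parameters
    ----------
    X
        cells x genes matrix of non-negative values (raw counts or a
        normalized layer); scipy sparse or dense ndarray.
    gene_names
        unique gene symbols, length equal to ``X.shape[1]``.
    cell_meta
        one record per cell with at least the columns in
        :data:`REQUIRED_META`; the frame index is reset internally so row i
        of ``X`` corresponds to row i of ``cell_meta``.
    layer_tag
        which processing layer the values represent.
    """

    X: Matrix
    gene_names: pd.Index
    cell_meta: pd.DataFrame
    layer_tag: str = "counts"
    mito_prefix: str = "MT-"
    _mito_mask: np.ndarray = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        self.gene_names = pd.Index(self.gene_names)
        if not self.gene_names.is_unique:
            raise ValueError("gene names must be unique")
        if self.X.shape[0] != len(self.cell_meta):
            raise ValueError(
                f"matrix has {self.X.shape[0]} rows but metadata has "
                f"{len(self.cell_meta)} records"
            )
        if self.X.shape[1] != len(self.gene_names):
            raise ValueError("matrix column count does not match gene_names")
        if self.layer_tag not in ("counts", "lognorm", "imputed", "scaled"):
            raise ValueError(f"unknown layer_tag {self.layer_tag!r}")
        self.cell_meta = self.cell_meta.reset_index(drop=True)
        if {"ga_days", "ga_weeks"} <= set(self.cell_meta.columns) and len(self.cell_meta):
            days = np.asarray(self.cell_meta["ga_days"], dtype=int)
            weeks = np.asarray(self.cell_meta["ga_weeks"], dtype=int)
            if not np.array_equal(weeks, days // 7):
                raise ValueError("ga_weeks must equal floor(ga_days / 7)")
        self._mito_mask = np.fromiter(
            (g.upper().startswith(self.mito_prefix.upper()) for g in self.gene_names),
            dtype=bool,
            count=len(self.gene_names),
        )

    # -- basic geometry -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    def dense(self) -> np.ndarray:
        """Return the matrix as a dense float array (copy if sparse)."""
        if sparse.issparse(self.X):
            return np.asarray(self.X.todense(), dtype=float)
        return np.asarray(self.X, dtype=float)

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            self.X.copy(),
            self.gene_names.copy(),
            self.cell_meta.copy(),
            self.layer_tag,
            self.mito_prefix,
        )

    def subset_cells(self, mask_or_idx) -> "ExpressionDataset":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        X = self.X[idx]
        return ExpressionDataset(
            X, self.gene_names, self.cell_meta.iloc[idx], self.layer_tag, self.mito_prefix
        )

    def subset_genes(self, genes) -> "ExpressionDataset":
        pos = self.gene_names.get_indexer(pd.Index(genes))
        if (pos < 0).any():
            missing = [g for g, p in zip(genes, pos) if p < 0]
            raise KeyError(f"genes not in dataset: {missing[:5]}")
        X = self.X[:, pos]
        return ExpressionDataset(
            X, self.gene_names[pos], self.cell_meta, self.layer_tag, self.mito_prefix
        )

    # -- per-cell QC quantities -----------------------------------------
    def detected_genes(self) -> np.ndarray:
        """Number of genes with nonzero value per cell (Seurat's nFeature)."""
        if sparse.issparse(self.X):
            return np.asarray((self.X != 0).sum(axis=1)).ravel()
        return (np.asarray(self.X) != 0).sum(axis=1)

    def total_counts(self) -> np.ndarray:
        return np.asarray(self.X.sum(axis=1), dtype=float).ravel()

    def mito_fraction(self) -> np.ndarray:
        """Fraction of each cell's total counts on mitochondrial genes.

        Mitochondrial genes are recognised by symbol prefix (default
        ``MT-``, case-insensitive).  Cells with zero total counts get 0.
        """
        total = self.total_counts()
        mito = np.asarray(self.X[:, self._mito_mask].sum(axis=1), dtype=float).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, mito / np.maximum(total, 1e-300), 0.0)
        return frac

    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (anndata must be installed)."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.X.copy() if sparse.issparse(self.X) else np.asarray(self.X, dtype=float).copy(),
            obs=self.cell_meta.copy(),
            var=pd.DataFrame(index=pd.Index(self.gene_names, name="gene")),
        )
        adata.uns["layer_tag"] = self.layer_tag
        return adata


def write_dataset(ds: ExpressionDataset, path) -> dict:
    """Write a dataset to ``path`` as matrix.mtx + genes.tsv + cells.tsv.

    Counts layers are written with an integer field type so the round trip
    through :func:`read_dataset` is lossless.  Returns the file paths.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    mtx = path / "matrix.mtx"
    X = ds.X
    if ds.layer_tag == "counts":
        mat = sparse.coo_matrix(X)
        mat.data = np.round(mat.data).astype(np.int64)
        mmwrite(str(mtx), mat, comment="cells x genes (rows are cells)", field="integer")
    else:
        mmwrite(str(mtx), sparse.coo_matrix(X), comment="cells x genes (rows are cells)")
    genes = path / "genes.tsv"
    genes.write_text("".join(f"{g}\n" for g in ds.gene_names))
    cells = path / "cells.tsv"
    ds.cell_meta.to_csv(cells, sep="\t", index=False)
    (path / "layer.txt").write_text(ds.layer_tag + "\n")
    return {"matrix": mtx, "genes": genes, "cells": cells}


def read_dataset(path) -> ExpressionDataset:
    """Read a dataset written by :func:`write_dataset`."""
    path = Path(path)
    X = mmread(str(path / "matrix.mtx"))
    if sparse.issparse(X):
        X = X.tocsr()
    genes_txt = (path / "genes.tsv").read_text().splitlines()
    gene_names = pd.Index([g.strip() for g in genes_txt if g.strip() != ""])
    meta = pd.read_csv(path / "cells.tsv", sep="\t")
    if len(meta.columns) and meta.shape[0] == 0:
        meta = meta.astype({c: object for c in meta.columns})
    layer_file = path / "layer.txt"
    layer_tag = layer_file.read_text().strip() if layer_file.exists() else "counts"
    if X.shape[0] == 0:
        # mmread of an empty matrix preserves the declared shape
        X = sparse.csr_matrix((0, len(gene_names)))
    return ExpressionDataset(X, gene_names, meta, layer_tag)
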
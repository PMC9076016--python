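"""Cell-level QC, normalization, cell-type subsetting, imputation, scaling.

The filters mirror standard droplet scRNA-seq practice for PBMC data:
cells are kept when their detected-gene count lies within
[``min_genes``, ``max_genes``] (cells with <800 or >6000 detected genes
are discarded) and their mitochondrial read percentage does not exceed
``max_mito_pct`` (default 5%).  Cell types with fewer than
``min_cells_per_type`` cells (default 1,000) are excluded before any
per-type modelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from scipy import sparse

from .dataset import ExpressionDataset

__all__ = [
    "QCThresholds",
    "FilterReport",
    "ScalerParams",
    "filter_cells",
    "lognormalize",
    "subset_cell_types",
    "impute",
    "scale_genes",
]

log = logging.getLogger(__name__)


class LayerError(ValueError):
    """Operation applied to the wrong expression layer."""


@dataclass(frozen=True)
class QCThresholds:
    """Cell- and type-level QC cutoffs.

    ``min_genes``/``max_genes`` bound the detected (nonzero) genes per
    cell, inclusive at both ends; ``max_mito_pct`` is the maximum allowed
    mitochondrial percentage (cells strictly above are removed);
    ``min_cells_per_type`` is the minimum cell count for a cell type to be
    modelled.
    """

    min_genes: int = 800
    max_genes: int = 6000
    max_mito_pct: float = 5.0
    min_cells_per_type: int = 1000

    def __post_init__(self) -> None:
        if not (0 < self.min_genes < self.max_genes):
            raise ValueError("need 0 < min_genes < max_genes")
        if self.max_mito_pct <= 0 or self.min_cells_per_type <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class FilterReport:
    """Counts of cells removed by each QC rule (rules applied jointly)."""

    n_input: int
    n_retained: int
    n_low_genes: int
    n_high_genes: int
    n_high_mito: int

    def to_dict(self) -> dict:
        return asdict(self)


def filter_cells(
    ds: ExpressionDataset, thresholds: QCThresholds = QCThresholds()
) -> Tuple[ExpressionDataset, FilterReport]:
    """Apply the detected-gene and mitochondrial-percentage cell filters.

    Requires the counts layer.  A cell is retained iff
    ``min_genes <= detected <= max_genes`` and mito% <= ``max_mito_pct``.
    Returns the filtered dataset and a per-rule removal report (a cell
    failing several rules is counted under each rule it fails).
    """
    if ds.layer_tag != "counts":
        raise LayerError(f"filter_cells requires the counts layer, got {ds.layer_tag!r}")
    detected = ds.detected_genes()
    mito_frac = ds.mito_fraction()
    low = detected < thresholds.min_genes
    high = detected > thresholds.max_genes
    # compare fractions rather than percentages: frac * 100 rounds past the
    # threshold for cells sitting exactly on the boundary
    mito_bad = mito_frac > thresholds.max_mito_pct / 100.0
    keep = ~(low | high | mito_bad)
    report = FilterReport(
        n_input=ds.n_cells,
        n_retained=int(keep.sum()),
        n_low_genes=int(low.sum()),
        n_high_genes=int(high.sum()),
        n_high_mito=int(mito_bad.sum()),
    )
    return ds.subset_cells(keep), report


def lognormalize(ds: ExpressionDataset, scale_factor: float = 1e4) -> ExpressionDataset:
    """Library-size normalize and log-transform: log1p(count/total * scale).

    Cells with zero total counts become all-zero rows (with a warning)
    rather than NaN.
    """
    if ds.layer_tag != "counts":
        raise LayerError(f"lognormalize requires the counts layer, got {ds.layer_tag!r}")
    totals = ds.total_counts()
    zero_cells = int((totals == 0).sum())
    if zero_cells:
        log.warning("lognormalize: %d cells with zero total counts set to all-zero", zero_cells)
    inv = np.where(totals > 0, scale_factor / np.maximum(totals, 1e-300), 0.0)
    if sparse.issparse(ds.X):
        X = ds.X.tocsr().astype(float)
        X = sparse.diags(inv) @ X
        X.data = np.log1p(X.data)
    else:
        X = np.log1p(np.asarray(ds.X, dtype=float) * inv[:, None])
    return ExpressionDataset(X, ds.gene_names, ds.cell_meta.copy(), "lognorm", ds.mito_prefix)


def subset_cell_types(
    ds: ExpressionDataset, thresholds: QCThresholds = QCThresholds()
) -> Tuple[Dict[str, ExpressionDataset], Dict[str, int]]:
    """Split by cell type, dropping types with < ``min_cells_per_type`` cells.

    Returns the per-type dataset map and a report of the excluded types
    with their cell counts.
    """
    counts = ds.cell_meta["cell_type"].value_counts()
    keep_types = counts[counts >= thresholds.min_cells_per_type].index
    excluded = {t: int(n) for t, n in counts.items() if t not in set(keep_types)}
    if excluded:
        log.info("subset_cell_types: excluded %s", excluded)
    out: Dict[str, ExpressionDataset] = {}
    for t in keep_types:
        mask = (ds.cell_meta["cell_type"] == t).to_numpy()
        out[str(t)] = ds.subset_cells(mask)
    return out, excluded


def impute(
    ds: ExpressionDataset,
    method: str = "none",
    k: int = 15,
    n_pcs: int = 20,
    seed: int = 0,
) -> ExpressionDataset:
    """Zero-expression imputation hook.

    ``method="none"`` is the identity (layer re-tagged ``imputed``).
    ``method="knn_smooth"`` replaces each cell by the mean of its ``k``
    nearest neighbours (including itself) in PCA space of the log-normal
    layer -- a simple diffusion-style smoother.  The interface is the
    pluggable point where a heavier imputation algorithm (e.g. a
    MAGIC-style diffusion) can be substituted.
    """
    if ds.layer_tag != "lognorm":
        raise LayerError(f"impute requires the lognorm layer, got {ds.layer_tag!r}")
    if method == "none":
        out = ds.copy()
        out.layer_tag = "imputed"
        return out
    if method != "knn_smooth":
        raise ValueError(f"unknown imputation method {method!r}")
    if k >= ds.n_cells:
        raise ValueError(f"k={k} must be < n_cells={ds.n_cells}")
    from sklearn.decomposition import PCA
    from sklearn.neighbors import NearestNeighbors

    dense = ds.dense()
    n_comp = min(n_pcs, ds.n_cells - 1, ds.n_genes)
    pcs = PCA(n_components=n_comp, svd_solver="full", random_state=seed).fit_transform(dense)
    nn = NearestNeighbors(n_neighbors=k).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    smoothed = dense[idx].mean(axis=1)
    return ExpressionDataset(smoothed, ds.gene_names, ds.cell_meta.copy(), "imputed", ds.mito_prefix)


@dataclass
class ScalerParams:
    """Per-gene centring/scaling parameters learned on training data.

    ``sd`` is the sample standard deviation (ddof=1); zero-variance genes
    are recorded with sd 1 so they map to all-zero columns.
    """

    mean: np.ndarray
    sd: np.ndarray
    gene_names: pd.Index

    def transform(self, ds: ExpressionDataset) -> ExpressionDataset:
        if not ds.gene_names.equals(self.gene_names):
            raise ValueError("gene universe differs from the scaler's training genes")
        X = (ds.dense() - self.mean) / self.sd
        return ExpressionDataset(X, ds.gene_names, ds.cell_meta.copy(), "scaled", ds.mito_prefix)

    def transform_matrix(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd

    def inverse_transform_matrix(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) * self.sd + self.mean

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "gene_names": list(self.gene_names),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalerParams":
        return cls(
            mean=np.asarray(d["mean"], dtype=float),
            sd=np.asarray(d["sd"], dtype=float),
            gene_names=pd.Index(d["gene_names"]),
        )


def scale_genes(train: ExpressionDataset) -> Tuple[ExpressionDataset, ScalerParams]:
    """Centre each gene to mean 0 and scale to unit variance on training data.

    Returns the scaled dataset and the stored :class:`ScalerParams`, which
    must be used to transform held-out data (never refit on test data).
    Constant genes become all-zero columns.
    """
    if train.layer_tag not in ("lognorm", "imputed"):
        raise LayerError(f"scale_genes requires lognorm or imputed layer, got {train.layer_tag!r}")
    X = train.dense()
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    sd = np.where(sd > 0, sd, 1.0)
    params = ScalerParams(mean=mean, sd=sd, gene_names=train.gene_names)
    scaled = ExpressionDataset(
        (X - mean) / sd, train.gene_names, train.cell_meta.copy(), "scaled", train.mito_prefix
    )
    return scaled, params
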
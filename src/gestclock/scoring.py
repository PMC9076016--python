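"""Gene-set module scores, stage comparisons, age correlations, DEGs.

The module score is the control-binned score of Tirosh-style cell-state
scoring (the scheme behind Seurat's ``AddModuleScore``): genes are ranked
by dataset-wide average expression and cut into ``n_bins``
equal-frequency bins; for every signature gene, ``n_ctrl`` control genes
are drawn from the same bin; the per-cell score is the mean expression of
the signature genes minus the mean expression of the pooled control set.
The subtraction makes the score robust to per-cell depth and to the
overall expression level of the signature.

Stage-wise comparisons use the two-sided Wilcoxon rank-sum test with
significance stars at 0.05 / 0.01 / 0.001 / 0.0001.  Differential
expression is per-gene Wilcoxon on the log-normal layer with
Benjamini-Hochberg correction and a fold-change computed on the
de-logged scale: log2((mean expm1 g1 + 1) / (mean expm1 g2 + 1)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .dataset import ExpressionDataset

__all__ = [
    "GeneSignature",
    "builtin_signatures",
    "load_signatures",
    "module_score",
    "stage_compare",
    "wilcoxon_rank_sum",
    "significance_stars",
    "gene_age_correlation",
    "differential_expression",
]

log = logging.getLogger(__name__)

SIGNATURE_ROLES = ("ISG", "cytotoxicity", "apoptosis", "exhaustion", "GO_pathway", "custom")


class EmptySignatureError(ValueError):
    """No signature gene matched the dataset's gene universe."""


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set with a functional role."""

    name: str
    genes: Tuple[str, ...]
    role: str = "custom"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("signature gene list must be non-empty")
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if list(self.genes).count(g) > 1})
            raise ValueError(f"duplicate genes in signature {self.name!r}: {dupes}")
        if self.role not in SIGNATURE_ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {SIGNATURE_ROLES}")
        object.__setattr__(self, "genes", tuple(self.genes))


def load_signatures(path) -> Dict[str, GeneSignature]:
    """Load signatures from a YAML file: {name: {role: ..., genes: [...]}}."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for name, entry in raw.items():
        out[name] = GeneSignature(name=name, genes=tuple(entry["genes"]), role=entry.get("role", "custom"))
    return out


def builtin_signatures() -> Dict[str, GeneSignature]:
    """The built-in signature set shipped with the package (data/signatures.yaml)."""
    from importlib.resources import files

    return load_signatures(files("gestclock.data") / "signatures.yaml")


def module_score(
    ds: ExpressionDataset,
    sig: GeneSignature,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Control-binned module score per cell.

    Genes are ranked by dataset-wide mean expression and cut into
    ``n_bins`` equal-frequency bins (ties broken by stable gene order).
    For each matched signature gene, ``min(n_ctrl, bin size)`` control
    genes are sampled without replacement from its bin; the pooled unique
    control set is used.  score(cell) = mean(signature) - mean(controls).
    Deterministic under ``seed``, which governs control sampling only.

    Returns a long-format frame: cell_id, signature, score plus any
    stage/cell_type metadata columns.
    """
    if ds.n_genes < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} genes, have {ds.n_genes}")
    matched = [g for g in sig.genes if g in ds.gene_names]
    unmatched = [g for g in sig.genes if g not in ds.gene_names]
    if unmatched:
        log.warning("module_score(%s): %d unmatched genes dropped", sig.name, len(unmatched))
    if not matched:
        raise EmptySignatureError(f"no gene of signature {sig.name!r} found in dataset")

    X = ds.X
    gene_means = np.asarray(X.mean(axis=0)).ravel()
    order = np.argsort(gene_means, kind="stable")  # stable: ties keep gene order
    # equal-frequency bins over the rank ordering
    bin_of = np.empty(ds.n_genes, dtype=int)
    bin_of[order] = np.floor(np.arange(ds.n_genes) * n_bins / ds.n_genes).astype(int)

    rng = np.random.default_rng(seed)
    gene_pos = ds.gene_names.get_indexer(matched)
    in_signature = np.zeros(ds.n_genes, dtype=bool)
    in_signature[gene_pos] = True
    control_pool: set = set()
    for gp in gene_pos:
        b = bin_of[gp]
        # controls are expression-matched *non-signature* genes from the
        # gene's bin; when the signature monopolizes a bin, expand to the
        # nearest bins so controls stay expression-matched
        candidates = np.empty(0, dtype=int)
        for offset in range(n_bins):
            bins_here = {b - offset, b + offset} & set(range(n_bins))
            members = np.flatnonzero(np.isin(bin_of, list(bins_here)))
            candidates = members[~in_signature[members]]
            if len(candidates) > 0:
                break
        if len(candidates) == 0:
            # signature covers the whole universe: controls fall back to the
            # universe itself, cancelling the signature mean exactly
            candidates = np.flatnonzero(bin_of == b)
        take = min(n_ctrl, len(candidates))
        control_pool.update(rng.choice(candidates, size=take, replace=False).tolist())
    ctrl_idx = np.array(sorted(control_pool), dtype=int)

    sig_mean = np.asarray(X[:, gene_pos].mean(axis=1)).ravel()
    ctrl_mean = np.asarray(X[:, ctrl_idx].mean(axis=1)).ravel()
    scores = sig_mean - ctrl_mean

    out = pd.DataFrame({"cell_id": ds.cell_meta["cell_id"], "signature": sig.name, "score": scores})
    for col in ("stage", "cell_type", "subject_id", "ga_weeks"):
        if col in ds.cell_meta.columns:
            out[col] = ds.cell_meta[col].to_numpy()
    return out


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum machinery


def significance_stars(p: float) -> str:
    """Map a p-value to the conventional star annotation."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact null distribution when both groups have <= 50 observations and
    the pooled data are tie-free; tie-corrected normal approximation
    otherwise.  Returns (U statistic of the first group, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        # every observation tied: no evidence either way
        return len(x) * len(y) / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(x), len(y)) <= 50 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def stage_compare(
    scores: pd.DataFrame,
    pairs: Optional[Sequence[Tuple[str, str]]] = None,
    group_col: str = "stage",
    value_col: str = "score",
    unit: str = "cell",
) -> pd.DataFrame:
    """Pairwise Wilcoxon rank-sum comparison of scores between stages.

    ``pairs`` defaults to all ordered pairs of the groups present.  With
    ``unit="subject"`` each subject's mean score is one observation (the
    conservative option when cells of one subject are correlated);
    the default follows per-cell testing.
    """
    df = scores
    if unit == "subject":
        df = (
            scores.groupby([group_col, "subject_id"], observed=True)[value_col]
            .mean()
            .reset_index()
        )
    elif unit != "cell":
        raise ValueError("unit must be 'cell' or 'subject'")
    groups = {g: sub[value_col].to_numpy() for g, sub in df.groupby(group_col, observed=True)}
    if pairs is None:
        names = list(groups)
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    rows = []
    for a, b in pairs:
        if a not in groups or b not in groups or len(groups[a]) == 0 or len(groups[b]) == 0:
            raise ValueError(f"empty or missing group in pair ({a!r}, {b!r})")
        w, p = wilcoxon_rank_sum(groups[a], groups[b])
        rows.append({"group1": a, "group2": b, "W": w, "p": p, "stars": significance_stars(p)})
    return pd.DataFrame(rows)


def gene_age_correlation(
    ds: ExpressionDataset,
    genes: Optional[Iterable[str]] = None,
    include_nonpregnant: bool = False,
) -> pd.DataFrame:
    """Pearson correlation of per-gestational-week mean expression with week.

    The aggregation unit is the gestational week: per-cell correlation
    would treat thousands of correlated cells as independent samples and
    inflate significance.  Non-pregnant samples (week 0) are excluded by
    default.  Genes with zero variance across weeks are reported with
    r = NaN and a reason.
    """
    meta = ds.cell_meta
    mask = np.ones(ds.n_cells, dtype=bool)
    if not include_nonpregnant:
        mask = (meta["ga_weeks"].to_numpy() >= 1)
    weeks_all = meta["ga_weeks"].to_numpy()[mask]
    uniq_weeks = np.unique(weeks_all)
    if len(uniq_weeks) < 3:
        raise ValueError("need at least 3 distinct gestational weeks")
    gene_list = list(genes) if genes is not None else list(ds.gene_names)
    sub = ds.subset_cells(mask).subset_genes(gene_list)
    dense = sub.dense()
    # per-week mean expression matrix: weeks x genes
    wk = sub.cell_meta["ga_weeks"].to_numpy()
    means = np.vstack([dense[wk == w].mean(axis=0) for w in uniq_weeks])
    rows = []
    for j, g in enumerate(gene_list):
        col = means[:, j]
        if np.allclose(col.std(), 0.0):
            rows.append({"gene": g, "r": np.nan, "p": np.nan, "reason": "zero variance"})
            continue
        r, p = stats.pearsonr(uniq_weeks.astype(float), col)
        rows.append({"gene": g, "r": float(r), "p": float(p), "reason": ""})
    return pd.DataFrame(rows)


def _group_matrices(ds: ExpressionDataset, mask1: np.ndarray, mask2: np.ndarray):
    X = ds.X
    if sparse.issparse(X):
        return np.asarray(X[mask1].todense()), np.asarray(X[mask2].todense())
    return np.asarray(X[mask1], dtype=float), np.asarray(X[mask2], dtype=float)


def differential_expression(
    ds: ExpressionDataset,
    group1_mask,
    group2_mask,
    min_abs_log2fc: float = 0.3,
    alpha: float = 0.05,
    marker_mode: bool = False,
    min_pct: float = 0.25,
) -> pd.DataFrame:
    """Per-gene Wilcoxon differential expression between two cell groups.

    Works on the log-normal layer.  ``log2fc`` compares de-logged means:
    log2((mean(expm1 x1) + 1) / (mean(expm1 x2) + 1)).  BH adjustment is
    applied across all tested genes; a gene is called significant when
    ``|log2fc| >= min_abs_log2fc`` and ``p_adj < alpha``.

    ``marker_mode=True`` reproduces the marker-finding variant: only genes
    expressed in >= ``min_pct`` of either group and with positive log-FC
    >= 0.25 are tested/reported.
    """
    from statsmodels.stats.multitest import multipletests

    if ds.layer_tag not in ("lognorm", "imputed"):
        raise ValueError("differential_expression expects the lognorm (or imputed) layer")
    m1 = np.asarray(group1_mask)
    m2 = np.asarray(group2_mask)
    if m1.dtype != bool:
        z = np.zeros(ds.n_cells, dtype=bool)
        z[m1] = True
        m1 = z
    if m2.dtype != bool:
        z = np.zeros(ds.n_cells, dtype=bool)
        z[m2] = True
        m2 = z
    if m1.sum() == 0 or m2.sum() == 0:
        raise ValueError("both groups must be non-empty")

    X1, X2 = _group_matrices(ds, m1, m2)
    pct1 = (X1 > 0).mean(axis=0)
    pct2 = (X2 > 0).mean(axis=0)
    mean1 = np.expm1(X1).mean(axis=0)
    mean2 = np.expm1(X2).mean(axis=0)
    log2fc = np.log2((mean1 + 1.0) / (mean2 + 1.0))

    if marker_mode:
        tested = ((pct1 >= min_pct) | (pct2 >= min_pct)) & (log2fc >= 0.25)
        min_abs_log2fc = max(min_abs_log2fc, 0.25)
    else:
        tested = np.ones(ds.n_genes, dtype=bool)
    idx = np.flatnonzero(tested)
    if len(idx) == 0:
        return pd.DataFrame(
            columns=["gene", "log2fc", "p", "p_adj", "direction", "pct_group1", "pct_group2", "significant"]
        )
    # vectorized tie-corrected Wilcoxon across genes; fully-tied genes carry
    # no evidence and are assigned p = 1 directly (the normal approximation
    # degenerates there)
    pooled = np.vstack([X1[:, idx], X2[:, idx]])
    const = np.all(pooled == pooled[0, :], axis=0)
    p = np.ones(len(idx), dtype=float)
    if (~const).any():
        res = stats.mannwhitneyu(
            X1[:, idx[~const]], X2[:, idx[~const]],
            alternative="two-sided", method="asymptotic", axis=0,
        )
        p[~const] = np.minimum(np.asarray(res.pvalue, dtype=float), 1.0)
    p_adj = multipletests(p, method="fdr_bh")[1]
    direction = np.where(log2fc[idx] >= 0, "up", "down")
    sig = (np.abs(log2fc[idx]) >= min_abs_log2fc) & (p_adj < alpha)
    if marker_mode:
        sig = sig & (log2fc[idx] > 0)
    out = pd.DataFrame(
        {
            "gene": np.asarray(ds.gene_names)[idx],
            "log2fc": log2fc[idx],
            "p": p,
            "p_adj": p_adj,
            "direction": direction,
            "pct_group1": pct1[idx],
            "pct_group2": pct2[idx],
            "significant": sig,
        }
    )
    return out.sort_values("p_adj", kind="stable").reset_index(drop=True)
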
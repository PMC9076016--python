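"""Shapley-value interpretation of the clock's random forest.

Implements path-dependent Tree SHAP for scikit-learn tree ensembles: the
polynomial-time tree-path algorithm that computes, exactly, the Shapley
values of the game whose value function is the tree's cover-weighted
conditional expectation.  For every instance the attributions satisfy the
additivity axiom

    base_value + sum_j phi_j = model prediction

to floating-point precision, and a feature the ensemble never splits on
receives exactly zero attribution (null-player axiom).

On top of the attribution kernel sit the gene-prioritization operations:
mean-|SHAP| ranking per model, minimum-MSE selection of the optimal gene
count with retraining, and cross-cell-type prioritization of genes that
matter in at least ``min_models`` models.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .clock import ClockModel, PseudoCell, stack_pseudocells

__all__ = [
    "tree_shap_values",
    "shap_rank",
    "select_top_genes_retrain",
    "cross_type_prioritize",
    "DEFAULT_K_LADDER",
]

log = logging.getLogger(__name__)

#: candidate gene counts for the minimum-MSE selection (truncated to the
#: number of available genes; the full set is always a candidate)
DEFAULT_K_LADDER = (5, 10, 20, 50, 100, 200)

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@njit
def _tree_shap_recurse(
    node,
    unique_depth,
    parent_d,
    parent_z,
    parent_o,
    parent_w,
    parent_zero,
    parent_one,
    parent_feat,
    x,
    phi,
    cl,
    cr,
    feat,
    thr,
    val,
    wts,
):
    # copy the parent's path and extend it with the incoming split
    maxd = parent_d.shape[0]
    d_ = np.empty(maxd, dtype=np.int64)
    z_ = np.empty(maxd, dtype=np.float64)
    o_ = np.empty(maxd, dtype=np.float64)
    w_ = np.empty(maxd, dtype=np.float64)
    for i in range(unique_depth):
        d_[i] = parent_d[i]
        z_[i] = parent_z[i]
        o_[i] = parent_o[i]
        w_[i] = parent_w[i]
    d_[unique_depth] = parent_feat
    z_[unique_depth] = parent_zero
    o_[unique_depth] = parent_one
    w_[unique_depth] = 1.0 if unique_depth == 0 else 0.0
    for i in range(unique_depth - 1, -1, -1):
        w_[i + 1] += parent_one * w_[i] * (i + 1.0) / (unique_depth + 1.0)
        w_[i] = parent_zero * w_[i] * (unique_depth - i) / (unique_depth + 1.0)

    if cr[node] < 0:  # leaf: unwind each path element and credit its feature
        leaf_val = val[node]
        for pi in range(1, unique_depth + 1):
            one_f = o_[pi]
            zero_f = z_[pi]
            next_one = w_[unique_depth]
            total = 0.0
            if one_f != 0.0:
                for i in range(unique_depth - 1, -1, -1):
                    tmp = next_one / ((i + 1.0) * one_f)
                    total += tmp
                    next_one = w_[i] - tmp * zero_f * (unique_depth - i)
            else:
                for i in range(unique_depth - 1, -1, -1):
                    total += w_[i] / (zero_f * (unique_depth - i))
            total *= unique_depth + 1.0
            phi[d_[pi]] += total * (one_f - zero_f) * leaf_val
    else:
        split = feat[node]
        if x[split] <= thr[node]:
            hot = cl[node]
            cold = cr[node]
        else:
            hot = cr[node]
            cold = cl[node]
        w_node = wts[node]
        hot_zero = wts[hot] / w_node
        cold_zero = wts[cold] / w_node
        inc_zero = 1.0
        inc_one = 1.0
        path_index = -1
        for i in range(unique_depth + 1):
            if d_[i] == split:
                path_index = i
                break
        ud = unique_depth
        if path_index >= 0:  # feature already on the path: undo that split
            inc_zero = z_[path_index]
            inc_one = o_[path_index]
            one_f = inc_one
            zero_f = inc_zero
            next_one = w_[ud]
            for i in range(ud - 1, -1, -1):
                if one_f != 0.0:
                    tmp = w_[i]
                    w_[i] = next_one * (ud + 1.0) / ((i + 1.0) * one_f)
                    next_one = tmp - w_[i] * zero_f * (ud - i) / (ud + 1.0)
                else:
                    w_[i] = w_[i] * (ud + 1.0) / (zero_f * (ud - i))
            for i in range(path_index, ud):
                d_[i] = d_[i + 1]
                z_[i] = z_[i + 1]
                o_[i] = o_[i + 1]
            ud -= 1
        _tree_shap_recurse(
            hot, ud + 1, d_, z_, o_, w_, hot_zero * inc_zero, inc_one, split,
            x, phi, cl, cr, feat, thr, val, wts,
        )
        _tree_shap_recurse(
            cold, ud + 1, d_, z_, o_, w_, cold_zero * inc_zero, 0.0, split,
            x, phi, cl, cr, feat, thr, val, wts,
        )


@njit
def _forest_shap(X, cl, cr, feat, thr, val, wts, offsets, maxd):
    n, m = X.shape
    phi = np.zeros((n, m), dtype=np.float64)
    base = 0.0
    n_trees = offsets.shape[0] - 1
    d0 = np.empty(maxd, dtype=np.int64)
    z0 = np.empty(maxd, dtype=np.float64)
    o0 = np.empty(maxd, dtype=np.float64)
    w0 = np.empty(maxd, dtype=np.float64)
    for t in range(n_trees):
        s = offsets[t]
        e = offsets[t + 1]
        base += val[s]
        for i in range(n):
            _tree_shap_recurse(
                0, 0, d0, z0, o0, w0, 1.0, 1.0, -1,
                X[i], phi[i], cl[s:e], cr[s:e], feat[s:e], thr[s:e], val[s:e], wts[s:e],
            )
    return phi / n_trees, base / n_trees


def _flatten_forest(forest):
    """Concatenate the node arrays of a fitted sklearn forest."""
    cls, crs, feats, thrs, vals, wts = [], [], [], [], [], []
    offsets = [0]
    maxd = 0
    for est in forest.estimators_:
        t = est.tree_
        cls.append(t.children_left.astype(np.int64))
        crs.append(t.children_right.astype(np.int64))
        feats.append(t.feature.astype(np.int64))
        thrs.append(t.threshold.astype(np.float64))
        vals.append(t.value.reshape(-1).astype(np.float64))
        wts.append(t.weighted_n_node_samples.astype(np.float64))
        offsets.append(offsets[-1] + t.node_count)
        maxd = max(maxd, t.max_depth)
    return (
        np.concatenate(cls),
        np.concatenate(crs),
        np.concatenate(feats),
        np.concatenate(thrs),
        np.concatenate(vals),
        np.concatenate(wts),
        np.asarray(offsets, dtype=np.int64),
        maxd + 2,
    )


def tree_shap_values(forest, X: np.ndarray) -> Tuple[np.ndarray, float]:
    """Path-dependent Tree SHAP attributions for a sklearn forest regressor.

    Returns ``(phi, base_value)`` with ``phi`` of shape
    ``(n_instances, n_features)`` such that
    ``base_value + phi[i].sum() == forest.predict(X)[i]`` for every i.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (instances x features)")
    if X.shape[1] != forest.n_features_in_:
        raise ValueError(
            f"feature mismatch: X has {X.shape[1]}, model expects {forest.n_features_in_}"
        )
    cl, cr, feat, thr, val, wts, offsets, maxd = _flatten_forest(forest)
    phi, base = _forest_shap(X, cl, cr, feat, thr, val, wts, offsets, maxd)
    return phi, float(base)


def shap_rank(
    model: ClockModel,
    pseudocells: Sequence[PseudoCell],
    gene_names: pd.Index,
) -> pd.DataFrame:
    """Mean-|SHAP| gene importance ranking for a fitted clock.

    Pseudo-cells are transformed to the model's feature space (training
    scaler, selected genes), attributions are computed per instance, and
    genes are ranked by the mean absolute attribution in days of
    gestational age.  Ties are broken by gene-name order.
    """
    X, _ = stack_pseudocells(pseudocells)
    feats = model.transform(X, gene_names)
    phi, _ = tree_shap_values(model.regressor, feats)
    imp = np.abs(phi).mean(axis=0)
    df = pd.DataFrame({"gene": model.selected_genes, "mean_abs_shap": imp})
    df = df.sort_values(["mean_abs_shap", "gene"], ascending=[False, True], kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    df["cell_type"] = model.cell_type
    return df.reset_index(drop=True)[["cell_type", "gene", "mean_abs_shap", "rank"]]


def select_top_genes_retrain(
    model: ClockModel,
    train_pseudocells: Sequence[PseudoCell],
    gene_names: pd.Index,
    cv_folds: int = 5,
    k_ladder: Sequence[int] = DEFAULT_K_LADDER,
) -> ClockModel:
    """Minimum-MSE gene-count selection and final retraining.

    Genes are ranked by mean |SHAP| on the training pseudo-cells; for
    every candidate count k in the ladder (plus the full selected set),
    the top-k genes are scored by cross-validated MSE with the model's
    fixed optimal hyperparameters; the smallest k achieving the minimum
    mean CV MSE wins and the final model is retrained on all training
    pseudo-cells with those genes.  Deterministic under the model's seed.
    """
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.model_selection import KFold, cross_val_score

    ranking = shap_rank(model, train_pseudocells, gene_names)
    ordered = ranking["gene"].tolist()
    n_avail = len(ordered)
    ladder = sorted({min(k, n_avail) for k in k_ladder if k > 0} | {n_avail})
    X, meta = stack_pseudocells(train_pseudocells)
    scaled = model.scaler.transform_matrix(X)
    pos_all = pd.Index(gene_names).get_indexer(ordered)
    y = meta["ga_days"].to_numpy(dtype=float)
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=model.seed)
    rows = []
    best_k, best_mse = None, np.inf
    for k in ladder:
        cols = pos_all[:k]
        est = RandomForestRegressor(random_state=model.seed, n_jobs=1, **model.best_params)
        scores = cross_val_score(est, scaled[:, cols], y, cv=cv, scoring="neg_mean_squared_error")
        mse = float(-scores.mean())
        rows.append({"k": k, "mean_cv_mse": mse})
        if mse < best_mse:  # strict: smallest k wins ties
            best_mse = mse
            best_k = k
    log.info("select_top_genes_retrain: optimal gene count k*=%d (CV MSE %.3f)", best_k, best_mse)
    final_genes = ordered[:best_k]
    est = RandomForestRegressor(random_state=model.seed, n_jobs=1, **model.best_params)
    est.fit(scaled[:, pos_all[:best_k]], y)
    return ClockModel(
        cell_type=model.cell_type,
        selected_genes=final_genes,
        scaler=model.scaler,
        lasso_penalty=model.lasso_penalty,
        regressor=est,
        best_params=dict(model.best_params),
        cv_summary=pd.DataFrame(rows),
        seed=model.seed,
        dataset_hash=model.dataset_hash,
    )


def cross_type_prioritize(
    importances: Dict[str, pd.DataFrame],
    min_models: int = 2,
    top_n: Optional[int] = None,
) -> pd.DataFrame:
    """Rank genes shared across cell-type-specific clocks.

    ``importances`` maps cell type -> the frame returned by
    :func:`shap_rank`.  Genes appearing in at least ``min_models`` models
    are scored by the unweighted mean of their per-type mean |SHAP| over
    the models that involve them; genes present in every model are
    flagged (``in_all_models``).
    """
    if len(importances) < 2:
        raise ValueError("need importances from at least 2 cell types")
    n_models = len(importances)
    per_gene: Dict[str, List[float]] = {}
    for ctype, df in importances.items():
        for gene, val in zip(df["gene"], df["mean_abs_shap"]):
            per_gene.setdefault(str(gene), []).append(float(val))
    rows = [
        {
            "gene": g,
            "n_models_involving": len(vals),
            "aggregate_score": float(np.mean(vals)),
            "in_all_models": len(vals) == n_models,
        }
        for g, vals in per_gene.items()
        if len(vals) >= min_models
    ]
    out = pd.DataFrame(rows, columns=["gene", "n_models_involving", "aggregate_score", "in_all_models"])
    out = out.sort_values(
        ["aggregate_score", "gene"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    if top_n is not None:
        out = out.head(top_n)
    return out
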
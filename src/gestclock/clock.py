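"""The cell-type-specific gestational-age clock.

Pipeline per cell type: build pseudo-cells (per-gene median over groups
of ``group_size`` cells randomly drawn without replacement within one
subject), split subjects 7:3 stratified by pregnancy period, scale genes
on the training side, select age-relevant genes with LASSO (alpha 0.1),
tune a random-forest regressor by randomized search with fivefold CV
minimizing RMSE, refit on the full training set, and evaluate on held-out
subjects: a subject's predicted gestational age is the mean of the model
outputs over that subject's pseudo-cells; models are retained when the
subject-level Pearson R reaches 0.8.

The statsmodels-style surface is :class:`GestationalAgeClock` (model,
built from an :class:`~gestclock.dataset.ExpressionDataset`) whose
``fit()`` returns :class:`ClockResults` carrying the fitted
:class:`ClockModel`, the :class:`EvaluationReport` and a ``summary()``
table.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import ExpressionDataset, period_from_weeks
from .qc import ScalerParams, scale_genes

__all__ = [
    "PseudoCell",
    "SplitPlan",
    "ClockModel",
    "EvaluationReport",
    "make_pseudocells",
    "stack_pseudocells",
    "split_subjects",
    "select_genes_lasso",
    "tune_and_train",
    "predict_subjects",
    "run_clock_all_types",
    "GestationalAgeClock",
    "ClockResults",
]

log = logging.getLogger(__name__)

#: randomized-search space for the random-forest regressor; sized for
#: pseudo-cell problems of a few hundred to a few thousand rows
RF_SEARCH_SPACE = {
    "n_estimators": (50, 300),         # uniform integer
    "max_depth": [None, 5, 10, 15, 20, 25, 30],
    "min_samples_leaf": (1, 10),       # uniform integer
    "max_features": (0.05, 0.3),       # uniform fraction of features per split
}


@dataclass(frozen=True)
class PseudoCell:
    """Median expression profile of ``group_size`` same-subject cells."""

    vector: np.ndarray
    subject_id: str
    ga_days: int
    cell_type: str
    group_index: int


def make_pseudocells(
    ds: ExpressionDataset, group_size: int = 10, seed: int = 0
) -> List[PseudoCell]:
    """Aggregate single cells into per-subject pseudo-cells.

    Within each subject the cells are randomly permuted (without
    replacement) and partitioned into consecutive groups of
    ``group_size``; leftovers smaller than a full group are discarded
    (pseudo-cells are single-subject by definition, so leftovers are
    never pooled across subjects).  Each group contributes its per-gene
    median; the even-group median uses the midpoint convention.
    """
    if group_size <= 0:
        raise ValueError("group_size must be >= 1")
    cell_types = ds.cell_meta["cell_type"].unique()
    if len(cell_types) > 1:
        raise ValueError("make_pseudocells expects a single-cell-type dataset")
    ctype = str(cell_types[0]) if len(cell_types) else "NA"
    rng = np.random.default_rng(seed)
    out: List[PseudoCell] = []
    meta = ds.cell_meta
    for subj in meta["subject_id"].unique():
        rows = np.flatnonzero((meta["subject_id"] == subj).to_numpy())
        perm = rng.permutation(len(rows))
        rows = rows[perm]
        n_groups = len(rows) // group_size
        if n_groups == 0:
            continue
        ga = int(meta["ga_days"].iloc[rows[0]])
        block = ds.X[rows[: n_groups * group_size]]
        dense = np.asarray(block.todense(), dtype=float) if hasattr(block, "todense") else np.asarray(block, dtype=float)
        for g in range(n_groups):
            grp = dense[g * group_size : (g + 1) * group_size]
            out.append(
                PseudoCell(
                    vector=np.median(grp, axis=0),
                    subject_id=str(subj),
                    ga_days=ga,
                    cell_type=ctype,
                    group_index=g,
                )
            )
    return out


def stack_pseudocells(pcs: Sequence[PseudoCell]) -> Tuple[np.ndarray, pd.DataFrame]:
    """Stack pseudo-cells into (matrix, metadata frame)."""
    if not pcs:
        return np.zeros((0, 0)), pd.DataFrame(columns=["subject_id", "ga_days", "cell_type", "group_index"])
    X = np.vstack([p.vector for p in pcs])
    meta = pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in pcs],
            "ga_days": [p.ga_days for p in pcs],
            "cell_type": [p.cell_type for p in pcs],
            "group_index": [p.group_index for p in pcs],
        }
    )
    return X, meta


@dataclass
class SplitPlan:
    """Subject-level train/test partition, stratified by pregnancy period."""

    train_subjects: Tuple[str, ...]
    test_subjects: Tuple[str, ...]
    ratio: float
    strata: Dict[str, Tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.train_subjects) & set(self.test_subjects)
        if overlap:
            raise ValueError(f"subjects on both sides of the split: {sorted(overlap)[:5]}")


def split_subjects(ds: ExpressionDataset, ratio: float = 0.7, seed: int = 0) -> SplitPlan:
    """Stratified 7:3 subject split by pregnancy period.

    Non-pregnant subjects (gestational age 0) are excluded: the clock
    predicts the age of normal pregnancy.  Within each period stratum
    subjects are shuffled and the first ``round(ratio * n)`` go to
    training.  A single-subject stratum is assigned to training with a
    warning.  Deterministic under ``seed``.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    meta = ds.cell_meta
    subj_weeks = meta.groupby("subject_id", observed=True)["ga_weeks"].first()
    subj_weeks = subj_weeks[subj_weeks >= 1]  # pregnant only
    rng = np.random.default_rng(seed)
    train: List[str] = []
    test: List[str] = []
    strata: Dict[str, Tuple[str, ...]] = {}
    for period in ("early", "middle", "late"):
        members = sorted(
            str(s) for s, w in subj_weeks.items() if period_from_weeks(int(w)) == period
        )
        if not members:
            continue
        strata[period] = tuple(members)
        if len(members) == 1:
            log.warning("split_subjects: single-subject stratum %r assigned to train", period)
            train.extend(members)
            continue
        perm = rng.permutation(len(members))
        n_train = int(round(ratio * len(members)))
        n_train = min(max(n_train, 1), len(members) - 1)  # both sides non-empty
        shuffled = [members[i] for i in perm]
        train.extend(shuffled[:n_train])
        test.extend(shuffled[n_train:])
    return SplitPlan(tuple(sorted(train)), tuple(sorted(test)), ratio, strata)


def select_genes_lasso(
    X: np.ndarray,
    y: np.ndarray,
    gene_names: Sequence[str],
    penalty: float = 0.1,
    fallback_top_n: int = 50,
) -> List[str]:
    """LASSO selection of age-relevant genes on scaled pseudo-cells.

    Genes with nonzero coefficient at the given L1 penalty, ordered by
    descending |coefficient| (deduplicated by name, first kept).  If the
    penalty shrinks everything to zero, falls back to the
    ``fallback_top_n`` genes with highest |Pearson correlation| with age
    (logged prominently).
    """
    from sklearn.linear_model import Lasso

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 pseudo-cells for gene selection")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings on collinear inputs
        lasso = Lasso(alpha=penalty, max_iter=20000).fit(X, y)
    coef = lasso.coef_
    nz = np.flatnonzero(coef != 0.0)
    names = np.asarray(list(gene_names))
    if len(nz) == 0:
        log.warning(
            "select_genes_lasso: empty selection at penalty %.3g; "
            "falling back to top %d genes by |correlation with age|",
            penalty,
            fallback_top_n,
        )
        sd = X.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(
                (sd > 0) & (y.std() > 0),
                ((X - X.mean(0)) * (y - y.mean())[:, None]).mean(0)
                / np.where(sd > 0, sd, 1.0)
                / max(y.std(), 1e-300),
                0.0,
            )
        order = np.argsort(-np.abs(r), kind="stable")[:fallback_top_n]
        selected = names[order]
    else:
        order = nz[np.argsort(-np.abs(coef[nz]), kind="stable")]
        selected = names[order]
    seen = set()
    out = []
    for g in selected:
        if g not in seen:
            seen.add(g)
            out.append(str(g))
    return out


@dataclass
class ClockModel:
    """A fitted per-cell-type gestational-age predictor."""

    cell_type: str
    selected_genes: List[str]
    scaler: ScalerParams
    lasso_penalty: float
    regressor: object
    best_params: dict
    cv_summary: pd.DataFrame
    seed: int
    dataset_hash: str = ""

    def predict_pseudocells(self, X_scaled_selected: np.ndarray) -> np.ndarray:
        return self.regressor.predict(np.asarray(X_scaled_selected, dtype=float))

    def transform(self, X_raw: np.ndarray, gene_names: pd.Index) -> np.ndarray:
        """Scale with the stored training scaler and restrict to selected genes."""
        scaled = self.scaler.transform_matrix(X_raw)
        pos = pd.Index(gene_names).get_indexer(self.selected_genes)
        if (pos < 0).any():
            raise ValueError("pseudo-cell gene universe lacks selected genes")
        return scaled[:, pos]

    def save(self, path) -> None:
        """Persist as a directory bundle (TSV/JSON + pickled regressor)."""
        import pickle

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        pd.Series(self.selected_genes, name="gene").to_csv(
            path / "selected_genes.tsv", sep="\t", index=False
        )
        (path / "scaler.json").write_text(json.dumps(self.scaler.to_dict()))
        (path / "hyperparameters.json").write_text(json.dumps(self.best_params, default=str))
        (path / "provenance.json").write_text(
            json.dumps(
                {
                    "cell_type": self.cell_type,
                    "lasso_penalty": self.lasso_penalty,
                    "seed": self.seed,
                    "dataset_hash": self.dataset_hash,
                },
                sort_keys=True,
            )
        )
        self.cv_summary.to_csv(path / "cv_summary.tsv", sep="\t", index=False)
        with open(path / "regressor.pkl", "wb") as fh:
            pickle.dump(self.regressor, fh)

    @classmethod
    def load(cls, path) -> "ClockModel":
        import pickle

        path = Path(path)
        prov = json.loads((path / "provenance.json").read_text())
        genes = pd.read_csv(path / "selected_genes.tsv", sep="\t")["gene"].tolist()
        scaler = ScalerParams.from_dict(json.loads((path / "scaler.json").read_text()))
        params = json.loads((path / "hyperparameters.json").read_text())
        cv = pd.read_csv(path / "cv_summary.tsv", sep="\t")
        with open(path / "regressor.pkl", "rb") as fh:
            reg = pickle.load(fh)
        return cls(
            cell_type=prov["cell_type"],
            selected_genes=genes,
            scaler=scaler,
            lasso_penalty=prov["lasso_penalty"],
            regressor=reg,
            best_params=params,
            cv_summary=cv,
            seed=prov["seed"],
            dataset_hash=prov.get("dataset_hash", ""),
        )


def tune_and_train(
    X: np.ndarray,
    y: np.ndarray,
    genes: Sequence[str],
    n_candidates: int = 25,
    cv_folds: int = 5,
    seed: int = 0,
    cell_type: str = "NA",
    scaler: Optional[ScalerParams] = None,
    lasso_penalty: float = 0.1,
    dataset_hash: str = "",
) -> ClockModel:
    """Randomized hyperparameter search + refit of the RF regressor.

    ``X`` must already be scaled and restricted to ``genes``.  Candidates
    are scored by mean cross-validated RMSE over ``cv_folds`` shuffled
    folds; the best is refit on all training pseudo-cells.
    """
    from scipy.stats import randint, uniform
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.model_selection import KFold, RandomizedSearchCV

    if len(genes) < 1:
        raise ValueError("need at least one selected gene")
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    lo_t, hi_t = RF_SEARCH_SPACE["n_estimators"]
    lo_l, hi_l = RF_SEARCH_SPACE["min_samples_leaf"]
    lo_f, hi_f = RF_SEARCH_SPACE["max_features"]
    dist = {
        "n_estimators": randint(lo_t, hi_t + 1),
        "max_depth": RF_SEARCH_SPACE["max_depth"],
        "min_samples_leaf": randint(lo_l, hi_l + 1),
        "max_features": uniform(lo_f, hi_f - lo_f),
    }
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    search = RandomizedSearchCV(
        RandomForestRegressor(random_state=seed, n_jobs=1),
        param_distributions=dist,
        n_iter=n_candidates,
        scoring="neg_root_mean_squared_error",
        cv=cv,
        random_state=seed,
        refit=True,
        n_jobs=1,
    )
    search.fit(X, y)
    cvres = pd.DataFrame(search.cv_results_)
    cv_summary = pd.DataFrame(
        {
            "rank": cvres["rank_test_score"],
            "mean_cv_rmse": -cvres["mean_test_score"],
            "std_cv_rmse": cvres["std_test_score"],
            "params": cvres["params"].astype(str),
        }
    ).sort_values("rank", kind="stable").reset_index(drop=True)
    return ClockModel(
        cell_type=cell_type,
        selected_genes=list(genes),
        scaler=scaler,
        lasso_penalty=lasso_penalty,
        regressor=search.best_estimator_,
        best_params=dict(search.best_params_),
        cv_summary=cv_summary,
        seed=seed,
        dataset_hash=dataset_hash,
    )


@dataclass
class EvaluationReport:
    """Subject-level predictions and accuracy metrics of one clock."""

    cell_type: str
    predictions: pd.DataFrame  # subject_id, ga_true_days, ga_predicted_days, period
    R: float
    p: float
    rmse: float
    per_period: pd.DataFrame  # period, n_subjects, R, p, rmse
    retained: bool
    retention_R: float = 0.8

    def summary(self) -> str:
        lines = [
            f"Gestational-age clock evaluation -- cell type: {self.cell_type}",
            f"  held-out subjects: {len(self.predictions)}",
            f"  Pearson R = {self.R:.3f} (p = {self.p:.3g})",
            f"  RMSE      = {self.rmse:.3f} days",
            f"  retained at R >= {self.retention_R:g}: {self.retained}",
            "  per period:",
        ]
        for _, row in self.per_period.iterrows():
            lines.append(
                f"    {row['period']:<7} n={int(row['n_subjects']):>3}  "
                f"R={row['R'] if np.isnan(row['R']) else format(row['R'], '.3f')}  "
                f"RMSE={row['rmse']:.3f}"
            )
        return "\n".join(lines)


def _pearson_with_p(truth: np.ndarray, pred: np.ndarray) -> Tuple[float, float]:
    """Pearson r with two-sided t-test p (n-2 df); NaN when degenerate."""
    if len(truth) < 3 or np.std(truth) == 0 or np.std(pred) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(truth, pred)
    return float(r), float(p)


def predict_subjects(
    model: ClockModel,
    test_pcs: Sequence[PseudoCell],
    gene_names: pd.Index,
    retention_R: float = 0.8,
) -> EvaluationReport:
    """Subject-level evaluation of a fitted clock on held-out pseudo-cells.

    A subject's predicted gestational age is the arithmetic mean of the
    regressor outputs over that subject's pseudo-cells.  Metrics (Pearson
    R with t-test p, RMSE in days) are computed across subjects, overall
    and per pregnancy period.  With fewer than 3 test subjects the
    metrics are reported as NaN but predictions are still emitted.
    """
    X, meta = stack_pseudocells(test_pcs)
    feats = model.transform(X, gene_names)
    meta = meta.copy()
    meta["pred"] = model.predict_pseudocells(feats)
    per_subj = (
        meta.groupby("subject_id", observed=True)
        .agg(ga_true_days=("ga_days", "first"), ga_predicted_days=("pred", "mean"))
        .reset_index()
        .sort_values("subject_id", kind="stable")
        .reset_index(drop=True)
    )
    per_subj["period"] = [period_from_weeks(int(d) // 7) for d in per_subj["ga_true_days"]]
    truth = per_subj["ga_true_days"].to_numpy(dtype=float)
    pred = per_subj["ga_predicted_days"].to_numpy(dtype=float)
    if len(per_subj) >= 3:
        R, p = _pearson_with_p(truth, pred)
        rmse = float(np.sqrt(np.mean((truth - pred) ** 2)))
    else:
        R, p, rmse = float("nan"), float("nan"), float("nan")
    rows = []
    for period in ("early", "middle", "late"):
        sub = per_subj[per_subj["period"] == period]
        if len(sub) == 0:
            continue
        t = sub["ga_true_days"].to_numpy(dtype=float)
        q = sub["ga_predicted_days"].to_numpy(dtype=float)
        rP, pP = _pearson_with_p(t, q)
        rows.append(
            {
                "period": period,
                "n_subjects": len(sub),
                "R": rP,
                "p": pP,
                "rmse": float(np.sqrt(np.mean((t - q) ** 2))),
            }
        )
    per_period = pd.DataFrame(rows, columns=["period", "n_subjects", "R", "p", "rmse"])
    retained = bool(np.isfinite(R) and R >= retention_R)
    return EvaluationReport(
        cell_type=model.cell_type,
        predictions=per_subj,
        R=R,
        p=p,
        rmse=rmse,
        per_period=per_period,
        retained=retained,
        retention_R=retention_R,
    )


def _hash_dataset(ds: ExpressionDataset) -> str:
    h = hashlib.sha256()
    X = ds.X
    if hasattr(X, "toarray"):
        h.update(np.ascontiguousarray(X.toarray()).tobytes())
    else:
        h.update(np.ascontiguousarray(np.asarray(X)).tobytes())
    h.update(ds.cell_meta.to_csv(index=False).encode())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# statsmodels-style model / results surface


class GestationalAgeClock:
    """Gestational-age clock for one cell type (model object).

    Parameters
    ----------
    dataset
        log-normal (or imputed) layer :class:`ExpressionDataset` restricted
        to one cell type; non-pregnant subjects are dropped at fit time.
    group_size
        cells per pseudo-cell (default 10).
    train_ratio
        subject-level train fraction of the stratified split (default 0.7).
    lasso_penalty
        L1 penalty for gene selection (default 0.1).
    cv_folds, n_candidates
        fivefold CV and 25 random-search candidates by default.
    retention_R
        minimum held-out Pearson R for the model to be retained (0.8).
    """

    def __init__(
        self,
        dataset: ExpressionDataset,
        cell_type: Optional[str] = None,
        group_size: int = 10,
        train_ratio: float = 0.7,
        lasso_penalty: float = 0.1,
        cv_folds: int = 5,
        n_candidates: int = 25,
        retention_R: float = 0.8,
    ) -> None:
        if dataset.layer_tag not in ("lognorm", "imputed"):
            raise ValueError("GestationalAgeClock expects the lognorm or imputed layer")
        types = dataset.cell_meta["cell_type"].unique()
        if cell_type is None:
            if len(types) != 1:
                raise ValueError("dataset has several cell types; pass cell_type=")
            cell_type = str(types[0])
        elif cell_type not in set(map(str, types)):
            raise ValueError(f"cell type {cell_type!r} not present in dataset")
        mask = (dataset.cell_meta["cell_type"].astype(str) == cell_type).to_numpy()
        self.dataset = dataset.subset_cells(mask)
        self.cell_type = cell_type
        self.group_size = group_size
        self.train_ratio = train_ratio
        self.lasso_penalty = lasso_penalty
        self.cv_folds = cv_folds
        self.n_candidates = n_candidates
        self.retention_R = retention_R

    def fit(self, seed: int = 0) -> "ClockResults":
        """Run the full per-type pipeline and return :class:`ClockResults`."""
        ds = self.dataset
        pregnant = (ds.cell_meta["ga_weeks"] >= 1).to_numpy()
        ds = ds.subset_cells(pregnant)
        if ds.cell_meta["subject_id"].nunique() < 4:
            raise ValueError("need at least 4 pregnant subjects to split and evaluate")
        plan = split_subjects(ds, ratio=self.train_ratio, seed=seed)
        in_train = ds.cell_meta["subject_id"].isin(plan.train_subjects).to_numpy()
        in_test = ds.cell_meta["subject_id"].isin(plan.test_subjects).to_numpy()
        train_ds = ds.subset_cells(in_train)
        test_ds = ds.subset_cells(in_test)
        # pseudo-cells are built inside each side so no group mixes information
        train_pcs = make_pseudocells(train_ds, self.group_size, seed=seed + 1)
        test_pcs = make_pseudocells(test_ds, self.group_size, seed=seed + 2)
        if len(train_pcs) < 2 or len(test_pcs) < 1:
            raise ValueError("too few pseudo-cells; lower group_size or add cells")
        Xtr, mtr = stack_pseudocells(train_pcs)
        pc_ds = ExpressionDataset(
            Xtr,
            ds.gene_names,
            pd.DataFrame(
                {
                    "cell_id": [f"pc{i}" for i in range(len(mtr))],
                    "subject_id": mtr["subject_id"],
                    "cell_type": mtr["cell_type"],
                    "ga_days": mtr["ga_days"],
                    "ga_weeks": mtr["ga_days"] // 7,
                    "stage": "first",
                }
            ),
            layer_tag=ds.layer_tag,
        )
        scaled_ds, scaler = scale_genes(pc_ds)
        y = mtr["ga_days"].to_numpy(dtype=float)
        genes = select_genes_lasso(
            scaled_ds.dense(), y, list(ds.gene_names), penalty=self.lasso_penalty
        )
        pos = ds.gene_names.get_indexer(genes)
        model = tune_and_train(
            scaled_ds.dense()[:, pos],
            y,
            genes,
            n_candidates=self.n_candidates,
            cv_folds=self.cv_folds,
            seed=seed,
            cell_type=self.cell_type,
            scaler=scaler,
            lasso_penalty=self.lasso_penalty,
            dataset_hash=_hash_dataset(ds),
        )
        report = predict_subjects(model, test_pcs, ds.gene_names, retention_R=self.retention_R)
        return ClockResults(
            model=model,
            report=report,
            split=plan,
            train_pseudocells=train_pcs,
            test_pseudocells=test_pcs,
            gene_names=ds.gene_names,
            seed=seed,
        )


@dataclass
class ClockResults:
    """Fit results of :class:`GestationalAgeClock`.

    Carries the fitted :class:`ClockModel`, the held-out
    :class:`EvaluationReport`, the split plan and the pseudo-cells, and
    exposes interpretation helpers (SHAP ranking, minimum-MSE gene-count
    selection) and plotting.
    """

    model: ClockModel
    report: EvaluationReport
    split: SplitPlan
    train_pseudocells: List[PseudoCell]
    test_pseudocells: List[PseudoCell]
    gene_names: pd.Index
    seed: int

    # convenience metric accessors
    @property
    def r(self) -> float:
        return self.report.R

    @property
    def rmse(self) -> float:
        return self.report.rmse

    @property
    def retained(self) -> bool:
        return self.report.retained

    @property
    def predictions(self) -> pd.DataFrame:
        return self.report.predictions

    def summary(self) -> str:
        head = [
            "=" * 64,
            "Gestational-age transcriptomic clock",
            "=" * 64,
            f"cell type:        {self.model.cell_type}",
            f"selected genes:   {len(self.model.selected_genes)} (LASSO alpha = {self.model.lasso_penalty:g})",
            f"train subjects:   {len(self.split.train_subjects)}",
            f"test subjects:    {len(self.split.test_subjects)}",
            f"train pseudocells:{len(self.train_pseudocells)}",
            f"test pseudocells: {len(self.test_pseudocells)}",
            f"best RF params:   {self.model.best_params}",
            "-" * 64,
        ]
        return "\n".join(head) + "\n" + self.report.summary()

    def shap_importances(self, on: str = "train") -> pd.DataFrame:
        """Mean |SHAP| gene importances of the fitted forest (see interpret)."""
        from .interpret import shap_rank

        pcs = self.train_pseudocells if on == "train" else self.test_pseudocells
        return shap_rank(self.model, pcs, self.gene_names)

    def refine_gene_count(self, cv_folds: Optional[int] = None) -> "ClockResults":
        """Minimum-MSE gene-count selection + retrain (see interpret)."""
        from .interpret import select_top_genes_retrain

        new_model = select_top_genes_retrain(
            self.model,
            self.train_pseudocells,
            self.gene_names,
            cv_folds=cv_folds or 5,
        )
        new_report = predict_subjects(
            new_model, self.test_pseudocells, self.gene_names, retention_R=self.report.retention_R
        )
        return ClockResults(
            model=new_model,
            report=new_report,
            split=self.split,
            train_pseudocells=self.train_pseudocells,
            test_pseudocells=self.test_pseudocells,
            gene_names=self.gene_names,
            seed=self.seed,
        )

    def plot_predictions(self, ax=None):
        """Scatter of predicted vs true gestational age (days) per subject."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4.5))
        df = self.predictions
        ax.scatter(df["ga_true_days"], df["ga_predicted_days"], s=18, alpha=0.8)
        lim = [0, max(300.0, df[["ga_true_days", "ga_predicted_days"]].to_numpy().max() * 1.05)]
        ax.plot(lim, lim, ls="--", c="grey", lw=1)
        ax.set_xlabel("GA by ultrasound (days)")
        ax.set_ylabel("GA predicted (days)")
        ax.set_title(
            f"{self.model.cell_type}: R={self.r:.3f}, RMSE={self.rmse:.1f} d"
        )
        return ax


def run_clock_all_types(
    datasets: Dict[str, ExpressionDataset],
    group_size: int = 10,
    train_ratio: float = 0.7,
    lasso_penalty: float = 0.1,
    cv_folds: int = 5,
    n_candidates: int = 25,
    retention_R: float = 0.8,
    seed: int = 0,
) -> Tuple[Dict[str, ClockResults], pd.DataFrame]:
    """Fit one clock per cell type and rank retained models by R.

    Types failing preconditions (too few subjects or pseudo-cells) are
    skipped with a logged reason.  Returns the per-type results map and a
    ranked summary table.
    """
    results: Dict[str, ClockResults] = {}
    rows = []
    for i, (ctype, ds) in enumerate(sorted(datasets.items())):
        try:
            clock = GestationalAgeClock(
                ds,
                cell_type=ctype,
                group_size=group_size,
                train_ratio=train_ratio,
                lasso_penalty=lasso_penalty,
                cv_folds=cv_folds,
                n_candidates=n_candidates,
                retention_R=retention_R,
            )
            res = clock.fit(seed=seed + i)
        except ValueError as err:
            log.warning("run_clock_all_types: skipping %r (%s)", ctype, err)
            continue
        results[ctype] = res
        rows.append(
            {
                "cell_type": ctype,
                "n_selected_genes": len(res.model.selected_genes),
                "R": res.r,
                "p": res.report.p,
                "rmse": res.rmse,
                "retained": res.retained,
            }
        )
    summary = pd.DataFrame(rows, columns=["cell_type", "n_selected_genes", "R", "p", "rmse", "retained"])
    if len(summary):
        summary = summary.sort_values("R", ascending=False, kind="stable").reset_index(drop=True)
    return results, summary
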
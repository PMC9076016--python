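"""End-to-end orchestration: config, derived seeds, the full run, reports.

A :class:`RunConfig` captures every tunable of the pipeline (QC cutoffs,
clock parameters, seeds, paths); :func:`run_pipeline` executes
qc -> subset -> (scoring) -> clock -> interpretation and writes a summary
JSON plus per-stage TSVs, all stamped with the config hash so reruns with
an identical config are byte-identical.

Seeding: a single global seed fans out to per-stage seeds as
``stage_seed = (global_seed * 100003 + crc32(stage_name)) mod 2^31`` so
each stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset, read_dataset
from .qc import QCThresholds, filter_cells, lognormalize, subset_cell_types, impute
from .scoring import builtin_signatures, load_signatures, module_score, stage_compare
from .clock import run_clock_all_types
from .interpret import shap_rank, cross_type_prioritize

__all__ = ["RunConfig", "stage_seed", "run_pipeline"]

log = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global seed (stable, < 2^31)."""
    return (global_seed * 100003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    input_dir: Optional[str] = None
    # QC
    min_genes: int = 800
    max_genes: int = 6000
    max_mito_pct: float = 5.0
    min_cells_per_type: int = 1000
    scale_factor: float = 1e4
    impute_method: str = "none"
    # clock
    group_size: int = 10
    train_ratio: float = 0.7
    lasso_penalty: float = 0.1
    cv_folds: int = 5
    n_candidates: int = 25
    retention_R: float = 0.8
    refine_gene_count: bool = False
    # scoring
    signatures_path: Optional[str] = None
    score_signatures: bool = False
    min_models: int = 2
    # seeds
    seed: int = 0

    def qc_thresholds(self) -> QCThresholds:
        return QCThresholds(
            min_genes=self.min_genes,
            max_genes=self.max_genes,
            max_mito_pct=self.max_mito_pct,
            min_cells_per_type=self.min_cells_per_type,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(
    config: RunConfig,
    outdir,
    dataset: Optional[ExpressionDataset] = None,
) -> dict:
    """Execute the full pipeline and write a report directory.

    ``dataset`` may be passed in memory; otherwise ``config.input_dir``
    is read.  Returns the summary dict (also written as summary.json).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    config.to_yaml(outdir / "config.yaml")

    if dataset is None:
        if config.input_dir is None:
            raise ValueError("either dataset or config.input_dir is required")
        dataset = read_dataset(config.input_dir)

    summary: dict = {"config_hash": chash, "stages": {}}
    thresholds = config.qc_thresholds()

    # --- QC ---------------------------------------------------------------
    filtered, report = filter_cells(dataset, thresholds)
    summary["stages"]["qc"] = report.to_dict()
    (outdir / "qc_report.json").write_text(
        json.dumps({"config_hash": chash, **report.to_dict()}, sort_keys=True, indent=2)
    )

    normed = lognormalize(filtered, scale_factor=config.scale_factor)

    # --- per-type subsets -------------------------------------------------
    subsets, excluded = subset_cell_types(normed, thresholds)
    summary["stages"]["subset"] = {
        "retained_types": sorted(subsets),
        "excluded_types": excluded,
    }
    if config.impute_method != "none":
        subsets = {
            t: impute(ds, method=config.impute_method, seed=stage_seed(config.seed, f"impute:{t}"))
            for t, ds in subsets.items()
        }

    # --- optional signature scoring ---------------------------------------
    if config.score_signatures:
        sigs = (
            load_signatures(config.signatures_path)
            if config.signatures_path
            else builtin_signatures()
        )
        score_frames = []
        for sig in sigs.values():
            try:
                sc = module_score(
                    normed, sig, seed=stage_seed(config.seed, f"score:{sig.name}")
                )
            except Exception as err:  # unmatched signature on synthetic genes
                log.warning("scoring %r skipped: %s", sig.name, err)
                continue
            score_frames.append(sc)
        if score_frames:
            scores = pd.concat(score_frames, ignore_index=True)
            scores.to_csv(outdir / "module_scores.tsv", sep="\t", index=False)
            comparisons = []
            for name, sub in scores.groupby("signature"):
                cmp_df = stage_compare(sub)
                cmp_df.insert(0, "signature", name)
                comparisons.append(cmp_df)
            pd.concat(comparisons, ignore_index=True).to_csv(
                outdir / "stage_comparisons.tsv", sep="\t", index=False
            )

    # --- clock ------------------------------------------------------------
    results, clock_summary = run_clock_all_types(
        subsets,
        group_size=config.group_size,
        train_ratio=config.train_ratio,
        lasso_penalty=config.lasso_penalty,
        cv_folds=config.cv_folds,
        n_candidates=config.n_candidates,
        retention_R=config.retention_R,
        seed=stage_seed(config.seed, "clock"),
    )
    if config.refine_gene_count:
        results = {t: r.refine_gene_count(config.cv_folds) for t, r in results.items()}
        rows = []
        for t, r in sorted(results.items()):
            rows.append(
                {
                    "cell_type": t,
                    "n_selected_genes": len(r.model.selected_genes),
                    "R": r.r,
                    "p": r.report.p,
                    "rmse": r.rmse,
                    "retained": r.retained,
                }
            )
        clock_summary = (
            pd.DataFrame(rows).sort_values("R", ascending=False, kind="stable").reset_index(drop=True)
        )
    clock_summary.to_csv(outdir / "clock_summary.tsv", sep="\t", index=False)
    summary["stages"]["clock"] = {
        "per_type": clock_summary.to_dict(orient="records"),
        "retained_types": clock_summary.loc[clock_summary["retained"], "cell_type"].tolist()
        if len(clock_summary)
        else [],
    }
    for t, res in results.items():
        res.predictions.assign(config_hash=chash).to_csv(
            outdir / f"predictions_{t}.tsv", sep="\t", index=False
        )
        res.model.save(outdir / "models" / t)

    # --- interpretation ---------------------------------------------------
    importances = {}
    for t, res in results.items():
        imp = shap_rank(res.model, res.train_pseudocells, res.gene_names)
        importances[t] = imp
    if importances:
        pd.concat(importances.values(), ignore_index=True).to_csv(
            outdir / "gene_importances.tsv", sep="\t", index=False
        )
    retained_imps = {
        t: importances[t] for t in importances if bool(results[t].retained)
    }
    if len(retained_imps) >= 2:
        cross = cross_type_prioritize(retained_imps, min_models=config.min_models)
        cross.to_csv(outdir / "cross_type_genes.tsv", sep="\t", index=False)
        summary["stages"]["interpretation"] = {
            "top_genes": cross.head(22).to_dict(orient="records")
        }
    else:
        summary["stages"]["interpretation"] = {"top_genes": []}

    (outdir / "summary.json").write_text(
        json.dumps(summary, sort_keys=True, indent=2, default=_json_default) + "\n"
    )
    return summary
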
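"""Synthetic single-cell pregnancy-cohort generator.

Emulates the statistical structure of a PBMC single-cell study sampled
across gestation: ~131 pregnant subjects spanning gestational weeks 6-40
plus a handful of non-pregnant controls, several cell types of very
unequal abundance, a minority of genes whose expression rises (or falls)
log-linearly with gestational age -- interferon-stimulated-gene-like
behaviour -- negative-binomial count noise with dropout, and a
subject-level batch effect.

Counts for gene g in a cell of subject s with gestational age t are drawn

    count ~ NB(mean = m_g * 2^(beta_g * (t - t_mid)) * exp(u_{s,g}),
               dispersion = theta)

followed by independent Bernoulli dropout.  ``beta_g`` is nonzero only for
the planted age-dependent genes and is scaled so the two extreme ages of
the cohort differ by ``age_effect_log2fc`` log2 units; ``u_{s,g}`` is a
N(0, subject_sd^2) subject random effect.  Mitochondrial genes (symbols
prefixed ``MT-``) receive a share of the expression budget so the
expected mitochondrial fraction matches ``mito_frac_mean``, exercising
the QC filter realistically.

The generator returns the planted truth (:class:`GroundTruth`) so every
downstream stage -- QC, scoring, the clock, SHAP ranking -- can be tested
for recovery of a known signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import sparse

from .dataset import ExpressionDataset, stage_from_weeks, write_dataset, read_dataset

__all__ = ["CohortSpec", "GroundTruth", "generate_cohort", "write_dataset", "read_dataset"]

#: default cell-type composition: (name, mean cells per subject); strongly
#: unequal abundances as in real PBMC data (T/NK/monocyte >> DC/platelet)
DEFAULT_CELL_TYPES: Tuple[Tuple[str, int], ...] = (
    ("CD8_naive_T", 120),
    ("NK", 80),
    ("monocyte", 60),
    ("naive_B", 30),
    ("DC", 8),
)


class InvalidSpecError(ValueError):
    """Raised when a CohortSpec violates its own constraints."""


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults mirror the study design being emulated: 131 pregnant women
    sampled across gestational days 42-280 (weeks 6-40) plus non-pregnant
    controls, 1,000 genes of which 50 carry an age effect of 2 log2 units
    across the gestational range, negative-binomial dispersion 2, 30%
    dropout, and a mild subject-level batch effect.
    """

    n_subjects: int = 131
    ga_range_days: Tuple[int, int] = (42, 280)
    frac_nonpregnant: float = 5 / 136
    cell_types: Sequence[Tuple[str, int]] = DEFAULT_CELL_TYPES
    n_genes: int = 1000
    n_age_genes: int = 50
    age_effect_log2fc: float = 2.0
    dispersion: float = 2.0
    dropout_rate: float = 0.3
    subject_sd: float = 0.1
    mito_frac_mean: float = 0.02
    n_mito_genes: int = 10
    frac_negative_age_genes: float = 0.2
    age_genes_per_type: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise InvalidSpecError("n_subjects must be positive")
        lo, hi = self.ga_range_days
        if not (0 < lo < hi):
            raise InvalidSpecError("ga_range_days must be an increasing positive interval")
        if not 0 <= self.frac_nonpregnant < 1:
            raise InvalidSpecError("frac_nonpregnant must be in [0, 1)")
        if self.n_genes <= 0:
            raise InvalidSpecError("n_genes must be positive")
        if not 0 <= self.n_age_genes <= self.n_genes:
            raise InvalidSpecError("n_age_genes must be in [0, n_genes]")
        if self.age_genes_per_type and self.n_age_genes * len(self.cell_types) > self.n_genes - self.n_mito_genes:
            raise InvalidSpecError("not enough genes for disjoint per-type age gene sets")
        if self.age_effect_log2fc < 0:
            raise InvalidSpecError("age_effect_log2fc must be non-negative")
        if self.dispersion <= 0:
            raise InvalidSpecError("dispersion must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise InvalidSpecError("dropout_rate must be in [0, 1)")
        if self.subject_sd < 0:
            raise InvalidSpecError("subject_sd must be non-negative")
        if not 0 <= self.mito_frac_mean < 1:
            raise InvalidSpecError("mito_frac_mean must be in [0, 1)")
        if self.n_mito_genes < 0 or self.n_mito_genes > self.n_genes:
            raise InvalidSpecError("n_mito_genes must be in [0, n_genes]")


@dataclass
class GroundTruth:
    """Planted signal of a generated cohort.

    ``slopes`` maps every gene to its log-scale (natural log) change per
    day of gestation; zero for all non-planted genes.  When disjoint
    per-cell-type age gene sets were requested, ``age_genes_by_type``
    records which planted genes act in which cell type.
    """

    age_gene_ids: List[str]
    slopes: pd.Series
    subject_ages: Dict[str, int]
    age_genes_by_type: Dict[str, List[str]] = field(default_factory=dict)
    baseline_means: np.ndarray = None  # cell-type x gene NB means before noise


def _baseline_means(rng: np.random.Generator, spec: CohortSpec, n_types: int) -> np.ndarray:
    """Cell-type x gene baseline NB means with unequal per-gene expression.

    Log-normal per-gene means (median ~0.5 counts/cell) with mild cell-type
    modulation; mitochondrial genes are rescaled so their expected share of
    the per-cell expression budget equals ``mito_frac_mean``.
    """
    base = rng.lognormal(mean=np.log(0.5), sigma=1.0, size=spec.n_genes)
    type_mod = rng.lognormal(mean=0.0, sigma=0.3, size=(n_types, spec.n_genes))
    means = base[None, :] * type_mod
    if spec.n_mito_genes and spec.mito_frac_mean > 0:
        mito = slice(0, spec.n_mito_genes)
        for t in range(n_types):
            m = means[t]
            mito_sum = m[mito].sum()
            rest_sum = m.sum() - mito_sum
            # solve for scale a: a*mito_sum / (a*mito_sum + rest_sum) = f
            f = spec.mito_frac_mean
            a = f * rest_sum / ((1 - f) * mito_sum)
            m[mito] *= a
    return means


def generate_cohort(spec: CohortSpec) -> Tuple[ExpressionDataset, GroundTruth]:
    """Generate a synthetic cohort according to ``spec``.

    Returns the count-layer :class:`ExpressionDataset` (sparse) and the
    :class:`GroundTruth` of planted age-dependent genes.  Fully
    deterministic under ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_types = len(spec.cell_types)
    type_names = [name for name, _ in spec.cell_types]

    # gene universe: mito genes first, then numbered symbols
    gene_names = [f"MT-G{i + 1}" for i in range(spec.n_mito_genes)] + [
        f"GENE{i + 1:05d}" for i in range(spec.n_genes - spec.n_mito_genes)
    ]
    gene_index = pd.Index(gene_names)

    # subjects and ages
    n_np = int(round(spec.frac_nonpregnant * spec.n_subjects))
    n_pregnant = spec.n_subjects - n_np
    lo, hi = spec.ga_range_days
    ages = np.concatenate(
        [rng.integers(lo, hi + 1, size=n_pregnant), np.zeros(n_np, dtype=int)]
    )
    subjects = [f"S{i + 1:04d}" for i in range(spec.n_subjects)]
    subject_ages = dict(zip(subjects, (int(a) for a in ages)))

    # planted age genes: drawn from the non-mito pool
    candidates = np.arange(spec.n_mito_genes, spec.n_genes)
    t_mid = 0.5 * (lo + hi)
    slope_per_day_log2 = spec.age_effect_log2fc / (hi - lo)
    slopes = np.zeros(spec.n_genes)
    age_genes_by_type: Dict[str, List[str]] = {}
    type_gene_mask = np.ones((n_types, spec.n_genes), dtype=bool)  # which planted genes act per type
    if spec.n_age_genes:
        if spec.age_genes_per_type:
            picked = rng.choice(candidates, size=spec.n_age_genes * n_types, replace=False)
            age_idx = picked
            type_gene_mask = np.zeros((n_types, spec.n_genes), dtype=bool)
            for t, tname in enumerate(type_names):
                block = picked[t * spec.n_age_genes : (t + 1) * spec.n_age_genes]
                type_gene_mask[t, block] = True
                age_genes_by_type[tname] = list(gene_index[np.sort(block)])
        else:
            age_idx = rng.choice(candidates, size=spec.n_age_genes, replace=False)
        sign = np.where(
            rng.random(len(age_idx)) < spec.frac_negative_age_genes, -1.0, 1.0
        )
        slopes[age_idx] = sign * slope_per_day_log2 * np.log(2.0)
    age_idx = np.flatnonzero(slopes != 0.0)
    age_gene_ids = list(gene_index[age_idx])

    means = _baseline_means(rng, spec, n_types)

    # subject x gene random effect (natural-log scale)
    u = (
        rng.normal(0.0, spec.subject_sd, size=(spec.n_subjects, spec.n_genes))
        if spec.subject_sd > 0
        else np.zeros((spec.n_subjects, spec.n_genes))
    )

    blocks = []
    meta_rows = []
    cell_counter = 0
    for s_i, subj in enumerate(subjects):
        ga = int(ages[s_i])
        for t_i, (tname, mean_cells) in enumerate(spec.cell_types):
            n_cells = int(rng.poisson(mean_cells))
            if n_cells == 0:
                continue
            mu = means[t_i] * np.exp(u[s_i])
            if ga > 0 and spec.n_age_genes:
                # log-linear age effect centred at the cohort midpoint
                effect = np.exp(slopes * (ga - t_mid))
                effect = np.where(type_gene_mask[t_i], effect, 1.0)
                mu = mu * effect
            theta = spec.dispersion
            p = theta / (theta + mu)
            counts = rng.negative_binomial(theta, p, size=(n_cells, spec.n_genes))
            if spec.dropout_rate > 0:
                keep = rng.random(counts.shape) >= spec.dropout_rate
                counts = counts * keep
            blocks.append(sparse.csr_matrix(counts))
            weeks = ga // 7
            for c in range(n_cells):
                meta_rows.append(
                    (
                        f"C{cell_counter + c + 1:07d}",
                        subj,
                        tname,
                        ga,
                        weeks,
                        stage_from_weeks(weeks),
                    )
                )
            cell_counter += n_cells

    if blocks:
        X = sparse.vstack(blocks, format="csr")
    else:
        X = sparse.csr_matrix((0, spec.n_genes))
    meta = pd.DataFrame(
        meta_rows, columns=["cell_id", "subject_id", "cell_type", "ga_days", "ga_weeks", "stage"]
    )
    ds = ExpressionDataset(X, gene_index, meta, layer_tag="counts")
    # record QC covariates the generator knows exactly
    ds.cell_meta["n_genes_detected"] = ds.detected_genes()
    ds.cell_meta["mito_frac"] = ds.mito_fraction()
    truth = GroundTruth(
        age_gene_ids=age_gene_ids,
        slopes=pd.Series(slopes, index=gene_index, name="slope_per_day"),
        subject_ages=subject_ages,
        age_genes_by_type=age_genes_by_type,
        baseline_means=means,
    )
    return ds, truth
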
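# Methods

This note records the models, parameter choices and numerical conventions
behind `gestclock`, in the spirit of a statistical-software methods
appendix: what is computed, under which assumptions, and where the design
was genuinely open.

## 1. The synthetic cohort model

The generator (`gestclock.synthetic`) is a negative-binomial hierarchical
model of a pregnancy PBMC cohort. For gene *g* in a cell of type *t* from
subject *s* with gestational age *a* (days):

```
count ~ NB(mean = m_tg · 2^(β_g (a − a_mid)) · exp(u_sg),  dispersion θ)
count ← count · Bernoulli(1 − p_drop)
```

* `m_tg` — baseline mean: log-normal across genes (median ≈ 0.5
  counts/cell, σ = 1), with mild log-normal cell-type modulation (σ = 0.3).
  Gives the heavy-tailed mean–abundance profile of droplet scRNA-seq.
* `β_g` — zero except for the planted **age genes**; scaled so expression
  at the two extreme gestational ages differs by `age_effect_log2fc` log2
  units, linear in days on the log scale (the simplest monotone profile for
  ISG-like behaviour; 20% of planted genes decline rather than rise by
  default). The effect is centred at the cohort age midpoint so planted
  genes keep their baseline average abundance.
* `u_sg ~ N(0, subject_sd²)` — a per-subject, per-gene log-scale random
  effect emulating subject-level batch variation.
* `θ` — NB dispersion (variance `μ + μ²/θ`), default 2; `p_drop` default
  0.3. NB-plus-dropout is the standard count model for scRNA-seq.

Defaults mirror the emulated study design: 131 subjects, gestational ages
uniform on days 42–280 (weeks 6–40), ~4% non-pregnant controls (assigned
age 0 and stage `non-pregnant`; they never enter clock training), five
cell types with strongly unequal abundance, 1,000 genes with 50 planted
age genes at 2 log2 units. Ten genes are named with the `MT-` prefix and
rescaled so the expected mitochondrial fraction matches `mito_frac_mean`
(default 2%), so the mito QC filter operates on realistic input.

What the generator does **not** emulate: doublets, ambient RNA, chemistry
batch effects, and the real 18-type composition. Passing recovery tests on
this cohort therefore demonstrates that the pipeline's statistics behave
as designed under its stated noise model — not that the clock attains any
particular accuracy on real cohorts.

## 2. QC and preprocessing

* Cell filter: detected (nonzero) genes per cell within [800, 6000]
  inclusive, mitochondrial fraction ≤ 5%. The bounds are read literally
  from the convention "cells with <800 or >6000 discarded", making 800 and
  6000 themselves survivors. The mito comparison is done on fractions
  (`frac > max_pct/100`), not percentages: multiplying by 100 first rounds
  a cell sitting exactly on the boundary past it in IEEE arithmetic.
* Mito genes are recognised by the case-insensitive symbol prefix `MT-`
  (configurable).
* Cell types with fewer than 1,000 cells are excluded ("fewer than" strict,
  so a 1,000-cell type survives).
* Normalization: per-cell depth scaling to `scale_factor` (10⁴) then
  log1p. Cells with zero total counts become all-zero rows with a warning.
* Imputation: a pluggable hook with two built-ins — `none` (identity) and
  `knn_smooth`, which replaces each cell by the mean of its k = 15 nearest
  neighbours (itself included) in 20-component PCA space of the log layer.
  `knn_smooth` is a deliberately simple diffusion-style smoother standing
  behind the imputation interface; any heavier algorithm with the same
  signature can be dropped in. The clock's correctness properties do not
  depend on the specific smoother, but smoothing dropout zeros before
  pseudo-cell aggregation substantially reduces the attenuation bias of
  the regressor (measured on the synthetic cohort: held-out RMSE ~34 days
  without imputation vs ~20 days with it, at the same R ≈ 0.99).
* Scaling: per-gene centre/scale to unit variance computed **on training
  pseudo-cells only** (sample sd, ddof = 1); the stored parameters
  transform held-out data. Constant genes map to zero columns with sd
  recorded as 1.

Stage map: `non-pregnant` = age 0; first trimester = weeks 1–13; second =
14–27; third = ≥ 28 (clinical convention). An optional finer map splits the
first trimester into `first-early` (≤ GW9) and `first-late` (GW10–13).

## 3. Gene-set module score

Per-cell score = mean expression of the signature genes − mean expression
of expression-matched control genes. Genes are ranked by dataset-wide mean
expression and cut into `n_bins` = 24 equal-frequency bins (ties broken by
stable gene order); for each signature gene, `n_ctrl` = 100 controls are
drawn without replacement from its bin, and the pooled unique control set
is used. The RNG seed governs control sampling only.

Design choice: signature genes are **excluded** from control candidates;
when a signature monopolizes a bin, candidates are taken from the nearest
bins so controls stay expression-matched, and only a whole-universe
signature falls back to its own bins (where the subtraction cancels
exactly). Allowing self-contamination biases the score toward zero
whenever a coherently regulated signature crowds the top expression bin —
on a planted +1 log-unit fixture the measured group separation drops from
≈ 1.0 to ≈ 0.33. Exclusion is also the behaviour of scanpy's
`score_genes`, against which the implementation is cross-checked in the
test suite.

Shipped signatures (`data/signatures.yaml`): 10 cytotoxicity genes (the
printed source list says 11 but lists 10, and "KLRDC1" is not a standard
symbol — kept verbatim with a comment), 13 apoptosis genes, 5 exhaustion
markers, and a documented placeholder ISG list (the original 58-gene list
is not public; all ISG operations take the list as input).

## 4. Stage statistics and differential expression

* Wilcoxon rank-sum, two-sided: exact null distribution when both groups
  have ≤ 50 observations and the pooled sample is tie-free; tie-corrected
  normal approximation otherwise. Fully tied input is defined as p = 1
  (the approximation degenerates there). Stars: * < 0.05, ** < 0.01,
  *** < 0.001, **** < 0.0001, `ns` otherwise. Cells are the default unit,
  with a subject-level option (per-subject mean) for correlated cells.
* Gene–age correlation: Pearson r between **per-gestational-week mean
  expression** and week, with the t-distribution p (n − 2 df). The week is
  the aggregation unit because per-cell correlation would count thousands
  of correlated cells as independent samples. Zero-variance genes are
  reported as missing with a reason.
* Differential expression: per-gene Wilcoxon on the log layer;
  `log2FC = log2((mean expm1 x₁ + 1)/(mean expm1 x₂ + 1))`;
  Benjamini–Hochberg across tested genes; significant when |log2FC| ≥ 0.3
  and adjusted p < 0.05. A marker mode restricts to genes expressed in
  ≥ 25% of either group with positive log-FC ≥ 0.25.
  Note that the log2FC threshold test is calibrated for balanced
  perturbations: when a large one-sided block of the transcriptome shifts,
  depth normalization redistributes the difference across all genes and
  produces compositional calls that no per-gene test can distinguish from
  signal.

## 5. The clock

* **Pseudo-cells**: within one subject and cell type, cells are randomly
  permuted (seeded, without replacement) and partitioned into consecutive
  groups of 10; leftovers are discarded (pseudo-cells are single-subject
  by definition, so leftovers are never pooled across subjects). Each
  group contributes its per-gene median (midpoint convention for even
  groups). Counts per subject = ⌊n/10⌋.
* **Split**: subjects are split 7:3 within each pregnancy-period stratum
  (shuffled, `round(0.7·n)` to train, both sides kept non-empty);
  single-subject strata go to training with a warning. Splitting happens
  **before** pseudo-cell construction so no group mixes train/test
  information. Non-pregnant subjects are excluded: the clock predicts the
  age of normal pregnancy.
* **Gene selection**: LASSO at α = 0.1 on scaled pseudo-cells against age
  in days; selected genes ordered by |coefficient|, deduplicated by name.
  An empty selection (possible at extreme penalties) falls back to the top
  50 genes by |Pearson correlation| with age, logged prominently.
* **Regressor**: random forest tuned by randomized search, 25 candidates,
  fivefold shuffled CV minimizing RMSE, then refit on all training
  pseudo-cells. Search space: trees ∈ {50…300}, max depth ∈ {None, 5, 10,
  15, 20, 25, 30}, min samples per leaf ∈ {1…10}, feature fraction per
  split ∈ [0.05, 0.3]. The space is sized for pseudo-cell problems of a
  few hundred to a few thousand rows with hundreds of selected genes:
  beyond ~300 trees and ~30% feature sampling the CV RMSE curve is flat on
  such problems while fit cost grows linearly, so the larger grid buys
  nothing but runtime.
* **Evaluation**: subject prediction = arithmetic mean over the subject's
  pseudo-cell predictions; Pearson R (t-test p, two-sided, n − 2 df) and
  RMSE in days across subjects, overall and per period; a model is
  retained when R ≥ 0.8. Fewer than 3 test subjects → metrics reported
  missing, predictions still emitted; constant predictions → R undefined
  and flagged, RMSE still computed.

## 6. Tree SHAP and gene prioritization

Attributions use the path-dependent Tree SHAP algorithm — the
polynomial-time dynamic program over decision paths whose value function
is the cover-weighted conditional expectation of the tree. It is
implemented from first principles in `gestclock.interpret` (numba-jitted)
and validated against a brute-force Shapley oracle (explicit enumeration
of all feature subsets on small trees) to 1e-10, plus the additivity
(Σφ + base = prediction) and null-player axioms on every evaluated
instance.

Gene importance = mean |SHAP| over pseudo-cells, in days of gestational
age; ties broken by gene name. The optimal gene count scans the ladder
{5, 10, 20, 50, 100, 200, all-selected} (truncated to the gene count) by
CV MSE at the model's fixed tuned hyperparameters, takes the smallest k at
the minimum, and retrains the final model on those genes. Importances are
computed on training pseudo-cells. Cross-type prioritization keeps genes
appearing in ≥ 2 per-type models and scores them by the unweighted mean of
per-type mean |SHAP|; genes present in all models are flagged.

## 7. Orchestration and reproducibility

A single global seed fans out per stage as
`stage_seed = (seed · 100003 + crc32(stage_name)) mod 2³¹`, so stages are
independently reproducible. Every run directory carries the configuration
hash; rerunning an identical configuration reproduces all outputs
byte-for-byte (JSON keys sorted, no timestamps).

## 8. Problem sizes used in the shipped checks

The end-to-end recovery checks run on a cohort of 100 pregnant subjects ×
120 cells × 1,000 genes (50 planted age genes at 2 log2 units, dispersion
2, dropout 0.3, subject effect 0.1) — large enough that subject-level
recovery (R ≥ 0.9, RMSE ≤ 25 days held-out) and SHAP gene recovery are
stable properties rather than lucky draws, while a full pipeline run
completes in minutes on one CPU. Statistical calibrations use 2,000
Wilcoxon null replicates, 5,000-cell scoring fixtures and 200 cells per
DEG group.

## 9. Known limitations

* The clock is validated on synthetic cohorts only; real-data accuracy
  depends on cohort composition, depth and annotation quality in ways the
  generator does not model.
* `knn_smooth` is a stand-in smoother, not a diffusion-operator
  imputation; it is applied per cell-type subset before splitting, so—as
  in the emulated workflow—the unsupervised smoothing sees all cells.
* Random forests do not extrapolate beyond the training age range;
  predictions compress slightly at the extremes of gestation (visible as
  larger early/late RMSE than mid-pregnancy RMSE).
* Women sampled repeatedly at different gestational ages are treated as
  distinct subjects only if presented as such; when a linkage column is
  available the split should be done on the physical subject.
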
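"""Module scores, Wilcoxon comparisons, age correlations, DEGs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_dataset
from gestclock.scoring import (
    EmptySignatureError,
    GeneSignature,
    builtin_signatures,
    differential_expression,
    gene_age_correlation,
    module_score,
    significance_stars,
    stage_compare,
    wilcoxon_rank_sum,
)


def lognorm_dataset(X, **kw):
    ds = make_dataset(np.asarray(X, dtype=float), **kw)
    ds.layer_tag = "lognorm"
    return ds


class TestGeneSignature:
    def test_rejects_duplicates_and_empty(self):
        with pytest.raises(ValueError):
            GeneSignature("s", ("A", "A"))
        with pytest.raises(ValueError):
            GeneSignature("s", ())

    def test_builtin_signatures_load(self):
        sigs = builtin_signatures()
        assert {"cytotoxicity", "apoptosis", "exhaustion", "isg_placeholder"} <= set(sigs)
        assert len(sigs["cytotoxicity"].genes) == 10
        assert len(sigs["apoptosis"].genes) == 13
        assert sigs["exhaustion"].genes == ("LAG3", "PDCD1", "CTLA4", "HAVCR2", "TOX")


class TestModuleScore:
    def test_constant_expression_scores_zero(self):
        ds = lognorm_dataset(np.full((20, 60), 3.0))
        sig = GeneSignature("s", tuple(f"G{j}" for j in range(5)))
        out = module_score(ds, sig, n_bins=10, n_ctrl=20, seed=0)
        np.testing.assert_allclose(out["score"], 0.0, atol=1e-12)

    def test_whole_universe_signature_near_zero(self):
        rng = np.random.default_rng(0)
        ds = lognorm_dataset(rng.gamma(2.0, 1.0, size=(300, 200)))
        sig = GeneSignature("all", tuple(f"G{j}" for j in range(200)))
        out = module_score(ds, sig, n_bins=24, n_ctrl=100, seed=1)
        assert abs(out["score"].mean()) < 0.02

    def test_planted_shift_recovered(self):
        rng = np.random.default_rng(2)
        X = rng.gamma(2.0, 0.5, size=(400, 150))
        sig_genes = [f"G{j}" for j in range(10)]
        shifted = np.arange(400) < 200
        X[np.ix_(shifted, np.arange(10))] += 1.0
        ds = lognorm_dataset(X)
        out = module_score(ds, GeneSignature("p", tuple(sig_genes)), n_bins=10, seed=3)
        diff = out["score"][shifted].mean() - out["score"][~shifted].mean()
        assert abs(diff - 1.0) < 0.1

    def test_invariant_to_cell_and_gene_order(self):
        rng = np.random.default_rng(4)
        X = rng.gamma(2.0, 0.5, size=(50, 40))
        genes = [f"G{j}" for j in range(40)]
        ds = lognorm_dataset(X, gene_names=genes)
        sig = GeneSignature("s", ("G3", "G7", "G11"))
        base = module_score(ds, sig, n_bins=8, n_ctrl=10, seed=5)
        cell_perm = rng.permutation(50)
        ds_cells = lognorm_dataset(X[cell_perm], gene_names=genes)
        ds_cells.cell_meta["cell_id"] = [f"c{i}" for i in cell_perm]
        out = module_score(ds_cells, sig, n_bins=8, n_ctrl=10, seed=5)
        merged = base.merge(out, on="cell_id", suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged["score_a"], merged["score_b"], atol=1e-12)

    def test_constant_offset_cancels(self):
        rng = np.random.default_rng(6)
        X = rng.gamma(2.0, 0.5, size=(30, 40))
        ds = lognorm_dataset(X)
        sig = GeneSignature("s", ("G1", "G2", "G3"))
        a = module_score(ds, sig, n_bins=8, n_ctrl=10, seed=7)["score"]
        ds_shift = lognorm_dataset(X + 5.0)
        b = module_score(ds_shift, sig, n_bins=8, n_ctrl=10, seed=7)["score"]
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_unmatched_signature_raises(self):
        ds = lognorm_dataset(np.ones((5, 30)))
        with pytest.raises(EmptySignatureError):
            module_score(ds, GeneSignature("s", ("NOPE",)), n_bins=5)


class TestWilcoxon:
    def test_identical_groups_p_one(self):
        w, p = wilcoxon_rank_sum(np.array([1.0, 2, 2, 3]), np.array([1.0, 2, 2, 3]))
        assert p == pytest.approx(1.0, abs=0.05)
        w, p = wilcoxon_rank_sum(np.array([5.0, 5, 5]), np.array([5.0, 5, 5]))
        assert p == 1.0

    def test_exact_small_sample_matches_enumeration(self):
        """{1,2,3} vs {4,5,6}: enumerate all C(6,3)=20 assignments."""
        from itertools import combinations

        pooled = [1, 2, 3, 4, 5, 6]
        obs_sum = 1 + 2 + 3  # rank-sum of group 1 (values are ranks here)
        count_as_extreme = 0
        for comb in combinations(range(6), 3):
            s = sum(sorted(pooled)[i] for i in comb)
            # two-sided: as or more extreme in either direction
            if abs(s - 10.5) >= abs(obs_sum - 10.5):
                count_as_extreme += 1
        expected = count_as_extreme / 20
        _, p = wilcoxon_rank_sum(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert p == pytest.approx(expected)
        assert p == pytest.approx(0.1)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=30), rng.normal(0.5, 1, size=25)
        _, p1 = wilcoxon_rank_sum(x, y)
        _, p2 = wilcoxon_rank_sum(np.exp(x), np.exp(y))
        assert p1 == pytest.approx(p2, rel=1e-10)

    def test_null_calibration(self):
        """Rejection rate at alpha=0.05 within binomial 95% CI over 2000 reps."""
        rng = np.random.default_rng(9)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            x = rng.normal(size=50)
            y = rng.normal(size=50)
            _, p = wilcoxon_rank_sum(x, y)
            rejections += p < 0.05
        rate = rejections / reps
        half = 1.96 * np.sqrt(0.05 * 0.95 / reps)
        assert 0.05 - half <= rate <= 0.05 + half

    def test_stars_mapping(self):
        assert significance_stars(0.2) == "ns"
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.009) == "**"
        assert significance_stars(0.0009) == "***"
        assert significance_stars(1e-5) == "****"


class TestStageCompare:
    def _scores(self):
        rng = np.random.default_rng(10)
        n = 60
        return pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(2 * n)],
                "subject_id": [f"s{i % 12}" for i in range(2 * n)],
                "signature": "sig",
                "score": np.concatenate([rng.normal(0, 1, n), rng.normal(1, 1, n)]),
                "stage": ["first"] * n + ["third"] * n,
            }
        )

    def test_detects_shift(self):
        out = stage_compare(self._scores(), pairs=[("first", "third")])
        assert out.loc[0, "p"] < 0.001
        assert out.loc[0, "stars"] in ("***", "****")

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            stage_compare(self._scores(), pairs=[("first", "non-pregnant")])

    def test_subject_unit_aggregates(self):
        out = stage_compare(self._scores(), pairs=[("first", "third")], unit="subject")
        assert len(out) == 1 and 0 <= out.loc[0, "p"] <= 1


class TestGeneAgeCorrelation:
    def _ds(self):
        weeks = np.repeat([6, 10, 20, 30, 40], 4)
        days = weeks * 7
        n = len(days)
        X = np.zeros((n, 3))
        X[:, 0] = weeks  # weekly mean equals the week
        X[:, 1] = 2.0  # constant
        X[:, 2] = np.random.default_rng(0).random(n)
        return lognorm_dataset(X, ga_days=days)

    def test_perfect_linear_gene(self):
        out = gene_age_correlation(self._ds())
        row = out[out["gene"] == "G0"].iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["p"] < 1e-8

    def test_constant_gene_reported_missing(self):
        out = gene_age_correlation(self._ds())
        row = out[out["gene"] == "G1"].iloc[0]
        assert np.isnan(row["r"]) and row["reason"] == "zero variance"

    def test_requires_three_weeks(self):
        days = np.repeat([70, 140], 5)
        ds = lognorm_dataset(np.random.default_rng(1).random((10, 2)), ga_days=days)
        with pytest.raises(ValueError):
            gene_age_correlation(ds)


class TestDifferentialExpression:
    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(11)
        X = rng.gamma(2, 0.5, size=(40, 50))
        ds = lognorm_dataset(X)
        mask = np.arange(40)
        out = differential_expression(ds, mask, mask)
        assert not out["significant"].any()
        assert (out["p"] == 1.0).all() | (out["p"] > 0.99).all()

    def test_bh_adjustment_closed_form(self):
        from statsmodels.stats.multitest import multipletests

        p = np.array([0.01, 0.02, 0.03, 0.04])
        adj = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_antisymmetry_under_group_swap(self):
        rng = np.random.default_rng(12)
        X = rng.gamma(2, 0.5, size=(60, 30))
        X[:30, :5] += 0.8
        ds = lognorm_dataset(X)
        g1, g2 = np.arange(30), np.arange(30, 60)
        a = differential_expression(ds, g1, g2).set_index("gene")
        b = differential_expression(ds, g2, g1).set_index("gene")
        np.testing.assert_allclose(a["log2fc"], -b.loc[a.index, "log2fc"], atol=1e-12)
        np.testing.assert_allclose(a["p"], b.loc[a.index, "p"], atol=1e-12)

    def test_planted_fold_change_sensitivity(self):
        """Planted 2x genes at 200 cells/group recovered at 0.3/0.05 thresholds."""
        rng = np.random.default_rng(13)
        n_genes, n_planted = 1000, 50
        base_mu = rng.gamma(2.0, 1.0, size=n_genes) + 0.5
        mu1 = base_mu.copy()
        # balanced design: half up, half down at |log2FC| = 1, so library
        # sizes stay comparable and depth normalization is unbiased
        mu1[: n_planted // 2] *= 2.0
        mu1[n_planted // 2 : n_planted] /= 2.0
        theta = 2.0
        c1 = rng.negative_binomial(theta, theta / (theta + mu1), size=(200, n_genes))
        c2 = rng.negative_binomial(theta, theta / (theta + base_mu), size=(200, n_genes))
        counts = make_dataset(np.vstack([c1, c2]).astype(float))
        from gestclock.qc import lognormalize

        ds = lognormalize(counts)
        out = differential_expression(ds, np.arange(200), np.arange(200, 400))
        called = set(out.loc[out["significant"], "gene"])
        planted = {f"G{j}" for j in range(n_planted)}
        sensitivity = len(called & planted) / n_planted
        fdr = len(called - planted) / max(len(called), 1)
        assert sensitivity >= 0.9
        assert fdr <= 0.1

    def test_marker_mode_positive_only(self):
        rng = np.random.default_rng(14)
        X = rng.gamma(2, 0.5, size=(80, 30))
        X[:40, :3] += 1.0
        X[40:, 3:6] += 1.0
        ds = lognorm_dataset(X)
        out = differential_expression(ds, np.arange(40), np.arange(40, 80), marker_mode=True)
        assert (out["log2fc"] >= 0.25).all()


class TestScanpyCrossCheck:
    def test_module_score_agrees_with_scanpy_score_genes(self):
        """Independent route: scanpy's control-binned score on the same data.

        Control sampling differs in detail (bin draws, RNG), so scores are
        compared by correlation across cells and by the planted group
        separation, not elementwise.
        """
        import scanpy as sc

        rng = np.random.default_rng(20)
        X = rng.gamma(2.0, 0.5, size=(600, 300))
        shifted = np.arange(600) < 300
        X[np.ix_(shifted, np.arange(12))] += 1.0
        ds = lognorm_dataset(X)
        sig = GeneSignature("p", tuple(f"G{j}" for j in range(12)))
        ours = module_score(ds, sig, n_bins=24, n_ctrl=100, seed=21)["score"].to_numpy()

        adata = ds.to_anndata()
        sc.tl.score_genes(
            adata, list(sig.genes), ctrl_size=100, n_bins=24, score_name="sc", random_state=21
        )
        theirs = adata.obs["sc"].to_numpy()
        # different control draws leave independent noise in each score, so
        # cell-wise agreement is high but not perfect
        assert np.corrcoef(ours, theirs)[0, 1] > 0.8
        ours_sep = ours[shifted].mean() - ours[~shifted].mean()
        theirs_sep = theirs[shifted].mean() - theirs[~shifted].mean()
        assert ours_sep == pytest.approx(theirs_sep, abs=0.1)
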
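"""Normalisation, batch correction, PCA and the NB Wald DE test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import silhouette_score

from oastrat import preprocess as pp
from oastrat.synthdata import SimulationDesign, simulate_counts


def _df(values, genes=None, samples=None):
    values = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = _df([[10, 10, 10], [5, 5, 5], [100, 100, 100]])
        assert np.allclose(pp.size_factors(counts), 1.0)

    def test_depth_scaling_equivariance(self):
        counts = _df([[10, 20], [4, 8], [7, 14]])
        factors = pp.size_factors(counts)
        assert factors.iloc[1] / factors.iloc[0] == pytest.approx(2.0)

    def test_matches_hand_computed_median_of_ratios(self):
        # geometric means: g0: sqrt(2*8)=4, g1: sqrt(3*27)=9, g2: sqrt(4*16)=8
        # ratios s0: 2/4, 3/9, 4/8 -> median 0.5; s1: 8/4, 27/9, 16/8 -> 2
        counts = _df([[2, 8], [3, 27], [4, 16]])
        factors = pp.size_factors(counts)
        assert factors.iloc[0] == pytest.approx(0.5)
        assert factors.iloc[1] == pytest.approx(2.0)

    def test_all_zero_sample_is_named_in_error(self):
        counts = _df([[5, 0], [3, 0]], samples=["ok", "bad"])
        with pytest.raises(ValueError, match="bad"):
            pp.size_factors(counts)

    def test_gene_order_invariance(self, small_cohort):
        cm, _ = small_cohort
        shuffled = cm.counts.sample(frac=1.0, random_state=0)
        pd.testing.assert_series_equal(
            pp.size_factors(cm.counts), pp.size_factors(shuffled)
        )


class TestNormalizeLog:
    def test_log2_values(self):
        counts = _df([[0], [7]])
        expr = pp.normalize_log(counts, pd.Series([1.0], index=counts.columns))
        assert expr.values.iloc[0, 0] == pytest.approx(0.0)
        assert expr.values.iloc[1, 0] == pytest.approx(3.0)

    def test_depth_scaled_duplicate_sample_normalises_away(self):
        rng = np.random.default_rng(0)
        base = rng.integers(10, 1000, size=50)
        counts = _df(np.column_stack([base, base * 4]))
        expr = pp.normalize_log(counts)
        assert np.allclose(expr.values.iloc[:, 0], expr.values.iloc[:, 1])

    def test_pseudocount_must_be_positive(self):
        with pytest.raises(ValueError, match="pseudocount"):
            pp.normalize_log(_df([[1]]), pseudocount=0.0)


class TestBatchCorrect:
    def test_single_batch_is_identity(self):
        expr = pp.ExpressionMatrix(_df(np.arange(12.0).reshape(3, 4)))
        batches = pd.Series(["b0"] * 4, index=expr.values.columns)
        out = pp.batch_correct(expr, batches)
        pd.testing.assert_frame_equal(out.values, expr.values)

    def test_planted_shift_removed(self):
        rng = np.random.default_rng(1)
        mat = rng.normal(5, 1, size=(20, 8))
        mat[:, 4:] += 2.5  # batch 2 shifted by delta
        expr = pp.ExpressionMatrix(_df(mat))
        batches = pd.Series(
            ["b1"] * 4 + ["b2"] * 4, index=expr.values.columns
        )
        out = pp.batch_correct(expr, batches).values
        for _, row in out.iterrows():
            assert row[:4].mean() == pytest.approx(row[4:].mean())

    def test_singleton_batch_rejected(self):
        expr = pp.ExpressionMatrix(_df(np.ones((3, 3))))
        batches = pd.Series(["b1", "b1", "b2"], index=expr.values.columns)
        with pytest.raises(ValueError, match="singleton"):
            pp.batch_correct(expr, batches)

    def test_batch_separation_in_pca_drops_after_correction(self):
        design = SimulationDesign(
            n_genes=500, n_control=8, n_groupA=8, n_groupB=8,
            n_shared_de=0, n_specificA=0, n_specificB=0,
            batch_lfc_sd=1.0, seed=21,
        )
        cm, _ = simulate_counts(design)
        expr = pp.normalize_log(cm.counts)
        batches = cm.metadata["batch"]
        before, _ = pp.pca_embed(expr, 2)
        corrected = pp.batch_correct(expr, batches)
        after, _ = pp.pca_embed(corrected, 2)
        sil_before = silhouette_score(before, batches.loc[before.index])
        sil_after = silhouette_score(after, batches.loc[after.index])
        assert sil_after < sil_before


class TestPCA:
    def test_explained_variance_non_increasing(self, small_cohort):
        cm, _ = small_cohort
        expr = pp.normalize_log(cm.counts)
        _, evr = pp.pca_embed(expr, 5)
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1 + 1e-9

    def test_rank_one_matrix_fully_explained_by_pc1(self):
        x = np.array([[1.0, 2.0, 3.0, 4.0]])
        mat = np.vstack([x, 2 * x])  # perfectly correlated genes
        _, evr = pp.pca_embed(pp.ExpressionMatrix(_df(mat)), 1)
        assert evr[0] == pytest.approx(1.0)

    def test_full_rank_reconstruction(self, rng):
        mat = rng.normal(size=(50, 20))
        expr = pp.ExpressionMatrix(_df(mat))
        coords, evr = pp.pca_embed(expr, 20)
        assert evr.sum() == pytest.approx(1.0, abs=1e-9)
        # sum of squared coordinates reproduces the centred total variance
        centred = mat - mat.mean(axis=1, keepdims=True)
        assert (coords.to_numpy() ** 2).sum() == pytest.approx((centred**2).sum())

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pp.pca_embed(pp.ExpressionMatrix(_df(np.ones((4, 4)))), 2)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert pp.bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_executed_step_up(self):
        # p*m/i = (.04, .04, .04, .04); cumulative minima keep .04 everywhere
        assert pp.bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_ties_unchanged(self):
        assert pp.bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=200)
        adj = pp.bh_adjust(p)
        _, expected, _, _ = multipletests(p, method="fdr_bh")
        assert adj == pytest.approx(expected)

    def test_empty_and_invalid(self):
        assert pp.bh_adjust([]).size == 0
        with pytest.raises(ValueError):
            pp.bh_adjust([0.5, 1.5])


def _null_design(seed, n_genes=500, n=10):
    return SimulationDesign(
        n_genes=n_genes, n_control=n, n_groupA=n, n_groupB=1,
        n_shared_de=0, n_specificA=0, n_specificB=0,
        n_batches=1, batch_lfc_sd=0.0, seed=seed,
    )


class TestDETest:
    def test_deg_rule_matches_thresholds(self, small_cohort):
        cm, _ = small_cohort
        de = pp.de_test(cm.counts, cm.metadata["condition"], reference="nonOA")
        expected = (np.abs(de["log2FC"]) >= np.log2(1.5)) & (de["padj"] <= 0.10)
        assert (de["is_deg"] == expected).all()

    def test_null_design_gives_uniformish_p(self):
        cm, truth = simulate_counts(_null_design(seed=31))
        cols = [s for s, l in truth.sample_labels.items() if l != "B"]
        condition = pd.Series(
            ["nonOA" if truth.sample_labels[s] == "control" else "OA" for s in cols],
            index=cols,
        )
        de = pp.de_test(cm.counts[cols], condition, reference="nonOA")
        assert np.abs(de["log2FC"]).median() < 0.2
        assert sps.kstest(de["pvalue"], "uniform").pvalue > 1e-3

    def test_planted_four_fold_gene_detected(self):
        design = SimulationDesign(
            n_genes=200, n_control=20, n_groupA=20, n_groupB=1,
            n_shared_de=0, n_specificA=10, n_specificB=0,
            lfc_magnitude=2.0, dispersion=0.05,
            n_batches=1, batch_lfc_sd=0.0, seed=17,
        )
        cm, truth = simulate_counts(design)
        cols = [s for s, l in truth.sample_labels.items() if l != "B"]
        condition = pd.Series(
            ["A" if truth.sample_labels[s] == "A" else "ctrl" for s in cols],
            index=cols,
        )
        de = pp.de_test(cm.counts[cols], condition, reference="ctrl")
        assert de.loc[sorted(truth.de_genes_A), "is_deg"].all()

    def test_sign_flips_with_labels_p_unchanged(self, small_cohort):
        cm, _ = small_cohort
        cond = cm.metadata["condition"]
        fwd = pp.de_test(cm.counts, cond, reference="nonOA")
        rev = pp.de_test(cm.counts, cond, reference="OA")
        assert fwd["log2FC"].to_numpy() == pytest.approx(
            -rev["log2FC"].to_numpy(), abs=1e-9
        )
        assert fwd["pvalue"].to_numpy() == pytest.approx(rev["pvalue"].to_numpy())

    def test_sample_reorder_invariance(self, small_cohort):
        cm, _ = small_cohort
        cond = cm.metadata["condition"]
        base = pp.de_test(cm.counts, cond, reference="nonOA")
        shuffled_cols = list(cm.counts.sample(frac=1.0, axis=1, random_state=1))
        again = pp.de_test(cm.counts[shuffled_cols], cond, reference="nonOA")
        pd.testing.assert_frame_equal(base, again)

    def test_all_zero_gene_excluded_not_error(self):
        counts = _df(
            [[5, 6, 7, 8], [0, 0, 0, 0], [9, 8, 7, 6]], genes=["a", "zero", "b"]
        )
        cond = pd.Series(["x", "x", "y", "y"], index=counts.columns)
        de = pp.de_test(counts, cond)
        assert "zero" not in de.index
        assert de.attrs["excluded_genes"] == ["zero"]

    def test_matches_deseq2_reference_on_small_cohort(self, small_cohort):
        """Independent cross-check: fold changes agree with pydeseq2."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        cm, _ = small_cohort
        de = pp.de_test(cm.counts, cm.metadata["condition"], reference="nonOA")
        dds = DeseqDataSet(
            counts=cm.counts.T,
            metadata=cm.metadata,
            design="~condition",
            quiet=True,
        )
        dds.deseq2()
        res = DeseqStats(dds, contrast=["condition", "OA", "nonOA"], quiet=True)
        res.summary()
        ref = res.results_df.reindex(de.index)
        r = np.corrcoef(de["log2FC"], ref["log2FoldChange"])[0, 1]
        assert r > 0.95
        # top calls broadly agree
        ours = set(de.index[de["padj"] <= 0.10])
        theirs = set(ref.index[ref["padj"] <= 0.10])
        jaccard = len(ours & theirs) / max(len(ours | theirs), 1)
        assert jaccard > 0.6


class TestCompareDegSets:
    def test_identical_inputs_all_shared(self, small_cohort):
        cm, _ = small_cohort
        de = pp.de_test(cm.counts, cm.metadata["condition"], reference="nonOA")
        out = pp.compare_deg_sets(de, de, de)
        assert out["n_distinctive_A"] == 0
        assert out["n_distinctive_B"] == 0
        assert out["pattern_counts"].get("allAB", 0) == out["n_union"]

    def test_disjoint_toy_sets(self):
        from conftest import toy_de_table

        genes = ["g1", "g2", "g3", "g4"]
        d_all = toy_de_table(genes, [0, 0, 0, 0], [1, 1, 1, 1])
        d_a = toy_de_table(genes, [2, 2, 0, 0], [0.01, 0.01, 1, 1])
        d_b = toy_de_table(genes, [0, 0, 2, 0], [1, 1, 0.01, 1])
        out = pp.compare_deg_sets(d_all, d_a, d_b)
        assert out["n_distinctive_A"] == 2
        assert out["n_distinctive_B"] == 1
        assert out["n_union"] == 3
        assert sum(out["pattern_counts"].values()) == 3

    def test_mismatched_universe_rejected(self):
        from conftest import toy_de_table

        a = toy_de_table(["g1"], [0], [1])
        b = toy_de_table(["g2"], [0], [1])
        with pytest.raises(ValueError, match="universe"):
            pp.compare_deg_sets(a, a, b)


def test_planted_lfc_recovery_mae():
    """On a large design the DE stage estimates planted log2 fold changes
    with small mean absolute error."""
    design = SimulationDesign(
        n_control=50, n_groupA=50, n_groupB=1,
        n_shared_de=200, n_specificA=0, n_specificB=0, seed=13,
    )
    cm, truth = simulate_counts(design)
    cols = [s for s, l in truth.sample_labels.items() if l != "B"]
    condition = pd.Series(
        ["nonOA" if truth.sample_labels[s] == "control" else "OA" for s in cols],
        index=cols,
    )
    de = pp.de_test(cm.counts[cols], condition, reference="nonOA")
    planted = pd.Series(truth.de_genes_shared)
    est = de["log2FC"].reindex(planted.index)
    assert float((est - planted).abs().mean()) <= 0.15
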
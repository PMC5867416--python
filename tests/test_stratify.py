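"""Network-NMF, consensus clustering, silhouette and patient assignment."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_samples

from oastrat import stratify as st
from oastrat.synthdata import SimulationDesign, simulate_counts, simulate_network
from oastrat import preprocess as pp


def _random_network(genes, p=0.2, seed=0):
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(genes)
    for i, u in enumerate(genes):
        for v in genes[i + 1 :]:
            if rng.random() < p:
                g.add_edge(u, v, weight=1.0)
    return st.GeneNetwork(g)


class TestNMF:
    def test_exact_factorisation_is_fixed_point(self, rng):
        W0 = rng.uniform(0.5, 1.5, size=(12, 3))
        H0 = rng.uniform(0.5, 1.5, size=(3, 8))
        X = W0 @ H0
        fit = st.nmf_fit(X, k=3, lam=0.0, init=(W0, H0), max_iter=20, tol=0)
        assert fit.objective_trace[0] == pytest.approx(0.0, abs=1e-18)
        assert fit.objective_trace[-1] == pytest.approx(0.0, abs=1e-18)
        assert np.allclose(fit.W @ fit.H, X)

    @pytest.mark.parametrize("lam", [0.0, 0.1, 1.0, 10.0])
    def test_objective_non_increasing(self, rng, lam):
        genes = [f"g{i}" for i in range(20)]
        X = pd.DataFrame(
            rng.uniform(size=(20, 10)), index=genes,
            columns=[f"s{j}" for j in range(10)],
        )
        network = _random_network(genes, seed=3)
        fit = st.nmf_fit(X, k=3, lam=lam, network=network, max_iter=100,
                         tol=0.0, seed=1)
        trace = np.array(fit.objective_trace)
        assert np.all(np.diff(trace) <= 1e-9 * np.maximum(trace[:-1], 1))

    def test_lambda_zero_equals_no_network(self, rng):
        genes = [f"g{i}" for i in range(15)]
        X = pd.DataFrame(rng.uniform(size=(15, 8)), index=genes,
                         columns=[f"s{j}" for j in range(8)])
        network = _random_network(genes, seed=5)
        a = st.nmf_fit(X, k=2, lam=0.0, network=network, seed=7, max_iter=50)
        b = st.nmf_fit(X, k=2, lam=1.0, network=None, seed=7, max_iter=50)
        assert np.array_equal(a.W, b.W)
        assert np.array_equal(a.H, b.H)

    def test_invalid_inputs_rejected(self, rng):
        X = rng.uniform(size=(6, 4))
        with pytest.raises(ValueError, match="non-negative"):
            st.nmf_fit(X - 1.0, k=2)
        with pytest.raises(ValueError, match="k="):
            st.nmf_fit(X, k=4)


class TestConsensus:
    def test_block_structure_recovered_exactly(self):
        rng = np.random.default_rng(0)
        block = np.zeros((40, 12))
        block[:20, :6] = rng.uniform(5, 6, size=(20, 6))
        block[20:, 6:] = rng.uniform(5, 6, size=(20, 6))
        X = pd.DataFrame(block + 0.01, index=[f"g{i}" for i in range(40)],
                         columns=[f"s{j}" for j in range(12)])
        C = st.consensus_cluster(X, k=2, n_runs=30, lam=0.0,
                                 subsample_fraction=1.0, seed=0)
        mat = C.to_numpy()
        assert np.allclose(mat[:6, :6], 1.0)
        assert np.allclose(mat[6:, 6:], 1.0)
        assert np.allclose(mat[:6, 6:], 0.0)

    def test_single_run_entries_binary(self, rng):
        X = pd.DataFrame(rng.uniform(size=(10, 6)))
        C = st.consensus_cluster(X, k=2, n_runs=1, subsample_fraction=1.0,
                                 lam=0.0, seed=1)
        assert set(np.unique(C.to_numpy())) <= {0.0, 1.0}

    def test_default_runs_is_500(self):
        import inspect

        assert inspect.signature(st.consensus_cluster).parameters["n_runs"].default == 500

    def test_symmetry_and_diagonal(self, rng):
        X = pd.DataFrame(rng.uniform(size=(15, 8)))
        C = st.consensus_cluster(X, k=2, n_runs=25, lam=0.0, seed=2).to_numpy()
        assert np.allclose(C, C.T)
        assert np.allclose(np.diag(C), 1.0)

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(3)
        block = np.zeros((30, 10))
        block[:15, :5] = rng.uniform(5, 6, size=(15, 5))
        block[15:, 5:] = rng.uniform(5, 6, size=(15, 5))
        X = pd.DataFrame(block + 0.01, columns=[f"s{j}" for j in range(10)])
        C1 = st.consensus_cluster(X, k=2, n_runs=60, lam=0.0, seed=4)
        perm = list(X.sample(frac=1.0, axis=1, random_state=5))
        C2 = st.consensus_cluster(X[perm], k=2, n_runs=60, lam=0.0, seed=6)
        # strong structure: both consensus matrices are essentially binary
        assert np.allclose(C1.loc[perm, perm].to_numpy(), C2.to_numpy(), atol=0.1)


class TestSilhouette:
    def test_four_point_toy_hand_computed(self):
        D = np.full((4, 4), 10.0)
        np.fill_diagonal(D, 0.0)
        D[0, 1] = D[1, 0] = 1.0
        D[2, 3] = D[3, 2] = 1.0
        s = st.silhouette(D, [0, 0, 1, 1])
        assert s == pytest.approx([0.9, 0.9, 0.9, 0.9])

    def test_perfect_separation(self):
        D = np.array(
            [[0, 0, 5, 5], [0, 0, 5, 5], [5, 5, 0, 0], [5, 5, 0, 0]], dtype=float
        )
        assert st.silhouette(D, [0, 0, 1, 1]) == pytest.approx([1.0] * 4)

    def test_relabelling_invariance(self, rng):
        D = rng.uniform(1, 2, size=(8, 8))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        labels = np.array([0, 0, 0, 1, 1, 2, 2, 2])
        s1 = st.silhouette(D, labels)
        s2 = st.silhouette(D, 10 - labels)
        assert s1 == pytest.approx(s2)

    def test_matches_sklearn(self, rng):
        D = rng.uniform(1, 3, size=(12, 12))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        labels = rng.integers(0, 3, size=12)
        if len(np.unique(labels)) < 2:
            labels[0] = (labels[0] + 1) % 3
        ours = st.silhouette(D, labels)
        theirs = silhouette_samples(D, labels, metric="precomputed")
        assert ours == pytest.approx(theirs, abs=1e-9)

    def test_single_cluster_rejected(self):
        D = np.zeros((3, 3))
        with pytest.raises(ValueError, match="2 clusters"):
            st.silhouette(D, [0, 0, 0])


def _planted_expression(n_groups, per_group=8, n_genes=200, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 0.5, size=(n_genes, n_groups * per_group))
    genes_per_group = n_genes // (n_groups + 1)
    for g in range(n_groups):
        rows = slice(g * genes_per_group, (g + 1) * genes_per_group)
        cols = slice(g * per_group, (g + 1) * per_group)
        X[rows, cols] += rng.uniform(4, 5, size=(genes_per_group, per_group))
    labels = np.repeat(np.arange(n_groups), per_group)
    return (
        pd.DataFrame(X, index=[f"g{i}" for i in range(n_genes)],
                     columns=[f"s{j}" for j in range(n_groups * per_group)]),
        labels,
    )


class TestSelectK:
    def test_recovers_two_planted_groups(self):
        X, truth = _planted_expression(2, seed=1)
        res = st.select_k(X, range(2, 5), n_runs=40, lam=0.0, seed=1)
        assert res.chosen_k == 2
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_recovers_three_planted_groups(self):
        X, truth = _planted_expression(3, seed=2)
        res = st.select_k(X, range(2, 5), n_runs=40, lam=0.0, seed=2)
        assert res.chosen_k == 3
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_degenerate_k_range(self):
        X, _ = _planted_expression(2, seed=3)
        res = st.select_k(X, [2], n_runs=10, lam=0.0, seed=3)
        assert res.chosen_k == 2
        assert list(res.per_k_mean_silhouette) == [2]

    def test_empty_k_range_rejected(self):
        X, _ = _planted_expression(2, seed=4)
        with pytest.raises(ValueError, match="empty"):
            st.select_k(X, [], n_runs=10)


class TestAssignWithExclusion:
    def _consensus(self, sil_values):
        n = len(sil_values)
        ids = [f"s{i}" for i in range(n)]
        C = pd.DataFrame(np.eye(n), index=ids, columns=ids)
        return st.ConsensusResult(
            coclustering=C,
            n_runs=10,
            labels=pd.Series([1] * (n // 2) + [2] * (n - n // 2), index=ids),
            per_sample_silhouette=pd.Series(sil_values, index=ids),
            per_k_mean_silhouette={2: float(np.mean(sil_values))},
            chosen_k=2,
        )

    def test_no_exclusions_when_all_fit(self):
        out = st.assign_with_exclusion(self._consensus([0.5, 0.8, 0.9, 0.7]))
        assert not out["excluded"].any()
        assert out.attrs["summary"]["n_unassigned"] == 0

    def test_threshold_one_excludes_everything_below_perfect(self):
        out = st.assign_with_exclusion(
            self._consensus([0.5, 0.8, 0.9, 0.7]), min_silhouette=1.0
        )
        assert (out["cluster"] == "unassigned").all()

    def test_threshold_outside_range_rejected(self):
        with pytest.raises(ValueError, match="min_silhouette"):
            st.assign_with_exclusion(self._consensus([0.5, 0.5]), min_silhouette=1.01)

    def test_negative_silhouette_samples_unassigned(self):
        out = st.assign_with_exclusion(self._consensus([0.6, -0.1, 0.7, -0.3]))
        assert list(out.index[out["excluded"]]) == ["s1", "s3"]
        assert (out.loc[["s1", "s3"], "cluster"] == "unassigned").all()
        assert out.attrs["summary"]["n_unassigned"] == 2


class TestCovariateAssociation:
    def _labels(self, n=20):
        return pd.Series(
            ["A"] * (n // 2) + ["B"] * (n - n // 2),
            index=[f"s{i}" for i in range(n)],
        )

    def test_label_identical_covariate_is_significant(self):
        labels = self._labels()
        meta = pd.DataFrame({"copy": labels}, index=labels.index)
        out = st.covariate_association(labels, meta, ["copy"])
        assert out.loc[0, "p"] < 1e-4

    def test_constant_covariate_reported_not_tested(self):
        labels = self._labels()
        meta = pd.DataFrame({"flat": ["x"] * len(labels)}, index=labels.index)
        out = st.covariate_association(labels, meta, ["flat"])
        assert out.loc[0, "p"] == 1.0
        assert "constant" in out.loc[0, "note"]

    def test_missing_covariate_rejected(self):
        labels = self._labels()
        meta = pd.DataFrame(index=labels.index)
        with pytest.raises(ValueError, match="absent"):
            st.covariate_association(labels, meta, ["age"])

    def test_null_continuous_covariate_p_uniform(self):
        labels = self._labels(24)
        pvals = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            meta = pd.DataFrame(
                {"bmi": rng.normal(28, 4, size=len(labels))}, index=labels.index
            )
            out = st.covariate_association(labels, meta, ["bmi"])
            pvals.append(out.loc[0, "p"])
        from scipy import stats as sps

        assert sps.kstest(pvals, "uniform").pvalue > 0.01


def test_network_regularisation_helps_on_module_signal():
    """When subgroup signal lives on network modules and is noisy, the graph
    penalty improves recovery over plain NMF."""
    design = SimulationDesign(
        n_genes=600, n_control=4, n_groupA=10, n_groupB=10,
        n_shared_de=0, n_specificA=60, n_specificB=60,
        lfc_magnitude=0.55, dispersion=0.4, n_batches=1, batch_lfc_sd=0.0,
        seed=12,
    )
    cm, truth = simulate_counts(design)
    network = st.GeneNetwork(
        simulate_network(truth, design.n_genes, module_density=0.6,
                         background_degree=2, seed=12)
    )
    expr = pp.normalize_log(cm.counts)
    oa = cm.metadata.index[cm.metadata["condition"] == "OA"]
    X = st.clustering_features(expr, oa, n_top=600)
    truth_labels = [truth.sample_labels[s] for s in X.columns]

    def ari(lam, net):
        C = st.consensus_cluster(X, 2, n_runs=60, lam=lam, network=net, seed=5)
        labels = st._cut_consensus(C, 2)
        return adjusted_rand_score(truth_labels, labels)

    assert ari(1.0, network) >= ari(0.0, None)


def test_gene_network_validation():
    g = nx.Graph()
    g.add_edge("a", "a")
    with pytest.raises(ValueError, match="self-loops"):
        st.GeneNetwork(g)
    g2 = nx.Graph()
    g2.add_edge("a", "b", weight=-1.0)
    with pytest.raises(ValueError, match="positive"):
        st.GeneNetwork(g2)
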
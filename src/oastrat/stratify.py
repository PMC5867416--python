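"""Patient subgroup discovery by network-regularised NMF consensus clustering.

The factorisation minimises ``||X - WH||_F^2 + lambda * tr(W' L W)`` where L
is the (degree-normalised) graph Laplacian of a gene-gene interaction
network, using Cai-style multiplicative updates.  With ``lambda = 0`` (or no
network) the updates reduce exactly to standard Lee-Seung NMF.  Repeated
stochastic runs are aggregated into a sample co-clustering matrix; the number
of clusters is chosen by the mean silhouette of an average-linkage cut of
``1 - coclustering``, and samples whose per-sample silhouette falls below a
threshold (default 0, i.e. closer to another cluster than their own) are
left unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .preprocess import ExpressionMatrix, bh_adjust

__all__ = [
    "GeneNetwork",
    "NMFDecomposition",
    "ConsensusResult",
    "nmf_fit",
    "consensus_cluster",
    "silhouette",
    "select_k",
    "assign_with_exclusion",
    "covariate_association",
    "clustering_features",
]

_EPS = 1e-10


class GeneNetwork:
    """Undirected weighted gene-gene network with Laplacian access.

    Wraps a :class:`networkx.Graph`; ``laplacian_parts`` returns the
    adjacency and degree aligned to an arbitrary gene ordering (genes absent
    from the network contribute zero rows, i.e. no penalty).
    """

    def __init__(self, graph: nx.Graph):
        if any(u == v for u, v in graph.edges):
            raise ValueError("self-loops not allowed")
        for _, _, data in graph.edges(data=True):
            if data.get("weight", 1.0) <= 0:
                raise ValueError("edge weights must be positive")
        self.graph = graph

    @property
    def nodes(self):
        return self.graph.nodes

    def laplacian_parts(
        self, gene_ids, normalized: bool = True
    ) -> tuple[sparse.csr_matrix, np.ndarray]:
        """(adjacency, degree) aligned to ``gene_ids``.

        With ``normalized=True`` the adjacency is D^{-1/2} A D^{-1/2} and the
        degree vector is 1 on network genes (normalised Laplacian I - A');
        genes not in the network get zero degree and no penalty.
        """
        gene_ids = list(gene_ids)
        pos = {g: i for i, g in enumerate(gene_ids)}
        rows, cols, vals = [], [], []
        for u, v, data in self.graph.edges(data=True):
            if u in pos and v in pos:
                w = data.get("weight", 1.0)
                rows += [pos[u], pos[v]]
                cols += [pos[v], pos[u]]
                vals += [w, w]
        n = len(gene_ids)
        adj = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
        degree = np.asarray(adj.sum(axis=1)).ravel()
        if normalized:
            inv_sqrt = np.zeros(n)
            nz = degree > 0
            inv_sqrt[nz] = 1.0 / np.sqrt(degree[nz])
            scale = sparse.diags(inv_sqrt)
            adj = scale @ adj @ scale
            degree = nz.astype(float)
        return adj.tocsr(), degree


@dataclass
class NMFDecomposition:
    W: np.ndarray  # gene x k
    H: np.ndarray  # k x sample
    k: int
    lam: float
    objective_trace: list[float] = field(default_factory=list)

    @property
    def labels(self) -> np.ndarray:
        """Hard sample labels: argmax over the k rows of H (ties -> lowest)."""
        return np.argmax(self.H, axis=0)


def _objective(
    X: np.ndarray,
    W: np.ndarray,
    H: np.ndarray,
    lam: float,
    adj: sparse.csr_matrix | None,
    degree: np.ndarray | None,
) -> float:
    resid = X - W @ H
    obj = float((resid**2).sum())
    if lam > 0 and adj is not None:
        # tr(W' L W) = tr(W' D W) - tr(W' A W)
        obj += lam * float((degree[:, None] * W * W).sum() - (W * (adj @ W)).sum())
    return obj


def nmf_fit(
    X: np.ndarray | pd.DataFrame,
    k: int,
    lam: float = 0.0,
    network: GeneNetwork | None = None,
    max_iter: int = 200,
    tol: float = 1e-4,
    seed: int | None = None,
    init: tuple[np.ndarray, np.ndarray] | None = None,
    gene_ids=None,
) -> NMFDecomposition:
    """Multiplicative-update (network-regularised) NMF.

    ``X`` is a non-negative gene x sample matrix.  Stops when the relative
    objective change per iteration drops below ``tol`` or at ``max_iter``.
    ``lam = 0`` or ``network = None`` is exactly Lee-Seung NMF.
    """
    if isinstance(X, pd.DataFrame):
        gene_ids = X.index if gene_ids is None else gene_ids
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if (X < 0).any():
        raise ValueError("X must be non-negative")
    n_genes, n_samples = X.shape
    if not 1 <= k < min(n_genes, n_samples):
        raise ValueError(f"k={k} must satisfy 1 <= k < min(X.shape)={min(X.shape)}")

    adj = degree = None
    if network is not None and lam > 0:
        if gene_ids is None:
            raise ValueError("gene_ids required to align the network with X")
        adj, degree = network.laplacian_parts(gene_ids)

    if init is not None:
        W = np.array(init[0], dtype=float)
        H = np.array(init[1], dtype=float)
        if W.shape != (n_genes, k) or H.shape != (k, n_samples):
            raise ValueError("init shapes do not match (genes, k), (k, samples)")
    else:
        rng = np.random.default_rng(seed)
        scale = np.sqrt(X.mean() / k) if X.mean() > 0 else 1.0
        W = rng.uniform(0.1, 1.0, size=(n_genes, k)) * scale
        H = rng.uniform(0.1, 1.0, size=(k, n_samples)) * scale

    trace = [_objective(X, W, H, lam, adj, degree)]
    for _ in range(max_iter):
        # W update: W * (XH' + lam*A W) / (W H H' + lam*D W)
        numer = X @ H.T
        denom = W @ (H @ H.T)
        if adj is not None:
            numer = numer + lam * (adj @ W)
            denom = denom + lam * (degree[:, None] * W)
        W = W * (numer / np.maximum(denom, _EPS))
        # H update: H * (W'X) / (W'W H)
        H = H * ((W.T @ X) / np.maximum((W.T @ W) @ H, _EPS))
        obj = _objective(X, W, H, lam, adj, degree)
        trace.append(obj)
        prev = trace[-2]
        if prev > 0 and (prev - obj) / prev < tol:
            break
    return NMFDecomposition(W=W, H=H, k=k, lam=lam, objective_trace=trace)


def consensus_cluster(
    X: pd.DataFrame | np.ndarray,
    k: int,
    n_runs: int = 500,
    lam: float = 1.0,
    network: GeneNetwork | None = None,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-4,
    gene_ids=None,
) -> pd.DataFrame:
    """Sample x sample co-clustering matrix over stochastic NMF runs.

    Each run subsamples ``subsample_fraction`` of the samples (without
    replacement), fits NMF from a random init, and labels the subsampled
    patients by the argmax row of H.  Entry (i, j) is the fraction of runs in
    which i and j were co-labelled among runs where both were sampled.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must be in (0, 1]")
    if isinstance(X, pd.DataFrame):
        sample_ids = list(X.columns)
        gene_ids = X.index if gene_ids is None else gene_ids
        mat = X.to_numpy(dtype=float)
    else:
        mat = np.asarray(X, dtype=float)
        sample_ids = list(range(mat.shape[1]))
    n = mat.shape[1]
    m = max(int(round(subsample_fraction * n)), k + 1)
    m = min(m, n)

    adjacency_cache = None
    if network is not None and lam > 0:
        adjacency_cache = network.laplacian_parts(gene_ids)

    rng = np.random.default_rng(seed)
    co_label = np.zeros((n, n))
    co_sample = np.zeros((n, n))
    for _ in range(n_runs):
        idx = np.sort(rng.choice(n, size=m, replace=False)) if m < n else np.arange(n)
        sub = mat[:, idx]
        run_seed = int(rng.integers(0, 2**31 - 1))
        fit = _nmf_raw(
            sub, k, lam, adjacency_cache, max_iter=max_iter, tol=tol, seed=run_seed
        )
        labels = np.argmax(fit[1], axis=0)
        sampled = np.zeros(n, dtype=bool)
        sampled[idx] = True
        co_sample += np.outer(sampled, sampled)
        same = labels[:, None] == labels[None, :]
        co_label[np.ix_(idx, idx)] += same
    if (co_sample == 0).any():
        raise ValueError(
            "some sample pairs were never co-sampled; increase subsample_fraction "
            "or n_runs"
        )
    C = co_label / co_sample
    C = (C + C.T) / 2.0
    np.fill_diagonal(C, 1.0)
    return pd.DataFrame(C, index=sample_ids, columns=sample_ids)


def _nmf_raw(X, k, lam, adjacency_cache, max_iter, tol, seed):
    """Inner NMF loop without validation overhead; returns (W, H)."""
    adj = degree = None
    if adjacency_cache is not None:
        adj, degree = adjacency_cache
    rng = np.random.default_rng(seed)
    n_genes, n_samples = X.shape
    scale = np.sqrt(X.mean() / k) if X.mean() > 0 else 1.0
    W = rng.uniform(0.1, 1.0, size=(n_genes, k)) * scale
    H = rng.uniform(0.1, 1.0, size=(k, n_samples)) * scale
    prev = None
    for it in range(max_iter):
        numer = X @ H.T
        denom = W @ (H @ H.T)
        if adj is not None:
            numer += lam * (adj @ W)
            denom += lam * (degree[:, None] * W)
        W *= numer / np.maximum(denom, _EPS)
        H *= (W.T @ X) / np.maximum((W.T @ W) @ H, _EPS)
        if it % 10 == 9:
            obj = float(((X - W @ H) ** 2).sum())
            if prev is not None and prev > 0 and (prev - obj) / prev < tol:
                break
            prev = obj
    return W, H


def silhouette(distances: np.ndarray | pd.DataFrame, labels) -> np.ndarray:
    """Per-sample silhouette values for a dissimilarity matrix.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)); a = mean distance to own cluster
    (excluding self), b = min over other clusters of the mean distance.
    Members of singleton clusters get s = 0.
    """
    D = np.asarray(
        distances.to_numpy() if isinstance(distances, pd.DataFrame) else distances,
        dtype=float,
    )
    labels = np.asarray(labels)
    if D.shape[0] != D.shape[1] or D.shape[0] != labels.size:
        raise ValueError("distance matrix and labels sizes disagree")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    unique = np.unique(labels)
    if unique.size < 2:
        raise ValueError("silhouette needs >= 2 clusters")
    n = labels.size
    s = np.zeros(n)
    masks = {c: labels == c for c in unique}
    for i in range(n):
        own = masks[labels[i]]
        n_own = own.sum()
        if n_own == 1:
            s[i] = 0.0
            continue
        a = D[i, own].sum() / (n_own - 1)
        b = min(D[i, masks[c]].mean() for c in unique if c != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s


@dataclass
class ConsensusResult:
    """Consensus clustering summary at the selected number of clusters."""

    coclustering: pd.DataFrame
    n_runs: int
    labels: pd.Series  # sample -> cluster id (int, 1-based)
    per_sample_silhouette: pd.Series
    per_k_mean_silhouette: dict[int, float]
    chosen_k: int

    @property
    def sample_ids(self):
        return list(self.coclustering.index)


def _cut_consensus(C: pd.DataFrame, k: int) -> np.ndarray:
    """Average-linkage cut of 1 - coclustering into k clusters."""
    D = 1.0 - C.to_numpy()
    np.fill_diagonal(D, 0.0)
    D = np.maximum((D + D.T) / 2.0, 0.0)
    condensed = squareform(D, checks=False)
    Z = linkage(condensed, method="average")
    return fcluster(Z, t=k, criterion="maxclust")


def select_k(
    X: pd.DataFrame,
    k_range=range(2, 6),
    n_runs: int = 500,
    lam: float = 1.0,
    network: GeneNetwork | None = None,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> ConsensusResult:
    """Consensus clustering over a range of k; silhouette-selected k.

    For each k a consensus matrix is built, cut by average linkage into k
    clusters, and scored by the mean silhouette on 1 - coclustering; the k
    with the highest mean silhouette wins (ties toward smaller k).
    """
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range:
        raise ValueError("empty k_range")
    n = X.shape[1]
    if any(not 2 <= k <= n - 1 for k in k_range):
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    per_k: dict[int, float] = {}
    consensus: dict[int, pd.DataFrame] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    sil_by_k: dict[int, np.ndarray] = {}
    base_rng = np.random.default_rng(seed)
    for k in k_range:
        k_seed = int(base_rng.integers(0, 2**31 - 1))
        C = consensus_cluster(
            X,
            k,
            n_runs=n_runs,
            lam=lam,
            network=network,
            subsample_fraction=subsample_fraction,
            seed=k_seed,
            max_iter=max_iter,
            tol=tol,
        )
        labels = _cut_consensus(C, k)
        D = 1.0 - C.to_numpy()
        np.fill_diagonal(D, 0.0)
        sil = silhouette(D, labels)
        per_k[k] = float(sil.mean())
        consensus[k] = C
        labels_by_k[k] = labels
        sil_by_k[k] = sil
    chosen = max(per_k, key=lambda k: (per_k[k], -k))
    return ConsensusResult(
        coclustering=consensus[chosen],
        n_runs=n_runs,
        labels=pd.Series(labels_by_k[chosen], index=X.columns, name="cluster"),
        per_sample_silhouette=pd.Series(
            sil_by_k[chosen], index=X.columns, name="silhouette"
        ),
        per_k_mean_silhouette=per_k,
        chosen_k=chosen,
    )


def assign_with_exclusion(
    consensus: ConsensusResult, min_silhouette: float = 0.0
) -> pd.DataFrame:
    """Final labels: samples with silhouette < threshold become "unassigned".

    Returns a table (cluster, silhouette, excluded) indexed by sample, with
    group sizes and fractions in ``attrs["summary"]``.
    """
    if not -1.0 <= min_silhouette <= 1.0:
        raise ValueError("min_silhouette must lie in [-1, 1]")
    sil = consensus.per_sample_silhouette
    excluded = sil < min_silhouette
    labels = consensus.labels.astype(str).where(~excluded, "unassigned")
    out = pd.DataFrame(
        {"cluster": labels, "silhouette": sil, "excluded": excluded}
    )
    sizes = labels.value_counts().to_dict()
    total = len(labels)
    out.attrs["summary"] = {
        "sizes": sizes,
        "fractions": {k: v / total for k, v in sizes.items()},
        "n_unassigned": int(excluded.sum()),
    }
    return out


def covariate_association(
    labels: pd.Series,
    metadata: pd.DataFrame,
    covariates: list[str],
    max_categories: int = 10,
) -> pd.DataFrame:
    """Association of final group labels with clinical covariates.

    Categorical covariates are tested on the group x level contingency table
    (Fisher exact for 2x2, chi-squared otherwise); continuous ones with the
    Wilcoxon rank-sum test.  P values are BH-adjusted across covariates.
    Report-only: nothing is filtered.
    """
    assigned = labels[labels != "unassigned"]
    groups = sorted(assigned.unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two assigned groups, got {groups}")
    missing = [c for c in covariates if c not in metadata.columns]
    if missing:
        raise ValueError(f"covariate(s) absent from metadata: {missing}")
    meta = metadata.loc[assigned.index]
    rows = []
    for cov in covariates:
        values = meta[cov]
        note = ""
        if values.nunique() <= 1:
            rows.append((cov, "degenerate", 1.0, "constant covariate"))
            continue
        numeric = pd.to_numeric(values, errors="coerce")
        if numeric.notna().all() and numeric.nunique() > max_categories:
            x = numeric[assigned == groups[0]]
            y = numeric[assigned == groups[1]]
            p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
            rows.append((cov, "rank-sum", p, note))
        else:
            table = pd.crosstab(values, assigned).to_numpy()
            if table.shape == (2, 2):
                p = float(stats.fisher_exact(table)[1])
                rows.append((cov, "fisher", p, note))
            else:
                p = float(stats.chi2_contingency(table)[1])
                rows.append((cov, "chi2", p, "r x c table: chi-squared used"))
    out = pd.DataFrame(rows, columns=["covariate", "test", "p", "note"])
    out["padj"] = bh_adjust(out["p"].to_numpy())
    return out[["covariate", "test", "p", "padj", "note"]]


def clustering_features(
    expr: ExpressionMatrix | pd.DataFrame,
    samples=None,
    n_top: int = 2000,
) -> pd.DataFrame:
    """Non-negative clustering input: top-variance genes, min-shifted per gene.

    Genes are ranked by variance across the given samples (default: all) of
    the (batch-corrected) log matrix; each retained gene is shifted by its
    minimum so the matrix is non-negative.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if samples is not None:
        values = values[list(samples)]
    variances = values.var(axis=1)
    top = variances.sort_values(ascending=False, kind="mergesort").index[:n_top]
    sub = values.loc[top]
    shifted = sub.sub(sub.min(axis=1), axis=0)
    return shifted
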
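"""Over-representation analysis and active-subnetwork discovery.

``ora`` is a standard upper-tail hypergeometric test of a DEG list against a
gene-set collection.  ``find_subnetworks`` scores connected gene sets by
their total (node-weighted) absolute differential expression, normalised by
sqrt(size), with seed-gene weights from a random walk with restart and a
permutation null — a simplified active-module formulation of the idea of
scoring gene sets with direct molecular interactions by the differential
expression they carry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse, stats

from .preprocess import bh_adjust

__all__ = [
    "GeneSetCollection",
    "SubnetworkResult",
    "ora",
    "rwr_weights",
    "find_subnetworks",
]


@dataclass
class GeneSetCollection:
    """Named gene sets restricted at analysis time to a testable universe."""

    sets: dict[str, list[str]]
    universe: set[str]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {name: list(dict.fromkeys(m)) for name, m in self.sets.items()}
        self.universe = set(self.universe)
        if not self.universe:
            raise ValueError("empty universe")


def ora(deg_genes, collection: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric over-representation of a DEG list against gene sets.

    p = P(X >= overlap) with population |universe|, successes |set ∩ universe|
    and draws |deg ∩ universe|; BH-adjusted across sets.  DEGs outside the
    universe are dropped; their count is in ``result.attrs["n_dropped"]``.
    """
    deg = set(deg_genes)
    dropped = len(deg - collection.universe)
    if dropped:
        warnings.warn(f"{dropped} DEG(s) outside the universe were dropped")
    deg &= collection.universe
    M = len(collection.universe)
    n_draws = len(deg)
    rows = []
    for name, members in collection.sets.items():
        in_universe = set(members) & collection.universe
        K = len(in_universe)
        overlap = len(deg & in_universe)
        if overlap == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(overlap - 1, M, K, n_draws))
        rows.append((name, overlap, K, p))
    out = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "p"])
    out["padj"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    out["n_deg"] = n_draws
    out = out.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
    out.attrs["n_dropped"] = dropped
    return out


def rwr_weights(
    network: nx.Graph,
    seed_genes,
    restart_prob: float = 0.3,
    tol: float = 1e-10,
    max_iter: int = 100000,
) -> pd.Series:
    """Random-walk-with-restart node weights from a seed-gene set.

    Solves w = (1 - r) P w + r e with P the column-normalised adjacency and
    e uniform on the seeds, to residual < ``tol``.  Weights sum to 1.
    """
    if not 0 < restart_prob <= 1:
        raise ValueError("restart_prob must be in (0, 1]")
    nodes = sorted(network.nodes)
    pos = {g: i for i, g in enumerate(nodes)}
    seeds = [g for g in seed_genes if g in pos]
    if not seeds:
        raise ValueError("no seed genes present in the network")
    n = len(nodes)
    adj = nx.to_scipy_sparse_array(network, nodelist=nodes, weight="weight", format="csc")
    col_sums = np.asarray(adj.sum(axis=0)).ravel()
    inv = np.where(col_sums > 0, 1.0 / np.maximum(col_sums, 1e-300), 0.0)
    P = adj @ sparse.diags(inv)
    e = np.zeros(n)
    for g in seeds:
        e[pos[g]] = 1.0 / len(seeds)
    w = e.copy()
    r = restart_prob
    for _ in range(max_iter):
        w_new = (1 - r) * (P @ w) + r * e
        # dangling columns lose mass; return it to the restart vector
        w_new += (1.0 - w_new.sum()) * e
        if np.abs(w_new - w).sum() < tol:
            w = w_new
            break
        w = w_new
    w = w / w.sum()
    return pd.Series(w, index=nodes, name="rwr_weight")


@dataclass
class SubnetworkResult:
    nodes: list[str]
    score: float
    perm_p: float
    adj_p: float
    node_lfc: dict[str, float]
    node_weight: dict[str, float]


def _subnetwork_score(total: float, size: int) -> float:
    return total / np.sqrt(size)


class _GraphArrays:
    """Index-based graph views for fast repeated greedy growth."""

    def __init__(self, network: nx.Graph):
        self.nodes = sorted(network.nodes)
        pos = {g: i for i, g in enumerate(self.nodes)}
        self.neighbors = [
            np.array(sorted(pos[v] for v in network.neighbors(g)), dtype=np.intp)
            for g in self.nodes
        ]
        edges = [(pos[u], pos[v]) for u, v in network.edges]
        src = np.fromiter((e[0] for e in edges), dtype=np.intp, count=len(edges))
        dst = np.fromiter((e[1] for e in edges), dtype=np.intp, count=len(edges))
        self.edge_src = np.concatenate([src, dst])
        self.edge_dst = np.concatenate([dst, src])

    def local_maxima(self, score: np.ndarray) -> np.ndarray:
        neighbor_max = np.zeros(len(self.nodes))
        np.maximum.at(neighbor_max, self.edge_src, score[self.edge_dst])
        return np.nonzero((score > 0) & (score >= neighbor_max))[0]


def _greedy_grow_idx(
    graph: _GraphArrays, score: np.ndarray, start: int, max_size: int
) -> tuple[list[int], float]:
    """Grow from ``start`` adding the boundary node with the best score;
    stop when the size-normalised score stops improving or at ``max_size``."""
    n = len(graph.nodes)
    in_set = np.zeros(n, dtype=bool)
    boundary = np.zeros(n, dtype=bool)
    members = [start]
    in_set[start] = True
    boundary[graph.neighbors[start]] = True
    total = float(score[start])
    best = total  # score at size 1
    while len(members) < max_size:
        boundary &= ~in_set
        cand_idx = np.nonzero(boundary)[0]
        if cand_idx.size == 0:
            break
        cand = int(cand_idx[np.argmax(score[cand_idx])])
        new_score = _subnetwork_score(total + score[cand], len(members) + 1)
        if new_score <= best:
            break
        members.append(cand)
        in_set[cand] = True
        total += float(score[cand])
        best = new_score
        boundary[graph.neighbors[cand]] = True
    return members, best


def _best_grown_score(
    graph: _GraphArrays, score: np.ndarray, max_size: int
) -> float:
    best = 0.0
    for start in graph.local_maxima(score):
        _, sc = _greedy_grow_idx(graph, score, int(start), max_size)
        best = max(best, sc)
    return best


def find_subnetworks(
    network: nx.Graph,
    de_result: pd.DataFrame,
    node_weights: pd.Series | None = None,
    max_size: int = 30,
    n_perm: int = 1000,
    seed: int = 0,
    jaccard_max: float = 0.5,
    top_n: int = 20,
) -> list[SubnetworkResult]:
    """Greedy seeded growth of high-differential-expression subnetworks.

    Node scores are weight * |log2FC| (weights default to uniform; nodes with
    no fold change get weight 0); subnetworks grow greedily from local score
    maxima, are deduplicated by Jaccard overlap, and get permutation p values
    by re-growing under node-label permutations of the fold changes.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; p values will be coarse")
    graph = _GraphArrays(network)
    nodes = graph.nodes
    lfc = de_result["log2FC"] if "log2FC" in de_result.columns else de_result
    have_fc = [g for g in nodes if g in lfc.index]
    if len(have_fc) < 0.5 * len(nodes):
        raise ValueError("fold changes available for < 50% of network nodes")
    if node_weights is None:
        node_weights = pd.Series(1.0, index=nodes)
    weight = np.array([float(node_weights.get(g, 0.0)) for g in nodes])
    abs_fc = np.array([abs(float(lfc.get(g, 0.0))) for g in nodes])
    node_score = weight * abs_fc

    if not (node_score > 0).any():
        # degenerate input: no differential expression anywhere
        return [
            SubnetworkResult(
                nodes=[nodes[0]], score=0.0, perm_p=1.0, adj_p=1.0,
                node_lfc={nodes[0]: 0.0}, node_weight={nodes[0]: weight[0]},
            )
        ]

    candidates = []
    for start in graph.local_maxima(node_score):
        members, score = _greedy_grow_idx(graph, node_score, int(start), max_size)
        candidates.append((members, score))
    candidates.sort(key=lambda t: (-t[1], t[0]))

    kept: list[tuple[list[int], float]] = []
    for members, score in candidates:
        mset = set(members)
        dup = False
        for km, _ in kept:
            ks = set(km)
            jac = len(mset & ks) / len(mset | ks)
            if jac > jaccard_max:
                dup = True
                break
        if not dup:
            kept.append((members, score))
        if len(kept) >= top_n:
            break

    rng = np.random.default_rng(seed)
    perm_shuffles = [rng.permutation(len(nodes)) for _ in range(n_perm)]
    sizes = sorted({len(m) for m, _ in kept})
    # best permuted score per (permutation, size cap); caps share growth work
    best_by_size: dict[int, np.ndarray] = {s: np.empty(n_perm) for s in sizes}
    for p_i, perm in enumerate(perm_shuffles):
        perm_score = weight * abs_fc[perm]
        for s in sizes:
            best_by_size[s][p_i] = _best_grown_score(graph, perm_score, s)
    results = []
    for members, score in kept:
        count = int((best_by_size[len(members)] >= score).sum())
        perm_p = (1.0 + count) / (1.0 + n_perm)
        member_names = [nodes[i] for i in members]
        results.append(
            SubnetworkResult(
                nodes=member_names,
                score=float(score),
                perm_p=float(perm_p),
                adj_p=np.nan,
                node_lfc={g: float(lfc.get(g, 0.0)) for g in member_names},
                node_weight={
                    nodes[i]: float(weight[i]) for i in members
                },
            )
        )
    if results:
        adj = bh_adjust(np.array([r.perm_p for r in results]))
        for r, a in zip(results, adj):
            r.adj_p = float(a)
    return results


def subnetworks_table(results: list[SubnetworkResult]) -> pd.DataFrame:
    rows = [
        {
            "rank": i + 1,
            "size": len(r.nodes),
            "score": r.score,
            "perm_p": r.perm_p,
            "adj_p": r.adj_p,
            "nodes": ",".join(r.nodes),
        }
        for i, r in enumerate(results)
    ]
    return pd.DataFrame(rows)
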
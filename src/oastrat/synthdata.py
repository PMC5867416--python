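"""Synthetic cohorts with the statistical structure the analysis assumes.

Counts are drawn gene-wise from a negative binomial with Var = mu + alpha*mu^2
(gamma-Poisson mixture), with planted shared and subgroup-specific log2 fold
changes, additive batch shifts on the log2 mean for a random subset of genes,
and log-uniform library-size factors.  A companion network generator plants
the differentially expressed gene sets as dense modules over a sparse random
background, and a fixture-bundle writer emits every file format the pipeline
reads, together with the ground truth needed by recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io
from .preprocess import CountMatrix

__all__ = [
    "SimulationDesign",
    "GroundTruth",
    "simulate_counts",
    "simulate_network",
    "simulate_mixture_cohort",
    "write_fixture_bundle",
]

BATCH_AFFECTED_FRACTION = 0.20  # fraction of genes carrying a batch shift
DEPTH_FACTOR_RANGE = (0.5, 2.0)  # library-size factors, log-uniform


@dataclass(frozen=True)
class SimulationDesign:
    """Parameters of a simulated two-subgroup OA cohort plus controls.

    Defaults mirror the cohort shape the analysis targets: 10 non-OA
    controls and 44 OA patients split 24/18 into subgroups A and B, with
    planted shared and subgroup-specific differential expression of one
    log2 unit on a negative-binomial background (dispersion 0.1).
    """

    n_genes: int = 2000
    n_control: int = 10
    n_groupA: int = 24
    n_groupB: int = 18
    n_shared_de: int = 300
    n_specificA: int = 150
    n_specificB: int = 150
    lfc_magnitude: float = 1.0
    dispersion: float = 0.1
    baseline_mean_log_range: tuple[float, float] = (1.0, 3.0)
    n_batches: int = 2
    batch_lfc_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_control", "n_groupA", "n_groupB"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_shared_de", "n_specificA", "n_specificB"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_shared_de + self.n_specificA + self.n_specificB > self.n_genes:
            raise ValueError("more planted DE genes than genes in the design")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        if self.batch_lfc_sd < 0:
            raise ValueError("batch_lfc_sd must be non-negative")
        lo, hi = self.baseline_mean_log_range
        if hi < lo:
            raise ValueError("baseline_mean_log_range must be (low, high)")


@dataclass
class GroundTruth:
    """Every planted quantity of a simulation, for recovery oracles."""

    sample_labels: dict[str, str]  # sample -> control | A | B
    de_genes_shared: dict[str, float]  # gene -> signed planted log2 fc
    de_genes_A: dict[str, float]
    de_genes_B: dict[str, float]
    batch_assignment: dict[str, str]
    secreted_genes: set[str] = field(default_factory=set)
    gene_ids: list[str] = field(default_factory=list)
    size_factors: dict[str, float] = field(default_factory=dict)
    baseline_mean: np.ndarray | None = None  # per-gene NB mean, gene_ids order

    def planted_lfc(self, contrast: str) -> dict[str, float]:
        """Planted log2 fold changes for contrast 'A', 'B' (vs control) or 'AB'."""
        if contrast == "A":
            return {**self.de_genes_shared, **self.de_genes_A}
        if contrast == "B":
            return {**self.de_genes_shared, **self.de_genes_B}
        if contrast == "AB":  # B over A
            out = {g: -v for g, v in self.de_genes_A.items()}
            for g, v in self.de_genes_B.items():
                out[g] = out.get(g, 0.0) + v
            return out
        raise ValueError(f"unknown contrast {contrast!r}")

    def oa_labels(self) -> dict[str, str]:
        return {s: g for s, g in self.sample_labels.items() if g != "control"}


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + alpha*mu^2."""
    shape = 1.0 / alpha
    lam = rng.gamma(shape, alpha * mu)
    return rng.poisson(lam)


def simulate_counts(design: SimulationDesign) -> tuple[CountMatrix, GroundTruth]:
    """Simulate a count matrix and the ground truth of its planted structure."""
    rng = np.random.default_rng(design.seed)
    width = max(4, len(str(design.n_genes)))
    genes = [f"G{i:0{width}d}" for i in range(design.n_genes)]
    samples = (
        [f"CTRL{i:02d}" for i in range(design.n_control)]
        + [f"A{i:02d}" for i in range(design.n_groupA)]
        + [f"B{i:02d}" for i in range(design.n_groupB)]
    )
    labels = (
        ["control"] * design.n_control
        + ["A"] * design.n_groupA
        + ["B"] * design.n_groupB
    )

    n_planted = design.n_shared_de + design.n_specificA + design.n_specificB
    planted_idx = rng.choice(design.n_genes, size=n_planted, replace=False)
    shared_idx = planted_idx[: design.n_shared_de]
    spec_a_idx = planted_idx[design.n_shared_de : design.n_shared_de + design.n_specificA]
    spec_b_idx = planted_idx[design.n_shared_de + design.n_specificA :]

    def _signed(idx: np.ndarray) -> dict[str, float]:
        # alternate up/down so both directions are represented
        return {
            genes[g]: design.lfc_magnitude * (1.0 if i % 2 == 0 else -1.0)
            for i, g in enumerate(idx)
        }

    shared = _signed(shared_idx)
    spec_a = _signed(spec_a_idx)
    spec_b = _signed(spec_b_idx)

    lo, hi = design.baseline_mean_log_range
    baseline = 10.0 ** rng.uniform(lo, hi, size=design.n_genes)

    # batch structure: round-robin over the sample order keeps batches
    # condition-balanced; a random 20% of genes carry N(0, sd) log2 shifts
    batch_of = {s: f"batch{i % design.n_batches}" for i, s in enumerate(samples)}
    batch_shift = np.zeros((design.n_genes, design.n_batches))
    if design.n_batches > 1 and design.batch_lfc_sd > 0:
        affected = rng.choice(
            design.n_genes,
            size=int(round(BATCH_AFFECTED_FRACTION * design.n_genes)),
            replace=False,
        )
        batch_shift[affected] = rng.normal(
            0.0, design.batch_lfc_sd, size=(len(affected), design.n_batches)
        )

    depth = np.exp(
        rng.uniform(
            math.log(DEPTH_FACTOR_RANGE[0]),
            math.log(DEPTH_FACTOR_RANGE[1]),
            size=len(samples),
        )
    )

    lfc_matrix = np.zeros((design.n_genes, len(samples)))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for j, lab in enumerate(labels):
        if lab == "A":
            for g, v in shared.items():
                lfc_matrix[gene_pos[g], j] += v
            for g, v in spec_a.items():
                lfc_matrix[gene_pos[g], j] += v
        elif lab == "B":
            for g, v in shared.items():
                lfc_matrix[gene_pos[g], j] += v
            for g, v in spec_b.items():
                lfc_matrix[gene_pos[g], j] += v

    batch_idx = np.array([int(batch_of[s][5:]) for s in samples])
    mu = (
        baseline[:, None]
        * 2.0**lfc_matrix
        * 2.0 ** batch_shift[:, batch_idx]
        * depth[None, :]
    )
    counts = _nb_draw(rng, mu, design.dispersion)

    # secreted annotation: a random half of the group-difference genes + decoys
    group_diff = sorted(set(spec_a) | set(spec_b))
    n_half = len(group_diff) // 2
    secreted = set(
        rng.choice(group_diff, size=n_half, replace=False) if n_half else []
    )
    null_genes = [g for g in genes if g not in shared and g not in spec_a and g not in spec_b]
    n_decoys = min(len(null_genes), max(n_half // 2, 5))
    secreted |= set(rng.choice(null_genes, size=n_decoys, replace=False))

    counts_df = pd.DataFrame(counts, index=genes, columns=samples, dtype="int64")
    metadata = pd.DataFrame(
        {
            "condition": ["nonOA" if l == "control" else "OA" for l in labels],
            "group": [l if l in ("A", "B") else "NA" for l in labels],
            "batch": [batch_of[s] for s in samples],
        },
        index=pd.Index(samples, name="sample"),
    )
    truth = GroundTruth(
        sample_labels=dict(zip(samples, labels)),
        de_genes_shared=shared,
        de_genes_A=spec_a,
        de_genes_B=spec_b,
        batch_assignment=batch_of,
        secreted_genes=secreted,
        gene_ids=genes,
        size_factors=dict(zip(samples, depth)),
        baseline_mean=baseline,
    )
    return CountMatrix(counts_df, metadata), truth


def simulate_mixture_cohort(
    design: SimulationDesign,
    n_mixture: int = 2,
    n_outpost: int = 3,
    mixture_co_a: float = 0.60,
    outpost_co_a: float = 0.35,
    calibration_runs: int = 500,
    calibration_iters: int = 4,
    calibration_tol: float = 0.025,
) -> tuple[CountMatrix, GroundTruth, list[str]]:
    """Cohort with planted intermediate ("mixture-profile") patients.

    The intermediates are noise-free expected-count profiles interpolating
    the *realised* (empirical) A and B group centroids of the simulated
    cohort (log scale).  Because they carry no sampling noise of their own,
    their per-run cluster assignment is driven entirely by the run-to-run
    wobble of the consensus boundary (random inits and sample subsampling),
    so they genuinely concord with neither group.  ``n_outpost`` group-B
    patients are likewise replaced by noise-free profiles slightly on the B
    side of the boundary; their flips are correlated with the intermediates'
    (both track the same boundary wobble), which lets the intermediates
    chain into the B consensus cluster while their co-occurrence stays
    closer to A — the negative-silhouette, "no concordance" configuration.

    Where exactly a given mixing fraction theta lands relative to the
    realised boundary varies with the noise realisation, so the generator
    self-calibrates: a short probe-ladder consensus pre-run measures the
    co-occurrence-with-A curve over theta and the intermediates/outposts
    are placed at the thetas whose predicted co-occurrence with group A is
    ``mixture_co_a`` (just A-ward of even odds) and ``outpost_co_a`` (B-ward
    of the boundary).

    Returns (cohort, truth, mixture_sample_ids).  Mixture samples are
    recorded as ``"mixture"`` in the ground truth and carry group "NA" in
    the metadata; the cohort shape (n_control/n_groupA/n_groupB) of the
    design is preserved.
    """
    from . import preprocess as pp  # local import avoids cycle at load
    from . import stratify as st

    # boundary placement is calibrated per sample; batch shifts would move
    # each planted profile differently after correction, so this fixture is
    # generated batch-free
    design = replace(design, n_batches=1, batch_lfc_sd=0.0)
    base, truth = simulate_counts(design)

    # empirical group centroids on the normalised log scale; interpolating
    # them (rather than the theoretical signatures) keeps the intermediates
    # near the realised cluster boundary for any seed
    sf = pp.size_factors(base.counts)
    q = base.counts / sf
    a_cols = [s for s, l in truth.sample_labels.items() if l == "A"]
    b_cols = [s for s, l in truth.sample_labels.items() if l == "B"]
    log_a = np.log2(q[a_cols] + 1).mean(axis=1).to_numpy()
    log_b = np.log2(q[b_cols] + 1).mean(axis=1).to_numpy()

    def _profile(theta: float) -> np.ndarray:
        mu = np.maximum(2.0 ** (theta * log_a + (1 - theta) * log_b) - 1.0, 0.0)
        return np.round(mu).astype("int64")

    def _consensus_co_a(counts: pd.DataFrame, meta: pd.DataFrame, probe_ids, seed):
        cohort = CountMatrix(counts, meta)
        filtered = pp.filter_low_counts(cohort.counts)
        expr = pp.normalize_log(filtered, pp.size_factors(filtered))
        expr = pp.batch_correct(expr, cohort.metadata["batch"])
        oa = cohort.metadata.index[cohort.metadata["condition"] == "OA"]
        X = st.clustering_features(expr, oa)
        C = st.consensus_cluster(
            X, 2, n_runs=calibration_runs, lam=0.0, seed=seed
        )
        core_a = [s for s in a_cols]
        return {p: float(C.loc[p, core_a].mean()) for p in probe_ids}

    def _interp_theta(thetas, curve, target: float) -> float:
        mono = np.maximum.accumulate(curve)  # enforce monotone in theta
        return float(np.interp(target, mono, thetas))

    def _slope(thetas, curve, theta_at: float) -> float:
        mono = np.maximum.accumulate(curve)
        grad = np.gradient(mono, thetas)
        return max(float(np.interp(theta_at, thetas, grad)), 1.0)

    # stage 1: symmetric probe ladder locates the boundary
    probe_thetas = [0.45, 0.50, 0.55, 0.60, 0.65]
    probe_counts = base.counts.copy()
    probe_meta = base.metadata.copy()
    probe_ids = []
    for i, th in enumerate(probe_thetas):
        pid = f"PROBE{i:02d}"
        probe_ids.append(pid)
        probe_counts[pid] = _profile(th)
        probe_meta.loc[pid] = {"condition": "OA", "group": "NA", "batch": "batch0"}
    curve = [
        _consensus_co_a(probe_counts, probe_meta, probe_ids, design.seed + 7)[p]
        for p in probe_ids
    ]
    theta_o = _interp_theta(probe_thetas, curve, outpost_co_a)
    theta_m = _interp_theta(probe_thetas, curve, mixture_co_a)

    b_samples = [s for s, l in truth.sample_labels.items() if l == "B"]
    outpost_ids = list(b_samples[-n_outpost:]) if n_outpost else []
    mixture_ids = [f"M{i:02d}" for i in range(n_mixture)]

    def _build(theta_o: float, theta_m: float):
        counts = base.counts.copy()
        meta = base.metadata.copy()
        for j, sid in enumerate(outpost_ids):
            counts[sid] = _profile(theta_o + 0.008 * (j - (n_outpost - 1) / 2))
        for i, sid in enumerate(mixture_ids):
            # slight theta spread keeps the intermediates distinct samples
            counts[sid] = _profile(theta_m + 0.004 * (i - (n_mixture - 1) / 2))
            meta.loc[sid] = {
                "condition": "OA", "group": "NA", "batch": "batch0",
            }
        return counts, meta

    # stage 2: the installed boundary samples shift the boundary themselves;
    # measure their realised co-occurrence on the assembled cohort and apply
    # slope-based corrections to both placements until they sit on target
    counts, meta = _build(theta_o, theta_m)
    for it in range(calibration_iters):
        realised = _consensus_co_a(counts, meta, outpost_ids + mixture_ids,
                                   design.seed + 13 + it)
        delta_o = (
            np.mean([realised[s] for s in outpost_ids]) - outpost_co_a
            if outpost_ids
            else 0.0
        )
        delta_m = np.mean([realised[s] for s in mixture_ids]) - mixture_co_a
        if abs(delta_o) <= calibration_tol and abs(delta_m) <= calibration_tol:
            break
        theta_o -= delta_o / _slope(probe_thetas, curve, theta_o)
        theta_m -= delta_m / _slope(probe_thetas, curve, theta_m)
        counts, meta = _build(theta_o, theta_m)

    truth.sample_labels.update({sid: "mixture" for sid in mixture_ids})
    truth.batch_assignment.update({sid: "batch0" for sid in mixture_ids})
    return CountMatrix(counts, meta), truth, mixture_ids


def simulate_validation_cohort(
    truth: GroundTruth,
    design: SimulationDesign,
    n_a: int = 8,
    n_b: int = 8,
    seed: int = 1,
) -> tuple[pd.DataFrame, pd.Series]:
    """Fresh patients drawn from the same planted structure as ``truth``.

    Returns (counts, labels) for ``n_a`` new group-A and ``n_b`` new group-B
    patients sharing the training cohort's baseline means and planted fold
    changes, with independent NB noise and depth factors — a held-out
    cohort for classifier validation.
    """
    rng = np.random.default_rng(seed)
    genes = truth.gene_ids
    gene_pos = {g: i for i, g in enumerate(genes)}
    effects = {"A": np.zeros(len(genes)), "B": np.zeros(len(genes))}
    for g, v in truth.de_genes_shared.items():
        effects["A"][gene_pos[g]] += v
        effects["B"][gene_pos[g]] += v
    for g, v in truth.de_genes_A.items():
        effects["A"][gene_pos[g]] += v
    for g, v in truth.de_genes_B.items():
        effects["B"][gene_pos[g]] += v
    samples = [f"VA{i:02d}" for i in range(n_a)] + [f"VB{i:02d}" for i in range(n_b)]
    labels = pd.Series(["A"] * n_a + ["B"] * n_b, index=samples)
    depth = np.exp(
        rng.uniform(
            math.log(DEPTH_FACTOR_RANGE[0]),
            math.log(DEPTH_FACTOR_RANGE[1]),
            size=len(samples),
        )
    )
    cols = {}
    for j, sid in enumerate(samples):
        mu = truth.baseline_mean * 2.0 ** effects[labels[sid]] * depth[j]
        cols[sid] = _nb_draw(rng, mu, design.dispersion)
    counts = pd.DataFrame(cols, index=genes)
    return counts, labels


def simulate_network(
    truth: GroundTruth,
    n_nodes: int,
    module_density: float = 0.5,
    background_degree: int = 2,
    seed: int = 0,
) -> nx.Graph:
    """Gene network whose planted DE sets form dense modules.

    Each planted set (shared, A-specific, B-specific) gets internal edges
    with probability ``module_density``; a sparse Erdos-Renyi background with
    expected degree ``background_degree`` covers all nodes; the graph is then
    augmented with a minimal spanning structure so it is connected.
    """
    if not 0 < module_density <= 1:
        raise ValueError("module_density must be in (0, 1]")
    planted = (
        sorted(truth.de_genes_shared)
        + sorted(truth.de_genes_A)
        + sorted(truth.de_genes_B)
    )
    planted = list(dict.fromkeys(planted))
    if n_nodes < len(planted):
        raise ValueError(
            f"n_nodes={n_nodes} smaller than number of planted genes {len(planted)}"
        )
    rng = np.random.default_rng(seed)
    others = [g for g in truth.gene_ids if g not in set(planted)]
    nodes = planted + others[: n_nodes - len(planted)]
    graph = nx.Graph()
    graph.add_nodes_from(nodes)

    for module in (truth.de_genes_shared, truth.de_genes_A, truth.de_genes_B):
        members = sorted(set(module) & set(nodes))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if module_density >= 1.0 or rng.random() < module_density:
                    graph.add_edge(members[i], members[j], weight=1.0)

    if background_degree > 0 and len(nodes) > 1:
        p = min(background_degree / (len(nodes) - 1), 1.0)
        # vectorised Bernoulli over the upper triangle
        n = len(nodes)
        for i in range(n):
            hits = np.nonzero(rng.random(n - i - 1) < p)[0]
            for h in hits:
                graph.add_edge(nodes[i], nodes[i + 1 + h], weight=1.0)

    components = sorted(nx.connected_components(graph), key=lambda c: (-len(c), sorted(c)[0]))
    anchor = sorted(components[0])[0]
    for comp in components[1:]:
        graph.add_edge(anchor, sorted(comp)[0], weight=1.0)
    return graph


def write_fixture_bundle(dir_path: str | Path, design: SimulationDesign) -> dict:
    """Simulate a full input bundle and write it under ``dir_path``.

    Emits counts, metadata, network edge list, GMT (planted sets plus random
    decoy sets), secreted-gene list and the ground truth as JSON; returns a
    manifest of files with row/column counts.
    """
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    cohort, truth = simulate_counts(design)
    network = simulate_network(
        truth, n_nodes=design.n_genes, module_density=0.5, background_degree=2,
        seed=design.seed + 1,
    )
    rng = np.random.default_rng(design.seed + 2)
    sets = {
        "planted_shared": sorted(truth.de_genes_shared),
        "planted_A": sorted(truth.de_genes_A),
        "planted_B": sorted(truth.de_genes_B),
    }
    for i in range(5):
        size = min(int(rng.integers(20, 80)), len(truth.gene_ids))
        sets[f"random_set_{i}"] = sorted(
            rng.choice(truth.gene_ids, size=size, replace=False)
        )

    files = {
        "counts": out / "counts.tsv",
        "metadata": out / "metadata.tsv",
        "network": out / "network.tsv",
        "gmt": out / "genesets.gmt",
        "secreted": out / "secreted.txt",
        "truth": out / "truth.json",
    }
    try:
        io.write_counts(cohort.counts, files["counts"])
        io.write_metadata(cohort.metadata, files["metadata"])
        io.write_network(network, files["network"])
        io.write_gmt(sets, files["gmt"])
        io.write_gene_list(sorted(truth.secreted_genes), files["secreted"])
        io.write_json(
            {
                "sample_labels": truth.sample_labels,
                "de_genes_shared": truth.de_genes_shared,
                "de_genes_A": truth.de_genes_A,
                "de_genes_B": truth.de_genes_B,
                "batch_assignment": truth.batch_assignment,
                "secreted_genes": sorted(truth.secreted_genes),
                "gene_ids": truth.gene_ids,
                "size_factors": truth.size_factors,
                "design": asdict(design),
            },
            files["truth"],
        )
    except OSError as exc:
        raise OSError(f"failed writing fixture bundle under {out}: {exc}") from exc

    manifest = {
        "dir": str(out),
        "design": asdict(design),
        "files": {
            name: {
                "path": str(path),
                "rows": _count_rows(path),
            }
            for name, path in files.items()
        },
        "n_genes": design.n_genes,
        "n_samples": design.n_control + design.n_groupA + design.n_groupB,
        "n_network_nodes": network.number_of_nodes(),
        "n_network_edges": network.number_of_edges(),
        "n_gene_sets": len(sets),
    }
    io.write_json(manifest, out / "manifest.json")
    return manifest


def read_truth(path: str | Path) -> GroundTruth:
    """Re-load a GroundTruth written by :func:`write_fixture_bundle`."""
    raw = io.read_json(path)
    return GroundTruth(
        sample_labels=raw["sample_labels"],
        de_genes_shared=raw["de_genes_shared"],
        de_genes_A=raw["de_genes_A"],
        de_genes_B=raw["de_genes_B"],
        batch_assignment=raw["batch_assignment"],
        secreted_genes=set(raw["secreted_genes"]),
        gene_ids=raw["gene_ids"],
        size_factors=raw.get("size_factors", {}),
    )


def _count_rows(path: Path) -> int:
    with open(path) as fh:
        return sum(1 for _ in fh)
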
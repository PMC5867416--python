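"""End-to-end orchestration: DE -> stratification -> classifier -> pathways
-> biomarkers, from one validated configuration.

Stages mirror the analysis order of the study design the package emulates:
differential expression of all OA vs control, network-NMF consensus
stratification of the OA patients only, per-subgroup differential
expression, a shrunken-centroid panel with an SVM validation, pathway
over-representation, subnetwork scoring, and secreted-biomarker
nomination.  All randomness flows from one root seed through named
per-stage substreams, so re-running a config reproduces every artefact
byte for byte.
"""

from __future__ import annotations

import hashlib
import logging
import zlib
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biomarkers as bm
from . import classify as cl
from . import io
from . import pathways as pw
from . import preprocess as pp
from . import stratify as st

__all__ = ["PipelineConfig", "ConfigError", "PipelineStageError", "validate_config", "run_pipeline"]

logger = logging.getLogger("oastrat")


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    # input/output paths
    counts: str = ""
    metadata: str = ""
    network: str = ""
    gmt: str = ""
    secreted: str = ""
    out_dir: str = "results/run"
    seed_genes: str = ""
    # preprocessing
    pseudocount: float = 1.0
    min_total_counts: int = 10
    # differential expression
    fc_min: float = 1.5
    fdr_max: float = 0.10
    # stratification
    n_features: int = 2000
    k_min: int = 2
    k_max: int = 5
    n_runs: int = 500
    nmf_lambda: float = 1.0
    subsample_fraction: float = 0.8
    min_silhouette: float = 0.0
    nmf_max_iter: int = 100
    nmf_tol: float = 1e-4
    # classifier
    panel_size: int = 10
    folds: int = 5
    svm_C: float = 1.0
    # pathways
    restart_prob: float = 0.3
    max_subnet_size: int = 30
    n_perm: int = 1000
    # stage toggles
    run_stratify: bool = True
    run_classifier: bool = True
    run_pathways: bool = True
    run_biomarkers: bool = True
    # reproducibility
    seed: int = 0


_REQUIRED_PATHS = ("counts", "metadata")


class _StrictLoader(yaml.SafeLoader):
    """YAML loader that rejects duplicate mapping keys."""


def _strict_map(loader, node, deep=False):
    mapping = {}
    for key_node, value_node in node.value:
        key = loader.construct_object(key_node, deep=deep)
        if key in mapping:
            raise ConfigError([f"duplicate key: {key!r}"])
        mapping[key] = loader.construct_object(value_node, deep=deep)
    return mapping


_StrictLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _strict_map
)


def validate_config(source: str | Path | dict) -> PipelineConfig:
    """Load, default-fill and validate a pipeline configuration.

    ``source`` is a YAML file path or a dict.  Unknown keys, out-of-range
    values and missing input files are collected and reported together.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.load(fh, Loader=_StrictLoader) or {}
    else:
        raw = dict(source)
    errors: list[str] = []
    known = set(PipelineConfig.__dataclass_fields__)
    for key in raw:
        if key not in known:
            errors.append(f"unknown key: {key!r}")
    if errors:
        raise ConfigError(errors)
    cfg = PipelineConfig(**raw)

    def check(cond: bool, msg: str) -> None:
        if not cond:
            errors.append(msg)

    check(0 < cfg.fdr_max <= 1, f"fdr_max={cfg.fdr_max} outside (0, 1]")
    check(cfg.fc_min >= 1, f"fc_min={cfg.fc_min} must be >= 1")
    check(cfg.pseudocount > 0, "pseudocount must be positive")
    check(0 < cfg.subsample_fraction <= 1, "subsample_fraction outside (0, 1]")
    check(2 <= cfg.k_min <= cfg.k_max, "need 2 <= k_min <= k_max")
    check(cfg.n_runs >= 2, "n_runs must be >= 2")
    check(-1 <= cfg.min_silhouette <= 1, "min_silhouette outside [-1, 1]")
    check(cfg.folds >= 2, "folds must be >= 2")
    check(cfg.panel_size >= 1, "panel_size must be >= 1")
    check(cfg.nmf_lambda >= 0, "nmf_lambda must be >= 0")
    check(0 < cfg.restart_prob <= 1, "restart_prob outside (0, 1]")
    check(cfg.n_perm > 0, "n_perm must be positive")
    for name in _REQUIRED_PATHS:
        path = getattr(cfg, name)
        check(bool(path), f"{name} path is required")
        if path and not Path(path).exists():
            errors.append(f"{name} path does not exist: {path}")
    if cfg.run_stratify and cfg.nmf_lambda > 0:
        check(bool(cfg.network), "network path required when nmf_lambda > 0")
        if cfg.network and not Path(cfg.network).exists():
            errors.append(f"network path does not exist: {cfg.network}")
    if cfg.run_pathways:
        check(bool(cfg.gmt), "gmt path required when run_pathways is on")
        if cfg.gmt and not Path(cfg.gmt).exists():
            errors.append(f"gmt path does not exist: {cfg.gmt}")
    if cfg.run_biomarkers:
        check(bool(cfg.secreted), "secreted path required when run_biomarkers is on")
        if cfg.secreted and not Path(cfg.secreted).exists():
            errors.append(f"secreted path does not exist: {cfg.secreted}")
    if errors:
        raise ConfigError(errors)
    return cfg


def _stage_seed(root: int, stage: str) -> int:
    """Deterministic per-stage substream seed below 2^31."""
    mix = np.random.SeedSequence([root & 0x7FFFFFFF, zlib.crc32(stage.encode())])
    return int(mix.generate_state(1)[0] % (2**31))


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig | dict | str | Path) -> dict:
    """Run every enabled stage; returns (and writes) the run manifest."""
    cfg = config if isinstance(config, PipelineConfig) else validate_config(config)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(asctime)s [%(stage)s] %(message)s"))
    logger.addHandler(log_handler)
    logger.setLevel(logging.INFO)

    manifest: dict = {
        "config": asdict(cfg),
        "inputs": {},
        "artefacts": [],
        "stage_seeds": {},
        "stages_completed": [],
    }
    for name in ("counts", "metadata", "network", "gmt", "secreted", "seed_genes"):
        path = getattr(cfg, name)
        if path:
            manifest["inputs"][name] = {"path": path, "sha256": _sha256(path)}

    def log(stage: str, msg: str) -> None:
        logger.info(msg, extra={"stage": stage})

    def emit(path: Path) -> None:
        manifest["artefacts"].append(str(path))

    state: dict = {}

    def _preprocess(seed: int) -> None:
        counts_df = io.read_counts(cfg.counts)
        metadata = io.read_metadata(cfg.metadata)
        cohort = pp.CountMatrix(counts_df, metadata)
        filtered = pp.filter_low_counts(cohort.counts, cfg.min_total_counts)
        factors = pp.size_factors(filtered)
        expr = pp.normalize_log(filtered, factors, cfg.pseudocount)
        batches = cohort.metadata["batch"]
        if batches.nunique() > 1:
            expr = pp.batch_correct(expr, batches)
        coords, evr = pp.pca_embed(expr, n_components=min(10, *expr.values.shape))
        state.update(cohort=cohort, filtered=filtered, factors=factors, expr=expr)
        io.write_matrix(factors.to_frame(), out / "size_factors.tsv", "sample")
        emit(out / "size_factors.tsv")
        coords["explained_var"] = ""
        coords.iloc[: len(evr), -1] = [f"{v:.6g}" for v in evr]
        io.write_matrix(coords, out / "pca.tsv", "sample")
        emit(out / "pca.tsv")
        log("preprocess", f"{filtered.shape[0]} genes after low-count filter")

    def _de_global(seed: int) -> None:
        cohort = state["cohort"]
        de = pp.de_test(
            state["filtered"],
            cohort.metadata["condition"],
            reference="nonOA",
            fc_min=cfg.fc_min,
            fdr_max=cfg.fdr_max,
        )
        state["de_all"] = de
        io.write_de_table(de, out / "de_oa_vs_nonoa.tsv")
        emit(out / "de_oa_vs_nonoa.tsv")
        log("de", f"OA vs nonOA: {int(de['is_deg'].sum())} DEGs")

    def _stratify(seed: int) -> None:
        cohort = state["cohort"]
        oa = cohort.metadata.index[cohort.metadata["condition"] == "OA"]
        features = st.clustering_features(state["expr"], oa, n_top=cfg.n_features)
        network = None
        if cfg.nmf_lambda > 0 and cfg.network:
            network = st.GeneNetwork(io.read_network(cfg.network))
        consensus = st.select_k(
            features,
            k_range=range(cfg.k_min, cfg.k_max + 1),
            n_runs=cfg.n_runs,
            lam=cfg.nmf_lambda,
            network=network,
            subsample_fraction=cfg.subsample_fraction,
            seed=seed,
            max_iter=cfg.nmf_max_iter,
            tol=cfg.nmf_tol,
        )
        assignment = st.assign_with_exclusion(consensus, cfg.min_silhouette)
        # name clusters by size: the largest assigned cluster is group A
        assigned = assignment[~assignment["excluded"]]
        order = assigned["cluster"].value_counts().index
        name_map = {c: chr(ord("A") + i) for i, c in enumerate(order)}
        assignment["group"] = assignment["cluster"].map(
            lambda c: name_map.get(c, "unassigned")
        )
        state["consensus"] = consensus
        state["assignment"] = assignment
        io.write_matrix(consensus.coclustering, out / "coclustering.tsv", "sample")
        emit(out / "coclustering.tsv")
        per_k = pd.DataFrame(
            sorted(consensus.per_k_mean_silhouette.items()),
            columns=["k", "mean_silhouette"],
        )
        per_k.to_csv(out / "per_k_silhouette.tsv", sep="\t", index=False,
                     float_format="%.10g")
        emit(out / "per_k_silhouette.tsv")
        io.write_matrix(
            assignment[["group", "cluster", "silhouette", "excluded"]],
            out / "labels.tsv",
            "sample",
        )
        emit(out / "labels.tsv")
        summary = assignment.attrs.get("summary", {})
        log(
            "stratify",
            f"chosen k={consensus.chosen_k}, "
            f"sizes={assignment['group'].value_counts().to_dict()}, "
            f"unassigned={summary.get('n_unassigned')}",
        )

    def _de_groups(seed: int) -> None:
        cohort = state["cohort"]
        assignment = state["assignment"]
        group = assignment["group"]
        meta = cohort.metadata
        tables = {}
        for g in ("A", "B"):
            members = group.index[group == g]
            controls = meta.index[meta["condition"] == "nonOA"]
            cols = list(controls) + list(members)
            condition = pd.Series(
                ["nonOA"] * len(controls) + [g] * len(members), index=cols
            )
            tables[g] = pp.de_test(
                state["filtered"][cols], condition, reference="nonOA",
                fc_min=cfg.fc_min, fdr_max=cfg.fdr_max,
            )
            io.write_de_table(tables[g], out / f"de_{g}_vs_nonoa.tsv")
            emit(out / f"de_{g}_vs_nonoa.tsv")
        a = group.index[group == "A"]
        b = group.index[group == "B"]
        cols = list(a) + list(b)
        condition = pd.Series(["A"] * len(a) + ["B"] * len(b), index=cols)
        de_ab = pp.de_test(
            state["filtered"][cols], condition, reference="A",
            fc_min=cfg.fc_min, fdr_max=cfg.fdr_max,
        )
        io.write_de_table(de_ab, out / "de_B_vs_A.tsv")
        emit(out / "de_B_vs_A.tsv")
        state["de_A"] = tables["A"]
        state["de_B"] = tables["B"]
        state["de_AB"] = de_ab
        shared_idx = state["de_all"].index
        overlap = pp.compare_deg_sets(
            state["de_all"],
            tables["A"].reindex(shared_idx).fillna({"is_deg": False}),
            tables["B"].reindex(shared_idx).fillna({"is_deg": False}),
        )
        io.write_json(overlap, out / "deg_overlap.json")
        emit(out / "deg_overlap.json")
        log(
            "de_groups",
            f"A: {int(tables['A']['is_deg'].sum())}, "
            f"B: {int(tables['B']['is_deg'].sum())}, "
            f"B vs A: {int(de_ab['is_deg'].sum())} DEGs; "
            f"distinctive A/B: {overlap['n_distinctive_A']}/{overlap['n_distinctive_B']}",
        )

    def _classify(seed: int) -> None:
        assignment = state["assignment"]
        assigned = assignment[~assignment["excluded"]]
        labels = assigned["group"]
        expr = state["expr"].values[list(assigned.index)]
        stats = cl.nsc_statistics(expr, labels)
        panel = cl.panel_of_size(stats, cfg.panel_size)
        model = cl.train_panel_classifier(
            expr, labels, panel, folds=cfg.folds, C=cfg.svm_C, seed=seed
        )
        state["panel"] = panel
        state["model"] = model
        table = panel.d_shrunk.copy()
        table.columns = [f"d_shrunk_{c}" for c in table.columns]
        table["rank"] = range(1, len(table) + 1)
        io.write_matrix(table, out / "panel.tsv", "gene")
        emit(out / "panel.tsv")
        cl.save_model(model, out / "model.json")
        emit(out / "model.json")
        log(
            "classify",
            f"panel of {len(panel.genes)} genes (delta={panel.delta:.3g}), "
            f"cv_auc={model.cv_auc:.3f}",
        )

    def _pathways(seed: int) -> None:
        sets, desc = io.read_gmt(cfg.gmt)
        universe = set(state["de_all"].index)
        collection = pw.GeneSetCollection(sets, universe, desc)
        for key, de in (("A", state.get("de_A")), ("B", state.get("de_B")),
                        ("AB", state.get("de_AB"))):
            if de is None:
                continue
            degs = de.index[de["is_deg"]]
            table = pw.ora(degs, collection)
            table.to_csv(out / f"ora_{key}.tsv", sep="\t", index=False,
                         float_format="%.10g")
            emit(out / f"ora_{key}.tsv")
        if cfg.network and state.get("de_AB") is not None:
            graph = io.read_network(cfg.network)
            weights = None
            if cfg.seed_genes:
                seeds = io.read_gene_list(cfg.seed_genes)
                weights = pw.rwr_weights(graph, seeds, cfg.restart_prob)
            results = pw.find_subnetworks(
                graph,
                state["de_AB"],
                node_weights=weights,
                max_size=cfg.max_subnet_size,
                n_perm=cfg.n_perm,
                seed=seed,
            )
            pw.subnetworks_table(results).to_csv(
                out / "subnetworks.tsv", sep="\t", index=False, float_format="%.10g"
            )
            emit(out / "subnetworks.tsv")
            state["subnetworks"] = results
        log("pathways", "over-representation and subnetwork tables written")

    def _biomarkers(seed: int) -> None:
        secreted = io.read_gene_list(cfg.secreted)
        table = bm.secreted_biomarkers(state["de_AB"], secreted)
        bm.write_biomarker_report(table, out / "biomarkers.tsv")
        emit(out / "biomarkers.tsv")
        state["biomarkers"] = table
        log("biomarkers", f"{len(table)} secreted biomarker candidate(s)")

    stages = [("preprocess", _preprocess), ("de", _de_global)]
    if cfg.run_stratify:
        stages += [("stratify", _stratify), ("de_groups", _de_groups)]
        if cfg.run_classifier:
            stages.append(("classify", _classify))
        if cfg.run_pathways:
            stages.append(("pathways", _pathways))
        if cfg.run_biomarkers:
            stages.append(("biomarkers", _biomarkers))

    try:
        for name, fn in stages:
            seed = _stage_seed(cfg.seed, name)
            manifest["stage_seeds"][name] = seed
            try:
                fn(seed)
            except Exception as exc:  # persist what completed, name the stage
                io.write_json(manifest, out / "manifest.json")
                raise PipelineStageError(name, exc) from exc
            manifest["stages_completed"].append(name)
        io.write_json(manifest, out / "manifest.json")
        manifest["state"] = state
        return manifest
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()
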
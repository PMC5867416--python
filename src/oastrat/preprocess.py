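"""Normalisation, batch correction, PCA and differential expression.

The differential-expression stage is a deliberately simplified negative-
binomial Wald test in the DESeq2 family: median-of-ratios size factors,
per-gene method-of-moments dispersion with a fitted mean-dispersion trend,
and a normal-reference Wald statistic on the log2 fold change.  Genes are
called differentially expressed when |fold change| >= 1.5 and the
Benjamini-Hochberg adjusted p value is <= 0.10.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "size_factors",
    "normalize_log",
    "filter_low_counts",
    "batch_correct",
    "pca_embed",
    "de_test",
    "bh_adjust",
    "compare_deg_sets",
    "FC_MIN",
    "FDR_MAX",
]

FC_MIN = 1.5
FDR_MAX = 0.10


@dataclass
class CountMatrix:
    """Raw gene x sample integer counts plus per-sample metadata.

    ``counts`` has gene ids on the index and sample ids on the columns;
    ``metadata`` is indexed by sample id and carries at least ``condition``
    (OA / nonOA), ``group`` (A / B / NA) and ``batch`` columns.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        missing = set(self.counts.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"metadata missing samples: {sorted(missing)[:5]}")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("negative counts")
        self.metadata = self.metadata.loc[self.counts.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns


@dataclass
class ExpressionMatrix:
    """Log2-scale normalised gene x sample values with a provenance trail."""

    values: pd.DataFrame
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("non-finite expression values")


def size_factors(counts: pd.DataFrame | CountMatrix) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    For each gene with a strictly positive geometric mean across samples the
    ratio count/geomean is formed; a sample's factor is the median of those
    ratios.  Samples with all-zero counts are an error.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    vals = df.to_numpy(dtype=float)
    zero_samples = df.columns[(vals.sum(axis=0) == 0)]
    if len(zero_samples):
        raise ValueError(f"all-zero sample(s): {list(zero_samples)}")
    positive = (vals > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in every sample")
    log_geomean = np.log(vals[positive]).mean(axis=1)
    ratios = np.log(vals[positive]) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=df.columns, name="size_factor")


def normalize_log(
    counts: pd.DataFrame | CountMatrix,
    factors: pd.Series | None = None,
    pseudocount: float = 1.0,
) -> ExpressionMatrix:
    """log2(count / size_factor + pseudocount) per gene and sample."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    if factors is None:
        factors = size_factors(df)
    scaled = df.to_numpy(dtype=float) / factors.loc[df.columns].to_numpy()
    values = pd.DataFrame(
        np.log2(scaled + pseudocount), index=df.index, columns=df.columns
    )
    return ExpressionMatrix(
        values, provenance=[{"step": "normalize_log", "pseudocount": pseudocount}]
    )


def filter_low_counts(df: pd.DataFrame, min_total: int = 10) -> pd.DataFrame:
    """Drop genes whose total count across samples is below ``min_total``."""
    keep = df.sum(axis=1) >= min_total
    out = df.loc[keep]
    out.attrs["n_filtered"] = int((~keep).sum())
    return out


def batch_correct(expr: ExpressionMatrix, batch_labels: pd.Series) -> ExpressionMatrix:
    """Location-only batch adjustment: per gene, per batch, subtract the batch
    mean and add back the grand mean.  Requires >= 2 samples per batch."""
    values = expr.values
    batches = batch_labels.loc[values.columns]
    sizes = batches.value_counts()
    singletons = sizes[sizes < 2]
    if len(singletons):
        raise ValueError(f"singleton batch(es): {list(singletons.index)}")
    mat = values.to_numpy(dtype=float)
    grand = mat.mean(axis=1, keepdims=True)
    corrected = np.empty_like(mat)
    for batch in sizes.index:
        cols = (batches == batch).to_numpy()
        batch_mean = mat[:, cols].mean(axis=1, keepdims=True)
        corrected[:, cols] = mat[:, cols] - batch_mean + grand
    out = pd.DataFrame(corrected, index=values.index, columns=values.columns)
    prov = list(expr.provenance) + [
        {"step": "batch_correct", "batches": sorted(map(str, sizes.index))}
    ]
    return ExpressionMatrix(out, provenance=prov)


def pca_embed(
    expr: ExpressionMatrix | pd.DataFrame, n_components: int = 10
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample coordinates on the principal components of the gene-centred
    matrix, plus explained-variance fractions (non-increasing)."""
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    n_components = int(n_components)
    if n_components > min(values.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    mat = values.to_numpy(dtype=float)
    centred = mat - mat.mean(axis=1, keepdims=True)
    total_var = float((centred**2).sum())
    if total_var == 0:
        raise ValueError("constant matrix: no variance to decompose")
    # samples are observations: SVD of the centred gene x sample matrix
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    coords = (s[:, None] * vt)[:n_components].T
    evr = (s**2) / (s**2).sum()
    table = pd.DataFrame(
        coords,
        index=values.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return table, evr[:n_components]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def _moment_dispersion(
    q: np.ndarray, groups: list[np.ndarray], inv_sf: np.ndarray
) -> np.ndarray:
    """Per-gene method-of-moments NB dispersion on normalised counts.

    Var(count/sf) = mu/sf + alpha*mu^2, so alpha is estimated from the pooled
    within-group variance after removing the Poisson part.
    """
    n_total = sum(g.sum() for g in groups)
    resid_ss = np.zeros(q.shape[0])
    mean_inv_sf = 0.0
    mu_bar = np.zeros(q.shape[0])
    for g in groups:
        sub = q[:, g]
        mu = sub.mean(axis=1)
        resid_ss += ((sub - mu[:, None]) ** 2).sum(axis=1)
        mu_bar += mu * g.sum()
        mean_inv_sf += inv_sf[g].sum()
    mu_bar /= n_total
    mean_inv_sf /= n_total
    dof = n_total - len(groups)
    var_hat = resid_ss / max(dof, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var_hat - mu_bar * mean_inv_sf) / np.square(mu_bar)
    alpha = np.where(np.isfinite(alpha), alpha, 0.0)
    return np.maximum(alpha, 1e-8)


def _dispersion_trend(alpha: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Fit alpha ~ a0 + a1/mu on informative genes; return trend values."""
    mask = (alpha > 1e-6) & (mu > 0)
    if mask.sum() < 10:
        return np.full_like(alpha, max(float(np.median(alpha)), 1e-8))
    x = 1.0 / mu[mask]
    y = alpha[mask]
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    a0, a1 = np.maximum(coef, 0.0)
    if a0 == 0 and a1 == 0:
        a0 = max(float(np.median(y)), 1e-8)
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.where(mu > 0, mu, np.inf)
    return np.maximum(trend, 1e-8)


def de_test(
    counts: pd.DataFrame | CountMatrix,
    condition: pd.Series,
    reference: str | None = None,
    fc_min: float = FC_MIN,
    fdr_max: float = FDR_MAX,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Two-condition NB Wald differential-expression test.

    Returns a per-gene table (baseMean, log2FC, pvalue, padj, is_deg,
    dispersion); log2FC is the non-reference condition over ``reference``.
    Genes with zero counts in every sample are excluded and reported in
    ``result.attrs["excluded_genes"]``.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    condition = condition.loc[df.columns]
    levels = sorted(condition.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two condition levels, got {levels}")
    if reference is None:
        reference = levels[0]
    if reference not in levels:
        raise ValueError(f"reference {reference!r} not among levels {levels}")
    other = levels[1] if levels[0] == reference else levels[0]
    ref_mask = (condition == reference).to_numpy()
    alt_mask = (condition == other).to_numpy()
    if ref_mask.sum() < 2 or alt_mask.sum() < 2:
        raise ValueError("each condition needs >= 2 samples")

    all_zero = df.sum(axis=1) == 0
    excluded = list(df.index[all_zero])
    work = df.loc[~all_zero]

    sf = size_factors(df).to_numpy()
    inv_sf = 1.0 / sf
    q = work.to_numpy(dtype=float) * inv_sf[None, :]

    mu_ref = q[:, ref_mask].mean(axis=1)
    mu_alt = q[:, alt_mask].mean(axis=1)
    base_mean = q.mean(axis=1)
    log2_fc = np.log2((mu_alt + prior_count) / (mu_ref + prior_count))

    alpha_mom = _moment_dispersion(q, [ref_mask, alt_mask], inv_sf)
    mu_bar = (mu_ref * ref_mask.sum() + mu_alt * alt_mask.sum()) / (
        ref_mask.sum() + alt_mask.sum()
    )
    trend = _dispersion_trend(alpha_mom, mu_bar)
    alpha = np.maximum(alpha_mom, trend)

    # delta-method SE of log2 group means; Var(q_j) = mu/sf_j + alpha*mu^2
    def _group_se(mu: np.ndarray, mask: np.ndarray) -> np.ndarray:
        n_k = mask.sum()
        var_mean = (
            mu[:, None] * inv_sf[None, mask] + alpha[:, None] * mu[:, None] ** 2
        ).sum(axis=1) / n_k**2
        return np.sqrt(var_mean) / ((mu + prior_count) * np.log(2))

    se = np.sqrt(_group_se(mu_ref, ref_mask) ** 2 + _group_se(mu_alt, alt_mask) ** 2)
    se = np.maximum(se, 1e-12)
    z = log2_fc / se
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    padj = bh_adjust(pvalue)
    is_deg = (np.abs(log2_fc) >= np.log2(fc_min)) & (padj <= fdr_max)

    result = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC": log2_fc,
            "pvalue": pvalue,
            "padj": padj,
            "is_deg": is_deg,
            "dispersion": alpha,
        },
        index=work.index,
    )
    result.attrs["excluded_genes"] = excluded
    result.attrs["contrast"] = f"{other} vs {reference}"
    result.attrs["fc_min"] = fc_min
    result.attrs["fdr_max"] = fdr_max
    return result


def compare_deg_sets(
    de_all: pd.DataFrame, de_group_a: pd.DataFrame, de_group_b: pd.DataFrame
) -> dict:
    """Partition DEG identifiers from three contrasts by membership pattern.

    Returns counts for every non-empty membership pattern plus the sets
    distinctive to the per-group contrasts (DEGs found only when the cohort
    is split into subgroups).
    """
    universes = [set(d.index) for d in (de_all, de_group_a, de_group_b)]
    if universes[0] != universes[1] or universes[0] != universes[2]:
        raise ValueError("DE tables must share one gene universe")
    degs = {
        "all": set(de_all.index[de_all["is_deg"]]),
        "A": set(de_group_a.index[de_group_a["is_deg"]]),
        "B": set(de_group_b.index[de_group_b["is_deg"]]),
    }
    union = degs["all"] | degs["A"] | degs["B"]
    patterns: dict[str, int] = {}
    for gene in union:
        key = "".join(name for name in ("all", "A", "B") if gene in degs[name])
        patterns[key] = patterns.get(key, 0) + 1
    distinct_a = degs["A"] - degs["all"] - degs["B"]
    distinct_b = degs["B"] - degs["all"] - degs["A"]
    return {
        "pattern_counts": patterns,
        "n_union": len(union),
        "n_all": len(degs["all"]),
        "n_A": len(degs["A"]),
        "n_B": len(degs["B"]),
        "distinctive_A": sorted(distinct_a),
        "distinctive_B": sorted(distinct_b),
        "n_distinctive_A": len(distinct_a),
        "n_distinctive_B": len(distinct_b),
        "n_extra_from_split": len((degs["A"] | degs["B"]) - degs["all"]),
    }
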
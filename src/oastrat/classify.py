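"""Nearest-shrunken-centroid gene panels and a cross-validated SVM classifier.

The panel selection follows the canonical NSC (PAM) formulation: per-gene,
per-class standardised centroid distances d_ik = (xbar_ik - xbar_i) /
(m_k (s_i + s0)) are soft-thresholded by delta; genes surviving shrinkage in
at least one class form the panel.  A linear soft-margin SVM on the panel
genes is validated by stratified k-fold cross-validation, with the AUC
computed rank-based (Mann-Whitney) from the pooled held-out decision scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "NSCStatistics",
    "ClassifierPanel",
    "PanelClassifier",
    "nsc_statistics",
    "shrink_and_select",
    "panel_of_size",
    "choose_delta_cv",
    "nsc_predict",
    "train_panel_classifier",
    "classify_samples",
    "rank_auc",
    "save_model",
    "load_model",
]


@dataclass
class NSCStatistics:
    """Per-gene NSC ingredients for a two-class problem."""

    classes: list[str]
    centroids: pd.DataFrame  # gene x class means
    overall: pd.Series  # gene overall means
    d: pd.DataFrame  # gene x class standardised distances
    s: pd.Series  # pooled within-class sd per gene
    s0: float
    m_k: dict[str, float]
    n_k: dict[str, int]


@dataclass
class ClassifierPanel:
    """Genes surviving shrinkage at ``delta``, ordered by max |d'| descending."""

    genes: list[str]
    delta: float
    d_shrunk: pd.DataFrame  # gene x class shrunken distances (panel rows)
    stats: NSCStatistics | None
    cv_error_by_delta: pd.DataFrame | None = None


@dataclass
class PanelClassifier:
    panel: ClassifierPanel
    weights: np.ndarray
    bias: float
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    classes: list[str]  # decision score > 0 -> classes[1]
    cv_auc: float
    cv_folds: int


def nsc_statistics(expr: pd.DataFrame, labels: pd.Series) -> NSCStatistics:
    """Compute centroids, pooled SDs and standardised distances d_ik.

    ``expr`` is gene x sample (log scale); ``labels`` maps sample -> class.
    """
    labels = labels.loc[expr.columns]
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    n = expr.shape[1]
    n_k = {c: int((labels == c).sum()) for c in classes}
    if min(n_k.values()) < 2:
        raise ValueError("each class needs >= 2 samples")
    mat = expr.to_numpy(dtype=float)
    overall = mat.mean(axis=1)
    centroids = {}
    within_ss = np.zeros(expr.shape[0])
    for c in classes:
        cols = (labels == c).to_numpy()
        mu = mat[:, cols].mean(axis=1)
        centroids[c] = mu
        within_ss += ((mat[:, cols] - mu[:, None]) ** 2).sum(axis=1)
    s = np.sqrt(within_ss / (n - len(classes)))
    s0 = float(np.median(s))
    m_k = {c: float(np.sqrt(1.0 / n_k[c] - 1.0 / n)) for c in classes}
    d = {c: (centroids[c] - overall) / (m_k[c] * (s + s0)) for c in classes}
    return NSCStatistics(
        classes=classes,
        centroids=pd.DataFrame(centroids, index=expr.index),
        overall=pd.Series(overall, index=expr.index),
        d=pd.DataFrame(d, index=expr.index),
        s=pd.Series(s, index=expr.index, name="s"),
        s0=s0,
        m_k=m_k,
        n_k=n_k,
    )


def shrink_and_select(stats: NSCStatistics, delta: float) -> ClassifierPanel:
    """Soft-threshold the distances by ``delta`` and keep surviving genes."""
    if delta < 0:
        raise ValueError("delta must be >= 0")
    d = stats.d
    d_shrunk = np.sign(d) * np.maximum(d.abs() - delta, 0.0)
    surviving = d_shrunk.abs().max(axis=1)
    panel = surviving[surviving > 0].sort_values(ascending=False, kind="mergesort")
    return ClassifierPanel(
        genes=list(panel.index),
        delta=float(delta),
        d_shrunk=d_shrunk.loc[panel.index],
        stats=stats,
    )


def panel_of_size(stats: NSCStatistics, size: int) -> ClassifierPanel:
    """Smallest delta whose surviving panel has at most ``size`` genes.

    Searches the sorted |d| magnitudes directly (the panel size is a step
    function of delta), giving exactly ``size`` genes when no ties straddle
    the cut.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    mags = stats.d.abs().max(axis=1).sort_values(ascending=False, kind="mergesort")
    nonzero = mags[mags > 0]
    if len(nonzero) <= size:
        return shrink_and_select(stats, 0.0)
    hi = nonzero.iloc[size - 1]  # smallest magnitude still kept
    lo = nonzero.iloc[size]  # largest magnitude to drop
    delta = float((hi + lo) / 2.0)
    panel = shrink_and_select(stats, delta)
    if len(panel.genes) > size:  # ties at the cut: push delta just past them
        delta = float(np.nextafter(hi, np.inf))
        panel = shrink_and_select(stats, delta)
    return panel


def nsc_predict(stats: NSCStatistics, delta: float, X: pd.DataFrame) -> pd.Series:
    """NSC discriminant classification of samples in gene x sample ``X``."""
    panel = shrink_and_select(stats, delta)
    n = sum(stats.n_k.values())
    priors = {c: stats.n_k[c] / n for c in stats.classes}
    if not panel.genes:
        # full shrinkage: all centroids collapse to the overall mean and the
        # discriminant reduces to the prior (majority class)
        majority = max(stats.classes, key=lambda c: priors[c])
        return pd.Series(majority, index=X.columns)
    genes = panel.genes
    denom = (stats.s.loc[genes] + stats.s0) ** 2
    scores = {}
    sub = X.loc[genes]
    for c in stats.classes:
        centroid = stats.overall.loc[genes] + stats.m_k[c] * (
            stats.s.loc[genes] + stats.s0
        ) * panel.d_shrunk[c].loc[genes]
        diff = sub.sub(centroid, axis=0)
        scores[c] = (diff**2).div(denom, axis=0).sum(axis=0) - 2.0 * np.log(priors[c])
    score_df = pd.DataFrame(scores)
    return score_df.idxmin(axis=1)


def choose_delta_cv(
    expr: pd.DataFrame,
    labels: pd.Series,
    delta_grid=None,
    folds: int = 5,
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Stratified CV of the NSC classifier over a delta grid.

    Returns (chosen_delta, table).  The chosen delta is the largest one
    achieving the minimum CV misclassification rate (parsimony tie-break).
    """
    labels = labels.loc[expr.columns]
    if delta_grid is None:
        d_max = float(nsc_statistics(expr, labels).d.abs().to_numpy().max())
        delta_grid = np.linspace(0.0, d_max, 30)
    delta_grid = sorted(float(d) for d in delta_grid)
    if not delta_grid:
        raise ValueError("empty delta grid")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = labels.to_numpy()
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    errors = np.zeros(len(delta_grid))
    n_tested = 0
    for train_idx, test_idx in skf.split(expr.columns, y):
        train_cols = expr.columns[train_idx]
        test_cols = expr.columns[test_idx]
        stats = nsc_statistics(expr[train_cols], labels.loc[train_cols])
        for i, delta in enumerate(delta_grid):
            pred = nsc_predict(stats, delta, expr[test_cols])
            errors[i] += (pred.to_numpy() != labels.loc[test_cols].to_numpy()).sum()
        n_tested += len(test_idx)
    rates = errors / n_tested
    table = pd.DataFrame({"delta": delta_grid, "cv_error": rates})
    best = rates.min()
    chosen = max(d for d, r in zip(delta_grid, rates) if r <= best + 1e-12)
    return float(chosen), table


def rank_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Mann-Whitney AUC of ``scores`` for the positive class (truth == 1)."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    pos = scores[truth]
    neg = scores[~truth]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need both classes to compute AUC")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))


def train_panel_classifier(
    expr: pd.DataFrame,
    labels: pd.Series,
    panel: ClassifierPanel,
    folds: int = 5,
    C: float = 1.0,
    seed: int = 0,
) -> PanelClassifier:
    """Linear SVM on panel genes with stratified CV AUC from held-out scores.

    Features are standardised per gene with training-fold statistics only;
    the reported ``cv_auc`` pools the held-out decision scores across folds.
    The final model is refit on all samples.
    """
    if not panel.genes:
        raise ValueError("empty panel")
    labels = labels.loc[expr.columns]
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    X = expr.loc[panel.genes].to_numpy(dtype=float).T  # samples x genes
    y = (labels.to_numpy() == classes[1]).astype(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ValueError(
            f"class with {counts.min()} samples cannot support {folds} folds; "
            "use fewer folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pooled_scores = np.zeros(len(y))
    for train_idx, test_idx in skf.split(X, y):
        mean = X[train_idx].mean(axis=0)
        sd = X[train_idx].std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        model = SVC(kernel="linear", C=C)
        model.fit((X[train_idx] - mean) / sd, y[train_idx])
        pooled_scores[test_idx] = model.decision_function((X[test_idx] - mean) / sd)
    cv_auc = rank_auc(pooled_scores, y)

    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    final = SVC(kernel="linear", C=C)
    final.fit((X - mean) / sd, y)
    return PanelClassifier(
        panel=panel,
        weights=final.coef_.ravel().copy(),
        bias=float(final.intercept_[0]),
        feature_mean=mean,
        feature_sd=sd,
        classes=classes,
        cv_auc=cv_auc,
        cv_folds=folds,
    )


def classify_samples(model: PanelClassifier, new_expr: pd.DataFrame) -> pd.DataFrame:
    """Assign new samples to a group with the stored linear decision rule."""
    missing = [g for g in model.panel.genes if g not in new_expr.index]
    if missing:
        raise ValueError(f"panel genes missing from input: {missing}")
    X = new_expr.loc[model.panel.genes].to_numpy(dtype=float).T
    Z = (X - model.feature_mean) / model.feature_sd
    scores = Z @ model.weights + model.bias
    predicted = np.where(scores > 0, model.classes[1], model.classes[0])
    return pd.DataFrame(
        {"predicted": predicted, "score": scores}, index=new_expr.columns
    )


def save_model(model: PanelClassifier, path: str | Path) -> None:
    obj = {
        "panel": model.panel.genes,
        "delta": model.panel.delta,
        "weights": model.weights.tolist(),
        "bias": model.bias,
        "feature_mean": model.feature_mean.tolist(),
        "feature_sd": model.feature_sd.tolist(),
        "classes": model.classes,
        "cv_auc": model.cv_auc,
        "cv_folds": model.cv_folds,
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2)
        fh.write("\n")


def load_model(path: str | Path) -> PanelClassifier:
    with open(path) as fh:
        obj = json.load(fh)
    panel = ClassifierPanel(
        genes=obj["panel"],
        delta=obj["delta"],
        d_shrunk=pd.DataFrame(index=obj["panel"]),
        stats=None,
    )
    return PanelClassifier(
        panel=panel,
        weights=np.asarray(obj["weights"], dtype=float),
        bias=float(obj["bias"]),
        feature_mean=np.asarray(obj["feature_mean"], dtype=float),
        feature_sd=np.asarray(obj["feature_sd"], dtype=float),
        classes=list(obj["classes"]),
        cv_auc=float(obj["cv_auc"]),
        cv_folds=int(obj["cv_folds"]),
    )
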
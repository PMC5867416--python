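"""Secreted-protein biomarker candidates from a subgroup contrast.

Group-discriminating DEGs are intersected with a secreted-protein annotation
to nominate proteins whose synovial-fluid concentration could distinguish
the two patient subgroups; the output mirrors a (gene, protein, group,
fold increase) candidate table.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd


__all__ = ["secreted_biomarkers", "write_biomarker_report", "read_biomarker_report"]


def secreted_biomarkers(
    de_group_ab: pd.DataFrame,
    secreted,
    descriptions: Mapping[str, str] | None = None,
    group_pos: str = "B",
    group_neg: str = "A",
) -> pd.DataFrame:
    """Filter the A-vs-B DEGs against a secreted-protein gene set.

    ``de_group_ab`` is a DE table on the subgroup contrast with positive
    log2FC meaning higher in ``group_pos``.  Rows are DEGs in the secreted
    list; fold increase is 2^|log2FC| (linear scale), sorted descending
    within each group.  Secreted genes absent from the DE universe are
    counted in ``result.attrs["n_secreted_not_tested"]``.
    """
    secreted = set(secreted)
    descriptions = descriptions or {}
    degs = de_group_ab[de_group_ab["is_deg"]]
    hits = degs.loc[sorted(secreted & set(degs.index))]
    rows = []
    for gene, row in hits.iterrows():
        lfc = float(row["log2FC"])
        rows.append(
            {
                "gene": gene,
                "protein": descriptions.get(gene, ""),
                "group": group_pos if lfc > 0 else group_neg,
                "fold_increase": float(2.0 ** abs(lfc)),
            }
        )
    out = pd.DataFrame(rows, columns=["gene", "protein", "group", "fold_increase"])
    if len(out):
        out = out.sort_values(
            ["group", "fold_increase", "gene"],
            ascending=[True, False, True],
            kind="mergesort",
        ).reset_index(drop=True)
    out.attrs["n_secreted_not_tested"] = len(secreted - set(de_group_ab.index))
    return out


def write_biomarker_report(table: pd.DataFrame, path: str | Path) -> None:
    """Write the biomarker table as TSV (header always present)."""
    try:
        table.to_csv(path, sep="\t", index=False, float_format="%.10g")
    except OSError as exc:
        raise OSError(f"failed writing biomarker report to {path}: {exc}") from exc


def read_biomarker_report(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        df = df.reindex(columns=["gene", "protein", "group", "fold_increase"])
    if "protein" in df.columns:
        df["protein"] = df["protein"].fillna("")
    return df
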
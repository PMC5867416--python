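"""Readers and writers for the plain-text formats the pipeline exchanges.

Counts and metadata travel as TSV, gene networks as 3-column edge lists,
gene-set collections as GMT, secreted-protein annotations as one-id-per-line
lists.  Everything round-trips losslessly so fixtures can be written and
re-read in tests.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

__all__ = [
    "read_counts",
    "write_counts",
    "read_metadata",
    "write_metadata",
    "read_network",
    "write_network",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "write_gene_list",
    "read_de_table",
    "write_de_table",
    "write_matrix",
    "read_matrix",
]

_FLOAT_FMT = "%.10g"


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample integer count matrix (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate gene ids")
    if df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate sample ids")
    return df.astype("int64")


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read per-sample metadata; index = sample id."""
    df = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False
    )
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate sample ids")
    return df


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="sample")


def read_network(path: str | Path) -> nx.Graph:
    """Read an undirected weighted edge list: gene_a <tab> gene_b <tab> weight."""
    graph = nx.Graph()
    with open(path) as fh:
        header = fh.readline()  # gene_a  gene_b  weight
        if not header.lower().startswith("gene"):
            fh.seek(0)
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: malformed edge line {line!r}")
            weight = float(parts[2]) if len(parts) > 2 else 1.0
            if weight <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive edge weight")
            if parts[0] == parts[1]:
                continue  # drop self-loops
            graph.add_edge(parts[0], parts[1], weight=weight)
    return graph


def write_network(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for u, v, data in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data.get('weight', 1.0):.10g}\n")


def read_gmt(path: str | Path) -> tuple[dict[str, list[str]], dict[str, str]]:
    """Read a GMT file; returns (sets, descriptions). Members are de-duplicated."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name, desc, *members = parts
            seen: dict[str, None] = {}
            for m in members:
                if m:
                    seen.setdefault(m, None)
            sets[name] = list(seen)
            descriptions[name] = desc
    return sets, descriptions


def write_gmt(
    sets: Mapping[str, Iterable[str]],
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


DE_COLUMNS = ["baseMean", "log2FC", "pvalue", "padj", "is_deg"]


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in DE_COLUMNS if c in de.columns]
    de[cols].to_csv(path, sep="\t", index_label="gene", float_format=_FLOAT_FMT)


def read_de_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "is_deg" in df.columns:
        df["is_deg"] = df["is_deg"].astype(bool)
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format=_FLOAT_FMT)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
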
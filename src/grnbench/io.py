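"""File formats and run configuration.

Canonical interchange is plain TSV throughout:

* expression matrix — first column ``gene``, header row of sample IDs;
* differential-expression table — ``mutant  gene  p_value  sign``;
* binding-score table — ``tf  gene  p  conservation``;
* directed edge list — ``regulator  target  sign``;
* undirected pair list — ``gene_a  gene_b`` (normalized lexicographically);
* SIF export — ``regulator  pd  target`` for graph viewers.

Published supplementary spreadsheets of regulatory/binding networks map
onto the edge-list schema directly: one row per interaction, TF first.
Configuration is YAML with unknown keys rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import DirectedEdgeSet, ExpressionMatrix, UndirectedNetwork

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_edges_tsv",
    "write_edges_tsv",
    "read_pairs_tsv",
    "write_pairs_tsv",
    "export_sif",
    "read_de_tsv",
    "write_de_tsv",
    "read_binding_tsv",
    "write_binding_tsv",
    "RunConfig",
    "read_config",
]


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a genes × samples TSV (first column gene IDs, header samples)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: ragged or malformed TSV: {exc}") from exc
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"{path}: duplicate gene identifiers: {dups}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[~df[col].astype(str).str.fullmatch(r"[-+0-9.eE]+")]
            row = bad.index[0] if len(bad) else "?"
            raise ValueError(f"{path}: non-numeric value in column {col!r} (gene {row!r})")
    if df.isna().any().any():
        stacked = df.isna().stack()
        gene, sample = stacked[stacked].index[0]
        raise ValueError(f"{path}: missing value at gene {gene!r}, sample {sample!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = "gene"
    return ExpressionMatrix(values=df.astype(float))


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    df = expr.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def read_edges_tsv(path: str | Path) -> DirectedEdgeSet:
    """Read a directed edge list with columns regulator, target, sign."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"regulator", "target"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: edge list needs columns {sorted(required)}")
    if "sign" not in df.columns:
        df["sign"] = "?"
    df["sign"] = df["sign"].fillna("?")
    edges: dict[tuple[str, str], str] = {}
    for _, row in df.iterrows():
        pair = (row["regulator"], row["target"])
        if pair[0] == pair[1]:
            raise ValueError(f"{path}: self-edge {pair[0]}->{pair[1]}")
        if pair in edges:
            raise ValueError(f"{path}: duplicate edge {pair[0]}->{pair[1]}")
        edges[pair] = row["sign"]
    return DirectedEdgeSet.from_edges(edges)


def write_edges_tsv(net: DirectedEdgeSet, path: str | Path) -> None:
    rows = [(r, t, net.edges[(r, t)]) for (r, t) in sorted(net.edges)]
    pd.DataFrame(rows, columns=["regulator", "target", "sign"]).to_csv(
        path, sep="\t", index=False
    )


def read_pairs_tsv(path: str | Path) -> UndirectedNetwork:
    """Read an undirected pair list with columns gene_a, gene_b."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_a", "gene_b"} <= set(df.columns):
        raise ValueError(f"{path}: pair list needs columns ['gene_a', 'gene_b']")
    seen = set()
    for _, row in df.iterrows():
        a, b = row["gene_a"], row["gene_b"]
        if a == b:
            raise ValueError(f"{path}: self-pair {a}")
        key = (a, b) if a <= b else (b, a)
        if key in seen:
            raise ValueError(f"{path}: duplicate pair {a}--{b}")
        seen.add(key)
    return UndirectedNetwork.from_pairs(seen)


def write_pairs_tsv(net: UndirectedNetwork, path: str | Path) -> None:
    pd.DataFrame(sorted(net.pairs), columns=["gene_a", "gene_b"]).to_csv(
        path, sep="\t", index=False
    )


def export_sif(net: DirectedEdgeSet | UndirectedNetwork, path: str | Path) -> None:
    """Write simple-interaction format lines for graph viewers."""
    with open(path, "w") as fh:
        if isinstance(net, DirectedEdgeSet):
            for r, t in sorted(net.edges):
                fh.write(f"{r}\tpd\t{t}\n")
        else:
            for a, b in sorted(net.pairs):
                fh.write(f"{a}\tpd\t{b}\n")


def read_de_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"mutant": str, "gene": str, "sign": str})
    required = {"mutant", "gene", "p_value", "sign"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: DE table needs columns {sorted(required)}")
    return df


def write_de_tsv(de: pd.DataFrame, path: str | Path) -> None:
    de.to_csv(path, sep="\t", index=False)


def read_binding_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"tf": str, "gene": str})
    required = {"tf", "gene", "p", "conservation"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: binding table needs columns {sorted(required)}")
    return df


def write_binding_tsv(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, sep="\t", index=False)


@dataclass
class RunConfig:
    """Full-pipeline configuration (all seeds explicit)."""

    out_dir: str = "grnbench_out"
    n_genes: int = 30
    n_tfs: int = 5
    mean_out_degree: float = 3.0
    noise_sd: float = 0.3
    n_samples: int = 120
    n_wt: int = 20
    n_mut: int = 20
    binding_fnr: float = 0.05
    binding_fpr: float = 0.01
    fdr_level: float = 0.05
    alpha_level: float = 0.05
    approaches: list[str] = field(default_factory=list)  # empty = all 18
    n_perm: int = 200
    seed: int = 0

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)


def read_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return RunConfig.from_mapping(data)
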
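"""Readers and writers for the plain-text formats used by the pipeline.

Expression matrices are tab-separated with a sample-ID header row and gene
IDs in the first column.  Annotations are CSV.  Gene sets use GMT.  Networks
export as long-format edge-list TSV and GraphML.  Floats are written with 10
significant digits so write-then-read round-trips within that precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection
from .network import CoexpressionNetwork, ModulePartition, NetworkConfig
from .preprocessing import CountMatrix, ExpressionMatrix

__all__ = [
    "read_expression_tsv", "write_expression_tsv",
    "read_counts_tsv", "write_counts_tsv",
    "read_annotations_csv", "write_annotations_csv",
    "read_gmt", "write_gmt",
    "write_edge_list", "read_edge_list",
    "write_graphml", "read_graphml",
    "write_partition", "read_partition",
    "write_json", "read_json",
]

FLOAT_FMT = "%.10g"


def _read_matrix(path, sep: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene IDs {dup[:5]}")
    if df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate sample IDs")
    bad = df.columns[df.dtypes == object]
    if len(bad):
        col = bad[0]
        row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
        raise ValueError(f"{path}: non-numeric value at gene {row!r}, sample {col!r}")
    return df


def read_expression_tsv(path, unit: str = "log2CPM", cohort: str = "") -> ExpressionMatrix:
    return ExpressionMatrix(values=_read_matrix(path, "\t"), unit=unit, cohort=cohort)


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="gene")


def read_counts_tsv(path, cohort: str = "") -> CountMatrix:
    df = _read_matrix(path, "\t")
    return CountMatrix(counts=df.astype(np.int64), cohort=cohort)


def write_counts_tsv(counts: CountMatrix, path) -> None:
    counts.counts.to_csv(path, sep="\t", index_label="gene")


def read_annotations_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate sample IDs")
    return df


def write_annotations_csv(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, index_label="sample")


def read_gmt(path, source: str = "") -> GeneSetCollection:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{i}: GMT rows need name, description, >=1 member")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{i}: duplicate set name {name!r}")
            members = {g for g in fields[2:] if g}
            if not members:
                raise ValueError(f"{path}:{i}: set {name!r} has no members")
            sets[name] = members
    return GeneSetCollection(sets=sets, source=source or str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, collection.source, *sorted(members)]) + "\n")


def write_edge_list(network: CoexpressionNetwork, path, min_tom: float = 0.0) -> None:
    """Upper-triangle edges with correlation, adjacency, and TOM columns.

    ``min_tom`` floors the exported edges to bound file size.
    """
    iu, ju = np.triu_indices(len(network.genes), k=1)
    keep = network.tom[iu, ju] >= min_tom
    df = pd.DataFrame({
        "gene_a": network.genes[iu[keep]],
        "gene_b": network.genes[ju[keep]],
        "correlation": network.corr[iu[keep], ju[keep]],
        "adjacency": network.adjacency[iu[keep], ju[keep]],
        "tom": network.tom[iu[keep], ju[keep]],
    })
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_edge_list(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_graphml(network: CoexpressionNetwork, path, min_tom: float = 0.0) -> None:
    g = nx.Graph()
    g.add_nodes_from(str(x) for x in network.genes)
    iu, ju = np.triu_indices(len(network.genes), k=1)
    keep = (network.tom[iu, ju] >= min_tom) & (network.adjacency[iu, ju] > 0)
    for i, j in zip(iu[keep], ju[keep]):
        g.add_edge(
            str(network.genes[i]), str(network.genes[j]),
            correlation=float(network.corr[i, j]),
            adjacency=float(network.adjacency[i, j]),
            tom=float(network.tom[i, j]),
        )
    nx.write_graphml(g, path)


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


def write_partition(partition: ModulePartition, path) -> None:
    partition.labels.rename("community").to_csv(path, sep="\t", index_label="gene")


def read_partition(path) -> ModulePartition:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ModulePartition(labels=df["community"].astype(int))


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (pd.Series,)):
            return o.to_dict()
        if isinstance(o, Path):
            return str(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
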
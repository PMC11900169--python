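"""Reading and writing the pipeline's file formats.

Counts travel as TSV (genes as rows, header = sample ids) or MatrixMarket
with sidecar gene/sample id files; metadata as TSV; networks as edge-list
TSV (sorted by MI descending) and GraphML; partitions and centrality tables
as TSV; annotations as GMT; reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .communities import Partition
from .minet import CoexNetwork, MIResult
from .preprocess import CountMatrix, NormalizedMatrix

__all__ = [
    "read_counts_tsv", "write_counts_tsv",
    "read_counts_mtx", "write_counts_mtx",
    "read_metadata_tsv",
    "write_normalized_tsv",
    "write_edge_list", "read_edge_list",
    "write_graphml",
    "write_partition_tsv", "read_partition_tsv",
    "write_ground_truth_tsv",
    "write_json", "read_json",
]


def read_counts_tsv(path, metadata: Optional[pd.DataFrame] = None) -> CountMatrix:
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    cond = None
    if metadata is not None and "condition" in metadata.columns:
        cond = metadata["condition"].reindex(df.columns)
    return CountMatrix(values=df.round().astype(np.int64), sample_condition=cond)


def write_counts_tsv(counts: CountMatrix, path) -> None:
    counts.values.to_csv(path, sep="\t")


def read_counts_mtx(path, genes_path, samples_path,
                    metadata: Optional[pd.DataFrame] = None) -> CountMatrix:
    mat = spio.mmread(path)
    genes = pd.Index(Path(genes_path).read_text().split())
    samples = pd.Index(Path(samples_path).read_text().split())
    values = pd.DataFrame(np.asarray(mat.todense() if sparse.issparse(mat) else mat,
                                     dtype=np.int64),
                          index=genes, columns=samples)
    cond = None
    if metadata is not None and "condition" in metadata.columns:
        cond = metadata["condition"].reindex(samples)
    return CountMatrix(values=values, sample_condition=cond)


def write_counts_mtx(counts: CountMatrix, path, genes_path, samples_path) -> None:
    spio.mmwrite(str(path), sparse.csr_matrix(counts.values.to_numpy()))
    Path(genes_path).write_text("\n".join(counts.gene_ids) + "\n")
    Path(samples_path).write_text("\n".join(counts.sample_ids) + "\n")


def read_metadata_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_normalized_tsv(matrix: NormalizedMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t")


def write_edge_list(net: CoexNetwork, path) -> None:
    rows = sorted(
        ((str(u), str(v), d.get("weight", np.nan))
         for u, v, d in net.graph.edges(data=True)),
        key=lambda r: (-r[2], min(r[0], r[1]), max(r[0], r[1])),
    )
    df = pd.DataFrame(
        [(min(u, v), max(u, v), w) for u, v, w in rows],
        columns=["gene_a", "gene_b", "mi"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_edge_list(path, percentile: float = float("nan")) -> CoexNetwork:
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    for _, row in df.iterrows():
        g.add_edge(row["gene_a"], row["gene_b"], weight=float(row["mi"]))
    thr = float(df["mi"].min()) if len(df) else float("nan")
    return CoexNetwork(graph=g, threshold_value=thr, percentile=percentile)


def write_graphml(net: CoexNetwork, path) -> None:
    nx.write_graphml(net.graph, str(path))


def write_partition_tsv(partition: Partition, path) -> None:
    df = pd.DataFrame(
        sorted(partition.assignment.items(), key=lambda kv: str(kv[0])),
        columns=["gene", "module"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_partition_tsv(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["gene"], df["module"].astype(int)))


def write_ground_truth_tsv(truth, path) -> None:
    genes = sorted(truth.partition_a)
    df = pd.DataFrame({
        "gene": genes,
        "module_a": [truth.partition_a[g] for g in genes],
        "module_b": [truth.partition_b[g] for g in genes],
        "is_hub_b": [g in truth.hub_genes_b for g in genes],
    })
    df.to_csv(path, sep="\t", index=False)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (set, frozenset)):
            return sorted(obj)
        return super().default(obj)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, cls=_NumpyEncoder)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
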
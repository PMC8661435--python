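"""Reading and writing the package's file formats.

Expression input: dense TSV/CSV (genes in rows, first column gene ids,
header row of cell ids) or MatrixMarket ``.mtx`` with ``features.tsv`` /
``barcodes.tsv`` sidecars in the same directory.  Outputs are plain TSV:
per-cell pseudotime tables and lineage edge lists.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread

from .containers import ClusterAssignment, ExpressionMatrix

__all__ = [
    "read_expression",
    "read_clusters",
    "write_expression",
    "write_pseudotime",
    "write_tree",
]


def _find_duplicate(ids) -> str | None:
    seen = set()
    for i in ids:
        if i in seen:
            return i
        seen.add(i)
    return None


def read_expression(path, fmt: str | None = None) -> ExpressionMatrix:
    """Read a genes x cells expression matrix.

    ``fmt`` is inferred from the suffix when omitted (``tsv``, ``csv`` or
    ``mtx``).  Duplicate gene or cell ids and sidecar/dimension mismatches
    are rejected.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt in ("tsv", "csv", "txt"):
        sep = "," if fmt == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        dup = _find_duplicate(df.index.astype(str))
        if dup is not None:
            raise ValueError(f"{path}: duplicated gene id {dup!r}")
        dup = _find_duplicate(df.columns.astype(str))
        if dup is not None:
            raise ValueError(f"{path}: duplicated cell id {dup!r}")
        try:
            values = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as e:
            raise ValueError(f"{path}: non-numeric expression values ({e})") from e
        return ExpressionMatrix(values, list(df.index.astype(str)), list(df.columns.astype(str)))
    if fmt == "mtx":
        raw = mmread(path)
        mat = np.asarray(raw.toarray() if hasattr(raw, "toarray") else raw, dtype=float)
        feat_path = path.with_name("features.tsv")
        if not feat_path.exists():
            feat_path = path.with_name("genes.tsv")
        bc_path = path.with_name("barcodes.tsv")
        genes = [line.split("\t")[0] for line in feat_path.read_text().splitlines() if line]
        cells = [line.split("\t")[0] for line in bc_path.read_text().splitlines() if line]
        if len(genes) != mat.shape[0]:
            raise ValueError(
                f"{feat_path}: {len(genes)} features but matrix has {mat.shape[0]} rows"
            )
        if len(cells) != mat.shape[1]:
            raise ValueError(
                f"{bc_path}: {len(cells)} barcodes but matrix has {mat.shape[1]} columns"
            )
        return ExpressionMatrix(mat, genes, cells)
    raise ValueError(f"unknown expression format: {fmt!r}")


def read_clusters(path, cell_ids: list[str]) -> ClusterAssignment:
    """Two-column TSV (cell_id, cluster) -> ClusterAssignment aligned to
    ``cell_ids``."""
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "cluster"], dtype=str)
    mapping = dict(zip(df["cell_id"], df["cluster"]))
    missing = [c for c in cell_ids if c not in mapping]
    if missing:
        raise ValueError(f"cluster file lacks labels for cells: {missing[:5]}")
    return ClusterAssignment.from_labels([mapping[c] for c in cell_ids])


def write_expression(expr: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.cell_ids)
    sep = "," if str(path).endswith(".csv") else "\t"
    df.to_csv(path, sep=sep)


def write_pseudotime(
    path,
    cell_ids: list[str],
    pseudotime_rank: np.ndarray,
    score: np.ndarray | None = None,
    cluster: np.ndarray | None = None,
    branch: np.ndarray | None = None,
) -> None:
    """Per-cell TSV with stable column order:
    cell_id, pseudotime_rank[, score][, cluster][, branch]."""
    data = {"cell_id": cell_ids, "pseudotime_rank": np.asarray(pseudotime_rank)}
    if score is not None:
        data["score"] = np.asarray(score)
    if cluster is not None:
        data["cluster"] = np.asarray(cluster)
    if branch is not None:
        data["branch"] = np.asarray(branch)
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def _node_name(node) -> str:
    if node[0] == "branch":
        return f"branch_{node[1]}"
    return f"cluster{node[0]}_{node[1]}"


def write_tree(tree, path) -> None:
    """Edge-list TSV.  Rooted trees list (parent, child, weight); undirected
    trees list each edge once as (node1, node2, weight)."""
    rows = []
    graph = tree.directed if tree.directed is not None else tree.graph
    for u, v, d in graph.edges(data=True):
        rows.append((_node_name(u), _node_name(v), d.get("weight", 0.0)))
    header = ("parent_node", "child_node", "weight") if tree.directed is not None else ("node1", "node2", "weight")
    pd.DataFrame(rows, columns=header).to_csv(path, sep="\t", index=False)
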
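"""Core in-memory containers shared across the package.

The central object is :class:`ExpressionMatrix`, a genes x cells numeric
matrix with string identifiers on both axes.  All downstream machinery
(rank transform, cost evaluation, the genetic algorithm) operates on plain
NumPy arrays derived from it, so the container stays deliberately thin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ExpressionMatrix", "ClusterAssignment"]


def _check_unique(ids: list[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {kind} id: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Genes x cells expression matrix (raw counts or normalised values).

    Parameters
    ----------
    values
        Non-negative numeric matrix of shape ``(n_genes, n_cells)`` with no
        missing entries.
    gene_ids, cell_ids
        Unique string identifiers for rows and columns respectively.
    """

    values: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be two-dimensional")
        if self.values.size == 0:
            raise ValueError("expression matrix is empty")
        if not self.gene_ids:
            self.gene_ids = [f"gene{j + 1:05d}" for j in range(self.values.shape[0])]
        if not self.cell_ids:
            self.cell_ids = [f"cell{i + 1:05d}" for i in range(self.values.shape[1])]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError("gene_ids length does not match matrix rows")
        if len(self.cell_ids) != self.values.shape[1]:
            raise ValueError("cell_ids length does not match matrix columns")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains missing or non-finite entries")
        if np.any(self.values < 0):
            raise ValueError("expression matrix contains negative entries")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, index: np.ndarray) -> "ExpressionMatrix":
        index = np.asarray(index)
        return ExpressionMatrix(
            self.values[index, :],
            [self.gene_ids[j] for j in index],
            list(self.cell_ids),
        )

    def subset_cells(self, index: np.ndarray) -> "ExpressionMatrix":
        index = np.asarray(index)
        return ExpressionMatrix(
            self.values[:, index],
            list(self.gene_ids),
            [self.cell_ids[i] for i in index],
        )


@dataclass
class ClusterAssignment:
    """Per-cell cluster labels, contiguous integers ``0 .. k-1``."""

    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be one-dimensional")
        if self.k < 1:
            raise ValueError("k must be at least 1")
        present = np.unique(self.labels)
        if present.min() < 0 or present.max() >= self.k:
            raise ValueError("labels must lie in 0..k-1")

    @classmethod
    def from_labels(cls, raw) -> "ClusterAssignment":
        """Build from arbitrary hashable labels, relabelling to 0..k-1
        in order of first appearance."""
        raw = list(raw)
        mapping: dict = {}
        out = np.empty(len(raw), dtype=int)
        for i, lab in enumerate(raw):
            if lab not in mapping:
                mapping[lab] = len(mapping)
            out[i] = mapping[lab]
        return cls(out, len(mapping))

    @property
    def n_cells(self) -> int:
        return self.labels.shape[0]

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)
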
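"""Optional gene filtering and cell clustering ahead of pseudotime estimation.

Filtering keeps the genes most informative about between-cluster structure:
with cluster labels the per-gene score is the Kruskal-Wallis H statistic
(a rank-based differential-expression test, consistent with the rank-based
cost model); without labels it falls back to the variance of the gene's
rank-transformed expression.  Both scores are invariant to strictly
monotone transforms of the expression values.

Clustering is k-means on the top principal components of the
rank-transformed matrix (components capped at 10); when ``k`` is not given
it is chosen by mean silhouette width over 2..k_max.  Clustering is only a
pre-step — externally supplied labels are equally valid input downstream.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .containers import ClusterAssignment, ExpressionMatrix
from .rank_cost import rank_transform

__all__ = ["filter_genes", "cluster_cells", "de_scores"]


def de_scores(expr: ExpressionMatrix, clusters: ClusterAssignment | None) -> np.ndarray:
    """Per-gene informativeness score used by :func:`filter_genes`."""
    ranks = rank_transform(expr).ranks
    if clusters is None:
        return ranks.var(axis=1)
    labels = clusters.labels
    groups = [labels == c for c in range(clusters.k)]
    scores = np.empty(expr.n_genes)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for j, row in enumerate(ranks):
            try:
                scores[j] = stats.kruskal(*(row[g] for g in groups)).statistic
            except ValueError:  # all values identical -> no between-cluster signal
                scores[j] = 0.0
    return np.nan_to_num(scores, nan=0.0)  # constant genes carry no signal


def filter_genes(
    expr: ExpressionMatrix,
    clusters: ClusterAssignment | None = None,
    n_top: int = 2000,
) -> ExpressionMatrix:
    """Keep the ``n_top`` genes with the strongest differential-expression
    (or rank-variance) score; the cell set is unchanged.

    Ties are broken by gene id (lexicographic) for reproducibility.
    """
    if n_top <= 0:
        raise ValueError("n_top must be positive")
    if n_top > expr.n_genes:
        raise ValueError(f"n_top={n_top} exceeds the number of genes ({expr.n_genes})")
    if clusters is not None and clusters.n_cells != expr.n_cells:
        raise ValueError("cluster assignment does not match the cell set")
    scores = de_scores(expr, clusters)
    order = sorted(range(expr.n_genes), key=lambda j: (-scores[j], expr.gene_ids[j]))
    return expr.subset_genes(np.asarray(order[:n_top]))


def cluster_cells(
    expr: ExpressionMatrix,
    k: int | None = None,
    *,
    seed: int = 0,
    k_max: int = 10,
    n_components: int = 10,
) -> ClusterAssignment:
    """Cluster cells on principal components of rank-transformed expression.

    ``k=None`` searches 2..k_max and picks the k with the best mean
    silhouette width.  Deterministic for a fixed seed.
    """
    n = expr.n_cells
    if n < 2:
        raise ValueError("need at least 2 cells to cluster")
    if k is not None and k > n:
        raise ValueError(f"k={k} exceeds the number of cells ({n})")
    if k == 1:
        return ClusterAssignment(np.zeros(n, dtype=int), 1)

    X = rank_transform(expr).ranks.T  # cells x genes
    if np.ptp(X, axis=0).max() == 0:
        warnings.warn("all cells have identical expression; returning an arbitrary 2-way split")
        labels = np.zeros(n, dtype=int)
        labels[n // 2 :] = 1
        return ClusterAssignment(labels, 2) if k is None or k == 2 else ClusterAssignment(labels % k, k)

    n_comp = min(n_components, n - 1, expr.n_genes)
    if n_comp >= 1 and n_comp < min(X.shape):
        X = PCA(n_components=n_comp, random_state=seed).fit_transform(X)

    def fit(kk: int) -> np.ndarray:
        return KMeans(n_clusters=kk, random_state=seed, n_init=10).fit_predict(X)

    if k is not None:
        labels = fit(k)
        return ClusterAssignment.from_labels(labels)

    best_labels, best_score, best_k = None, -np.inf, None
    for kk in range(2, min(k_max, n - 1) + 1):
        labels = fit(kk)
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(X, labels)
        if score > best_score:
            best_labels, best_score, best_k = labels, score, kk
    if best_labels is None:
        warnings.warn("silhouette search degenerate; returning k=2")
        best_labels = fit(2)
    return ClusterAssignment.from_labels(best_labels)
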
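"""Rank-polynomial BIC cost over cell orderings.

The model: for gene *j*, the rank ``R_ij`` of cell *i* among that gene's
expression values is a polynomial in the cell's pseudotime ``t_i`` of degree
at most 3,

    ``R_ij = beta_j0 + beta_j1 t_i + beta_j2 t_i^2 + beta_j3 t_i^3 + eps_ij``

with ``(t_1 .. t_n)`` a permutation of ``1 .. n``.  Each degree ``d`` in
{1, 2, 3} is fit by least squares; its score is

    ``BIC_dj = n ln(sigma2_dj) + d ln(n)``

where ``sigma2_dj`` is the mean squared residual.  The per-gene cost is
``C_j = min_d BIC_dj`` and the cost of an ordering is ``C = sum_j C_j``,
which the genetic algorithm minimises over the permutation space.

Ranks are computed once from expression (average ranks for ties, zeros
ranked as numeric zeros) and never recomputed per ordering: an ordering only
permutes the pseudotime labels ``1..n`` over cells.

Numerics: fits use an orthonormalised polynomial basis in ``t`` (QR of a
standardised Vandermonde matrix).  Residual sums of squares — hence the BIC —
are basis-invariant, while raw powers of ``t`` up to ``n^3`` would be badly
conditioned for large ``n``.  A configurable variance floor keeps the BIC of
perfect fits finite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .containers import ExpressionMatrix

__all__ = [
    "RankMatrix",
    "GeneFit",
    "CostValue",
    "rank_transform",
    "gene_cost",
    "total_cost",
    "argmin_bruteforce",
    "VAR_FLOOR_SCALE",
]

#: sigma^2 floor = VAR_FLOOR_SCALE * n^2.  Rank residuals scale with n, so
#: the floor is made scale-free in the number of cells.
VAR_FLOOR_SCALE = 1e-8

#: minimum cells per fitted unit: a cubic fit (4 coefficients) plus at least
#: one residual degree of freedom.
MIN_CELLS = 5


@dataclass
class RankMatrix:
    """Per-gene ranks of cells (genes x cells), average ranks for ties."""

    ranks: np.ndarray

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=float)
        if self.ranks.ndim != 2:
            raise ValueError("rank matrix must be two-dimensional")

    @property
    def n_genes(self) -> int:
        return self.ranks.shape[0]

    @property
    def n_cells(self) -> int:
        return self.ranks.shape[1]


@dataclass
class GeneFit:
    """Best polynomial fit of one gene's ranks on pseudotime."""

    degree: int
    coefficients: np.ndarray  # beta_0..beta_3 in raw powers of t; unused terms 0
    resid_var: float
    bic: float


@dataclass
class CostValue:
    total: float
    per_gene: np.ndarray


def rank_transform(expr) -> RankMatrix:
    """Row-wise rank transform with average ranks for ties.

    Zero expression values are treated as numeric zeros: they take the
    lowest ranks and, when tied, share the average of the tied positions.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else np.asarray(expr, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
    if values.size == 0:
        raise ValueError("cannot rank an empty matrix")
    return RankMatrix(rankdata(values, axis=1, method="average"))


def _poly_basis(n: int, max_degree: int = 3) -> np.ndarray:
    """Orthonormal basis spanning polynomials of degree <= max_degree on
    t = 1..n.  Column 0 is the constant."""
    d = min(max_degree, n - 1)
    t = np.arange(1, n + 1, dtype=float)
    ts = (t - t.mean()) / t.std()
    V = np.vander(ts, N=d + 1, increasing=True)
    Q, _ = np.linalg.qr(V)
    return Q


def _effective_degree(n: int, max_degree: int) -> int:
    """Largest degree fit on n points keeping >= 1 residual df (min 1)."""
    return max(1, min(max_degree, n - 2))


def population_costs(
    ranks: RankMatrix | np.ndarray,
    perms: np.ndarray,
    *,
    max_degree: int = 3,
    var_floor: float | None = None,
    per_gene: bool = False,
    chunk_elems: int = 30_000_000,
):
    """Vectorised cost of many orderings at once.

    Parameters
    ----------
    ranks
        Genes x cells rank matrix.
    perms
        Integer array ``(m, n)``; row ``p`` lists cell indices in pseudotime
        order, i.e. cell ``perms[p, k]`` receives pseudotime ``k + 1``.
    per_gene
        Also return the ``(n_genes, m)`` matrix of per-gene costs ``C_j``.

    Returns
    -------
    costs : ndarray of shape (m,), or ``(costs, per_gene_costs)``.
    """
    R = ranks.ranks if isinstance(ranks, RankMatrix) else np.asarray(ranks, dtype=float)
    perms = np.asarray(perms, dtype=np.intp)
    if perms.ndim == 1:
        perms = perms[None, :]
    n_genes, n = R.shape
    if perms.shape[1] != n:
        raise ValueError("ordering length does not match number of cells")
    d_max = _effective_degree(n, max_degree)
    Q = _poly_basis(n, d_max)
    floor = VAR_FLOOR_SCALE * n * n if var_floor is None else var_floor
    sq = np.einsum("gn,gn->g", R, R)
    log_n = math.log(n)
    penalties = np.arange(1, d_max + 1) * log_n

    m = perms.shape[0]
    costs = np.empty(m)
    pg = np.empty((n_genes, m)) if per_gene else None
    step = max(1, chunk_elems // max(1, n_genes * n))
    for lo in range(0, m, step):
        chunk = perms[lo : lo + step]
        c = chunk.shape[0]
        Y = R[:, chunk]  # (G, c, n)
        P = Y.reshape(n_genes * c, n) @ Q  # (G*c, d_max+1)
        rss = sq[:, None, None] - np.cumsum(P * P, axis=1).reshape(n_genes, c, d_max + 1)
        sigma2 = np.maximum(rss[..., 1:] / n, floor)
        bic = n * np.log(sigma2) + penalties
        cj = bic.min(axis=2)  # (G, c)
        costs[lo : lo + c] = cj.sum(axis=0)
        if per_gene:
            pg[:, lo : lo + c] = cj
    if per_gene:
        return costs, pg
    return costs


def gene_cost(
    ranks_row: np.ndarray,
    ordering: np.ndarray,
    *,
    max_degree: int = 3,
    var_floor: float | None = None,
) -> GeneFit:
    """Fit one gene's ranks on the pseudotime implied by ``ordering`` and
    return the BIC-minimising polynomial fit (degrees 1..3)."""
    ranks_row = np.asarray(ranks_row, dtype=float)
    ordering = np.asarray(ordering, dtype=np.intp)
    n = ranks_row.shape[0]
    if ordering.shape[0] != n:
        raise ValueError("ordering length does not match rank vector")
    if max_degree >= 3 and n < MIN_CELLS:
        raise ValueError(
            f"need at least {MIN_CELLS} cells per fitted unit (got {n}); "
            "clusters below this size cannot be ordered"
        )
    d_max = _effective_degree(n, max_degree)
    Q = _poly_basis(n, d_max)
    floor = VAR_FLOOR_SCALE * n * n if var_floor is None else var_floor
    y = ranks_row[ordering]
    proj = y @ Q
    rss = np.maximum(y @ y - np.cumsum(proj * proj), 0.0)
    sigma2 = np.maximum(rss[1:] / n, floor)
    bic = n * np.log(sigma2) + np.arange(1, d_max + 1) * math.log(n)
    d = int(np.argmin(bic)) + 1
    # raw-power coefficients for the winning degree (report only)
    t = np.arange(1, n + 1, dtype=float)
    V = np.vander(t, N=d + 1, increasing=True)
    beta, *_ = np.linalg.lstsq(V, y, rcond=None)
    coefficients = np.zeros(4)
    coefficients[: d + 1] = beta
    return GeneFit(degree=d, coefficients=coefficients, resid_var=float(sigma2[d - 1]), bic=float(bic[d - 1]))


def total_cost(
    ranks: RankMatrix | np.ndarray,
    ordering: np.ndarray,
    *,
    max_degree: int = 3,
    var_floor: float | None = None,
) -> CostValue:
    """Cost ``C`` of one ordering: sum over genes of ``C_j``."""
    R = ranks.ranks if isinstance(ranks, RankMatrix) else np.asarray(ranks, dtype=float)
    n = R.shape[1]
    if max_degree >= 3 and n < MIN_CELLS:
        raise ValueError(
            f"need at least {MIN_CELLS} cells per fitted unit (got {n}); "
            "clusters below this size cannot be ordered"
        )
    costs, pg = population_costs(
        R, np.asarray(ordering, dtype=np.intp)[None, :], max_degree=max_degree,
        var_floor=var_floor, per_gene=True,
    )
    return CostValue(total=float(costs[0]), per_gene=pg[:, 0])


def argmin_bruteforce(
    ranks: RankMatrix | np.ndarray,
    *,
    max_n: int = 9,
    var_floor: float | None = None,
) -> tuple[np.ndarray, float]:
    """Exhaustive minimisation of the cost over all n! orderings.

    Intended as a test oracle for small instances; by reversal invariance
    the reverse of the returned ordering attains the same cost.

    Returns ``(ordering, cost)``.
    """
    R = ranks.ranks if isinstance(ranks, RankMatrix) else np.asarray(ranks, dtype=float)
    n = R.shape[1]
    if n > max_n:
        raise ValueError(f"brute force limited to n <= {max_n} cells (got {n})")
    best_perm: np.ndarray | None = None
    best_cost = np.inf
    batch = 20_000
    it = itertools.permutations(range(n))
    while True:
        block = np.array(list(itertools.islice(it, batch)), dtype=np.intp)
        if block.size == 0:
            break
        costs = population_costs(R, block, var_floor=var_floor,
                                 max_degree=3 if n >= MIN_CELLS else n - 2)
        k = int(np.argmin(costs))
        if costs[k] < best_cost:
            best_cost = float(costs[k])
            best_perm = block[k].copy()
    assert best_perm is not None
    return best_perm, best_cost


def ordering_to_pseudotime(ordering: np.ndarray) -> np.ndarray:
    """Per-cell pseudotime ranks ``1..n`` from an ordering (cell index at
    each position)."""
    ordering = np.asarray(ordering, dtype=np.intp)
    t = np.empty(ordering.shape[0], dtype=float)
    t[ordering] = np.arange(1, ordering.shape[0] + 1)
    return t
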
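"""Scaling pseudotime estimation to large cell numbers.

For N cells, the GA is run on a random subsample of n << N cells; every
cell j (subsampled or not) then receives the score

    ``S_j = (1/r) * sum of the pseudotimes t of the r nearest subsampled
    cells``

with distances measured in rank-transformed expression space.  Ordering
the scores extends the subsample trajectory to all N cells.  Pooling B
such subsamples gives each cell a B-dimensional score vector; after
sign-aligning the columns (each subsample's orientation is arbitrary), a
one-dimensional principal curve is fitted through the N points in score
space and cells are ordered by arc length along it — the consensus
pseudotime.

Subsample runs use independent seeds spawned from the master seed, so the
result is identical whether the runs execute sequentially or concurrently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import UnivariateSpline
from scipy.stats import spearmanr
from sklearn.neighbors import NearestNeighbors

from .containers import ExpressionMatrix
from .ga import GAConfig, GAResult, evolve
from .rank_cost import MIN_CELLS, RankMatrix, rank_transform

__all__ = [
    "SubsampleScore",
    "subsample_order",
    "knn_scores",
    "principal_curve",
    "consensus_curve",
    "pseudotime_large",
    "BigResult",
]


@dataclass
class SubsampleScore:
    """Per-cell scores from one subsample trajectory."""

    scores: np.ndarray          # length N
    subsample_ids: np.ndarray   # the n directly ordered cells
    r: int


@dataclass
class BigResult:
    ordering: np.ndarray        # all N cells, consensus pseudotime order
    scores: np.ndarray          # N x B score matrix (sign-aligned)
    arc_length: np.ndarray      # per-cell position along the principal curve
    subsample_results: list[tuple[np.ndarray, GAResult]]


def subsample_order(
    expr: ExpressionMatrix,
    n: int,
    config: GAConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[GAResult, np.ndarray]:
    """Order a uniform random subsample of ``n`` cells with the GA.

    Returns the GA result (ordering indexes into the subsample) and the
    global indices of the subsampled cells.
    """
    config = config or GAConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    N = expr.n_cells
    if not (MIN_CELLS <= n <= N):
        raise ValueError(f"subsample size must be in [{MIN_CELLS}, {N}] (got {n})")
    sub_ids = np.sort(rng.choice(N, size=n, replace=False))
    ranks = rank_transform(expr.subset_cells(sub_ids))
    res = evolve(ranks, config, rng=rng)
    return res, sub_ids


def knn_scores(
    expr: ExpressionMatrix,
    sub_ordering: np.ndarray,
    subsample_ids: np.ndarray,
    r: int = 5,
    *,
    ranks: RankMatrix | None = None,
) -> SubsampleScore:
    """Score every cell by the mean pseudotime of its ``r`` nearest
    subsampled cells (Euclidean distance in rank-transformed expression
    space).  Only subsampled cells carry pseudotime values; a subsampled
    cell is its own nearest neighbour, so with ``r=1`` its score equals its
    own pseudotime."""
    sub_ordering = np.asarray(sub_ordering, dtype=np.intp)
    subsample_ids = np.asarray(subsample_ids, dtype=np.intp)
    n = len(subsample_ids)
    if r < 1:
        raise ValueError("r must be at least 1")
    if r > n:
        raise ValueError(f"r={r} exceeds the subsample size ({n})")
    if ranks is None:
        ranks = rank_transform(expr)
    X = ranks.ranks.T  # cells x genes
    t = np.empty(n)
    t[sub_ordering] = np.arange(1, n + 1)
    nn = NearestNeighbors(n_neighbors=r).fit(X[subsample_ids])
    _, ind = nn.kneighbors(X)
    scores = t[ind].mean(axis=1)
    return SubsampleScore(scores=scores, subsample_ids=subsample_ids, r=r)


def _sign_align(S: np.ndarray) -> np.ndarray:
    """Flip score columns so all correlate positively (Spearman) with a
    reference column: the first column, or the largest-variance column if
    the first is constant."""
    S = np.array(S, dtype=float, copy=True)
    if S.shape[1] == 1:
        return S
    var = S.var(axis=0)
    ref = 0 if var[0] > 0 else int(np.argmax(var))
    for b in range(S.shape[1]):
        if b == ref:
            continue
        rho = spearmanr(S[:, b], S[:, ref]).statistic
        if np.isfinite(rho) and rho < 0:
            S[:, b] = -S[:, b]
    return S


def principal_curve(
    X: np.ndarray,
    *,
    max_iter: int = 50,
    chunk: int = 2048,
) -> np.ndarray:
    """One-dimensional principal curve by projection-smoothing iteration.

    Initialised from the first principal component; each coordinate is
    spline-smoothed against the current arc-length parameter (smoothing
    level from a difference-based residual-variance estimate), points are
    re-projected onto the fitted polyline, and iteration stops when the
    arc-length ordering stabilises or after ``max_iter`` rounds.

    Returns the arc-length parameter per point.
    """
    X = np.asarray(X, dtype=float)
    n, B = X.shape
    if np.allclose(X, X[0]):
        raise ValueError("degenerate input: all points identical")
    Xc = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    lam = Xc @ vt[0]
    prev_order = None
    arc = lam.copy()
    for _ in range(max_iter):
        order = np.argsort(lam, kind="stable")
        if prev_order is not None and np.array_equal(order, prev_order):
            break
        prev_order = order
        lam_s = lam[order]
        lam_s = lam_s + np.arange(n) * (1e-9 * (np.ptp(lam_s) + 1.0) / n)  # strictly increasing
        curve = np.empty_like(Xc)
        for b in range(B):
            y = Xc[order, b]
            if n > 4:
                sig2 = float(np.mean(np.diff(y) ** 2)) / 2.0
                spl = UnivariateSpline(lam_s, y, k=3, s=n * sig2)
                curve[:, b] = spl(lam_s)
            else:
                curve[:, b] = y
        seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
        node_arc = np.concatenate([[0.0], np.cumsum(seg)])
        new_lam = np.empty(n)
        for lo in range(0, n, chunk):
            pts = Xc[lo : lo + chunk]
            d2 = ((pts[:, None, :] - curve[None, :, :]) ** 2).sum(axis=2)
            nearest = np.argmin(d2, axis=1)
            for i, k in enumerate(nearest):
                best_d, best_a = d2[i, k], node_arc[k]
                for s0 in (k - 1, k):
                    if 0 <= s0 < n - 1 and seg[s0] > 0:
                        a, bseg = curve[s0], curve[s0 + 1] - curve[s0]
                        tt = float(np.clip(np.dot(pts[i] - a, bseg) / (seg[s0] ** 2), 0.0, 1.0))
                        dd = float(((pts[i] - a - tt * bseg) ** 2).sum())
                        if dd < best_d:
                            best_d, best_a = dd, node_arc[s0] + tt * seg[s0]
                new_lam[lo + i] = best_a
        lam = new_lam
        arc = lam
    return arc


def consensus_curve(score_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Order all cells along the principal curve through score space.

    Returns ``(ordering, arc_length)``.  With a single score column the
    curve degenerates to the line, i.e. the ordering of that column.
    """
    S = np.asarray(score_matrix, dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    if S.shape[1] == 1 or np.allclose(S, S[:, :1]):
        lam = S[:, 0].astype(float)
        return np.argsort(lam, kind="stable"), lam
    lam = principal_curve(S)
    return np.argsort(lam, kind="stable"), lam


def pseudotime_large(
    expr: ExpressionMatrix,
    B: int = 30,
    M: int = 100,
    r: int = 5,
    config: GAConfig | None = None,
) -> BigResult:
    """Subsample-consensus pseudotime for all N cells.

    Runs ``B`` independent subsample orderings of size ``M`` (seeds spawned
    from the master seed), scores every cell per subsample, sign-aligns the
    score columns and orders cells along the principal curve through the
    B-dimensional score cloud.
    """
    config = config or GAConfig()
    if B < 1:
        raise ValueError("B must be at least 1")
    if M < MIN_CELLS:
        raise ValueError(f"M must be at least {MIN_CELLS}")
    ranks_full = rank_transform(expr)
    children = np.random.SeedSequence(config.seed).spawn(B)
    cols = []
    sub_results = []
    for b in range(B):
        rng = np.random.default_rng(children[b])
        res, sub_ids = subsample_order(expr, M, config, rng=rng)
        sc = knn_scores(expr, res.ordering, sub_ids, r, ranks=ranks_full)
        cols.append(sc.scores)
        sub_results.append((sub_ids, res))
    S = _sign_align(np.column_stack(cols))
    ordering, arc = consensus_curve(S)
    return BigResult(ordering=ordering, scores=S, arc_length=arc, subsample_results=sub_results)
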
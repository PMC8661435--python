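"""Accuracy metrics for estimated pseudotimes.

``abs_spearman`` is the absolute Spearman rank correlation between an
estimated pseudotime (ordering or score vector) and a reference; because a
trajectory has no intrinsic direction the absolute value is taken, and for
references given as a handful of ordered stage labels whose order is itself
uncertain (e.g. cell-cycle stages) the maximum over all stage-label
permutations can be requested.

``count_functional_genes`` counts the genes whose rank profile shows a
significant polynomial relationship (degree <= 3, the same model class as
the ordering cost) with the estimated pseudotime: per gene, the
BIC-selected polynomial fit is tested against the intercept-only model
with an F statistic, and Benjamini-Hochberg correction is applied across
genes.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix
from .rank_cost import MIN_CELLS, _effective_degree, _poly_basis, rank_transform

__all__ = ["abs_spearman", "count_functional_genes"]


def _as_scores(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def abs_spearman(est, ref, *, stages_permutable: bool = False) -> float:
    """Absolute Spearman correlation in [0, 1] between two pseudotimes.

    ``est`` and ``ref`` may be orderings converted to scores, raw score
    vectors, or (for ``ref`` with ``stages_permutable=True``) categorical
    stage labels; in the latter case the maximum |rho| over all orderings
    of the stages is returned.
    """
    est = _as_scores(est)
    if stages_permutable:
        ref = np.asarray(ref)
        if len(est) != len(ref):
            raise ValueError("length mismatch between estimate and reference")
        levels = list(dict.fromkeys(ref.tolist()))  # stable unique
        best = 0.0
        for perm in itertools.permutations(range(len(levels))):
            mapping = {lab: perm[i] for i, lab in enumerate(levels)}
            mapped = np.array([mapping[x] for x in ref.tolist()], dtype=float)
            rho = stats.spearmanr(est, mapped).statistic
            if np.isfinite(rho):
                best = max(best, abs(float(rho)))
        return best
    ref = _as_scores(ref)
    if len(est) != len(ref):
        raise ValueError("length mismatch between estimate and reference")
    rho = stats.spearmanr(est, ref).statistic
    return abs(float(rho)) if np.isfinite(rho) else 0.0


def count_functional_genes(
    expr: ExpressionMatrix,
    ordering: np.ndarray,
    alpha: float = 0.05,
) -> int:
    """Number of genes with a BH-significant rank-polynomial relationship
    to the estimated pseudotime."""
    ordering = np.asarray(ordering, dtype=np.intp)
    n = expr.n_cells
    if n < MIN_CELLS:
        raise ValueError(f"need at least {MIN_CELLS} cells")
    R = rank_transform(expr).ranks[:, ordering]
    d_max = _effective_degree(n, 3)
    Q = _poly_basis(n, d_max)
    P = R @ Q
    sq = np.einsum("gn,gn->g", R, R)
    rss = np.maximum(sq[:, None] - np.cumsum(P * P, axis=1), 0.0)
    tss = rss[:, 0]
    sigma2 = np.maximum(rss[:, 1:] / n, 1e-300)
    bic = n * np.log(sigma2) + np.arange(1, d_max + 1) * math.log(n)
    best_d = np.argmin(bic, axis=1) + 1
    rss_d = rss[np.arange(len(best_d)), best_d]
    df2 = n - best_d - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((tss - rss_d) / best_d) / (rss_d / df2)
    pvals = np.where(
        tss <= 0, 1.0,
        np.where(rss_d <= 0, 0.0, stats.f.sf(F, best_d, df2)),
    )
    reject = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    return int(reject.sum())
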
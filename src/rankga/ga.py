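"""Genetic algorithm over the permutation space of cell orderings.

One generation takes a population of N orderings through three operators:

* **mutation** — segment inversion between two uniformly chosen positions,
  adding N mutants (N -> 2N);
* **recombination** — the 2N individuals are split at random into two halves
  and paired across them; each pair produces two children by a
  Poisson-cut-point crossover with bipartite-matching repair (2N -> 4N);
* **selection** — the N lowest-cost members of the 4N pool survive
  (ties broken by insertion order).

Because the parents stay in the pool, the best cost is non-increasing
across generations.  Iteration stops after at least ``min_generations``
once the best-cost improvement over the previous generation falls below a
small threshold ``epsilon``.

Crossover repair: after a child retains alternate equal-length fragments of
one parent, the positions left open are filled with the missing values taken
from the other parent via a minimum-weight bipartite matching between the
open position indices and the positions those values occupy in the donor,
with weight = absolute difference of positions.  For this weight an optimal
assignment matches both index sets in sorted order (rearrangement
inequality), which is what the implementation does; tests verify optimality
against an exact assignment solver.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .rank_cost import RankMatrix, population_costs, MIN_CELLS

__all__ = ["GAConfig", "GAResult", "mutate", "segment_reverse", "recombine", "select", "evolve"]

logger = logging.getLogger(__name__)


@dataclass
class GAConfig:
    """Tuning knobs of the genetic algorithm.

    Defaults follow the published operating point: population N = 100, so
    the cost is evaluated on a pool of 4N = 400 candidate orderings per
    generation, with a minimum of 30 generations before the convergence
    test applies.
    """

    pop_size: int = 100
    min_generations: int = 30
    max_generations: int = 200
    epsilon: float | None = None        # absolute convergence threshold
    epsilon_rel: float = 1e-6           # used when epsilon is None: eps = rel * |best at gen 1|
    poisson_lambda: float = 2.0         # mean number of crossover cut points
    seed: int = 0
    init_pc1: bool = False              # seed one member with a PC1 ordering
    var_floor: float | None = None

    def __post_init__(self) -> None:
        if self.pop_size < 4 or self.pop_size % 4 != 0:
            raise ValueError("pop_size must be >= 4 and divisible by 4")
        if self.min_generations < 1:
            raise ValueError("min_generations must be >= 1")
        if self.max_generations < self.min_generations:
            raise ValueError("max_generations must be >= min_generations")
        if self.poisson_lambda <= 0:
            raise ValueError("poisson_lambda must be positive")


@dataclass
class GAResult:
    """Outcome of one GA run."""

    ordering: np.ndarray          # best ordering found (orientation arbitrary)
    cost: float
    history: list[float] = field(default_factory=list)  # best cost per generation
    n_generations: int = 0
    converged: bool = False


def segment_reverse(x: np.ndarray, i: int, j: int) -> np.ndarray:
    """Reverse the (inclusive) segment between positions ``i <= j``."""
    y = np.array(x, copy=True)
    y[i : j + 1] = y[i : j + 1][::-1]
    return y


def mutate(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Inversion mutation: reverse a segment between two uniform positions."""
    n = len(x)
    i, j = sorted(rng.integers(0, n, size=2))
    return segment_reverse(x, int(i), int(j))


def _fragment_bounds(n: int, n_cuts: int) -> np.ndarray:
    """Boundaries of ``n_cuts + 1`` equal-length fragments of ``0..n``; the
    last fragment absorbs the remainder."""
    n_frag = min(n_cuts + 1, n)
    size = n // n_frag
    bounds = np.arange(0, n_frag + 1) * size
    bounds[-1] = n
    return bounds


def _fill_child(keeper: np.ndarray, donor: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    """Child retaining even-index fragments of ``keeper``; gaps filled from
    ``donor`` by sorted-order minimum-weight matching."""
    n = len(keeper)
    child = np.array(keeper, copy=True)
    keep_mask = np.zeros(n, dtype=bool)
    for f in range(0, len(bounds) - 1, 2):
        keep_mask[bounds[f] : bounds[f + 1]] = True
    gap_pos = np.flatnonzero(~keep_mask)
    if gap_pos.size == 0:
        return child
    retained = np.zeros(n, dtype=bool)
    retained[keeper[keep_mask]] = True
    donor_pos = np.flatnonzero(~retained[donor])
    # both position lists ascend, which is an optimal |i - j| matching
    child[gap_pos] = donor[donor_pos]
    return child


def recombine(
    parent1: np.ndarray,
    parent2: np.ndarray,
    rng: np.random.Generator,
    *,
    poisson_lambda: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson-cut crossover with bipartite-matching repair.

    Returns two children; with zero cut points the children are copies of
    the parents.
    """
    parent1 = np.asarray(parent1, dtype=np.intp)
    parent2 = np.asarray(parent2, dtype=np.intp)
    n = len(parent1)
    n_cuts = int(rng.poisson(poisson_lambda))
    bounds = _fragment_bounds(n, n_cuts)
    child_a = _fill_child(parent1, parent2, bounds)
    child_b = _fill_child(parent2, parent1, bounds)
    return child_a, child_b


def select(members: np.ndarray, costs: np.ndarray, n_keep: int) -> tuple[np.ndarray, np.ndarray]:
    """Quarter selection: keep the ``n_keep`` lowest-cost members of a pool
    of ``4 * n_keep``; ties broken by insertion order.

    Distinct orderings take precedence over duplicates: once the population
    converges, copies of the incumbent carry no information, and filling
    the survivor slots with them reduces the search to single-inversion
    hill climbing.  Duplicates are only used to pad the population when
    fewer than ``n_keep`` distinct orderings exist.
    """
    members = np.asarray(members)
    costs = np.asarray(costs, dtype=float)
    if members.shape[0] != 4 * n_keep:
        raise ValueError(f"selection pool must hold 4N = {4 * n_keep} members (got {members.shape[0]})")
    order = np.argsort(costs, kind="stable")
    seen: set[bytes] = set()
    firsts: list[int] = []
    dupes: list[int] = []
    for i in order:
        key = members[i].tobytes()
        if key in seen:
            dupes.append(i)
        else:
            seen.add(key)
            firsts.append(i)
        if len(firsts) == n_keep:
            break
    keep = np.array((firsts + dupes)[:n_keep])
    return members[keep], costs[keep]


def _pc1_ordering(R: np.ndarray) -> np.ndarray:
    X = R.T - R.mean(axis=1)
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    return np.argsort(X @ vt[0], kind="stable")


def evolve(
    ranks: RankMatrix | np.ndarray,
    config: GAConfig | None = None,
    rng: np.random.Generator | None = None,
) -> GAResult:
    """Run the GA on a rank matrix and return the best ordering found.

    The orientation of the result is arbitrary: by reversal invariance of
    the cost, the reversed ordering is an equally valid answer.
    """
    config = config or GAConfig()
    R = ranks.ranks if isinstance(ranks, RankMatrix) else np.asarray(ranks, dtype=float)
    n = R.shape[1]
    if n < MIN_CELLS:
        raise ValueError(f"need at least {MIN_CELLS} cells to run the GA (got {n})")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    N = config.pop_size

    members = np.array([rng.permutation(n) for _ in range(N)], dtype=np.intp)
    if config.init_pc1:
        members[0] = _pc1_ordering(R)
    kw = dict(var_floor=config.var_floor)
    costs = population_costs(R, members, **kw)
    order0 = np.argsort(costs, kind="stable")
    members, costs = members[order0], costs[order0]
    history = [float(costs[0])]

    result = GAResult(ordering=members[0].copy(), cost=float(costs[0]))
    epsilon = config.epsilon
    for gen in range(1, config.max_generations + 1):
        mutants = np.array([mutate(m, rng) for m in members], dtype=np.intp)
        combined = np.vstack([members, mutants])           # 2N
        shuffled = rng.permutation(2 * N)
        half_a, half_b = shuffled[:N], shuffled[N:]
        children = np.empty((2 * N, n), dtype=np.intp)
        for p, (a, b) in enumerate(zip(half_a, half_b)):
            ca, cb = recombine(combined[a], combined[b], rng, poisson_lambda=config.poisson_lambda)
            children[2 * p] = ca
            children[2 * p + 1] = cb
        new = np.vstack([mutants, children])               # 3N fresh candidates
        new_costs = population_costs(R, new, **kw)
        pool = np.vstack([members, new])                   # 4N pool incl. parents
        pool_costs = np.concatenate([costs, new_costs])
        members, costs = select(pool, pool_costs, N)

        best = float(costs[0])
        improvement = history[-1] - best
        history.append(best)
        logger.debug("generation %d: best cost %.6f (improvement %.3g)", gen, best, improvement)
        if epsilon is None:
            epsilon = config.epsilon_rel * abs(best) if best != 0 else config.epsilon_rel
        if gen >= config.min_generations and improvement < epsilon:
            result.converged = True
            result.n_generations = gen
            break
    else:
        result.n_generations = config.max_generations

    result.ordering = members[0].copy()
    result.cost = float(costs[0])
    result.history = history
    return result
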
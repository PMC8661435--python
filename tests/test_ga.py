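"""Genetic-algorithm operators and the evolution loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import linear_sum_assignment

import rankga.ga as ga_mod
from rankga import GAConfig, argmin_bruteforce, evolve, mutate, rank_transform, recombine, select
from rankga.ga import _fill_child, _fragment_bounds, segment_reverse


def is_permutation(x, n):
    return sorted(x) == list(range(n))


def test_segment_reverse_printed_example():
    # reversing the (1-based) positions 2..4 of (3,1,4,2,5) gives (3,2,4,1,5)
    out = segment_reverse(np.array([3, 1, 4, 2, 5]), 1, 3)
    assert list(out) == [3, 2, 4, 1, 5]


def test_segment_reverse_single_position_is_identity():
    x = np.array([2, 0, 1, 3])
    assert list(segment_reverse(x, 2, 2)) == list(x)


@given(st.integers(2, 30), st.integers(0, 10_000))
@settings(deadline=None, max_examples=60)
def test_mutation_yields_valid_permutation(n, seed):
    rng = np.random.default_rng(seed)
    x = rng.permutation(n)
    y = mutate(x, rng)
    assert is_permutation(y, n)
    assert is_permutation(x, n)  # input unmodified


class _FixedPoisson:
    """rng stub drawing a fixed Poisson value, delegating everything else."""

    def __init__(self, value, rng):
        self._value = value
        self._rng = rng

    def poisson(self, lam):
        return self._value

    def __getattr__(self, name):
        return getattr(self._rng, name)


def test_recombine_zero_cuts_copies_parents(rng):
    p1, p2 = rng.permutation(10), rng.permutation(10)
    a, b = recombine(p1, p2, _FixedPoisson(0, rng))
    assert list(a) == list(p1) and list(b) == list(p2)


def test_recombine_identical_parents(rng):
    p = rng.permutation(12)
    a, b = recombine(p, p, rng)
    assert list(a) == list(p) and list(b) == list(p)


def test_recombination_validity_many_trials(rng):
    for _ in range(1000):
        n = int(rng.integers(2, 25))
        p1, p2 = rng.permutation(n), rng.permutation(n)
        a, b = recombine(p1, p2, rng)
        assert is_permutation(a, n) and is_permutation(b, n)


def test_repair_matching_is_minimum_weight(rng):
    """Sorted-order gap filling attains the exact assignment optimum for
    |position difference| weights."""
    for _ in range(50):
        n = int(rng.integers(6, 20))
        p1, p2 = rng.permutation(n), rng.permutation(n)
        bounds = _fragment_bounds(n, int(rng.integers(1, 5)))
        keep = np.zeros(n, dtype=bool)
        for f in range(0, len(bounds) - 1, 2):
            keep[bounds[f] : bounds[f + 1]] = True
        gap_pos = np.flatnonzero(~keep)
        if gap_pos.size == 0:
            continue
        retained = np.zeros(n, dtype=bool)
        retained[p1[keep]] = True
        donor_pos = np.flatnonzero(~retained[p2])
        W = np.abs(gap_pos[:, None] - donor_pos[None, :])
        ri, ci = linear_sum_assignment(W)
        optimal = W[ri, ci].sum()
        sorted_cost = np.abs(gap_pos - donor_pos).sum()
        assert sorted_cost == optimal
        child = _fill_child(p1, p2, bounds)
        assert is_permutation(child, n)
        np.testing.assert_array_equal(child[keep], p1[keep])


def test_select_keeps_lowest_costs():
    members = np.arange(8)[:, None]
    costs = np.array([5, 1, 7, 3, 2, 9, 4, 8], dtype=float)
    kept, kept_costs = select(members, costs, 2)
    assert sorted(kept_costs.tolist()) == [1, 2]


def test_select_tie_break_by_insertion_order():
    members = np.arange(8)[:, None]
    kept, _ = select(members, np.ones(8), 2)
    assert kept[:, 0].tolist() == [0, 1]


def test_select_matches_sort_oracle(rng):
    for _ in range(20):
        costs = rng.uniform(size=12)
        members = np.arange(12)[:, None]
        kept, _ = select(members, costs, 3)
        assert set(kept[:, 0]) == set(np.argsort(costs)[:3])


def test_select_rejects_wrong_pool_size():
    with pytest.raises(ValueError, match="4N"):
        select(np.arange(6)[:, None], np.zeros(6), 2)


def test_best_cost_monotone_non_increasing(small_truth, fast_ga):
    res = evolve(rank_transform(small_truth.counts), fast_ga)
    hist = np.array(res.history)
    assert np.all(np.diff(hist) <= 1e-9)


def test_pool_arithmetic_counts(monkeypatch, rng):
    """Each generation evaluates 3N fresh candidates on top of the N parents."""
    counts = []
    original = ga_mod.population_costs

    def counting(R, perms, **kw):
        counts.append(np.atleast_2d(perms).shape[0])
        return original(R, perms, **kw)

    monkeypatch.setattr(ga_mod, "population_costs", counting)
    R = rank_transform(rng.uniform(0, 5, size=(3, 10)))
    cfg = GAConfig(pop_size=8, min_generations=3, max_generations=3, seed=0)
    evolve(R, cfg)
    assert counts[0] == 8  # initial population
    assert all(c == 24 for c in counts[1:])  # N mutants + 2N children per generation


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_evolve_attains_bruteforce_optimum_small(seed):
    rng = np.random.default_rng(seed)
    hidden = rng.permutation(8)
    t = np.empty(8)
    t[hidden] = np.arange(8)
    expr = np.vstack([t + rng.normal(0, 0.3, 8), -t + rng.normal(0, 0.3, 8)])
    R = rank_transform(expr)
    _, best_cost = argmin_bruteforce(R)
    res = evolve(R, GAConfig(seed=seed))
    assert res.cost == pytest.approx(best_cost, rel=1e-9, abs=1e-6)


def test_evolve_terminates_on_noise(rng):
    R = rank_transform(rng.uniform(0, 1, size=(20, 15)))
    res = evolve(R, GAConfig(pop_size=20, min_generations=5, max_generations=40, seed=1))
    assert res.n_generations <= 40
    assert is_permutation(res.ordering, 15)


def test_evolve_every_member_valid(monkeypatch, rng):
    seen = []
    original = ga_mod.population_costs

    def recording(R, perms, **kw):
        seen.append(np.atleast_2d(perms).copy())
        return original(R, perms, **kw)

    monkeypatch.setattr(ga_mod, "population_costs", recording)
    R = rank_transform(rng.uniform(0, 5, size=(2, 9)))
    evolve(R, GAConfig(pop_size=8, min_generations=2, max_generations=2, seed=3))
    for block in seen:
        for p in block:
            assert is_permutation(p, 9)


def test_gaconfig_validation():
    with pytest.raises(ValueError):
        GAConfig(pop_size=10)  # not divisible by 4
    with pytest.raises(ValueError):
        GAConfig(min_generations=0)
    with pytest.raises(ValueError):
        GAConfig(poisson_lambda=0.0)


def test_evolve_reproducible(small_truth):
    cfg = GAConfig(pop_size=20, min_generations=5, max_generations=10, seed=9)
    a = evolve(rank_transform(small_truth.counts), cfg)
    b = evolve(rank_transform(small_truth.counts), cfg)
    np.testing.assert_array_equal(a.ordering, b.ordering)
    assert a.cost == b.cost
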
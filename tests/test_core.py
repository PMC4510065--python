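"""Coalescent simulation and infinite-sites mutation placement."""

import numpy as np
import pytest
from scipy import stats

from coalgrow.core import (
    place_mutations,
    sfs_from_mutations,
    simulate_tree,
    tree_summaries,
)
from coalgrow.errors import InvalidParameterError


@pytest.mark.parametrize("n", [2, 3, 5, 10, 25])
def test_simulated_tree_structure(n, rng):
    tree = simulate_tree(n, rng)
    tree.validate()
    assert tree.n == n
    assert tree.num_nodes == 2 * n - 1
    assert np.all(tree.height[tree.tip_ids] == 0.0)
    assert sorted(tree.tip_labels) == list(range(1, n + 1))
    # every internal node has exactly two children
    kids = tree.children()
    internal = [v for v in range(tree.num_nodes) if v not in set(tree.tip_ids)]
    assert all(len(kids[v]) == 2 for v in internal)
    # heights strictly increase from child to parent
    nonroot = tree.parent != -1
    assert np.all(
        tree.height[tree.parent[nonroot]] > tree.height[nonroot] - 1e-15
    )


@pytest.mark.parametrize("n", [0, 1, -3])
def test_simulate_rejects_tiny_samples(n, rng):
    with pytest.raises(InvalidParameterError):
        simulate_tree(n, rng)


def test_tmrca_equals_interval_sum_exactly(rng):
    for _ in range(50):
        n = int(rng.integers(2, 12))
        tree = simulate_tree(n, rng)
        tmrca, total, intervals = tree_summaries(tree)
        assert len(intervals) == n - 1
        assert tmrca == pytest.approx(intervals.sum(), abs=1e-12)
        assert tmrca == pytest.approx(tree.height[tree.root], abs=0)
        # total length = sum_i i * t_i with i running n..2
        weights = np.arange(n, 1, -1)
        assert total == pytest.approx((weights * intervals).sum(), rel=1e-12)


def test_pairwise_coalescence_time_mean(rng):
    reps = 4000
    t2 = np.array([simulate_tree(2, rng).t_mrca() for _ in range(reps)])
    se = t2.std(ddof=1) / np.sqrt(reps)
    assert abs(t2.mean() - 0.5) < 4 * se


def test_interval_means_match_coalescent_rates(rng):
    # each epoch with i lineages should last 1/(i(i-1)) on average
    n, reps = 6, 4000
    acc = np.zeros((reps, n - 1))
    for r in range(reps):
        acc[r] = simulate_tree(n, rng).coalescent_intervals()
    means = acc.mean(axis=0)
    ses = acc.std(axis=0, ddof=1) / np.sqrt(reps)
    expect = np.array([1.0 / (i * (i - 1)) for i in range(n, 1, -1)])
    assert np.all(np.abs(means - expect) < 4 * ses)


def test_first_coalescence_pair_is_exchangeable(rng):
    # each of the C(4,2)=6 tip pairs should be first to merge equally often
    n, reps = 4, 6000
    counts = {}
    for _ in range(reps):
        tree = simulate_tree(n, rng)
        first = int(np.argmin(tree.height[n:]) + n)
        kids = tuple(sorted(np.flatnonzero(tree.parent == first)))
        counts[kids] = counts.get(kids, 0) + 1
    observed = np.array(list(counts.values()))
    assert len(observed) == 6
    chi2 = ((observed - reps / 6) ** 2 / (reps / 6)).sum()
    assert chi2 < stats.chi2.ppf(0.999, df=5)


def test_zero_rate_gives_no_mutations(rng):
    tree = simulate_tree(7, rng)
    ms = place_mutations(tree, 0.0, rng)
    assert len(ms) == 0
    assert np.array_equal(ms.sfs(), np.zeros(6, dtype=int))


def test_negative_theta_rejected(rng):
    tree = simulate_tree(3, rng)
    with pytest.raises(InvalidParameterError):
        place_mutations(tree, -0.5, rng)


@pytest.mark.parametrize(
    "n,theta,expected_mean",
    [
        (2, 3.0, 3.0),                      # E(S) = theta at n=2
        (4, 6.0, 6.0 * (1 + 1 / 2 + 1 / 3)),  # theta * H_3 = 11
    ],
)
def test_mean_segregating_sites(n, theta, expected_mean, rng):
    reps = 20000
    counts = np.empty(reps)
    for r in range(reps):
        tree = simulate_tree(n, rng)
        counts[r] = len(place_mutations(tree, theta, rng))
    se = counts.std(ddof=1) / np.sqrt(reps)
    assert abs(counts.mean() - expected_mean) < 4 * se


def test_mutation_record_invariants(rng):
    tree = simulate_tree(8, rng)
    ms = place_mutations(tree, 20.0, rng)
    assert len(ms) > 0
    lengths = tree.branch_lengths()
    for mut in ms:
        low = tree.height[mut.branch]
        high = low + lengths[mut.branch]
        assert low <= mut.height <= high
        assert 1 <= mut.size <= tree.n - 1
        assert 0.0 <= mut.position < 1.0
    assert len(np.unique(ms.position)) == len(ms)


def test_sfs_of_dated_fixture(two_clade_tree):
    _, ms = two_clade_tree
    assert np.array_equal(sfs_from_mutations(ms), [0, 1, 1, 0])


def test_sfs_conservation_and_range(rng):
    for _ in range(30):
        n = int(rng.integers(2, 10))
        tree = simulate_tree(n, rng)
        ms = place_mutations(tree, 8.0, rng)
        sfs = ms.sfs()
        assert len(sfs) == n - 1
        assert sfs.sum() == len(ms)
        assert np.all(sfs >= 0)


def test_sfs_mean_matches_branch_length_oracle(rng):
    # n=3 by hand: E(external length) = 3 E(t3) + E(t2) = 1/2 + 1/2 = 1 and
    # the single internal branch (the first cherry) has expected length
    # E(t2) = 1/2, so E(sfs) = (theta, theta/2).
    theta, reps = 2.0, 30000
    acc = np.zeros((reps, 2))
    for r in range(reps):
        tree = simulate_tree(3, rng)
        acc[r] = place_mutations(tree, theta, rng).sfs()
    means = acc.mean(axis=0)
    ses = acc.std(axis=0, ddof=1) / np.sqrt(reps)
    assert np.all(np.abs(means - [theta, theta / 2]) < 4 * ses)
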
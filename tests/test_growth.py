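"""Tip-extension growth and the exact star-mutation bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coalgrow.core import place_mutations, simulate_tree
from coalgrow.errors import InvalidParameterError, InvalidStateError
from coalgrow.growth import check_recurrence, grow_tree, star_counts


def test_star_counts_on_fixture(two_clade_tree, two_clade_star_tip):
    # the star tip sits under mutation B (size 2) but not under A (size 3)
    _, ms = two_clade_tree
    counts = star_counts(ms, two_clade_star_tip)
    assert counts.tolist() == [0, 1, 0, 0]


def test_star_counts_unknown_tip(two_clade_tree):
    _, ms = two_clade_tree
    with pytest.raises(InvalidParameterError):
        star_counts(ms, 8)  # the root is not a tip


def test_star_counts_mutation_free(rng):
    tree = simulate_tree(5, rng)
    ms = place_mutations(tree, 0.0, rng)
    assert star_counts(ms, int(tree.tip_ids[0])).tolist() == [0, 0, 0, 0]


def test_growth_promotes_exactly_the_star_lineage(two_clade_tree,
                                                  two_clade_star_tip, rng):
    # splitting a tip below B: A keeps size 3, B becomes size 3, every new
    # extension mutation has size 1
    _, ms = two_clade_tree
    grown, rec = grow_tree(ms, rng, star_tip=two_clade_star_tip)
    assert grown.n == 6
    sizes = grown.sizes()
    assert sizes[0] == 3          # A unchanged
    assert sizes[1] == 3          # B promoted
    assert np.all(sizes[2:] == 1)  # extension mutations are singletons
    assert rec.extension_mutation_count == len(grown) - 2
    assert check_recurrence(ms, grown, rec)
    sfs = grown.sfs()
    assert sfs[1] == 0 and sfs[2] == 2
    assert sfs[0] == rec.extension_mutation_count


def test_zero_rate_growth_only_relabels(two_clade_tree, rng):
    tree, ms = two_clade_tree
    ms.theta = 0.0
    grown, rec = grow_tree(ms, rng)
    assert rec.extension_mutation_count == 0
    before = np.append(ms.sfs(), 0)
    star = np.append(rec.star_counts, 0)
    expected = before - star
    expected[1:] += star[:-1]
    assert np.array_equal(grown.sfs(), expected)


def test_grown_tree_is_renormalized_and_composable(rng):
    tree = simulate_tree(3, rng)
    ms = place_mutations(tree, 4.0, rng)
    for expected_n in range(4, 9):
        ms, rec = grow_tree(ms, rng)
        assert ms.n == expected_n
        assert np.all(ms.tree.height[ms.tree.tip_ids] == 0.0)
        ms.tree.validate()
        assert rec.extension_length > 0


def test_growth_rejects_unnormalized_tips(rng):
    tree = simulate_tree(4, rng)
    ms = place_mutations(tree, 1.0, rng)
    tree.height[tree.tip_ids[0]] = 0.01  # pretend a tip was left extended
    with pytest.raises(InvalidStateError):
        grow_tree(ms, rng)


def test_star_labels_are_retired_not_reused(rng):
    tree = simulate_tree(4, rng)
    ms = place_mutations(tree, 2.0, rng)
    seen = set(ms.tree.tip_labels)
    for _ in range(5):
        ms, rec = grow_tree(ms, rng)
        labels = set(ms.tree.tip_labels.tolist())
        assert rec.star_label not in labels
        assert set(rec.child_labels) <= labels
        assert not (set(rec.child_labels) & seen)
        seen |= labels
        assert len(labels) == ms.n


@settings(max_examples=150, derandomize=True, deadline=None)
@given(
    n=st.integers(2, 9),
    theta=st.floats(0.0, 15.0),
    seed=st.integers(0, 2**31 - 1),
)
def test_recurrence_identity_holds_on_every_replicate(n, theta, seed):
    # the size-class bookkeeping is exact, not statistical
    rng = np.random.default_rng(seed)
    tree = simulate_tree(n, rng)
    ms = place_mutations(tree, theta, rng)
    grown, rec = grow_tree(ms, rng)
    assert check_recurrence(ms, grown, rec)
    assert np.all(rec.star_counts <= ms.sfs())


def test_recurrence_detects_tampering(rng):
    tree = simulate_tree(6, rng)
    ms = place_mutations(tree, 8.0, rng)
    grown, rec = grow_tree(ms, rng)
    assert len(grown) > 0
    # silently drop one mutation: one size class loses a count, identity breaks
    grown.branch = grown.branch[1:]
    grown.height = grown.height[1:]
    grown.position = grown.position[1:]
    grown.origin = grown.origin[1:]
    assert not check_recurrence(ms, grown, rec)


def test_recurrence_rejects_mismatched_sizes(rng):
    tree = simulate_tree(4, rng)
    ms = place_mutations(tree, 3.0, rng)
    grown, rec = grow_tree(ms, rng)
    grown2, _ = grow_tree(grown, rng)
    with pytest.raises(InvalidParameterError):
        check_recurrence(ms, grown2, rec)


def test_star_probability_matches_mutation_size(rng):
    # a size-i mutation carries the uniformly chosen star tip w.p. i/n
    n, theta, reps = 6, 6.0, 4000
    num = np.zeros(n - 1)
    den = np.zeros(n - 1)
    for _ in range(reps):
        tree = simulate_tree(n, rng)
        ms = place_mutations(tree, theta, rng)
        star_tip = int(tree.tip_ids[rng.integers(n)])
        sc = star_counts(ms, star_tip)
        num += sc
        den += ms.sfs()
    frac = num[den > 0] / den[den > 0]
    expect = np.arange(1, n)[den > 0] / n
    # binomial-scale tolerance; classes are rare at high i, so allow 5 sigma
    se = np.sqrt(expect * (1 - expect) / den[den > 0])
    assert np.all(np.abs(frac - expect) < 5 * np.maximum(se, 1e-3))
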
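"""Recursive tip-extension growth of a mutated genealogy.

An (n+1)-sample genealogy distributed as a direct standard-coalescent draw
can be produced from an n-sample one by picking a uniformly random tip (the
*-tip), splitting it into two zero-length children, and extending all n+1
tips downward by a shared exponential increment e with mean 1/(n(n+1))
(distributed like t_{n+1}).  New mutations fall on the n+1 extension
segments at rate theta per unit length and are all of size 1; a pre-existing
mutation gains exactly one descendant iff it lies on the *-tip's root path
(a *-mutation), and is otherwise untouched.

This is a tip split, not the coalescence of an (n+1)-th sampled lineage into
the existing tree -- the two constructions are different processes.

The per-size counts of *-mutations, s_{i,*}, are the whole bookkeeping: the
size-i class loses its *-mutations to size i+1 and gains the *-mutations of
size i-1, so s_i^(n+1) = s_i^(n) - s_{i,*} + s_{i-1,*} for i >= 2 exactly on
every realization, and the singleton class obeys the same identity with the
realized extension-mutation count in place of the incoming term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GenealogyTree, MutationSet, sfs_from_mutations
from .errors import InvalidParameterError, InvalidStateError

__all__ = ["StarRecord", "grow_tree", "star_counts", "check_recurrence"]

_TIP_HEIGHT_ATOL = 1e-9


@dataclass(frozen=True)
class StarRecord:
    """Audit of one growth step n -> n+1.

    ``star_counts[i-1]`` is s_{i,*}, the number of size-i mutations on the
    *-tip's root path, for i = 1..n-1 (s_{n,*} is zero by definition and not
    stored).  ``label_map`` records the retired *-tip label and the fresh
    labels issued to its two children.
    """

    step: int
    n_before: int
    star_tip: int                 # node id of the split tip in the n-tree
    star_label: int               # its sample label (retired after the split)
    star_counts: np.ndarray       # s_{i,*} for i = 1..n-1
    extension_length: float       # the shared increment e, coalescent units
    extension_mutation_count: int  # new size-1 mutations on the n+1 extensions
    child_ids: tuple[int, int]
    child_labels: tuple[int, int]

    @property
    def label_map(self) -> dict[int, tuple[int, int]]:
        return {self.star_label: self.child_labels}


def star_counts(ms: MutationSet, star_tip: int) -> np.ndarray:
    """Per-size counts s_{i,*} of mutations on ``star_tip``'s root path.

    Entry i-1 counts the size-i mutations whose branch lies on the path from
    the tip to the root, i.e. the mutations carried by the *-tip.
    """
    tree = ms.tree
    if star_tip not in tree.tip_ids:
        raise InvalidParameterError(f"node {star_tip} is not a tip of the tree")
    n = tree.n
    path = tree.root_path(star_tip)
    on_path = np.isin(ms.branch, path)
    counts = np.zeros(n - 1, dtype=np.int64)
    if on_path.any():
        sizes = ms.sizes()[on_path]
        counts = np.bincount(sizes, minlength=n)[1:n]
    return counts


def grow_tree(
    ms: MutationSet,
    rng: np.random.Generator,
    star_tip: int | None = None,
) -> tuple[MutationSet, StarRecord]:
    """Grow an n-sample mutated genealogy into an (n+1)-sample one.

    Parameters
    ----------
    ms
        MutationSet on an ultrametric tree with all tips at height 0.
    rng
        Random stream; draws are, in order: star tip (unless supplied),
        extension length e, then the n+1 per-segment Poisson mutation counts
        in new-tip order followed by their heights and positions.
    star_tip
        Node id of the tip to split.  Default: uniform over the n tips.
        Supplying it makes a growth step reproducible for audits and tests;
        the uniform draw is what realizes the coalescent distribution.

    Returns
    -------
    (grown MutationSet, StarRecord)
        The grown tree is re-normalized so all n+1 tips sit at height 0
        again (all old heights shift up by e), keeping growth composable.
    """
    tree = ms.tree
    n = tree.n
    if n < 2:
        raise InvalidParameterError(f"cannot grow a tree with n={n} < 2 tips")
    if np.max(np.abs(tree.height[tree.tip_ids])) > _TIP_HEIGHT_ATOL:
        raise InvalidStateError(
            "all tips must sit at height 0 before growth; re-normalize the tree"
        )
    if star_tip is None:
        star_tip = int(tree.tip_ids[rng.integers(n)])
    elif star_tip not in tree.tip_ids:
        raise InvalidParameterError(f"node {star_tip} is not a tip of the tree")

    s_star = star_counts(ms, star_tip)
    e = float(rng.exponential(1.0 / (n * (n + 1))))

    m = tree.num_nodes
    child_ids = (m, m + 1)
    parent = np.concatenate([tree.parent, [star_tip, star_tip]])
    # shift the whole old tree up by e; the split tip becomes an internal
    # node at height e and the new tips (old tips + the two children) at 0.
    height = np.concatenate([tree.height + e, [0.0, 0.0]])
    old_tip_mask = np.zeros(m + 2, dtype=bool)
    old_tip_mask[tree.tip_ids] = True
    old_tip_mask[star_tip] = False
    height[old_tip_mask] = 0.0

    keep = tree.tip_ids != star_tip
    star_label = int(tree.tip_labels[~keep][0])
    fresh = int(tree.tip_labels.max())
    child_labels = (fresh + 1, fresh + 2)
    tip_ids = np.concatenate([tree.tip_ids[keep], child_ids])
    tip_labels = np.concatenate([tree.tip_labels[keep], child_labels])
    grown = GenealogyTree(parent, height, tip_ids, tip_labels)

    # labels grow by 2 and n by 1 per step, so max_label - n counts past steps
    step = int(tree.tip_labels.max()) - n + 1
    seg_counts = rng.poisson(ms.theta * e, size=n + 1)
    total_new = int(seg_counts.sum())
    new_branch = np.repeat(tip_ids, seg_counts)
    new_height = rng.random(total_new) * e
    new_position = rng.random(total_new)

    grown_ms = MutationSet(
        tree=grown,
        theta=ms.theta,
        branch=np.concatenate([ms.branch, new_branch]),
        height=np.concatenate([ms.height + e, new_height]),
        position=np.concatenate([ms.position, new_position]),
        origin=np.concatenate([ms.origin, np.full(total_new, step, dtype=np.int64)]),
    )
    record = StarRecord(
        step=step,
        n_before=n,
        star_tip=int(star_tip),
        star_label=star_label,
        star_counts=s_star,
        extension_length=e,
        extension_mutation_count=total_new,
        child_ids=child_ids,
        child_labels=child_labels,
    )
    return grown_ms, record


def check_recurrence(
    before: MutationSet, after: MutationSet, rec: StarRecord
) -> bool:
    """Verify the exact size-class bookkeeping of one growth step.

    Returns True iff, with s the SFS of the n-tree and s' that of the
    (n+1)-tree, s'_i = s_i - s_{i,*} + s_{i-1,*} holds for i = 2..n (with
    s_n and s_{n,*} taken as zero) and s'_1 = s_1 - s_{1,*} + (the realized
    number of extension mutations).  These identities hold by construction
    on every replicate; a False return means corrupted bookkeeping.
    """
    n = before.n
    if after.n != n + 1:
        raise InvalidParameterError(
            f"after must have {n + 1} tips, found {after.n}"
        )
    sfs_b = np.append(sfs_from_mutations(before), 0)      # s_i, i = 1..n
    star = np.append(rec.star_counts, 0)                  # s_{i,*}, i = 1..n
    sfs_a = sfs_from_mutations(after)                     # s'_i, i = 1..n
    expected = sfs_b - star
    expected[1:] += star[:-1]
    expected[0] += rec.extension_mutation_count
    return bool(np.array_equal(sfs_a, expected))
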
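"""Standard neutral coalescent simulation with infinite-sites mutation.

Time is measured in coalescent units of 4N generations throughout, so the
epoch during which i lineages are ancestral to the sample is exponential with
mean 1/(i(i-1)), the expected time to the most recent common ancestor of n
alleles is (n-1)/n, and a branch of length L carries a Poisson(theta * L)
number of mutations with theta = 4Nu.  N and u never appear separately.

A genealogy is stored as flat parent/height arrays over node ids; tips are
the childless nodes and carry integer labels (rendered ``t1``..``tn`` in
Newick output).  Mutations live on the branch above a node and record the
height at which they occurred and a site position in [0, 1) standing in for
the infinite-sites assumption.  A mutation's *size* -- the number of sampled
alleles carrying the derived allele -- is always derived from the current
tree, which is what makes the tip-extension growth bookkeeping exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "GenealogyTree",
    "Mutation",
    "MutationSet",
    "simulate_tree",
    "place_mutations",
    "sfs_from_mutations",
    "tree_summaries",
]

NO_PARENT = -1


@dataclass
class GenealogyTree:
    """Rooted binary ultrametric genealogy for n sampled alleles.

    Parameters
    ----------
    parent
        ``parent[v]`` is the node id of v's parent, ``-1`` for the root.
    height
        Node heights above the present in units of 4N generations.  Tips sit
        at height 0; heights strictly increase from child to parent.
    tip_ids
        Node ids of the tips, in label order.
    tip_labels
        Integer sample labels, one per entry of ``tip_ids``.  Fresh labels are
        issued when a tip is split during growth, so labels are unique across
        the life of a tree but not necessarily contiguous.
    """

    parent: np.ndarray
    height: np.ndarray
    tip_ids: np.ndarray
    tip_labels: np.ndarray

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.height = np.asarray(self.height, dtype=np.float64)
        self.tip_ids = np.asarray(self.tip_ids, dtype=np.int64)
        self.tip_labels = np.asarray(self.tip_labels, dtype=np.int64)

    @property
    def n(self) -> int:
        return len(self.tip_ids)

    @property
    def num_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == NO_PARENT)[0])

    def copy(self) -> "GenealogyTree":
        return GenealogyTree(
            self.parent.copy(), self.height.copy(),
            self.tip_ids.copy(), self.tip_labels.copy(),
        )

    def is_tip(self) -> np.ndarray:
        """Boolean mask over node ids, True for childless nodes."""
        mask = np.zeros(self.num_nodes, dtype=bool)
        mask[self.tip_ids] = True
        return mask

    def children(self) -> list[list[int]]:
        """Children lists indexed by node id."""
        kids: list[list[int]] = [[] for _ in range(self.num_nodes)]
        for v, p in enumerate(self.parent):
            if p != NO_PARENT:
                kids[p].append(v)
        return kids

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each node; 0 for the root."""
        lengths = np.zeros(self.num_nodes)
        nonroot = self.parent != NO_PARENT
        lengths[nonroot] = self.height[self.parent[nonroot]] - self.height[nonroot]
        return lengths

    def subtree_tip_counts(self) -> np.ndarray:
        """Number of sampled tips below (and including) every node."""
        counts = np.zeros(self.num_nodes, dtype=np.int64)
        parent = self.parent
        for tip in self.tip_ids:
            v = int(tip)
            while v != NO_PARENT:
                counts[v] += 1
                v = parent[v]
        return counts

    def root_path(self, node: int) -> np.ndarray:
        """Node ids on the path from ``node`` up to and including the root."""
        path = []
        v = int(node)
        while v != NO_PARENT:
            path.append(v)
            v = int(self.parent[v])
        return np.asarray(path, dtype=np.int64)

    def coalescent_intervals(self) -> np.ndarray:
        """Inter-coalescent intervals (t_n, t_{n-1}, ..., t_2).

        Entry j is the duration of the epoch with n - j ancestral lineages;
        the entries partition [0, t_MRCA].
        """
        internal = np.sort(self.height[~self.is_tip()])
        return np.diff(internal, prepend=0.0)

    def t_mrca(self) -> float:
        return float(self.height[self.root])

    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def validate(self, atol: float = 1e-9) -> None:
        """Check structural invariants; raises InvalidParameterError on failure."""
        n = self.n
        if n < 2:
            raise InvalidParameterError("a genealogy needs at least 2 tips")
        if self.num_nodes != 2 * n - 1:
            raise InvalidParameterError(
                f"expected {2 * n - 1} nodes for n={n}, found {self.num_nodes}"
            )
        if np.count_nonzero(self.parent == NO_PARENT) != 1:
            raise InvalidParameterError("tree must have exactly one root")
        nonroot = self.parent != NO_PARENT
        if np.any(self.height[self.parent[nonroot]] - self.height[nonroot] <= -atol):
            raise InvalidParameterError("heights must increase from child to parent")
        if len(np.unique(self.tip_labels)) != n:
            raise InvalidParameterError("tip labels must be unique")


@dataclass(frozen=True)
class Mutation:
    """One infinite-sites mutation: a view row of a :class:`MutationSet`."""

    identifier: int
    branch: int        # node id below the branch carrying the mutation
    height: float      # coalescent units above the present
    position: float    # site position in [0, 1)
    size: int          # number of descendant tips (derived-allele count)
    origin: int        # 0 = initial simulation, k = growth step k


@dataclass
class MutationSet:
    """Infinite-sites mutations attached to the branches of a genealogy.

    Column arrays are aligned: ``branch[j]`` is the node id below the branch
    carrying mutation j, ``height[j]`` its height above the present,
    ``position[j]`` its site coordinate and ``origin[j]`` the growth step that
    created it (0 for the initial simulation).
    """

    tree: GenealogyTree
    theta: float
    branch: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    height: np.ndarray = field(default_factory=lambda: np.empty(0))
    position: np.ndarray = field(default_factory=lambda: np.empty(0))
    origin: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self) -> None:
        self.branch = np.asarray(self.branch, dtype=np.int64)
        self.height = np.asarray(self.height, dtype=np.float64)
        self.position = np.asarray(self.position, dtype=np.float64)
        self.origin = np.asarray(self.origin, dtype=np.int64)
        if self.theta < 0:
            raise InvalidParameterError("theta must be nonnegative")

    def __len__(self) -> int:
        return len(self.branch)

    @property
    def n(self) -> int:
        return self.tree.n

    def sizes(self) -> np.ndarray:
        """Derived-allele count of every mutation, recomputed from the tree."""
        counts = self.tree.subtree_tip_counts()
        return counts[self.branch]

    def __iter__(self) -> Iterator[Mutation]:
        sizes = self.sizes()
        for j in range(len(self)):
            yield Mutation(
                identifier=j,
                branch=int(self.branch[j]),
                height=float(self.height[j]),
                position=float(self.position[j]),
                size=int(sizes[j]),
                origin=int(self.origin[j]),
            )

    def sfs(self) -> np.ndarray:
        """Sample frequency spectrum (s_1, ..., s_{n-1})."""
        return sfs_from_mutations(self)


def simulate_tree(n: int, rng: np.random.Generator) -> GenealogyTree:
    """Simulate a standard-coalescent genealogy for ``n`` alleles.

    Working backwards in time, while i lineages remain an exponential
    interval with mean 1/(i(i-1)) is drawn, then a uniformly chosen unordered
    pair of the i lineages merges.  The draw order per coalescence is
    interval first, then pair, so runs are reproducible from the stream.
    """
    if n < 2:
        raise InvalidParameterError(f"sample size must be >= 2, got {n}")
    num_nodes = 2 * n - 1
    parent = np.full(num_nodes, NO_PARENT, dtype=np.int64)
    height = np.zeros(num_nodes)
    active = list(range(n))
    t = 0.0
    nxt = n
    for i in range(n, 1, -1):
        t += rng.exponential(1.0 / (i * (i - 1)))
        j = int(rng.integers(i))
        k = int(rng.integers(i - 1))
        if k >= j:
            k += 1
        if j > k:
            j, k = k, j
        parent[active[j]] = nxt
        parent[active[k]] = nxt
        height[nxt] = t
        active[j] = nxt
        active[k] = active[-1]
        active.pop()
        nxt += 1
    return GenealogyTree(
        parent=parent,
        height=height,
        tip_ids=np.arange(n, dtype=np.int64),
        tip_labels=np.arange(1, n + 1, dtype=np.int64),
    )


def place_mutations(
    tree: GenealogyTree, theta: float, rng: np.random.Generator
) -> MutationSet:
    """Drop infinite-sites mutations on a genealogy at scaled rate ``theta``.

    Each branch of length L receives Poisson(theta * L) mutations with
    heights uniform along the branch and site positions uniform on [0, 1).
    Branches are visited in node-id order.
    """
    if theta < 0:
        raise InvalidParameterError(f"theta must be >= 0, got {theta}")
    lengths = tree.branch_lengths()
    nodes = np.flatnonzero(lengths > 0)
    counts = rng.poisson(theta * lengths[nodes])
    total = int(counts.sum())
    branch = np.repeat(nodes, counts)
    low = tree.height[branch]
    span = lengths[branch]
    heights = low + rng.random(total) * span
    positions = rng.random(total)
    return MutationSet(
        tree=tree,
        theta=float(theta),
        branch=branch,
        height=heights,
        position=positions,
        origin=np.zeros(total, dtype=np.int64),
    )


def sfs_from_mutations(ms: MutationSet) -> np.ndarray:
    """Sample frequency spectrum: entry i-1 counts the size-i mutations.

    Length n-1; the entries sum to the number of segregating sites S.
    """
    n = ms.n
    if len(ms) == 0:
        return np.zeros(n - 1, dtype=np.int64)
    return np.bincount(ms.sizes(), minlength=n)[1:n]


def tree_summaries(tree: GenealogyTree) -> tuple[float, float, np.ndarray]:
    """Return (t_MRCA, total branch length, intervals t_n..t_2).

    t_MRCA is the root height and equals the interval sum exactly; the total
    length equals sum_i i * t_i.
    """
    intervals = tree.coalescent_intervals()
    return tree.t_mrca(), tree.total_branch_length(), intervals
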
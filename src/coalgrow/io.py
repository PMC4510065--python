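"""Serialization: Newick trees, ms-style haplotype blocks, TSV tables.

Trees are written in plain Newick with branch lengths in coalescent units
to 6 decimal places and tips labelled ``t1``..``tn``.  Reading goes through
dendropy and enforces the contract needed by the growth operation: strictly
binary topology and ultrametricity within 1e-6.  The ms-style block is the
conventional coalescent-simulator text output: a ``segsites:`` count, a
``positions:`` line, and one 0/1 haplotype row per tip (1 = derived allele),
so each column sum equals the corresponding mutation's size.

Every table writer prefixes ``#`` header lines recording the package
version, the run parameters and the seed.
"""

from __future__ import annotations

import io as _io
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .core import GenealogyTree, MutationSet
from .errors import NewickFormatError
from .growth import StarRecord

__all__ = [
    "write_newick",
    "read_newick",
    "write_ms_block",
    "write_sfs_tsv",
    "write_theory_tsv",
    "write_audit_tsv",
    "header_lines",
]

ULTRAMETRIC_TOL = 1e-6


def write_newick(tree: GenealogyTree,
                 labels: Mapping[int, str] | None = None) -> str:
    """Render a genealogy as a Newick string.

    ``labels`` optionally maps node ids to tip names; the default renders
    the integer sample label k as ``tk``.  Branch lengths carry 6 decimals;
    the root carries no length.
    """
    if labels is None:
        labels = {int(v): f"t{int(lab)}"
                  for v, lab in zip(tree.tip_ids, tree.tip_labels)}
    kids = tree.children()
    heights = tree.height

    def render(v: int) -> str:
        if not kids[v]:
            return labels[v]
        inner = ",".join(
            f"{render(c)}:{heights[v] - heights[c]:.6f}" for c in kids[v]
        )
        return f"({inner})"

    return render(tree.root) + ";"


def read_newick(text: str) -> GenealogyTree:
    """Parse a Newick string into a :class:`GenealogyTree`.

    The tree must be strictly binary and ultrametric within 1e-6 (tips are
    re-normalized to height exactly 0).  Tip names of the form ``t<k>`` keep
    the integer label k; otherwise labels 1..n are assigned in tip order.
    """
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickFormatError(f"unparseable Newick input: {exc}") from exc

    nodes = list(dtree.preorder_node_iter())
    for node in nodes:
        k = len(node.child_nodes())
        if k not in (0, 2):
            name = node.taxon.label if node.taxon else "<internal>"
            raise NewickFormatError(
                f"tree must be strictly binary; node {name!r} has {k} children"
            )
    n_tips = sum(1 for node in nodes if node.is_leaf())
    if n_tips < 2:
        raise NewickFormatError("tree must have at least 2 tips")

    index = {id(node): i for i, node in enumerate(nodes)}
    depth = np.zeros(len(nodes))
    parent = np.full(len(nodes), -1, dtype=np.int64)
    for node in nodes:
        i = index[id(node)]
        if node.parent_node is not None:
            p = index[id(node.parent_node)]
            parent[i] = p
            depth[i] = depth[p] + (node.edge.length or 0.0)

    tip_idx = [index[id(node)] for node in nodes if node.is_leaf()]
    tip_depths = depth[tip_idx]
    max_depth = tip_depths.max()
    # each written branch length carries up to 5e-7 rounding, so the allowed
    # tip-depth deviation scales with the number of edges on the root path
    n_edges = np.zeros(len(nodes), dtype=np.int64)
    for node in nodes:
        i = index[id(node)]
        if node.parent_node is not None:
            n_edges[i] = n_edges[index[id(node.parent_node)]] + 1
    allowed = ULTRAMETRIC_TOL * (1 + n_edges[tip_idx])
    excess = np.abs(tip_depths - max_depth) - allowed
    if excess.max() > 0:
        worst = int(np.argmax(excess))
        bad = [node for node in nodes if node.is_leaf()][worst]
        name = bad.taxon.label if bad.taxon else f"tip #{worst}"
        raise NewickFormatError(
            f"tree is not ultrametric within {ULTRAMETRIC_TOL} per edge: "
            f"tip {name!r} at depth {tip_depths[worst]:.8f} vs {max_depth:.8f}"
        )
    height = max_depth - depth
    height[tip_idx] = 0.0

    labels = []
    for k, node in enumerate(node for node in nodes if node.is_leaf()):
        name = node.taxon.label if node.taxon else ""
        if name.startswith("t") and name[1:].isdigit():
            labels.append(int(name[1:]))
        else:
            labels.append(k + 1)
    if len(set(labels)) != n_tips:
        labels = list(range(1, n_tips + 1))

    tree = GenealogyTree(
        parent=parent,
        height=height,
        tip_ids=np.asarray(tip_idx, dtype=np.int64),
        tip_labels=np.asarray(labels, dtype=np.int64),
    )
    tree.validate(atol=ULTRAMETRIC_TOL)
    return tree


def write_ms_block(ms: MutationSet) -> str:
    """Render a MutationSet as an ms-style text block.

    ``segsites: K`` then ``positions:`` (ascending, 6 decimals) then one 0/1
    row per tip in sample-label order; 1 marks the derived allele, so column
    sums equal the mutation sizes.
    """
    out = _io.StringIO()
    k = len(ms)
    out.write(f"segsites: {k}\n")
    if k == 0:
        return out.getvalue()
    order = np.argsort(ms.position)
    out.write("positions: " +
              " ".join(f"{p:.6f}" for p in ms.position[order]) + "\n")

    tree = ms.tree
    parent = tree.parent
    mut_branches = ms.branch[order]
    label_order = np.argsort(tree.tip_labels)
    for t in tree.tip_ids[label_order]:
        path = set()
        v = int(t)
        while v != -1:
            path.add(v)
            v = int(parent[v])
        row = "".join("1" if int(b) in path else "0" for b in mut_branches)
        out.write(row + "\n")
    return out.getvalue()


def header_lines(params: Mapping[str, object], seed: int | None) -> list[str]:
    from . import __version__

    lines = [f"# coalgrow {__version__}"]
    items = " ".join(f"{k}={v}" for k, v in params.items())
    if seed is not None:
        items += f" seed={seed}"
    lines.append(f"# {items}")
    return lines


def write_sfs_tsv(path, sfs_rows: Iterable[Sequence[int]],
                  params: Mapping[str, object], seed: int | None) -> None:
    """Write SFS vectors, one (replicate, i, s_i) row per entry."""
    with open(path, "w") as fh:
        for line in header_lines(params, seed):
            fh.write(line + "\n")
        fh.write("replicate\ti\ts_i\n")
        for rep, sfs in enumerate(sfs_rows):
            for i, s in enumerate(sfs, start=1):
                fh.write(f"{rep}\t{i}\t{int(s)}\n")


def write_theory_tsv(path_or_buf, table, seed: int | None = None) -> None:
    """Write a :class:`~coalgrow.theory.TheoryTable` as TSV."""
    rows = []
    for i, v in enumerate(table.expected_sfs, start=1):
        rows.append(("E_s_i", i, v))
    rows.append(("E_S", "", table.expected_S))
    for i, v in zip(range(2, table.n + 1), table.expected_intervals):
        rows.append(("E_t_i", i, v))
    rows.append(("E_t_mrca", "", table.expected_tmrca))
    rows.append(("E_s_star", "", table.expected_star))
    for i in range(1, table.n):
        rows.append(("star_probability", i, table.star_probability(i)))

    own = isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__")
    fh = open(path_or_buf, "w") if own else path_or_buf
    try:
        for line in header_lines({"n": table.n, "theta": table.theta}, seed):
            fh.write(line + "\n")
        fh.write("quantity\ti\tvalue\n")
        for name, i, v in rows:
            fh.write(f"{name}\t{i}\t{v:.10g}\n")
    finally:
        if own:
            fh.close()


def write_audit_tsv(path, records: Iterable[StarRecord],
                    params: Mapping[str, object], seed: int | None) -> None:
    """Write the growth audit log, one row per growth step.

    ``records`` holds StarRecords or (replicate, StarRecord) pairs.
    """
    with open(path, "w") as fh:
        for line in header_lines(params, seed):
            fh.write(line + "\n")
        fh.write("replicate\tstep\tn_before\tstar_label\textension_length\t"
                 "extension_mutation_count\tstar_counts\tchild_labels\n")
        for item in records:
            rep, r = item if isinstance(item, tuple) else (0, item)
            counts = ",".join(str(int(c)) for c in r.star_counts)
            children = ",".join(str(c) for c in r.child_labels)
            fh.write(
                f"{rep}\t{r.step}\t{r.n_before}\t{r.star_label}\t"
                f"{r.extension_length:.6f}\t{r.extension_mutation_count}\t"
                f"{counts}\t{children}\n"
            )
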
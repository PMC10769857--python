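"""Array-backed rooted binary trees.

dendropy does the parsing, midpoint rooting and pruning; this module keeps a
flat array representation because the numeric routines (parsimony, the D
statistic, Mk likelihoods and simulation) traverse the same tree many
thousands of times and per-node object access would dominate the runtime.

Node numbering convention: tips are ``0 .. n_tips-1`` in ``tip_labels``
order, internal nodes are ``n_tips .. 2*n_tips-2`` assigned in postorder, so
every child index is smaller than its parent index and the root is the last
node. Iterating internal nodes in increasing index order is therefore a
postorder sweep, and decreasing order (children after parents) a preorder
sweep.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np


@dataclass
class Phylogeny:
    """A rooted, strictly bifurcating phylogeny with branch lengths.

    ``blen[i]`` is the length of the edge above node ``i`` (0 at the root).
    """

    tip_labels: list[str]
    parent: np.ndarray  # int32, -1 at the root
    left: np.ndarray    # int32, -1 at tips
    right: np.ndarray   # int32, -1 at tips
    blen: np.ndarray    # float64

    tip_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n = len(self.tip_labels)
        if n < 2:
            raise ValueError("a phylogeny needs at least two tips")
        if len(set(self.tip_labels)) != n:
            raise ValueError("duplicate tip labels")
        if len(self.parent) != 2 * n - 1:
            raise ValueError("node arrays inconsistent with tip count")
        if np.any(self.blen < 0):
            raise ValueError("negative branch length")
        self.tip_index = {lab: i for i, lab in enumerate(self.tip_labels)}

    # ------------------------------------------------------------------ #
    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def internal_nodes(self) -> range:
        """Internal node indices in postorder (children before parents)."""
        return range(self.n_tips, self.n_nodes)

    def node_depths(self) -> np.ndarray:
        """Distance from the root to every node."""
        depth = np.zeros(self.n_nodes)
        for v in range(self.n_nodes - 2, -1, -1):
            depth[v] = depth[self.parent[v]] + self.blen[v]
        return depth

    def height(self) -> float:
        return float(self.node_depths()[: self.n_tips].max())

    def total_length(self) -> float:
        return float(self.blen.sum())

    def scaled(self, height: float = 1.0) -> "Phylogeny":
        """Return a copy with branch lengths rescaled to the given height."""
        h = self.height()
        if h <= 0:
            raise ValueError("cannot rescale a zero-height tree")
        return Phylogeny(
            list(self.tip_labels),
            self.parent.copy(),
            self.left.copy(),
            self.right.copy(),
            self.blen * (height / h),
        )

    # ------------------------------------------------------------------ #
    def to_newick(self) -> str:
        parts: dict[int, str] = {}
        for i, lab in enumerate(self.tip_labels):
            parts[i] = f"{_quote(lab)}:{self.blen[i]:.12g}"
        for v in self.internal_nodes():
            sub = f"({parts[self.left[v]]},{parts[self.right[v]]})"
            if v == self.root:
                parts[v] = sub + ";"
            else:
                parts[v] = f"{sub}:{self.blen[v]:.12g}"
        return parts[self.root]

    def to_dendropy(self, taxon_namespace=None) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.to_newick(),
            schema="newick",
            preserve_underscores=True,
            taxon_namespace=taxon_namespace,
        )


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]':;,"):
        return "'" + label.replace("'", "''") + "'"
    return label


def from_dendropy(dtree: dendropy.Tree) -> Phylogeny:
    """Convert a rooted, bifurcating dendropy tree to array form.

    Edge lengths of ``None`` are treated as 0 (this only legitimately occurs
    at the root or on edges inserted when resolving polytomies).
    """
    leaves = [nd for nd in dtree.leaf_node_iter()]
    tip_labels = []
    for nd in leaves:
        lab = nd.taxon.label if nd.taxon is not None else nd.label
        if lab is None:
            raise ValueError("unlabelled tip in tree")
        tip_labels.append(lab)
    n = len(leaves)
    index: dict[int, int] = {id(nd): i for i, nd in enumerate(leaves)}
    nxt = n
    for nd in dtree.postorder_node_iter():
        if nd.is_leaf():
            continue
        ch = nd.child_nodes()
        if len(ch) != 2:
            raise ValueError(
                f"non-binary node with {len(ch)} children; resolve polytomies first"
            )
        index[id(nd)] = nxt
        nxt += 1
    n_nodes = 2 * n - 1
    if nxt != n_nodes:
        raise ValueError("tree is not a strictly bifurcating rooted tree")
    parent = np.full(n_nodes, -1, dtype=np.int32)
    left = np.full(n_nodes, -1, dtype=np.int32)
    right = np.full(n_nodes, -1, dtype=np.int32)
    blen = np.zeros(n_nodes)
    for nd in dtree.postorder_node_iter():
        v = index[id(nd)]
        if nd.edge.length is not None:
            blen[v] = float(nd.edge.length)
        if not nd.is_leaf():
            a, b = nd.child_nodes()
            left[v] = index[id(a)]
            right[v] = index[id(b)]
            parent[left[v]] = v
            parent[right[v]] = v
    return Phylogeny(tip_labels, parent, left, right, blen)


def from_newick(text: str) -> Phylogeny:
    dtree = dendropy.Tree.get(
        data=text, schema="newick", preserve_underscores=True
    )
    return from_dendropy(dtree)


def write_newick(tree: Phylogeny, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
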
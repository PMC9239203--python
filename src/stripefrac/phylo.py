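"""Rooted phylogenies as postorder-indexed arrays.

UniFrac distances are sums over tree edges of branch length times a
per-vertex statistic of the two samples being compared.  A postorder array
layout (children stored before their parent, root last) lets sample mass be
propagated from leaves to root in a single forward pass over a ``parent``
array, and lets every kernel treat the tree as plain aligned vectors.

Newick parsing and serialization are delegated to scikit-bio's
:class:`skbio.TreeNode`; this module owns the array conversion and the
structural invariants (unique leaf names, non-negative branch lengths,
postorder ordering).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import skbio

from .errors import NewickError

__all__ = ["PhyloTree", "parse_newick", "write_newick", "total_branch_length"]


@dataclass(frozen=True)
class PhyloTree:
    """A rooted tree stored in postorder.

    Parameters
    ----------
    parent : ndarray of int
        ``parent[i]`` is the postorder index of vertex *i*'s parent; the
        root (last vertex) has sentinel ``-1``.  Postorder guarantees
        ``parent[i] > i`` for every non-root vertex.
    branch_length : ndarray of float
        Length of the edge above each vertex (``b_i``); the root edge has
        length 0 by construction.
    is_leaf : ndarray of bool
        Whether each vertex is a tip.
    name : ndarray of object
        Vertex labels; tips always carry their (unique) leaf name, internal
        vertices carry their label or ``None``.
    """

    parent: np.ndarray
    branch_length: np.ndarray
    is_leaf: np.ndarray
    name: np.ndarray
    _leaf_index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        n = len(self.parent)
        if n == 0:
            raise NewickError("empty tree")
        if self.parent[-1] != -1 or np.count_nonzero(self.parent == -1) != 1:
            raise NewickError("tree must have exactly one root, stored last")
        idx = np.arange(n - 1)
        if not np.all(self.parent[:-1] > idx):
            raise NewickError("vertices are not in postorder (parent[i] > i violated)")
        if np.any(self.branch_length < 0):
            raise NewickError("negative branch length")
        if self.branch_length[-1] != 0:
            raise NewickError("root branch length must be 0")
        leaves = [self.name[i] for i in np.flatnonzero(self.is_leaf)]
        if any(not nm for nm in leaves):
            raise NewickError("empty leaf name")
        if len(set(leaves)) != len(leaves):
            dup = sorted({nm for nm in leaves if leaves.count(nm) > 1})
            raise NewickError(f"duplicate leaf name(s): {', '.join(dup)}")
        object.__setattr__(
            self,
            "_leaf_index",
            {self.name[i]: int(i) for i in np.flatnonzero(self.is_leaf)},
        )

    @property
    def n_vertices(self) -> int:
        return len(self.parent)

    @property
    def n_leaves(self) -> int:
        return int(self.is_leaf.sum())

    @property
    def leaf_names(self) -> list:
        return [self.name[i] for i in np.flatnonzero(self.is_leaf)]

    def leaf_vertex(self, name: str) -> int:
        """Postorder index of the tip carrying ``name`` (KeyError if absent)."""
        return self._leaf_index[name]


def _from_treenode(root: skbio.TreeNode) -> PhyloTree:
    nodes = list(root.postorder(include_self=True))
    index = {id(node): i for i, node in enumerate(nodes)}
    n = len(nodes)
    parent = np.full(n, -1, dtype=np.int64)
    blen = np.zeros(n, dtype=np.float64)
    is_leaf = np.zeros(n, dtype=bool)
    names = np.empty(n, dtype=object)
    for i, node in enumerate(nodes):
        if node.parent is not None:
            parent[i] = index[id(node.parent)]
        blen[i] = 0.0 if node.length is None else float(node.length)
        is_leaf[i] = node.is_tip()
        names[i] = node.name
    if np.any(blen < 0):
        bad = int(np.flatnonzero(blen < 0)[0])
        raise NewickError(f"negative branch length at vertex {bad} ({names[bad]!r})")
    blen[-1] = 0.0  # the root has no edge above it
    return PhyloTree(parent=parent, branch_length=blen, is_leaf=is_leaf, name=names)


def parse_newick(source) -> PhyloTree:
    """Parse a single rooted Newick tree into a :class:`PhyloTree`.

    ``source`` may be a Newick string or a path to a file containing one.
    Missing branch lengths become 0; internal labels are preserved but play
    no role in distances.  Raises :class:`NewickError` on malformed input or
    duplicate leaf names.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
        if not text.strip():
            raise NewickError("empty Newick input")
        if not text.lstrip().startswith("(") and ";" not in text:
            with open(text) as fh:
                text = fh.read()
    text = text.strip()
    if not text:
        raise NewickError("empty Newick input")
    try:
        root = skbio.TreeNode.read(io.StringIO(text), format="newick",
                                   convert_underscores=False)
    except Exception as exc:  # skbio raises NewickFormatError subclasses
        raise NewickError(f"Newick parse failure: {exc}") from exc
    return _from_treenode(root)


def _to_treenode(tree: PhyloTree) -> skbio.TreeNode:
    nodes = [skbio.TreeNode(name=tree.name[i]) for i in range(tree.n_vertices)]
    for i, node in enumerate(nodes):
        node.length = float(tree.branch_length[i])
        p = tree.parent[i]
        if p >= 0:
            nodes[p].append(node)
    root = nodes[-1]
    root.length = None
    return root


def write_newick(tree: PhyloTree, path=None) -> str:
    """Serialize to Newick; returns the string and optionally writes a file."""
    buf = io.StringIO()
    _to_treenode(tree).write(buf, format="newick")
    text = buf.getvalue().strip()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def total_branch_length(tree: PhyloTree) -> float:
    """Sum of all branch lengths, the upper bound of any UniFrac denominator."""
    return float(tree.branch_length.sum())
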
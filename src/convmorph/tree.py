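"""Rooted phylogenies and the Brownian-motion covariance structure they imply.

The tree is the backbone of every downstream analysis: trait covariance under
Brownian motion (BM), root-to-tip path matrices for phylogenetic ridge
regression, and patristic distances for time-adjusted convergence angles all
derive from it.  Newick parsing and writing are delegated to :mod:`dendropy`;
the numerical work happens on a flat array representation (:class:`PhyloTree`)
that is cheap to traverse and hash.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "BMCovariance",
    "NewickParseError",
    "TreeValidationError",
    "parse_newick",
    "write_newick",
    "read_newick_file",
    "collapse_low_support",
    "prune_to_taxa",
    "bm_covariance",
    "patristic_matrix",
]


class NewickParseError(ValueError):
    """Malformed Newick input."""


class TreeValidationError(ValueError):
    """Structurally invalid tree (negative branch lengths, bad taxa, ...)."""


@dataclass
class PhyloTree:
    """A rooted tree with branch lengths, stored as parent-pointer arrays.

    Node ids are integers ``0 .. n_nodes-1`` in preorder (root first).  The
    root's branch length is 0 by convention.  ``labels[i]`` is the species
    name for tips and ``None`` for internal nodes; ``support[i]`` is the
    bootstrap-style support of internal node ``i`` in [0, 100], or ``None``
    when the input carried no value (treated as fully supported: only nodes
    known to be weak are ever collapsed).
    """

    parent: np.ndarray  # int, -1 at root
    brlen: np.ndarray  # float, >= 0, 0 at root
    labels: tuple  # str for tips, None for internal nodes
    support: tuple  # float or None per node (tips: None)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.brlen = np.asarray(self.brlen, dtype=float)
        if (self.parent == -1).sum() != 1:
            raise TreeValidationError("tree must have exactly one root")
        if not np.all(np.isfinite(self.brlen)):
            raise TreeValidationError("branch lengths must be finite")
        if np.any(self.brlen < 0):
            raise TreeValidationError("negative branch length")
        tips = [l for l in self.labels if l is not None]
        if len(set(tips)) != len(tips):
            raise TreeValidationError("tip labels must be unique")

    # -- basic structure -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.nonzero(self.parent == -1)[0][0])

    @property
    def tip_ids(self) -> list[int]:
        return [i for i, l in enumerate(self.labels) if l is not None]

    @property
    def taxa(self) -> list[str]:
        """Tip labels in node-id (preorder) order."""
        return [self.labels[i] for i in self.tip_ids]

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    def children(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {i: [] for i in range(self.n_nodes)}
        for i, p in enumerate(self.parent):
            if p >= 0:
                ch[int(p)].append(i)
        return ch

    def postorder(self) -> list[int]:
        ch = self.children()
        out: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(ch[v])
        return out[::-1]

    def depths(self) -> np.ndarray:
        """Root-to-node path length for every node."""
        d = np.zeros(self.n_nodes)
        order = self.postorder()[::-1]  # preorder
        for v in order:
            p = self.parent[v]
            if p >= 0:
                d[v] = d[p] + self.brlen[v]
        return d

    def path_to_root(self, v: int) -> list[int]:
        """Nodes from ``v`` up to (and including) the root."""
        path = [v]
        while self.parent[path[-1]] >= 0:
            path.append(int(self.parent[path[-1]]))
        return path

    def mrca(self, i: int, j: int) -> int:
        anc = set(self.path_to_root(i))
        for v in self.path_to_root(j):
            if v in anc:
                return v
        raise TreeValidationError("disconnected tree")  # pragma: no cover

    def tip_descendants(self) -> dict[int, set[int]]:
        """Map node id -> set of descendant tip ids (tips include themselves)."""
        ch = self.children()
        desc: dict[int, set[int]] = {}
        for v in self.postorder():
            if not ch[v]:
                desc[v] = {v}
            else:
                s: set[int] = set()
                for c in ch[v]:
                    s |= desc[c]
                desc[v] = s
        return desc

    def is_ultrametric(self, rtol: float = 1e-8) -> bool:
        d = self.depths()[self.tip_ids]
        return bool(np.allclose(d, d[0], rtol=rtol, atol=1e-12))

    def height(self) -> float:
        return float(self.depths()[self.tip_ids].max())


@dataclass
class BMCovariance:
    """Expected tip covariance of a unit-rate Brownian motion on the tree.

    ``C[i, j]`` is the shared root-to-MRCA path length of taxa i and j;
    ``R`` is the derived correlation matrix (``C`` scaled by tree height for
    ultrametric trees, else ``C_ij / sqrt(C_ii C_jj)``).
    """

    taxa: list[str]
    C: np.ndarray
    R: np.ndarray = field(default=None)  # type: ignore[assignment]


# ---------------------------------------------------------------------------
# Newick I/O (via dendropy)
# ---------------------------------------------------------------------------

def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=int)
    brlen = np.zeros(len(nodes))
    labels: list = []
    support: list = []
    for i, nd in enumerate(nodes):
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                raise TreeValidationError("branch length missing on a non-root edge")
            if nd.edge.length < 0:
                raise TreeValidationError(f"negative branch length {nd.edge.length}")
            brlen[i] = float(nd.edge.length)
        if nd.is_leaf():
            if nd.taxon is None or not nd.taxon.label:
                raise TreeValidationError("unlabeled tip")
            labels.append(str(nd.taxon.label))
            support.append(None)
        else:
            labels.append(None)
            sup = None
            if nd.label is not None and str(nd.label).strip():
                try:
                    sup = float(nd.label)
                except ValueError:
                    sup = None
            support.append(sup)
    return PhyloTree(parent, brlen, tuple(labels), tuple(support))


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Internal node labels are read as support values in [0, 100] when they
    are numeric (RAxML convention); branch lengths are required on all
    non-root edges.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed Newick: {exc}") from None
    return _from_dendropy(dtree)


def read_newick_file(path) -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read())


def _newick_rec(tree: PhyloTree, v: int, ch: dict[int, list[int]], buf: io.StringIO) -> None:
    kids = ch[v]
    if kids:
        buf.write("(")
        for k, c in enumerate(kids):
            if k:
                buf.write(",")
            _newick_rec(tree, c, ch, buf)
        buf.write(")")
        if tree.support[v] is not None:
            buf.write(format(tree.support[v], "g"))
    else:
        buf.write(str(tree.labels[v]))
    if tree.parent[v] >= 0:
        buf.write(":" + format(tree.brlen[v], ".17g"))


def write_newick(tree: PhyloTree) -> str:
    """Serialize to Newick with full float precision (round-trip safe)."""
    buf = io.StringIO()
    _newick_rec(tree, tree.root, tree.children(), buf)
    buf.write(";")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Topology editing
# ---------------------------------------------------------------------------

def _rebuild(tree: PhyloTree, drop: set[int]) -> PhyloTree:
    """Remove ``drop`` nodes, re-attaching children to grandparents with
    branch lengths summed (path lengths to surviving nodes preserved)."""
    parent = tree.parent.copy()
    brlen = tree.brlen.copy()
    for v in sorted(drop):  # preorder: parents processed before children
        p = parent[v]
        if p < 0:
            raise TreeValidationError("cannot remove the root")
        for c in np.nonzero(parent == v)[0]:
            parent[c] = p
            brlen[c] += brlen[v]
    keep = [i for i in range(tree.n_nodes) if i not in drop]
    remap = {old: new for new, old in enumerate(keep)}
    new_parent = np.array(
        [remap[int(parent[i])] if parent[i] >= 0 else -1 for i in keep], dtype=int
    )
    return PhyloTree(
        new_parent,
        brlen[keep],
        tuple(tree.labels[i] for i in keep),
        tuple(tree.support[i] for i in keep),
    )


def collapse_low_support(tree: PhyloTree, threshold: float) -> PhyloTree:
    """Collapse internal nodes whose support is below ``threshold`` percent.

    Children of a collapsed node re-attach to its parent with the collapsed
    branch length added, so root-to-tip depths are preserved exactly.  Nodes
    with missing support are kept (only nodes known to be weak collapse).
    """
    ch = tree.children()
    drop = {
        v
        for v in range(tree.n_nodes)
        if ch[v]
        and tree.parent[v] >= 0
        and tree.support[v] is not None
        and tree.support[v] < threshold
    }
    if not drop:
        return tree
    return _rebuild(tree, drop)


def prune_to_taxa(tree: PhyloTree, keep) -> PhyloTree:
    """Induced subtree on the taxa in ``keep``.

    Unary internal nodes created by the pruning are suppressed with their
    branch lengths summed, so patristic distances and root-to-tip depths of
    the kept taxa are unchanged.  A unary root is retained (it anchors the
    depth of the surviving subtree).
    """
    keep = list(keep)
    if len(keep) < 2:
        raise TreeValidationError("need at least 2 taxa to keep")
    have = set(tree.taxa)
    missing = [t for t in keep if t not in have]
    if missing:
        raise TreeValidationError(f"unknown taxa: {missing}")
    keepset = set(keep)
    cur = tree
    # drop unwanted tips
    drop_tips = {i for i in cur.tip_ids if cur.labels[i] not in keepset}
    if drop_tips:
        # removing a tip cannot be done by _rebuild (children reattach logic);
        # simply delete them then suppress empty/unary internals iteratively
        parent = cur.parent.copy()
        alive = np.ones(cur.n_nodes, dtype=bool)
        for t in drop_tips:
            alive[t] = False
        ch = cur.children()
        changed = True
        while changed:
            changed = False
            for v in range(cur.n_nodes):
                if alive[v] and cur.labels[v] is None:
                    if not any(alive[c] for c in ch[v]):
                        alive[v] = False
                        changed = True
        keep_ids = np.nonzero(alive)[0]
        remap = {int(o): n for n, o in enumerate(keep_ids)}
        new_parent = np.array(
            [remap[int(parent[i])] if parent[i] >= 0 else -1 for i in keep_ids],
            dtype=int,
        )
        cur = PhyloTree(
            new_parent,
            cur.brlen[keep_ids],
            tuple(cur.labels[i] for i in keep_ids),
            tuple(cur.support[i] for i in keep_ids),
        )
    # suppress unary non-root internal nodes
    while True:
        ch = cur.children()
        unary = [
            v
            for v in range(cur.n_nodes)
            if cur.labels[v] is None and len(ch[v]) == 1 and cur.parent[v] >= 0
        ]
        if not unary:
            break
        cur = _rebuild(cur, {unary[0]})
    return cur


# ---------------------------------------------------------------------------
# BM structure
# ---------------------------------------------------------------------------

def bm_covariance(tree: PhyloTree) -> BMCovariance:
    """Brownian-motion tip covariance: ``C[i, j]`` = depth of MRCA(i, j).

    Equivalently, every branch contributes its length to all tip pairs that
    descend from it.  ``R`` is C scaled by tree height on ultrametric trees
    (so R is the relatedness correlation matrix used in the regressions) and
    ``C_ij / sqrt(C_ii C_jj)`` otherwise.
    """
    tips = tree.tip_ids
    pos = {t: k for k, t in enumerate(tips)}
    n = len(tips)
    C = np.zeros((n, n))
    desc = tree.tip_descendants()
    for v in range(tree.n_nodes):
        if tree.parent[v] < 0:
            continue
        idx = np.array([pos[t] for t in desc[v]], dtype=int)
        C[np.ix_(idx, idx)] += tree.brlen[v]
    if tree.is_ultrametric():
        R = C / tree.height()
    else:
        d = np.sqrt(np.diag(C))
        R = C / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return BMCovariance(taxa=tree.taxa, C=C, R=R)


def patristic_matrix(tree: PhyloTree) -> np.ndarray:
    """Tip-to-tip path-length matrix (taxa in :attr:`PhyloTree.taxa` order)."""
    cov = bm_covariance(tree)
    d = np.diag(cov.C)
    return d[:, None] + d[None, :] - 2.0 * cov.C
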
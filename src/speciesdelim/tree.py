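"""Rooted binary ultrametric time trees and threshold-based clustering.

The :class:`TimeTree` is the object every tree prior, proposal kernel and
posterior summary in this package operates on.  Leaves sit at height 0
(all samples are extant), internal node heights increase towards the root,
and an optional origin height may sit above the root.  Heights are stored
in "tree-time" units, whatever the user's calibration makes those
(substitutions per site, millions of years, ...).

Clusters ("species") are read off a tree by cutting every branch at a
threshold height ``epsilon``: the leaves of each resulting sub-tree form
one cluster.  A node whose height is exactly ``epsilon`` is *not*
collapsed (it counts as part of the branching process above the
threshold).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "TimeTree",
    "Partition",
    "NewickError",
    "parse_newick",
    "write_newick",
    "extract_clusters",
    "count_collapsed",
    "tree_statistics",
    "read_tree_log",
    "write_tree_log",
]

#: leaves whose height computed from branch lengths deviates from zero by
#: more than this (relative to max(1, root height)) are rejected as
#: non-extant rather than silently clamped.
LEAF_CLAMP_TOL = 1e-8


class NewickError(ValueError):
    """Malformed Newick/NEXUS input (parse failure or invalid tree shape)."""


class TimeTree:
    """Rooted binary time tree with node heights.

    Nodes are indexed ``0 .. 2n-2``: leaves ``0..n-1`` (carrying taxon
    labels), internal nodes ``n..2n-2``.  Structure is stored in flat
    arrays, which keeps copying cheap inside MCMC.

    Parameters
    ----------
    labels
        Taxon labels of the ``n`` leaves, in leaf-index order.
    parent
        ``parent[i]`` is the parent index of node ``i`` (``-1`` for the root).
    left, right
        Child indices per node (``-1`` for leaves).
    heights
        Node heights; leaves must be exactly 0.
    origin
        Optional origin height strictly above the root.
    """

    __slots__ = ("labels", "parent", "left", "right", "heights", "root", "origin")

    def __init__(
        self,
        labels: Sequence[str],
        parent: Sequence[int],
        left: Sequence[int],
        right: Sequence[int],
        heights: Sequence[float],
        origin: float | None = None,
        *,
        validate: bool = True,
    ) -> None:
        self.labels = list(labels)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.left = np.asarray(left, dtype=np.int64)
        self.right = np.asarray(right, dtype=np.int64)
        self.heights = np.asarray(heights, dtype=np.float64)
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise NewickError(f"tree must have exactly one root, found {roots.size}")
        self.root = int(roots[0])
        self.origin = origin
        if validate:
            self.validate()

    # ------------------------------------------------------------------
    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_leaves - 1

    @property
    def internal_nodes(self) -> range:
        return range(self.n_leaves, self.n_nodes)

    def is_leaf(self, i: int) -> bool:
        return i < self.n_leaves

    def children(self, i: int) -> tuple[int, int]:
        return int(self.left[i]), int(self.right[i])

    @property
    def root_height(self) -> float:
        return float(self.heights[self.root])

    def branch_length(self, i: int) -> float:
        """Length of the branch above node ``i`` (0 for the root)."""
        p = self.parent[i]
        if p < 0:
            return 0.0
        return float(self.heights[p] - self.heights[i])

    def copy(self) -> "TimeTree":
        t = object.__new__(TimeTree)
        t.labels = self.labels  # labels are immutable by convention
        t.parent = self.parent.copy()
        t.left = self.left.copy()
        t.right = self.right.copy()
        t.heights = self.heights.copy()
        t.root = self.root
        t.origin = self.origin
        return t

    # ------------------------------------------------------------------
    def validate(self) -> None:
        n = self.n_leaves
        if n < 1:
            raise NewickError("a time tree needs at least 1 leaf")
        # n == 1 is a degenerate tree (single population, no internal
        # nodes); it is allowed so the coalescent machinery can run on a
        # single species, but Newick input requires n >= 2.
        if len(set(self.labels)) != n:
            dup = sorted({x for x in self.labels if self.labels.count(x) > 1})
            raise NewickError(f"duplicate taxon labels: {dup}")
        if self.parent.shape[0] != 2 * n - 1:
            raise NewickError("node arrays must have length 2n-1")
        for i in range(n):
            if self.left[i] != -1 or self.right[i] != -1:
                raise NewickError(f"leaf {i} has children")
            if self.heights[i] != 0.0:
                raise NewickError(f"leaf {self.labels[i]} has nonzero height")
        for i in self.internal_nodes:
            l, r = self.children(i)
            if l < 0 or r < 0:
                raise NewickError(f"internal node {i} is not binary")
            for c in (l, r):
                if self.parent[c] != i:
                    raise NewickError("parent/child links inconsistent")
                if not self.heights[i] > self.heights[c]:
                    raise NewickError(
                        f"node {i} height {self.heights[i]} does not exceed "
                        f"child {c} height {self.heights[c]}"
                    )
        if self.origin is not None and not self.origin > self.root_height:
            raise NewickError("origin height must exceed the root height")

    # ------------------------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "TimeTree":
        return parse_newick(text)

    def to_newick(self, *, precision: int = 17) -> str:
        return write_newick(self, precision=precision)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TimeTree(n={self.n_leaves}, h_S={self.root_height:.6g})"


# ----------------------------------------------------------------------
# Newick I/O (dendropy does the actual parsing; we impose the time-tree
# contract on top: binary, ultrametric, extant leaves).
# ----------------------------------------------------------------------

def _from_dendropy(dtree: "dendropy.Tree") -> TimeTree:
    seed = dtree.seed_node
    nodes = list(dtree.preorder_node_iter())
    leaves = [nd for nd in nodes if nd.is_leaf()]
    n = len(leaves)
    if n < 2:
        raise NewickError("tree has fewer than 2 leaves (or a single-child root)")
    labels = []
    for nd in leaves:
        if nd.taxon is None or not nd.taxon.label:
            raise NewickError("unlabeled leaf in Newick input")
        labels.append(str(nd.taxon.label))
    if len(set(labels)) != n:
        dup = sorted({x for x in labels if labels.count(x) > 1})
        raise NewickError(f"duplicate taxon labels: {dup}")
    internal = [nd for nd in nodes if not nd.is_leaf()]
    for nd in internal:
        kids = nd.child_nodes()
        if len(kids) != 2:
            raise NewickError(
                f"non-binary node with {len(kids)} children (root included)"
            )
    # depth from root via branch lengths
    depth: dict[int, float] = {id(seed): 0.0}
    for nd in nodes:
        if nd is seed:
            continue
        bl = nd.edge.length
        if bl is None:
            raise NewickError(f"missing branch length above node {nd}")
        if bl < 0:
            raise NewickError(f"negative branch length {bl}")
        depth[id(nd)] = depth[id(nd.parent_node)] + float(bl)
    maxdepth = max(depth[id(nd)] for nd in leaves)
    tol = LEAF_CLAMP_TOL * max(1.0, maxdepth)
    index = {id(nd): i for i, nd in enumerate(leaves)}
    for j, nd in enumerate(internal):
        index[id(nd)] = n + j
    m = 2 * n - 1
    parent = np.full(m, -1, dtype=np.int64)
    left = np.full(m, -1, dtype=np.int64)
    right = np.full(m, -1, dtype=np.int64)
    heights = np.zeros(m)
    for nd in nodes:
        i = index[id(nd)]
        h = maxdepth - depth[id(nd)]
        if nd.is_leaf():
            if abs(h) > tol:
                raise NewickError(
                    f"leaf {nd.taxon.label} is not extant (height {h:.3g}); "
                    "only ultrametric trees with contemporaneous tips are supported"
                )
            h = 0.0
        heights[i] = h
        if nd is not seed:
            parent[i] = index[id(nd.parent_node)]
        kids = nd.child_nodes()
        if kids:
            left[i], right[i] = index[id(kids[0])], index[id(kids[1])]
    return TimeTree(labels, parent, left, right, heights)


def parse_newick(text: str) -> TimeTree:
    """Parse a rooted Newick string with branch lengths into a :class:`TimeTree`.

    Heights are recovered from branch lengths with leaves clamped to 0;
    round-trips with :func:`write_newick` up to float formatting.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise NewickError(f"could not parse Newick: {exc}") from exc
    return _from_dendropy(dtree)


def write_newick(tree: TimeTree, *, precision: int = 17) -> str:
    fmt = f"%.{precision}g"

    def rec(i: int) -> str:
        if tree.is_leaf(i):
            body = tree.labels[i]
        else:
            l, r = tree.children(i)
            body = f"({rec(l)},{rec(r)})"
        if i == tree.root:
            return body
        return body + ":" + (fmt % tree.branch_length(i))

    return rec(tree.root) + ";"


def read_tree_log(path) -> list[TimeTree]:
    """Read a NEXUS (or Newick) tree log into a list of time trees.

    NEXUS translate tables are resolved by dendropy.
    """
    path = str(path)
    schema = "nexus"
    with open(path) as fh:
        head = fh.read(64).lstrip()
    if not head.lower().startswith("#nexus"):
        schema = "newick"
    tl = dendropy.TreeList.get(path=path, schema=schema, preserve_underscores=True)
    if len(tl) == 0:
        raise NewickError(f"no trees found in {path}")
    return [_from_dendropy(t) for t in tl]


def write_tree_log(trees: Sequence[TimeTree], path) -> None:
    """Write trees to a NEXUS TREES block sharing one taxon namespace."""
    if not trees:
        raise ValueError("empty tree log")
    tns = dendropy.TaxonNamespace(sorted(trees[0].labels))
    tl = dendropy.TreeList(taxon_namespace=tns)
    for t in trees:
        tl.append(
            dendropy.Tree.get(
                data=t.to_newick(),
                schema="newick",
                taxon_namespace=tns,
                preserve_underscores=True,
            )
        )
    tl.write(path=str(path), schema="nexus", translate_tree_taxa=True)


# ----------------------------------------------------------------------
# Partitions and threshold clustering
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class Partition:
    """A set partition of taxon labels in canonical form.

    Clusters are tuples of sorted labels; clusters are ordered by their
    lexicographically smallest member, so equal partitions compare equal
    regardless of construction order.
    """

    clusters: tuple[tuple[str, ...], ...]

    @staticmethod
    def from_clusters(clusters: Iterable[Iterable[str]]) -> "Partition":
        canon = tuple(
            sorted((tuple(sorted(str(x) for x in c)) for c in clusters),
                   key=lambda c: c[0])
        )
        seen: set[str] = set()
        for c in canon:
            if not c:
                raise ValueError("empty cluster")
            for x in c:
                if x in seen:
                    raise ValueError(f"taxon {x!r} appears in two clusters")
                seen.add(x)
        return Partition(canon)

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(x for c in self.clusters for x in c)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def __contains__(self, cluster) -> bool:
        return tuple(sorted(cluster)) in set(self.clusters)

    def __iter__(self):
        return iter(self.clusters)


def extract_clusters(tree: TimeTree, epsilon: float) -> Partition:
    """Cut all branches at height ``epsilon``; each sub-tree's leaves form a cluster.

    Two taxa share a cluster iff every internal node on the path between
    them has height < ``epsilon``.  ``epsilon`` above the root gives one
    cluster; below every internal node, all singletons.
    """
    if not epsilon > 0:
        raise ValueError("epsilon must be > 0")
    rep: dict[int, list[str]] = {}
    for leaf in range(tree.n_leaves):
        node = leaf
        while tree.parent[node] >= 0 and tree.heights[tree.parent[node]] < epsilon:
            node = int(tree.parent[node])
        rep.setdefault(node, []).append(tree.labels[leaf])
    return Partition.from_clusters(rep.values())


def count_collapsed(tree: TimeTree, epsilon: float) -> int:
    """Number of internal nodes with height < ``epsilon`` (the symbol *k*)."""
    if not epsilon > 0:
        raise ValueError("epsilon must be > 0")
    hs = tree.heights[tree.n_leaves:]
    return int(np.count_nonzero(hs < epsilon))


def tree_statistics(tree: TimeTree) -> tuple[float, float]:
    """Return (tree height h_S, tree length l_S).

    h_S is the root height; l_S sums branch lengths over all non-root nodes.
    """
    h = tree.root_height
    total = 0.0
    for i in range(tree.n_nodes):
        if i != tree.root:
            total += tree.heights[tree.parent[i]] - tree.heights[i]
    return float(h), float(total)
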
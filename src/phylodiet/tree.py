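"""Rooted phylogenetic trees: I/O, covariance construction, branch-length schemes.

The tree model here is deliberately minimal: a rooted tree of ``Node`` objects
with ordered children, so that preorder/postorder traversals are deterministic
given the order in which the tree was read.  Parsing and serialisation of
Newick and NEXUS (including TRANSLATE blocks) are delegated to dendropy; the
comparative algorithms in the rest of the package traverse this structure
directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterator, Sequence

import dendropy
import numpy as np

__all__ = [
    "Node",
    "PhyloTree",
    "TreeSet",
    "CovarianceMatrix",
    "TreeError",
    "parse_newick",
    "write_newick",
    "vcv_matrix",
    "transform_branch_lengths",
    "clade_tipsets",
    "read_treeset",
    "BRANCH_LENGTH_SCHEMES",
]


class TreeError(ValueError):
    """Raised for malformed or invalid trees."""


class Node:
    """A node in a rooted tree; tips carry labels, edges carry lengths."""

    __slots__ = ("label", "length", "parent", "children")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.length = length
        self.parent: Node | None = None
        self.children: list[Node] = []

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover
        kind = "tip" if self.is_tip else f"internal({len(self.children)})"
        return f"<Node {self.label or ''} {kind}>"


class PhyloTree:
    """A rooted tree with unique tip labels and deterministic traversal order."""

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    # -- construction / validation -------------------------------------------------

    def _validate(self) -> None:
        labels = [t.label for t in self.tips()]
        if any(lbl is None or lbl == "" for lbl in labels):
            raise TreeError("every tip must carry a label")
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise TreeError(f"duplicate tip labels: {sorted(dupes)}")
        for node in self.preorder():
            if node is not self.root and node.length is not None:
                if not math.isfinite(node.length) or node.length < 0:
                    raise TreeError(
                        f"branch length above {node.label or 'internal node'} "
                        f"must be finite and >= 0, got {node.length}"
                    )

    # -- traversal -----------------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def tips(self) -> Iterator[Node]:
        return (n for n in self.preorder() if n.is_tip)

    def internals(self) -> Iterator[Node]:
        return (n for n in self.preorder() if not n.is_tip)

    # -- properties ----------------------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tips())

    @property
    def is_bifurcating(self) -> bool:
        return all(len(n.children) == 2 for n in self.internals())

    def has_branch_lengths(self) -> bool:
        return all(
            n.length is not None for n in self.preorder() if n is not self.root
        )

    def require_bifurcating(self, context: str = "this operation") -> None:
        bad = [n for n in self.internals() if len(n.children) != 2]
        if bad:
            raise TreeError(
                f"{context} requires a fully bifurcating tree; found "
                f"{len(bad)} node(s) with != 2 children (polytomies are not "
                "resolved silently)"
            )

    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.length)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return PhyloTree(clone(self.root))

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path lengths."""
        depth: dict[Node, float] = {self.root: 0.0}
        out: dict[str, float] = {}
        for node in self.preorder():
            if node is not self.root:
                depth[node] = depth[node.parent] + (node.length or 0.0)
            if node.is_tip:
                out[node.label] = depth[node]
        return out

    def max_depth(self) -> float:
        return max(self.tip_depths().values())

    def scale_branch_lengths(self, factor: float) -> "PhyloTree":
        new = self.copy()
        for node in new.preorder():
            if node is not new.root and node.length is not None:
                node.length *= factor
        return new

    # -- dendropy bridge -----------------------------------------------------------

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "PhyloTree":
        def convert(dnode) -> Node:
            label = None
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            node = Node(label=label, length=dnode.edge.length)
            for dchild in dnode.child_nodes():
                node.add_child(convert(dchild))
            return node

        return cls(convert(dtree.seed_node))

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=taxa)

        def build(node: Node, dnode) -> None:
            if node.is_tip:
                dnode.taxon = taxa.require_taxon(label=node.label)
            elif node.label:
                dnode.label = node.label
            dnode.edge.length = node.length
            for child in node.children:
                build(child, dnode.new_child())

        build(self.root, dtree.seed_node)
        return dtree

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree with {self.n_tips} tips>"


@dataclass
class TreeSet:
    """An ordered collection of trees sharing one tip-label set."""

    trees: list[PhyloTree]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.trees:
            raise TreeError("a TreeSet must contain at least one tree")
        ref = set(self.trees[0].tip_labels)
        for i, t in enumerate(self.trees[1:], start=1):
            if set(t.tip_labels) != ref:
                missing = ref ^ set(t.tip_labels)
                raise TreeError(
                    f"tree {i} has a different tip-label set "
                    f"(symmetric difference: {sorted(missing)})"
                )

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[PhyloTree]:
        return iter(self.trees)


@dataclass
class CovarianceMatrix:
    """Brownian-motion phylogenetic covariance: entry (i, j) is the shared
    root-to-MRCA path length of tips i and j, in branch-length units."""

    labels: list[str]
    values: np.ndarray

    def reorder(self, labels: Sequence[str]) -> "CovarianceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return CovarianceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("labels/matrix shape mismatch")


# -------------------------------------------------------------------------------
# Parsing and writing
# -------------------------------------------------------------------------------


def parse_newick(text: str) -> PhyloTree:
    """Parse a single Newick string into a :class:`PhyloTree`.

    Raises :class:`TreeError` with the offending location for malformed input
    and for duplicate tip labels.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise TreeError(f"malformed Newick: {exc}") from exc
    return PhyloTree.from_dendropy(dtree)


def write_newick(tree: PhyloTree) -> str:
    """Serialise to a Newick string (branch lengths as ``:`` reals)."""

    def fmt(node: Node) -> str:
        if node.is_tip:
            core = node.label
        else:
            core = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.label:
                core += node.label
        if node.length is not None:
            core += f":{node.length:g}"
        return core

    return fmt(tree.root) + ";"


def read_treeset(path: str, format: str = "newick") -> TreeSet:
    """Read a file of one or more trees (Newick list or NEXUS TREES block).

    NEXUS TRANSLATE blocks are resolved to full tip labels.  All trees must
    share the same tip-label set.
    """
    if format not in ("newick", "nexus"):
        raise ValueError(f"unknown tree format {format!r}")
    try:
        dlist = dendropy.TreeList.get(
            path=path, schema=format, preserve_underscores=True
        )
    except Exception as exc:
        raise TreeError(f"could not read tree file {path}: {exc}") from exc
    trees = [PhyloTree.from_dendropy(t) for t in dlist]
    return TreeSet(trees=trees, source=str(path))


# -------------------------------------------------------------------------------
# Covariance
# -------------------------------------------------------------------------------


def vcv_matrix(tree: PhyloTree) -> CovarianceMatrix:
    """Phylogenetic variance-covariance matrix under Brownian motion.

    C[i, j] = summed branch lengths from the root to MRCA(i, j); the diagonal
    is the root-to-tip distance.
    """
    if not tree.has_branch_lengths():
        raise TreeError("vcv_matrix requires branch lengths on every edge")
    labels = tree.tip_labels
    index = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))

    depth: dict[Node, float] = {tree.root: 0.0}
    for node in tree.preorder():
        if node is not tree.root:
            depth[node] = depth[node.parent] + node.length

    # Postorder: at each internal node of depth d, tip pairs whose MRCA is
    # that node (one tip per distinct child subtree) share covariance d.
    tipsets: dict[Node, list[int]] = {}
    for node in tree.postorder():
        if node.is_tip:
            i = index[node.label]
            tipsets[node] = [i]
            C[i, i] = depth[node]
        else:
            child_sets = [tipsets.pop(c) for c in node.children]
            d = depth[node]
            for a in range(len(child_sets)):
                for b in range(a + 1, len(child_sets)):
                    for i in child_sets[a]:
                        for j in child_sets[b]:
                            C[i, j] = C[j, i] = d
            tipsets[node] = [i for s in child_sets for i in s]
    return CovarianceMatrix(labels, C)


# -------------------------------------------------------------------------------
# Branch-length schemes
# -------------------------------------------------------------------------------


def _height_transform(tree: PhyloTree, height: Callable[[Node, int], float]) -> PhyloTree:
    """Assign node heights (tips at 0) and set each branch to h(parent)-h(child)."""
    new = tree.copy()
    ntips: dict[Node, int] = {}
    heights: dict[Node, float] = {}
    for node in new.postorder():
        if node.is_tip:
            ntips[node] = 1
            heights[node] = 0.0
        else:
            ntips[node] = sum(ntips[c] for c in node.children)
            heights[node] = height(node, ntips[node])
    for node in new.preorder():
        if node is new.root:
            node.length = None
        else:
            bl = heights[node.parent] - heights[node]
            assert bl >= 0, "height scheme produced a negative branch"
            node.length = bl
    return new


def _unity(tree: PhyloTree) -> PhyloTree:
    new = tree.copy()
    for node in new.preorder():
        node.length = None if node is new.root else 1.0
    return new


def _pagel(tree: PhyloTree) -> PhyloTree:
    # node height = 1 + max internode count to any descendant tip;
    # _height_transform calls this in postorder, so children are already done
    heights: dict[Node, float] = {}

    def height(node: Node, ntips: int) -> float:
        val = 1.0 + max(heights.get(c, 0.0) for c in node.children)
        heights[node] = val
        return val

    return _height_transform(tree, height)


def _grafen(tree: PhyloTree) -> PhyloTree:
    return _height_transform(tree, lambda node, ntips: float(ntips - 1))


def _nee(tree: PhyloTree, log: Callable[[float], float] = math.log) -> PhyloTree:
    return _height_transform(tree, lambda node, ntips: log(ntips))


BRANCH_LENGTH_SCHEMES = {
    "unity": _unity,
    "pagel_unit_internodes": _pagel,
    "grafen_tips_minus_one": _grafen,
    "nee_log_tips": _nee,
}


def transform_branch_lengths(
    tree: PhyloTree, method: str, log_base: float | None = None
) -> PhyloTree:
    """Replace branch lengths with one of four arbitrary schemes.

    ``unity``
        every branch length set to 1.0 (speciational model);
    ``pagel_unit_internodes``
        contemporaneous tips, node height = max internode count to a tip;
    ``grafen_tips_minus_one``
        contemporaneous tips, node height = number of descendant tips - 1;
    ``nee_log_tips``
        contemporaneous tips, node height = log of number of descendant tips
        (natural log by default; pass ``log_base`` to change).
    """
    if method not in BRANCH_LENGTH_SCHEMES:
        raise ValueError(
            f"unknown branch-length scheme {method!r}; choose one of "
            f"{sorted(BRANCH_LENGTH_SCHEMES)}"
        )
    if method == "nee_log_tips" and log_base is not None:
        return _nee(tree, lambda x: math.log(x, log_base))
    return BRANCH_LENGTH_SCHEMES[method](tree)


# -------------------------------------------------------------------------------
# Clade tipsets
# -------------------------------------------------------------------------------


def clade_tipsets(tree: PhyloTree) -> dict[Node, frozenset[str]]:
    """Map each internal node to the frozenset of its descendant tip labels.

    These sets are the node identities used when matching ancestral nodes
    across a set of alternative trees.
    """
    sets: dict[Node, frozenset[str]] = {}
    acc: dict[Node, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_tip:
            acc[node] = frozenset([node.label])
        else:
            merged = frozenset().union(*(acc.pop(c) for c in node.children))
            acc[node] = merged
            sets[node] = merged
    return sets
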
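"""Rooted tree representation, Newick I/O and tree-shape covariates.

Trees here are rooted, leaf-labelled and may contain polytomies.  Branch
lengths are parsed and carried along but are ignored by every congruence
metric (parsimony fit is purely topological); node ages in Ma are optional
and used only by the simulator and the stratigraphic metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import dendropy


class TreeError(ValueError):
    """Raised for malformed or degenerate tree input."""


class Node:
    """A single tree node with parent/children links.

    Leaves carry a non-empty ``label``; internal nodes have ``label`` None.
    ``age`` (Ma before present) is optional.
    """

    __slots__ = ("label", "children", "parent", "age", "length")

    def __init__(self, label: Optional[str] = None, age: Optional[float] = None,
                 length: Optional[float] = None):
        self.label = label
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.age = age
        self.length = length

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover
        return f"Node({self.label!r})" if self.is_leaf else f"Node(<{len(self.children)} children>)"


class PhyloTree:
    """A rooted, possibly multifurcating, leaf-labelled phylogenetic tree.

    Invariants (checked by :meth:`validate`): exactly one root; every
    internal node has at least two children; leaf labels are unique and
    non-empty; if node ages are present, a parent is never younger than
    any of its children.
    """

    def __init__(self, root: Node):
        self.root = root
        self.validate()

    # -- traversal ---------------------------------------------------------

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

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_leaf]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        labels = []
        for node in self.preorder():
            if node is not self.root and node.parent is None:
                raise TreeError("non-root node without a parent")
            if node.is_leaf:
                if not node.label:
                    raise TreeError("leaf with empty label")
                labels.append(node.label)
            elif len(node.children) < 2:
                raise TreeError(
                    f"internal node with {len(node.children)} child(ren); "
                    "unifurcations are not allowed"
                )
            if node.age is not None:
                for child in node.children:
                    if child.age is not None and node.age < child.age - 1e-9:
                        raise TreeError("parent age younger than child age")
        if len(labels) != len(set(labels)):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise TreeError(f"duplicate leaf labels: {dupes}")

    # -- structure helpers -------------------------------------------------

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions as frozensets of leaf labels (the
        smaller-side-free convention: each internal edge is identified by
        the leaf set below it)."""
        all_leaves = frozenset(self.leaf_labels)
        bips = set()
        for node in self.internal_nodes():
            if node is self.root:
                continue
            below = frozenset(_leafset(node))
            if 1 < len(below) < len(all_leaves):
                bips.add(below)
        return bips

    def copy(self) -> "PhyloTree":
        return PhyloTree(_copy_node(self.root))

    def node_ages(self) -> dict[Node, float]:
        ages = {n: n.age for n in self.preorder() if n.age is not None}
        if len(ages) != sum(1 for _ in self.preorder()):
            raise TreeError("tree is not fully dated")
        return ages

    # -- I/O ---------------------------------------------------------------

    def to_newick(self) -> str:
        return _write_node(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree({self.n_leaves} leaves)"


def _leafset(node: Node) -> list[str]:
    return [n.label for n in _subtree_preorder(node) if n.is_leaf]


def _subtree_preorder(node: Node) -> Iterator[Node]:
    stack = [node]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)


def _copy_node(node: Node) -> Node:
    new = Node(node.label, node.age, node.length)
    for child in node.children:
        new.add_child(_copy_node(child))
    return new


def _write_node(node: Node) -> str:
    if node.is_leaf:
        label = node.label
        if any(c in label for c in " \t();,:'"):
            label = "'" + label.replace("'", "''") + "'"
        out = label
    else:
        out = "(" + ",".join(_write_node(c) for c in node.children) + ")"
    if node.length is not None:
        out += f":{node.length:g}"
    return out


def parse_newick(text: str) -> PhyloTree:
    """Parse a rooted Newick string into a :class:`PhyloTree`.

    Branch lengths are retained but unused downstream.  Malformed input
    raises :class:`TreeError` with the parser's position diagnostics;
    duplicate or empty leaf labels fail validation.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"Newick parse error: {exc}") from exc

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else None
            node = Node(label=label, length=dnode.edge.length)
        else:
            node = Node(length=dnode.edge.length)
            for dchild in dnode.child_nodes():
                node.add_child(convert(dchild))
        return node

    return PhyloTree(convert(dtree.seed_node))


def prune_to_taxa(tree: PhyloTree, keep: Iterable[str], *,
                  allow_pair: bool = False) -> PhyloTree:
    """Restrict a tree to ``keep`` ∩ leaves, suppressing unifurcations.

    The relative topology of the surviving leaves is preserved.  Fewer
    than three survivors raises ``TreeError("pruned tree degenerate")``
    by default, since a two-leaf rooted tree carries no comparable
    topology; pass ``allow_pair=True`` to permit a two-leaf result.
    """
    keep = set(keep)
    survivors = keep & set(tree.leaf_labels)
    minimum = 2 if allow_pair else 3
    if len(survivors) < minimum:
        raise TreeError(
            f"pruned tree degenerate: only {len(survivors)} leaves would survive"
        )

    def build(node: Node) -> Optional[Node]:
        if node.is_leaf:
            if node.label in survivors:
                return Node(node.label, node.age, node.length)
            return None
        kept = [c for c in (build(ch) for ch in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            # suppress the unifurcation, accumulating branch length
            child = kept[0]
            if node.length is not None and child.length is not None:
                child.length += node.length
            return child
        new = Node(age=node.age, length=node.length)
        for c in kept:
            new.add_child(c)
        return new

    root = build(tree.root)
    root.parent = None
    return PhyloTree(root)


@dataclass(frozen=True)
class TreeShape:
    """Tree-shape covariates used in the comparison layer.

    ``res`` is the proportion of resolved nodes, (number of internal nodes
    excluding the root) / (n − 2): exactly 1 on a fully bifurcating rooted
    tree and 0 on a star tree.  ``colless`` is the normalised Colless
    imbalance, summed |L − R| over bifurcating internal nodes divided by
    (n−1)(n−2)/2; polytomous nodes contribute nothing (the classical index
    has no polytomy extension, and that convention is recorded here).
    """

    n_taxa: int
    res: float
    colless: float
    n_polytomies: int
    polytomy_leaf_count: int
    conventions: dict = field(default_factory=lambda: {
        "res_excludes_root": True,
        "colless_bifurcating_only": True,
    }, compare=False, repr=False)


def tree_shape_metrics(tree: PhyloTree) -> TreeShape:
    """Resolution and Colless balance of a rooted tree with ≥3 leaves."""
    n = tree.n_leaves
    if n < 3:
        raise TreeError("tree shape metrics require at least 3 leaves")

    leafcount: dict[Node, int] = {}
    for node in tree.postorder():
        leafcount[node] = 1 if node.is_leaf else sum(leafcount[c] for c in node.children)

    internal = tree.internal_nodes()
    n_internal_nonroot = sum(1 for nd in internal if nd is not tree.root)
    res = n_internal_nonroot / (n - 2) if n > 2 else 1.0

    colless_sum = 0
    n_polytomies = 0
    polytomy_leaf_count = 0
    for node in internal:
        k = len(node.children)
        if k == 2:
            left, right = (leafcount[c] for c in node.children)
            colless_sum += abs(left - right)
        else:
            n_polytomies += 1
            polytomy_leaf_count += k
    denom = (n - 1) * (n - 2) / 2
    colless = colless_sum / denom if denom > 0 else 0.0

    return TreeShape(
        n_taxa=n,
        res=res,
        colless=colless,
        n_polytomies=n_polytomies,
        polytomy_leaf_count=polytomy_leaf_count,
    )
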
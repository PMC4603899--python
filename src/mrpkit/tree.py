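"""Rooted trees with polytomies: parsing, canonical writing, clade primitives.

Every downstream stage (curation, matrix encoding, parsimony search, consensus,
support scoring) works on :class:`RootedTree`. Trees are rooted, leaf-labelled,
and may contain polytomies; branch lengths and internal node labels are parsed
(via dendropy) and discarded, since the supertree protocol only uses topology.
"""

from __future__ import annotations

import io
import logging
from typing import Iterable, Iterator, Sequence

import dendropy

logger = logging.getLogger(__name__)

__all__ = [
    "TreeError",
    "NewickParseError",
    "DuplicateLeafError",
    "LeafSetMismatchError",
    "TreeNode",
    "RootedTree",
    "parse_newick",
    "write_newick",
    "read_trees",
    "write_trees",
    "clades",
    "restrict",
    "rf_distance",
    "reroot_on_leaf",
]


class TreeError(ValueError):
    """Base class for tree-structure errors."""


class NewickParseError(TreeError):
    """Raised when Newick/NEXUS text cannot be parsed."""


class DuplicateLeafError(TreeError):
    """Raised when a tree carries the same leaf label more than once."""

    def __init__(self, labels: Sequence[str]):
        self.labels = sorted(labels)
        super().__init__(f"duplicate leaf label(s): {', '.join(self.labels)}")


class LeafSetMismatchError(TreeError):
    """Raised when an operation requires identical leaf sets."""

    def __init__(self, only_first: set[str], only_second: set[str]):
        self.only_first = sorted(only_first)
        self.only_second = sorted(only_second)
        super().__init__(
            "leaf sets differ: only in first tree: "
            f"{self.only_first or '-'}; only in second tree: {self.only_second or '-'}"
        )


class TreeNode:
    """A node of a rooted tree: a leaf (label, no children) or internal node."""

    __slots__ = ("label", "children")

    def __init__(self, label: str | None = None, children: list["TreeNode"] | None = None):
        self.label = label
        self.children: list[TreeNode] = children if children is not None else []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_labels(self) -> set[str]:
        """Leaf labels subtended by this node (labels of self if a leaf)."""
        if self.is_leaf:
            return {self.label}
        out: set[str] = set()
        stack = [self]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.add(node.label)
            else:
                stack.extend(node.children)
        return out

    def copy(self) -> "TreeNode":
        if self.is_leaf:
            return TreeNode(self.label)
        return TreeNode(self.label, [c.copy() for c in self.children])

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.label!r})" if self.is_leaf else f"TreeNode(<{len(self.children)} children>)"


def _suppress_unifurcations(node: TreeNode) -> TreeNode:
    """Collapse chains of single-child nodes below (and including) ``node``."""
    while len(node.children) == 1:
        node = node.children[0]
    node.children = [_suppress_unifurcations(c) for c in node.children]
    return node


class RootedTree:
    """A rooted leaf-labelled tree; polytomies allowed, leaf labels unique.

    Unifurcations are suppressed at construction, so every internal node of a
    well-formed tree has at least two children.
    """

    __slots__ = ("root", "_leaves")

    def __init__(self, root: TreeNode):
        self.root = _suppress_unifurcations(root)
        labels: list[str] = [n.label for n in self.iter_nodes() if n.is_leaf]
        if any(lab is None for lab in labels):
            raise TreeError("every leaf must carry a label")
        dupes = {lab for lab in labels if labels.count(lab) > 1}
        if dupes:
            raise DuplicateLeafError(sorted(dupes))
        self._leaves = frozenset(labels)

    # -- basic accessors ---------------------------------------------------

    @property
    def leaves(self) -> frozenset[str]:
        """The set of leaf labels."""
        return self._leaves

    def __len__(self) -> int:
        return len(self._leaves)

    def iter_nodes(self) -> Iterator[TreeNode]:
        """Pre-order traversal of all nodes."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def iter_internal(self, include_root: bool = True) -> Iterator[TreeNode]:
        for node in self.iter_nodes():
            if not node.is_leaf and (include_root or node is not self.root):
                yield node

    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.iter_internal())

    def copy(self) -> "RootedTree":
        return RootedTree(self.root.copy())

    # -- clade primitives --------------------------------------------------

    def clades(self) -> set[frozenset[str]]:
        """Nontrivial clades: leaf sets of internal nodes other than the root."""
        return clades(self)

    def newick(self, underscore_spaces: bool = False) -> str:
        return write_newick(self, underscore_spaces=underscore_spaces)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RootedTree):
            return NotImplemented
        return self.leaves == other.leaves and self.clades() == other.clades()

    def __hash__(self) -> int:
        return hash((self._leaves, frozenset(self.clades())))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        s = write_newick(self)
        return f"RootedTree({s if len(s) < 60 else s[:57] + '...'})"


# ---------------------------------------------------------------------------
# Parsing and writing
# ---------------------------------------------------------------------------


def _from_dendropy(node: dendropy.Node) -> TreeNode:
    if node.is_leaf():
        label = node.taxon.label if node.taxon is not None else node.label
        return TreeNode(label)
    return TreeNode(children=[_from_dendropy(c) for c in node.child_nodes()])


def _convert_dendropy_tree(dtree: dendropy.Tree) -> RootedTree:
    has_lengths = any(e.length is not None for e in dtree.preorder_edge_iter())
    has_internal_labels = any(
        (n.label is not None) or (n.taxon is not None)
        for n in dtree.preorder_node_iter()
        if not n.is_leaf()
    )
    if has_lengths:
        logger.info("branch lengths present in input tree: parsed and discarded")
    if has_internal_labels:
        logger.info("internal node labels present in input tree: parsed and discarded")
    return RootedTree(_from_dendropy(dtree.seed_node))


def parse_newick(text: str) -> RootedTree:
    """Parse a single Newick tree string into a :class:`RootedTree`.

    Underscores in unquoted labels are literal underscores. Branch lengths
    and internal labels are accepted and discarded with a log notice.
    Unifurcations are suppressed.

    Raises
    ------
    NewickParseError
        On malformed input (message names the character position where the
        underlying parser reports one).
    DuplicateLeafError
        If a leaf label occurs more than once.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        msg = str(exc)
        if "Duplicate taxon labels" in msg:
            labels = [w.strip(" ,.'\"") for w in msg.rpartition(":")[2].split()]
            raise DuplicateLeafError(labels or ["<unknown>"]) from exc
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    return _convert_dendropy_tree(dtree)


_SAFE_LABEL_CHARS = set("abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789_.-")


def _format_label(label: str, underscore_spaces: bool) -> str:
    if underscore_spaces and " " in label:
        candidate = label.replace(" ", "_")
        if set(candidate) <= _SAFE_LABEL_CHARS:
            return candidate
    if label and set(label) <= _SAFE_LABEL_CHARS:
        return label
    return "'" + label.replace("'", "''") + "'"


def write_newick(tree: RootedTree, underscore_spaces: bool = False) -> str:
    """Serialise a tree to canonical Newick.

    Children are ordered lexicographically by their smallest contained leaf
    label, so output is byte-reproducible. Labels with characters outside the
    unquoted Newick alphabet are single-quoted; with ``underscore_spaces``
    spaces become underscores instead where that yields a safe label.
    """

    def fmt(node: TreeNode) -> tuple[str, str]:
        # returns (min leaf label, newick fragment)
        if node.is_leaf:
            return node.label, _format_label(node.label, underscore_spaces)
        parts = sorted(fmt(c) for c in node.children)
        return parts[0][0], "(" + ",".join(p[1] for p in parts) + ")"

    return fmt(tree.root)[1] + ";"


def _looks_like_nexus(text: str) -> bool:
    return text.lstrip()[:6].upper() == "#NEXUS"


def read_trees(source: str) -> list[RootedTree]:
    """Read one or more trees from a file path or literal text.

    Accepts multi-tree Newick and NEXUS TREES blocks (translate tables are
    honoured; other NEXUS blocks are ignored with a warning).
    """
    import os

    if os.path.exists(source):
        with open(source) as fh:
            text = fh.read()
    else:
        text = source
    schema = "nexus" if _looks_like_nexus(text) else "newick"
    if schema == "nexus":
        upper = text.upper()
        extra = [
            b for b in ("BEGIN DATA", "BEGIN CHARACTERS", "BEGIN ASSUMPTIONS")
            if b in upper
        ]
        if extra:
            logger.warning("ignoring non-TREES NEXUS blocks: %s", ", ".join(extra))
    try:
        tlist = dendropy.TreeList.get(
            file=io.StringIO(text),
            schema=schema,
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise NewickParseError(f"cannot parse {schema} input: {exc}") from exc
    return [_convert_dendropy_tree(t) for t in tlist]


def write_trees(trees: Iterable[RootedTree], path: str) -> None:
    """Write trees as a multi-tree Newick file, one canonical tree per line."""
    with open(path, "w") as fh:
        for t in trees:
            fh.write(write_newick(t) + "\n")


# ---------------------------------------------------------------------------
# Clade primitives
# ---------------------------------------------------------------------------


def clades(tree: RootedTree) -> set[frozenset[str]]:
    """Nontrivial clades of ``tree``: one per internal node, root excluded.

    Singletons never occur (internal nodes have >= 2 children) and the root's
    full leaf set is excluded, so every returned clade C satisfies
    ``2 <= |C| < |leaves|``.
    """
    out: set[frozenset[str]] = set()
    for node in tree.iter_internal(include_root=False):
        out.add(frozenset(node.leaf_labels()))
    return out


def restrict(tree: RootedTree, keep: Iterable[str]) -> RootedTree:
    """Induced subtree on ``keep`` ∩ leaves, with unifurcations suppressed.

    The clades of the result are exactly the nontrivial intersections of the
    original clades with ``keep``.
    """
    keep = set(keep) & tree.leaves
    if not keep:
        raise TreeError("restriction would remove every leaf")

    def prune(node: TreeNode) -> TreeNode | None:
        if node.is_leaf:
            return TreeNode(node.label) if node.label in keep else None
        kids = [p for p in (prune(c) for c in node.children) if p is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        return TreeNode(children=kids)

    pruned = prune(tree.root)
    assert pruned is not None
    return RootedTree(pruned)


def rf_distance(t1: RootedTree, t2: RootedTree) -> int:
    """Robinson-Foulds distance: symmetric difference of nontrivial clade sets.

    Requires identical leaf sets.
    """
    if t1.leaves != t2.leaves:
        raise LeafSetMismatchError(set(t1.leaves - t2.leaves), set(t2.leaves - t1.leaves))
    return len(t1.clades() ^ t2.clades())


def reroot_on_leaf(tree: RootedTree, leaf: str) -> RootedTree:
    """Reroot ``tree`` (regarded as unrooted) on the edge leading to ``leaf``.

    The result's root has the named leaf as one child and the rest of the
    tree as the other. Fitch length is invariant under this operation.
    """
    if leaf not in tree.leaves:
        raise TreeError(f"leaf {leaf!r} not in tree")
    root = tree.root
    if any(c.is_leaf and c.label == leaf for c in root.children) and len(root.children) == 2:
        return tree.copy()

    work = tree.copy().root
    parent: dict[int, TreeNode | None] = {id(work): None}
    target = None
    for node in _preorder(work):
        for c in node.children:
            parent[id(c)] = node
        if node.is_leaf and node.label == leaf:
            target = node
    assert target is not None

    def rebuild(node: TreeNode, came_from: TreeNode | None) -> TreeNode:
        neighbours = [c for c in node.children if c is not came_from]
        p = parent[id(node)]
        if p is not None and p is not came_from:
            neighbours.append(p)
        rebuilt = [n if (n in node.children and n.is_leaf) else rebuild(n, node)
                   for n in neighbours]
        if node.is_leaf:
            assert not rebuilt
            return TreeNode(node.label)
        if len(rebuilt) == 1:  # old root of degree 2: splice it out
            return rebuilt[0]
        return TreeNode(children=rebuilt)

    anchor = parent[id(target)]
    assert anchor is not None
    new_root = TreeNode(children=[TreeNode(leaf), rebuild(anchor, target)])
    return RootedTree(new_root)


def _preorder(node: TreeNode) -> Iterator[TreeNode]:
    stack = [node]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)
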
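"""Per-node supertree support against the source trees: V and V+ indices.

Every nontrivial supertree clade is scored against each source tree, which is
classified as supporting (the clade, restricted to the source tree's taxa, is
one of its clades), conflicting (some source-tree clade partially overlaps
it), permitting (neither, e.g. compatible via a polytomy), or irrelevant
(fewer than two clade members, or no outside taxon, in the source tree).
With counts s (support), q (conflict), p (permit):

    V  = (s - q) / (s + q)            defined iff s + q > 0
    V+ = (s + p - q) / (s + p + q)    defined iff s + p + q > 0

Both range over [-1, 1]; V+ >= V wherever both are defined. Counts are per
source tree and unweighted: the independence weights used in the parsimony
analysis do not enter support scoring. Nodes no source tree can evaluate are
reported as undefined, never as 0.

A "novel clade" is a supertree clade relevant to at least one source tree yet
supported by none — a known artefact of MRP worth flagging.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import pandas as pd

from .curation import Dataset, SourceTreeRecord
from .tree import RootedTree, TreeNode, restrict
from .tree import _format_label

__all__ = ["NodeSupport", "classify_source_tree", "v_indices", "novel_clades",
           "support_table", "annotated_newick", "v_category"]

SUPPORT = "support"
CONFLICT = "conflict"
PERMIT = "permit"
IRRELEVANT = "irrelevant"


@dataclass(frozen=True)
class NodeSupport:
    """Support/conflict/permit/irrelevant counts and V, V+ for one node."""

    clade: frozenset[str]
    s: int
    q: int
    p: int
    r: int

    @property
    def V(self) -> Fraction | None:
        if self.s + self.q == 0:
            return None
        return Fraction(self.s - self.q, self.s + self.q)

    @property
    def V_plus(self) -> Fraction | None:
        if self.s + self.p + self.q == 0:
            return None
        return Fraction(self.s + self.p - self.q, self.s + self.p + self.q)

    @property
    def n_trees(self) -> int:
        return self.s + self.q + self.p + self.r

    @property
    def is_novel(self) -> bool:
        return self.s == 0 and (self.q + self.p) >= 1


def classify_source_tree(node: frozenset[str], record: SourceTreeRecord,
                         universe: frozenset[str] | None = None) -> str:
    """Classify one source tree against one supertree clade.

    With A = clade members present in the source tree and B = the source
    tree's other (considered) taxa: the tree is irrelevant if |A| < 2 or
    |B| < 1; it supports the node if A is one of its clades; it conflicts if
    one of its clades X straddles A (A∩X, A\\X and X\\A all nonempty);
    otherwise it permits the node.

    ``universe`` restricts the comparison to a shared taxon set (the
    supertree's leaves): the source tree is pruned to ``universe`` before
    its clades are read. Without it taxa absent from the supertree would
    straddle every large node and register spurious conflict. ``None``
    compares against the full source tree.
    """
    taxa = record.taxa if universe is None else record.taxa & universe
    a = node & taxa
    if len(a) < 2 or len(taxa - node) < 1:
        return IRRELEVANT
    if universe is None or taxa == record.taxa:
        tree_clades = record.tree.clades()
    else:
        tree_clades = restrict(record.tree, taxa).clades()
    return _classify_against_clades(a, tree_clades)


def _classify_against_clades(a: frozenset[str], tree_clades) -> str:
    if a in tree_clades:
        return SUPPORT
    for x in tree_clades:
        if (a & x) and (a - x) and (x - a):
            return CONFLICT
    return PERMIT


def v_indices(supertree: RootedTree, dataset: Dataset,
              outgroup: str | None = None) -> list[NodeSupport]:
    """Score every nontrivial supertree clade against all source trees.

    The synthetic outgroup (if named and present) is removed from the
    supertree first. Each source tree is compared on the taxa it shares with
    the supertree (it is pruned to the supertree's leaf set before its
    clades are read), so taxa the consensus dropped cannot register
    spurious conflict. Nodes are returned in decreasing clade size, then by
    name, so output order is deterministic.
    """
    if outgroup is not None and outgroup in supertree.leaves:
        supertree = restrict(supertree, supertree.leaves - {outgroup})
    universe = supertree.leaves
    # prune every source tree to the shared taxon set once
    shared: list[tuple[frozenset[str], set[frozenset[str]]]] = []
    for rec in dataset.records:
        common = rec.taxa & universe
        if len(common) == len(rec.taxa):
            shared.append((common, rec.tree.clades()))
        elif len(common) >= 2:
            shared.append((common, restrict(rec.tree, common).clades()))
        else:
            shared.append((common, set()))
    out = []
    for clade in sorted(supertree.clades(), key=lambda c: (-len(c), sorted(c))):
        counts = {SUPPORT: 0, CONFLICT: 0, PERMIT: 0, IRRELEVANT: 0}
        for common, tree_clades in shared:
            a = clade & common
            if len(a) < 2 or len(common - clade) < 1:
                counts[IRRELEVANT] += 1
            else:
                counts[_classify_against_clades(a, tree_clades)] += 1
        out.append(NodeSupport(clade, counts[SUPPORT], counts[CONFLICT],
                               counts[PERMIT], counts[IRRELEVANT]))
    return out


def novel_clades(supertree: RootedTree, dataset: Dataset,
                 outgroup: str | None = None) -> list[frozenset[str]]:
    """Supertree clades supported by no source tree yet relevant to at least
    one (s = 0 and q + p >= 1). Clades irrelevant to every source tree are
    not novel: no tree could have contained them."""
    return [ns.clade for ns in v_indices(supertree, dataset, outgroup) if ns.is_novel]


def v_category(ns: NodeSupport) -> str:
    """Colour-class of a node by its V value: 'full' (V = 1), 'partial'
    (0 < V < 1), 'zero' (V = 0, i.e. s = q > 0), 'negative' (V < 0), or
    'undefined' (no source tree supports or conflicts)."""
    v = ns.V
    if v is None:
        return "undefined"
    if v == 1:
        return "full"
    if v > 0:
        return "partial"
    if v == 0:
        return "zero"
    return "negative"


def support_table(supports: list[NodeSupport]) -> pd.DataFrame:
    """Per-node table: clade members, s/q/p/r counts, V, V+ (empty where
    undefined) and the V colour class."""
    rows = []
    for ns in supports:
        rows.append({
            "clade": ";".join(sorted(ns.clade)),
            "size": len(ns.clade),
            "s": ns.s, "q": ns.q, "p": ns.p, "r": ns.r,
            "V": float(ns.V) if ns.V is not None else None,
            "V_plus": float(ns.V_plus) if ns.V_plus is not None else None,
            "category": v_category(ns),
        })
    return pd.DataFrame(rows, columns=["clade", "size", "s", "q", "p", "r",
                                       "V", "V_plus", "category"])


def annotated_newick(supertree: RootedTree, supports: list[NodeSupport],
                     outgroup: str | None = None) -> str:
    """Newick string with V values as internal node labels (canonical child
    order; nodes with undefined V are labelled 'NA')."""
    if outgroup is not None and outgroup in supertree.leaves:
        supertree = restrict(supertree, supertree.leaves - {outgroup})
    labels = {}
    for ns in supports:
        labels[ns.clade] = "NA" if ns.V is None else f"{float(ns.V):g}"

    def fmt(node: TreeNode) -> tuple[str, str]:
        if node.is_leaf:
            return node.label, _format_label(node.label, underscore_spaces=False)
        parts = sorted(fmt(c) for c in node.children)
        body = "(" + ",".join(p[1] for p in parts) + ")"
        clade = frozenset(node.leaf_labels())
        return parts[0][0], body + labels.get(clade, "")

    return fmt(supertree.root)[1] + ";"
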
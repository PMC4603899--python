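"""Summaries of most-parsimonious-tree sets: strict consensus and MAST.

The Maximum Agreement Subtree (MAST) of a tree set is the largest leaf
subset on which every tree induces the same topology; it is the summary used
for the supertree itself, discarding taxa that wander between equally
parsimonious placements. The pairwise rooted MAST is exact (dynamic
programming over node pairs); for more than two trees the problem is
NP-hard, so beyond a configurable exact limit an iterated-pairwise heuristic
is used and its result verified to be a genuine agreement set.
"""

from __future__ import annotations

import itertools
import logging
import random
from dataclasses import dataclass

from .tree import (LeafSetMismatchError, RootedTree, TreeNode, restrict,
                   rf_distance, write_newick)

logger = logging.getLogger(__name__)

__all__ = ["AgreementResult", "MastVerificationError", "strict_consensus",
           "mast_pair", "mast_k", "drop_taxon", "tree_from_clades"]


class MastVerificationError(RuntimeError):
    """The heuristic produced a set that is not an agreement set (a bug)."""


@dataclass(frozen=True)
class AgreementResult:
    """An agreement subtree: restricting any input tree to ``leafset`` gives
    ``tree``. ``is_exact`` records whether the exact or heuristic path ran."""

    leafset: frozenset[str]
    tree: RootedTree
    is_exact: bool

    @property
    def size(self) -> int:
        return len(self.leafset)


def _require_same_leaves(trees: list[RootedTree]) -> frozenset[str]:
    leaves = trees[0].leaves
    for t in trees[1:]:
        if t.leaves != leaves:
            raise LeafSetMismatchError(set(leaves - t.leaves), set(t.leaves - leaves))
    return leaves


def tree_from_clades(leaves: frozenset[str],
                     clade_sets: set[frozenset[str]]) -> RootedTree:
    """Build the rooted tree realising a nested (pairwise compatible) set of
    nontrivial clades on ``leaves``."""

    def build(leafset: frozenset[str], available: list[frozenset[str]]) -> TreeNode:
        inner = [c for c in available if c < leafset]
        maximal = [c for c in inner if not any(c < d for d in inner)]
        covered: set[str] = set().union(*maximal) if maximal else set()
        children = [build(c, inner) for c in maximal]
        children += [TreeNode(l) for l in sorted(leafset - covered)]
        if len(children) == 1:
            return children[0]
        return TreeNode(children=children)

    if len(leaves) == 1:
        return RootedTree(TreeNode(next(iter(leaves))))
    return RootedTree(build(leaves, list(clade_sets)))


def strict_consensus(trees: list[RootedTree]) -> RootedTree:
    """The tree containing exactly the clades present in every input tree."""
    if not trees:
        raise ValueError("strict consensus of an empty tree set")
    leaves = _require_same_leaves(list(trees))
    common = set.intersection(*(t.clades() for t in trees)) if len(trees) > 1 \
        else trees[0].clades()
    return tree_from_clades(leaves, common)


# ---------------------------------------------------------------------------
# Pairwise rooted MAST (exact DP)
# ---------------------------------------------------------------------------


def _better(a: tuple[int, tuple[str, ...]], b: tuple[int, tuple[str, ...]]):
    """Prefer larger agreement sets; break ties by the lexicographically
    smallest sorted taxon-name tuple."""
    if a[0] != b[0]:
        return a if a[0] > b[0] else b
    return a if a[1] <= b[1] else b


def mast_pair(t1: RootedTree, t2: RootedTree) -> AgreementResult:
    """Exact rooted MAST of two binary trees on the same leaf set.

    Dynamic programming over node pairs: an optimal agreement set at
    (u, v) either matches the children of u against the children of v
    (in either pairing) or descends into one child. Ties are broken toward
    the lexicographically smallest taxon-name set, making the result
    deterministic and symmetric in its arguments.
    """
    _require_same_leaves([t1, t2])
    for name, t in (("first", t1), ("second", t2)):
        if not t.is_binary():
            raise ValueError(f"{name} tree is not binary; MAST DP requires binary trees")

    nodes1 = list(t1.iter_nodes())
    nodes2 = list(t2.iter_nodes())
    idx1 = {id(n): i for i, n in enumerate(nodes1)}
    idx2 = {id(n): i for i, n in enumerate(nodes2)}
    leaves2 = [frozenset(n.leaf_labels()) for n in nodes2]
    leaves1 = [frozenset(n.leaf_labels()) for n in nodes1]

    memo: dict[tuple[int, int], tuple[int, tuple[str, ...]]] = {}

    def best(u: TreeNode, v: TreeNode) -> tuple[int, tuple[str, ...]]:
        key = (idx1[id(u)], idx2[id(v)])
        if key in memo:
            return memo[key]
        if u.is_leaf:
            res = (1, (u.label,)) if u.label in leaves2[idx2[id(v)]] else (0, ())
        elif v.is_leaf:
            res = (1, (v.label,)) if v.label in leaves1[idx1[id(u)]] else (0, ())
        else:
            u1, u2 = u.children
            v1, v2 = v.children
            res = (0, ())
            for a, b in ((u1, v), (u2, v), (u, v1), (u, v2)):
                res = _better(res, best(a, b))
            for (a1, b1), (a2, b2) in (((u1, v1), (u2, v2)), ((u1, v2), (u2, v1))):
                s1, s2 = best(a1, b1), best(a2, b2)
                merged = tuple(sorted(s1[1] + s2[1]))
                res = _better(res, (s1[0] + s2[0], merged))
        memo[key] = res
        return res

    size, names = best(t1.root, t2.root)
    leafset = frozenset(names)
    assert size == len(leafset) >= 2
    tree = restrict(t1, leafset)
    assert rf_distance(tree, restrict(t2, leafset)) == 0
    return AgreementResult(leafset, tree, True)


# ---------------------------------------------------------------------------
# k-tree MAST
# ---------------------------------------------------------------------------


def _is_agreement_set(trees: list[RootedTree], leafset: frozenset[str]) -> bool:
    if len(leafset) < 2:
        return False
    first = restrict(trees[0], leafset)
    return all(rf_distance(first, restrict(t, leafset)) == 0 for t in trees[1:])


def mast_k(trees: list[RootedTree], exact_limit: int = 8,
           max_trees: int | None = None, seed: int = 0) -> AgreementResult:
    """MAST of two or more trees on a shared leaf set.

    With at most ``exact_limit`` leaves the search is exact: leaf subsets are
    tried in order of decreasing size (lexicographic within a size), so the
    result is the maximum-size agreement set with the smallest name set.
    Otherwise the heuristic iterates :func:`mast_pair` over the trees in
    input order, restricting as it goes, and verifies that the final set is
    an agreement set for every input. If ``max_trees`` is given and exceeded,
    the tree set is subsampled uniformly with the fixed ``seed`` (logged).
    """
    trees = list(trees)
    if len(trees) < 2:
        raise ValueError("mast_k requires at least two trees")
    leaves = _require_same_leaves(trees)

    if max_trees is not None and len(trees) > max_trees:
        rng = random.Random(seed)
        trees = [trees[i] for i in sorted(rng.sample(range(len(trees)), max_trees))]
        logger.info("mast_k: subsampled %d of %d trees (seed=%d)",
                    max_trees, len(trees), seed)

    if len(leaves) <= exact_limit:
        ordered = sorted(leaves)
        for size in range(len(ordered), 1, -1):
            for combo in itertools.combinations(ordered, size):
                ls = frozenset(combo)
                if _is_agreement_set(trees, ls):
                    return AgreementResult(ls, restrict(trees[0], ls), True)
        raise MastVerificationError("no agreement set of size >= 2 exists")

    current = trees[0]
    for t in trees[1:]:
        current = mast_pair(current, restrict(t, current.leaves)).tree
    leafset = frozenset(current.leaves)
    if not _is_agreement_set(trees, leafset):
        raise MastVerificationError(
            "heuristic MAST produced a non-agreement set; please report this bug"
        )
    return AgreementResult(leafset, current, False)


def drop_taxon(trees: list[RootedTree], taxon: str) -> list[RootedTree]:
    """Restrict every tree to its leaves minus ``taxon`` (used to strip the
    synthetic outgroup before consensus and support scoring)."""
    out = []
    for t in trees:
        out.append(restrict(t, t.leaves - {taxon}) if taxon in t.leaves else t)
    return out
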
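"""Weighted Fitch parsimony scoring and supertree search over MRP matrices.

The scorer packs every character into two bits of a Python integer (state 0,
state 1, or both for "?"), grouped by character weight, so one Fitch merge is
a handful of bitwise operations regardless of matrix width. The heuristic
search follows standard practice: random-addition-sequence starting trees,
then SPR branch swapping to local optimality, then TBR; equal-length trees
found on the final plateau are retained. An exact branch-and-bound search
(taxon addition with partial-length pruning) serves as the small-instance
oracle.

All lengths are exact rationals: character weights are scaled to integers by
the LCM of their denominators and divided back out at the end, so length
comparisons never touch floating point.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Iterator

from .mrp import MISSING, MRPMatrix
from .tree import RootedTree, TreeNode, reroot_on_leaf, write_newick

__all__ = ["SearchResult", "TooManyTaxaError", "fitch_length", "heuristic_search",
           "branch_and_bound"]


class TooManyTaxaError(ValueError):
    """Raised when an exact search is asked for more taxa than it can handle."""


@dataclass(frozen=True)
class SearchResult:
    """Outcome of a parsimony search.

    ``mpts`` holds distinct minimum-length binary trees (up to the configured
    cap), each rooted on the synthetic outgroup; distinctness is judged on
    the outgroup-rooted topology, so rerootings of one unrooted tree are not
    counted repeatedly.
    """

    best_length: Fraction
    mpts: tuple[RootedTree, ...]
    replicates_run: int
    seed: int

    @property
    def n_mpts(self) -> int:
        return len(self.mpts)


# ---------------------------------------------------------------------------
# Fitch scoring
# ---------------------------------------------------------------------------


class _Scorer:
    """Bit-packed weighted Fitch scorer for a fixed matrix.

    Characters sharing a weight are packed into one big integer, two bits per
    character: 0 -> 01, 1 -> 10, ? -> 11. A Fitch merge intersects the packed
    state sets; characters whose intersection is empty contribute one change
    and take the union instead.
    """

    def __init__(self, matrix: MRPMatrix):
        int_weights, self.scale = matrix.integer_weights()
        groups: dict[int, list[int]] = {}
        for j, w in enumerate(int_weights):
            groups.setdefault(w, []).append(j)
        self.group_weights = sorted(groups)
        self.masks = []  # per group: ...010101 over its characters
        self.leaf_states: dict[str, tuple[int, ...]] = {t: () for t in matrix.taxa}
        for w in self.group_weights:
            chars = groups[w]
            self.masks.append(int("01" * len(chars), 2) if chars else 0)
            for i, t in enumerate(matrix.taxa):
                packed = 0
                for j in chars:
                    v = matrix.data[i, j]
                    bits = 0b11 if v == MISSING else (0b10 if v == 1 else 0b01)
                    packed = (packed << 2) | bits
                self.leaf_states[t] = self.leaf_states[t] + (packed,)
        self.taxa = set(matrix.taxa)

    def score_scaled(self, root: TreeNode) -> int:
        """Total weighted changes, scaled by the integer weight factor."""
        total = 0
        masks, weights = self.masks, self.group_weights

        def rec(node: TreeNode) -> tuple[int, ...]:
            nonlocal total
            if node.is_leaf:
                return self.leaf_states[node.label]
            it = iter(node.children)
            acc = list(rec(next(it)))
            for child in it:
                s = rec(child)
                for g in range(len(acc)):
                    a, b = acc[g], s[g]
                    inter = a & b
                    occ = (inter | (inter >> 1)) & masks[g]
                    z = occ ^ masks[g]  # low bit set where the field is empty
                    if z:
                        total += weights[g] * z.bit_count()
                        acc[g] = inter | ((a | b) & (z | (z << 1)))
                    else:
                        acc[g] = inter
            return tuple(acc)

        rec(root)
        return total

    def length(self, root: TreeNode) -> Fraction:
        return Fraction(self.score_scaled(root), self.scale)


def fitch_length(tree: RootedTree, matrix: MRPMatrix) -> Fraction:
    """Weighted Fitch length of ``tree`` against ``matrix``.

    "?" entries behave as the full state set {0, 1}. The length is invariant
    to rerooting and to child order. Polytomies are scored by sequential
    Fitch folding of the children (for binary trees this is exact Fitch).
    """
    if tree.leaves != set(matrix.taxa):
        missing = sorted(set(matrix.taxa) - tree.leaves)
        extra = sorted(tree.leaves - set(matrix.taxa))
        raise ValueError(
            f"tree/matrix taxa differ: missing from tree {missing or '-'}, "
            f"absent from matrix {extra or '-'}"
        )
    return _Scorer(matrix).length(tree.root)


# ---------------------------------------------------------------------------
# Tree-move machinery (private)
# ---------------------------------------------------------------------------


def _preorder_nodes(root: TreeNode) -> list[TreeNode]:
    out, stack = [], [root]
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(reversed(n.children))
    return out


def _parent_map(root: TreeNode) -> dict[int, TreeNode | None]:
    pm: dict[int, TreeNode | None] = {id(root): None}
    for n in _preorder_nodes(root):
        for c in n.children:
            pm[id(c)] = n
    return pm


def _detach(root: TreeNode, target: TreeNode, pm: dict[int, TreeNode | None]) -> TreeNode:
    """Remove ``target``'s subtree; return the (unifurcation-suppressed) root
    of what remains. Mutates the structure."""
    parent = pm[id(target)]
    assert parent is not None
    parent.children.remove(target)
    if len(parent.children) == 1:
        only = parent.children[0]
        gp = pm[id(parent)]
        if gp is None:
            return only
        gp.children[gp.children.index(parent)] = only
        pm[id(only)] = gp
    return root


def _attach_at(root: TreeNode, position: int | None, subtree: TreeNode) -> TreeNode:
    """Attach ``subtree`` at a regraft position of (a fresh copy of) ``root``.

    ``position``: pre-order index of an existing node whose parent edge is
    split, or None for a new root above the current one. Mutates ``root``.
    """
    if position is None:
        return TreeNode(children=[root, subtree])
    nodes = _preorder_nodes(root)
    target = nodes[position]
    pm = _parent_map(root)
    parent = pm[id(target)]
    assert parent is not None
    joint = TreeNode(children=[target, subtree])
    parent.children[parent.children.index(target)] = joint
    return root


def _regraft_positions(root: TreeNode) -> list[int | None]:
    # every non-root node's parent edge, plus a new root
    return [None] + list(range(1, len(_preorder_nodes(root))))


def _all_rootings(root: TreeNode) -> list[TreeNode]:
    """All rootings of the subtree regarded as unrooted (fresh copies),
    deduplicated by topology. Includes the original rooting."""
    leaves = root.leaf_labels()
    if len(leaves) < 3:
        return [root.copy()]
    out: dict[str, TreeNode] = {}

    def canon(n: TreeNode) -> str:
        return write_newick(RootedTree(n.copy()))

    out[canon(root)] = root.copy()
    pm = _parent_map(root)
    nodes = _preorder_nodes(root)

    def rebuild(node: TreeNode, came_from: TreeNode) -> TreeNode:
        neighbours: list[TreeNode] = [c for c in node.children if c is not came_from]
        p = pm[id(node)]
        if p is not None and p is not came_from:
            neighbours.append(p)
        if node.is_leaf:
            return TreeNode(node.label)
        rebuilt = [rebuild(n, node) for n in neighbours]
        if len(rebuilt) == 1:
            return rebuilt[0]
        return TreeNode(children=rebuilt)

    for target in nodes[1:]:
        parent = pm[id(target)]
        assert parent is not None
        new_root = TreeNode(children=[
            target.copy() if target.is_leaf else rebuild(target, parent),
            rebuild(parent, target),
        ])
        key = canon(new_root)
        if key not in out:
            out[key] = new_root
    return list(out.values())


def _iter_spr(root: TreeNode) -> Iterator[TreeNode]:
    """Rooted SPR neighbourhood: prune any non-root subtree, regraft on any
    remaining edge or above the root. Yields fresh trees."""
    n_nodes = len(_preorder_nodes(root))
    for prune_idx in range(1, n_nodes):
        base = root.copy()
        nodes = _preorder_nodes(base)
        pm = _parent_map(base)
        pruned = nodes[prune_idx]
        remaining = _detach(base, pruned, pm)
        if not remaining.children:
            continue  # pruning left a single leaf
        for pos in _regraft_positions(remaining):
            yield _attach_at(remaining.copy(), pos, pruned.copy())


def _iter_tbr(root: TreeNode) -> Iterator[TreeNode]:
    """TBR neighbourhood: as SPR, but the pruned subtree is also rerooted on
    each of its edges before regrafting."""
    n_nodes = len(_preorder_nodes(root))
    for prune_idx in range(1, n_nodes):
        base = root.copy()
        nodes = _preorder_nodes(base)
        pm = _parent_map(base)
        pruned = nodes[prune_idx]
        remaining = _detach(base, pruned, pm)
        if not remaining.children:
            continue
        rootings = _all_rootings(pruned)
        for pos in _regraft_positions(remaining):
            for rooting in rootings:
                yield _attach_at(remaining.copy(), pos, rooting.copy())


# ---------------------------------------------------------------------------
# Starting trees and hill climbing
# ---------------------------------------------------------------------------


def _best_addition(root: TreeNode, label: str, scorer: _Scorer) -> TreeNode:
    """Insert ``label`` at the length-minimising position (first on ties)."""
    best_root, best_score = None, None
    for pos in _regraft_positions(root):
        cand = _attach_at(root.copy(), pos, TreeNode(label))
        s = scorer.score_scaled(cand)
        if best_score is None or s < best_score:
            best_root, best_score = cand, s
    assert best_root is not None
    return best_root


def _stepwise_addition(order: list[str], scorer: _Scorer) -> TreeNode:
    root = TreeNode(children=[TreeNode(order[0]), TreeNode(order[1])])
    for label in order[2:]:
        root = _best_addition(root, label, scorer)
    return root


def _scan(neighbours: Callable[[TreeNode], Iterator[TreeNode]],
          root: TreeNode, score: int, scorer: _Scorer,
          ) -> tuple[bool, TreeNode, int, list[TreeNode]]:
    """One first-improvement pass. Returns (improved, tree, score, ties):
    ties are equal-length neighbours seen before any improvement."""
    ties: list[TreeNode] = []
    for cand in neighbours(root):
        s = scorer.score_scaled(cand)
        if s < score:
            return True, cand, s, []
        if s == score:
            ties.append(cand)
    return False, root, score, ties


def _hill_climb(root: TreeNode, scorer: _Scorer,
                use_tbr: bool = True) -> tuple[TreeNode, int, list[TreeNode]]:
    score = scorer.score_scaled(root)
    while True:
        improved, root, score, ties = _scan(_iter_spr, root, score, scorer)
        if improved:
            continue
        if use_tbr:
            improved, root, score, tbr_ties = _scan(_iter_tbr, root, score, scorer)
            if improved:
                continue
            ties = tbr_ties  # TBR neighbourhood is a superset of SPR's
        return root, score, ties


# ---------------------------------------------------------------------------
# Public searches
# ---------------------------------------------------------------------------


def _canonical_rooted(root: TreeNode, outgroup: str) -> RootedTree:
    return reroot_on_leaf(RootedTree(root.copy()), outgroup)


def heuristic_search(matrix: MRPMatrix, replicates: int = 20, seed: int = 0,
                     maxtrees: int = 1000, use_tbr: bool = True) -> SearchResult:
    """Heuristic minimum-length search over binary trees on the matrix taxa.

    Each replicate draws a random addition sequence (seeded with
    ``seed + replicate index``), builds a greedy starting tree, and branch
    swaps (SPR, then TBR) to local optimality with first-improvement
    acceptance. Equal-length trees found on the final plateau are pooled,
    deduplicated on their outgroup-rooted topology, and capped at
    ``maxtrees``. Identical (matrix, seed, config) gives identical results.
    """
    if maxtrees < 1:
        raise ValueError("maxtrees must be >= 1")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    scorer = _Scorer(matrix)
    outgroup = matrix.outgroup
    best_scaled: int | None = None
    pool: dict[str, tuple[int, RootedTree]] = {}

    for rep in range(replicates):
        rng = random.Random(seed + rep)
        order = list(matrix.taxa)
        rng.shuffle(order)
        root = _stepwise_addition(order, scorer)
        root, score, ties = _hill_climb(root, scorer, use_tbr=use_tbr)
        if best_scaled is None or score < best_scaled:
            best_scaled = score
        if score > best_scaled:
            continue
        for cand in [root] + ties:
            s = scorer.score_scaled(cand)
            if s > best_scaled:
                continue
            rooted = _canonical_rooted(cand, outgroup)
            pool[write_newick(rooted)] = (s, rooted)

    assert best_scaled is not None
    keep = sorted(k for k, (s, _) in pool.items() if s == best_scaled)
    mpts = tuple(pool[k][1] for k in keep[:maxtrees])
    return SearchResult(Fraction(best_scaled, scorer.scale), mpts, replicates, seed)


def branch_and_bound(matrix: MRPMatrix, max_taxa: int = 12) -> SearchResult:
    """Exact minimum length and the complete MPT set by taxon-addition
    enumeration with partial-length pruning.

    Enumerates every unrooted binary topology exactly once (as rooted trees
    on the non-outgroup taxa, attached below the outgroup), pruning partial
    trees whose length already exceeds the best complete tree. Intended as
    the small-instance oracle; refuses more than ``max_taxa`` taxa.
    """
    if matrix.n_taxa > max_taxa:
        raise TooManyTaxaError(
            f"{matrix.n_taxa} taxa exceeds the exact-search limit of {max_taxa}; "
            "use heuristic_search"
        )
    scorer = _Scorer(matrix)
    outgroup = matrix.outgroup
    others = [t for t in matrix.taxa if t != outgroup]

    def with_outgroup(subroot: TreeNode) -> TreeNode:
        return TreeNode(children=[TreeNode(outgroup), subroot])

    # upper bound from a greedy addition tree
    ub_root = _stepwise_addition(list(matrix.taxa), scorer)
    best = scorer.score_scaled(ub_root)
    mpts: list[TreeNode] = []

    def recurse(subroot: TreeNode, next_idx: int) -> None:
        nonlocal best, mpts
        score = scorer.score_scaled(with_outgroup(subroot))
        if score > best:
            return
        if next_idx == len(others):
            if score < best:
                best = score
                mpts = [subroot]
            else:
                mpts.append(subroot)
            return
        label = others[next_idx]
        for pos in _regraft_positions(subroot):
            recurse(_attach_at(subroot.copy(), pos, TreeNode(label)), next_idx + 1)

    if len(others) == 1:
        final = with_outgroup(TreeNode(others[0]))
        return SearchResult(scorer.length(final), (RootedTree(final),), 0, 0)
    start = TreeNode(children=[TreeNode(others[0]), TreeNode(others[1])])
    recurse(start, 2)
    trees = tuple(
        sorted((RootedTree(with_outgroup(m)) for m in mpts),
               key=lambda t: write_newick(t))
    )
    return SearchResult(Fraction(best, scorer.scale), trees, 0, 0)
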
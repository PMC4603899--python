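"""Shared helpers: random tree/matrix generators and brute-force oracles.

The oracles here are deliberately independent of the package's
implementations: Fitch length by exhaustive internal-state enumeration,
topology enumeration by recursive bipartition, and clade compatibility
checked from first principles.
"""

import random
from fractions import Fraction

import numpy as np
import pytest

from mrpkit.mrp import MISSING, MRPMatrix
from mrpkit.tree import RootedTree, TreeNode


def random_tree(labels, rng, polytomy_prob=0.0):
    """Random rooted tree on ``labels`` by recursive random partition."""
    labels = list(labels)

    def build(lbls):
        if len(lbls) == 1:
            return TreeNode(lbls[0])
        k = 2
        if len(lbls) > 2 and rng.random() < polytomy_prob:
            k = rng.randint(3, min(4, len(lbls)))
        shuffled = lbls[:]
        rng.shuffle(shuffled)
        cuts = sorted(rng.sample(range(1, len(lbls)), k - 1))
        parts = [shuffled[i:j] for i, j in zip([0] + cuts, cuts + [len(lbls)])]
        return TreeNode(children=[build(p) for p in parts])

    return RootedTree(build(labels))


def all_rooted_binary_trees(labels):
    """Every rooted binary topology on ``labels`` (recursive bipartition;
    the first label is fixed to the left side to avoid double counting)."""
    labels = list(labels)
    if len(labels) == 1:
        yield TreeNode(labels[0])
        return
    first, rest = labels[0], labels[1:]
    for mask in range(2 ** len(rest) - 1):  # right side must be nonempty
        left = [first] + [x for i, x in enumerate(rest) if mask >> i & 1]
        right = [x for i, x in enumerate(rest) if not mask >> i & 1]
        for lt in all_rooted_binary_trees(left):
            for rt in all_rooted_binary_trees(right):
                yield TreeNode(children=[lt.copy(), rt.copy()])


def brute_fitch_char(root, allowed):
    """Minimum changes of one binary character on a tree, by enumerating all
    0/1 assignments to internal nodes. ``allowed``: leaf label -> state set."""
    internals, leaves = [], []
    stack = [(root, None)]
    edges = []  # (child, parent) index pairs into internals, or leaf entries
    while stack:
        node, parent = stack.pop()
        if node.children:
            internals.append(node)
        else:
            leaves.append((node, parent))
        for c in node.children:
            stack.append((c, node))
    index = {id(n): i for i, n in enumerate(internals)}
    best = None
    for assign in range(2 ** len(internals)):
        state = {id(n): (assign >> i) & 1 for i, n in enumerate(internals)}
        cost = 0
        for n in internals:
            for c in n.children:
                if c.children:
                    cost += state[id(n)] != state[id(c)]
        for leaf, parent in leaves:
            if state[id(parent)] not in allowed[leaf.label]:
                cost += 1
        if best is None or cost < best:
            best = cost
    return best


def brute_fitch(tree, matrix):
    """Brute-force weighted parsimony length of ``tree`` on ``matrix``."""
    total = Fraction(0)
    for j in range(matrix.n_characters):
        allowed = {}
        for i, t in enumerate(matrix.taxa):
            v = matrix.data[i, j]
            allowed[t] = {0, 1} if v == MISSING else {int(v)}
        total += matrix.weights[j] * brute_fitch_char(tree.root, allowed)
    return total


def random_matrix(n_taxa, n_chars, rng, missing_prob=0.2, outgroup="OG"):
    """Random valid MRP-style matrix: outgroup all zero, each character with
    >= 2 ones and >= 1 zero among non-missing entries."""
    taxa = (outgroup, *[f"x{i}" for i in range(n_taxa - 1)])
    cols = []
    weights = []
    while len(cols) < n_chars:
        col = np.full(n_taxa, MISSING, dtype=np.int8)
        col[0] = 0
        for i in range(1, n_taxa):
            if rng.random() >= missing_prob:
                col[i] = rng.randint(0, 1)
        inner = col[1:]
        if (inner == 1).sum() >= 2 and (col == 0).sum() >= 1:
            cols.append(col)
            weights.append(Fraction(rng.choice([1, 1, 1, 2]), rng.choice([1, 2])))
    data = np.stack(cols, axis=1)
    return MRPMatrix(taxa, data, tuple(weights), outgroup)


@pytest.fixture
def rng():
    return random.Random(20240915)
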
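"""Synthetic source-tree collections with known truth.

Emulates the raw material of a supertree study: a binary model tree (Yule
growth), a set of partially overlapping source trees obtained by restricting
the model tree to random taxon subsets and perturbing them (NNI moves for
topological conflict, edge contraction for polytomies), and nomenclature
noise (pseudo-synonyms and invented higher-taxon leaves) together with the
synonym/taxonomy key that lets the curation stage undo it. Everything is
deterministic per seed.

The default parameters mirror, at desk scale, a collection like the one the
pipeline is built for: a few dozen taxa, a dozen trees dominated by small
(< 20 taxon) leaf sets, publication years 1992-2013, and a mix of
morphological and single-gene molecular character sources with mild
topological conflict.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from fractions import Fraction

from .curation import CurationEvent, Dataset, SourceTreeRecord
from .tree import RootedTree, TreeNode, restrict

__all__ = ["SynthParams", "SyntheticTruth", "yule_tree", "sample_source_trees",
           "inject_noise", "make_truth", "CHARACTER_POOL", "YEAR_RANGE"]

# character-class and year pools the meta-data are drawn from
CHARACTER_POOL: tuple[tuple[str, ...], ...] = (
    ("morphology",), ("16S",), ("18S",), ("28S",), ("COI",), ("H3",), ("12S",),
    ("16S", "COI"), ("18S", "28S"), ("morphology", "16S"),
)
YEAR_RANGE = (1992, 2013)
_METHODS = ("parsimony", "likelihood", "bayesian", "distance")


@dataclass(frozen=True)
class SynthParams:
    """Generation parameters; defaults are the package's standard study
    conditions (see docs/methods.md for the rationale)."""

    n_taxa: int = 32
    k_trees: int = 12
    subsample_min: int = 6
    subsample_max: int = 16
    nni_moves: int = 1
    contract_probability: float = 0.1
    synonym_rate: float = 0.1
    higher_taxon_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        if not (2 <= self.subsample_min <= self.subsample_max <= self.n_taxa):
            raise ValueError("need 2 <= subsample_min <= subsample_max <= n_taxa")
        for name in ("contract_probability", "synonym_rate", "higher_taxon_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticTruth:
    """The model tree and the parameters that generated a synthetic dataset."""

    model_tree: RootedTree
    params: SynthParams


def yule_tree(n_taxa: int, seed: int) -> RootedTree:
    """Binary rooted tree grown by splitting a uniformly chosen leaf at each
    step (equal-rates / Yule growth). Deterministic per seed; leaves are
    labelled t01, t02, ... in the order they were created."""
    if n_taxa < 3:
        raise ValueError("n_taxa must be >= 3")
    rng = random.Random(seed)
    width = len(str(n_taxa))
    labels = [f"t{i + 1:0{width}d}" for i in range(n_taxa)]
    # grow the unlabelled shape first ...
    nodes = [TreeNode("_"), TreeNode("_")]
    root = TreeNode(children=list(nodes))
    while len(nodes) < n_taxa:
        leaf = nodes[rng.randrange(len(nodes))]
        # split: the chosen leaf becomes internal with two fresh leaves
        left, right = TreeNode("_"), TreeNode("_")
        leaf.label = None
        leaf.children = [left, right]
        nodes[nodes.index(leaf)] = left
        nodes.append(right)
    # ... then attach the labels as a uniform random permutation, so the
    # distribution over labelled topologies is exactly the Yule law
    rng.shuffle(labels)
    for leaf, label in zip(nodes, labels):
        leaf.label = label
    return RootedTree(root)


def make_truth(params: SynthParams | None = None, **overrides) -> SyntheticTruth:
    """Convenience constructor: model tree grown from ``params.seed``."""
    params = replace(params or SynthParams(), **overrides) if overrides \
        else (params or SynthParams())
    return SyntheticTruth(yule_tree(params.n_taxa, params.seed), params)


# ---------------------------------------------------------------------------
# Perturbations
# ---------------------------------------------------------------------------


def _nni(tree: RootedTree, rng: random.Random) -> RootedTree:
    """One random rooted NNI: swap a child of an internal non-root node with
    one of that node's siblings. No-op on trees without an internal edge."""
    root = tree.copy().root
    candidates: list[tuple[TreeNode, TreeNode]] = []  # (parent, internal child)
    stack = [root]
    while stack:
        node = stack.pop()
        for c in node.children:
            if not c.is_leaf:
                candidates.append((node, c))
                stack.append(c)
    if not candidates:
        return RootedTree(root)
    parent, v = candidates[rng.randrange(len(candidates))]
    sibs = [c for c in parent.children if c is not v]
    s = sibs[rng.randrange(len(sibs))]
    c = v.children[rng.randrange(len(v.children))]
    parent.children[parent.children.index(s)] = c
    v.children[v.children.index(c)] = s
    return RootedTree(root)


def _contract(tree: RootedTree, prob: float, rng: random.Random) -> RootedTree:
    """Contract each internal non-root edge to a polytomy with probability
    ``prob`` (edge-by-edge, in pre-order)."""
    root = tree.copy().root

    def walk(node: TreeNode) -> None:
        new_children: list[TreeNode] = []
        queue = list(node.children)
        while queue:  # adopted grandchildren are themselves candidates
            c = queue.pop(0)
            if not c.is_leaf and rng.random() < prob:
                queue = list(c.children) + queue
            else:
                new_children.append(c)
        node.children = new_children
        for c in node.children:
            walk(c)

    walk(root)
    return RootedTree(root)


def sample_source_trees(truth: SyntheticTruth) -> Dataset:
    """Draw the synthetic source-tree collection defined by ``truth``.

    Each of the k trees is the model tree restricted to a uniform random
    taxon subsample (size uniform on the configured range), perturbed by the
    configured number of NNI moves and per-edge contraction probability.
    Meta-data (year, character types, method) are drawn from fixed pools.
    Trees violating pairwise overlap connectivity (>= 2 shared taxa, whole
    collection connected) are resampled, up to a retry cap.
    """
    from .curation import check_overlap  # local import avoids cycle at module load

    p = truth.params
    rng = random.Random((p.seed * 1000003 + 7919) % (2**31))
    taxa = sorted(truth.model_tree.leaves)

    def draw(index: int) -> SourceTreeRecord:
        size = rng.randint(p.subsample_min, p.subsample_max)
        subsample = rng.sample(taxa, size)
        t = restrict(truth.model_tree, subsample)
        for _ in range(p.nni_moves):
            t = _nni(t, rng)
        if p.contract_probability > 0:
            t = _contract(t, p.contract_probability, rng)
        year = rng.randint(*YEAR_RANGE)
        return SourceTreeRecord(
            tree=t,
            study_key=f"study_{index:02d}_{year}",
            year=year,
            character_types=CHARACTER_POOL[rng.randrange(len(CHARACTER_POOL))],
            method=_METHODS[rng.randrange(len(_METHODS))],
            weight=Fraction(1),
        )

    records = [draw(i) for i in range(p.k_trees)]
    if p.k_trees >= 2:
        for attempt in range(50):
            report = check_overlap(Dataset(list(records)), min_shared=2)
            if report.passes:
                break
            for i in report.removal_candidates:
                records[i] = draw(i)
        else:
            raise RuntimeError(
                "could not connect the overlap graph after 50 retries; "
                "increase subsample sizes or reduce k_trees"
            )
    return Dataset(records)


# ---------------------------------------------------------------------------
# Nomenclature noise
# ---------------------------------------------------------------------------


def inject_noise(dataset: Dataset, truth: SyntheticTruth
                 ) -> tuple[Dataset, list[CurationEvent]]:
    """Add reversible nomenclature noise to a clean synthetic dataset.

    A fraction of leaf occurrences (``higher_taxon_rate``) is replaced by an
    invented higher-taxon label whose definition — recorded in the emitted
    taxonomy map — is the leaf set of the parent clade in the model tree, so
    the curation stage exercises its polytomy-substitution rule. A fraction
    of the remaining species leaves (``synonym_rate``) is renamed to a
    pseudo-synonym recorded in the emitted synonym map. The returned
    dataset's synonym_map/taxonomy are the key that lets curation restore
    the clean names.
    """
    p = truth.params
    rng = random.Random((p.seed * 1000003 + 104729) % (2**31))
    events: list[CurationEvent] = []

    # higher-taxon definitions from the model tree: parent clade of each leaf
    parent_clade: dict[str, frozenset[str]] = {}
    stack = [truth.model_tree.root]
    while stack:
        node = stack.pop()
        members = frozenset(node.leaf_labels()) if not node.is_leaf else None
        for c in node.children:
            if c.is_leaf:
                parent_clade[c.label] = members
            else:
                stack.append(c)

    taxonomy: dict[str, frozenset[str]] = {}
    ht_name: dict[frozenset[str], str] = {}
    synonyms: dict[str, str] = {}

    def higher_taxon_for(leaf: str) -> str:
        clade = parent_clade[leaf]
        if clade not in ht_name:
            name = f"HTaxon_{len(ht_name) + 1:02d}"
            ht_name[clade] = name
            taxonomy[name] = clade
        return ht_name[clade]

    def alias_for(leaf: str) -> str:
        alias = f"{leaf}_syn"
        synonyms[alias] = leaf
        return alias

    new_records = []
    for rec in dataset.records:
        present = set(rec.taxa)

        def rebuild(node: TreeNode) -> TreeNode:
            if not node.is_leaf:
                return TreeNode(children=[rebuild(c) for c in node.children])
            label = node.label
            if label in parent_clade and rng.random() < p.higher_taxon_rate:
                ht = higher_taxon_for(label)
                if ht not in present:
                    present.add(ht)
                    events.append(CurationEvent("noise", rec.study_key,
                                                "higher_taxon", f"{label} -> {ht}"))
                    return TreeNode(ht)
            if rng.random() < p.synonym_rate:
                alias = alias_for(label)
                events.append(CurationEvent("noise", rec.study_key,
                                            "synonym", f"{label} -> {alias}"))
                return TreeNode(alias)
            return TreeNode(label)

        new_records.append(replace(rec, tree=RootedTree(rebuild(rec.tree.root))))
    return Dataset(new_records, synonyms, taxonomy), events
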
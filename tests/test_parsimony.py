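"""Fitch scoring and parsimony search against brute-force oracles."""

import random
from fractions import Fraction

import numpy as np
import pytest

from mrpkit.mrp import MISSING, MRPMatrix
from mrpkit.parsimony import (TooManyTaxaError, branch_and_bound, fitch_length,
                              heuristic_search)
from mrpkit.tree import RootedTree, TreeNode, parse_newick, reroot_on_leaf

from conftest import all_rooted_binary_trees, brute_fitch, random_matrix


def matrix_of(taxa, columns, weights=None, outgroup=None):
    data = np.array(columns, dtype=np.int8).T
    weights = weights or [Fraction(1)] * data.shape[1]
    outgroup = outgroup or taxa[0]
    return MRPMatrix(tuple(taxa), data, tuple(weights), outgroup)


class TestFitchLength:
    def test_single_origin(self):
        m = matrix_of(["O", "A", "B", "C", "D"], [[0, 1, 1, 0, 0]])
        t = parse_newick("(O,((A,B),(C,D)));")
        assert fitch_length(t, m) == 1

    def test_split_origin(self):
        m = matrix_of(["O", "A", "B", "C", "D"], [[0, 1, 1, 0, 0]])
        t = parse_newick("(O,((A,C),(B,D)));")
        assert fitch_length(t, m) == 2

    def test_missing_state_and_weight(self):
        # B is "?" (full state set): it adopts whichever state is cheapest,
        # so the character changes once; hand Fitch gives 1, weighted 1/2
        data = np.array([[0, 1, 1, MISSING, 0]], dtype=np.int8).T
        m = MRPMatrix(("O", "A", "A2", "B", "C"), data, (Fraction(1, 2),), "O")
        t = parse_newick("(O,(((A,A2),B),C));")
        assert fitch_length(t, m) == Fraction(1, 2)

    def test_invariant_to_rerooting_and_child_order(self, rng):
        for _ in range(20):
            m = random_matrix(7, 5, rng)
            trees = list(all_rooted_binary_trees(list(m.taxa)))
            t = RootedTree(trees[rng.randrange(len(trees))])
            base = fitch_length(t, m)
            leaf = rng.choice(sorted(t.leaves))
            assert fitch_length(reroot_on_leaf(t, leaf), m) == base
            shuffled = t.copy()
            for node in shuffled.iter_internal():
                rng.shuffle(node.children)
            assert fitch_length(shuffled, m) == base

    def test_taxon_mismatch_raises(self):
        m = matrix_of(["O", "A", "B", "C"], [[0, 1, 1, 0]])
        with pytest.raises(ValueError) as err:
            fitch_length(parse_newick("(O,(A,B));"), m)
        assert "C" in str(err.value)

    def test_matches_brute_force_on_small_instances(self, rng):
        # exhaustive internal-state enumeration as the independent oracle
        for _ in range(30):
            n = rng.randint(4, 7)
            m = random_matrix(n, rng.randint(2, 5), rng)
            trees = list(all_rooted_binary_trees(list(m.taxa)))
            for root in rng.sample(trees, min(5, len(trees))):
                t = RootedTree(root)
                assert fitch_length(t, m) == brute_fitch(t, m)


class TestBranchAndBound:
    def test_matches_exhaustive_search(self, rng):
        for _ in range(25):
            m = random_matrix(6, rng.randint(2, 6), rng)
            others = [t for t in m.taxa if t != m.outgroup]
            best = None
            for sub in all_rooted_binary_trees(others):
                t = RootedTree(TreeNode(children=[TreeNode(m.outgroup), sub]))
                length = brute_fitch(t, m)
                best = length if best is None else min(best, length)
            result = branch_and_bound(m)
            assert result.best_length == best

    def test_complete_mpt_set_on_seven_taxa(self, rng):
        for _ in range(5):
            m = random_matrix(7, 4, rng)
            result = branch_and_bound(m)
            others = [t for t in m.taxa if t != m.outgroup]
            exhaustive = []
            for sub in all_rooted_binary_trees(others):
                t = RootedTree(TreeNode(children=[TreeNode(m.outgroup), sub]))
                if brute_fitch(t, m) == result.best_length:
                    exhaustive.append(t)
            assert len(result.mpts) == len(exhaustive)
            assert set(result.mpts) == set(exhaustive)

    def test_single_character_four_taxa(self):
        m = matrix_of(["O", "A", "B", "C", "D"], [[0, 1, 1, 0, 0]])
        result = branch_and_bound(m)
        assert result.best_length == 1
        # every MPT realises the character with a single origin
        for t in result.mpts:
            assert fitch_length(t, m) == 1

    def test_compatible_matrix_reaches_character_count(self, rng):
        m = random_matrix(6, 1, rng, missing_prob=0.0)
        # one conflict-free character: minimal length is one step
        assert branch_and_bound(m).best_length == 1

    def test_refuses_large_instances(self, rng):
        m = random_matrix(13, 3, rng)
        with pytest.raises(TooManyTaxaError):
            branch_and_bound(m)


class TestHeuristicSearch:
    def test_recovers_compatible_tree(self, rng):
        # matrix encoding a single binary 8-taxon tree: the heuristic must
        # reach the compatibility bound and include the generating tree
        from mrpkit.curation import Dataset, SourceTreeRecord
        from mrpkit.mrp import encode_brs
        from mrpkit.tree import restrict, rf_distance

        newick = "(((A,B),(C,D)),((E,(F,G)),H));"
        ds = Dataset([SourceTreeRecord(tree=parse_newick(newick), study_key="s1",
                                       year=2000, character_types=("16S",))])
        m = encode_brs(ds)
        result = heuristic_search(m, replicates=5, seed=11)
        assert result.best_length == m.n_characters
        ingroup = [restrict(t, t.leaves - {"MRP_Outgroup"}) for t in result.mpts]
        assert any(rf_distance(t, parse_newick(newick)) == 0 for t in ingroup)

    def test_never_beats_exact_search_and_usually_matches(self, rng):
        matches = 0
        for trial in range(10):
            m = random_matrix(8, 6, rng)
            exact = branch_and_bound(m)
            heur = heuristic_search(m, replicates=3, seed=trial)
            assert heur.best_length >= exact.best_length
            matches += heur.best_length == exact.best_length
        assert matches >= 9  # equality expected on desk-scale instances

    def test_monotone_in_replicates(self, rng):
        m = random_matrix(9, 8, rng, missing_prob=0.4)
        lengths = [heuristic_search(m, replicates=r, seed=5, use_tbr=False).best_length
                   for r in (1, 3, 6)]
        assert lengths[0] >= lengths[1] >= lengths[2]

    def test_deterministic_per_seed(self, rng):
        from mrpkit.tree import write_newick

        m = random_matrix(8, 6, rng)
        a = heuristic_search(m, replicates=3, seed=42)
        b = heuristic_search(m, replicates=3, seed=42)
        assert a.best_length == b.best_length
        assert [write_newick(t) for t in a.mpts] == [write_newick(t) for t in b.mpts]

    def test_results_rooted_on_outgroup(self, rng):
        m = random_matrix(7, 5, rng)
        result = heuristic_search(m, replicates=2, seed=1)
        for t in result.mpts:
            assert any(c.is_leaf and c.label == m.outgroup for c in t.root.children)

    def test_invalid_parameters(self, rng):
        m = random_matrix(5, 3, rng)
        with pytest.raises(ValueError):
            heuristic_search(m, maxtrees=0)
        with pytest.raises(ValueError):
            heuristic_search(m, replicates=0)
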
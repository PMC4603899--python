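"""V/V+ node support, classification and novel-clade detection."""

import random
from fractions import Fraction

import pytest

from mrpkit.curation import Dataset, SourceTreeRecord
from mrpkit.support import (CONFLICT, IRRELEVANT, PERMIT, SUPPORT, NodeSupport,
                            annotated_newick, classify_source_tree, novel_clades,
                            support_table, v_category, v_indices)
from mrpkit.tree import parse_newick, restrict

from conftest import random_tree


def rec(newick, study="s1"):
    return SourceTreeRecord(tree=parse_newick(newick), study_key=study, year=2005,
                            character_types=("16S",))


def independent_classify(node, record):
    """Cross-check via clade compatibility instead of straddle detection:
    A supports if present; conflicts iff A is incompatible with the source
    tree (some clade neither nests with it nor is disjoint from it)."""
    taxa = record.taxa
    a = frozenset(node & taxa)
    if len(a) < 2 or not (taxa - node):
        return IRRELEVANT
    cl = record.tree.clades()
    if a in cl:
        return SUPPORT
    compatible = all(a <= x or x <= a or not (a & x) for x in cl)
    return PERMIT if compatible else CONFLICT


class TestClassify:
    def test_present_clade_supports(self):
        assert classify_source_tree(frozenset("AB"), rec("((A,B),C);")) == SUPPORT

    def test_straddling_clade_conflicts(self):
        assert classify_source_tree(frozenset("AB"), rec("((A,C),B);")) == CONFLICT

    def test_polytomy_permits(self):
        assert classify_source_tree(frozenset("AB"), rec("(A,B,C);")) == PERMIT

    def test_fewer_than_two_members_irrelevant(self):
        assert classify_source_tree(frozenset("AZ"), rec("((A,B),C);")) == IRRELEVANT

    def test_no_outside_taxon_irrelevant(self):
        assert classify_source_tree(frozenset("ABC"), rec("((A,B),C);")) == IRRELEVANT

    def test_agrees_with_compatibility_formulation(self, rng):
        labels = [f"s{i}" for i in range(9)]
        for _ in range(100):
            source = SourceTreeRecord(
                tree=random_tree(rng.sample(labels, rng.randint(3, 9)), rng,
                                 polytomy_prob=0.3),
                study_key="s", year=2000, character_types=("16S",))
            node = frozenset(rng.sample(labels, rng.randint(2, 6)))
            assert classify_source_tree(node, source) == \
                independent_classify(node, source)


class TestVIndices:
    def _dataset(self):
        return Dataset([
            rec("((A,B),C);", "s1"),   # supports {A,B}
            rec("((A,B),D);", "s2"),   # supports {A,B}
            rec("(A,B,C);", "s3"),     # permits {A,B}
            rec("((A,C),B);", "s4"),   # conflicts with {A,B}
            rec("((C,D),E);", "s5"),   # irrelevant to {A,B}
        ])

    def test_counts_and_values(self):
        supertree = parse_newick("((A,B),(C,(D,E)));")
        supports = {ns.clade: ns for ns in v_indices(supertree, self._dataset())}
        ab = supports[frozenset("AB")]
        assert (ab.s, ab.q, ab.p, ab.r) == (2, 1, 1, 1)
        assert ab.V == Fraction(1, 3)
        assert ab.V_plus == Fraction(1, 2)

    def test_counts_partition_all_source_trees(self):
        supertree = parse_newick("((A,B),(C,(D,E)));")
        ds = self._dataset()
        for ns in v_indices(supertree, ds):
            assert ns.n_trees == len(ds.records)

    def test_unanimous_support_scores_one(self):
        ds = Dataset([rec("((A,B),C);", f"s{i}") for i in range(4)])
        supports = v_indices(parse_newick("((A,B),C);"), ds)
        assert all(ns.V == 1 and ns.V_plus == 1 for ns in supports)

    def test_balanced_support_scores_zero(self):
        ns = NodeSupport(frozenset("AB"), s=1, q=1, p=0, r=0)
        assert ns.V == 0 and ns.V_plus == 0

    def test_permission_relaxes_v(self):
        ns = NodeSupport(frozenset("AB"), s=1, q=1, p=2, r=0)
        assert ns.V == 0 and ns.V_plus == Fraction(1, 2)

    def test_undefined_reported_as_none_not_zero(self):
        ns = NodeSupport(frozenset("AB"), s=0, q=0, p=3, r=1)
        assert ns.V is None
        assert ns.V_plus == 1
        assert v_category(ns) == "undefined"

    def test_outgroup_excluded(self):
        ds = self._dataset()
        supertree = parse_newick("(OG,((A,B),(C,(D,E))));")
        supports = v_indices(supertree, ds, outgroup="OG")
        assert all("OG" not in ns.clade for ns in supports)
        assert frozenset("ABCDE") not in {ns.clade for ns in supports}

    def test_bounds_and_vplus_dominance(self, rng):
        labels = [f"s{i}" for i in range(10)]
        for _ in range(20):
            supertree = random_tree(labels, rng)
            ds = Dataset([
                SourceTreeRecord(tree=random_tree(rng.sample(labels, 5), rng,
                                                  polytomy_prob=0.4),
                                 study_key=f"s{k}", year=2000,
                                 character_types=("16S",))
                for k in range(6)])
            for ns in v_indices(supertree, ds):
                if ns.V is not None:
                    assert -1 <= ns.V <= 1
                if ns.V_plus is not None:
                    assert -1 <= ns.V_plus <= 1
                if ns.V is not None and ns.V_plus is not None:
                    assert ns.V_plus >= ns.V
                if ns.q == 0 and ns.s > 0 and ns.p == 0:
                    assert ns.V == 1 and ns.V_plus == 1


class TestNovelClades:
    def test_supported_clade_not_novel(self):
        ds = Dataset([rec("((A,B),C);")])
        assert novel_clades(parse_newick("((A,B),C);"), ds) == []

    def test_unsupported_relevant_clade_is_novel(self):
        ds = Dataset([rec("((A,C),B);", "s1"), rec("((A,C),(B,D));", "s2"),
                      rec("(A,B,C);", "s3")])
        novel = novel_clades(parse_newick("((A,B),(C,D));"), ds)
        assert frozenset("AB") in novel

    def test_irrelevant_everywhere_is_not_novel(self):
        ds = Dataset([rec("((A,B),C);")])
        supertree = parse_newick("((A,B),((X,Y),C));")
        # {X,Y} is invisible to the only source tree: unsupported but not novel
        assert frozenset("XY") not in novel_clades(supertree, ds)


class TestOutputs:
    def test_support_table_columns(self):
        ds = Dataset([rec("((A,B),C);")])
        table = support_table(v_indices(parse_newick("((A,B),C);"), ds))
        assert list(table.columns) == ["clade", "size", "s", "q", "p", "r",
                                       "V", "V_plus", "category"]
        assert table.iloc[0]["V"] == 1.0
        assert table.iloc[0]["category"] == "full"

    def test_annotated_newick_carries_v_labels(self):
        ds = Dataset([rec("((A,B),C);"), rec("((A,B),D);", "s2")])
        supertree = parse_newick("(((A,B),C),D);")
        out = annotated_newick(supertree, v_indices(supertree, ds))
        assert "(A,B)1" in out
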
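"""Curation protocol: standardisation, substitution, independence, overlap."""

import random
from fractions import Fraction

import pytest

from mrpkit.curation import (Dataset, SourceTreeRecord, apply_independence,
                             check_overlap, dataset_summary, load_bundle,
                             load_xml_bundle, save_bundle, save_xml_bundle,
                             standardize_names, substitute_higher_taxa)
from mrpkit.tree import parse_newick, rf_distance, write_newick


def rec(newick, study="s1", year=2005, chars=("16S",), **kw):
    return SourceTreeRecord(tree=parse_newick(newick), study_key=study, year=year,
                            character_types=chars, **kw)


class TestRecordInvariants:
    def test_weight_bounds(self):
        with pytest.raises(ValueError):
            rec("(A,B);", weight=Fraction(0))
        with pytest.raises(ValueError):
            rec("(A,B);", weight=Fraction(3, 2))

    def test_year_floor(self):
        with pytest.raises(ValueError):
            rec("(A,B);", year=1975)

    def test_empty_character_types(self):
        with pytest.raises(ValueError):
            rec("(A,B);", chars=())

    def test_synonym_map_completed_to_idempotence(self):
        ds = Dataset([rec("(A,B);")], synonym_map={"A_old": "A"})
        assert ds.synonym_map["A"] == "A"


class TestStandardizeNames:
    def test_rename(self):
        ds = Dataset([rec("(Panulirus_ornatus,(A,B));")],
                     synonym_map={"Panulirus_ornatus": "Panulirus ornatus"})
        out, events = standardize_names(ds)
        assert "Panulirus ornatus" in out.records[0].taxa
        assert any(e.action == "renamed" for e in events)

    def test_duplicate_merge_keeps_first_preorder(self):
        ds = Dataset([rec("((X,Y),Z);")], synonym_map={"X": "W", "Y": "W"})
        out, events = standardize_names(ds)
        assert write_newick(out.records[0].tree) == "(W,Z);"
        assert any(e.action == "merged_duplicate" for e in events)

    def test_empty_map_is_identity(self):
        ds = Dataset([rec("((A,B),C);")])
        out, events = standardize_names(ds)
        assert rf_distance(out.records[0].tree, ds.records[0].tree) == 0
        assert events == []

    def test_idempotent(self):
        ds = Dataset([rec("((X,Y),(Z,Q));")], synonym_map={"X": "W", "Y": "W", "Q": "R"})
        once, _ = standardize_names(ds)
        twice, _ = standardize_names(once)
        assert write_newick(once.records[0].tree) == write_newick(twice.records[0].tree)


class TestSubstituteHigherTaxa:
    def test_polytomy_substitution(self):
        ds = Dataset(
            [rec("(Scyllaridae,(A,B));", study="s1"),
             rec("((S1,S2),A);", study="s2")],
            taxonomy={"Scyllaridae": {"S1", "S2", "S3"}},
        )
        out, events = substitute_higher_taxa(ds)
        t = out.records[0].tree
        assert t.leaves == {"S1", "S2", "A", "B"}
        assert frozenset({"S1", "S2"}) in t.clades()  # substituted as a polytomy
        assert any(e.action == "polytomy_substituted" for e in events)

    def test_singleton_renames(self):
        ds = Dataset(
            [rec("(Fam,(A,B));", study="s1"), rec("(S1,A);", study="s2")],
            taxonomy={"Fam": {"S1", "S9"}},
        )
        out, events = substitute_higher_taxa(ds)
        assert out.records[0].tree.leaves == {"S1", "A", "B"}
        assert any(e.action == "leaf_renamed" for e in events)

    def test_empty_intersection_removes_leaf(self):
        ds = Dataset(
            [rec("(Fam,(A,B));", study="s1"), rec("(A,C);", study="s2")],
            taxonomy={"Fam": {"S1", "S2"}},
        )
        out, events = substitute_higher_taxa(ds)
        assert out.records[0].tree.leaves == {"A", "B"}
        assert any(e.action == "leaf_removed" for e in events)

    def test_never_invents_names(self):
        ds = Dataset(
            [rec("(Fam,(A,B));", study="s1"), rec("((S1,S2),(A,C));", study="s2")],
            taxonomy={"Fam": {"S1", "S2", "S3"}},
        )
        out, _ = substitute_higher_taxa(ds)
        known = set().union(*(r.taxa for r in ds.records)) | \
            set().union(*ds.taxonomy.values())
        for r in out.records:
            assert r.taxa <= known


class TestApplyIndependence:
    def test_identical_trees_get_inverse_weights(self):
        ds = Dataset([rec("((A,B),C);", study="s1"), rec("((A,C),B);", study="s2")])
        out, events = apply_independence(ds)
        assert [r.weight for r in out.records] == [Fraction(1, 2), Fraction(1, 2)]
        assert sum(r.weight for r in out.records) == 1

    def test_same_study_subset_removed(self):
        ds = Dataset([
            rec("((A,B),C);", study="s1"),
            rec("(((A,B),C),D);", study="s1"),
        ])
        out, events = apply_independence(ds)
        assert len(out.records) == 1
        assert out.records[0].taxa == {"A", "B", "C", "D"}
        assert any(e.action == "subset_removed" for e in events)

    def test_cross_study_subset_only_reported(self):
        ds = Dataset([
            rec("((A,B),C);", study="s1"),
            rec("(((A,B),C),D);", study="s2"),
        ])
        out, events = apply_independence(ds)
        assert len(out.records) == 2
        assert any(e.action == "cross_study_subset_reported" for e in events)

    def test_distinct_records_keep_weight_one(self):
        ds = Dataset([rec("((A,B),C);", chars=("16S",)),
                      rec("((A,B),C);", chars=("COI",)),
                      rec("((A,B),D);", chars=("16S",))])
        out, _ = apply_independence(ds)
        assert all(r.weight == 1 for r in out.records)

    def test_group_weight_sums_to_one(self):
        ds = Dataset([rec("((A,B),C);", study=f"s{i}") for i in range(3)])
        out, _ = apply_independence(ds)
        assert sum(r.weight for r in out.records) == 1


class TestCheckOverlap:
    def test_two_shared_taxa_pass(self):
        ds = Dataset([rec("((A,B),C);"), rec("((B,C),D);", study="s2")])
        assert check_overlap(ds).passes

    def test_single_shared_taxon_fails(self):
        ds = Dataset([rec("((A,B),C);"), rec("((C,D),E);", study="s2")])
        report = check_overlap(ds)
        assert not report.passes
        assert report.n_components == 2
        assert report.removal_candidates == (1,)

    def test_chain_connectivity_is_transitive(self):
        ds = Dataset([rec("((A,B),C);", study="s1"),
                      rec("((B,C),D);", study="s2"),
                      rec("((D,E),(C,F));", study="s3")])
        # s1 and s3 share only one taxon, but are connected through s2
        assert check_overlap(ds).passes

    def test_order_independent(self, rng):
        records = [rec("((A,B),C);", study="s1"), rec("((C,D),E);", study="s2"),
                   rec("((E,D),F);", study="s3"), rec("((A,C),B);", study="s4")]
        base = check_overlap(Dataset(list(records)))
        sizes = sorted(len(c) for c in base.components)
        for _ in range(5):
            shuffled = records[:]
            rng.shuffle(shuffled)
            report = check_overlap(Dataset(shuffled))
            assert sorted(len(c) for c in report.components) == sizes

    def test_requires_two_records(self):
        with pytest.raises(ValueError):
            check_overlap(Dataset([rec("(A,B);")]))


class TestDatasetSummary:
    def test_year_table(self):
        ds = Dataset([rec("(A,B);", year=2001), rec("(A,C);", year=2001, study="s2"),
                      rec("(B,C);", year=2005, study="s3")])
        tables = dataset_summary(ds)
        counts = dict(zip(tables.trees_per_year["year"], tables.trees_per_year["n_trees"]))
        assert counts == {2001: 2, 2005: 1}

    def test_sizes(self):
        ds = Dataset([rec("((A,B),(C,(D,E)));"), rec("(A,B,C);", study="s2")])
        sizes = sorted(dataset_summary(ds).tree_sizes["n_taxa"])
        assert sizes == [3, 5]

    def test_empty_dataset(self):
        tables = dataset_summary(Dataset([]))
        assert len(tables.trees_per_year) == 0
        assert len(tables.taxon_presence) == 0


class TestBundleIO:
    def _dataset(self):
        return Dataset(
            [rec("((A,B),C);", study="s1", year=1999, chars=("16S", "COI"),
                 weight=Fraction(1, 2)),
             rec("((B,C),D);", study="s2", year=2010, chars=("morphology",))],
            synonym_map={"A_old": "A"},
            taxonomy={"Fam": {"C", "D"}},
        )

    def test_directory_bundle_round_trip(self, tmp_path):
        ds = self._dataset()
        save_bundle(ds, tmp_path / "bundle")
        back = load_bundle(tmp_path / "bundle")
        assert len(back.records) == 2
        for a, b in zip(ds.records, back.records):
            assert rf_distance(a.tree, b.tree) == 0
            assert (a.study_key, a.year, a.character_types, a.weight) == \
                (b.study_key, b.year, b.character_types, b.weight)
        assert back.synonym_map["A_old"] == "A"
        assert back.taxonomy["Fam"] == {"C", "D"}

    def test_xml_bundle_round_trip(self, tmp_path):
        ds = self._dataset()
        save_xml_bundle(ds, tmp_path / "data.xml")
        back = load_xml_bundle(tmp_path / "data.xml")
        assert len(back.records) == 2
        assert back.records[0].weight == Fraction(1, 2)
        assert back.taxonomy["Fam"] == {"C", "D"}
        assert rf_distance(back.records[1].tree, ds.records[1].tree) == 0

    def test_inclusion_flags_filter(self):
        ds = Dataset([rec("(A,B);"), rec("(A,C);", study="s2", has_explicit_matrix=False)])
        kept, events = ds.filter_included()
        assert len(kept.records) == 1
        assert events[0].action == "excluded"
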
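"""Source-tree curation: the data-processing protocol applied before encoding.

A supertree analysis starts from published source trees plus meta-data. Before
matrix encoding the collection must be made consistent: taxon names are
standardised against a synonym map, higher-taxon leaves are replaced by the
constituent species that occur in other source trees, non-independent trees
are down-weighted or removed, and taxonomic overlap between trees is checked.
All of that lives here, together with the dataset summaries used to
characterise a collection (trees per year, character sources, tree sizes).

Synonymy and higher-taxon definitions come from local, user-editable tabular
files so that runs are reproducible and testable offline.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping
from xml.etree import ElementTree as ET

import networkx as nx
import pandas as pd

from .tree import RootedTree, TreeNode, parse_newick, write_newick

__all__ = [
    "SourceTreeRecord",
    "Dataset",
    "CurationEvent",
    "OverlapReport",
    "SummaryTables",
    "standardize_names",
    "substitute_higher_taxa",
    "apply_independence",
    "check_overlap",
    "dataset_summary",
    "load_bundle",
    "save_bundle",
    "load_xml_bundle",
    "save_xml_bundle",
]


@dataclass(frozen=True)
class SourceTreeRecord:
    """One published source tree with its analysis meta-data.

    Parameters
    ----------
    tree
        The (rooted) topology as published, possibly with polytomies.
    study_key
        Bibliographic identifier, e.g. ``"palero_2009"``.
    year
        Publication year (>= 1980, the start of the literature window).
    character_types
        Character classes the tree was inferred from, e.g. ``("16S", "COI")``
        or ``("morphology",)``.
    method
        Inference-method tag ("parsimony", "bayesian", ...). Informational.
    weight
        Analysis weight in (0, 1]; adjusted by :func:`apply_independence`.
    has_explicit_matrix, taxa_identifiable
        Inclusion-criteria flags recorded at data entry: the tree derives from
        an explicit character matrix, and its terminals are identifiable taxa.
        Records failing either flag are excluded at load time.
    """

    tree: RootedTree
    study_key: str
    year: int
    character_types: tuple[str, ...]
    method: str = "unspecified"
    weight: Fraction = Fraction(1)
    has_explicit_matrix: bool = True
    taxa_identifiable: bool = True

    def __post_init__(self):
        if not (0 < self.weight <= 1):
            raise ValueError(f"record {self.study_key}: weight must be in (0, 1]")
        if not self.character_types:
            raise ValueError(f"record {self.study_key}: character_types must be nonempty")
        if self.year < 1980:
            raise ValueError(f"record {self.study_key}: year {self.year} < 1980")

    @property
    def taxa(self) -> frozenset[str]:
        return self.tree.leaves


def _complete_synonym_map(mapping: Mapping[str, str]) -> dict[str, str]:
    """Make a synonym map idempotent: accepted names map to themselves."""
    out = dict(mapping)
    for accepted in list(out.values()):
        out.setdefault(accepted, accepted)
    return out


@dataclass
class Dataset:
    """An ordered collection of source-tree records plus the name resources.

    ``synonym_map`` maps any name to its accepted name and is idempotent
    (accepted names map to themselves; this is enforced at construction).
    ``taxonomy`` maps a higher-taxon name to its constituent species.
    """

    records: list[SourceTreeRecord]
    synonym_map: dict[str, str] = field(default_factory=dict)
    taxonomy: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self):
        self.synonym_map = _complete_synonym_map(self.synonym_map)
        self.taxonomy = {k: frozenset(v) for k, v in self.taxonomy.items()}

    def taxa(self) -> frozenset[str]:
        """Union of leaf labels over all records."""
        out: set[str] = set()
        for rec in self.records:
            out |= rec.taxa
        return frozenset(out)

    def filter_included(self) -> tuple["Dataset", list["CurationEvent"]]:
        """Drop records failing the inclusion-criteria flags."""
        events = []
        kept = []
        for i, rec in enumerate(self.records):
            if rec.has_explicit_matrix and rec.taxa_identifiable:
                kept.append(rec)
            else:
                why = []
                if not rec.has_explicit_matrix:
                    why.append("no explicit character matrix")
                if not rec.taxa_identifiable:
                    why.append("taxa not identifiable")
                events.append(CurationEvent("inclusion", rec.study_key, "excluded", "; ".join(why)))
        return Dataset(kept, self.synonym_map, self.taxonomy), events


@dataclass(frozen=True)
class CurationEvent:
    """One logged curation decision (rename, merge, substitution, weight...)."""

    stage: str
    study_key: str
    action: str
    detail: str


# ---------------------------------------------------------------------------
# Nomenclature standardisation
# ---------------------------------------------------------------------------


def standardize_names(dataset: Dataset) -> tuple[Dataset, list[CurationEvent]]:
    """Replace every leaf label by its accepted name from the synonym map.

    If renaming makes two leaves of one tree identical they are merged into a
    single leaf: the first occurrence in a pre-order traversal is retained and
    the merge is logged. Names absent from the map pass through unchanged and
    are logged as unmatched (only when a map is loaded).
    """
    events: list[CurationEvent] = []
    synmap = dataset.synonym_map
    new_records: list[SourceTreeRecord] = []
    for rec in dataset.records:
        renamed: list[tuple[str, str]] = []
        unmatched: list[str] = []

        seen: set[str] = set()
        merged: list[str] = []

        def rebuild(node: TreeNode) -> TreeNode | None:
            if node.is_leaf:
                label = node.label
                if label in synmap:
                    accepted = synmap[label]
                    if accepted != label:
                        renamed.append((label, accepted))
                    label = accepted
                elif synmap:
                    unmatched.append(node.label)
                if label in seen:
                    merged.append(label)
                    return None
                seen.add(label)
                return TreeNode(label)
            kids = [k for k in (rebuild(c) for c in node.children) if k is not None]
            if not kids:
                return None
            return kids[0] if len(kids) == 1 else TreeNode(children=kids)

        root = rebuild(rec.tree.root)
        assert root is not None
        new_records.append(replace(rec, tree=RootedTree(root)))
        for old, new in renamed:
            events.append(CurationEvent("standardize", rec.study_key, "renamed", f"{old} -> {new}"))
        for label in merged:
            events.append(
                CurationEvent("standardize", rec.study_key, "merged_duplicate",
                              f"{label}: kept first pre-order occurrence")
            )
        for label in sorted(set(unmatched)):
            events.append(CurationEvent("standardize", rec.study_key, "unmatched", label))
    return Dataset(new_records, dataset.synonym_map, dataset.taxonomy), events


# ---------------------------------------------------------------------------
# Higher-taxon substitution
# ---------------------------------------------------------------------------


def substitute_higher_taxa(dataset: Dataset) -> tuple[Dataset, list[CurationEvent]]:
    """Replace higher-taxon leaves by a polytomy of constituent species.

    Each leaf whose label is a key of the taxonomy map is replaced by the
    constituent species that occur in *other* source trees of the dataset: as
    a polytomy if several, a rename if exactly one, a deletion if none. This
    avoids inflating the taxon set with species no other tree can place.
    Species already present in the focal tree are not duplicated.
    """
    events: list[CurationEvent] = []
    leafsets = [rec.taxa for rec in dataset.records]
    new_records: list[SourceTreeRecord] = []
    for i, rec in enumerate(dataset.records):
        taxa_elsewhere: set[str] = set()
        for j, ls in enumerate(leafsets):
            if j != i:
                taxa_elsewhere |= ls
        focal = rec.taxa
        inserted: set[str] = set()  # constituents already placed in this tree

        def rebuild(node: TreeNode) -> TreeNode | None:
            if node.is_leaf:
                label = node.label
                if label not in dataset.taxonomy:
                    return TreeNode(label)
                constituents = sorted(dataset.taxonomy[label] & taxa_elsewhere)
                dropped_in_focal = [c for c in constituents if c in focal or c in inserted]
                constituents = [c for c in constituents if c not in focal and c not in inserted]
                inserted.update(constituents)
                for c in dropped_in_focal:
                    events.append(
                        CurationEvent("substitute", rec.study_key, "constituent_already_present",
                                      f"{label}: {c}")
                    )
                if not constituents:
                    events.append(CurationEvent("substitute", rec.study_key, "leaf_removed",
                                                f"{label}: no constituents in other trees"))
                    return None
                if len(constituents) == 1:
                    events.append(CurationEvent("substitute", rec.study_key, "leaf_renamed",
                                                f"{label} -> {constituents[0]}"))
                    return TreeNode(constituents[0])
                events.append(CurationEvent("substitute", rec.study_key, "polytomy_substituted",
                                            f"{label} -> {{{', '.join(constituents)}}}"))
                return TreeNode(children=[TreeNode(c) for c in constituents])
            kids = [k for k in (rebuild(c) for c in node.children) if k is not None]
            if not kids:
                return None
            return kids[0] if len(kids) == 1 else TreeNode(children=kids)

        root = rebuild(rec.tree.root)
        if root is None or len(root.leaf_labels()) < 2:
            events.append(CurationEvent("substitute", rec.study_key, "record_dropped",
                                        "fewer than two leaves after substitution"))
            continue
        new_records.append(replace(rec, tree=RootedTree(root)))
    return Dataset(new_records, dataset.synonym_map, dataset.taxonomy), events


# ---------------------------------------------------------------------------
# Independence weighting / removal
# ---------------------------------------------------------------------------


def apply_independence(dataset: Dataset) -> tuple[Dataset, list[CurationEvent]]:
    """Down-weight identical source trees and remove within-study subsets.

    Non-independence is judged from the (character types, taxon set)
    signature. Records with identical signatures are weighted in inverse
    proportion to their number. When two records from the same study share
    character types and one taxon set is a strict subset of the other, the
    less inclusive record is removed. Cross-study subsets are reported but
    never removed automatically.
    """
    events: list[CurationEvent] = []
    records = list(dataset.records)

    # -- subset removal (same study lineage only) --
    removed: set[int] = set()
    for i, j in itertools.combinations(range(len(records)), 2):
        if i in removed or j in removed:
            continue
        a, b = records[i], records[j]
        if frozenset(a.character_types) != frozenset(b.character_types):
            continue
        small, big, small_idx = None, None, None
        if a.taxa < b.taxa:
            small, big, small_idx = a, b, i
        elif b.taxa < a.taxa:
            small, big, small_idx = b, a, j
        if small is None:
            continue
        if a.study_key == b.study_key:
            removed.add(small_idx)
            events.append(CurationEvent("independence", small.study_key, "subset_removed",
                                        f"taxa are a strict subset of a same-study tree "
                                        f"({len(small.taxa)} < {len(big.taxa)} taxa)"))
        else:
            events.append(CurationEvent("independence", small.study_key, "cross_study_subset_reported",
                                        f"taxa are a strict subset of {big.study_key}; not removed"))
    records = [r for k, r in enumerate(records) if k not in removed]

    # -- identical-signature down-weighting --
    groups: dict[tuple[frozenset, frozenset], list[int]] = {}
    for k, rec in enumerate(records):
        groups.setdefault((frozenset(rec.character_types), rec.taxa), []).append(k)
    new_records = list(records)
    for members in groups.values():
        if len(members) > 1:
            w = Fraction(1, len(members))
            for k in members:
                new_records[k] = replace(records[k], weight=w)
                events.append(CurationEvent("independence", records[k].study_key, "reweighted",
                                            f"identical signature shared by {len(members)} trees; "
                                            f"weight set to 1/{len(members)}"))
    return Dataset(new_records, dataset.synonym_map, dataset.taxonomy), events


# ---------------------------------------------------------------------------
# Taxonomic overlap
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OverlapReport:
    """Connectivity of the pairwise taxon-overlap graph."""

    passes: bool
    min_shared: int
    components: tuple[frozenset[int], ...]  # record indices
    removal_candidates: tuple[int, ...]  # indices outside the largest component

    @property
    def n_components(self) -> int:
        return len(self.components)


def check_overlap(dataset: Dataset, min_shared: int = 2) -> OverlapReport:
    """Check that every source tree shares >= ``min_shared`` taxa with another.

    Builds a graph with one vertex per record and an edge whenever two records
    share at least ``min_shared`` taxa; the dataset passes when the graph has
    a single connected component. On failure the records outside the largest
    component are listed as candidates for removal.
    """
    if len(dataset.records) < 2:
        raise ValueError("overlap check requires at least two records")
    g = nx.Graph()
    g.add_nodes_from(range(len(dataset.records)))
    for i, j in itertools.combinations(range(len(dataset.records)), 2):
        if len(dataset.records[i].taxa & dataset.records[j].taxa) >= min_shared:
            g.add_edge(i, j)
    comps = sorted((frozenset(c) for c in nx.connected_components(g)),
                   key=lambda c: (-len(c), min(c)))
    passes = len(comps) == 1
    candidates: tuple[int, ...] = ()
    if not passes:
        largest = comps[0]
        candidates = tuple(sorted(i for i in range(len(dataset.records)) if i not in largest))
    return OverlapReport(passes, min_shared, tuple(comps), candidates)


# ---------------------------------------------------------------------------
# Dataset summaries
# ---------------------------------------------------------------------------


@dataclass
class SummaryTables:
    trees_per_year: pd.DataFrame  # columns: year, n_trees
    characters_per_year: pd.DataFrame  # columns: year, character_type, n_trees
    taxon_presence: pd.DataFrame  # columns: taxon, group, n_trees
    tree_sizes: pd.DataFrame  # columns: study_key, n_taxa


def dataset_summary(dataset: Dataset,
                    grouping: Mapping[str, str] | None = None) -> SummaryTables:
    """Summary tables: trees per year, character sources per year, per-taxon
    presence counts (optionally partitioned by a user-supplied grouping, e.g.
    family), and the source-tree size distribution."""
    years = pd.DataFrame(
        [(rec.year,) for rec in dataset.records], columns=["year"]
    )
    trees_per_year = (years.value_counts().rename("n_trees").reset_index()
                      .sort_values("year").reset_index(drop=True)
                      if len(years) else pd.DataFrame(columns=["year", "n_trees"]))

    rows = [(rec.year, ct) for rec in dataset.records for ct in rec.character_types]
    chars = pd.DataFrame(rows, columns=["year", "character_type"])
    characters_per_year = (chars.value_counts().rename("n_trees").reset_index()
                           .sort_values(["year", "character_type"]).reset_index(drop=True)
                           if len(chars) else
                           pd.DataFrame(columns=["year", "character_type", "n_trees"]))

    presence: dict[str, int] = {}
    for rec in dataset.records:
        for t in rec.taxa:
            presence[t] = presence.get(t, 0) + 1
    grouping = grouping or {}
    taxon_presence = pd.DataFrame(
        [(t, grouping.get(t, ""), n) for t, n in sorted(presence.items())],
        columns=["taxon", "group", "n_trees"],
    )

    tree_sizes = pd.DataFrame(
        [(rec.study_key, len(rec.taxa)) for rec in dataset.records],
        columns=["study_key", "n_taxa"],
    )
    return SummaryTables(trees_per_year, characters_per_year, taxon_presence, tree_sizes)


# ---------------------------------------------------------------------------
# Bundle I/O
# ---------------------------------------------------------------------------

_META_COLUMNS = ["study_key", "year", "character_types", "method", "weight",
                 "tree_file", "has_explicit_matrix", "taxa_identifiable"]


def save_bundle(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset bundle: trees/ (Newick), metadata.csv, synonyms.csv,
    taxonomy.csv."""
    path = Path(path)
    (path / "trees").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(dataset.records):
        fname = f"trees/tree_{i:03d}.nwk"
        (path / fname).write_text(write_newick(rec.tree) + "\n")
        rows.append({
            "study_key": rec.study_key,
            "year": rec.year,
            "character_types": ";".join(rec.character_types),
            "method": rec.method,
            "weight": str(rec.weight),
            "tree_file": fname,
            "has_explicit_matrix": rec.has_explicit_matrix,
            "taxa_identifiable": rec.taxa_identifiable,
        })
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path / "metadata.csv", index=False)
    pd.DataFrame(sorted(dataset.synonym_map.items()),
                 columns=["name", "accepted"]).to_csv(path / "synonyms.csv", index=False)
    tax_rows = [(ht, sp) for ht, members in sorted(dataset.taxonomy.items())
                for sp in sorted(members)]
    pd.DataFrame(tax_rows, columns=["higher_taxon", "species"]).to_csv(
        path / "taxonomy.csv", index=False)


def load_bundle(path: str | Path) -> Dataset:
    """Read a dataset bundle written by :func:`save_bundle`."""
    path = Path(path)
    meta = pd.read_csv(path / "metadata.csv")
    records = []
    for _, row in meta.iterrows():
        tree = parse_newick((path / row["tree_file"]).read_text())
        records.append(SourceTreeRecord(
            tree=tree,
            study_key=str(row["study_key"]),
            year=int(row["year"]),
            character_types=tuple(str(row["character_types"]).split(";")),
            method=str(row.get("method", "unspecified")),
            weight=Fraction(str(row["weight"])) if "weight" in row else Fraction(1),
            has_explicit_matrix=bool(row.get("has_explicit_matrix", True)),
            taxa_identifiable=bool(row.get("taxa_identifiable", True)),
        ))
    synonym_map: dict[str, str] = {}
    syn_path = path / "synonyms.csv"
    if syn_path.exists():
        syn = pd.read_csv(syn_path)
        if len(syn):
            synonym_map = dict(zip(syn["name"].astype(str), syn["accepted"].astype(str)))
    taxonomy: dict[str, set[str]] = {}
    tax_path = path / "taxonomy.csv"
    if tax_path.exists():
        tax = pd.read_csv(tax_path)
        for _, row in tax.iterrows():
            taxonomy.setdefault(str(row["higher_taxon"]), set()).add(str(row["species"]))
    return Dataset(records, synonym_map, {k: frozenset(v) for k, v in taxonomy.items()})


def save_xml_bundle(dataset: Dataset, path: str | Path) -> None:
    """Write the dataset as a single self-describing XML file (sources with
    meta-data and Newick strings plus the name resources)."""
    root = ET.Element("supertree_dataset")
    sources = ET.SubElement(root, "sources")
    for rec in dataset.records:
        src = ET.SubElement(sources, "source", {
            "study_key": rec.study_key,
            "year": str(rec.year),
            "method": rec.method,
            "weight": str(rec.weight),
            "has_explicit_matrix": str(rec.has_explicit_matrix).lower(),
            "taxa_identifiable": str(rec.taxa_identifiable).lower(),
        })
        chars = ET.SubElement(src, "character_types")
        for ct in rec.character_types:
            ET.SubElement(chars, "character").text = ct
        ET.SubElement(src, "tree").text = write_newick(rec.tree)
    syns = ET.SubElement(root, "synonyms")
    for name, accepted in sorted(dataset.synonym_map.items()):
        ET.SubElement(syns, "synonym", {"name": name, "accepted": accepted})
    tax = ET.SubElement(root, "taxonomy")
    for ht, members in sorted(dataset.taxonomy.items()):
        el = ET.SubElement(tax, "higher_taxon", {"name": ht})
        for sp in sorted(members):
            ET.SubElement(el, "species").text = sp
    ET.indent(root)
    ET.ElementTree(root).write(str(path), encoding="unicode", xml_declaration=True)


def load_xml_bundle(path: str | Path) -> Dataset:
    """Read a single-file XML dataset written by :func:`save_xml_bundle`."""
    root = ET.parse(str(path)).getroot()
    records = []
    for src in root.find("sources") or []:
        records.append(SourceTreeRecord(
            tree=parse_newick(src.findtext("tree")),
            study_key=src.get("study_key"),
            year=int(src.get("year")),
            character_types=tuple(c.text for c in src.find("character_types")),
            method=src.get("method", "unspecified"),
            weight=Fraction(src.get("weight", "1")),
            has_explicit_matrix=src.get("has_explicit_matrix", "true") == "true",
            taxa_identifiable=src.get("taxa_identifiable", "true") == "true",
        ))
    synonym_map = {el.get("name"): el.get("accepted")
                   for el in (root.find("synonyms") or [])}
    taxonomy = {el.get("name"): frozenset(sp.text for sp in el)
                for el in (root.find("taxonomy") or [])}
    return Dataset(records, synonym_map, taxonomy)
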
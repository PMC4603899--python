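"""End-to-end supertree pipeline: curate -> encode -> search -> summarise.

Runs the full protocol over a dataset bundle and writes every intermediate
artifact (curated bundle, MRP matrix, MPT set, consensus/MAST tree, support
table, dataset summaries) plus a machine-readable run log. Every stage is a
pure function of (inputs, config, seed), so a rerun with identical inputs is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .consensus import drop_taxon, mast_k, strict_consensus
from .curation import (Dataset, apply_independence, check_overlap, dataset_summary,
                       load_bundle, save_bundle, standardize_names,
                       substitute_higher_taxa)
from .mrp import DEFAULT_OUTGROUP, encode_brs, write_matrix
from .parsimony import heuristic_search
from .support import annotated_newick, novel_clades, support_table, v_indices
from .tree import write_newick, write_trees

__all__ = ["PipelineConfig", "PipelineError", "PipelineResult", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")


@dataclass
class PipelineConfig:
    """Configuration of a full run.

    ``consensus`` selects the MPT summary: ``"mast"`` (the protocol's
    choice) or ``"strict"``. ``exact_limit`` bounds the exact MAST subset
    search; above it the iterated-pairwise heuristic runs.
    ``auto_remove_disconnected`` lets the overlap stage drop records outside
    the largest overlap component instead of halting.
    """

    outdir: str | Path
    seed: int = 0
    replicates: int = 20
    maxtrees: int = 1000
    consensus: str = "mast"
    exact_limit: int = 8
    min_shared: int = 2
    matrix_format: str = "tnt"
    outgroup: str = DEFAULT_OUTGROUP
    auto_remove_disconnected: bool = False
    mast_max_trees: int = 50
    use_tbr: bool = True

    def __post_init__(self):
        if self.consensus not in ("mast", "strict"):
            raise PipelineError("config", f"unknown consensus method {self.consensus!r}")
        if self.matrix_format not in ("tnt", "nexus"):
            raise PipelineError("config", f"unknown matrix format {self.matrix_format!r}")


@dataclass
class PipelineResult:
    """In-memory results of a run (artifacts are also written to outdir)."""

    curated: Dataset
    matrix: object
    search: object
    supertree: object
    supports: list
    novel: list
    events: list = field(default_factory=list)
    artifacts: dict = field(default_factory=dict)


def run_pipeline(dataset: Dataset, config: PipelineConfig) -> PipelineResult:
    """Execute the full protocol on ``dataset`` and write artifacts.

    Stages: inclusion filter -> standardise names -> substitute higher taxa
    -> independence weighting -> overlap check -> Baum-Ragan encoding ->
    heuristic parsimony search -> consensus/MAST -> V/V+ support -> summary
    tables. Any stage failure raises :class:`PipelineError` naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    events = []
    log: dict = {
        "version": __version__,
        "config": {k: str(v) if isinstance(v, Path) else v
                   for k, v in dataclasses.asdict(config).items()},
        "stages": {},
    }

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrap

    # -- curation ----------------------------------------------------------
    def _curate():
        ds, ev = dataset.filter_included()
        all_ev = list(ev)
        ds, ev = standardize_names(ds)
        all_ev += ev
        ds, ev = substitute_higher_taxa(ds)
        all_ev += ev
        ds, ev = apply_independence(ds)
        all_ev += ev
        return ds, all_ev

    curated, ev = stage("curate")(_curate)
    events += ev
    log["stages"]["curate"] = {
        "records": len(curated.records),
        "taxa": len(curated.taxa()),
        "events": len(ev),
    }

    def _overlap():
        nonlocal curated
        report = check_overlap(curated, min_shared=config.min_shared)
        if not report.passes:
            if not config.auto_remove_disconnected:
                raise PipelineError(
                    "overlap",
                    f"overlap graph has {report.n_components} components; records "
                    f"{list(report.removal_candidates)} lack sufficient overlap",
                )
            keep = [r for i, r in enumerate(curated.records)
                    if i not in report.removal_candidates]
            curated = Dataset(keep, curated.synonym_map, curated.taxonomy)
            report = check_overlap(curated, min_shared=config.min_shared)
            if not report.passes:
                raise PipelineError("overlap", "still disconnected after auto-removal")
        return report

    report = _overlap()
    log["stages"]["overlap"] = {"components": report.n_components,
                                "records": len(curated.records)}
    save_bundle(curated, outdir / "curated")

    # -- encoding ----------------------------------------------------------
    matrix = stage("encode")(lambda: encode_brs(curated, config.outgroup))
    matrix_path = outdir / f"matrix.{'tnt' if config.matrix_format == 'tnt' else 'nex'}"
    matrix_path.write_text(write_matrix(matrix, config.matrix_format))
    log["stages"]["encode"] = {"taxa": matrix.n_taxa, "characters": matrix.n_characters}

    # -- search ------------------------------------------------------------
    search = stage("search")(lambda: heuristic_search(
        matrix, replicates=config.replicates, seed=config.seed,
        maxtrees=config.maxtrees, use_tbr=config.use_tbr))
    write_trees(search.mpts, str(outdir / "mpts.tre"))
    log["stages"]["search"] = {
        "best_length": str(search.best_length),
        "n_mpts": search.n_mpts,
        "replicates": search.replicates_run,
        "seed": search.seed,
    }

    # -- consensus ---------------------------------------------------------
    def _consensus():
        ingroup_trees = drop_taxon(list(search.mpts), config.outgroup)
        if len(ingroup_trees) == 1:
            return ingroup_trees[0]
        if config.consensus == "strict":
            return strict_consensus(ingroup_trees)
        return mast_k(ingroup_trees, exact_limit=config.exact_limit,
                      max_trees=config.mast_max_trees, seed=config.seed).tree

    supertree = stage("consensus")(_consensus)
    (outdir / "supertree.tre").write_text(write_newick(supertree) + "\n")
    log["stages"]["consensus"] = {"method": config.consensus,
                                  "n_leaves": len(supertree.leaves)}

    # -- support -----------------------------------------------------------
    supports = stage("support")(lambda: v_indices(supertree, curated, config.outgroup))
    novel = [ns.clade for ns in supports if ns.is_novel]
    support_table(supports).to_csv(outdir / "support.csv", index=False)
    (outdir / "supertree_annotated.tre").write_text(
        annotated_newick(supertree, supports, config.outgroup) + "\n")
    defined = [ns for ns in supports if ns.V is not None]
    log["stages"]["support"] = {
        "nodes": len(supports),
        "novel_clades": len(novel),
        "negative_V": sum(1 for ns in defined if ns.V < 0),
    }

    # -- summaries ---------------------------------------------------------
    tables = stage("summarize")(lambda: dataset_summary(curated))
    tables.trees_per_year.to_csv(outdir / "trees_per_year.csv", index=False)
    tables.characters_per_year.to_csv(outdir / "characters_per_year.csv", index=False)
    tables.taxon_presence.to_csv(outdir / "taxon_presence.csv", index=False)
    tables.tree_sizes.to_csv(outdir / "tree_sizes.csv", index=False)

    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return PipelineResult(curated, matrix, search, supertree, supports, novel,
                          events, {"outdir": str(outdir)})


def run_pipeline_from_bundle(bundle: str | Path, config: PipelineConfig) -> PipelineResult:
    """Load a dataset bundle from disk and run the pipeline on it."""
    return run_pipeline(load_bundle(bundle), config)
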
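# Methods

This note documents the models, algorithms and numerical choices behind
`mrpkit`, and what its synthetic experiments do and do not demonstrate.

## Trees and canonical serialisation

All stages operate on rooted, leaf-labelled topologies; polytomies are
allowed, branch lengths and internal labels are parsed (dendropy) and
discarded, and unifurcations are suppressed at construction. Underscores in
unquoted Newick labels are read literally — source trees in the wild use
them as word separators inside names, and silently mapping them to spaces
creates phantom synonym pairs. Duplicate leaf labels are a hard parse error:
the curation stage handles post-synonymisation duplicates explicitly, and
silent merging at parse time would hide data errors.

Output Newick is canonical: children are ordered lexicographically by their
smallest contained leaf, labels outside the safe alphabet are single-quoted
(doubling embedded quotes), and an option writes spaces as underscores for
tools that dislike quoting. Canonical output is what makes whole-pipeline
reruns byte-identical and lets tree sets be deduplicated by string equality.

## Curation

*Standardisation* replaces each leaf label by its accepted name from a
local, user-editable synonym table (names absent from the table pass through
and are logged). The table is completed to idempotence at load: accepted
names map to themselves. If renaming makes two leaves of one tree identical
they are merged, keeping the first pre-order occurrence — an arbitrary but
deterministic tie-break, logged per event.

*Higher-taxon substitution* replaces a leaf named in the taxonomy table by
the constituent species that occur in **other** source trees, as a polytomy
(singleton → rename, empty → deletion). Using only species other trees
contain avoids inflating the taxon set with terminals nothing else can
place. The polytomy deliberately encodes ignorance of intra-group structure;
as a consequence substitution can flatten true structure, and in adversarial
cases the flattened group can even pull the supertree away from the true
resolution. This is a property of the protocol, not of the implementation,
and the synthetic tests assert compatibility rather than identity wherever
higher-taxon noise is active.

*Independence*: records with identical (character types, taxon set)
signatures are weighted 1/k each, so a group of k republished trees carries
the evidence of one. A record whose taxon set is a strict subset of a
same-study record with the same character types is removed. Cross-study
subsets are only reported: deciding that two studies' matrices are truly
nested needs the matrices, which the meta-data signature cannot prove.

*Overlap*: a graph with one vertex per record and an edge where two records
share at least `min_shared` (default 2) taxa must be connected; otherwise
records outside the largest component are listed for removal (the pipeline
halts unless auto-removal is enabled). Two shared taxa is the minimum for a
source tree to constrain anything relative to the rest of the data.

## Baum–Ragan encoding

One character per nontrivial, non-root clade per source tree, in record
order then pre-order: clade members 1, other taxa of the same tree 0, taxa
absent from the tree ?. A hypothetical all-zero outgroup row roots the
analysis; its reserved name (`MRP_Outgroup`) is rejected if it collides with
a real taxon. The root node contributes no character — against the all-zero
outgroup it would be constant. Character weights are the record weights kept
as exact `Fraction`s; serialisation (TNT `xread`/`ccode`, NEXUS
DATA + `WTSET`) scales them to integers by the LCM of denominators, the only
point where weights leave exact arithmetic.

For a dataset consisting of one binary tree on n taxa the matrix has n − 2
characters and is compatible: its minimum parsimony length equals its
character count, which the tests use as a closed-form oracle.

## Parsimony

Fitch state sets are packed two bits per character into Python integers,
grouped by weight, so one Fitch merge is a handful of bitwise operations on
the whole character block and the score is an exact rational
(integer-weighted changes / common denominator). "?" is the full state set
{0, 1}. Length is invariant to rerooting and child order (tested), which is
why the search can work with rooted representations throughout and root on
the outgroup only when reporting.

The heuristic search runs `replicates` random-addition sequences (RNG seeded
`seed + replicate`, so replicate sets nest and the best length is monotone
non-increasing in the replicate count), each followed by SPR to local
optimality and then TBR (the pruned subtree re-rooted on each of its edges),
with first-improvement acceptance. Equal-length trees seen on the final
plateau are pooled, deduplicated on their outgroup-rooted canonical form,
and capped at `maxtrees`. Library defaults are desk-scale (20 replicates,
1000 trees); both are plain parameters. The number of equally parsimonious
trees found is cap- and neighbourhood-dependent and is never treated as a
result.

`branch_and_bound` enumerates each unrooted topology exactly once (rooted
trees on the non-outgroup taxa, attached under the outgroup) with
partial-length pruning against a greedy upper bound, returning the complete
set of minimum-length trees. It refuses more than 12 taxa; its purpose is to
be an exact oracle, and above that size exhaustive verification is no longer
practical anyway.

## Consensus and MAST

Strict consensus intersects clade sets. The Maximum Agreement Subtree of a
tree pair is computed exactly by dynamic programming over node pairs
(binary trees; ties broken toward the lexicographically smallest taxon-name
set so the result is deterministic and argument-symmetric). For k > 2 trees
the problem is NP-hard: up to `exact_limit` leaves (default 8) an exact
descending-size subset search runs; above it the pairwise DP is iterated
over the trees in input order and the final leaf set is verified to be a
genuine agreement set for every input — a verification failure is raised as
an internal error, never returned. Very large tree sets can be subsampled
uniformly with a fixed, logged seed before MAST. The synthetic outgroup is
dropped before any consensus, and reported taxon counts never include it.

## Node support: V and V⁺

For each nontrivial supertree clade, each source tree is classified on the
taxa it shares with the supertree: with A = clade members in the source
tree and B = the source tree's other shared taxa, the tree is irrelevant if
|A| < 2 or |B| < 1; supporting if A is one of its clades; conflicting if one
of its clades straddles A (A∩X, A\X, X\A all nonempty); permitting
otherwise (e.g. compatible through a polytomy). Then

V = (s − q)/(s + q) (defined iff s + q > 0),
V⁺ = (s + p − q)/(s + p + q) (defined iff s + p + q > 0).

Choices worth making explicit:

* **Shared-taxon comparison.** Source trees are pruned to the supertree's
  leaf set before their clades are read. When the supertree is a MAST,
  unpruned comparison would let any source-tree clade containing a dropped
  taxon straddle every deep node, driving all deep nodes to V = −1
  regardless of actual agreement; pruning makes V measure disagreement
  about taxa both trees actually place.
* **Undefined vs zero.** Nodes with s + q = 0 report V as undefined
  (never 0); V = 0 means balanced support (s = q > 0). The distinction
  matters for summaries such as "share of nodes positive for both".
* **Unweighted counts.** Independence weights shape the parsimony analysis,
  not the support census: s, q, p, r count source trees.
* **Novel clades** are nodes with s = 0 and q + p ≥ 1. A clade no source
  tree can evaluate (all irrelevant) is reported separately, not as novel —
  it is vacuously absent rather than spurious.

Outputs: a per-node CSV (members, s, q, p, r, V, V⁺, and a colour class:
full V = 1, partial 0 < V < 1, zero, negative, undefined) and a Newick file
with V values as internal labels.

## Synthetic data

The generator emulates the raw material of a supertree study at desk scale.
A binary model tree grows by uniform random leaf splitting (Yule / equal
rates). Yule growth is uniform over labelled *histories*, not topologies:
at n = 4 each labelled caterpillar has probability 1/18 and each balanced
tree 1/9, and the test suite checks those exact frequencies over 3000
draws. Leaf labels are attached as a uniform random permutation after the
shape is grown, which is what makes the law exact.

Each of k source trees is the model tree restricted to a uniform random
subsample (size uniform on a configured range), perturbed by a configured
number of rooted NNI moves (topological conflict) and per-edge contraction
probability (polytomies), with meta-data drawn from fixed pools
(years 1992–2013; morphology and common single-gene character classes).
Overlap connectivity is enforced by resampling offending trees — rejection
keeps the subsample distribution uniform conditional on acceptance — with a
hard retry cap. Nomenclature noise renames a fraction of leaf occurrences to
pseudo-synonyms and replaces a fraction with invented higher-taxon labels
defined (in the emitted taxonomy key) as the parent clade of the leaf in the
model tree; the emitted key is exactly what curation needs to undo the
renaming (higher-taxon substitution is only invertible up to its polytomy
effects, see above).

Defaults (32-taxon model, 12 trees of 6–16 taxa, 1 NNI move, 10% edge
contraction, 10% synonym and 5% higher-taxon noise) are chosen to mirror the
shape of a real curated collection — small trees dominating, mild but real
conflict, mixed character sources — at a size where the full pipeline runs
in seconds. What passing tests show is that the machinery is correct and
that the protocol recovers truth under clean conditions; they do not show
robustness to systematic conflict (e.g. deep gene-tree discordance),
branch-length effects, or literature-scale taxon sampling, none of which
the generator models.

A note on exact recovery: even with zero perturbation, a model clade that no
subsampled source tree witnesses yields no MRP character, so the strict
consensus is correctly less resolved than the model tree, and the MAST drops
taxa whose placement the equally parsimonious trees cannot agree on. The
guaranteed properties — asserted by the tests and recomputed by the
acceptance script — are that every strict-consensus clade is a true model
clade with V = 1 wherever V is defined and no novel clades, and that the
MAST matches the model tree exactly on the MAST's own leaf set.

## Pipeline and reproducibility

`run_pipeline` chains the stages, writes every intermediate (curated bundle,
matrix, MPT set, supertree, support table, summary tables) and a
machine-readable run log (config, seed, package version, per-stage
summaries). All randomness flows from the single config seed; artifacts are
byte-identical across reruns with identical inputs. The acceptance script
(`scripts/acceptance.py --seed N --out file.json`) recomputes the recovery
experiment, a default-conditions run and the oracle agreement rates from
scratch at the problem sizes stated above, chosen so the whole script
completes in well under a minute.

## Known limitations

* Polytomies are scored by sequential Fitch folding of children; for the
  binary trees the search manipulates this is exact Fitch.
* The k-tree MAST heuristic is order-dependent and carries no approximation
  guarantee; its result is verified to be an agreement set, and compared
  against the exact search wherever the exact search is feasible.
* Cross-study non-independence is detected only through meta-data
  signatures, not through the underlying character matrices.
* Input trees must be rooted; how originally unrooted source trees were
  rooted is the curator's responsibility, not inferred here.
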
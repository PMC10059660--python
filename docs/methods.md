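# Methods

This note documents the models, conventions, and numerical choices behind
`aoxsom`, and what the shipped tests do and do not demonstrate.

## Problem setting

Human aldehyde oxidase (hAOX) oxidizes electron-poor carbons of
N-heteroaromatic rings, converting a ring C–H into C–OH (or the lactam
tautomer). The prediction task is atom-level: given a substrate, propose the
candidate carbons and rank them by their probability of being the observed
site of metabolism (SOM). The package treats this as supervised binary
classification of candidate atoms, followed by per-molecule ranking.

## Molecule standardization and atom identity

All molecules pass through one standardization: keep the largest fragment by
heavy-atom count (salt/solvent stripping), neutralize charges where RDKit's
uncharger deems it safe, perceive aromaticity, and re-parse from the
canonical SMILES so the in-memory atom order *is* the canonical order. Every
downstream index — candidate sites, labels, rankings — refers to this order.
Tautomer canonicalization is available but off by default: forcing a
canonical tautomer can move aromatic hydrogen counts that the site-type
patterns depend on, and it destroys the input→canonical atom correspondence.

Two conventions worth stating:

* **Atom maps vs indices.** Atom-map numbers in reaction SMILES (1-based,
  arbitrary) are a separate namespace, translated to canonical 0-based
  indices at the boundary and never used internally.
* **Symmetry orbits.** Canonical-SMILES output order breaks ties between
  graph-equivalent atoms using the current atom order, so an index on a
  symmetric molecule (benzene is the extreme case) is only meaningful up to
  the automorphism orbit. Label extraction therefore renumbers the reactant
  into map order first, making the result a pure function of (graph, maps)
  and invariant to how the reaction string was written. Equivalent atoms
  have identical atom-environment fingerprints, so orbit ambiguity cannot
  change a model's scores — only which of two chemically identical atoms
  carries the printed index.

## Label extraction from mapped reactions

A reactant atom is a SOM iff its total hydrogen count or its multiset of
heavy neighbors differs between the two sides of the mapped reaction.
Neighbors are keyed by map number when the map exists on the reactant side
and by element otherwise, so the incoming oxygen (unmapped, or mapped only
in the product) registers as a new neighbor. Bond-order-only changes —
aromatic bond reorganization in an otherwise intact ring — are ignored on
purpose: hAOX chemistry is an oxygen addition at a ring carbon, and the
enol/lactam drawing of the product should not relabel untouched atoms.
Substrates with several reported metabolites contribute the union of their
per-reaction labels (one record per substrate).

## Candidate-site types

Type A (α to a ring N) and type B (γ to a ring N through three conjugated
bonds) are each defined twice: a brute-force atom-iteration routine that is
the normative semantics, and a SMARTS pattern used as the fast path. The
"conjugated" steps of type B accept aromatic or double bonds; a
conjugated-but-single linkage (e.g. a biaryl bond) does not count, which
keeps the two routes provably identical predicates. Equality of the two
routes is asserted on 500 generated azaheteroaromatics plus the worked
examples. The site definitions ship as an editable YAML file; a user-added
type with a new code has only the SMARTS route.

## Fingerprints

Atom-environment descriptors come from RDKit's fingerprint generators with
the `fromAtoms` restriction: Morgan environments rooted at the center atom
(radius 1–5), atom pairs having the center as an endpoint, torsion paths
containing the center. Widths 256–2048 bits; folding is the generators'
native modulo hashing, collisions accepted. The default sweep is 28 recipes
(5 Morgan radii × 4 widths + AtomPair × 4 + TopologicalTorsion × 4); with
three classifier families this spans 84 baseline configurations. Bits are
binary; no counts, physicochemical, or 3-D descriptors.

## Feature selection

* **VT** (variance threshold): drops columns with variance ≤ t, default
  t = 0 (constant bits only).
* **SPF** (select percentile): scores columns by χ² association with the
  label (`f_classif` available by config) and keeps the top ⌈p% of
  columns⌉, ties broken toward the lower column index, NaN scores ranked
  last. The exact-count ceiling convention is implemented in-package; the
  common percentile-threshold convention can keep a different number of
  columns on ties, and an exact contract is easier to test and reproduce.
* **PCA**: mean-centered only — the variance of a bit column is meaningful,
  so no scaling — with full SVD and a deterministic sign convention (the
  largest-magnitude loading of each component is made positive).

Selection stages are part of the model pipeline and are refitted inside
every cross-validation training fold, never on held-out rows.

Default sweep values where a single run needs them: VT threshold {0}, SPF
percentile {5, 10, 15, 20, 30, 50}, PCA components {32, 64, 128, 256}.
These are reconstructions chosen to bracket the useful range on
2048-bit inputs, not values with external provenance.

## Classifiers and model selection

SVM (`SVC`), random forest, and gradient-boosted trees, each with a
reconstructed default grid (overridable per run):

| family | grid |
|---|---|
| SVM | kernel ∈ {rbf, linear}; C ∈ {0.1, 1, 10, 100}; γ ∈ {scale, 0.01, 0.001} |
| RF | trees ∈ {100, 300, 500}; depth ∈ {∞, 5, 10} |
| GBDT | rate ∈ {0.05, 0.1, 0.2}; stages ∈ {100, 300}; depth ∈ {2, 3, 5} |

Grid search runs under stratified k-fold CV (default k = 10, seed default 7,
always logged); the selection metric is mean fold AUC by default (F1 by
config) — AUC is threshold-free, which suits a ranking application. Ties
between grid points resolve to the first point in deterministic grid order;
the best point is refitted on all rows; all per-fold scores are retained.
Class weighting is available but off by default (the curated data are close
to balanced at the site level).

**Scores.** Tree ensembles score candidates with their positive-class
probability. SVMs score with a logistic squash of the raw decision value:
a monotone map to (0, 1), so rankings equal raw-score rankings while
avoiding the run-to-run nondeterminism of internal Platt calibration. The
decision threshold for site-level confusion metrics defaults to 0.5 and is
a config/CLI option. Ranking ties break toward the lower atom index.

## Evaluation

Site-level SE/SP/ACC/F1/MCC are computed from confusion counts; any metric
with a zero denominator is reported as explicit `null` with a flag, never
silently 0. AUC uses midrank tie handling. Top-k accuracy counts a molecule
as correct iff *any* of its true SOMs appears among the k best-ranked
candidates — with several experimental SOMs, hitting one is a correct
prediction. Molecules whose true SOM is not proposed by any candidate
pattern count as failures at every k; their fraction is reported separately
as the coverage ceiling. Tanimoto diagnostics use whole-molecule
Morgan-1024/r2 fingerprints, mean over unordered distinct pairs, 0.05-wide
histogram bins; a pair with an empty fingerprint gets similarity 0 with a
warning. Chemical-space PCA pools all sets before centering so clouds are
comparable.

## Synthetic substrates

The generator emulates the *shape* of a curated hAOX collection:
azaheteroaromatic scaffolds (pyridine, pyrimidine, quinoline, quinazoline,
cinnoline, purine) decorated with 0–2 small substituents (alkyl, halogen,
OH, OMe, NH₂, CF₃) at non-candidate ring positions, labeled by a
deterministic rule over the candidate sites:

* `A-only` — every α-type candidate is a SOM;
* `bis-N-flanked` (default) — candidates with two aromatic ring-N neighbors
  are SOMs; scaffolds without such a carbon are resampled away;
* `distance-weighted` — one SOM drawn with probability ∝ 1/d² to the
  nearest two-connected ring N (a stochastic, harder task).

Same seed ⇒ byte-identical molecules, labels, and reactions. Every
generated molecule has ≥ 1 candidate and ≥ 1 SOM, so a batch's coverage
ceiling is exactly 1. Mapped oxidation reactions are written with map
i + 1 on reactant atom i and the incoming oxygen mapped next, hydroxyl
tautomer by default (lactam by flag), so label extraction inverts the
construction exactly.

**What passing tests show — and don't.** Synthetic labels are a
deterministic function of local structure, so end-to-end recovery (top-1
≥ 0.9 on held-out substrates, trained on 200) demonstrates that
enumeration, featurization, selection, training, and ranking compose
without information loss. It does not demonstrate predictive accuracy on
real hAOX data, whose labels carry experimental noise, tautomer ambiguity,
and chemistry outside the two site types; the small combinatorial space
also yields duplicate molecules between batches, which the pipeline
deduplicates but which makes "held-out" a weaker notion than for real
chemistry. Full-scale numbers require a locally supplied copy of the
curated 198/53 collection via `load_deposited_dataset`.

The end-to-end checks train on 200 synthetic substrates and test on 50,
with a single-point GBDT grid; these sizes keep the whole suite under a
minute of model fitting while leaving the recovery margin wide.

## Degenerate inputs and errors

Unparseable SMILES name the offending input; empty input is its own error.
A selection stage that would drop every column, single-class labels, CV
folds that cannot contain both classes, AUC with one class, and PCA beyond
the data rank all raise typed errors (mapped to CLI exit codes 2/3/4).
Model archives embed the fingerprint recipe, selector recipe, CV seed, and
library version stamps; a truncated or version-mismatched archive is
refused with both versions named.

## Known limitations

* Only the two ring-carbon site types are modeled; aldehyde-group oxidation
  and non-ring chemistry are out of scope, and molecules like bare pyridine
  with electron-rich rings may be called non-substrates even though rare
  substituted pyridines are experimentally oxidized.
* Atom maps are consumed, never computed; unmapped reactions cannot be
  labeled.
* The printed site-type SMARTS in the source literature are not
  syntactically valid; the repaired patterns plus brute-force oracles fix
  one reading (γ path through aromatic/double bonds, candidate in-ring).
  A dataset-driven revisit could loosen or tighten the type-B bond rule.
* SPF's ceiling-count convention and the PCA sign convention are package
  choices; other stacks may select ±1 column or flip component signs.
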
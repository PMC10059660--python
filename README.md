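# aoxsom

Site-of-metabolism (SOM) prediction for **human aldehyde oxidase (hAOX)**.

hAOX is a cytosolic molybdenum enzyme that oxidizes electron-poor carbons of
N-containing heteroaromatic rings — exactly the rings medicinal chemists add
to block CYP450 metabolism. Candidate drugs cleared mainly by hAOX have failed
in the clinic because rodent models under-predict the human enzyme, so a fast
in-silico call on *whether* and *where* a molecule is oxidized is genuinely
useful during lead optimization. `aoxsom` is a ligand-based tool for that
call, aimed at computational and medicinal chemists: no docking, no quantum
chemistry, just substructure typing plus a fingerprint classifier, fully
automatable from SMILES in.

## Method

1. **Candidate enumeration.** Two mechanistic site types propose potential
   SOM atoms:
   * **type A** — aromatic C–H adjacent to a two-connected aromatic ring
     nitrogen (α position), SMARTS `[$([c;H1;R]:[n;X2;R])]`;
   * **type B** — ring C–H with two heavy neighbors, three conjugated bonds
     from a two-connected ring nitrogen (γ position), SMARTS
     `[$([#6;X3;H1;R]:,=[*]:,=[*]:,=[#7;X2;R])]`.

   Both types also exist as brute-force atom-iteration reference routines
   that define the semantics; the SMARTS are the fast path and are tested to
   agree exactly. Site types are user-extensible via a YAML file. A molecule
   with no candidate is reported as a predicted non-substrate.

2. **Atom-environment featurization.** Each candidate atom c is described by
   a binary fingerprint restricted to its own environment: Morgan circular
   environments rooted at c (radius r ∈ 1…5), atom pairs with c as an
   endpoint, or topological torsions containing c, folded to
   256/512/1024/2048 bits — a sweep of 28 descriptor recipes.

3. **Feature selection and classification.** Variance threshold (VT),
   select-percentile (SPF, top ⌈p%⌉ of columns by χ² association), and/or
   PCA, followed by an SVM, random forest, or gradient-boosted tree
   classifier. Hyperparameters are chosen by grid search under seeded,
   stratified 10-fold cross-validation; selectors are refitted inside every
   training fold.

4. **Ranking and evaluation.** At predict time the candidate atoms of a
   molecule are scored and ranked (ties by atom index). Site-level quality
   is summarized by SE, SP, ACC, F1, MCC and ROC AUC

   SE = TP/(TP+FN)  SP = TN/(TN+FP)  ACC = (TP+TN)/N
   F1 = 2TP/(2TP+FN+FP)  MCC = (TP·TN−FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN))

   and molecule-level quality by **top-k accuracy**: the fraction of
   substrates with at least one true SOM among the k best-ranked atoms.
   Dataset diagnostics (pairwise Tanimoto similarity on whole-molecule
   Morgan-1024/r2 fingerprints, 2-D chemical-space PCA) are included.

Training labels come either from a CSV of substrates with known SOM atom
indices or from **atom-mapped reaction SMILES** (`reactants>>products`): the
mapped reactant is diffed against the product, and the atom whose hydrogen
count or heavy-neighbor set changes — the carbon gaining the oxygen — is the
SOM. A regex SMILES tokenizer (bracket atoms, `Br`/`Cl`, `%NN` ring closures
as single tokens) is provided for sequence-model preprocessing.

Because curated hAOX data cannot be redistributed here, the package ships a
deterministic synthetic-substrate generator (azaheteroaromatic scaffolds,
rule-defined labels) so the full pipeline is testable offline, plus a loader
for a locally supplied copy of the curated collection (198 training / 53
test substrates).

## Worked example

Generate 60 labeled synthetic substrates, prepare the site table, train, and
evaluate:

```bash
aoxsom fixtures --seed 1 --n 60 --out-dir fx
aoxsom prepare --reactions fx/reactions.smi --out sites.csv
aoxsom train --table sites.csv --config config.yaml --seed 7 --out model.joblib
aoxsom evaluate --model model.joblib --table sites.csv --out report.json
```

with `config.yaml`:

```yaml
algorithm: GBDT
fingerprint_spec: {family: AtomPair, n_bits: 2048}
selector_recipe:
  - {method: VT, threshold: 0.0}
  - {method: SPF, percentile: 15}
hyperparameter_grid: {learning_rate: [0.1], n_estimators: [100], max_depth: [3]}
cv_folds: 10
```

`prepare` reports the site inventory (60 draws collapse to 20 unique
substrates, 70 candidate atoms of which 21 are labeled SOMs, every SOM
covered by a candidate):

```json
{"n_molecules": 20, "n_candidate_sites": 70, "n_positive_sites": 21,
 "n_uncovered_soms": 0, "coverage_ceiling": 1.0}
```

and `evaluate` writes the report — the synthetic labels follow a
deterministic structural rule, so the trained model recovers them perfectly
(`"SE": 1.0, ..., "AUC": 1.0, "topk": {"1": 1.0, "2": 1.0, "3": 1.0}`).

Predicting on new molecules ranks every candidate atom; quinazoline's C2
(the C–H flanked by both ring nitrogens, atom 5 of the canonical SMILES) is
ranked first with score 0.99997, and benzene is flagged a non-substrate:

```
molecule_id,rank,atom_index,canonical_smiles,smiles_with_site_highlight,score
quinazoline,1,5,c1ccc2ncncc2c1,c1ccc2n[cH:1]ncc2c1,0.999970
quinazoline,2,1,c1ccc2ncncc2c1,c1[cH:1]cc2ncncc2c1,0.000013
...
benzene,0,-1,c1ccccc1,,non-substrate
```

The library API mirrors the CLI (`standardize_molecule`,
`enumerate_candidate_sites`, `featurize_site`, `cross_validated_grid_search`,
`rank_sites`, `topk_accuracy`, …); see the module docstrings and
`docs/methods.md`.

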
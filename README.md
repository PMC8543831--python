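# hotregion

Prediction of **hot regions** at protein–protein interfaces.

Only a few residues at a protein–protein interface — the *hot spots* —
contribute most of the binding free energy, and they tend to pack tightly
into clusters called *hot regions*. Identifying these regions matters for
drug design, interface engineering, and the prediction of functional sites.
`hotregion` implements the full computational route from raw
alanine-scanning affinity measurements to evaluated hot-region predictions,
for structural bioinformaticians working with SKEMPI-style mutation tables
and PDB structures.

## The method

1. **Labeling.** Each mutation record carries wild-type and mutant
   dissociation constants (Kd) at temperature T. Binding free energy is
   ΔG = −RT ln(Kd) with R = 8.314/4184 kcal/(K·mol), and the mutation effect
   is ΔΔG = ΔG_mut − ΔG_wt. Repeated measurements at one site are averaged
   on the ΔΔG scale; records missing an affinity are dropped. A residue is a
   hot spot when ΔΔG > 1.0 kcal/mol (a two-threshold scheme, hot > 2.0 /
   non-hot < 0.4 with the window discarded, is available).
2. **Features.** Raw per-residue descriptors (bound/unbound solvent
   accessible surface area, protrusion index, conservation, hydrophobicity,
   side-chain class, interaction counts) are consumed from delimited tables;
   the package derives RctASA = (ASA_unbound − ASA_bound)/ASA_unbound, the
   analogous RctmPI for the mean protrusion index, and a one-hot encoding of
   the nine side-chain classes. Interface membership requires more than
   1 Å² of ASA buried on complex formation.
3. **Feature selection.** Features are ranked by
   max-relevance/min-redundancy (mRMR) mutual information — relevance
   D = (1/|F|) Σ I(Xi, c), redundancy R = (1/|F|²) Σ I(Xi, Xj) — estimated by
   equal-frequency binning, then the best prefix of the ranking is chosen by
   incremental selection with cross-validated F-measure.
4. **Classification.** A from-scratch Gaussian naive Bayes classifier:
   per-class, per-feature normal densities and class priors, with the
   posterior odds ratio f(E) = [p(C=1)/p(C=0)] · Π p(x_i|C=1)/p(x_i|C=0)
   accumulated in log space; a residue is called hot when f(E) ≥ 1. Other
   classifiers (SVM, boosted trees, random forests, neural networks) plug in
   through a uniform fit/predict interface rather than being reimplemented.
5. **Clustering.** Predicted hot spots are grouped per complex by a
   from-scratch DBSCAN over Cα coordinates (core residues have ≥ Min
   neighbors within ε; clusters are reachability closures; unreachable
   points are noise and are discarded). (Min, ε) are chosen by grid search
   over Min ∈ {3..6}, ε ∈ {4.0..9.5} Å maximizing region-level F-measure.
6. **Evaluation.** Ground-truth *standard hot regions* are connected
   components of the sphere-contact graph over true hot spots: each hot spot
   is a sphere centered at its Cα with radius (3V/4π)^(1/3) from its residue
   volume, two spheres touch when their centers are closer than the radius
   sum plus 2 Å, and components need ≥ 3 members. A standard region counts
   as correctly predicted when ≥ 60% of its hot spots fall inside one
   predicted region (one-to-one matching); recall, precision and F-measure
   are reported at both the residue and the region level.

A synthetic-data module generates complexes with planted hot regions —
blob geometries, class-conditional Gaussian features, and Kd pairs
back-solved from target ΔΔG values — so the entire pipeline is testable
with known ground truth and no downloads.

## Worked example

```bash
hotregion demo --seed 17 --out demo
```

simulates two synthetic complexes (two planted regions of five hot spots
each plus twenty background residues per complex) and runs the full
pipeline on them. It prints:

```json
{
  "residue": {"recall": 1.0, "precision": 0.909, "f_measure": 0.952, "accuracy": 0.967},
  "region":  {"recall": 1.0, "precision": 1.0,   "f_measure": 1.0,   "accuracy": null},
  "region_counts": {"tp": 4, "fp": 0, "fn": 0, "tn": 0},
  "best_params": {"min_pts": 3, "eps": 4.0},
  "selected_features": ["conservation"]
}
```

Reading: every true hot spot was recalled at the residue level, with two
background residues misclassified as hot (precision 0.909); those two false
positives are spatially isolated, so DBSCAN discards them as noise and all
four planted regions are recovered exactly (region F-measure 1.0, four true
positives, no false regions). The grid search settled on the smallest
parameter pair among the many that score perfectly on this well-separated
benchmark, and incremental mRMR selection kept a single informative feature.

Individual stages are also exposed (`hotregion label`, `features`,
`select`, `train`, `predict`, `cluster`, `evaluate`, `simulate`, `run`);
see `hotregion --help`.

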
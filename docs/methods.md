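# Methods

## Model and pipeline

The package treats hot-region prediction as a four-stage procedure:
thermodynamic labeling, per-residue classification, spatial clustering, and
region-level scoring. The stages are independent library modules joined by a
thin orchestrator; every stage is deterministic given its inputs and seed.

### Thermodynamic labeling

Binding free energy is ΔG = −RT ln(Kd), with the gas constant stored as the
exact expression 8.314/4184 kcal/(K·mol) rather than a rounded decimal so
repeated conversions do not drift. Temperatures outside the usual
experimental window of 273–323 K raise a warning but do not block the
computation — the window describes the provenance of typical calorimetry and
surface-plasmon-resonance data, not a physical constraint.

Mutation effects are ΔΔG = ΔG_mut − ΔG_wt. Aggregation over repeated
measurements at one site averages ΔΔG (not Kd): the arithmetic mean of free
energies is the convention for merging replicate alanine-scanning entries.
Records missing either affinity are dropped, never imputed. Two records at
the same (complex, chain, position) that disagree on the wild-type residue
are rejected as a data inconsistency rather than silently merged.

The default label rule is hot iff ΔΔG > 1.0 kcal/mol, strict at the
boundary ("more than" reads as a strict inequality; a site at exactly
1.0 kcal/mol is non-hot). The stricter two-threshold convention
(hot > 2.0, non-hot < 0.4, discard between) is selectable because it is
widespread in the hot-spot literature, but it discards data and skews class
balance on alanine-scanning compilations, which is why the single 1.0
kcal/mol threshold is the default.

Train/test splitting is by complex, never by residue, so no structural
information leaks across the split. Which complexes count as "expansion"
data (eligible for the test side) is supplied explicitly in configuration:
database provenance cannot be inferred from a mutation table, and the
published composition of such splits is ambiguous enough that a config-driven
list is the only reproducible reading. Expansion complexes with fewer than
3 interface residues are folded into training.

### Features

Raw descriptors come from external programs (PSAIA-style geometry, ConSurf
conservation) as delimited tables; the package does not recompute
solvent-accessible surface area or protrusion indices. Derived on top:

* RctASA = (unbound − bound)/unbound total ASA — the relative burial of the
  residue upon complex formation, dimensionless, in (−∞, 1];
* RctmPI — the same construction on the mean protrusion index;
* a one-hot block over the nine side-chain classes (acid, aliphatic, amid,
  aromatic, basic, basic aromatic, cyclic, hydroxyl-containing,
  sulfur-containing) in a fixed, documented column order.

Interface membership requires strictly more than 1 Å² of ASA buried. The
threshold is configurable; the unit is an area because ASA is an area.
Rows with missing required values are dropped with a logged count — no
imputation rule exists for these descriptors that would not fabricate
geometry. PDB parsing (via gemmi) takes the first model only and, for
alternate locations, the highest-occupancy conformer with ties broken
toward altloc A; author residue numbering is retained.

### mRMR feature selection

Mutual information uses the plug-in estimator on discretized columns:
equal-frequency binning with 10 bins by default (columns with ≤ 10 distinct
values pass through as categorical), natural logarithm. The base only
rescales scores and can never change a ranking. Equal-frequency bins were
chosen over equal-width because interface feature distributions are heavily
skewed, and equal-width binning would concentrate most samples in one bin.

Relevance of a candidate set is the mean feature–label MI; redundancy is the
pairwise-MI sum normalized by |F|², read literally as running over ordered
pairs including i = j (so each diagonal term contributes the feature's own
entropy); a configuration switch excludes the diagonal. The greedy ranking
combines the two criteria in the difference (MID) form — the next feature
maximizes I(X, c) − (1/|S|) Σ_{Xj∈S} I(X, Xj) — the standard first-order
incremental scheme when only max-relevance and min-redundancy are stated.
Ties break lexicographically by feature name for reproducibility.

The prefix length is chosen by incremental selection: for each k, the
classifier is scored by stratified 5-fold cross-validation on the training
split (pooled confusion counts across folds, a deterministic seeded fold
assignment), and the k with the best F-measure wins, smaller k on ties. The
cross-validation protocol is the package's own choice; published
descriptions of incremental selection rarely state one.

### Gaussian naive Bayes

Fitted parameters are class priors (class frequencies) and per-class,
per-feature sample means and standard deviations. The class-conditional
density is the standard univariate normal
g(x; μ, σ) = (1/√(2πσ²)) exp(−(x−μ)²/(2σ²)). (A commonly reprinted form of
this density omits the square on (x−μ) and places σ un-squared under the
radical; that expression is not a probability density and is not what any
Gaussian naive Bayes implementation computes, so the standard density is
used here.)

σ is floored at 1e−9 times the largest feature range so zero-variance
features (one-hot columns constant within a class are common) cannot
produce infinite likelihoods. The posterior odds ratio is accumulated in
log space — at ~80 features a direct product of densities underflows — with
the contract, enforced by test, that it equals the direct product wherever
the product is representable. The decision rule is hot iff the ratio ≥ 1;
the boundary goes to the hot class.

Alternative classifiers are not reimplemented: a uniform fit/predict
protocol (plus an adapter for scikit-learn-style estimators) lets support
vector machines, boosted trees, random forests or neural networks
participate in incremental selection and evaluation. The interface carries a
`uses_feature_selection` flag because feature-fusing models (neural
networks) conventionally skip the mRMR stage.

### DBSCAN and the parameter grid

The clustering is a from-scratch DBSCAN over Cα coordinates, per complex. A
residue is core when its closed ε-ball (Euclidean, the residue itself
included — the standard counting convention) holds at least Min residues;
clusters are transitive expansions of cores; everything unreachable is noise
and is discarded, which is exactly the mechanism by which the clustering
stage filters residue-level false positives. Points are visited in
lexicographic (chain, position) order, so border residues reachable from two
clusters are assigned deterministically and reruns are bit-identical.

The default grid is Min ∈ {3, 4, 5, 6} and ε ∈ {4.0, 4.5, …, 9.5} Å. The
lower bound on Min is the defining minimum size of a hot region (three hot
spots); the upper bound on ε is the largest distance observed between two
contacting amino acids within one hot region, 9.5 Å. Grid points are scored
by region-level F-measure against the standard regions; an undefined
F-measure ranks below any defined one, and ties prefer smaller Min, then
smaller ε.

### Standard hot regions and scoring

Ground truth is geometric: each true hot spot is a sphere centered at its
Cα with radius (3V/4π)^(1/3) from the residue's mean volume; two hot spots
are in contact when their center distance is strictly less than the radius
sum plus a 2 Å tolerance; connected components of the contact graph with at
least three members are the standard regions. The bundled volume table is
the Chothia-style set of mean residue volumes (Å³); because published volume
sets differ by a few Å³ per residue, the table is overridable in
configuration.

Region matching uses the coverage rule: a standard region is correctly
predicted when at least 60% of its hot spots (boundary inclusive) lie inside
a single predicted region. Matching is one-to-one — greedy by descending
coverage fraction, ties to the larger predicted region then lexicographic
ids — the stricter reading when one predicted region could cover two
standard regions. TP is the number of matched pairs, FN the unmatched
standard regions, FP the unmatched predicted regions; recall, precision,
and F follow the usual formulas, and there is no region-level accuracy
because a region-level true negative has no meaning. Metrics with zero
denominators are reported as null, never coerced to 0, which matters in the
grid search (null ranks below any number).

## Synthetic data: what it emulates and what it does not

The generator produces, per complex: region centers 30 Å apart on a line,
hot spots as Gaussian blobs (σ = 1.5 Å) around the centers, and background
residues rejection-sampled at least one full separation away from every
center. Affinity pairs are back-solved from target ΔΔG values (hot uniform
on [1.2, 5.0], non-hot on [0, 0.8] kcal/mol — a 0.2 kcal/mol margin keeps
zero-noise labels unambiguous) at 298 K with a fixed 1 nM wild-type Kd.
Informative features are class-conditional Gaussians with means 3σ apart;
ASA and protrusion bookkeeping columns are generated so the derived RctASA
and RctmPI also carry signal; noise features are standard normal in both
classes. The defaults — 2 complexes × 2 regions × 5 hot spots, 20 background
residues, 3σ feature separation, zero label noise — are the benchmark under
which the full pipeline must recover every planted region (region
F-measure 1.0), and the test suite and acceptance script hold it to that.

What the geometry does *not* emulate: real interfaces are quasi-2-D patches
with excluded volume, sequence-local correlations, and hot-spot density
gradients; features here are conditionally independent Gaussians, which is
the naive Bayes assumption made true by construction. Passing the recovery
benchmark therefore demonstrates correctness of the pipeline mechanics and
the planted-truth bookkeeping, not classifier performance on real interface
data, where feature correlations and class overlap are substantially worse.
Label noise flips the ΔΔG class of a configurable fraction of residues, and
region F-measure degrades monotonically in expectation as noise rises —
tested over 20 seeds — which is the generator's handle for studying
robustness.

## Numerical choices and degenerate inputs

* Strict inequalities at every published boundary: interface burial
  (> 1 Å²), hot-spot threshold (> 1.0 kcal/mol), sphere contact
  (< sum + 2 Å). The classifier boundary (≥ 1) and the coverage boundary
  (≥ 60%) are inclusive.
* MI of a constant column is 0 by convention (zero entropy), not an error;
  estimates are clipped at 0 against floating-point negatives.
* Empty inputs return empty outputs (aggregation, clustering); truly
  undefined quantities (relevance of an empty set, RctASA at zero unbound
  ASA, metrics with empty denominators) raise or return null rather than
  fabricating a number.
* Sample standard deviations use the population normalization (ddof = 0),
  matching the maximum-likelihood Gaussian fit.
* Problem sizes in the test and acceptance suites — 200 random DBSCAN
  instances of up to 30 points across the full 48-point parameter grid, 50
  random classifier tables, 100 random sphere sets, the 60-residue recovery
  benchmark — were chosen as the smallest sizes at which the brute-force
  oracles still exercise every code path (multi-cluster instances, border
  points, noise, multi-component contact graphs) while the whole suite runs
  in seconds.

## Known limitations

* Raw features must be precomputed externally; the package neither runs nor
  wraps PSAIA/ConSurf.
* The exact published 83-feature inventory lives in supplementary material
  that is not machine-readable here; the feature list is therefore
  configuration, with a representative default schema.
* Only single mutations to alanine are meaningful for the labeling model;
  multi-residue mutants carry non-additive effects and are out of scope.
* Reproducing published corpus-level results requires the SKEMPI 2.0 and
  PDB downloads; the package supports that workflow but ships no corpus.
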
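# Methods

## The relevance model

The core question is feature relevance under `p ≫ n`: which of hundreds of
OTUs carry information about a binary dietary group label, given a few
dozen samples per arm.  A random-forest classifier handles the
dimensionality and multivariate interactions; the inferential problem is
turning its importance scores into a calibrated keep/drop decision.  The
package follows the shadow-feature (Boruta-family) idea:

1. **Shadows.** Every feature is paired with a permuted copy of itself.  A
   shadow has the feature's exact marginal distribution but is independent
   of the label by construction, so the shadow block is an empirical null
   for "how important can an uninformative feature look here".
2. **VIM.** Importance is the out-of-bag (OOB) permutation metric: for each
   tree, the drop in accuracy on the tree's OOB samples when the feature is
   shuffled among them, averaged over trees.  Features a tree never splits
   on contribute exactly zero for that tree (the implementation skips them;
   this is an identity, not an approximation).  The metric is an absolute
   accuracy fraction, which is the scale on which the default
   `importance_threshold = 0.001` lives.
3. **Stability.** The forest fit is repeated `n_repetitions` times with
   fresh shadow permutations each time, yielding per-feature samples of
   VIMs.  Regenerating shadows every repetition is essential: it makes the
   strongest shadow's VIM sample a proper draw from the null rather than
   one frozen permutation's quirk.
4. **Likelihood.** Each feature's VIM sample is compared with that of the
   shadow having the highest mean VIM, by a one-sided Welch t-test
   (unequal variances, Welch–Satterthwaite degrees of freedom; repetitions
   treated as independent draws).  `likelihood = 100 × (1 − p)`.
5. **Selection.** `likelihood ≥ likelihood_threshold` and
   `mean VIM ≥ importance_threshold`.  The default likelihood threshold of
   99.5 reads "100% at integer reporting precision" (p ≤ 0.005).

The learner is a standard scikit-learn `RandomForestClassifier`.  The
shadow/VIM/t-test statistics are learner-agnostic, and OOB-permutation
importance already mitigates the split-selection bias that
conditional-inference forests target; a different forest could be swapped
in behind `fit_forest_vim` without touching the inference.

Inputs are per-sample relative abundances by default — library size is a
nuisance variable — with a raw-count mode behind a flag.  No multiplicity
correction is applied beyond the max-shadow reference, which is itself the
family-wise control device of the construction.

### Direction of change

Selected OTUs are annotated by the ratio of group-mean relative abundances
(treatment / control).  When either group mean is exactly zero a
pseudo-fraction ε — half the smallest nonzero relative abundance in the
table — is added to both means so the ratio stays finite; otherwise the
ratio is exact.  Ratio > 1 is "increased", < 1 "decreased"; an exact tie is
reported "unchanged" and counted in neither direction.

### Calibration behaviour, honestly stated

The max-mean-shadow t-test controls the rate of *high-likelihood* features
well: on pure-null communities about 1% of features reach likelihood ≥ 97
(checked in the acceptance suite, bound 5%).  It does **not** drive the
selected set to empty in nearly all null datasets.  The reason is
structural: a real feature keeps its (chance) correlation with the labels
across all repetitions, while shadows are redrawn, so as repetitions
accumulate, the t-test gains power against any null feature whose
dataset-level chance association also lifts its mean VIM past 0.001.  At
200 OTUs × 48 samples with 20 repetitions × 200 trees, roughly half of null
datasets yield 1–4 such selections (measured in the acceptance suite,
where the empty-in-≥95%-of-runs assertion is deliberately left failing
rather than weakened).  A per-repetition max-shadow reference would
calibrate this away but is a different statistic from the one this package
implements.  Practical consequence: on real data, treat selections with
borderline importance (~0.001) as candidates, not confirmations.

## Beta diversity

Generalized UniFrac is computed by a single postorder traversal
accumulating, per branch, the fraction of each sample's reads descending
through it; pairwise distances then weight branch lengths by
`(p^A + p^B)^α`.  Branches with no mass in either sample contribute to
neither numerator nor denominator, so `α = 0` stays well-defined.  `α = 1`
is weighted-normalized UniFrac (the test suite checks equality with
scikit-bio's implementation); `α = 0.5`, the customary compromise between
rare- and abundant-lineage sensitivity, is the default and is exposed as a
parameter.

Ordination of a distance matrix is classical metric scaling (principal
coordinates): double-centred Gower matrix, eigendecomposition, axes with
non-positive eigenvalues discarded but reported.  Explained-variance
fractions are relative to the positive-eigenvalue sum.  "PCA on pairwise
distances" in this field conventionally means exactly this.

PERMANOVA is one-factor with freely permuted labels (no strata), pseudo-F
from the within/between partition of squared distances, and the add-one
p-value convention `p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)`, so p is
never zero and equals `1/(n_perm+1)` at maximal separation.  It is
implemented in-package (rather than delegated) because runs must be
reproducible from a single seed; scikit-bio's PERMANOVA serves as the
independent cross-check on the statistic in the tests.

## Table algebra

Rarefaction draws from the multivariate hypergeometric distribution
(sampling reads without replacement) at a user-chosen depth; samples below
the depth are dropped with a warning, never upsampled.  Aggregation,
pooling and day-filtering are exact count re-arrangements and are
property-tested for conservation.  Pooled sample ids are prefixed by trial
label to keep id spaces disjoint.  On-disk formats are plain TSV
(`#SampleID` header token) and newick.

## The synthetic-data generator

`simulate_community` emulates the multi-trial feeding-study design the
analysis is built for: `n_trials` independent trials, control and treatment
arms of `n_per_group` samples each, one collection day.  Its defaults are
the emulated study design — 4 trials × 12 samples per group per trial
(96 samples), 500 OTUs, day 35 — with fixture-scale library sizes of
2,000–5,000 reads per sample.

* **Baselines.** One log-normal abundance per OTU
  (`base_log_mean = 0`, `base_log_sd = 2`), shared across samples: a
  heavy-tailed community in which a handful of phylotypes dominate.
* **Planted effects.** The first `n_sensitive` OTUs are multiplied by their
  fold change in every treatment sample, on the composition scale before
  renormalization — so "increased" OTUs mechanically depress all others, the
  same closure artefact real relative-abundance data carries.  Default: 10
  sensitive OTUs, 5 at fold 4 and 5 at fold 0.25.  Sensitive baselines are
  drawn from the upper half of the baseline distribution (|N(0, σ)| above
  the median) so the planted effect is expressed above the sampling-depth
  detection floor — otherwise "ground truth" could label OTUs whose counts
  are all zeros, and direction recovery would be undefined.
* **Trial effects.** Per-trial log-normal offsets (σ = 0.2) emulate
  between-trial variation; effects stay directionally consistent across
  trials, which is the signal the pooled analysis exploits.
* **Noise.** Per-entry zero inflation (default 0.1) and per-sample library
  sizes uniform on the configured range, with counts drawn multinomially
  from the sample's composition — totals land exactly on the drawn library
  size.
* **Seeding.** A single seed feeds a `SeedSequence` spawn tree (community /
  per-trial / per-sample streams), so identical configurations are
  byte-identical and enlarging one part of the design does not disturb the
  draws of another.

What the generator does *not* emulate: sequencing error and chimeras,
taxon–taxon ecological interactions, overdispersion beyond the
multinomial + zero-inflation compound, phylogenetic signal in the planted
effects (the simulated tree is random-join, independent of abundance), or
realistic day-course dynamics (a single day is generated).  Passing tests
therefore demonstrate correctness of the statistical machinery and
recoverability of compositional fold-change signals under heavy tails,
zero inflation and trial heterogeneity — not performance under ecological
confounding or technical batch artefacts.

`simulate_tree` builds a rooted binary tree by random pairwise joins with
exponential branch lengths (offset 0.05 so lengths are strictly positive);
`simulate_taxonomy` assigns phyla by configurable weights, defaulting to
frequencies typical of broiler cecum surveys, with synthetic nested labels
for the lower ranks.

## Numerical choices and degenerate inputs

* Welch test with both variances zero: p = 0 / 1 / 0.5 by comparison of
  means (deterministic difference, deterministic deficit, exact tie).
* PCoA eigenvalue cutoff: relative 1e-12; requesting more axes than
  positive eigenvalues truncates with a warning.
* Ties in the output ranking are broken lexicographically by OTU id
  (stable sort), so reports are reproducible.
* Zero-total samples are rejected by name in every composition-based
  operation; empty day-filters warn rather than raise.
* The selected-feature mask is exactly reproducible per seed: the master
  seed spawns per-repetition (shadow, forest, OOB-permutation) streams.

## Problem sizes in the test and acceptance runs

The statistical acceptance tests run at sizes chosen for a routine
single-CPU CI pass: Welch-oracle equivalence on 1,000 random instances;
null calibration on 25 simulations of 200 OTUs × 48 samples with
20 repetitions × 200 trees; planted recovery at the full default design
(500 OTUs, 96 samples, 10 planted) with 20 repetitions × 200 trees at
5 fixed seeds; UniFrac oracle agreement on 50 random instances (≤ 10
samples, ≤ 16 leaves) at α ∈ {0, 0.5, 1}; PERMANOVA calibration on 500
null simulations; conservation properties on 200 random tables.  The
production defaults (50 repetitions × 500 trees) simply extend the same
computation with more replication.

## Known limitations

* Selection calibration under pure null is imperfect by construction (see
  above); the likelihood column, not the binary `selected` flag, is the
  primary evidence measure.
* OOB sets are reconstructed from scikit-learn's internal bootstrap
  helpers, which couples the VIM computation to the installed
  scikit-learn's forest internals.
* PERMANOVA assumes exchangeable samples; with strong trial structure a
  stratified permutation scheme (not implemented) would be more
  conservative.
* Generalized UniFrac is quadratic in samples with a per-pair branch scan;
  fine for hundreds of samples, not tuned for thousands.
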
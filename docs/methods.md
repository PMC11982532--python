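# Methods

`dendrocensus` implements a quantitative census pipeline for excitatory
dendritic morphology: deciding whether a population of per-neuron morphology
embeddings is organized into discrete types or a continuum, measuring
skeleton morphometrics in a standardized cortical frame, running the
quality-control and layer-assignment stages that precede any population
claim, and linking morphology to function with cross-validated regression.
This note records the models, the conventions, the numerical choices, and
what the synthetic generators do and do not emulate.

## Coordinate standardization

Imaged cortical volumes are tilted and of variable thickness. All
depth-dependent quantities are computed after a two-step standardization:

1. a rotation about the z-axis (default 3.5°) removes the systematic tilt;
2. per (x, z) column, an affine map in y sends the local pia depth to the
   mean pia depth and the local white-matter depth to the mean white-matter
   depth. Surfaces are least-squares planes `y = a·x + b·z + c` fit to
   landmark points on a regular (x, z) grid (25 μm spacing).

The y-map is a single affine per column, extended linearly above the pia and
below the white matter; x and z are not rescaled. Depth is reported relative
to the pia (pia = 0, depth increasing downward). Points in degenerate
columns (local white matter not deeper than local pia) raise an error with
the offending (x, z).

## Morphometrics

Six descriptors per neuron, computed on the standardized skeleton, axon
nodes excluded throughout; an edge inherits its child node's compartment
label (unambiguous on a tree):

* **soma depth** — depth of the (single) soma node;
* **height** — depth extent of all non-axon nodes;
* **total apical / basal length** — summed Euclidean edge lengths;
* **apical width** — maximum pairwise distance of apical nodes projected to
  the (x, z) plane; chosen over a bounding-box reading of "widest extent"
  because it is invariant to rotations about the depth axis;
* **basal bias** — depth of the length-weighted mean of basal edge midpoints
  minus soma depth (positive = basal arbor below the soma). Length weighting
  makes the center of mass invariant to resampling density, which the
  edge-subdivision test checks directly.

Oblique dendrites count toward neither apical nor basal totals; their length
is available through the generic per-compartment accessor.

## The dip statistic

Hartigan's dip — the sup-norm distance from the empirical CDF to the nearest
unimodal CDF (convex, then concave, with an atom allowed at the mode) — is
implemented from first principles and scaled by 4 so that a balanced
two-point sample scores exactly 1. The algorithm bisects on the band
half-width `d` and decides feasibility exactly: for every candidate mode
placement, a convex nondecreasing function fits the band left of the mode
iff the greatest convex minorant of the band ceilings clears every band
floor; the minimal value any feasible convex fit can carry to a later
abscissa is the upper envelope of one forced-slope support line per point
(maintained in a Li Chao container, forced slopes from an incremental hull);
and the convex and concave pieces must hand over at the mode without leaving
the band, which reduces to two linear conditions (mode adjacent to the left
or the right flank). The concave side is the same sweep on the mirrored
sample. Each feasibility test is O(m log m) in the number of distinct
values; 48 bisection steps give ~1e-14 accuracy.

The test suite validates this implementation against an independent oracle
that solves the defining minimax problem by linear programming (one LP per
mode placement), exhaustively over all ternary samples of size ≤ 8 and over
random small and midsize samples. Degenerate samples (fewer than two
distinct values) return 0 with a flag. p-values are never computed — the
statistic is used descriptively.

## Cluster-versus-continuum analysis

* **Synthetic mixtures.** 32-dimensional Gaussian mixtures with isotropic
  variance swept over σ² ∈ {0.005, 0.01, 0.03, 0.05, 0.07, 0.1, 0.3, 0.5,
  0.7, 1.0} and component counts in {10, 20, 40}; 32,571 samples per
  condition (the size of a typical curated excitatory population). Means
  are either taken from a diagonal-covariance reference GMM fit to real
  embeddings, or generated de novo: drawn i.i.d. isotropic Gaussian and
  rescaled in closed form so the mean distance to the third-nearest
  neighboring mean equals 2.38 — the embedding-space distance threshold used
  by the neighbor graph — which pins the overlap geometry without any data
  download. Third-neighbor distances scale exactly linearly under isotropic
  rescaling, so one rescale lands on the target to float precision. Weights
  are Dirichlet(10): mildly imbalanced, never degenerate.
* **Ensemble consistency.** For each component count, isotropic GMMs are fit
  with distinct seeds on a shared 90% training split (one fixed split per
  analysis so every comparison scores identical held-out items); the mean
  pairwise adjusted Rand index of the validation-split labelings is the
  consistency score. ARI is computed from the pair-counting contingency
  formula in-package; sklearn's implementation serves as a cross-check in
  tests only. EM details: each run keeps the best of 3 k-means++
  initializations by training log-likelihood (ensemble consistency should
  measure the data's recoverability, not the optimizer's local-optimum
  noise), variance floor 1e-8, tolerance 1e-4 on the per-sample average
  log-likelihood, at most 500 iterations; the model is stepped one EM
  iteration at a time so the monotone log-likelihood path is observable and
  testable. The default
  ensemble size is 100 runs; desk-scale analyses (tests, the acceptance
  script) use 10, which keeps the mean pairwise ARI stable to a few
  hundredths.
* **Cluster graph.** Clusters connect to their k = 3 nearest neighbors by
  Euclidean distance between means; edges beyond the mean third-neighbor
  distance are dropped. Each retained unordered pair carries the scaled dip
  of the 1-d sample obtained by projecting both clusters' points onto the
  line joining their means (origin at the first mean); display weight is the
  inverse dip. The continuum summary is the maximum over clusters of the
  scaled dip to their single nearest neighbor, computed on the best run by
  validation log-likelihood (ties broken by lowest seed).

A note on magnitudes: the scaled dip reaches 1 only for two point masses.
For two *Gaussian* clusters the dip saturates below 1 even at large
separation, because a unimodal CDF can absorb one cluster in the modal atom
and track the other up to the concavity cost of its sigmoid; well-separated
isotropic components at the calibrated spacing score ≈ 0.5–0.9 depending on
σ², and the σ²-sweep of the maximum neighbor dip is strictly decreasing.

## Quality control and layers

The cascade order is: lateral-boundary filter (default margin 20 μm on x
and z faces — "close to the boundary" is not quantified in the source
conventions, so the margin is configurable), fragment classifier on the
embeddings, removal of rows lacking synapse/spine density features, then the
excitatory/inhibitory classifier on embeddings + the two density features.
Per-stage removal counts are reported and conserved by construction.

Classifier tuning is an exhaustive grid search with stratified 10-fold CV:
logistic regression over penalty {none, L1, L2, elastic net (mixing ratio
fixed at 0.5)} × C ∈ {0.5, 1, 3, 5, 10, 20, 30} × class weights
{balanced, none}; SVMs over kernel {linear, RBF, polynomial} × the same C
grid × class weights, with polynomial degree ∈ {2, 3, 5, 7, 10, 20} applying
only to the polynomial kernel (112 SVM configurations in total). Balanced
accuracy is the default selection score; the winning configuration is refit
on the full labeled set.

Layer boundaries are continuous piecewise-linear functions depth(x) (z
pooled), with breakpoints equally spaced over the x range (default 3
segments) and knot depths optimized by Nelder–Mead on a hinge-smoothed
misclassification loss; the source conventions say only "optimal piece-wise
linear", so segment count, domain and objective are package choices.
Boundaries are post-processed to be strictly ordered in depth, and layer
membership afterwards depends only on soma depth versus the boundaries —
never on classifier output.

Apical-termination exclusions: L4 neurons whose apical terminates more than
96 μm below the pia (the 96 μm cutoff is reproducible as the F1-optimal
retention threshold on a labeled validation set via
`select_f1_threshold`; ties resolve to the shallower cutoff); whole L5
clusters with strictly more than 50% unnatural terminations; L6 neurons
whose apical left the volume.

## Graph augmentations

Views for self-supervised training compose: subsample to 200 nodes (root,
branch points and terminal tips always retained — tips are kept because
dropping them truncates real cable rather than bridging it; dropped
pass-through nodes are bridged child-to-grandparent), uniform rotation about
the y-axis through the soma, deletion of 5 terminal subbranches (a
subbranch = leaf-to-nearest-branch-point segment), per-node Gaussian jitter
(σ = 1 node unit), global Gaussian translation (σ = 1). All steps are
seed-deterministic and return valid trees. On 1 μm-resampled synthetic
neurons a jitter-free, deletion-free subsampled view preserves total
compartment lengths to within 2%.

## Structure-function statistics

* Nested cross-validation for elastic net: outer and inner 10-fold loops,
  α ∈ {0.01, 0.1, 0.5, 1, 5, 10} × L1 ratio ∈ {0, 0.25, 0.5, 0.75, 1};
  features standardized inside each outer-fold training split;
  R² (1 − SSE/SST) and Pearson r reported on concatenated outer-fold
  held-out predictions only. Folds are positional (unstratified).
* Fisher's z for the difference of two correlations:
  `z = (atanh r1 − atanh r2)/sqrt(1/(n1−3) + 1/(n2−3))`, two-tailed normal
  p. The two correlations are treated as independent even when they come
  from nested models on one cohort; this matches the printed arithmetic of
  the worked example (r = 0.53 vs 0.46 at n = 2347 → p ≈ 0.0015) and is
  stated openly as a simplification.
* Area contrasts: two-tailed Student's t (equal variances), pooled-SD
  Cohen's d, Bonferroni-corrected significance level (α/n_tests, e.g.
  0.01/4 = 0.0025).

## Synthetic data: what it emulates and what it does not

The generators reproduce the *structure* of the study inputs — mixture
geometry with controllable overlap, pyramidal skeletons with exact
descriptor ground truth inside a tilted volume (closed-form trunk + tuft
arms + two basal segments solved for exact length and center of mass),
labeled cohorts for classifier stages — at parameter ranges chosen to be
cortically plausible (soma depths 250–650 μm, basal lengths 0.9–2.5 mm,
tuft widths 5–300 μm, basal bias −40 to +60 μm). They do not emulate
reconstruction-error physics, axons, realistic branching statistics beyond
the descriptors, or the real data's cluster means. Passing tests therefore
demonstrate correctness of the *measurements and decision procedures*, not
that real cortical data contains any particular type structure; quantities
that depend on the real EM volume and trained embeddings (classifier
accuracy percentages, the neuronal-data ARI, layer thicknesses, area effect
sizes) are out of desk-scale reach by design.

## Problem sizes used by tests and the acceptance script

Mixture analyses run at the full n = 32,571 × 32-d scale with 10-run
ensembles; unit tests use smaller mixtures (≤ 8 components, ≤ 4000 samples)
chosen to make their expected behavior provable. The morphometric round
trip uses 200 random feasible specs; the dip oracle equivalence is
exhaustive over ternary samples of size ≤ 8. The 1-d toy uses n = 30,000
where its limits are asserted, and smaller n where only ordering matters.

## Known limitations

* The dip's LP oracle is exact but exponential-ish in sample size; oracle
  validation stops at midsize samples (~100 points). The production
  algorithm has no size limit.
* Layer-boundary fitting is non-convex; Nelder–Mead from the midpoint
  initialization is deterministic but can in principle settle in a local
  optimum for pathological label noise.
* `fisher_z_test` assumes independent samples (see above).
* Elastic-net at l1_ratio = 0 delegates ridge behavior to sklearn's
  coordinate descent, which warns and is slightly slower than a dedicated
  ridge solver; results are unaffected.
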
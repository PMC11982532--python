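# dendrocensus

Tools for a data-driven census of excitatory dendritic morphology: deciding
whether a population of per-neuron morphology embeddings forms **discrete
cell types or a continuum**, measuring **skeleton morphometrics** in a
standardized cortical frame, running the **quality-control and
layer-inference** stages that precede any population claim, and linking
**structure to function** with cross-validated regression.

Who it is for: anatomists and computational neuroscientists who have (or
simulate) per-neuron embedding vectors and compartment-labeled SWC
skeletons from large EM volumes and want principled, tested answers to
"how many types are really here?" and "how do dendritic features vary with
depth, layer and area?".

## The core quantities

* **Clustering consistency.** Fit an ensemble of isotropic Gaussian mixture
  models (different seeds, shared 90/10 train/validation split) and report
  the mean pairwise adjusted Rand index (ARI) of the held-out labelings.
  If K components can be recovered reliably, ARI stays near 1 at that K.
* **Scaled dip statistic.** For two neighboring clusters, project all their
  points onto the line joining the cluster means and compute Hartigan's dip
  of the 1-d sample — the sup-norm distance between its empirical CDF and
  the nearest unimodal CDF — scaled by 4 so that two balanced point masses
  score exactly 1. High dip = a real gap between the clusters.
* **Cluster graph.** Connect each cluster to its k = 3 nearest neighbors in
  embedding space (edges beyond the mean third-neighbor distance dropped),
  annotate edges with the scaled dip; the maximum nearest-neighbor dip
  summarizes how discrete the population is.
* **Six morphometrics** per neuron, after standardizing the volume so pia
  and white matter are horizontal: soma depth, height, total apical length,
  apical width (widest (x,z) extent), total basal length, and basal bias
  (signed depth offset of the length-weighted basal center of mass relative
  to the soma).
* **Statistics**: nested cross-validated elastic-net regression
  (out-of-fold R² and Pearson r), Fisher's z-test
  `z = (atanh r1 − atanh r2) / sqrt(1/(n1−3) + 1/(n2−3))` for comparing
  correlations, Student's t with pooled-SD Cohen's d and Bonferroni
  correction for area contrasts.

Synthetic generators produce every input at known ground truth: calibrated
Gaussian mixtures spanning the discrete-to-continuous range, and parametric
pyramidal-cell skeletons (soma / apical / basal / oblique compartments)
embedded in a tilted synthetic volume.

## Worked example

`examples/01_cluster_vs_continuum.py` sweeps a calibrated 10-component
16-dimensional mixture from tight clusters to a near-continuum:

```
10 calibrated means in 16-d, third-neighbor spacing 2.38 um-equivalents
 sigma^2  mean ARI  max NN dip
    0.01     1.000       0.657
    0.10     0.983       0.392
    0.50     0.962       0.113
    1.00     0.776       0.078
```

At σ² = 0.01 every ensemble run refinds the same 10 components (ARI 1.0)
and neighboring clusters are separated by real gaps (dip 0.66); by σ² = 1.0
runs disagree (ARI 0.78) and no pair of neighbors is bimodal (dip 0.08) —
the mixture has become a continuum. The other examples demonstrate skeleton
morphometrics with exact ground-truth recovery (`02`), the QC cascade and
geometric layer assignment (`03`), and confound-controlled
structure-function regression (`04`).

## Layout

```
src/dendrocensus/
  dip.py                exact Hartigan dip (bisection + feasibility sweep)
  mixtures.py           mixture specs, calibrated means, samplers, 1-d toy
  continuum.py          GMM ensembles, ARI, projections, cluster graph
  skeleton.py           SkeletonGraph + SWC read/write/validate
  tables.py             embedding tables (CSV round trip)
  coords.py             tilt removal + pia/white-matter standardization
  synth_neurons.py      parametric skeletons with exact ground truth
  morphometrics.py      the six descriptors
  qc.py                 classifier grids, QC cascade, layer boundaries,
                        termination filters
  augment.py            identity-preserving graph augmentations
  structure_function.py nested-CV regression, Fisher z, area contrasts
  pipeline.py           end-to-end study drivers with manifests
examples/               one narrative script per capability
tests/                  pytest suite (LP dip oracle, pair-counting ARI
                        oracle, generator round trips, property tests)
```
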
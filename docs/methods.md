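# Methods

## Overview

`jssenet` implements an individual (single-subject) morphologic brain
network analysis: regional gray-matter voxel-intensity distributions are
compared pairwise with a Jensen-Shannon-type divergence, the resulting
weighted network is thresholded and summarized with graph-theoretical
metrics, and subjects are classified (low versus high levodopa responders
in Parkinson disease) with a multi-kernel SVM under nested leave-one-out
cross-validation.  Because no public cohort accompanies this design, a
synthetic cohort generator with controllable ground truth is a first-class
part of the package and drives all end-to-end validation.

## Cohort model

A subject's responsiveness to a levodopa challenge is
`LR = 100 * (UPDRS_off - UPDRS_on_peak) / UPDRS_off` (percent improvement
of the motor score); subjects with `LR <= 33` form the low-improvement
group (`LCT_L`), the rest the high-improvement group (`LCT_H`).  The
generator draws `UPDRS_off` as uniform integers in 30-70 and chooses the
peak "on" score to hit a target responsiveness drawn uniformly from
(10, 33] for low and (33, 80) for high responders, so the labeling formula
is exercised on every generated subject and group sizes are exact by
construction.  The default cohort is 13 low plus 25 high responders.

Regional intensities are truncated normals on [0, 1] with mean 0.4 and
standard deviation 0.12 (gray-matter-probability-like; smooth unimodal
densities keep kernel density estimation well behaved), 200 voxels per
region and 90 regions by default.  Group effects are injected per
designated region pair (a, b): in high responders, region b's mean is
shifted by `effect_size` within-region standard deviations (or its variance
inflated, with `effect_mode="variance"`), which changes the a-b divergence
between groups without touching low responders.  One master seed feeds
deterministic per-subject substreams.

What the generator does *not* emulate: spatial autocorrelation of real
gray-matter maps, segmentation and registration artifacts, site or scanner
effects, age/sex covariates, and anatomically realistic region geometry.
Passing tests therefore demonstrate that the pipeline recovers the effects
it assumes, at the stated sizes and noise levels — not that those effects
exist in, or are recoverable from, clinical MRI.

## Volumetric path

The pipeline consumes already-segmented gray-matter volume maps plus an
integer parcellation on the same grid (segmentation/normalization are
upstream tools and out of scope).  Smoothing is a separable Gaussian
parameterized by FWHM in mm (default 6 mm), converted per axis to voxel
units via `sigma = FWHM / voxel_size / (2 sqrt(2 ln 2))`, with zero-padded
boundaries (edge regions lose a little mass; the synthetic fixtures keep a
background margin).  Whether divergences are computed on smoothed or raw
maps is a pipeline flag; smoothing is on by default.  Extraction collects,
per region, the gm values at voxels carrying the region's label, in
deterministic row-major order; a region with fewer than two voxels is a
hard error because a density cannot be estimated for it.  The default label
table follows the atlas convention of alternating left/right homologues: 90
regions, 45 per hemisphere.

## Divergence networks

For each unordered region pair, both intensity densities are estimated by
Gaussian KDE on a shared 128-point grid spanning the pooled sample range
padded by one bandwidth per side.  Bandwidths follow Scott's rule with a
floor of 1e-3 intensity units (degenerate spreads); densities are floored
at 1e-10 and renormalized so log-ratios stay finite for near-disjoint
supports.  Two divergence variants are available:

* `jeffreys` (default): the inner operator of the JS construction is the
  symmetrized KL divergence `J(P,Q) = sum_x (P-Q) ln(P/Q)`, and the edge
  weight is `(1/2)[J(P,M) + J(Q,M)]` with `M = (P+Q)/2`.  Unbounded above;
  consistent with reported morphologic-connectome edge weights well above
  ln 2.
* `standard`: the textbook JS divergence `(1/2)[KL(P||M) + KL(Q||M)]`,
  bounded by ln 2.

Both variants are symmetric, nonnegative, and zero iff the densities
coincide; the Jeffreys-based variant dominates the standard one pointwise
(since `J(P,M) >= KL(P||M)`).  Weights are in nats by default (a base-2
switch exists).  Which variant a given published analysis used is often
ambiguous; both are first-class and config-selectable here.

## Graph metrics

Weighted matrices are binarized by keeping the `floor(s * n(n-1)/2)`
strongest edges at each sparsity `s` of the grid 0.02-0.50 in steps of 0.01
(49 levels), ties broken lexicographically for reproducibility.  Global
metrics: clustering coefficient (mean nodal clustering), characteristic
path length (over connected pairs; disconnected pairs are excluded and
flagged, while efficiencies use 1/inf = 0), global and local efficiency,
modularity of the deterministic greedy (CNM) partition, degree
assortativity (0 when undefined on regular graphs), hierarchy (slope of
ln NCp on -ln DC over nodes with degree > 1 and positive clustering),
synchronizability (ratio of second-smallest to largest Laplacian
eigenvalue), and small-world gamma/lambda/sigma normalized by
degree-preserving double-edge-swap nulls (10 |E| attempted swaps; 100 nulls
per graph by default; sigma = gamma/lambda).  When graph and null
clustering are both zero the ratio is taken as 1; a positive value over a
zero null mean is reported as NaN with a warning.  Nodal metrics: degree,
unnormalized betweenness, nodal efficiency, nodal local efficiency, nodal
clustering, nodal shortest-path length, with zero conventions for isolated
nodes.  Metrics are summed across the sparsity grid (the mean is reported
alongside), giving one value per metric family (global) or per family and
region (nodal).

## Multi-kernel SVM

Each modality m (connection weights, global metrics, nodal metrics)
contributes a linear Gram matrix `K_m`; the classifier kernel is
`sum_m beta_m K_m` with `beta` on the unit simplex.  Training solves the
standard box-constrained SVM dual by sequential minimal optimization with
second-order (maximal-gain) working-set selection; the bias comes from the
KKT conditions averaged over free support vectors, falling back to the
midpoint of the violation interval when none exist.  On rank-deficient
Grams (e.g. the 11-feature global block with more samples than features)
SMO converges sublinearly once the KKT gap is around 1e-5; training
accepts a residual gap that is tiny relative to the kernel scale at the
iteration cap (the induced objective error is O(gap * n * C)), mirroring
the loose default tolerances of production SVM libraries, while
well-conditioned problems are driven to 1e-10.

Hyperparameters are chosen by inner leave-one-out accuracy over a simplex
grid for `beta` (step 0.1, i.e. 66 candidates for three modalities) and
`C` in {2^-5, 2^-3, ..., 2^5}; ties prefer the smallest `C`, then the
lexicographically smallest `beta`, so model selection is deterministic.

## Nested cross-validation

The outer loop holds out one subject at a time.  On each training fold the
connection block is screened by a two-sided two-sample Student t-test at
alpha = 0.05 (no multiplicity correction in the primary path — the
screening is an embedded filter inside cross-validation, not an inference;
a Benjamini-Hochberg column is available for descriptive reporting, and a
Welch switch exists).  If nothing passes, the full connection block is used
for that fold (logged), keeping the pipeline total.  All blocks are
z-scored with training-fold statistics.  Feature selection is computed once
per outer fold and reused across the inner hyperparameter loop; a stricter
per-inner-fold reselection flag exists.  The held-out prediction uses the
winning (beta, C) refit on the whole training fold.  The positive class is
the high-responder group.  Connections selected in every outer fold form
the consensus set; the union is reported alongside, since "selected in
every loop" and "all features selected during training" are both defensible
readings.  Performance is accuracy, sensitivity, specificity (NaN rather
than a division fault when a denominator is empty), and AUC computed as the
Mann-Whitney rank statistic on pooled outer-fold decision values (ties
counted one half); ROC points come from the pooled scores.  Seven method
variants are compared: C, G, N, N+G, C+G, C+N, C+G+N.

## Simulation-study problem sizes

The many-cohort studies in `jssenet.experiments` (and the acceptance
script) run at reduced sizes chosen to keep a full study on a single CPU
while preserving the design: 38 subjects, 20 regions, 80 voxels per region,
a 64-point density grid, sparsity levels 0.2-0.5 in steps of 0.1, three
rewired nulls per level, beta step 0.5 and C = 1.  The no-effect (null)
study uses balanced 19/19 cohorts: 0.5 is the correct chance level only for
balanced classes, whereas with the 13/25 split the no-information rate is
25/38 ~ 0.66 and a chance-level check would conflate leakage with class
imbalance.  The injected-effect study keeps the 13/25 split, with ten
disjoint effect pairs at 1.5 within-region standard deviations.

## Numerical and design choices

* Sparsity edge counts use floor; tie-break is deterministic.
* Equal-variance (Student) t is the screening default, matching common
  practice in this literature; Welch is a switch.
* The t-test level on divergence features is slightly conservative
  (~3.5-4% at the study sizes) because divergences are right-skewed; the
  calibration test bounds the level rather than pinning 5% exactly.
* Density grids are per-pair; permutation equivariance and symmetry of the
  resulting matrix are exact by construction and verified.
* Random-graph gamma is checked as an ensemble mean over instances: a
  single sparse graph's mean nodal clustering is noisy enough that
  per-instance gamma ranges roughly 0.8-1.25.
* Hierarchy and synchronizability follow the conventional power-law
  regression and Laplacian eigenvalue-ratio definitions.

## Known limitations

* No weighted-graph metric variants or minimum-spanning-tree thresholding.
* No nonlinear kernels, probability calibration, or multi-class support.
* The synthetic generator's independence across regions understates the
  spatial correlation of real morphometry; classification accuracies on
  synthetic cohorts are not forecasts of clinical performance.
* Published group-level values from the motivating study design depend on
  a private 38-subject MRI cohort and are not reproduction targets here.
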
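# jssenet

Individual morphologic brain networks from gray-matter intensity
divergence, graph-theoretical features, and multi-kernel SVM
classification — with a fully synthetic, ground-truth-controlled cohort
generator.

## The problem

The levodopa challenge test stratifies Parkinson disease patients into low
and high responders (percent improvement of the UPDRS-III motor score,
`LR = 100 (off - peak_on) / off`, thresholded at 33%), a decision that
gates deep-brain-stimulation candidacy.  `jssenet` implements an imaging
pipeline that asks whether that stratification is predictable from
structural MRI alone:

1. **Individual morphologic network.**  For one subject, each atlas region
   contributes the distribution of its gray-matter voxel intensities.  The
   edge between regions i and j is a Jensen-Shannon-type divergence between
   the two kernel-density-estimated distributions P and Q,

   D_JS(P‖Q) = ½ [ D(P‖M) + D(Q‖M) ],  M = (P+Q)/2,

   where the inner operator D is, by default, the symmetrized
   (Jeffreys) Kullback-Leibler divergence
   D(P‖Q) = Σ_x [P ln(P/Q) + Q ln(Q/P)] (a switch selects plain KL,
   giving the textbook JS bounded by ln 2).  This yields a symmetric,
   nonnegative 90 × 90 connectivity matrix per subject.
2. **Graph metrics.**  The matrix is binarized at sparsity thresholds
   0.02–0.50 (step 0.01) and eleven global metrics (Cp, Lp, E_global,
   E_local, modularity, assortativity, hierarchy, synchronizability, and
   small-world γ, λ, σ = γ/λ against degree-preserving rewired nulls) plus
   six nodal metrics (degree, betweenness, nodal efficiency, nodal local
   efficiency, nodal clustering, nodal path length) are summed across the
   grid.
3. **Classification.**  Connection weights, global metrics, and nodal
   metrics form three feature blocks with linear kernels K_m, combined as
   Σ_m β_m K_m (β on the unit simplex).  The SVM dual
   max_α Σα_i − ½ Σ α_i α_j y_i y_j Σ_m β_m K_m(i,j), 0 ≤ α_i ≤ C,
   Σ α_i y_i = 0, is solved by an in-package SMO; (β, C) are tuned by inner
   leave-one-out accuracy inside a nested leave-one-out cross-validation
   with per-fold t-test screening (p < 0.05) of connection features, and
   connections selected in every fold are reported as *consensus
   connections*.

No public dataset accompanies this design, so the package ships a synthetic
cohort generator (`jssenet.cohort`) whose group effects — mean shifts of
designated region-pair intensity distributions — are known exactly,
letting every stage be validated end to end: chance-level behavior on null
cohorts, high accuracy and consensus recovery of injected pairs on
effect cohorts.

Audience: methods researchers in morphometric connectomics and anyone who
needs a transparent, testable reference implementation of divergence-based
single-subject networks with multi-kernel classification.

## Worked example

```python
from jssenet.cohort import CohortSpec
from jssenet.cv import CVConfig, PipelineConfig, run_pipeline

config = PipelineConfig(
    cohort=CohortSpec(n_low=6, n_high=8, n_rois=12, voxels_per_roi=60,
                      effect_pairs=((0, 1), (2, 3), (4, 5)),
                      effect_size=0.7, seed=7),
    methods=("C", "G", "N", "C+G+N"),
    sparsity_grid=(0.2, 0.3, 0.4, 0.5),
    n_null=3, grid_points=64,
    cv=CVConfig(beta_step=0.5, c_grid=(1.0,)),
    seed=7,
)
report = run_pipeline(config, "out/")
```

This simulates 14 subjects (6 low / 8 high responders, 12 regions) whose
high responders carry a 0.7-SD intensity shift in three region pairs,
builds all divergence networks and metric bundles, and runs the nested
cross-validation for four method variants.  The returned report (also
written to `out/report.json`, with TSV tables alongside) reads:

```
"C":     {"accuracy": 1.0,   "sensitivity": 1.0, "specificity": 1.0,   "auc": 1.0,
          "n_consensus": 28, "n_union": 38}
"G":     {"accuracy": 0.929, "sensitivity": 1.0, "specificity": 0.833, "auc": 1.0}
"N":     {"accuracy": 1.0,   "sensitivity": 1.0, "specificity": 1.0,   "auc": 1.0}
"C+G+N": {"accuracy": 1.0,   "sensitivity": 1.0, "specificity": 1.0,   "auc": 1.0}
```

Reading: the connection block alone separates the groups perfectly (the
injected pairs sit in the 28 consensus connections selected in every
fold); the global-metric block alone misclassifies one low responder
(specificity 5/6 = 0.833); combining kernels recovers perfect accuracy.
`out/consensus_C_G_N.tsv` lists each consensus connection with its region
names, group means, and p-value.

A command-line interface mirrors the stages:
`jssenet simulate`, `jssenet network`, `jssenet metrics`,
`jssenet classify`, and `jssenet report` (YAML config).

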
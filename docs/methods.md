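# Methods

This note documents the statistical model behind `voxelreuse`, the
choices made where the procedure is genuinely underdetermined, and what
the synthetic-data validation does and does not establish.

## The question and the statistic

Two binary discriminations (one per task) are decoded from the same ROI.
Each task's multivoxel code is summarised by the set of voxels that
contribute the most *signal* to the discrimination; the **voxel re-use
index** is the proportion of the top-fraction voxels (default 10 %)
shared between the two tasks' sets. For independent selections of k out
of N voxels the index has hypergeometric expectation k/N, which is the
chance level all inference is measured against.

### From classifier weights to signal contributions

A linear SVM is a backward model: its weight vector w extracts the label
from the data, and a voxel can earn a large |w| purely by cancelling
structured noise. The forward-model activation pattern is obtained as

    a = Σ w,

where Σ is the covariance of the training data. For a single binary
discriminant the full transformation also divides by the variance of the
decision value — a positive scalar that cannot change the ranking of
|a|, so it is omitted; ranking is the only downstream consumer.

**Ranking by |a| vs signed a.** Voxels are ranked by |a| by default: the
planted effects (and, plausibly, real condition contrasts) have
arbitrary sign per voxel, and "contributing the most signal" is a
magnitude notion. A `ranking="signed"` option exists.

**Covariance estimation.** Σ is estimated from the same 16 samples
(8 blocks × 2 conditions) used to fit the classifier, pooled across
classes after demeaning each voxel. With hundreds of voxels and 16
samples the empirical estimate is singular, so in that regime the
default is shrinkage toward the diagonal of the sample covariance with
an analytically chosen intensity λ* = Σ_{i≠j} Var̂(s_ij) / Σ_{i≠j} s²_ij
(clipped to [0, 1]); `kind="empirical"` is available, and `shrinkage=1`
returns the diagonal target exactly. Shrinkage stabilises the |a|
ranking without changing its noiseless-limit support: at σ = 0 the
covariance is a scaled outer product of the planted pattern, and a is
supported exactly on the planted voxels.

### Two-step permutation inference

Within subject, B (default 100) label permutations are drawn: each
task's 16 condition labels are permuted among that task's samples (both
tasks independently per draw), the full re-use computation is rerun, and
the B proportions form the subject's null. At the group level, M
(default 10 000) null values are formed by drawing one value per subject
(uniformly, with replacement) and averaging; the one-sided p-value is
(1 + #{null ≥ observed}) / (1 + M), never exactly zero. The
within-subject step makes the null conditional on each subject's own
data covariance — voxels that would win any discrimination for
uninteresting reasons (vasculature, coil sensitivity) inflate the null
exactly as they inflate the observed value.

Because the pooled covariance is invariant to condition relabelling, Σ
is computed once per subject and task and cached across permutations;
this is an exact optimisation, not an approximation (a test asserts
value-for-value equality with the explicit permute-and-recompute route).

**Permutation unit.** Unrestricted permutation of the 16 labels is the
right null for full-data fits and is what the re-use test uses. For
*cross-validated accuracy* nulls it is not: permutations that unbalance
the training folds bias CV accuracy below chance (≈47 % measured here
over 1000 simulated subjects — a known artifact of CV under
permutation). `permute_condition_labels(unit="block")` therefore swaps
condition labels within each block, respecting block exchangeability and
keeping every leave-one-block-out fold balanced; decoding-null
calibration uses this scheme (measured 49.7 % over 1000 subjects).

### Decoding and gating

Decoding uses a linear SVM with C = 1 (no per-fold tuning — tuning would
change the weight vectors the transformation consumes), no feature
scaling by default (betas share a scale; a per-fold standardisation flag
exists), leave-one-block-out cross-validation (the block is the beta
estimation unit), and accuracy pooled over test samples. Group inference
is a one-sided one-sample t-test against 50 %.

Re-use is computed only in ROI × relevance cells whose decoding passes
that gate (p < α, optionally Bonferroni-divided across ROIs), because a
re-use value between unreliable codes is uninterpretable; a flag
disables gating for sanity checks. Two pipeline-specific choices: the
gate uses each subject's *mean* of the two within-task accuracies in a
single t-test (the two codes are decoded separately but re-use needs
both); and a degenerate zero-variance group (every subject at the same
accuracy, e.g. all 100 %) passes the gate iff that common accuracy
exceeds chance, since the t statistic is undefined there.

## The synthetic world

The generator emits, per subject, one beta pattern per (task, block,
condition, feature-relevance) cell — 2 × 8 × 2 × 2 = 64 samples — on a
voxel grid treated as the ROI. At each task's planted informative voxels
(fraction 0.1 of the grid by default, matching the top-10 % selection),
condition 1 and 2 means are ±a_v with |a_v| = d/2 and random sign, so
the condition separation is d noise-SD units. A fraction ρ of each
task's informative voxels is shared, and shared voxels carry the *same*
signed effect (a genuinely shared code — this is what makes ρ = 1
cross-task generalization perfect in the noiseless limit). The
never-attended feature dimension gets an independent pattern with its
own effect size (0 by default: pure noise). Noise is iid Gaussian per
voxel and sample, optionally spatially smoothed (variance-renormalised)
for searchlight work.

Defaults describe the stated world: 12 subjects, a 200-voxel ROI
(10 × 5 × 4 grid, 3 mm voxels), 8 blocks per task, d = 1.5, σ = 1,
ρ = 1 — the regime in which the test's power is validated (≥ 90 %
rejection), with ρ = 0 variants for calibration and specificity.

**What the simulation does not model:** spatially correlated or
heteroscedastic noise (real fMRI noise has both; the iid choice is a
modelling decision, the data-generating noise covariance of the original
setting being unknown), HRF/trial-level structure (the generator emits
GLM outputs directly), between-subject variation in effect size, and
anatomical ROI geometry. Green tests therefore establish internal
statistical correctness — calibration, power, recovery, determinism —
not robustness to realistic noise covariance.

## Numerical conventions

- Set sizes: k = round-half-away-from-zero(fraction · N), minimum 1 in
  top-k selection; a configuration whose informative fraction rounds to
  zero voxels is rejected as degenerate.
- Ties in |a|: broken toward the lower voxel index (stable sort on
  descending value) — deterministic, and only relevant in degenerate
  (e.g. noiseless, duplicate-value) inputs.
- Voxel order: ascending linear index, C order over (x, y, z); mm
  coordinates via the NIfTI affine; sphere membership by centre-to-centre
  mm distance ≤ radius (a 5 mm sphere on a 3 mm grid has 19 voxels).
- Determinism: every stochastic step takes a seed or Generator;
  identical config + seed reproduces datasets, null distributions and
  reports bit-exactly. Reports carry a config hash (output paths
  excluded), the seed and the package version.
- Cluster extent thresholding uses 6-connectivity (faces only) and
  reports size-sorted clusters; it performs no random-field inference.

## Known limitations

- Calibration and power figures are specific to the simulated world's
  iid-noise assumption; under strongly correlated noise the shrinkage
  intensity and the permutation null both adapt, but no claim is
  validated there.
- The searchlight is a straightforward per-sphere loop — adequate for
  ROI-scale grids, not optimised for whole-brain volumes.
- Only binary discriminations are supported end to end; multi-class
  weight transformation is out of scope.
- Re-use values are compared against chance within an ROI; the package
  deliberately provides no between-ROI comparison of re-use values.
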
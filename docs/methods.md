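# Methods

## Labeled volumes and the discrete surface

All markers operate on a `LabeledVolume`: a 3-D array of non-negative integer
labels (0 = background), per-axis voxel spacing in mm, and a label-name map.
Voxel centers sit at (index + 0.5) · spacing; world affines in NIfTI headers
are ignored because every marker is computed within a single subject's grid
and never compared across grids in absolute coordinates.

Adjacency is **6-connectivity face sharing** throughout: the discrete surface
of a region is the set of voxel faces whose across-face neighbor carries a
different label.  Faces on the grid boundary count as background contact — a
region touching the field of view still has that surface.  The same
convention drives the connectivity marker, the divergence-theorem centroid
and the morphological atrophy operators, so all components agree about what
"the boundary of a region" means.

### Surface connectivity

Entry (i, j) of the connectivity matrix is 100 · F<sub>ij</sub> / F<sub>i</sub>,
where F<sub>ij</sub> is the number of faces shared by regions i and j and
F<sub>i</sub> is region i's total exposed surface **against all labels in the
volume**, not just those of the reporting grouping — a region's surface must
not depend on which regions are reported against.  Background contact enters
the denominator only; it is never a feature column.  Feature ordering is
row-major over the grouping's declared region order, and the groupings ship
as JSON so feature columns are stable across runs.  A region with zero voxels
produces a zero row and a logged warning rather than an error, since
longitudinal segmentations occasionally lose small structures.

The terms "percentile" and "percentage" are sometimes used interchangeably
for this quantity; here it is always the percentage in [0, 100].

### Centroids

Two interchangeable computations are provided: the arithmetic mean of voxel
centers, and a surface integral over exposed faces (each face normal to axis
d contributes ± (plane position)² · face area to coordinate d, divided by
2V).  For axis-aligned voxel solids the two are mathematically identical;
the test suite asserts agreement to 1e−9 relative error on random solids, and
the surface form documents that the centroid — like the connectivity marker —
is a functional of the region's boundary alone.

### Volume fractions

Whole-brain fraction = (intracranial volume minus CSF-like/vessel regions) /
intracranial volume; hippocampal fraction = (left + right hippocampus) /
intracranial volume.  Which labels play which role is configuration
(`FractionDefs`); for the phantom, the intracranial volume is the whole head
and the CSF shell plus lateral ventricles are excluded from the whole-brain
numerator.

## Procrustes alignment

Landmark sets (one region centroid each, K ≥ 3) are normalized by centering
and scaling to unit centroid size, then aligned by full-similarity
generalized Procrustes analysis: starting from the normalized mean of the
normalized sets, each iteration rotates and rescales every set onto the
current mean (optimal proper rotation via SVD of the cross-covariance;
reflections are never allowed because anatomical configurations must not be
mirrored), recomputes the mean, renormalizes it, and stops when the mean
changes by less than 1e−10 in Frobenius norm (default; at most 100
iterations — GPA at K ≤ 40 typically converges in 3–5).  The arbitrary global
rotation is then fixed by rotating the mean to its principal axes with a
deterministic sign convention (the largest-magnitude coordinate along each
axis is made positive, properness enforced on the last axis), which makes the
feature vectors bit-reproducible.

In cross-validation the mean shape is fit on the training fold only; held-out
subjects are aligned to that fixed mean (`align_to_mean`) without refitting.
Whether the original study fit the alignment per fold or once on the full
cohort is not documented anywhere we could find; per-fold fitting is chosen
because refitting with test subjects would leak information into the
features.

## Classification

* **Residualization.**  For each feature column, each covariate is tested for
  Pearson correlation on the training rows; if any covariate is significant
  at gate α = 0.05 the column is replaced by the residuals of an OLS fit
  (intercept + the significant covariates), fit on training rows and applied
  to all rows.  Sex is coded 0/1; constant covariates are skipped with a
  warning; α = 0 disables adjustment.  The gate operationalizes "adjust when
  a linear correlation exists" as a per-column per-covariate size-α test.
  For the landmark marker the adjustment is applied to the raw centroid
  columns *before* per-fold alignment; note the caveat that residualized
  coordinates are no longer positions, so adjusted landmark runs trade shape
  interpretability for covariate control.
* **PLS.**  NIPALS with X-deflation only and a scalar response (class code
  ±1): each weight vector is the normalized covariance of the deflated
  columns with y — the first provably maximizes cov(Xw, y) over unit
  vectors — with 10 components by default, truncated with a warning to
  min(n−1, p) or the effective rank.  Features and response are centered on
  training means; **no unit-variance scaling** is applied, because scaling
  would distort the geometry of connectivity percentages.  At full rank the
  PLS regression reproduces least squares, which the tests assert.
* **LDA.**  Two-class Fisher discriminant in PLS score space:
  w ∝ S<sub>pooled</sub>⁻¹(μ₊ − μ₋), with a ridge of 1e−6 · trace(S)/d added
  only if the pooled covariance is numerically singular.  The decision value
  is wᵀx − wᵀ(μ₊ + μ₋)/2, so scores from different folds share the training
  midpoint as their origin.
* **Cross-validation.**  Leave-one-of-each-class-out: both classes are
  shuffled once with the run seed; fold t holds out subject t of the larger
  class and subject t mod n<sub>small</sub> of the smaller, so the larger
  class indexes the folds, smaller-class subjects are reused as holdouts, and
  each subject's recorded score comes from the first fold that held it out —
  every subject is scored exactly once and all data is used.  Shuffling is
  the only seeded randomness; all numerics are deterministic.
* **Evaluation.**  AUC in the Mann-Whitney formulation with midranks for
  ties; the rank-sum test uses exact enumeration when the combined sample is
  ≤ 12 and tie-free, otherwise the normal approximation with midranks,
  tie-corrected variance and continuity correction (both via
  `scipy.stats.mannwhitneyu`).  Significance is reported at the two
  conventional thresholds (0.05, 0.001) with **no multiple-comparison
  correction**, stated in the report footer.

## The phantom

The generator emulates the features of a segmented longitudinal cohort that
the downstream analysis actually consumes:

* a multi-region labeled head (CSF shell, paired cortex / white matter /
  lateral ventricle / thalamus / hippocampus / amygdala, brain stem) painted
  as ellipsoids in painter's order, mirror-symmetric across the mid-sagittal
  plane;
* class-graded atrophy as integer 6-connectivity morphology steps: by
  default AD = 2 hippocampal erosion layers + 1 ventricular dilation layer at
  baseline, MCI = half the AD effect (1 hippocampal layer after integer
  halving), NC = none.  Eroded voxels are relabeled to CSF (more fluid
  between regions); dilation consumes only neighboring tissue voxels, so the
  labeled volume is conserved;
* longitudinal progression: AD gains one further layer of each effect at
  month 12; MCI converters receive the AD-rate increment while non-converters
  are modeled as longitudinally stable, which gives the delta markers a real
  converter signal;
* nuisance variability per subject: global scale jitter (σ = 3 %, clipped at
  2.5 σ), a rigid shift of up to half a voxel per axis (drawn once per
  subject so both timepoints share one anatomy), random flips of 0.5 % of
  inter-region boundary voxels to a neighboring label per timepoint
  (segmentation noise — the source of longitudinal marker noise), and an
  age-linked extra cortical erosion (0.5 layers per decade above 65, floored
  to an integer) so that age genuinely correlates with the features and the
  residualization path is exercised;
* demographics: age ~ N(73, 6²) clipped to [55, 90], sex Bernoulli(½),
  configurable class counts; one independent random stream per subject
  derived from the cohort seed, so cohorts reproduce byte-identically.

What the phantom does **not** emulate: MRI intensities, bias fields,
segmentation algorithms (labels are generated directly), absolute region
volumes in mm³, within-class heterogeneity of atrophy patterns (all subjects
of a class receive the same integer steps; variability enters only through
pose, scale and boundary noise), and any distinction between longitudinal and
cross-sectional segmentation pipelines (per-timepoint "static" volumes have
no phantom equivalent).  Passing tests therefore demonstrate that the
pipeline recovers geometric effects of this kind at these noise levels — not
clinical performance on real MRI.

Because atrophy steps are whole voxel layers, the default magnitudes assume
grids of at least ~48 voxels per axis; on coarser grids a 2–3-layer erosion
can empty the hippocampus, which the generator reports as an error rather
than silently clamping.  The shipped default configuration
(`data/phantom_default.json`) is a 64³ grid at 1 mm isotropic spacing.

## Study conditions used by the acceptance script

`scripts/acceptance.py` uses an effect cohort of NC = 60, MCI = 80 (40
converters), AD = 60 on a 48³ grid with the default atrophy, and a null
calibration of 200 cohorts of 30 + 30 subjects on a 32³ grid with all effects
disabled.  These sizes keep the complete recomputation within a few minutes
on one CPU while leaving the per-cohort statistics (30–80 subjects per class)
in the regime the pipeline targets.  Under the default conditions the induced
group differences are strong relative to the phantom's noise, so baseline
AUCs saturate near 1.0; the label-permutation control and the null
calibration verify that this separation vanishes when the class structure is
removed.

## Known limitations

* **Rank-sum p-values on cross-validated scores are anti-conservative.**
  Out-of-fold decision scores are not independent: all folds share nearly all
  training data, each fold's model applies a common offset to the one subject
  of each class it scores, and excluding a subject from training biases its
  own score away from its class.  The acceptance suite measures the
  consequences on zero-effect cohorts: the mean out-of-fold AUC sits slightly
  below chance (≈ 0.48–0.50) and the rank-sum rejection rate at α = 0.05 is
  ≈ 0.12–0.16 instead of 0.05 — an inflation that persists (≈ 0.12) even when
  the phantom is replaced by pure i.i.d. Gaussian features, while the same
  rank-sum implementation is exactly nominal on independent samples.  The
  p-values produced by this protocol should therefore be read as descriptive
  ranking scores, not calibrated error rates; a permutation test over the
  whole CV loop would be the calibrated (but far more expensive) alternative.
* The fold construction for unequal classes (larger class indexes folds,
  smaller class cycles, first-holdout scoring) is one reasonable convention
  among several; results can shift slightly under a different pairing.
* Connectivity uses 6-connectivity faces; 26-connectivity or mesh-based
  surfaces would give different (generally larger) contact estimates.
* The converter model is deliberately simple (a single AD-rate increment);
  real MCI progression is heterogeneous in both rate and anatomy.
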
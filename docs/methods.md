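# Methods

This note records the models, numerical choices and known limitations of
`nodulecad`, in the order the pipeline runs. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinate and intensity conventions

Volumes are arrays indexed `(z, y, x)` with per-axis spacing `(dz, dy,
dx)` in mm; physical coordinates follow the voxel-center convention
`mm = origin + index × spacing`. All processing happens after a linear
min–max normalization to `[0, 255]` (`normalized8bit`); constant volumes
map to zero. Min–max rather than percentile normalization is the default
because the thresholding stage adapts per scan anyway; percentile
clipping can be added upstream for noisy clinical data.

## Lung extraction

The minimum-error threshold minimizes the two-Gaussian criterion
J(t) = 1 + 2[P₁ln σ₁ + P₂ln σ₂] − 2[P₁ln P₁ + P₂ln P₂] by exhaustive
search over the 256-bin histogram. A threshold `t` assigns bins `< t` to
the dark class; ties break toward the smaller `t`. Degenerate single-spike
classes receive a variance floor of 1/12 (the variance of a uniform
spread within one bin), which keeps J finite without changing the argmin
on non-degenerate histograms.

Border-touching dark components are removed per slice in 2D: the top and
bottom slices legitimately cut through lung tissue, so a 3D border
criterion would be wrong. Component retention keeps the largest dark
component and the second-largest only if it holds ≥ 10% of the largest's
volume (otherwise the two lungs are assumed fused into one component).

Pleural reconstruction is per-slice morphological closing (disk) followed
by hole filling. Hole filling alone cannot recover a nodule that truly
crosses the pleural boundary: its bright voxels connect to the bright
chest wall, so it is not an enclosed 2D hole. Closing first bridges the
pleural notch; the filled region then includes the nodule. The closing
radius must be at least half the widest expected notch — about the radius
of the largest nodule of interest — and defaults to 7 mm. Tangent-point
rim voxels (a few per nodule) can still be lost; the lung-extraction test
asserts ≥ 95% recovery of a wall-attached nodule rather than exact
containment. Hole filling is 2D per slice, not 3D, because 3D filling
would not fill regions open to the airways.

## Candidate segmentation

The 2D area floor is the pixel count of the smallest target nodule's
equatorial cross-section, ⌈π(d/2)²/(dy·dx)⌉ with d = 4 mm by default
(26 px at 0.7 mm pixels). The bright-structure threshold is Otsu over
lung-interior intensities, computed once per scan; the mean-intensity
floor of the AND-filter defaults to that same threshold. Both indicators
must agree for a structure to survive.

3D grouping uses 26-connectivity; candidate ids follow the ascending
lexicographic order of each component's first voxel, so output is
deterministic.

Blob scores: sphericity is component volume over the volume of the sphere
whose radius is the maximum centroid-to-voxel distance (clipped to
(0, 1]; a single voxel scores 1 by convention). This avoids surface-area
estimation on small digitized blobs but is deliberately pessimistic: one
attached stray voxel at 1.5× the blob radius drops a perfect digitized
sphere from ~1.0 to ~0.28, while tubular components score ≲ 0.11. The
default `sphericity_min = 0.15` sits in that gap; it was tuned on phantom
suites and is exposed in the config. Width is the smallest bounding-box
edge, each edge computed as (index extent + 1) × spacing. The default
`width_min_mm = 2.5` equals a typical slice thickness on purpose: bounding
boxes quantize to whole slices, so any stricter floor would reject every
single-slice candidate regardless of its in-plane size — and a 5–6 mm
nodule can legitimately digitize into one 2.5 mm slice. Elongation
(max/min bbox edge) ≤ 4 rejects residual tube fragments. There is no
upper size filter; large masses must reach classification.

Vessel-bifurcation centers are handled only implicitly by these
thresholds; junction blobs that pass are the pipeline's dominant
false-positive source, by design left to the classifier.

## Features

d1 (area) and d2 (circularity) are computed on the candidate's
largest-area axial cross-section (ties: lowest slice), because the
slice-wise stage reasons in pixels; d7/d8 are volumetric. The circularity
diameter is the maximum pairwise pixel-center distance + 1 px, making the
formula total (a single pixel has D = 1, d2 = 1/π) and accounting for
pixels having unit extent; a perfect digital disk tends to 1/4 as its
radius grows. Moments are population (1/n) moments; kurtosis is raw, not
excess (normal ⇒ 3, uniform ⇒ 9/5). Zero-variance regions raise rather
than return a sentinel — on noiseless synthetic data the moment features
are genuinely undefined, and `detect(..., compute_features=False)` stops
before them.

Correlation selection greedily drops, from the most correlated pair, the
member with the larger mean absolute correlation to the rest (ties: the
later column), until no pair exceeds `r_max` (default 0.95). Constant
columns are dropped first with a warning. The fixed eight-descriptor
preset `MINIMAL8` bypasses selection.

## Classification

The classifier is an ε-SVR (RBF kernel) on ±1 targets, thresholded at a
decision threshold; ε defaults to 0.4. Training uses a balanced matrix
(20 per class by default, reduced with a warning when a class is
scarcer), drawn without replacement from the labeled candidate pool; a
deterministic quantile-spaced alternative (`select_representatives`,
ordering each class by d8 and picking evenly spaced ranks so both
extremes always enter) is provided for protocols that train on extreme
cases.

Normalization is per-feature min–max to [0, 1]. Two protocols exist: the
default fits statistics on training data only and applies them to new
data (leak-free deployment); the transductive protocol pools training and
new data before scaling (`transductive=True` in cross-validation, or
`joint_normalize(train, new)` directly). The stored statistics make
deployment independent of the data being classified.

C and γ come from an exhaustive grid (C ∈ 2⁻⁵..2¹⁵, γ ∈ 2⁻¹⁵..2³, steps
of ×4) ranked by stratified 5-fold cross-validated accuracy of
sign(score), averaged over 3 reshuffles — a single shuffle is too noisy
to rank kernels on a 40-row matrix. Ties go to the first grid point.

The decision threshold is selected on training data only: held-out
balanced-matrix scores (5-fold at the chosen C/γ/ε) are swept for the
threshold minimizing `2·FN + FP`, capped at 0, with the midpoint of the
optimal-cost interval as tie-break. Weighting misses twice as heavily as
false alarms places the operating point toward sensitivity, which is the
stated purpose of tuning this classifier's operating parameters.

Models persist as JSON storing hyperparameters, normalization statistics
and the (small) training matrix; loading refits the SVR, which is
deterministic, so persisted and in-memory models classify identically.

## Evaluation

A predicted nodule is a true positive when its centroid lies within the
ground-truth radius of an unclaimed planted nodule, matched nearest
first; every predicted non-nodule counts as a true negative, so
TP + FP + TN equals the number of candidates and TP + FN the number of
truths. Percentages are rounded half-up to 2 decimals; a zero denominator
yields "undefined" (None), never 0.

Leave-two-out cross-validation enumerates all C(n, 2) pairs up to
`max_folds` (default 500), else samples that many distinct pairs.
Hyperparameters are selected once on the full balanced matrix and reused
across folds with a per-fold refit; per-fold grid search is available
(`optimize_each_fold`) but multiplies cost by the grid size for little
measured benefit. Folds whose training side lacks two rows of a class are
skipped with a warning.

## The phantom generator

The generator emulates what this pipeline assumes about a chest scan, not
CT physics: piecewise-constant materials (body 200, lung/background air
60, structures 220 on the 8-bit-like scale), additive Gaussian noise
(default σ = 5, seed-controlled, clipped to [0, 255]), no partial-volume
effects, no beam hardening, no sinogram model. Default geometry is
desk-scale: 128×128 in-plane at 0.7 mm, 40–80 slices at 2.5 mm. The two
lung ellipsoids are separated by a mediastinum wider than twice the
pleural-closing diameter so per-slice closing cannot bridge them.

Vessels are capsule unions (segment + radius) with Y-bifurcations. Trunk
radii (1.0–1.5 mm) sit below the 4 mm-equivalent area floor so plain
tubes vanish in the 2D stage; each bifurcation carries a bulb (a
degenerate capsule of 2.0–2.4 mm radius) whose lobed union with the tube
stubs is the deliberate false-positive source — compact enough to pass
blob discrimination, at roughly one surviving FP candidate per two scans.
Vessel directions keep |z-component| ≥ 0.5 (≥ 0.75 for the trunk that
carries vessel-attached nodules): at 2.5 mm slice spacing a near-in-plane
tube leaves long in-slice runs that graze attached nodules and collapse
their bounding-sphere sphericity.

Nodules (0–2 per scan, radii uniform on 2.5–7.0 mm, i.e. diameters
5–14 mm, strictly above the 4 mm detectability floor the area filter is
built around) come in three kinds. Isolated: fully interior with ≥ 1 mm
clearance. Vessel-attached: the near-vertical trunk passes through the
nodule interior (center within 0.3 r of the axis), placement retried
until the sphere is interior to the lung. Juxtapleural: center 0.95–1.15
radii inside the wall measured along the ellipsoid surface normal (the
direction toward the ellipsoid center is nearly tangent to the wall at
the poles), resampled until ≥ 55% of the sphere lies inside the lung —
on a strongly curved wall patch a tangent sphere otherwise buries itself
in the chest wall. Distinct nodules keep ≥ 4 mm clearance; overlapping
spheres would merge into one dumbbell candidate matching neither truth.
Irregular nodules modulate the radius by a seeded low-order quadratic
form on the unit sphere, scaled by `irregularity` (≤ ±35% /2 at the
maximum setting).

What passing phantom tests does and does not show: the phantom exercises
the pipeline's geometry and logic — bimodal thresholding, pleural
reconstruction, slice-wise filtering, 3D blob discrimination, the
feature/classifier protocol — under controlled ground truth. It does not
show performance on clinical CT: real parenchyma has texture, vessels
taper and curve, nodules have partial-volume gradients and varied
density, and non-nodule candidates there differ in intensity as well as
shape. Results on the phantom suite are internal regression bars, not
clinical claims.

## The phantom study

`run_phantom_study(seed)` generates a training suite (40 scans, from
`seed + 10007`) and a test suite (20 scans, from `seed`), labels training
candidates by the centroid-within-radius criterion, draws the balanced
matrix, trains with automatic C/γ selection and threshold tuning, then
classifies the test suite and scores against ground truth. Forty training
scans are what it takes to fill the 20+20 balanced matrix at this
generator's candidate rates (~1 nodule and ~0.5 surviving non-nodule
candidates per scan). FPs/scan is reported both before and after
classification, since a candidate-level and a post-classifier rate answer
different questions.

Known limitation: the smallest nodules (2.5–2.9 mm radius) and the
largest junction bulbs occupy the same region of the eight-feature space
— they are near-identical objects in this phantom — so a few such nodules
per suite may be classified as non-nodules depending on the training
draw. Detection sensitivity on 20-scan suites therefore fluctuates
roughly between 0.7 and 1.0 across seeds (the suite-level bars asserted
in the tests use their stated fixed seeds). This mirrors the documented
behaviour of the underlying method, which both misses a small fraction of
nodules and accepts the occasional bifurcation as a nodule.
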
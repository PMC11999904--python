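# Methods

`headms` implements an automated pipeline for quantifying head muscles and
subcutaneous fat in axial T1-weighted head MRI: semantic segmentation of five
tissues (left/right masseter, left/right subcutaneous fat, tongue) with
U-Net-family networks, evaluation under subject-level k-fold
cross-validation, tissue area/volume morphometry, and an age/sex-adjusted
regression of tissue size on BMI.  Because the motivating clinical dataset
(1.5 T T1 head MRI of a dementia cohort) is not publicly deposited, the
package ships a synthetic head-phantom generator that reproduces the
*statistical structure* the downstream stages assume, so that every stage is
testable end to end.

## Label scheme and formats

Six classes, fixed across every stage and the one-hot channel order of the
networks: 0 background, 1 right masseter, 2 left masseter, 3 right
subcutaneous fat, 4 left subcutaneous fat, 5 tongue.  Images and labels are
NIfTI-1 (`.nii.gz`, labels as uint8); covariates are CSV; configurations are
YAML; run manifests are JSON.  Default grid: 256x256 pixels at
260/256 ≈ 1.016 mm in-plane (26 cm field of view over a 256 matrix).  The
acquisition description the in-plane default derives from is internally
inconsistent about the through-plane sampling (2 mm slices with a 1 mm gap
versus contiguous 1 mm slices), so the slice increment is an explicit
parameter, default 3 mm.

## Synthetic phantom cohort

Each subject is a stack of `n_slices` (default 7) axial slices.  Per slice,
five mutually exclusive regions are rasterized in fractional coordinates:
bilateral masseter ellipses, a subcutaneous-fat crescent lateral to each
masseter (an ellipse minus a medially shifted copy of itself), and a central
tongue ellipse.  The per-slice region area follows a parabolic profile
`1 - 0.3 u^2` (u in [-1, 1]) peaking at the central slice, which gives the
slice-selection stage something to find.  Intensities follow the T1 contrast
ordering background (0.10) < muscle (0.50) < fat (0.90) with additive
Gaussian noise (sd 0.05) clipped to [0, 1]; an optional smooth multiplicative
bias field is off by default.

Covariates: age ~ Normal(76, 7) truncated at 50; sex ~ Bernoulli(0.5);
BMI ~ Normal(26, 4) truncated to [15, 45]; diagnosis AD/DLB in a 33:20 ratio.
Each tissue's linear size is multiplied by `sqrt(1 + beta_t (BMI - 26))`, so
its expected cross-sectional area is `base_area_t (1 + beta_t (BMI - 26))`.
Defaults: beta = 0.02 per BMI unit (2% of base area per kg/m^2, a realistic
soft-tissue effect that gives essentially full power at n = 53) for tongue,
left masseter and both fat regions, and beta = 0 for the right masseter,
which serves as the built-in negative control.  Per-subject shape jitter —
2.5% sd multiplicative on each semi-axis and 0.4% of image size on centers,
both truncated at 3 sd — breaks exact left/right mirror symmetry and supplies
the measurement noise (area CV about 5%) for the association stage.

Seeding: one master seed drives the covariate draws; each subject's geometry
and noise use a seed hashed from (master seed, subject index) via
`numpy.random.SeedSequence`, so cohorts are reproducible subject-by-subject
and under parallel generation.

The generator's analytic ground truth is available in closed form:
`analytic_base_area_cm2` returns the continuous-geometry area of each region
(ellipse `pi a b`; the crescent via the two-circle lens formula after
rescaling axes), and the injected BMI slope for a tissue is `beta_t` times
that area.  The pixel-counted area of the thin fat crescent at a 256 grid is
biased low by roughly 1%, so the analytic value — not a pixel-counted
reference subject — is the correct recovery target for regression tests at
large n.

What the phantom does *not* model: MRI physics, motion, coil inhomogeneity,
3-D anatomical continuity (slices are scaled copies), inter-tissue contact
(regions are separated by construction, whereas real masseter and fat
touch), or anatomical shape variation beyond affine jitter.  Passing
segmentation tests on phantoms therefore demonstrates that the
implementation is correct and the pipeline wired properly, not that any
architecture reaches clinical-grade accuracy on real MRI.

## Network engine

No deep-learning framework is part of the dependency set; the segmentation
networks run on a small NumPy engine (`headms.nn`) with reverse-mode
autodiff.  Convolutions are lowered to BLAS matrix products via im2col; the
input gradient is itself a same-padded convolution with the spatially
flipped, channel-transposed kernel, so no scatter-add is needed.  Transposed
convolutions are zero-dilation followed by an ordinary convolution, with the
kernel stored in correlation form.  All activations are float32 NHWC.
Max-pooling resolves ties by first occurrence; batch normalization uses
momentum 0.1 and eps 1e-5.  Every op's analytic gradient is tested against
central finite differences.

## Architecture zoo and parameter accounting

All seven families share canonical block conventions: encoder level =
[3x3 conv (bias) -> channel-wise norm -> ReLU] x 2 with 2x2 max-pooling;
decoder step = 3x3 stride-2 transposed conv (bias, no norm) -> concatenate
skip -> double conv; terminal 1x1 conv + softmax; "same" padding throughout.
Parameter accounting counts *stored* values: conv weights and biases plus
4 values per normalized channel (affine pair + running mean/variance).  The
reported totals are therefore "stored parameters"; a count that excluded
running statistics would be smaller by 2 values per normalized channel.

Under these conventions, closed-form per-layer summation gives exactly
2,164,390 for the base U-Net (widths 16/32/64/128/256, 1 input channel,
6 classes), 7,596,306 for the Wide U-Net (widths 30/60/120/240/480), and
2,555,702 for U-Net++ (nested double-conv skip nodes, deep supervision
off) — and the runtime count of the built models agrees integer-for-integer.

The remaining variants have no universally fixed hyperparameters; the
defaults were chosen once so the seven totals are strictly ordered
U-Net < Attention < U-Net++ < Inception < Residual < Wide < Dense:

* **Attention U-Net** — additive attention gates on the four skips, gated by
  the pre-upsampling decoder feature; inter-channel width F equals the skip
  width (gate cost 3C^2 + 3C + 1).  Total 2,230,394.
* **Inception U-Net** — per level, parallel 1x1 / 3x3 / 5x5 / average-pooled
  1x1 branches each of width 23w/16, concatenated and projected by 1x1 to w.
  Total 5,532,154.
* **Residual U-Net** — double-conv blocks with 1x1 projection shortcuts and
  encoder widths 28/56/112/224/448.  Total 6,886,018.
* **Dense U-Net** — per block, 2 densely connected 3x3 layers of growth
  31w/16 plus a 1x1 transition to w.  Total 7,640,162.

## Training and cross-validation

The full-scale recipe is mini-batch gradient descent with Adam (lr 1e-4,
batch 8), categorical cross-entropy (probabilities clipped to [1e-7,
1 - 1e-7]), 200 epochs, no early stopping, no schedule, k = 10.  Inputs are
min-max normalized per slice.  Optional augmentation (horizontal flip with
left/right label-channel swap) exists but is off by default.

Splitting is by **subject**: a random permutation assigns subjects to k
near-equal folds (sizes differ by at most one).  In run i, fold i is the
test set and fold i+1 (cyclically) is the validation set used for per-epoch
monitoring; the other k-2 folds train.  With k = 2 there is no spare fold
and validation is empty.  This guarantees no subject's slices leak across
train/validation/test.  Metrics are computed per subject (that subject's
five analysis slices pooled), then averaged within each split; per-fold
records and mean/SD/median/IQR aggregates are emitted.  Cross-validation
trains and evaluates on each subject's five selected analysis slices (see
morphometry), matching the data the manual ground-truth protocol would
produce.

Desk-scale runs (the test suite, `TrainConfig.desk_scale`) shrink epochs to
the teens and compensate by raising the learning rate to 1e-3 and lowering
the batch size to 2, so the number of Adam updates (a few hundred) is
adequate for the high-contrast phantom task; at the full-scale recipe the
update count at 15 epochs would be a factor ~25 too small to move a
randomly initialized network.  On a 20-subject, 128x128 phantom cohort with
k = 3 and 15 epochs, the base U-Net reaches mean test DSC above 0.99 with a
validation-test gap below 0.01; the suite asserts the looser floor of 0.85
and gap < 0.05.  Determinism: with a fixed seed the run is bit-reproducible
on one machine; across BLAS implementations small float differences can
grow, so cross-machine agreement is only expected at the metric level
(~0.01 DSC).

## Evaluation metrics

DSC = 2|P∩G| / (|P| + |G|), reported as a percent; two empty masks give 1,
one empty mask gives 0.  ASSD averages, symmetrically over both boundary
sets, the shortest Euclidean distance (mm, anisotropic spacing supported via
an exact distance transform) from each boundary pixel to the other boundary;
it is undefined — recorded as missing, never 0 — when either mask is empty.
Boundaries are inner 4-connected borders per 2-D slice (the manual ground
truth is five discrete slices 3 mm apart; a 3-D surface distance is not
meaningful at that sampling, so 2-D per slice was chosen and the per-tissue
ASSD averages the defined slices containing the tissue in the ground truth).
The extended suite (Jaccard, precision, recall, sensitivity, specificity,
F1) comes from one-vs-rest pixel confusion counts, as fractions;
zero-denominator cases are missing.  F1 equals DSC/100 and recall equals
sensitivity by definition; both identities, and the Dice-Jaccard relation
d = 2j/(1+j), are pinned against brute-force set-arithmetic and
pairwise-distance oracles.

## Morphometry and BMI association

Per subject, the five analysis slices are those with the largest
min(left, right) masseter area (ties to the lower index).  The "single
slice" area of a tissue is its pixel count times the in-plane pixel area on
the **median** of the five selected slices (the rule had to be fixed
somewhere; the median slice is the profile peak); the volume sums the five
slice areas times the slice increment.  Units: cm^2 / cm^3; raw pixel
counts are recoverable from the spacing.

For each tissue x measure (10 models), ordinary least squares regresses the
measure on BMI, age and sex (male = 1); the BMI coefficient, its 95% CI and
p-value are reported, evaluated at the 5% level with no multiple-testing
correction.  The orientation (measure as outcome) follows the scatter-plot
convention of size-versus-BMI validation; a flag swaps the roles.  A
constant outcome yields slope 0 and p = 1 by convention.  Quantification can
run on ground-truth labels or on any model's predictions.

On default cohorts this stage recovers the injected structure: at n = 500
the BMI-slope CI covers `beta_t x analytic_base_area_t` for every
injected-effect tissue, and over 200 replicate 53-subject cohorts the
rejection rate is 1.0 for the four injected tissues and ~0.04 for the null
right masseter (audited at 0.041 over 1000 replicates with a fast
label-free replica).

## Problem sizes in the test suite

The suite runs at deliberately scaled-down sizes chosen once: metric oracles
on 200 random 16x16 mask pairs; the cross-validation property on 20
subjects at 128x128, k = 3, 15 epochs; slope recovery on one 500-subject
label-only cohort; power/size on 200 replicate 53-subject label-only
cohorts.  Label-only generation (no intensity synthesis) makes the
replicate studies cheap.

## Known limitations

* The phantom's left/right distinction is positional only; a network could
  in principle exploit absolute position more than a real cohort allows.
* Stored-parameter accounting is a convention; frameworks that report
  "trainable" counts exclude normalization running statistics.
* Variant hyperparameters (attention gate widths, inception branch widths,
  dense growth) are calibration choices constrained by the count ordering,
  not canonical definitions from the variant literature.
* The engine is CPU-only and single-threaded beyond BLAS; it is sized for
  the desk-scale experiments above, not for 200-epoch full-scale training.
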
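# Methods

## Pipeline

Quantitative Tc-99m DTPA kidney SPECT/CT uses the CT twice: its attenuation
map (µ-map, cm⁻¹) corrects photon attenuation, and its anatomy is the canvas
on which the kidneys are segmented. This package removes the CT from both
roles:

1. **µ-map generation** — a 3D U-Net maps the two emission windows
   (primary photopeak and a lower scatter window, both log-maximum
   normalized, the scatter window Butterworth-filtered) to a synthetic µ-map.
2. **Kidney segmentation** — a second 3D U-Net maps the normalized µ-map to
   per-voxel class probabilities over {background, right kidney, left
   kidney}.
3. **Quantification** — the segmented masks applied to the quantitative
   (attenuation/scatter/resolution-corrected) SPECT in MBq/mL give each
   kidney's percent injected dose, converted linearly to GFR:
   `GFR (mL/min) = 9.1462 × %ID + 23.0653`, applied per present kidney and
   summed for the total. The alternative (one conversion of the summed %ID)
   is a config switch; the per-kidney default reproduces additive per-kidney
   reporting. Decay between injection and the 2–3 min acquisition is
   neglected: with a 6.01 h half-life the correction is below 0.6 %.
4. **Dosimetry bookkeeping** — total effective dose of SPECT/CT is the SPECT
   component (1.813 mSv at 370 MBq) plus DLP × 15 µSv/mGy-cm for the CT;
   the CT-free reduction is the CT share of that total. Percentages are
   reported to 1 decimal, doses to 3, matching clinical reporting precision.

## Digital phantom

Clinical SPECT/CT volumes cannot ship with the package, so a seeded torso
phantom supplies fully ground-truthed cases. The body is an elliptical
soft-tissue cylinder (µ = 0.15 cm⁻¹ at 140 keV) with partial lung bases
(0.04), a posterior spine column (0.25), and two bean-shaped kidneys — two
overlapping ellipsoidal lobes minus a medial hilum notch, so the boundary is
non-trivial. Kidney parenchyma is set slightly denser than generic soft
tissue (0.162) and is wrapped in a perirenal fat shell (0.135): this is the
contrast a CT-derived µ-map actually exhibits at the renal boundary and is
what makes the organ segmentable from attenuation alone. A calcified stone
uses 0.45, below the 0.5 ceiling used by the windowing normalization. All
tissue values are configuration (`TissueTable`), not constants, and the map
is lightly smoothed (σ = 0.6 voxel), so generated values lie in the table's
convex blends within [0, 0.5].

Case categories mirror a renal SPECT/CT referral population — normal
(donor), renal tumor (cold intrarenal nodule), urinary stone (dense cold
calculus), post partial nephrectomy (truncated pole), post total nephrectomy
(absent kidney) — drawn by default in the proportions 10 : 307 : 151 : 516 : 8
with per-category right/left/bilateral side frequencies from the same
population table. Activity is uniform over functioning parenchyma (each
kidney's uptake fraction drawn from 2.5–5 % of the injected activity, the
normal single-kidney DTPA uptake at 2–3 min) plus a circulating background
fraction (default 25 %) spread over non-renal soft tissue. The ground-truth
%ID per kidney is recorded from the activity map before degradation and is
exact by construction.

**Degradation model.** The clinical images come from vendor OSEM
reconstruction of sinograms; no sinograms exist for the phantom, so
post-reconstruction images are simulated directly: per-voxel depth
attenuation `exp(−∫µ dl)` along a single fixed anterior axis (a deliberate
one-projection simplification), Gaussian system PSF (default 12 mm FWHM),
scaling to expected counts (`counts_scale`, default 2000 counts per MBq/mL
per voxel) and Poisson sampling. The scatter window is a wider-blurred
(×1.8), down-weighted (×0.35) copy; the quantitative volume is the blurred
activity with calibrated Poisson noise, i.e. an idealized fully corrected
image in MBq/mL. This preserves the statistical features the networks must
cope with — attenuation-dependent intensity loss, finite resolution,
counting noise — but it is not projection-domain physics: no
collimator-detector response modelling, no energy-resolved scatter, no
reconstruction artifacts. Passing tests therefore demonstrate that the
pipeline's machinery is correct and learnable, not that clinical-grade
accuracy would be reached on patient data.

Two grid profiles are used. The clinical profile is 64×128×128 at 3.45 mm
isotropic voxels (training crop 64×64×96). The small CPU profile
(`PhantomSpec.desk()`) is 32×48×48 at 6.9 mm — doubling the voxel keeps the
field of view torso-sized while dividing the voxel count by ~16.

## Preprocessing

* **Maximum normalization**: `v / max(v)`.
* **Logarithmic maximum normalization** (count data): `log(1+v) / log(1+max v)`,
  mapping counts to [0, 1] while compressing the hot kidneys.
* **Windowing-maximum normalization** (µ-maps): clip to [0, w] (w ∈ {0.3,
  0.4, 0.5}; default 0.5), then divide by the observed post-clip maximum, so
  the output always reaches 1 even when no voxel reaches the ceiling.
* **Butterworth low-pass** (scatter-window denoising): multiplication in the
  3D radial frequency domain by `H(f) = 1/√(1 + (f/fc)^(2n))` with order
  n = 10 and fc = 0.48 cycles/cm. The magnitude form gives gain exactly 1 at
  DC and 1/√2 at the cutoff — documented so tests are unambiguous. The
  filter is applied in 3D (not per-slice) and requires isotropic voxels.
* **Training crop** to 64×64×96, centered by default with a configurable
  offset; the inverse zero-padding restores predictions to the full grid. A
  crop that discards kidney-labelled voxels raises a `KidneyCropWarning`.
* **Label closing**: per-class binary morphological closing with a 3×3×3
  cube, one iteration. Original voxels are never reassigned — closing only
  fills background voxels, with the right kidney claiming contested fill —
  so per-class counts never decrease and the operation is idempotent.

## Networks

Both networks are 3D U-Nets: channel width doubles per level from
`initial_neurons`, factor-2 average pooling down, nearest-neighbor
upsampling and skip concatenation up, two conv3–instance-norm–ReLU stages
per block. The residual variant adds an identity shortcut per block (1×1×1
projection on channel change). The attention variant gates each skip
connection with an additive attention coefficient: skip and upsampled
decoder signals are projected to an intermediate width, summed, rectified
and squashed to a per-voxel coefficient in (0, 1); optionally the spatial
gradient magnitude of the skip tensor joins the sum, biasing the gate toward
organ boundaries. The segmenter ends in a per-voxel softmax; the generator
ends in a softplus so the µ-map is non-negative. Argmax ties break toward
the lowest class index (background) — deterministic and conservative.

Because no deep-learning framework is assumed, the networks run on a compact
reverse-mode autodiff engine over numpy (`ctfree_gfr.nn`): convolution is
decomposed into one channels-last transpose, 27 BLAS matmuls (one per kernel
offset) and shifted accumulations, with the backward pass recomputing rather
than caching intermediate matrices to bound memory. Gradients are verified
against finite differences and convolution against an independent
`scipy.ndimage` oracle in the test suite. Batch normalization and transposed
convolution are accepted in the config vocabulary but not implemented
(instance norm and nearest-neighbor interpolation are the variants the
method uses); requesting them raises `NotImplementedError`.

**Training protocol.** Adam at learning rate 10⁻³ with per-epoch exponential
decay 0.96 (the decay granularity is an interpretation; per-step decay is
the other reading), batch 8, 100 epochs at clinical scale; early stopping on
validation loss with patience 10, active from the first epoch. Datasets
split 8:1:1 into train/validation/test. Flip augmentation acts on the x
(left-right) and z (axial) axes; an x flip mirrors anatomy, so 3-class
segmentation targets swap the right/left labels (2-class and regression
targets flip unchanged). Segmentation trains with categorical cross-entropy
or the generalized Dice loss; µ-map regression trains with voxel-wise MAE
(default) or MSE.

The small CPU profile used throughout the test suite is: 8 initial neurons,
depth 2, grid 32×48×48, batch 2, initial rate 3×10⁻³, 12 epochs — chosen so
both networks converge in minutes on a single core while exercising exactly
the same code paths as the clinical profile (64 neurons, depth 4, 100
epochs), which remains available via `NetworkConfig.paper_scale()`.

## Losses and metrics

The cross-entropy loss is the printed per-class form averaged over the n
classes and over voxels:

    CCE = −(1/n) · mean_voxels Σᵢ [ yᵢ log ŷᵢ + (1−yᵢ) log(1−ŷᵢ) ]

i.e. each class contributes a binary cross-entropy term (for one-hot targets
and a 3-class uniform prediction this gives (ln 3 + 2 ln 3/2)/3 ≈ 0.637 per
voxel, not ln 3). Probabilities are clipped to [10⁻⁷, 1−10⁻⁷].

The generalized Dice loss is

    GDSC = 1 − 2 Σᵢ wᵢ[yᵢŷᵢ] / (Σᵢ wᵢ[yᵢ] + Σᵢ wᵢ[ŷᵢ])

with [·] a voxel sum and weights wᵢ = 1/((Σ yᵢ)² + ε), the
inverse-squared-volume rule that rebalances the small kidney classes against
the vast background; ε = 10⁻⁶ keeps weights finite for absent classes. When
every weighted class is empty in both target and prediction the loss is
defined as 0. Both losses are checked against literal per-voxel loops, and
their training-time (autodiff) counterparts against the numpy versions.

Segmentation metrics: DSC per class with "total" defined as the DSC of the
union of both kidney classes (left/right are also reported separately, which
hedges the alternative average-of-sides reading); empty-vs-empty is defined
as 1 (perfect agreement on absence, the post-total-nephrectomy case) and
empty-vs-nonempty as 0. Volume difference is ground truth − prediction in
mL, so negative VD means over-segmentation. µ-map agreement is R², MSE and
%NMAE over a mask defaulting to the body contour of the reference map;
the %NMAE normalizer is the dynamic range of the reference within the mask,
isolated behind one function so a different normalizer (e.g. the reference
mean) is a one-line change.

## Validation strategy and limitations

The acceptance suite validates (a) exact self-contained arithmetic
(dosimetry bounds, the GFR line, loss formulas against brute-force loops,
filter transfer gains), (b) exact activity conservation: a background-free
phantom quantified with its true masks recovers the recorded %ID to float
precision and hence GFR exactly, and (c) parameter recovery at small scale:
trained on 40 phantom cases, the segmenter reaches mean total DSC ≥ 0.7 and
the generator body-masked R² ≥ 0.9 on 10 held-out cases (the runs in this
repository reach ≈0.91 and ≈0.93 respectively).

Known limitations: single-axis attenuation and Gaussian-blur degradation
instead of projection-domain reconstruction; stereotyped torso geometry
(position/size jitter only, no pose or organ-shape population variation); no
collimator response or energy-resolved scatter, so the realism of the
scatter-window surrogate is untested against real data; small-scale training
results do not predict clinical-scale accuracy. The DICOM clinical ingestion
path is out of scope — volumes are NIfTI-1 throughout.
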
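# Methods

This note records the modelling choices, defaults, and known limitations of
the package, stage by stage.

## Coordinate and data conventions

Volumes are 3-D scalar fields with a 4×4 voxel→world affine (RAS
millimetres, 0-based voxel indices). When a NIfTI header carries both a
qform and an sform and they disagree, the qform is used and the conflict is
logged; this makes parsing deterministic. Label maps are integer-coded and
share a volume's grid; the tissue schema has 4 classes (background, WM, GM,
CSF) and the structural schema 23 (background + 22 structures). Label maps
are always resampled with nearest-neighbour interpolation, intensity
volumes trilinearly.

The "template" grid standing in for an atlas space is a bundled synthetic
96³, 1 mm isotropic grid centred on the world origin. Any user-supplied
template volume can replace it.

## Synthetic phantoms

The phantom generator is the package's data source and defines the
conditions under which everything is tested.

* **Geometry.** Nested ellipsoidal shells: an outer CSF layer (3 mm), a GM
  shell (4 mm) and a WM core, head semi-axes (30, 36, 28) mm by default.
  Twenty-two substructures (9 bilateral pairs — WM, cortical GM, lateral
  ventricle, cerebellar GM/WM, caudate, hippocampus, globus pallidus,
  putamen — plus 4 midline structures) are rendered as pairwise-disjoint
  ellipsoids, each carrying a structural code and a tissue class. Overlap
  or placement outside the head is an error, never a silent overwrite.
* **Voxelisation.** Substructure masks use a 4³ subvoxel majority rule,
  which keeps voxel counts within a few percent of the analytic
  4/3·π·abc volume at 1 mm (the centre-point rule overshoots small
  ellipsoids systematically). The residual discrepancy is bounded by the
  surface-to-volume ratio: the tests assert |count − V|/V ≤ ½·S·h/V per
  structure. Structures below ~100 voxels remain noisy at coarse grids —
  a real limitation of 1 mm volumetry, not just of the phantom.
* **Intensities.** Class means on an arbitrary scale (CSF 0.2, GM 0.55,
  WM 0.75; pediatric-like "inverted" mode: WM 0.40, GM 0.60), multiplied by
  a smooth bias field (exponential of a random order-≤2 polynomial, default
  amplitude ±10%, up to ±20%), plus Gaussian noise (sd 0.03 — about 5% of
  the intensity range, a mid-range SNR for T1 acquisitions).
* **Repeat scans** re-render the identical anatomy after a random rigid
  transform (defaults ±2 mm, ±2°) with fresh noise and bias, so true region
  volumes are equal by construction and measured differences are method
  variability only.
* **Cohorts** draw a per-subject global head scale (CV 3%) and independent
  per-structure volume factors (CV 5%); group B's affected structure is
  additionally scaled by a fixed factor. `scale_factor_for_cohens_d` solves
  the factor that produces a stated Cohen's d between group volume means,
  accounting for group B's proportionally smaller spread.
* **What the phantom does not emulate:** cortical folding, partial-volume
  mixtures, MRI physics (k-space sampling, Rician noise, motion/ghosting
  artefacts), and inter-subject anatomical variability beyond size scaling.
  Passing tests demonstrate the correctness and stability of the pipeline
  machinery under controlled conditions; they do not certify accuracy on
  clinical images.

## Preprocessing

Order is fixed: bias correction → registration + resampling → clipping →
normalisation.

* **Clipping** at the 1st/99th percentiles, computed over all voxels. No
  brain mask is applied at this step; the later normalisation is computed on
  banded percentiles and tolerates the background mass.
* **Robust z-scoring**: location m = median of voxels strictly above the
  10th percentile; scale s = SD of voxels in the (10th, 90th] percentile
  band. Both the strictness of the floor and the band variant
  ((p10, p90] vs [0, p90]) are config switches, since either reading is
  defensible; the default is the symmetric band. The map is invariant to
  positive affine intensity transforms. A constant band is an error.
* **Bias correction** (fallback implementation): a low-order (≤2)
  polynomial is fitted to log-intensities of a bright-tissue reference set —
  voxels inside the mask whose intensity lies in the 60th–95th percentile
  band, predominantly WM in a T1 image. Fitting on the full mask would
  absorb genuine anatomy (the radial CSF/GM/WM pattern is itself low-order);
  restricting to a nearly-uniform tissue attributes smooth variation to
  bias. The fitted field is divided out with the mean intensity inside the
  mask preserved. Non-positive intensities trigger a shift-and-warn policy
  (volume shifted positive for the log fit, shift removed afterwards). An
  external corrector (e.g. an N4 wrapper) can be slotted in via config and
  takes precedence.
* **Affine registration**: 12 parameters (translation, rotation,
  log-scales, shears). Translation and per-axis scale are initialised from
  intensity moments — deterministic, no random restarts — then refined by
  Powell maximisation of normalised cross-correlation on a two-level
  pyramid (×4, ×2 downsampling; an optional full-resolution polish is off
  by default for speed). NCC is appropriate because the data are
  mono-modal. On noise-free phantoms this recovers simulated translations
  to ≲0.1 mm and scale determinants to ≲1%; the determinant of the
  moving→template transform is the head-size scaling factor used by
  quantification (|det| — orientation flips must not negate volumes).

## Network geometry

The recurrence (two 3×3×3 valid convolutions per block: s → s−4; stride-2
downsampling: s → s/2, requiring s even; transposed-convolution upsampling:
s → 2s) fixes the admissible input sides: s ≡ 0 (mod 4), s ≥ 52. The
default 128 → 88; the margin between input and output footprint is always
20 voxels per side. `compute_output_size` raises naming the first failing
stage (e.g. side 50 reaches the odd size 19 at the second downsampling).

Properties exploited downstream:

* The output side is always a multiple of 4 (the product of the stride-2
  downsamplings), so tiling with stride equal to the output side keeps all
  tile origins on the stride-alignment grid, where the network is exactly
  shift-equivariant. Whole-volume inference pads the volume by the margin
  (reflection — the paper-silent choice that avoids intensity cliffs) plus
  whatever is needed to complete the last tile, stitches without blending,
  and crops. Custom tile origins must be multiples of the stride product;
  this is validated, because off-grid tiles would produce subtly different
  (seam-visible) outputs.
* The network is fully convolutional: weights trained at one patch side run
  unchanged at any admissible side (`with_patch_side`), which inference
  uses to cut the tile count.

Filter counts (8 at the top level, doubling per level), the upsampling
operator (2³ transposed convolution) and the two 1×1×1 head convolutions
are package choices where the source architecture is not fully specified;
all are config-exposed.

## Engine

The layers (valid 3³ conv, 2³ stride-2 conv, 2³ transposed conv, 1×1×1
conv, leaky ReLU), weight normalisation (W = g·V/‖V‖ per output channel,
He-initialised with g = ‖V‖), hand-derived backward passes and Adam are
implemented directly in numpy. Convolutions are evaluated as sums of
shifted-view channel contractions, keeping peak memory proportional to
activation size (im2col was measured slower here due to copy overhead).
Gradients are verified against central finite differences in the test
suite at tolerance consistent with float32 arithmetic.

## Losses

Soft Dice (1 − mean over classes of (2Σpg+ε)/(Σp+Σg+ε), ε = 1e-5) averaged
over **all** classes including background, plus weighted categorical
cross-entropy (mean over voxels of w·(−log p), probabilities clipped).
Per-task sums are combined with α₁ = 1 (tissue), α₂ = 10 (structural).
Dice counts are summed over the batch before the ratio (stabler for small
structures than per-sample averaging). CE class weights default to inverse
voxel frequency normalised to mean 1 (a cap at 10× the mean guards against
degenerate weight spikes when a schema contains extremely rare classes; for
the default phantom schemas the normalised weights stay below 2 and the cap
is inactive).

## Training

Subject-level split (validation = round(0.15·n), at least 1, never used for
weight updates), Adam at λ = 0.001 (constant — only the initial rate is
specified by the reference operating point), batch size 2, patches sampled
per volume per epoch with an optional structure-centred fraction (default
50%) so small structures appear in patches at all. Validation loss is
evaluated each epoch on a fixed per-subject patch set (8 patches/volume —
larger than the training draw, to reduce model-selection noise); the
best-validation parameters are retained. Early stopping: no relative
improvement above 1e-4 for 10 epochs. Optional augmentation: per
subject-epoch with probability 0.5, a GMM draw of magnitude m perturbs
component means by uniform shifts within ±m × (smallest inter-component
gap) and scales SDs within [1/(1+m), 1+m]; these bounds are a documented
re-parameterisation of the published augmentation's defaults, not a
byte-level reproduction.

Determinism: all sampling flows from the config seed (per-subject
validation seeds use CRC32 of the subject id, not Python's randomised
`hash`), so identical configs reproduce identical training logs.

## Desk-scale operating points

Tests and the demo run reduced geometries so the whole stack fits one CPU:
64³ phantoms, 52³ patches (12³ output), 8 base filters, 20 subjects,
20 epochs × 4 patches/volume. Under these conditions the trained model
reaches held-out tissue DSC well above 85 for WM/GM/CSF, and test-retest
tissue volume differences stay under 5% — but subcortical-structure DSC
remains far below the levels a full-scale model reaches; the structural
head needs orders of magnitude more training than a desk run provides.
Inference on the 150³ seam-freeness check uses the full default 128→88
geometry.

## Evaluation statistics

* **Dice** as a percentage; both-empty = 100, one-empty = 0 (continuity
  convention).
* **HD95**: 6-connectivity boundary voxels, centre-to-centre distances in
  mm (anisotropy-aware), symmetrised as max of the two directed 95th
  percentiles — matching the "maximal contour distance" reading; the
  directed sets are exposed so other symmetrisations can be formed. Meshes
  are not used; the voxel-boundary definition has an exact brute-force
  oracle.
* **Test-retest relative difference**: 100·|V₁−V₂|/denominator; default
  denominator is the within-pair mean, a supplied cross-method mean is used
  verbatim.
* **Wilcoxon signed-rank** (scipy behind the interface): exact enumeration
  for n ≤ 25 without ties, tie/continuity-corrected normal approximation
  otherwise; flags at 0.01 and 0.001.
* **AUC** via the Mann–Whitney identity (ties ½); **Youden** operating
  point by exhaustive scan over observed cut-points, ties broken toward
  higher specificity; **DeLong** paired test from placement values, with
  degenerate variance (identical placements) reported as p = 1 plus a flag.
  Calibration of both tests is verified by simulation in the suite.

## Known limitations

* The bias-correction fallback assumes a bright, nearly-uniform reference
  tissue; heavy pathology violating that assumption needs a real N4 via the
  external hook.
* Registration is deterministic but local; it assumes the moving head is
  within the template's capture range (true for phantoms; arbitrary
  clinical orientations would need an initialisation search).
* The GMM augmentation operates on global intensity components and cannot
  emulate spatially varying contrast changes.
* Structural segmentation quality at desk scale is limited (see above);
  the structural head's machinery is validated by geometry, loss and
  gradient checks rather than by reaching clinical-grade DSC.
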
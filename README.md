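# neuroquant

A brain MRI quantification pipeline for T1-weighted head volumes:
preprocessing, simultaneous tissue and structure segmentation with a
dual-head patch-based 3-D convolutional network, volumetry with head-size
normalisation, and the statistical machinery used to validate such pipelines
(overlap and surface-distance metrics, test-retest reproducibility,
ROC/Youden/DeLong diagnostics). Everything runs at desk scale on synthetic
head phantoms with analytic ground truth, so the full pipeline — including
network training — is testable on one CPU without any external imaging data.

It is aimed at researchers and engineers who build or evaluate volumetric
neuroimaging methods and want a transparent, fully inspectable reference
implementation of each stage.

## The model

The segmentation core is a single-trunk, two-head 3-D U-Net operating on
cubic patches with **valid convolutions only** (no padding anywhere):

- 3×3×3 valid convolutions, two per resolution block, so each block maps a
  spatial side s → s−4;
- two stride-2 **strided-convolution** downsamplings (s → s/2) instead of
  max pooling, transposed-convolution upsampling (s → 2s), skip connections
  center-cropped to the decoder size;
- **weight normalisation** in place of batch normalisation, leaky ReLU with
  slope 0.20, He initialisation;
- two segmentation heads (1×1×1 convolutions + per-voxel softmax): a
  4-class tissue head (background, WM, GM, CSF) and a 23-class structural
  head (background + 22 structures). The tasks are not mutually exclusive
  and are predicted independently.

With the default 128³ input patch the valid-convolution recurrence

```
128 →(conv×2) 124 →(↓2) 62 →(conv×2) 58 →(↓2) 29 →(conv×2) 25
    →(↑2) 50 →(conv×2) 46 →(↑2) 92 →(conv×2) 88
```

yields an 88³ output patch. Because every output voxel is a pure function of
its receptive field, whole-volume inference tiles the volume with stride 88
and stitches **exactly seam-free** (tilings at any stride-aligned offsets
agree voxel for voxel).

Training minimises the multi-task loss

```
L_total = α₁ (L_wCE⁽¹⁾ + L_Dice⁽¹⁾) + α₂ (L_wCE⁽²⁾ + L_Dice⁽²⁾),   α₁ = 1, α₂ = 10
```

(soft Dice plus weighted categorical cross-entropy per head) with Adam at
λ = 0.001, a 15% subject-level validation split, early stopping on the
validation loss, and GMM-based intensity augmentation that remaps tissue
component intensities while leaving geometry untouched.

Preprocessing follows the order: bias-field correction (polynomial fallback,
pluggable N4-style interface) → affine registration to a template grid
(moments initialisation + NCC Powell refinement) → clipping at the 1st/99th
percentiles → robust z-scoring (median of voxels above the 10th percentile,
SD within the (10th, 90th] band). The determinant of the registration
affine is retained and multiplies raw volumes for head-size normalisation.

The network engine (forward and backward passes, Adam) is implemented
directly in numpy; there is no deep-learning framework dependency.

## Worked example

```bash
neuroquant demo --out demo_run --seed 1
```

generates twenty 64³ phantoms, trains a small dual-head model (52³ patches,
8 base filters, 20 epochs — roughly 12 minutes on one CPU), segments three
held-out phantoms and writes one volumetric report each. The report
`demo_run/test000_report.csv` begins:

```
subject,task,region,code,voxels,raw_mL,normalized_mL,det
test000,tissue,background,0,224560,224.56,224.56,1.0
test000,tissue,WM,1,17627,17.627,17.627,1.0
test000,tissue,GM,2,9967,9.967,9.967,1.0
test000,tissue,CSF,3,9990,9.99,9.99,1.0
test000,structural,background,0,246052,246.052,246.052,1.0
...
```

`voxels` is the voxel count of the predicted region, `raw_mL` the volume at
the native 1 mm isotropic grid (1 mL = 1000 mm³), and `normalized_mL` the
head-size-normalised volume (raw × |det| of the subject→template affine —
here the identity, det = 1). The tissue rows partition the grid
(224.56 + 17.627 + 9.967 + 9.99 = 262.144 mL = 64³ voxels) and track the
phantom's ground truth (224.568 / 16.042 / 11.5 / 10.034 mL): CSF and
background within a fraction of a percent, WM/GM within ~10% at this desk
scale. Subcortical structures in the structural-task rows remain rough
after a short CPU training run — see `docs/methods.md` for what the
desk-scale operating point does and does not demonstrate.

Individual stages are exposed as `neuroquant phantom|preprocess|train|
segment|quantify|evaluate` — see `neuroquant --help`.

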
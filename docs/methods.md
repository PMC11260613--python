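# Methods

## Problem setting

Locally advanced cervical cancer is treated with external-beam radiotherapy
(EBRT, whole pelvis, typically 45–50 Gy in 25 fractions) followed by a
high-dose-rate brachytherapy boost (BT, several ~6 Gy fractions through a
tandem/ovoid applicator). The two courses are planned independently, so the
clinically decisive *accumulated* dose to the bladder and rectum is only
known after the fact. This package implements the computational pipeline
around that problem: radiobiological dose accumulation, a voxel-wise
predictor of the accumulated dose from planning anatomy, plan scoring
(DVH metrics, NTCP), and the isodose-overlap avoidance contour used to
redesign the EBRT plan before treatment starts.

## Dose accumulation model

Doses are compared on the equivalent-dose-in-2-Gy-fractions scale of the
linear-quadratic model,

    EQD2 = D * (d + α/β) / (2 + α/β),    d = D / n_fractions (per voxel),

with α/β = 10 Gy for tumor and 3 Gy for late-responding normal tissue.
Conversion is voxel-wise: each voxel's fraction dose is its total divided
by the fraction count, so heterogeneous fields convert correctly. A BT
course of n identical fractions is the per-fraction EQD2 times n (EQD2 is
additive over identical fractions); this matches the clinical surrogate of
magnifying a single CT-planned BT fraction. The BT dose is mapped onto the
EBRT grid either by trilinear resampling or through an externally supplied
pull-back deformation field (displacement vectors in mm on the reference
grid); deformable registration itself is out of scope, as it is the
province of dedicated registration software. Accumulation is a voxel-wise
sum on a shared grid and frame of reference.

Numerical conventions: voxel centers, 0-based indices, physical position =
origin + index·spacing, mm everywhere; trilinear interpolation with zero
fill outside the source extent; dose grids reject negative or non-finite
values at construction rather than clamping, so format errors surface
early. The EQD2 factor is computed before multiplying so that a course at
exactly 2 Gy/fraction is a bit-exact fixed point.

## Anatomical input channels

The dose predictor consumes three channels per axial slice:

* **CT**, windowed to [−1000, 1000] HU and scaled to [0, 1].
* **Structure label map.** Each target/OAR gets a base label; overlapping
  voxels hold the *sum* of their labels, body-only voxels 1, exterior 0.
  Default base labels are powers of two starting at 2, which makes every
  overlap sum uniquely decodable for arbitrary overlaps; custom tables are
  validated against every overlap combination actually present.
* **Distance-to-target (DTT) map**: for each body voxel outside the PTV,
  the Euclidean distance in mm (anisotropic spacing respected, exact
  distance transform) to the nearest PTV voxel; 0 inside the PTV and
  outside the body. "Distance to the PTV surface" is operationalized as
  distance to the nearest PTV voxel center, so a face-adjacent voxel is one
  spacing away — stated explicitly because the half-voxel convention is
  ambiguous.

CT-number override (setting each listed structure to a fixed intensity,
later entries winning on overlaps) is provided as the standard
preprocessing step for intensity-consistent registration of applicator and
packing regions.

## Dose predictor

A slice-wise residual encoder–decoder maps the 3-channel anatomy to the
normalized accumulated dose. Two presets share one I/O contract:

* `reduced` — widths (8, 16), one 2× pooling level, ~9.6 k parameters;
  trainable on one CPU in minutes and used throughout the tests.
* `full` — widths (32, 64, 128), two pooling levels; the shape intended
  for real cohorts at clinical resolution.

Both are fully convolutional (any in-plane size divisible by the
downsampling factor), with long skip connections adding encoder features
back at each decoder level and a 1×1 output head. The engine is written in
numpy: same-size convolutions as a single GEMM over an im2col matrix in
float32, explicit backpropagation (verified against finite differences in
the test suite), and Adam with a step learning-rate decay. Loss is mean
squared error on normalized dose. Dose is normalized by the summed
prescription EQD2, labels by the largest label value, DTT by the cohort
maximum. Training applies seeded left-right mirror flips (pelvic anatomy
and the analytic dose are statistically symmetric about the sagittal
plane), which matters on cohorts of ten patients, and can centre-crop
training slices to the body region (the network is fully convolutional,
so inference still runs on full slices); cropping away trivial air both
speeds training and stops the loss being diluted by zero-dose voxels.
Training is patient-level k-fold (default 5): folds are disjoint, cover
all patients, and never split a patient's slices across folds. All
stochasticity — fold assignment, weight initialisation, batch shuffling —
derives from the single seed in `TrainingConfig`, so a rerun reproduces the
loss trajectory exactly. Inference denormalizes to Gy and clamps negatives
to zero.

Default optimisation settings (epochs 45, lr 5e-3 halved every 15 epochs,
batch 8) are sized for the reduced preset on the synthetic cohort below;
the end-to-end test trains 60 epochs with a 64×48 body crop, which on this
cohort reaches mean held-out whole-body MAE ≈ 0.95 Gy, below the
leave-fold-out cohort-mean-dose baseline (≈ 1.03 Gy) and an order of
magnitude below 10% of the summed prescription.

## Evaluation metrics

* **MAE** — mean absolute voxel dose difference inside a structure.
* **DSC of isodose volumes** — dice 2|A∩B|/(|A|+|B|) of thresholded dose
  masks, by default at 10, 20, …, 160 Gy (16 levels). Thresholds are
  inclusive; two empty masks score 1 (agreement of absence), which matters
  at high levels that can vanish on both grids.
* **DVH** — cumulative, relative, inclusive thresholds, default bin width
  0.1 Gy; absolute volume from voxel count × voxel volume.
* **V_x** — percent of structure volume at or above x Gy.
* **D_2cc** — minimum dose to the hottest 2 cm³, by discrete voxel sorting
  without sub-voxel interpolation: with phantom voxels of 0.08 cm³ the
  discretisation error is below the DVH bin width.

## NTCP model

The Lyman–Kutcher–Burman model with gEUD volume reduction:

    gEUD = ( (1/N) Σ d_i^(1/n) )^n ,   NTCP = Φ( (gEUD − D50) / (m · D50) )

with the literature parameter sets rectum D50 = 80 Gy, m = 0.15, n = 0.12
and bladder D50 = 80 Gy, m = 0.11, n = 0.50. The power mean is computed in
units of the in-mask maximum for numerical safety at small n (1/n up to
1000 is tested). Φ is the error-function normal CDF, accurate to ~1e-12;
under uniform dose gEUD equals the dose independent of n, so root-finding
the 50% dose recovers D50 exactly — the package's self-consistency anchor.
NTCP is evaluated on accumulated EQD2 grids, the only dose representation
the pipeline produces.

Paired plan comparisons (conventional vs redesigned) use the two-sided
Wilcoxon signed-rank test at α = 0.05: exact null distribution up to 25
informative pairs, tie-corrected normal approximation above; identical
pairs give p = 1 rather than an error.

## Synthetic pelvic cohort

No patient data ship with the package; the phantom generator provides a
seeded stand-in cohort with a known ground truth. Each case is an
elliptical body (115 × 95 mm semi-axes) with a bony rim, a central
uterus+vagina (U+V) ellipsoid, an anterior bladder and a posterior rectum
*packed against* the jittered U+V surface with a 1–3 mm gap — pelvic organs
sit against the cervix, and this keeps the BT hotspot abutting both OARs in
every realisation. The PTV is the U+V dilated by 18 mm, wide enough that
the abutting OAR walls lie inside the prescription plateau, as they do in a
whole-pelvis target that deliberately includes parts of bladder and rectum.
Default grid: 64×64×24 voxels at (4, 4, 5) mm. Per-patient jitter: ±4 mm
centers, ±12% radii, seeded; a cohort is generated from per-patient seeds
derived from one root seed and is byte-reproducible.

The ground-truth accumulated dose is analytic, already in EQD2:

* **EBRT term** — prescription EQD2 (44.25 Gy for 45 Gy/25 fx at α/β 10)
  times a Gaussian-smoothed PTV indicator (penumbra σ = 6 mm).
* **BT term** — the 4-fraction course EQD2 (32 Gy at the reference point)
  times an inverse-square kernel summed over 7 dwell positions spaced 10 mm
  along the applicator line through the U+V center, normalised to 1 at a
  20 mm lateral reference radius and capped at 160 Gy. This is deliberately
  *not* TG-43 source dosimetry: it exists to produce the steep central
  gradients and 10–160 Gy dynamic range the pipeline must handle, nothing
  more.

CT is tissue-class intensities (air −1000, soft tissue 40, bone 700,
bladder 15, rectum −80, U+V 45 HU) plus 20 HU Gaussian noise. A small
smooth random deformation field (≤3 mm, 12 mm correlation length) ships
with each case as a stand-in for registration output.

What the phantom does **not** emulate: realistic CT texture, applicator and
packing artifacts, organ filling variation between courses, nodal boost
volumes, true VMAT/TG-43 physics, and inter-observer contouring noise.
Passing tests therefore demonstrate that the pipeline's machinery is
correct and that the predictor can learn a deterministic anatomy→dose map
at this scale — not that clinical accuracy figures transfer.

## Redesign surrogate

`simulate_redesign` models the effect of replanning EBRT against the
avoidance contour (the predicted 70 Gy isodose ∩ bladder/rectum): the EBRT
component is scaled by 1 − reduction·s, where s is 1 inside the contour and
ramps linearly to 0 over 30 mm outside it — a replanned arc lowers dose in
a broad neighbourhood of a hotspot, not just inside a contour. Dose never
increases anywhere, is untouched beyond the ramp, and the BT component is
unchanged. On the default cohort a 30% reduction strictly lowers V50, V60,
D2cc and NTCP for both OARs on every phantom.

## Problem sizes used in the shipped tests

Unit tests run on ≤32³ grids against exhaustive oracles. The end-to-end
study uses 10 phantoms at 64×64×24, 5-fold cross-validation of the reduced
preset for 60 epochs; the redesign statistics use the same 10 phantoms.
These sizes were chosen so the whole suite runs on a single CPU in well
under half an hour while still exercising every pipeline stage at full
fidelity.

## Known limitations

* The predictor presets are *shape-compatible* stand-ins for a clinical
  ResNet-scale model, not a reproduction of any published architecture;
  clinical MAE/DSC values require a real cohort and full-scale training.
* D_2cc has no sub-voxel interpolation; on coarse grids it is biased by up
  to one voxel's worth of volume.
* Voxel-level α/β assignment at structure boundaries is unresolved in the
  underlying accumulation workflow; the package converts each course with
  a single scheme at a time and leaves per-structure masking to the caller.
* NIfTI I/O supports axis-aligned (diagonal-affine) volumes only.
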
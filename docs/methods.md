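# Methods

This note documents the models, conventions and numerical choices behind
`neurorads`, and what its synthetic validation does and does not show.

## Data model and geometry

Volumes are rank-3 scalar grids with spacing (mm), origin (physical
position of the centre of voxel (0,0,0), mm) and an orthonormal direction
matrix. On load every volume is reoriented to canonical RAS; this makes
left/right logic (laterality, hemisphere masks) well defined without
per-dataset bookkeeping. Annotation masks must match their parent scan's
geometry — shape exactly, spacing/origin and direction cosines within
1e-3 — mirroring how clinical tools refuse mislinked annotations rather
than silently resampling them.

## Preprocessing

The chain is resample → clip → normalize → (skull-strip):

- **Isotropic resampling** to `target_spacing_mm` (default **0.75 mm**),
  linear for images, nearest for labels. Output shape per axis is
  `round(shape·spacing/t)`; resampling aligns cell edges so physical
  extent is preserved up to the sub-voxel shape rounding. Label
  resampling can never invent labels (nearest neighbour).
- **Intensity clipping** replaces values above the
  `1 − clip_upper_fraction` quantile (default **0.0005**, i.e. the 0.05 %
  highest values) with that quantile. The quantile is the
  linear-interpolation quantile of the flattened volume; a flag restricts
  the statistics to brain-masked voxels, but the default uses the whole
  volume since enhancing lesions are bright enough to dominate either way.
- **Normalization** maps min→0, max→1 affinely; a constant volume maps to
  all-zeros (the only consistent degenerate choice once background = low).
- **Skull-stripping** zeroes voxels outside the brain mask (background 0,
  consistent with the normalized range). It is optional because some
  tumor types — extra-axial meningiomas in particular — extend beyond the
  brain mask.

## Inference

Tumor predictors run **patch-wise** (default patch 160³ voxels). The
tiling places the minimal number of patches per axis achieving coverage
at the requested overlap fraction (default 0), evenly spaced with the
last patch flush against the far edge; volumes smaller than the patch are
symmetrically zero-padded. Overlapping predictions are fused by **mean**
(default) or max. The defining correctness property — checked exhaustively
in the tests — is that any *voxel-local* predictor gives a bit-identical
result patch-wise and whole-volume, for every tiling and both fusion
rules. Brain extraction instead runs **single-shot on a downsampled
copy** (default working shape 128³) and upsamples the probability map
back to the native grid before thresholding; down/upsampling replicates
edge samples so a constant probability field stays constant at volume
borders. Probability maps are binarized at 0.5 by default.

Predictors are pluggable objects (`patch → same-shape probabilities in
[0,1]`); the package ships a voxel-local threshold predictor for testing
and leaves runtime wrappers (e.g. ONNX) to the caller. Contract
violations (wrong shape, out-of-range values) raise instead of being
clipped silently — a mis-wired model should fail loudly.

## Atlas space and registration

Tumor features are computed in a reference space (clinically, the
symmetric MNI ICBM2009a template; in tests, a toy bundle on a phantom
grid). Deformable registration is intentionally **not** reimplemented:
the `SpatialTransform` interface (3×3 matrix + translation acting on
physical points) accepts parameters from any external backend, and the
built-in `centered_affine` method matches intensity centres of mass and
per-axis second moments — an axis-aligned scale plus translation. On
phantoms it recovers synthetic translations to ≪ one voxel and isotropic
scales to ≪ 2 %; on real heads it is a coarse initialization, not a SyN
substitute. Profiles are computed after warping the tumor into reference
space (nearest neighbour), not by warping the atlas into patient space,
so all patients are profiled against the identical parcellation grid.

Overlap profiles report, per named structure, the percentage of tumor
volume inside it, plus an `unlabeled` bucket for tumor voxels outside all
labels; buckets always sum to 100. Serialized profiles are rounded to two
decimals.

## Standardized reports

Preoperative: volume in **both** patient and reference space (affine
registration changes volume, so neither alone is sufficient), laterality
(percentages over tumor voxels carrying a hemisphere label; midline
crossing when both sides exceed 5 %; ties dominant-left by convention),
multifocality (26-connected components ≥ 0.1 ml by default; smaller
specks count toward total volume but are not reported as foci; the
distance from the main focus to its nearest satellite is reported as an
informational field only), and one location profile per parcellation.

Postoperative: preop and postop volumes each on their native grid,
`EOR = 100·(V_pre − V_post)/V_pre` (negative values flag growth), and a
residual-volume class. The class bands default to a RANO-resect-style
scheme — complete (0 ml), near-total (≤ 1 ml), subtotal (≤ 5 ml), partial
(> 5 ml) — and are entirely configuration-driven, since published
guidelines evolve.

Reports serialize to JSON (canonical nested form, sorted keys), flattened
key/value CSV, and human-readable text. Provenance carries input file
identifiers, a configuration hash and the package version — but no wall
clock, so a rerun with identical inputs is byte-identical.

## Evaluation

Three tiers, with conventions chosen to be explicit where the literature
is often silent:

- **Voxel-wise**: Dice (%) per patient; both-empty pairs score 100 (the
  convention needed for tumor-free postoperative scans), configurable.
- **Patient-wise**: detection = Dice strictly above a threshold (default
  0, i.e. any overlap); recall over tumor patients, precision over
  positive predictions, F1 harmonic mean; Dice-TP averages Dice over
  detected patients only. Undefined ratios (no tumor patients, no
  positive predictions) are reported as `None` and flagged — never as 0.
- **Object-wise**: connected foci (26-connectivity default); a
  ground-truth focus is recalled if any predicted component overlaps it
  by ≥ 1 voxel, a predicted component is a precision hit if it overlaps
  any ground-truth focus; an optional per-pair Dice threshold tightens
  the match rule.

**Stratification** splits the cohort at a ground-truth volume cut-off
(strictly below = small): 2 ml by default, 5 ml for cohorts of diffuse
lower-grade gliomas, whose average volumes are larger.

**Fold pooling** combines per-fold `{n, mean, sd}` with the n-weighted
mean and the variance `[Σ(nᵢ−1)sᵢ² + Σnᵢ(mᵢ−M)²]/(N−1)`. This estimator
was chosen precisely because it makes pooling an *exact inverse* of
partitioning: pooled mean/sd equal those of the concatenated cohort for
any partition, including all-singleton folds — a property the tests
verify directly.

## Synthetic study conditions

The generators exist to make every downstream number checkable against a
closed form, not to look like MRI:

- **Head phantom**: darker head ellipsoid, brighter brain ellipsoid
  (plateaus 0.2 / 0.55), optional Gaussian noise (default σ 0.01),
  exact analytic brain mask. Default grids are 40–64 voxels per axis at
  1 mm — a deliberately desk-scale stand-in for clinical scans, since the
  geometry/stitching/accounting logic under test is resolution-agnostic.
- **Tumors**: unions of enhancing ellipsoids (plateau 0.9) with
  closed-form volumes `4/3·π·abc`; placement guarantees containment in
  the brain via the normalized-coordinate bound ‖c/R‖ + max(rᵢ/Rᵢ) < 1.
- **Cohorts**: per patient, a preoperative timestamp (T0) with a main
  focus (radii ~3–8 mm, i.e. volumes straddling fractions of the 2 ml
  cut-off at this phantom scale), a satellite in ~30 % of patients
  (placed with a > 2-voxel gap so component labelling agrees with the
  manifest), and a postoperative timestamp (T1) with the main focus
  shrunk by 0.25–0.6 or removed entirely (~25 % complete resections).
  The manifest stores closed-form volumes, grid-predicate volumes
  (recomputed from the ellipsoid inequality over voxel centres, never
  read back from the written arrays), focus counts and the implied EOR.
- **Predictor**: the threshold predictor is voxel-local by construction,
  which is exactly what the stitching-equivalence property requires.

What passing these tests shows: the geometry, tiling/fusion, accounting,
reporting and evaluation machinery is correct to its stated tolerances.
What it does not show: segmentation accuracy on real MR contrast, noise,
bias fields or infiltrative margins — that depends entirely on the
plugged-in predictor — nor the adequacy of an affine transform for real
inter-subject registration.

## Degenerate inputs and tie-breaks

Empty tumor masks are errors for profiling/laterality/preop reports and
valid (EOR = 100 %) postoperatively; constant images cannot be registered
(zero spatial variance → registration error); non-invertible transforms
are rejected at construction; laterality of a tumor entirely outside both
hemisphere labels is reported 50/50 rather than failing; probability maps
outside [0,1] and predictors breaking their contract raise.

## Problem sizes

Tests and the acceptance script run phantoms of 32–72 voxels per axis
with patches of 12–64 voxels, 10–100 randomized replicates per property,
and 3-patient cohorts — sizes chosen so the full validation executes in
seconds on a single CPU while still exercising every code path, including
padding, multi-patch tiling, anisotropic grids and multi-timestamp
cohorts.
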
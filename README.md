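# neurorads

Preoperative and postoperative characterization of central-nervous-system
tumors from volumetric MR data: segmentation inference, standardized
reporting, and rigorous segmentation evaluation — as a library plus a small
CLI, fully testable end-to-end on synthetic phantoms.

## Who this is for

Research groups working on CNS tumor segmentation (glioblastoma, diffuse
lower-grade glioma, meningioma, metastasis) who need the *computational
plumbing around a segmentation model*: reproducible preprocessing, tiled 3D
inference for any voxel classifier, atlas-space tumor feature extraction,
extent-of-resection reports, and the lesion-aware evaluation metrics used
to validate such models. Trained network weights are deliberately out of
scope — any predictor satisfying a simple patch-in/probabilities-out
contract plugs in (an ONNX-runtime wrapper, or the bundled synthetic
threshold predictor).

## What it computes

**Preprocessing** (`neurorads.image_core`) — isotropic resampling (default
0.75 mm), optional skull-stripping with a brain mask, clipping of the
0.05 % highest intensities, min–max normalization to [0, 1].

**Inference** (`neurorads.inference`) — tumor models run patch-wise
(default 160³-voxel patches) with mean or max fusion of overlapping
predictions; brain extraction runs single-shot on a downsampled copy and
is upsampled back. The central correctness property: for any voxel-local
predictor, the stitched result is voxel-exact equal to a whole-volume pass.

**Atlas space** (`neurorads.atlas`) — patient-to-reference registration
(moment-matching affine built in; deformable backends plug in through the
same `SpatialTransform` interface), nearest-neighbour mask warping, and
region-overlap profiles: for each named structure `s` of a parcellation,

```
profile(s) = 100 · |tumor ∩ s| / |tumor|        (Σ over structures + unlabeled = 100)
```

**Reports** (`neurorads.reporting`) — tumor volume (ml) in patient and
reference space, laterality with midline-crossing, multifocality via
connected components above a minimum focus volume, one location profile
per parcellation; postoperatively the extent of resection

```
EOR = 100 · (V_pre − V_post) / V_pre   [%]
```

and a residual-volume resection class (complete / near-total ≤ 1 ml /
subtotal ≤ 5 ml / partial, configurable).

**Evaluation** (`neurorads.evaluation`) — three tiers: voxel-wise Dice,
patient-wise detection → cohort recall/precision/F1 and Dice-TP (mean Dice
over detected patients), and object-wise recall/precision/F1 over
connected foci; volume stratification (small vs non-small at 2 ml, or
5 ml for low-grade-glioma-style cohorts) and cross-validation fold pooling
that exactly reproduces concatenated-cohort statistics.

**Synthetic data** (`neurorads.synthetic`) — deterministic head phantoms,
union-of-ellipsoid tumors with closed-form volumes, toy atlases, and
multi-timestamp cohort trees with an analytic ground-truth manifest.

## Worked example

```python
from neurorads.synthetic import (PhantomSpec, TumorSpec, TumorFocus,
                                 make_head_phantom, make_tumor, make_toy_atlas)
from neurorads.reporting import assemble_preop_report

image, brain = make_head_phantom(PhantomSpec(shape=(48, 48, 48), seed=11, noise_sd=0.0))
spec = TumorSpec(foci=(TumorFocus(center_mm=(16.0, 24.0, 24.0), radii_mm=(5.0, 5.0, 5.0)),))
tumor, enhanced, analytic_ml = make_tumor(spec, image, brain)
atlas = make_toy_atlas(image, n_regions=4, brain=brain)
report = assemble_preop_report(tumor, tumor, atlas)
print(round(analytic_ml[0], 3), round(report.volumes["patient_space_ml"], 3))
print(report.laterality.dominant, report.multifocal)
print(report.profiles["toy_parcellation"])
```

prints

```
0.524 0.515
left False
{'unlabeled': 0.0, 'region_1': 0.0, 'region_2': 42.14, 'region_3': 57.86, 'region_4': 0.0}
```

i.e. a 5 mm-radius sphere of analytic volume 0.524 ml is measured at
0.515 ml on the 1 mm grid (within one surface-voxel shell), sits entirely
in the left hemisphere as a single focus, and straddles two parcellation
slabs with percentages summing to 100.

The same flows run from the shell:

```bash
neurorads synth-cohort --n-patients 3 --seed 1 --out cohort/
neurorads batch cohort/ --task report_postop --out results/ \
    --config myconfig.json
```

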
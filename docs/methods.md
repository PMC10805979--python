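# Methods

`adenovol` automates volumetric assessment of pituitary adenoma on
T1-weighted contrast-enhanced MRI: it conforms volumes to a canonical
grid, segments tumor with a slice-wise 2D U-Net ensemble, cleans up
postoperative masks morphologically, and derives volumes, extent of
resection (EOR) and gross-total-resection (GTR) statistics. This note
records the model, its assumptions, the parameters that matter, and the
choices made where the design was genuinely open.

## Canonical grid and preprocessing

Every study is conformed before anything else sees it:

1. **Reorientation** to RAS (voxel axes increasing toward
   Right/Anterior/Superior) by pure axis permutation/flip; world
   coordinates of every voxel are unchanged. Volumes whose voxel axes are
   oblique to the world axes beyond a tolerance (default 10°) are
   rejected rather than silently resliced.
2. **Resampling** to isotropic spacing (default 1.0 mm), linear for
   images, nearest-neighbor for masks so labels stay binary. The field of
   view is preserved to within one voxel per axis.
3. **Crop/pad** to a fixed cubic shape (clinical scale 256³). Cropping
   and padding are centered; an odd remainder goes to the high-index
   side, so pad-then-crop round-trips exactly. Images pad with their
   minimum intensity, masks with 0.
4. **Intensity normalization** per study by z-score (zero mean, unit SD;
   constant volumes map to zero). The z-score is invariant to positive
   affine intensity rescalings, which removes scanner-dependent intensity
   scales; min–max scaling would be the main alternative and differs only
   in its sensitivity to intensity outliers.

The order reorient → resample → conform → normalize is the physically
coherent one (cropping before spacing normalization would make the crop
extent scanner-dependent). "Coronal" slices are planes of constant
anterior–posterior coordinate, i.e. slices along axis 1 of the RAS
lattice, ascending.

The grid is a parameter (`GridSpec`): all development and validation in
this repository runs at 64³ (and tests down to 32³), exercising the
identical code paths as the 256³ clinical setting at a fraction of the
cost. Problem sizes quoted below were chosen as the package's own
desk-scale study conditions.

## Phantom cohort

No public imaging cohort exists for this task, so validation runs on a
seeded phantom generator that emulates the *structure* of a
transsphenoidal-surgery cohort rather than MR physics:

* **Tumor**: union of 1–3 overlapping ellipsoids (primary semi-axes drawn
  uniformly from 6–12 mm; satellites centered inside the primary with
  0.4–0.7× its radii), jittered up to 4 mm off grid center. The
  single-ellipsoid case has the analytic volume 4/3·π·abc as an exact
  cross-check; lobulated unions carry a 2×-supersampled voxelization as
  their reference volume (discretization error well under 1% at mm
  scale).
* **Image**: smooth low-frequency background field (Gaussian-filtered
  noise, SD 0.5) + tumor contrast offset (3.0) on the mask + i.i.d.
  Gaussian noise (SD 0.5). Contrast-to-noise is deliberately generous:
  the phantoms are meant to verify machinery, not to pose a hard
  perception problem.
* **Resection**: the postoperative mask is grown from the tumor voxel
  most distal along a random direction, by priority-queue region growing
  within the preoperative mask, to exactly `round(f·N)` voxels — a
  connected residual rim, as after surgery. A configurable fraction of
  the cohort (default 0.5) has residual fraction exactly 0 (GTR), the
  rest draw uniformly from 0.05–0.5, so the GTR confusion machinery sees
  both classes.
* **Determinism**: each patient's stream derives from (master seed,
  CRC32 of the patient id); regenerating patient `P007` of cohort seed 42
  is bit-identical anywhere.

What the phantoms do *not* emulate — bias fields, Rician noise, partial
volume, anatomy, inter-rater label noise, heterogeneous acquisition —
bounds what passing tests show: they validate the pipeline's mechanics
and its volumetric algebra, not clinical segmentation difficulty.
Phantom performance numbers are therefore sanity floors, far above what
heterogeneous clinical data yields.

## Segmentation model

A compact 2D U-Net runs on every coronal slice: `depth` resolution
levels (two 3×3 convolutions + ReLU per level, 2× max-pooling between),
a decoder with nearest-neighbor upsampling and skip concatenation, and a
1×1 sigmoid head. Training minimizes binary cross-entropy with Adam.
The engine is implemented directly on numpy (float32 by default) with
exact backpropagation, verified against finite differences; it keeps the
package dependency-light and CPU-deterministic, with checkpoints as
`.npz` + JSON sidecars that reload bit-exactly.

Hyperparameters are configurable since the architecture reference fixes
none of them: defaults are depth 4 / 16 base filters / learning rate
1e-3 / batch 8; the desk-scale studies use depth 3 / 4 base filters /
learning rate 3e-3 / 2 epochs, enough to converge on the high-contrast
phantoms in a few minutes of CPU time.

* **Cross-validation**: k = 5, split *by patient* (both scans stay
  together), deterministic given the seed, fold sizes within 1.
* **Empty slices are kept in training** — the postoperative task is
  dominated by tumor-free slices, and dropping them would bias the
  foreground prior.
* **Augmentation** (optional): per-slice rotation 0–90° and zoom 0–30%,
  identical transform for image (linear) and mask (nearest). The
  `sampling_ratio` (reference value 1/255) is read as the fraction of
  training slices augmented per epoch; other readings cost one config
  value.
* **Transfer learning**: a postoperative model may be initialized by
  cloning a trained preoperative fold model; before its first step the
  clone predicts bit-identically to the donor, and training the clone
  never mutates the donor.
* **Seeding**: one master seed fans out (via `SeedSequence`) to fold
  assignment, weight initialization, shuffling and augmentation; no
  global RNG state is touched.

## Inference and postprocessing

The k fold models each predict every coronal slice; per-model
probability volumes are averaged voxel-wise with equal weights, then
binarized at 0.6 (preoperative) or 0.44 (postoperative). A voxel exactly
at the cutoff counts as foreground — the tie needs *some* deterministic
convention and ≥ is the documented one. Thresholding before or after
restacking is voxel-wise identical; the implementation restacks first.

Postoperative masks (only) then pass the cleanup chain, in this order:

1. remove 26-connected components smaller than 50 voxels (50 mm³ at the
   canonical grid — the floor is read in 3D, since all volumetry is 3D);
2. fill enclosed cavities (6-connectivity to the lattice border defines
   "outside");
3. one binary dilation with a 3×3×3 cube.

Connectivity choices and the dilation element are fixed defaults, all
configurable. Because dilation can regrow or merge regions, the size
floor is only guaranteed before step 3; tests document this.

## Evaluation conventions

* **Dice / Jaccard** by direct set counts; J = D/(2−D) holds to 1e-12.
* **Empty-mask policy**: both-empty scores Dice = Jaccard = 1 and
  HD95 = 0 by default (predicting "no residual" for a true GTR is a
  correct prediction); a compatibility flag scores both-empty overlap as
  0 for comparison with conventions that treat empties as failures.
  One-empty scores Dice = Jaccard = 0 and HD95 = NaN (distance to an
  empty surface is undefined). Aggregations expose both NaN-propagating
  and NaN-omitting modes.
* **HD95**: boundary voxels are foreground voxels with a background
  6-neighbor (the lattice border counts as background); the metric is
  the max of the two directed 95th-percentile Euclidean surface
  distances in mm, computed exactly via Euclidean distance transforms
  and the linear-interpolation percentile. A brute-force all-pairs
  oracle confirms equality to 1e-9 mm on random masks.
* **Volumetry**: volume = voxel count × voxel volume; EOR =
  100·(pre − post)/pre, *not* clamped (tumor growth yields negative EOR;
  clinical cohorts do contain such outliers); GTR ⇔ residual volume
  exactly 0 ⇔ EOR exactly 100%. An EOR for a case whose *predicted*
  preoperative mask is empty is undefined; the cohort assessor
  substitutes one voxel's volume and keeps the case, rather than
  dropping it.
* **GTR confusion**: GTR-present is the positive class, so sensitivity
  is the GTR-detection rate; rates are NaN on empty denominators and
  rounded only at the I/O boundary.
* **Correlation**: plain Pearson product-moment; degenerate variance
  yields NaN with a warning.

## Validation study sizes

The package's own end-to-end validation (`scaled_validation_config`)
simulates 40 phantom study pairs at 64³, trains five preoperative folds
on the 32 training patients (depth-3, 4-filter U-Net, 2 epochs, lr 3e-3)
and ensemble-predicts the 8 held-out phantoms at threshold 0.6 — about
four minutes on one CPU core. Floors asserted on it (median holdout
Dice ≥ 0.7, automated-vs-true volume r ≥ 0.8) are sanity bars for easy
synthetic data, not clinical expectations. The tiny integration test and
the examples run even smaller (8–10 patients at 32³, 1 epoch), where the
models are deliberately undertrained: those runs validate plumbing,
determinism and artifact consistency only.

## Known limitations

* The phantom's simplicity means segmentation quality numbers do not
  transfer to clinical data; only the machinery and the algebra do.
* No DICOM ingestion, bias-field correction, skull stripping, or
  pre/post registration; volumes must arrive as NIfTI.
* Oblique acquisitions beyond the orientation tolerance are rejected,
  not resliced.
* The numpy engine targets small CPU studies; it has no GPU path and no
  3D variant.
* GTR is strict (zero residual voxels after postprocessing); a
  near-zero-residual tolerance is a plausible alternative reading and
  would raise apparent GTR rates.
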
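# Methods

## Problem and pipeline

Progressive muscular dystrophies replace muscle tissue by fat; the imaging
biomarker is the proton-density fat fraction (FF%) computed from Dixon MRI,
quantified per muscle over its full 3-D extent. Volumetric quantification
requires segmenting each muscle individually, which this package automates
with a patch-based 3-D U-Net plus rule-based postprocessing, and evaluates
with overlap/surface metrics and paired statistics.

The pipeline stages, in execution order:

1. **Acquisition model** — four co-registered Dixon channels (water, fat,
   in-phase = W+F, out-of-phase = |W−F|) on a regular anisotropic grid,
   acquired as 1–3 partially overlapping axial stacks that are stitched
   into one volume.
2. **FF map** — per voxel, `FF% = 100·F/(F+W)` wherever `F+W > 0`; voxels
   with no Dixon signal are flagged invalid and excluded from all means
   (clinical images never hit this case inside muscle, but phantom
   backgrounds are exactly zero).
3. **Preprocessing** — mid-sagittal split into two single-leg images; the
   left half is mirrored to right-leg orientation, halving the problem and
   doubling the training data. Training samples are slabs of consecutive
   axial slices at full in-plane extent (2 channels: OP, IP).
4. **Segmentation** — a 3-D U-Net predicts per-voxel class probabilities
   patch-wise; whole volumes are covered by overlapping slabs whose
   probabilities are coverage-averaged, then argmaxed.
5. **Postprocessing** — per muscle keep the two largest 26-connected
   components (one per leg), then fill enclosed background cavities.
6. **Quantification** — per-muscle FF% (mean of per-voxel FF over the
   muscle, legs pooled) and volume (voxel count × voxel volume).
7. **Evaluation** — per-muscle Dice (DSC) and average symmetric surface
   distance (ASSD), per-image generalized DSC, Wilcoxon signed-rank for
   paired model comparisons (significance 0.05), Bland-Altman agreement of
   FF% and volumes.

## Synthetic phantom

The phantom generates what the pipeline needs to be exercised end to end
with exactly known truth, not a physically realistic MR simulation. Per
axial slice, each leg is an outer ellipse (subcutaneous fat rind), an inner
ellipse of muscle tissue, and a central femur (signal-free cortex ring
around fatty marrow). The muscle region is divided into angular wedges
around the femur — one muscle per wedge, each with its own outer-radius
factor so compartments differ in shape; the space beyond a muscle's radius
is filled as intermuscular fat. In-plane size tapers linearly (25%) along
the slice axis, mimicking proximodistal change. The left leg is the exact
mirror of the right, so mirror symmetry holds by construction in noise-free
geometry.

Signal model: muscle voxels carry `water = (1−f)·S`, `fat = f·S` with `f`
the muscle's infiltration fraction and `S = 1000` arbitrary units (the
models are trained on raw intensities, so one consistent amplitude is used
throughout); fat-like tissue carries `fat = S`. Optional zero-mean Gaussian
noise (default sd 2% of `S`, clipped at 0) is added to water and fat
independently; IP/OP are derived afterwards so the four channels stay
consistent. Designed per-muscle FF% is therefore `100·f` exactly, and
noise-free quantification must recover it to machine precision.

Cohorts draw per-muscle infiltration uniformly from a range — [0, 0.2]
for the low-infiltration (LI) group, [0.4, 0.8] for the high-infiltration
(HI) group — and jitter the anatomy per subject (ellipse axes and leg
position ±8%, wedge rotation) so subjects differ in both shape and fat
load. Acquisition noise makes repeated scans differ.

What the phantom does **not** emulate: MR physics (relaxation, B0
inhomogeneity, multi-echo reconstruction), partial-volume mixtures at
boundaries, scanner-to-scanner intensity variation, and real muscle
anatomy. Passing tests demonstrate that the pipeline machinery —
learning, inference, stitching, metrics, quantification — behaves
correctly, not that the network would segment clinical anatomy at the
reported level.

## Network and training protocol

Architecture: encoder-decoder with 3×3×3 kernels everywhere, including
strided (×2) down-sampling convolutions and the channel-reducing
convolutions that precede nearest-neighbour up-sampling; the deepest level
holds 4 convolutional layers (its strided entry plus three more); other
levels hold one convolution each by default. Channel widths double per
level from `base_filters`. Instance normalisation follows every
convolution — the protocol fixes batch size 1, where instance
normalisation is the standard choice — and skip connections are additive.
Inputs are scaled by a fixed global constant (1/1000); this is a units
choice, not per-image normalisation. Spatial input extents must be
divisible by `2^(depth−1)`.

Training: per epoch, 2 patches are sampled uniformly along the slice axis
from every single-leg training image, optionally augmented (one shared
small affine — rotation ±10°, scale ±10%, in-plane translation ±5 voxels,
defaults configurable — applied linearly to channels and nearest-neighbour
to labels, plus additive Gaussian intensity noise on channels only), and
optimised with Adam under voxel-wise cross-entropy (no class weighting).
The learning rate starts at 1e-4 and halves when the validation loss has
not improved for 25 consecutive epochs; "improvement" means a strict
decrease by more than 1e-6 (the tolerance is a package choice). Training
stops at `max_epochs` or, when configured, after `early_stop_patience`
(e.g. 40) non-improving epochs; the parameters with the best validation
loss are returned. The validation loss is computed on a fixed
minimal-coverage tiling of patches so the schedule is not driven by
sampling noise.

Inference: deterministic slab tiling with ≥50% overlap by default (a
random-until-coverage policy is available); per-voxel probabilities are
the average over covering patches, renormalised. Argmax ties resolve to
the lowest class id. Cross-validation folds are dealt round-robin over
shuffled subjects so that every scan of a subject stays in one fold.
Ensembles fuse fold models by per-voxel majority vote; vote ties are
broken by the highest mean class probability, then lowest id —
deterministic either way.

The network, its backward passes and Adam are implemented directly on
float32 NumPy arrays, with the 3×3×3 convolution inner loops JIT-compiled
(numba) for thin-channel layers and expressed as 27-shift BLAS matrix
products for wide-channel and strided layers; the two paths compute the
same arithmetic, and the hand-written gradients are spot-checked against
finite differences in the test suite. Everything is single-threaded and
deterministic for a fixed seed.

## Desk-scale study conditions

The clinical-scale configuration (384×384×140 voxels at 1.2×1.2×2 mm, 18
muscles, 81-slice patches, 160–500 epochs) is expressible but not what the
tests run. The desk-scale study in `protocols.py` fixes: 8 phantom
subjects on a 96×96×48 grid with 6 muscles per leg, 2% channel noise,
a depth-3 U-Net with 8 base filters on 24-slice patches, 40 epochs,
subject-grouped 2-fold split (4 subjects held out; of the training
subjects the last provides validation scans). With roughly two orders of
magnitude fewer optimizer steps than a clinical-scale run, the Adam step
size is scaled up tenfold to 1e-3 — Adam's total parameter displacement is
approximately `lr × steps`, so this keeps the optimisation budget
comparable; it is the one deliberate departure from the clinical protocol
and the package's own miniaturisation rule. Augmentation is kept mild
(±5°, ±5%, ±2 voxels, noise sd 1% of signal) to match the phantom's
modest anatomical variability.

## Postprocessing and ground-truth preparation conventions

- Connected components use 26-connectivity (standard for 3-D blobs); the
  two largest components per muscle are kept, a size tie at rank 2 going
  to the lower centroid x.
- Holes are defined in 3-D per muscle: 6-connected background components
  that do not reach the volume border and touch exactly one muscle id.
  Cavities bordering several muscles are inter-muscle space and are kept.
- Boundary erosion for ground-truth preparation acts in-plane per axial
  slice with a 4-connected cross element: voxels are strongly anisotropic
  (1.2×1.2×2 mm) and delineations are drawn per axial slice, so a
  "1-pixel layer" is read as in-plane. Applied to references, not to
  predictions.
- Components are filtered before holes are filled.
- Sparse annotation (GT5/GT10) keeps every k-th slice and copies the
  nearest kept slice into the gaps, equidistant ties going to the
  inferior slice.

## Metric conventions

- DSC of two empty masks is 100 (perfect agreement on absence); such
  muscles are flagged in reports rather than silently averaged.
- ASSD boundary voxels are foreground voxels with a 6-neighbour outside
  the mask, the volume border counting as outside; distances are
  voxel-centre to voxel-centre under the anisotropic spacing, averaged
  over the union of both boundary sets. ASSD is undefined (reported
  missing) when either mask is empty.
- Generalized DSC pools intersections and sizes over all foreground
  labels, unweighted.
- Wilcoxon signed-rank: zero differences dropped, mid-ranks for ties;
  the null is enumerated exactly (dynamic programme over doubled ranks)
  for n ≤ 25 and approximated by a tie-corrected normal (no continuity
  correction) above.
- Bland-Altman limits are bias ± 1.96 × sample sd (ddof 1) of the paired
  differences; pair order is preserved for plotting.

## Numerical and degenerate-input choices

Activations and parameters are float32; metric and FF arithmetic is
float64. Channel noise is clipped at zero (magnitudes cannot be
negative), which introduces a bias only where the mean signal is within a
few sd of zero — negligible at the default 2% noise. Stitching weights
are tent-shaped (linear ramp from each stack end), which is exact when
overlapping values agree and artifact-free otherwise. Volumes shorter
than the patch length are rejected, never padded. Muscles with no valid
voxels yield missing FF% with a recorded reason rather than zeros.

## Known limitations

- The phantom's geometric anatomy is far simpler than real thighs; the
  desk-scale accuracy figures do not transfer to clinical data.
- No intensity harmonisation across scans is modelled or applied
  (deliberately, matching the single-scanner setting).
- The hole-filling definition (3-D, single-muscle adjacency) is one
  reasonable reading of "holes inside a segmented muscle"; a per-slice
  2-D variant would fill slightly different sets.
- Training at clinical scale (384×384×140, hundreds of epochs) is out of
  reach for the pure-CPU implementation; the code paths are identical,
  only the configured sizes differ.
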
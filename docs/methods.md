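# Methods

## The segmentation model

`pupilkit` segments the pupil with a constant-width encoder–decoder
network ("mini-UNet"). For a 128×128 single-channel input the encoder
applies two 3×3/16-kernel ReLU convolutions per resolution level and 2×2
max pooling between levels (3 levels: 128 → 64 → 32); the decoder mirrors
it with parameter-free nearest-neighbor ×2 upsampling, concatenation with
the same-resolution encoder map, and a 32→16 fusion convolution followed
by one 16→16 convolution per level. A 1×1 convolution produces the pixel
logit map. Eye-present and blink logits come from global average pooling
of the 16-channel bottleneck into a single 16→2 fully connected layer
(34 parameters). Sigmoids map all three outputs to probabilities.

The depth (3 levels), the two convolutions per level, concatenation
fusion, and interpolation upsampling are this package's design choices:
together they give 25,699 trainable parameters, i.e. 0.03 M after
rounding, which is the architecture's printed budget;
`build_segmenter()` asserts the rounded value and refuses configurations
that miss it (pass `expected_param_millions=None` to experiment). No
normalization layers are used. The pixel-head bias is initialized to
−3.0, the logit of the ≈5% pupil-pixel prior; starting at the class
prior instead of 0.5 removes the early all-background phase that
otherwise dominates short training runs on imbalanced masks.

### Why NumPy + numba

The network (~26k parameters) is small enough that a hand-written
implementation is practical: each layer implements an explicit
forward/backward pair, and 3×3 convolutions run through numba-compiled
row-blocked kernels (~30 GFLOP/s on one core). Correctness of the
backward pass is enforced by a finite-difference gradient check in the
test suite (float64, relative tolerance 1e-4 on sampled coordinates of
every parameter tensor). The input-gradient pass reuses the forward
kernel with spatially flipped, channel-transposed weights; the
weight-gradient pass is the matching row-dot reduction.

## Training recipe

- **Split**: seeded uniform shuffle, then floor(0.7·n) training,
  floor(0.2·n) validation, remainder test — exact (70, 20, 10) on
  n = 100.
- **Loss**: the binary cross-entropy of *every* output — each pixel of
  the map plus the eye and blink logits — summed, then averaged over
  the batch. Summing rather than averaging the pixel terms weights the
  segmentation task by its output count; empirically this is what makes
  the minority bright-pupil regime learnable in short schedules, since
  a pixel-averaged map term is drowned out by the two scalar heads on
  the shared encoder weights. The training loop computes the loss from
  logits in the numerically stable form; the public `total_loss()`
  diagnostic reports the conventional per-frame quantity (mean pixel
  BCE + eye BCE + blink BCE) on probabilities clipped to
  [1e-7, 1 − 1e-7]. The reduction is a `TrainConfig` option
  (`pixel_loss_reduction`, default `"sum"`). One consequence of the
  summed weighting is that the scalar heads converge more slowly: the
  blink head needs on the order of 500 optimizer steps to become
  discriminative (verified at small scale in the tests), which the
  reference 750-epoch schedule provides many times over but the
  12-epoch scaled study does not — its checks therefore concern
  segmentation and area recovery, not blink classification.
- **Optimizer**: AdaBelief (β₁ = 0.9, β₂ = 0.999, ε = 1e-8, ε added
  inside the second-moment accumulation as in its published algorithm),
  default learning rate 0.001, batch 32 (batch size is a convention, not
  a printed value).
- **Augmentation** (training stream only): rotation ±30°, random crop
  at scale 0.7–1.0, horizontal/vertical flips at p = 0.5, brightness/
  contrast/sharpness factors 0.7–1.3, then resize to 128. Geometric
  transforms use bilinear interpolation for images and nearest-neighbor
  for masks so labels stay binary; magnitudes are exposed configuration,
  not claims about the original recipe. Validation/test images instead
  get a deterministic 128×128 crop centered on the mask centroid
  (image center for blink frames), clamped to bounds.
- **Selection**: per-epoch validation mean Dice (maps thresholded at
  0.5); the best snapshot is returned. Dice of two empty masks is
  defined as 1.0 — a blink frame whose prediction is also empty is a
  perfect match, and 0/0 is thereby avoided.

### Scaled-down schedule

The reference schedule (750 epochs at lr 0.001 on ~12k annotated
images) is impractical for routine verification, so the test suite
trains a scaled-down study: 500 synthetic training images, with
separately generated 100-image validation and 200-image held-out sets,
batch 32, 12 epochs at the published lr 0.001, fixed seeds. Two
deviations from the reference recipe are deliberate and documented:
train-time augmentation is disabled (with only ~200 optimizer steps the
augmentation noise dominates and the minority bright-pupil regime is
not reached), and the dataset is the synthetic population rather than
the annotated recordings. Under these conditions the recipe reaches a
held-out mean Dice above 0.9, with the bright-pupil class — learned
last, because its contrast is inverted through shared features — above
0.8. `TrainConfig.warm_restart_every` additionally offers warm restarts
(reset optimizer moments, resume from the best snapshot) for schedule
experiments; the scaled-down study does not need it. The long-schedule
defaults remain `TrainConfig()`'s defaults.

## Synthetic eye generator

Each frame is a sclera disk, an iris disk concentric with the pupil, an
elliptical pupil at dark or bright polarity, optional specular spots, an
eyelid covering the top (1 − openness) fraction of rows, and additive
Gaussian noise, all in [0, 1] floats (quantized to 8-bit PNG on write).
Class populations (`mouse`, `2P-mouse`, `human`) differ in gray-level
ranges, polarity, and specular-spot counts; the default class mix
(43/21/36%) and blink rate (13.4%) follow the composition of the public
annotated eye dataset the network family was trained on. A pixel belongs
to the pupil mask iff its center satisfies the ellipse inequality
(0-based coordinates, x right, y down) — the same rule the dataset
reader uses to rasterize ellipse annotations, and the rule all area
oracles in the tests are written against. A frame with eyelid openness
below 0.15 is labeled a blink and its mask is empty; raters flag blinks
on visually closed frames, and 0.15 marks the point where the aperture
has essentially vanished.

Dynamic sequences superpose double-exponential dilation transients
(normalized so the peak equals the stated fractional dilation of the
baseline area), an optional seeded random-walk drift, and half-open
blink epochs `[onset, onset + duration)` resolved on the frame grid
(so a 0.3 s blink at 30 fps is exactly 9 frames). The ground-truth trace
carries the analytic area, the true center, and blink flags.

**What the generator does not emulate**: photorealistic texture, gaze-
dependent pupil foreshortening, corneal reflections beyond simple
spots, motion blur, or compression artifacts. Passing tests therefore
demonstrate that the machinery — rendering, training, measurement,
analysis — is correct on a controlled population, not that a network
trained on synthetic eyes transfers to real recordings; training on the
real annotated dataset uses the same code paths via `dataset_io`.

## Measurement pipeline

Preprocessing applies, in this fixed order: optional inversion
(1 − I), contrast gain and brightness offset, clipping to [0, 1], then
gamma. Thresholding is closed at the cutoff (map ≥ t, so t = 0 gives the
all-ones mask). Morphological refinement — enabled per species preset —
is a binary opening with the 3×3 cross followed by retention of the
largest 8-connected component; the recipe is this package's minimal
reading of "refinement via mathematical morphology" that removes
speckle and enforces a single pupil, and it is idempotent and never adds
pixels. ROI tracking re-centers the 128×128 window on the current
frame's measured centroid (no smoothing), clamped to frame bounds.
Centroids are undefined (empty CSV fields, NaN in memory) when the mask
is empty rather than being reported as zeros. Trigger channels are four
booleans expanded from timestamped event rows.

## Analysis conventions

- Blink epochs: maximal runs of blink probability ≥ 0.5, merged when
  separated by fewer than 2 frames (both unprinted; 0.5 is the
  symmetric cutoff for a sigmoid output, merging suppresses flicker).
- Deblinking: linear interpolation from nearest valid neighbors (edges
  held), then median filtering over round(0.5 s · fps) samples, forced
  odd by +1 (the 0.5 s span is the defined procedure; discretization is
  ours).
- z-scoring uses each trial's own baseline mean and sample SD
  (ddof = 1); trials with zero baseline SD are excluded with a warning.
- Event-related transients default to a 15 s window centered on onset
  (7.5 s + 7.5 s at the trace's own frame rate; 450 samples at 30 fps),
  with the full pre-onset half as the default baseline (the baseline
  span is exposed as a parameter).
- Pointwise significance: per post-onset sample, a paired t test of
  trial values against trial baseline means, then Benjamini–Hochberg
  FDR across samples (delegated to scipy/statsmodels; the procedure —
  per-sample comparison, BH across the family — is what this module
  defines). Zero-variance differences yield p = 1.
- Locomotion: moving ⇔ speed ≥ 10% of the session maximum; invariant
  to positive rescaling; an all-zero trace is all-stationary.
- Device agreement: min–max normalization to [−1, 1], linear
  interpolation of the slower trace onto the faster grid over the
  common support, then mean absolute error. Constant traces are
  rejected (zero range).

## Problem sizes used in verification

The automated suite uses: 500 synthetic images / 16 epochs for the
training check; a 40 s, 30 fps synthetic sequence (two +30% dilation
events, two blinks) for end-to-end area recovery (Pearson r against the
analytic truth on non-blink frames, and ERT peak-amplitude recovery);
100 random maps for the threshold-monotonicity sweep; and 100 null
simulations of 8 trials × 30 samples for the FDR-control check (the
acceptance run uses 1000). These sizes are the package's verification
conditions; the full reference schedule is available through the same
interfaces.

## Known limitations

- No GPU path; throughput is a few dozen 128×128 inferences per second
  per core.
- Video containers (MP4/AVI) are read through imageio and require a
  suitable backend plugin; directories of PNG/TIFF frames are the
  always-available path.
- The deposit reader auto-detects two layout families (annotation table
  / image+mask pairs) and fails loudly on anything else rather than
  guessing.
- `pointwise_significance` implements the defined pointwise procedure
  only; omnibus repeated-measures ANOVA and Bayes-factor analyses are
  out of scope and should be run in a dedicated stats package.
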
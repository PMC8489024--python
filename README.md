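# pupilkit

**CNN-based pupillometry: pupil segmentation, blink detection, and
event-related pupil analysis for mouse and human eye videos.**

Pupil size is a window on arousal and brain state, and modern
neuroscience setups measure it from infrared eye videos in very different
regimes: head-fixed mice under IR illumination (dark pupil), mice under
two-photon imaging where IR backscatter *inverts* the contrast (bright
pupil), and IR-lit human eyes. `pupilkit` implements a compact
segmentation network and the full measurement/analysis chain around it:

- **mini-UNet segmenter** (`pupilkit.model`) — an encoder–decoder
  "hourglass" network for 128×128 grayscale inputs. Every hidden
  convolution has 16 kernels of 3×3 (ReLU, same padding); the encoder
  halves resolution with 2×2 max pooling, the decoder upsamples ×2 and
  fuses the same-resolution encoder maps by concatenation + convolution.
  Outputs, all through a sigmoid: a 128×128 per-pixel pupil probability
  map, an eye-present probability, and a blink probability (the latter
  two from global average pooling of the bottleneck + a 2-way fully
  connected layer). Total: **25,699 trainable parameters (0.03 M)** —
  asserted at build time. The network is implemented in NumPy with
  explicit backpropagation and numba-compiled convolution kernels, so it
  trains and runs on a plain CPU with no deep-learning framework.
- **training recipe** (`pupilkit.training`) — seeded 70/20/10 split,
  strong augmentation (rotation, crop, flips, brightness/contrast/
  sharpness), loss = mean pixel binary cross-entropy + eye BCE + blink
  BCE, the AdaBelief optimizer, and best-validation-Dice snapshot
  selection. Segmentation quality is scored with the Dice coefficient
  2|A∩B|/(|A|+|B|), averaged per image (mDice).
- **synthetic ground truth** (`pupilkit.synth`) — a seeded renderer of
  all three imaging regimes with exact pupil masks, blinks, eyelid
  occlusion, illumination variation, and dynamic sequences whose pupil
  area follows known dilation transients — so every downstream number
  can be checked against an analytic truth.
- **measurement pipeline** (`pupilkit.pipeline`) — ROI tracking that
  follows the pupil centroid, tunable preprocessing (invert /
  contrast / brightness / gamma), probability-map thresholding,
  morphological refinement (3×3-cross opening + largest connected
  component), per-frame area/centroid/blink measures, trigger channels,
  and a fixed CSV dialect
  (`frame,time_s,area_px,pupil_x,pupil_y,eye_prob,blink_prob,trig1..4`).
  Species presets for offline video analysis: threshold 0.25/0.15/0.5
  with morphology off/on/on for human / mouse / 2P-mouse.
- **analysis** (`pupilkit.analysis`) — blink removal (linear
  interpolation + 0.5 s median filter), per-trial z-scoring
  z = (x − x̄_baseline)/s_baseline, 15 s event-related transients,
  locomotion tagging (moving ⇔ speed ≥ 10% of session max), pointwise
  post-onset significance with Benjamini–Hochberg FDR correction, and
  cross-device trace agreement (normalize to [−1,1], upsample by linear
  interpolation, mean absolute error).

## Worked example

```bash
python examples/02_train_segmenter.py   # train on synthetic eyes (minutes)
python examples/03_video_pipeline.py    # run the pipeline on a synthetic video
python examples/04_ert_analysis.py      # event-related transients + FDR stats
```

Even after the quick demo training in `02` (4 epochs on 200 images),
`03` tracks a dynamic synthetic eye:

```
measured vs true area: Pearson r = 0.992 over 588 non-blink frames
recovered event amplitude: +28% (injected +30%)
```

`examples/04_ert_analysis.py` builds a 10-minute synthetic session with
+30% dilation events every 2 minutes and three blinks, then prints:

```
3 blink epochs interpolated (36 frames)
5 trials x 450 samples; mean ERT peaks at 51.0 SD, 1.43 s after onset
significant dilation (BH-adjusted p < 0.05) from 0.00 to 7.47 s after onset
moving 52% of samples; mean pupil area moving 424 px^2 vs stationary 424 px^2
```

i.e. the blink interpolator patched 36 frames, the z-scored
event-related transient peaks ~1.4 s after stimulus onset, the
FDR-corrected pointwise test marks the dilation window as significant,
and (with velocity uncorrelated to pupil by construction) the
moving/stationary areas agree.

A quick look at the architecture from the shell:

```bash
pupilkit describe      # layer table + "total trainable parameters: 25699 (0.03 M)"
pupilkit simulate --n 200 --seed 1 --out eyes/
pupilkit run eyes/images --model segmenter.npz --preset mouse --out trace.csv
```

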
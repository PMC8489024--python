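"""Training recipe and segmentation evaluation.

The recipe follows the published one: a seeded 70/20/10 train/val/test
split, strong data augmentation on the training stream (random rotation,
cropping, horizontal/vertical flips, brightness/contrast/sharpness), a
loss summing the binary cross-entropies of all three outputs (pixel map,
eye logit, blink logit), the AdaBelief optimizer at learning rate 0.001,
and selection of the snapshot with the best validation mean Dice.
Validation and test images are center-cropped to 128×128 on the pupil.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import transform as sktf

from ._layers import bce_with_logits, sigmoid
from .model import Prediction, Segmenter
from .synth import LabeledFrame

_BCE_EPS = 1e-7


@dataclass
class AugmentPolicy:
    """Ranges of the random train-time transforms.

    Geometric transforms (rotation, crop, flips) are applied identically
    to image and mask — bilinear interpolation for the image, nearest
    neighbor for the mask so labels stay binary.  Photometric factors
    multiply brightness, scale contrast about the mean, and blend an
    unsharp mask, on the image only.  The exact magnitudes of the original
    recipe are not published; these defaults are configuration, not claim.
    """

    rotation_range: float = 30.0  # degrees, +/-
    crop_scale_range: tuple[float, float] = (0.7, 1.0)
    horizontal_flip_p: float = 0.5
    vertical_flip_p: float = 0.5
    brightness_range: tuple[float, float] = (0.7, 1.3)
    contrast_range: tuple[float, float] = (0.7, 1.3)
    sharpness_range: tuple[float, float] = (0.7, 1.3)
    output_size: int = 128

    def __post_init__(self) -> None:
        for p in (self.horizontal_flip_p, self.vertical_flip_p):
            if not 0 <= p <= 1:
                raise ValueError("flip probabilities must be in [0, 1]")


@dataclass
class TrainConfig:
    """Optimization hyperparameters; defaults are the published recipe."""

    epochs: int = 750
    learning_rate: float = 0.001
    batch_size: int = 32
    split: tuple[float, float, float] = (0.70, 0.20, 0.10)
    seed: int = 0
    augment: AugmentPolicy | None = field(default_factory=AugmentPolicy)
    #: optional step decay: ((epoch, lr), ...) switches the learning rate at
    #: the start of the 1-based epoch; useful for short schedules
    lr_schedule: tuple[tuple[int, float], ...] | None = None
    #: optional warm restarts: every k epochs, reset the optimizer moments
    #: and restart from the best validation snapshot so far
    warm_restart_every: int | None = None
    #: how the pixel-map cross-entropies enter the loss: "sum" weights the
    #: segmentation task by its output count (each pixel is an output);
    #: "mean" weights the map, eye and blink outputs equally
    pixel_loss_reduction: str = "sum"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.pixel_loss_reduction not in ("sum", "mean"):
            raise ValueError("pixel_loss_reduction must be 'sum' or 'mean'")


def split_dataset(
    frames: list, split: tuple[float, float, float] = (0.70, 0.20, 0.10), seed: int = 0
) -> tuple[list, list, list]:
    """Seeded disjoint train/val/test split.

    Sizes: floor(n*train), floor(n*val), remainder to test — so 100 frames
    give (70, 20, 10) and 10 frames give (7, 2, 1).
    """
    if not frames:
        raise ValueError("empty dataset")
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    n = len(frames)
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(np.floor(n * split[0]))
    n_val = int(np.floor(n * split[1]))
    pick = lambda idx: [frames[i] for i in idx]
    return (
        pick(order[:n_train]),
        pick(order[n_train:n_train + n_val]),
        pick(order[n_train + n_val:]),
    )


def _resize(img: np.ndarray, size: int, order: int) -> np.ndarray:
    if img.shape == (size, size):
        return img
    return sktf.resize(img.astype(float), (size, size), order=order,
                       anti_aliasing=False, preserve_range=True)


def augment(frame: LabeledFrame, policy: AugmentPolicy, seed) -> LabeledFrame:
    """One random augmentation draw; image and mask stay in register."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    img = frame.image.astype(float)
    mask = frame.mask.astype(float)

    angle = rng.uniform(-policy.rotation_range, policy.rotation_range)
    if angle != 0.0:
        img = sktf.rotate(img, angle, order=1, mode="edge", preserve_range=True)
        mask = sktf.rotate(mask, angle, order=0, mode="constant", cval=0, preserve_range=True)

    lo, hi = policy.crop_scale_range
    scale = rng.uniform(lo, hi)
    h, w = img.shape
    side = int(round(scale * min(h, w)))
    if side < 8:
        raise ValueError("crop smaller than 8 px")
    if side > min(h, w):
        raise ValueError("crop larger than source image")
    if side < min(h, w):
        top = rng.integers(0, h - side + 1)
        left = rng.integers(0, w - side + 1)
        img = img[top:top + side, left:left + side]
        mask = mask[top:top + side, left:left + side]

    if rng.uniform() < policy.horizontal_flip_p:
        img, mask = img[:, ::-1], mask[:, ::-1]
    if rng.uniform() < policy.vertical_flip_p:
        img, mask = img[::-1, :], mask[::-1, :]

    img = _resize(img, policy.output_size, order=1)
    mask = _resize(mask, policy.output_size, order=0)

    fb = rng.uniform(*policy.brightness_range)
    fc = rng.uniform(*policy.contrast_range)
    fs = rng.uniform(*policy.sharpness_range)
    if fb != 1.0:
        img = img * fb
    if fc != 1.0:
        m = img.mean()
        img = (img - m) * fc + m
    if fs != 1.0:
        img = img + (fs - 1.0) * (img - ndi.gaussian_filter(img, 1.0))
    img = np.clip(img, 0.0, 1.0)

    return LabeledFrame(
        image=np.ascontiguousarray(img),
        mask=np.ascontiguousarray(mask) > 0.5,
        eye_present=frame.eye_present,
        blink=frame.blink,
        class_tag=frame.class_tag,
    )


def eval_crop(frame: LabeledFrame, size: int = 128) -> LabeledFrame:
    """Deterministic evaluation crop centered on the pupil.

    Crops a ``size``×``size`` window centered on the ground-truth mask
    centroid, clamped to the image bounds; empty-mask frames (blinks) use
    the image center.  Inputs already at target size pass through.
    """
    h, w = frame.image.shape
    if (h, w) == (size, size):
        return frame
    if h < size or w < size:
        raise ValueError(f"frame {h}x{w} smaller than crop size {size}")
    if frame.mask.any():
        ys, xs = np.nonzero(frame.mask)
        cy, cx = ys.mean(), xs.mean()
    else:
        cy, cx = (h - 1) / 2, (w - 1) / 2
    top = int(np.clip(round(cy - size / 2), 0, h - size))
    left = int(np.clip(round(cx - size / 2), 0, w - size))
    return LabeledFrame(
        image=frame.image[top:top + size, left:left + size].copy(),
        mask=frame.mask[top:top + size, left:left + size].copy(),
        eye_present=frame.eye_present,
        blink=frame.blink,
        class_tag=frame.class_tag,
    )


def total_loss(pred: Prediction, target: LabeledFrame) -> float:
    """Summed binary cross-entropy of the three outputs.

    Mean pixel-wise BCE of the pupil map plus the BCE of the eye and
    blink probabilities; probabilities are clipped to [1e-7, 1 - 1e-7].
    """
    if pred.pupil_map.shape != target.mask.shape:
        raise ValueError("prediction/target shape mismatch")

    def bce(p, t):
        p = np.clip(p, _BCE_EPS, 1.0 - _BCE_EPS)
        return -(t * np.log(p) + (1.0 - t) * np.log(1.0 - p))

    map_term = float(np.mean(bce(pred.pupil_map, target.mask.astype(float))))
    eye_term = float(bce(pred.eye_prob, float(target.eye_present)))
    blink_term = float(bce(pred.blink_prob, float(target.blink)))
    return map_term + eye_term + blink_term


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("mask shape mismatch")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


class AdaBelief:
    """AdaBelief: Adam-like steps scaled by belief in the gradient.

    The second moment tracks the variance of the gradient around its EMA
    prediction, (g - m)^2, instead of the raw g^2; both moments are
    bias-corrected.
    """

    def __init__(self, params: list[np.ndarray], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-16):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.s = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, g, m, s in zip(self.params, grads, self.m, self.s, strict=True):
            m *= self.b1
            m += (1.0 - self.b1) * g
            diff = g - m
            s *= self.b2
            s += (1.0 - self.b2) * diff * diff + self.eps
            p -= self.lr * (m / bc1) / (np.sqrt(s / bc2) + self.eps)


def _to_arrays(frames: list[LabeledFrame], dtype=np.float32):
    x = np.stack([f.image for f in frames]).astype(dtype)[:, None]
    m = np.stack([f.mask for f in frames]).astype(dtype)[:, None]
    cls = np.array([[float(f.eye_present), float(f.blink)] for f in frames], dtype=dtype)
    return x, m, cls


def batch_loss_and_grads(model: Segmenter, x, m, cls, pixel_reduction: str = "sum"):
    """Training loss and backward pass, from logits.

    The loss is the binary cross-entropy of every output — the pixel map
    plus the eye and blink logits — combined and averaged over the
    batch.  With ``pixel_reduction="sum"`` each pixel counts as one
    output (the segmentation task is weighted by its output count),
    which is what lets the minority bright-pupil regime be learned in
    short schedules; ``"mean"`` weights the three outputs equally.
    """
    map_logits, cls_logits = model.forward(x)
    n = x.shape[0]
    scale = 1.0 if pixel_reduction == "sum" else map_logits.shape[2] * map_logits.shape[3]
    loss = float(
        bce_with_logits(map_logits, m).sum(axis=(1, 2, 3)).mean() / scale
        + bce_with_logits(cls_logits, cls).sum(axis=1).mean()
    )
    d_map = (sigmoid(map_logits) - m) / (n * scale)
    d_cls = (sigmoid(cls_logits) - cls) / n
    model.backward(d_map, d_cls)
    return loss


def evaluate_dice(model: Segmenter, frames: list[LabeledFrame], threshold: float = 0.5,
                  batch_size: int = 32) -> float:
    """Mean per-image Dice of the thresholded maps over a frame set."""
    scores = []
    for i in range(0, len(frames), batch_size):
        chunk = frames[i:i + batch_size]
        maps, _, _ = model.predict_batch(np.stack([f.image for f in chunk]))
        for f, pm in zip(chunk, maps):
            scores.append(dice(pm >= threshold, f.mask))
    return float(np.mean(scores))


def train(
    model: Segmenter,
    train_set: list[LabeledFrame],
    val_set: list[LabeledFrame],
    config: TrainConfig,
) -> tuple[Segmenter, list[dict]]:
    """Run the recipe and return the best validation snapshot plus history.

    Each epoch streams seeded augmentations of the training frames (when a
    policy is configured), records the mean training loss and the
    validation mean Dice, and keeps the parameter snapshot with the best
    validation Dice seen so far.  History rows: epoch, train_loss,
    val_dice.
    """
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be nonempty")
    rng = np.random.default_rng(config.seed)
    opt = AdaBelief(model.parameters(), lr=config.learning_rate)
    history: list[dict] = []
    best_state = model.get_state()
    best_dice = -np.inf
    val_set = [eval_crop(f, size=model.config.input_size) for f in val_set]
    for epoch in range(config.epochs):
        if config.lr_schedule:
            for start_epoch, lr in config.lr_schedule:
                if epoch + 1 == start_epoch:
                    opt.lr = lr
        if (config.warm_restart_every and epoch > 0
                and epoch % config.warm_restart_every == 0):
            model.set_state(best_state)
            opt = AdaBelief(model.parameters(), lr=opt.lr)
        order = rng.permutation(len(train_set))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = [train_set[i] for i in idx]
            if config.augment is not None:
                batch = [augment(f, config.augment, rng) for f in batch]
            x, m, cls = _to_arrays(batch, dtype=model.dtype)
            losses.append(
                batch_loss_and_grads(model, x, m, cls, config.pixel_loss_reduction))
            opt.step(model.gradients())
        val_dice = evaluate_dice(model, val_set)
        history.append({"epoch": epoch + 1, "train_loss": float(np.mean(losses)),
                        "val_dice": val_dice})
        if val_dice > best_dice:
            best_dice = val_dice
            best_state = model.get_state()
    best_model = copy.deepcopy(model)
    best_model.set_state(best_state)
    return best_model, history
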
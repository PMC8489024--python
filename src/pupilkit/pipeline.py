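"""Frame-to-measurement engine.

Turns raw video frames into a :class:`~pupilkit.trace.PupilTrace`: crop a
128×128 region of interest (optionally re-centered every frame on the
tracked pupil), apply tunable preprocessing (inversion, contrast/
brightness, gamma), run the segmenter, threshold the probability map,
optionally refine it morphologically (3×3-cross opening, then keep the
largest 8-connected component), and measure pupil area and centroid in
source-frame coordinates.  Species presets reproduce the offline-analysis
settings: human → threshold 0.25 / no morphology, mouse → 0.15 / with,
2P-mouse → 0.5 / with.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi

from .model import Prediction
from .trace import FrameMeasure, PupilTrace, read_csv, write_csv  # noqa: F401  (re-export)

#: (threshold, morphology) per species, as used for offline video analysis.
PRESETS = {
    "human": (0.25, False),
    "mouse": (0.15, True),
    "2P-mouse": (0.5, True),
}

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_CONN8 = np.ones((3, 3), dtype=bool)


@dataclass
class RoiState:
    """Region-of-interest tracker state; ``size`` × ``size`` window."""

    center: tuple[float, float]  # (x, y) source-frame px
    size: int = 128
    follow: bool = True


@dataclass
class PreprocSettings:
    """Tunable preprocessing: out = clip(invert? → ·gain + offset → ^gamma)."""

    brightness: float = 0.0  # additive offset
    contrast: float = 1.0  # multiplicative gain
    gamma: float = 1.0
    invert: bool = False

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass
class PostprocSettings:
    threshold: float = 0.5
    morphology: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 1:
            raise ValueError("threshold must be in [0, 1]")


def apply_preprocess(image: np.ndarray, settings: PreprocSettings) -> np.ndarray:
    """Fixed order: inversion, then contrast/brightness, then gamma."""
    if settings.gamma <= 0:
        raise ValueError("gamma must be positive")
    out = np.asarray(image, dtype=float)
    if settings.invert:
        out = 1.0 - out
    out = out * settings.contrast + settings.brightness
    out = np.clip(out, 0.0, 1.0)
    if settings.gamma != 1.0:
        out = out**settings.gamma
    return np.clip(out, 0.0, 1.0)


def threshold_map(pmap: np.ndarray, threshold: float) -> np.ndarray:
    """Binary mask of pixels whose probability is >= the cutoff."""
    return np.asarray(pmap) >= threshold


def morph_refine(mask: np.ndarray, enabled: bool = True) -> np.ndarray:
    """Morphological cleanup: 3×3-cross opening, keep largest 8-CC.

    Identity when disabled; never adds pixels; empty in → empty out.
    """
    mask = np.asarray(mask).astype(bool)
    if not enabled or not mask.any():
        return mask.copy()
    opened = ndi.binary_opening(mask, structure=_CROSS)
    if not opened.any():
        return opened
    labels, n = ndi.label(opened, structure=_CONN8)
    if n == 1:
        return opened
    sizes = ndi.sum_labels(opened, labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def roi_window(roi: RoiState, frame_shape: tuple[int, int]) -> tuple[int, int]:
    """Top-left (row, col) of the ROI window clamped inside the frame."""
    h, w = frame_shape
    if h < roi.size or w < roi.size:
        raise ValueError(f"frame {h}x{w} smaller than ROI size {roi.size}")
    cx, cy = roi.center
    top = int(np.clip(round(cy - roi.size / 2), 0, h - roi.size))
    left = int(np.clip(round(cx - roi.size / 2), 0, w - roi.size))
    return top, left


def measure_mask(mask: np.ndarray, roi: RoiState, frame_shape: tuple[int, int] | None = None):
    """Pixel-count area and source-frame centroid of a binary ROI mask.

    Returns ``(area, centroid)`` with ``centroid`` None when the mask is
    empty.  When ``frame_shape`` is given, the ROI window is clamped to it
    before mapping coordinates; otherwise the window's nominal top-left
    (center − size/2, unclamped) is used.
    """
    mask = np.asarray(mask).astype(bool)
    area = int(mask.sum())
    if area == 0:
        return 0, None
    if frame_shape is not None:
        top, left = roi_window(roi, frame_shape)
    else:
        top = round(roi.center[1] - roi.size / 2)
        left = round(roi.center[0] - roi.size / 2)
    ys, xs = np.nonzero(mask)
    return area, (float(xs.mean() + left), float(ys.mean() + top))


def step(
    frame: np.ndarray,
    model,
    roi: RoiState,
    pre: PreprocSettings,
    post: PostprocSettings,
    frame_index: int = 0,
    time_s: float = 0.0,
    triggers: tuple[bool, bool, bool, bool] = (False, False, False, False),
) -> tuple[FrameMeasure, RoiState]:
    """Process one frame: crop → preprocess → predict → threshold → morph → measure.

    ``model`` is anything exposing ``predict(image) -> Prediction``.  With
    ``follow`` on and a nonempty mask, the returned ROI is re-centered on
    the measured centroid (clamped to the frame).
    """
    frame = np.asarray(frame, dtype=float)
    top, left = roi_window(roi, frame.shape)
    crop = frame[top:top + roi.size, left:left + roi.size]
    pred: Prediction = model.predict(apply_preprocess(crop, pre))
    mask = morph_refine(threshold_map(pred.pupil_map, post.threshold), post.morphology)
    area = int(mask.sum())
    if area > 0:
        ys, xs = np.nonzero(mask)
        centroid = (float(xs.mean() + left), float(ys.mean() + top))
    else:
        centroid = None
    new_roi = roi
    if roi.follow and centroid is not None:
        h, w = frame.shape
        half = roi.size / 2
        cx = float(np.clip(centroid[0], half, w - half))
        cy = float(np.clip(centroid[1], half, h - half))
        new_roi = replace(roi, center=(cx, cy))
    measure = FrameMeasure(
        frame=frame_index,
        time_s=time_s,
        pupil_area=float(area),
        centroid=centroid,
        eye_prob=pred.eye_prob,
        blink_prob=pred.blink_prob,
        triggers=triggers,
    )
    return measure, new_roi


def _iter_frames(source, fps: float | None):
    """Yield grayscale float frames; returns (iterator, fps, count or None)."""
    path = Path(source)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff", ".jpg", ".jpeg")
        )
        if not files:
            raise ValueError(f"no image frames found in {path}")

        def gen():
            for f in files:
                yield _to_gray(iio.imread(f))

        return gen(), fps or 30.0, len(files)
    if not path.exists():
        raise IOError(f"cannot read video source {path}")
    try:
        if fps is None:
            meta = iio.immeta(path)
            fps = float(meta.get("fps", 30.0))
        frames = iio.imiter(path)
    except Exception as exc:  # no suitable backend for this container
        raise IOError(f"cannot open video container {path}: {exc}") from exc
    return (_to_gray(f) for f in frames), fps, None


def _to_gray(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    if arr.dtype != float:
        arr = arr.astype(float)
    if arr.max() > 1.0:
        arr = arr / 255.0
    return arr


def triggers_from_events(events, n_frames: int, fps: float) -> np.ndarray:
    """Expand (time_s, channel[, duration_s]) rows into per-frame booleans.

    Channels are 1-based (1–4); a missing duration marks a single frame.
    """
    trig = np.zeros((n_frames, 4), dtype=bool)
    for row in events:
        t0, ch = float(row[0]), int(row[1])
        dur = float(row[2]) if len(row) > 2 else 1.0 / fps
        if not 1 <= ch <= 4:
            raise ValueError(f"trigger channel {ch} out of range 1-4")
        i0 = int(np.ceil(t0 * fps - 1e-9))
        i1 = int(np.ceil((t0 + dur) * fps - 1e-9))
        trig[max(i0, 0):min(max(i1, i0 + 1), n_frames), ch - 1] = True
    return trig


def run_video(
    source,
    model,
    preset: str | None = None,
    threshold: float | None = None,
    morphology: bool | None = None,
    pre: PreprocSettings | None = None,
    follow: bool = True,
    fps: float | None = None,
    roi_center: tuple[float, float] | None = None,
    events=None,
    progress_every: int = 1000,
    log=None,
) -> PupilTrace:
    """Run the pipeline over a video file or frame directory.

    ``preset`` selects the species defaults (see :data:`PRESETS`);
    explicit ``threshold`` / ``morphology`` override it.  ``events`` is an
    iterable of (time_s, channel[, duration_s]) trigger rows.
    """
    if preset is not None:
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
        p_thr, p_morph = PRESETS[preset]
    else:
        p_thr, p_morph = 0.5, True
    post = PostprocSettings(
        threshold=p_thr if threshold is None else threshold,
        morphology=p_morph if morphology is None else morphology,
    )
    pre = pre or PreprocSettings()

    frames, fps, _ = _iter_frames(source, fps)
    measures = []
    roi = None
    collected = []
    for i, frame in enumerate(frames):
        if roi is None:
            h, w = frame.shape
            center = roi_center or ((w - 1) / 2, (h - 1) / 2)
            size = min(128, h, w)
            roi = RoiState(center=center, size=size, follow=follow)
        m, roi = step(frame, model, roi, pre, post, frame_index=i, time_s=i / fps)
        collected.append(m)
        if log is not None and (i + 1) % progress_every == 0:
            log(f"processed {i + 1} frames")
    if not collected:
        raise ValueError("source contained zero frames")
    if events is not None:
        trig = triggers_from_events(events, len(collected), fps)
        for i, m in enumerate(collected):
            collected[i] = FrameMeasure(
                frame=m.frame, time_s=m.time_s, pupil_area=m.pupil_area,
                centroid=m.centroid, eye_prob=m.eye_prob, blink_prob=m.blink_prob,
                triggers=tuple(bool(t) for t in trig[i]),
            )
    measures = collected
    return PupilTrace.from_measures(measures, fps)
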
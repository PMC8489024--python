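"""Seeded renderer of synthetic eye images, datasets, and dynamic sequences.

The generator emulates the three imaging regimes the segmentation network
must handle — IR-lit dark-pupil mice, bright-pupil mice under two-photon
imaging (IR backscatter inverts the pupil/iris contrast), and IR-lit human
eyes — each as a sclera disk, a concentric iris disk, an elliptical pupil
at the stated polarity, optional specular spots, eyelid occlusion from the
top, and additive Gaussian noise.  Every frame carries exact ground truth:
the binary pupil mask, an eye-present flag, and a blink flag.

Geometry convention (used across the whole package): 0-based pixel
coordinates, x right, y down, pixel centers at integer coordinates.  A
pixel belongs to an ellipse iff its center satisfies the ellipse
inequality — this is the rasterization rule every mask-area oracle in the
test suite is written against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import imageio.v3 as iio
import numpy as np

from .trace import PupilTrace

#: An eye with eyelid_openness below this fraction is labeled a blink.
#: Human raters flag blinks on visually (near-)closed frames; 0.15 marks
#: frames where the palpebral opening has all but vanished.
BLINK_OPENNESS_CUTOFF = 0.15

#: Class tags for the three imaging regimes.
CLASSES = ("mouse", "2P-mouse", "human")


@dataclass
class EyeAppearance:
    """Static parameters of one rendered eye.

    Intensities are gray levels in [0, 1]; lengths are pixels.  The iris
    disk is concentric with the pupil, so the pupil stays inside the iris
    whenever ``max(pupil_semi_axes) <= iris_radius``.
    """

    image_size: int = 128
    pupil_center: tuple[float, float] = (64.0, 64.0)  # (x, y)
    pupil_semi_axes: tuple[float, float] = (16.0, 13.0)  # (a, b)
    pupil_angle: float = 0.0  # radians
    pupil_polarity: str = "dark"  # "dark" or "bright"
    iris_radius: float = 42.0
    iris_level: float = 0.45
    pupil_level: float = 0.08
    sclera_level: float = 0.75
    eyelid_openness: float = 1.0  # 0 = fully closed
    specular_spot_count: int = 0
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        a, b = self.pupil_semi_axes
        if a <= 0 or b <= 0:
            raise ValueError("pupil semi-axes must be positive")
        if self.pupil_polarity not in ("dark", "bright"):
            raise ValueError("pupil_polarity must be 'dark' or 'bright'")
        if self.pupil_polarity == "dark" and not self.pupil_level < self.iris_level:
            raise ValueError("dark polarity requires pupil_level < iris_level")
        if self.pupil_polarity == "bright" and not self.pupil_level > self.iris_level:
            raise ValueError("bright polarity requires pupil_level > iris_level")
        if max(a, b) > self.iris_radius:
            raise ValueError("pupil ellipse must fit inside the iris disk")
        if not 0 <= self.eyelid_openness <= 1:
            raise ValueError("eyelid_openness must be in [0, 1]")
        if self.specular_spot_count < 0:
            raise ValueError("specular_spot_count must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class LabeledFrame:
    """A grayscale eye image with its supervised targets.

    Invariants: a blink frame has an all-zero mask; a nonzero mask implies
    an eye is present.  ``class_tag`` is generator bookkeeping (which
    imaging regime produced the frame), not a supervised target.
    """

    image: np.ndarray  # (S, S) float in [0, 1]
    mask: np.ndarray  # (S, S) bool, True = pupil
    eye_present: bool
    blink: bool
    class_tag: str | None = None

    def __post_init__(self) -> None:
        if self.blink and self.mask.any():
            raise ValueError("blink frame must have an empty mask")
        if self.mask.any() and not self.eye_present:
            raise ValueError("nonzero mask implies eye_present")


def ellipse_area(a: float, b: float) -> float:
    """Exact area pi*a*b of an ellipse with semi-axes ``a``, ``b`` (px)."""
    if a <= 0 or b <= 0:
        raise ValueError("semi-axes must be positive")
    return math.pi * a * b


def ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    semi_axes: tuple[float, float],
    angle: float = 0.0,
) -> np.ndarray:
    """Rasterize an ellipse by the pixel-center rule.

    A pixel (x, y) is inside iff its center satisfies
    ``(u/a)^2 + (v/b)^2 <= 1`` where (u, v) are the pixel-center offsets
    from ``center`` rotated by ``-angle``.
    """
    h, w = shape
    cx, cy = center
    a, b = semi_axes
    y, x = np.mgrid[0:h, 0:w]
    dx = x - cx
    dy = y - cy
    ca, sa = math.cos(angle), math.sin(angle)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def render_frame(appearance: EyeAppearance, seed: int = 0) -> LabeledFrame:
    """Render one labeled frame from an :class:`EyeAppearance`.

    Painting order: sclera background, iris disk, pupil ellipse, specular
    spots, eyelid (covering the top ``1 - eyelid_openness`` fraction of
    rows), then additive Gaussian noise clipped to [0, 1].  The mask is
    the visible (non-occluded) pupil ellipse; a frame whose openness falls
    below :data:`BLINK_OPENNESS_CUTOFF` is flagged a blink and its mask is
    empty (a blink's pupil is ground-truth invisible).
    """
    app = appearance
    rng = np.random.default_rng(seed)
    s = app.image_size
    img = np.full((s, s), app.sclera_level, dtype=float)

    cx, cy = app.pupil_center
    y, x = np.mgrid[0:s, 0:s]
    iris = (x - cx) ** 2 + (y - cy) ** 2 <= app.iris_radius**2
    img[iris] = app.iris_level

    pupil = ellipse_mask((s, s), app.pupil_center, app.pupil_semi_axes, app.pupil_angle)
    img[pupil] = app.pupil_level

    for _ in range(app.specular_spot_count):
        r = app.iris_radius * 0.7 * math.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * math.pi)
        sx, sy = cx + r * math.cos(th), cy + r * math.sin(th)
        rad = rng.uniform(1.0, 3.0)
        spot = (x - sx) ** 2 + (y - sy) ** 2 <= rad**2
        img[spot] = 1.0

    lid_rows = int(round((1.0 - app.eyelid_openness) * s))
    if lid_rows > 0:
        img[:lid_rows, :] = 0.85 * app.sclera_level  # lid skin tone
        pupil = pupil.copy()
        pupil[:lid_rows, :] = False

    if app.noise_sigma > 0:
        img = img + rng.normal(0.0, app.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    blink = app.eyelid_openness < BLINK_OPENNESS_CUTOFF
    if blink:
        pupil = np.zeros_like(pupil)
    return LabeledFrame(image=img, mask=pupil, eye_present=True, blink=blink)


def _sample_appearance(rng: np.random.Generator, class_tag: str, blink: bool) -> EyeAppearance:
    """Draw one appearance from the class's population statistics."""
    size = 128
    cx, cy = 64.0 + rng.uniform(-16, 16, size=2)
    a = rng.uniform(10.0, 24.0)
    b = a * rng.uniform(0.65, 1.0)
    angle = rng.uniform(0.0, math.pi)
    iris_radius = max(a, b) + rng.uniform(10.0, 22.0)
    if class_tag == "mouse":
        pupil_level = rng.uniform(0.02, 0.12)
        iris_level = rng.uniform(0.30, 0.55)
        sclera_level = rng.uniform(0.35, 0.60)
        polarity, spots = "dark", int(rng.integers(0, 2))
    elif class_tag == "2P-mouse":
        pupil_level = rng.uniform(0.70, 0.95)
        iris_level = rng.uniform(0.10, 0.35)
        sclera_level = rng.uniform(0.15, 0.40)
        polarity, spots = "bright", 0
    elif class_tag == "human":
        pupil_level = rng.uniform(0.02, 0.12)
        iris_level = rng.uniform(0.25, 0.50)
        sclera_level = rng.uniform(0.65, 0.90)
        polarity, spots = "dark", int(rng.integers(0, 4))
    else:
        raise ValueError(f"unknown class tag {class_tag!r}")
    openness = rng.uniform(0.0, 0.12) if blink else rng.uniform(0.6, 1.0)
    return EyeAppearance(
        image_size=size,
        pupil_center=(float(cx), float(cy)),
        pupil_semi_axes=(float(a), float(b)),
        pupil_angle=float(angle),
        pupil_polarity=polarity,
        iris_radius=float(iris_radius),
        iris_level=float(iris_level),
        pupil_level=float(pupil_level),
        sclera_level=float(sclera_level),
        eyelid_openness=float(openness),
        specular_spot_count=spots,
        noise_sigma=float(rng.uniform(0.01, 0.05)),
    )


def make_training_set(
    n: int,
    mix: dict[str, float] | None = None,
    blink_fraction: float = 0.134,
    seed: int = 0,
) -> list[LabeledFrame]:
    """Generate ``n`` labeled frames mixing the three imaging regimes.

    ``mix`` maps class tags (``mouse``, ``2P-mouse``, ``human``) to
    fractions summing to 1; the default matches the composition of the
    annotated deposit (roughly 43% dark-pupil mouse, 21% two-photon mouse,
    36% human).  ``blink_fraction`` defaults to the deposit's blink rate
    (1596 of 11,897 images).  Fixed seed gives bit-identical output.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mix is None:
        mix = {"mouse": 0.43, "2P-mouse": 0.21, "human": 0.36}
    tags = list(mix)
    probs = np.array([mix[t] for t in tags], dtype=float)
    if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("mix fractions must be nonnegative and sum to 1")
    if not 0 <= blink_fraction <= 1:
        raise ValueError("blink_fraction must be in [0, 1]")
    for t in tags:
        if t not in CLASSES:
            raise ValueError(f"unknown class tag {t!r}")
    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(n):
        tag = tags[rng.choice(len(tags), p=probs)]
        blink = bool(rng.uniform() < blink_fraction)
        app = _sample_appearance(rng, tag, blink)
        frame = render_frame(app, seed=int(rng.integers(0, 2**31)))
        frame.class_tag = tag
        frames.append(frame)
    return frames


@dataclass
class SequenceSpec:
    """Recipe for a dynamic eye sequence with analytic ground truth.

    Pupil area (px²) follows ``baseline_area`` plus a sum of event
    kernels — each a double-exponential transient ``(onset s, peak
    fractional dilation, rise tau s, decay tau s)`` normalized so its peak
    equals ``peak × baseline_area`` — plus an optional seeded random walk
    (``drift_sigma`` px² per step).  Blink epochs are half-open intervals
    ``[onset, onset + duration)`` in seconds; frames whose time falls
    inside are rendered closed.  The pupil center moves linearly from
    ``center_start`` to ``center_end`` (both default to the template's
    center) over the sequence, letting tracking experiments drift the eye.
    """

    fps: float = 30.0
    duration: float = 40.0
    baseline_area: float = 450.0
    events: list[tuple[float, float, float, float]] = field(default_factory=list)
    blink_epochs: list[tuple[float, float]] = field(default_factory=list)
    drift_sigma: float = 0.0
    seed: int = 0
    appearance: EyeAppearance | None = None
    center_start: tuple[float, float] | None = None
    center_end: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.baseline_area <= 0:
            raise ValueError("baseline_area must be positive")
        for onset, dur in self.blink_epochs:
            if not (0 <= onset and onset + dur <= self.duration):
                raise ValueError("blink epochs must lie within [0, duration]")


def _event_kernel(t: np.ndarray, onset: float, peak: float, tau_r: float, tau_d: float) -> np.ndarray:
    """Double-exponential transient, unit peak scaled to ``peak`` (fraction)."""
    dt = t - onset
    out = np.zeros_like(t)
    pos = dt > 0
    if tau_r <= 0 or tau_d <= 0:
        raise ValueError("time constants must be positive")
    if abs(tau_r - tau_d) < 1e-12:
        # alpha function: peak 1 at dt = tau
        out[pos] = (dt[pos] / tau_r) * np.exp(1.0 - dt[pos] / tau_r)
        return peak * out
    if tau_r > tau_d:
        tau_r, tau_d = tau_d, tau_r
    u = np.exp(-dt[pos] / tau_d) - np.exp(-dt[pos] / tau_r)
    t_star = tau_r * tau_d / (tau_d - tau_r) * math.log(tau_d / tau_r)
    norm = math.exp(-t_star / tau_d) - math.exp(-t_star / tau_r)
    out[pos] = u / norm
    return peak * out


def _blink_frames(n: int, fps: float, epochs: list[tuple[float, float]]) -> np.ndarray:
    flags = np.zeros(n, dtype=bool)
    for onset, dur in epochs:
        i0 = int(math.ceil(onset * fps - 1e-9))
        i1 = int(math.ceil((onset + dur) * fps - 1e-9))
        flags[max(i0, 0):min(i1, n)] = True
    return flags


def make_sequence(spec: SequenceSpec) -> tuple[list[LabeledFrame], PupilTrace]:
    """Render a dynamic sequence and its exact ground-truth trace.

    The returned :class:`PupilTrace` carries the analytic per-frame pupil
    area (baseline + events + drift), the true pupil center, and
    ``blink_prob`` 1.0 on blink frames (whose area is ground-truth
    invalid: the eye is closed, so no area is observable).
    """
    n = int(round(spec.duration * spec.fps))
    t = np.arange(n) / spec.fps
    rng = np.random.default_rng(spec.seed)

    area = np.full(n, spec.baseline_area)
    for onset, peak, tau_r, tau_d in spec.events:
        area = area + spec.baseline_area * _event_kernel(t, onset, peak, tau_r, tau_d)
    if spec.drift_sigma > 0:
        area = area + np.cumsum(rng.normal(0.0, spec.drift_sigma, size=n))
    area = np.maximum(area, 1.0)

    template = spec.appearance or EyeAppearance()
    a0, b0 = template.pupil_semi_axes
    rho = a0 / b0  # aspect ratio held constant while area varies
    c0 = np.array(spec.center_start or template.pupil_center, dtype=float)
    c1 = np.array(spec.center_end or c0, dtype=float)
    frac = t / t[-1] if n > 1 else np.zeros(1)
    centers = c0[None, :] + (c1 - c0)[None, :] * frac[:, None]

    blink = _blink_frames(n, spec.fps, spec.blink_epochs)

    frames = []
    for i in range(n):
        a = math.sqrt(area[i] * rho / math.pi)
        b = a / rho
        app = replace(
            template,
            pupil_center=(float(centers[i, 0]), float(centers[i, 1])),
            pupil_semi_axes=(a, b),
            iris_radius=max(template.iris_radius, a + 4.0),
            eyelid_openness=0.05 if blink[i] else template.eyelid_openness,
        )
        frames.append(render_frame(app, seed=int(rng.integers(0, 2**31))))

    truth = PupilTrace(
        fps=spec.fps,
        frame=np.arange(n),
        time_s=t,
        area_px=area,
        pupil_x=centers[:, 0].copy(),
        pupil_y=centers[:, 1].copy(),
        eye_prob=np.ones(n),
        blink_prob=blink.astype(float),
    )
    return frames, truth


def write_dataset(frames: list[LabeledFrame], outdir) -> None:
    """Write frames as 8-bit grayscale PNGs plus a sidecar index CSV.

    Layout: ``images/NNNNN.png``, ``masks/NNNNN.png`` (255 = pupil), and
    ``index.csv`` with columns filename, class, blink, eye_present, mask.
    """
    from pathlib import Path

    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    rows = ["filename,class,blink,eye_present,mask"]
    for i, f in enumerate(frames):
        name = f"{i:05d}.png"
        iio.imwrite(outdir / "images" / name, np.round(f.image * 255).astype(np.uint8))
        iio.imwrite(outdir / "masks" / name, (f.mask.astype(np.uint8) * 255))
        rows.append(
            f"images/{name},{f.class_tag or ''},{int(f.blink)},{int(f.eye_present)},masks/{name}"
        )
    (outdir / "index.csv").write_text("\n".join(rows) + "\n")


def write_sequence_truth(truth: PupilTrace, path) -> None:
    """Write a ground-truth CSV (frame, time_s, area_px, blink)."""
    with open(path, "w") as fh:
        fh.write("frame,time_s,area_px,blink\n")
        for i in range(len(truth)):
            fh.write(
                f"{int(truth.frame[i])},{truth.time_s[i]:.6g},"
                f"{truth.area_px[i]:.6g},{int(truth.blink_prob[i] >= 0.5)}\n"
            )
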
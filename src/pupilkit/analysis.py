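"""Pupillometric time-series analysis.

Implements the standard post-processing of pupil traces: blink-epoch
detection from the network's blink probability, blink removal by linear
interpolation plus 0.5 s median filtering, per-trial z-scoring against a
pre-stimulus baseline, event-related transient (ERT) extraction, a
velocity-threshold locomotion state (moving ⇔ speed ≥ 10% of the session
maximum), pointwise post-onset significance with Benjamini–Hochberg FDR
correction, and agreement between traces from two devices via min–max
normalization to [−1, 1], linear upsampling to the faster grid, and mean
absolute error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.ndimage import median_filter
from statsmodels.stats.multitest import multipletests

from .trace import PupilTrace


@dataclass(frozen=True)
class BlinkEpoch:
    """Half-open frame interval [start, end) flagged as a blink."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("blink epoch requires start < end")


@dataclass
class TrialMatrix:
    """Event-aligned trials × timepoints array on a common frame grid.

    ``time_s`` is relative to event onset (0 at onset); the baseline
    window ``[t0, t1)`` precedes the onset and is the reference for
    z-scoring and pointwise comparisons.
    """

    values: np.ndarray  # (n_trials, n_time)
    time_s: np.ndarray  # (n_time,)
    baseline: tuple[float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.time_s = np.asarray(self.time_s, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != self.time_s.size:
            raise ValueError("values must be (n_trials, n_time) matching time_s")
        t0, t1 = self.baseline
        if not t0 < t1 or t1 > 0:
            raise ValueError("baseline window must be nonempty and precede onset")
        if not self.baseline_cols().any():
            raise ValueError("baseline window contains no samples")

    def baseline_cols(self) -> np.ndarray:
        t0, t1 = self.baseline
        return (self.time_s >= t0) & (self.time_s < t1)


def blink_epochs(trace: PupilTrace, cutoff: float = 0.5, merge_gap: int = 2) -> list[BlinkEpoch]:
    """Maximal runs of frames with blink probability >= ``cutoff``.

    Runs separated by fewer than ``merge_gap`` non-blink frames are merged
    (avoids flickering micro-epochs around a real blink).
    """
    flags = np.asarray(trace.blink_prob) >= cutoff
    if not flags.any():
        return []
    padded = np.concatenate([[False], flags, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    merged: list[list[int]] = [[int(starts[0]), int(ends[0])]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] < merge_gap:
            merged[-1][1] = int(e)
        else:
            merged.append([int(s), int(e)])
    return [BlinkEpoch(s, e) for s, e in merged]


def deblink(trace: PupilTrace, epochs: list[BlinkEpoch],
            median_window_s: float = 0.5) -> PupilTrace:
    """Fill blink epochs by linear interpolation, then median-filter.

    Area samples inside each epoch are replaced by linear interpolation
    between the nearest valid neighbors (edge epochs are held at the
    nearest valid value), after which the whole area trace is median
    filtered with a window of round(``median_window_s`` · fps) samples,
    forced odd by +1.  A window of 1 sample disables the filter.
    """
    n = len(trace)
    bad = np.zeros(n, dtype=bool)
    for ep in epochs:
        if ep.start < 0 or ep.end > n:
            raise ValueError(f"epoch [{ep.start}, {ep.end}) outside trace of length {n}")
        bad[ep.start:ep.end] = True
    if bad.all():
        raise ValueError("all frames are blinks; nothing to interpolate from")
    area = trace.area_px.astype(float).copy()
    good = ~bad
    idx = np.arange(n)
    area[bad] = np.interp(idx[bad], idx[good], area[good])
    window = int(round(median_window_s * trace.fps))
    if window % 2 == 0:
        window += 1
    if window > 1:
        area = median_filter(area, size=window, mode="nearest")
    return trace.replace_area(area)


def zscore_trials(m: TrialMatrix, ddof: int = 1) -> TrialMatrix:
    """Per-trial z-score against the trial's own baseline mean and SD.

    Trials with zero baseline SD cannot be normalized; they are dropped
    with a warning.
    """
    cols = m.baseline_cols()
    base = m.values[:, cols]
    mu = base.mean(axis=1)
    sd = base.std(axis=1, ddof=ddof)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"excluding {np.count_nonzero(~keep)} trial(s) with zero baseline SD",
            stacklevel=2,
        )
    z = (m.values[keep] - mu[keep, None]) / sd[keep, None]
    return TrialMatrix(values=z, time_s=m.time_s, baseline=m.baseline)


def event_align(
    trace: PupilTrace,
    events: list[float],
    window: tuple[float, float] = (7.5, 7.5),
    baseline: tuple[float, float] | None = None,
    column: str = "area_px",
) -> TrialMatrix:
    """Cut event-aligned trials out of a trace on its own frame grid.

    ``window`` is (seconds before, seconds after) the event onset; the
    default 7.5 + 7.5 reproduces a 15 s window centered on stimulation.
    ``baseline`` defaults to the full pre-onset half.  Events whose window
    does not fit inside the trace are dropped with a warning.
    """
    pre_s, post_s = window
    if pre_s < 0 or post_s <= 0:
        raise ValueError("window must extend before and after the onset")
    fps = trace.fps
    n_pre = int(round(pre_s * fps))
    n_post = int(round(post_s * fps))
    values = np.asarray(getattr(trace, column), dtype=float)
    rows = []
    for t_event in events:
        i0 = int(round(t_event * fps)) - n_pre
        i1 = i0 + n_pre + n_post
        if i0 < 0 or i1 > len(trace):
            warnings.warn(f"event at {t_event} s: window outside trace, dropped", stacklevel=2)
            continue
        rows.append(values[i0:i1])
    if not rows:
        raise ValueError("no event window fits inside the trace")
    time_s = (np.arange(n_pre + n_post) - n_pre) / fps
    if baseline is None:
        baseline = (-pre_s, 0.0)
    return TrialMatrix(values=np.stack(rows), time_s=time_s, baseline=baseline)


def locomotion_state(velocity: np.ndarray, fraction: float = 0.10) -> np.ndarray:
    """Moving ⇔ speed at or above ``fraction`` of the session maximum.

    An all-zero velocity trace yields all-stationary (no movement to key
    the threshold on).
    """
    v = np.asarray(velocity, dtype=float)
    if v.size == 0:
        raise ValueError("empty velocity trace")
    vmax = v.max()
    if vmax <= 0:
        return np.zeros(v.size, dtype=bool)
    return v >= fraction * vmax


def pointwise_significance(m: TrialMatrix, alpha: float = 0.05):
    """Post-onset pointwise comparison against the baseline, BH-corrected.

    For each timepoint after onset, the trial values are compared with the
    trials' own baseline means by a paired t test; the resulting family of
    p values is Benjamini–Hochberg adjusted across timepoints.  Returns
    ``(times, p_adjusted, significant_mask)``.
    """
    if m.values.shape[0] < 3:
        raise ValueError("need at least 3 trials for the paired comparison")
    base_mean = m.values[:, m.baseline_cols()].mean(axis=1)
    post = m.time_s >= 0
    if not post.any():
        raise ValueError("no post-onset timepoints")
    pvals = np.empty(np.count_nonzero(post))
    for j, col in enumerate(np.nonzero(post)[0]):
        x = m.values[:, col]
        if np.allclose(x - base_mean, (x - base_mean)[0]):
            pvals[j] = 1.0  # zero-variance difference: no evidence either way
        else:
            pvals[j] = stats.ttest_rel(x, base_mean).pvalue
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return m.time_s[post], p_adj, reject


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p values (convenience wrapper)."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def trace_mae(
    a: np.ndarray, fps_a: float, b: np.ndarray, fps_b: float
) -> float:
    """Agreement of two device traces: normalize, upsample, mean |Δ|.

    Each trace is min–max normalized to [−1, 1]; the lower-rate trace is
    linearly interpolated onto the higher-rate grid over the common time
    support; the mean absolute error is returned.  Constant traces have no
    range to normalize and are rejected.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("traces must have at least 2 samples")

    def norm(x):
        rng = x.max() - x.min()
        if rng == 0:
            raise ValueError("constant trace: zero range, cannot normalize")
        return 2.0 * (x - x.min()) / rng - 1.0

    a, b = norm(a), norm(b)
    ta = np.arange(a.size) / fps_a
    tb = np.arange(b.size) / fps_b
    if fps_a >= fps_b:
        hi_t, hi, lo_t, lo = ta, a, tb, b
    else:
        hi_t, hi, lo_t, lo = tb, b, ta, a
    t_end = min(hi_t[-1], lo_t[-1])
    sel = hi_t <= t_end + 1e-12
    lo_up = np.interp(hi_t[sel], lo_t, lo)
    return float(np.mean(np.abs(hi[sel] - lo_up)))
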
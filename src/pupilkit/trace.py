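"""Pupillometry time-series containers and their CSV dialect.

A :class:`PupilTrace` is the unit of all downstream analysis: one
:class:`FrameMeasure` per video frame at a known, constant nominal frame
rate.  The CSV dialect is bit-exact: the header is always

    frame,time_s,area_px,pupil_x,pupil_y,eye_prob,blink_prob,trig1,trig2,trig3,trig4

floats are written with 6 significant digits, and frames with zero pupil
area leave the centroid columns empty (the centroid is undefined, not at
the origin).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CSV_COLUMNS = (
    "frame",
    "time_s",
    "area_px",
    "pupil_x",
    "pupil_y",
    "eye_prob",
    "blink_prob",
    "trig1",
    "trig2",
    "trig3",
    "trig4",
)

_FLOAT_FMT = "%.6g"


class TraceParseError(ValueError):
    """Raised when a trace CSV cannot be parsed; the message names the line."""


@dataclass
class FrameMeasure:
    """One frame's pupillometry record.

    ``centroid`` is ``None`` when ``pupil_area`` is zero (no pupil pixels —
    e.g. during a blink); coordinates are source-frame pixels, x right,
    y down, 0-based.
    """

    frame: int
    time_s: float
    pupil_area: float
    centroid: tuple[float, float] | None
    eye_prob: float
    blink_prob: float
    triggers: tuple[bool, bool, bool, bool] = (False, False, False, False)

    def __post_init__(self) -> None:
        if self.pupil_area < 0:
            raise ValueError("pupil_area must be >= 0")
        if self.pupil_area == 0 and self.centroid is not None:
            raise ValueError("centroid must be None when area is 0")


@dataclass
class PupilTrace:
    """Time-ordered frame measures at a constant nominal frame rate.

    Internally columnar: NumPy arrays of equal length.  ``pupil_x`` /
    ``pupil_y`` are NaN where ``area_px`` is zero.
    """

    fps: float
    frame: np.ndarray
    time_s: np.ndarray
    area_px: np.ndarray
    pupil_x: np.ndarray
    pupil_y: np.ndarray
    eye_prob: np.ndarray
    blink_prob: np.ndarray
    triggers: np.ndarray = field(default=None)  # (n, 4) bool

    def __post_init__(self) -> None:
        n = len(self.frame)
        if self.triggers is None:
            self.triggers = np.zeros((n, 4), dtype=bool)
        for name in ("time_s", "area_px", "pupil_x", "pupil_y", "eye_prob", "blink_prob"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name!r} length mismatch")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if n > 1 and not np.all(np.diff(self.time_s) > 0):
            raise ValueError("time_s must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_measures(cls, measures: list[FrameMeasure], fps: float) -> "PupilTrace":
        n = len(measures)
        xs = np.full(n, np.nan)
        ys = np.full(n, np.nan)
        for i, m in enumerate(measures):
            if m.centroid is not None:
                xs[i], ys[i] = m.centroid
        return cls(
            fps=fps,
            frame=np.array([m.frame for m in measures], dtype=int),
            time_s=np.array([m.time_s for m in measures]),
            area_px=np.array([m.pupil_area for m in measures], dtype=float),
            pupil_x=xs,
            pupil_y=ys,
            eye_prob=np.array([m.eye_prob for m in measures]),
            blink_prob=np.array([m.blink_prob for m in measures]),
            triggers=np.array([m.triggers for m in measures], dtype=bool),
        )

    def measures(self) -> list[FrameMeasure]:
        out = []
        for i in range(len(self)):
            area = float(self.area_px[i])
            cent = None if area == 0 or np.isnan(self.pupil_x[i]) else (
                float(self.pupil_x[i]), float(self.pupil_y[i]))
            out.append(FrameMeasure(
                frame=int(self.frame[i]), time_s=float(self.time_s[i]),
                pupil_area=area, centroid=cent,
                eye_prob=float(self.eye_prob[i]), blink_prob=float(self.blink_prob[i]),
                triggers=tuple(bool(t) for t in self.triggers[i]),
            ))
        return out

    def replace_area(self, area: np.ndarray) -> "PupilTrace":
        """A copy of the trace with a new area column (analysis steps use this)."""
        return PupilTrace(
            fps=self.fps, frame=self.frame.copy(), time_s=self.time_s.copy(),
            area_px=np.asarray(area, dtype=float).copy(),
            pupil_x=self.pupil_x.copy(), pupil_y=self.pupil_y.copy(),
            eye_prob=self.eye_prob.copy(), blink_prob=self.blink_prob.copy(),
            triggers=self.triggers.copy(),
        )


def _fmt(x: float) -> str:
    return _FLOAT_FMT % x


def write_csv(trace: PupilTrace, path) -> None:
    """Write a trace to CSV in the documented column order.

    Floats carry 6 significant digits; centroid columns are empty strings
    on zero-area frames; triggers are 0/1.
    """
    with open(path, "w") as fh:
        fh.write("# fps=%s\n" % _fmt(trace.fps))
        fh.write(",".join(CSV_COLUMNS) + "\n")
        for i in range(len(trace)):
            area = trace.area_px[i]
            if area == 0 or np.isnan(trace.pupil_x[i]):
                px, py = "", ""
            else:
                px, py = _fmt(trace.pupil_x[i]), _fmt(trace.pupil_y[i])
            row = [
                str(int(trace.frame[i])),
                _fmt(trace.time_s[i]),
                _fmt(trace.area_px[i]),
                px,
                py,
                _fmt(trace.eye_prob[i]),
                _fmt(trace.blink_prob[i]),
            ] + ["%d" % t for t in trace.triggers[i]]
            fh.write(",".join(row) + "\n")


def read_csv(path) -> PupilTrace:
    """Read a trace CSV written by :func:`write_csv`.

    Raises :class:`TraceParseError` naming the offending line on malformed
    input.
    """
    rows = []
    fps = None
    with open(path) as fh:
        lines = fh.readlines()
    start = 0
    if lines and lines[0].startswith("# fps="):
        fps = float(lines[0].strip().split("=", 1)[1])
        start = 1
    if start >= len(lines) or lines[start].strip() != ",".join(CSV_COLUMNS):
        raise TraceParseError(f"line {start + 1}: expected header {','.join(CSV_COLUMNS)!r}")
    for ln, line in enumerate(lines[start + 1:], start=start + 2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split(",")
        if len(parts) != len(CSV_COLUMNS):
            raise TraceParseError(f"line {ln}: expected {len(CSV_COLUMNS)} fields, got {len(parts)}")
        try:
            rows.append((
                int(parts[0]), float(parts[1]), float(parts[2]),
                float(parts[3]) if parts[3] != "" else np.nan,
                float(parts[4]) if parts[4] != "" else np.nan,
                float(parts[5]), float(parts[6]),
                *(bool(int(p)) for p in parts[7:11]),
            ))
        except ValueError as exc:
            raise TraceParseError(f"line {ln}: {exc}") from exc
    if not rows:
        raise TraceParseError("no data rows")
    arr = list(zip(*rows))
    time_s = np.array(arr[1])
    if fps is None:
        fps = 1.0 / float(np.median(np.diff(time_s))) if len(time_s) > 1 else 1.0
    return PupilTrace(
        fps=fps,
        frame=np.array(arr[0], dtype=int),
        time_s=time_s,
        area_px=np.array(arr[2]),
        pupil_x=np.array(arr[3]),
        pupil_y=np.array(arr[4]),
        eye_prob=np.array(arr[5]),
        blink_prob=np.array(arr[6]),
        triggers=np.array(arr[7:11], dtype=bool).T,
    )
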
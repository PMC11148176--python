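"""Gaze/head data model and signal preprocessing.

Implements the raw-signal layer of the CEA pipeline: pixel-to-degree
conversion that tracks per-sample viewing distance, blink removal,
unfiltered central-difference velocity, duration+velocity saccade
detection, distance-based trial exclusion, and anticipatory-latency
screening.

Conventions
-----------
* Gaze angles are screen-centered degrees of visual angle, +x rightward,
  +y upward (so a positive vertical fixation error means gaze above the
  target).
* Binocular gaze has already been reduced to a single cyclopean point.
* Velocity is a two-point central difference with **no** low-pass
  filtering; at 133 Hz a filter would blunt saccadic peaks more than the
  sampling itself does.
* A blink is any run of invalid samples.  Velocity is never computed
  across the resulting gap, and gaps are never interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from . import config


class InsufficientDataError(ValueError):
    """Raised when a trace is too short for the requested computation."""


class InvalidSampleError(ValueError):
    """Raised for physically impossible samples (e.g. distance <= 0)."""


# ---------------------------------------------------------------------------
# geometry and conversion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenGeometry:
    """Physical screen description used for angular conversion.

    Defaults approximate a 13.5-inch 3:2 laptop panel viewed at 70 cm.
    """

    width_px: int = 3000
    height_px: int = 2000
    width_mm: float = 285.0
    height_mm: float = 190.0
    nominal_distance_mm: float = config.NOMINAL_DISTANCE_MM

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "width_mm", "height_mm",
                     "nominal_distance_mm"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"ScreenGeometry.{name} must be positive")

    @property
    def mm_per_px_x(self) -> float:
        return self.width_mm / self.width_px

    @property
    def mm_per_px_y(self) -> float:
        return self.height_mm / self.height_px


def px_to_deg(
    x_px: np.ndarray | float,
    y_px: np.ndarray | float,
    geometry: ScreenGeometry,
    distance_mm: np.ndarray | float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Convert screen-pixel coordinates to degrees of visual angle.

    Screen-centered, +x rightward, +y upward (pixel rows grow downward).
    ``distance_mm`` may vary per sample so that angular extent tracks the
    actual viewing distance; missing distances fall back to the nominal
    70 cm.
    """
    if distance_mm is None:
        distance_mm = geometry.nominal_distance_mm
    d = np.asarray(distance_mm, dtype=float)
    d = np.where(np.isfinite(d), d, geometry.nominal_distance_mm)
    if np.any(d <= 0):
        raise InvalidSampleError("eye-to-screen distance must be positive")
    cx = geometry.width_px / 2.0
    cy = geometry.height_px / 2.0
    dx_mm = (np.asarray(x_px, dtype=float) - cx) * geometry.mm_per_px_x
    dy_mm = (cy - np.asarray(y_px, dtype=float)) * geometry.mm_per_px_y
    return np.degrees(np.arctan2(dx_mm, d)), np.degrees(np.arctan2(dy_mm, d))


def deg_to_px(
    x_deg: np.ndarray | float,
    y_deg: np.ndarray | float,
    geometry: ScreenGeometry,
    distance_mm: np.ndarray | float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact inverse of :func:`px_to_deg`."""
    if distance_mm is None:
        distance_mm = geometry.nominal_distance_mm
    d = np.asarray(distance_mm, dtype=float)
    dx_mm = np.tan(np.radians(np.asarray(x_deg, dtype=float))) * d
    dy_mm = np.tan(np.radians(np.asarray(y_deg, dtype=float))) * d
    x_px = geometry.width_px / 2.0 + dx_mm / geometry.mm_per_px_x
    y_px = geometry.height_px / 2.0 - dy_mm / geometry.mm_per_px_y
    return x_px, y_px


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

@dataclass
class GazeTrace:
    """Time-stamped cyclopean gaze samples in screen pixels.

    ``gaps`` records (start, end) time intervals where blink runs were
    removed, so downstream velocity computations can mask across them.
    """

    t: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    valid: np.ndarray
    distance_mm: np.ndarray
    geometry: ScreenGeometry
    hz: float = config.GAZE_HZ
    gaps: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.distance_mm = np.asarray(self.distance_mm, dtype=float)
        n = len(self.t)
        if not all(len(a) == n for a in
                   (self.x_px, self.y_px, self.valid, self.distance_mm)):
            raise ValueError("GazeTrace arrays must share one length")
        if n > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("GazeTrace timestamps must strictly increase")

    def __len__(self) -> int:
        return len(self.t)

    def to_deg(self) -> tuple[np.ndarray, np.ndarray]:
        return px_to_deg(self.x_px, self.y_px, self.geometry, self.distance_mm)


@dataclass
class HeadTrace:
    """Head pose samples (33 Hz nominal): yaw/pitch deg, position mm."""

    t: np.ndarray
    yaw_deg: np.ndarray
    pitch_deg: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    hz: float = config.HEAD_HZ

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.yaw_deg = np.asarray(self.yaw_deg, dtype=float)
        self.pitch_deg = np.asarray(self.pitch_deg, dtype=float)
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.y_mm = np.asarray(self.y_mm, dtype=float)
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("HeadTrace timestamps must strictly increase")

    def yaw_at(self, t: np.ndarray) -> np.ndarray:
        """Yaw linearly interpolated onto an arbitrary (gaze) clock."""
        return np.interp(t, self.t, self.yaw_deg)


@dataclass
class TargetTrajectory:
    """Stimulus position over time, in screen-centered degrees.

    ``kind`` + ``params`` make the trajectory serializable; ``position``
    is the dense evaluation used by the extractors.
    """

    kind: str
    onset: float
    offset: float
    params: dict = field(default_factory=dict)
    _fn: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]] | None = None

    def position(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if self._fn is None:
            raise ValueError(f"trajectory of kind {self.kind!r} has no "
                             "position function attached")
        return self._fn(np.asarray(t, dtype=float))


@dataclass
class Saccade:
    """A detected rapid eye movement."""

    onset_t: float
    offset_t: float
    duration: float
    amplitude: float
    peak_velocity: float
    direction: tuple[float, float]
    onset_idx: int
    offset_idx: int


@dataclass
class Trial:
    """One run of one CEA test for one participant."""

    test_id: str
    trial_index: int
    participant_id: str
    group: str
    gaze: GazeTrace
    target: TargetTrajectory
    head: HeadTrace | None = None
    events: list[tuple[str, float]] = field(default_factory=list)
    excluded: bool = False
    exclude_reason: str | None = None
    session: int = 1
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e[1])
        if self.excluded and not self.exclude_reason:
            raise ValueError("excluded trials need a machine-readable reason")

    def event_time(self, label: str) -> float | None:
        for lab, t in self.events:
            if lab == label or lab.split("=", 1)[0] == label:
                return t
        return None

    def event_value(self, label: str) -> str | None:
        for lab, _t in self.events:
            if lab.startswith(label + "="):
                return lab.split("=", 1)[1]
        return None


# ---------------------------------------------------------------------------
# preprocessing operations
# ---------------------------------------------------------------------------

def remove_blinks(trace: GazeTrace) -> GazeTrace:
    """Drop invalid-sample runs and record the removed intervals as gaps.

    Any run of invalid samples counts as a blink (minimum length 0);
    empty output is allowed for an all-invalid trace, whose single gap
    spans the whole trial.
    """
    valid = trace.valid
    if valid.all():
        return trace
    gaps = list(trace.gaps)
    n = len(trace)
    invalid = ~valid
    edges = np.flatnonzero(np.diff(np.concatenate(([False], invalid, [False]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        t0 = trace.t[start - 1] if start > 0 else trace.t[0]
        t1 = trace.t[stop] if stop < n else trace.t[-1]
        gaps.append((float(t0), float(t1)))
    return GazeTrace(
        t=trace.t[valid], x_px=trace.x_px[valid], y_px=trace.y_px[valid],
        valid=np.ones(int(valid.sum()), dtype=bool),
        distance_mm=trace.distance_mm[valid],
        geometry=trace.geometry, hz=trace.hz, gaps=gaps,
    )


def compute_velocity(trace: GazeTrace) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-axis angular velocity (deg/s) by two-point central difference.

    Returns ``(vx, vy, speed)`` aligned with the trace samples.  The first
    and last sample, and any sample whose central-difference window spans
    a removed blink gap (detected as an over-long inter-sample interval),
    are NaN: velocity across a gap is undefined, never interpolated.  No
    smoothing or low-pass filtering is applied.
    """
    if len(trace) < 2:
        raise InsufficientDataError("need at least 2 samples for velocity")
    x_deg, y_deg = trace.to_deg()
    t = trace.t
    n = len(t)
    vx = np.full(n, np.nan)
    vy = np.full(n, np.nan)
    dt = np.diff(t)
    # an interval materially longer than nominal marks a removed gap
    gap_interval = dt > 1.5 / trace.hz
    if n >= 3:
        span = t[2:] - t[:-2]
        vx[1:-1] = (x_deg[2:] - x_deg[:-2]) / span
        vy[1:-1] = (y_deg[2:] - y_deg[:-2]) / span
        bad = gap_interval[:-1] | gap_interval[1:]
        vx[1:-1][bad] = np.nan
        vy[1:-1][bad] = np.nan
    speed = np.hypot(vx, vy)
    return vx, vy, speed


def detect_saccades(
    trace: GazeTrace,
    velocity_threshold: float = config.SACCADE_VELOCITY_DEG_S,
    min_duration: float = config.SACCADE_MIN_DURATION_S,
) -> list[Saccade]:
    """Duration + velocity saccade detection.

    A saccade is a maximal run of consecutive samples whose speed is
    strictly above ``velocity_threshold`` (100 deg/s) and whose span is at
    least ``min_duration`` (50 ms, inclusive).  Runs interrupted by blink
    gaps are never merged — velocity adjacent to a gap is undefined, which
    breaks the run.  Amplitude is the onset-to-offset displacement.
    """
    if len(trace) < 3:
        return []
    _vx, _vy, speed = compute_velocity(trace)
    x_deg, y_deg = trace.to_deg()
    above = np.zeros(len(trace), dtype=bool)
    finite = np.isfinite(speed)
    above[finite] = speed[finite] > velocity_threshold
    edges = np.flatnonzero(np.diff(np.concatenate(([False], above, [False]))))
    out: list[Saccade] = []
    for start, stop in zip(edges[::2], edges[1::2]):
        i, j = int(start), int(stop) - 1
        duration = float(trace.t[j] - trace.t[i])
        if duration < min_duration:
            continue
        dx = float(x_deg[j] - x_deg[i])
        dy = float(y_deg[j] - y_deg[i])
        amplitude = float(np.hypot(dx, dy))
        direction = (dx / amplitude, dy / amplitude) if amplitude > 0 else (0.0, 0.0)
        out.append(Saccade(
            onset_t=float(trace.t[i]), offset_t=float(trace.t[j]),
            duration=duration, amplitude=amplitude,
            peak_velocity=float(np.nanmax(speed[i:j + 1])),
            direction=direction, onset_idx=i, offset_idx=j,
        ))
    return out


def saccade_mask(
    trace: GazeTrace,
    saccades: Sequence[Saccade],
    pad_s: float = config.SACCADE_MASK_PAD_S,
    pre_pad_s: float | None = None,
) -> np.ndarray:
    """Boolean keep-mask that drops samples inside padded saccade windows.

    ``pre_pad_s`` widens the window before onset only — pursuit analyses
    use it to also exclude the pre-saccadic error build-up that a
    catch-up saccade corrects.
    """
    pre = pad_s if pre_pad_s is None else pre_pad_s
    keep = np.ones(len(trace), dtype=bool)
    for s in saccades:
        keep &= ~((trace.t >= s.onset_t - pre) & (trace.t <= s.offset_t + pad_s))
    return keep


def screen_distance_filter(
    trial: Trial,
    min_mm: float = config.DISTANCE_MIN_MM,
    max_mm: float = config.DISTANCE_MAX_MM,
) -> Trial:
    """Flag a trial excluded if any valid sample left the tracker's range.

    The Tobii measurement volume spans roughly 500–950 mm; outside it the
    gaze estimate is unreliable, so the whole trial is dropped.  Idempotent.
    """
    if trial.excluded:
        return trial
    d = trial.gaze.distance_mm[trial.gaze.valid]
    if d.size and (np.any(d < min_mm) or np.any(d > max_mm)):
        return replace(trial, excluded=True, exclude_reason="out_of_range")
    return trial


def saccade_latency(
    trial: Trial,
    cue_label: str = "secondary_onset",
    floor_s: float = config.LATENCY_FLOOR_S,
    saccades: Sequence[Saccade] | None = None,
) -> tuple[float | None, str]:
    """Latency of the first detected saccade after a cue event.

    Returns ``(latency_s, flag)`` where flag is ``"ok"``, ``"anticipatory"``
    (latency strictly below the 60 ms floor — the gaze was already moving,
    like a false start) or ``"missing"`` (no saccade after the cue).  A
    latency of exactly 60 ms is retained.
    """
    cue_t = trial.event_time(cue_label)
    if cue_t is None:
        raise ValueError(f"trial has no {cue_label!r} event")
    if saccades is None:
        saccades = detect_saccades(trial.gaze)
    after = [s for s in saccades if s.onset_t >= cue_t]
    if not after:
        return None, "missing"
    latency = after[0].onset_t - cue_t
    if latency < floor_s:
        return float(latency), "anticipatory"
    return float(latency), "ok"


def preprocess_trial(trial: Trial) -> Trial:
    """Standard preprocessing: blink removal then distance screening."""
    trial = replace(trial, gaze=remove_blinks(trial.gaze))
    return screen_distance_filter(trial)
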
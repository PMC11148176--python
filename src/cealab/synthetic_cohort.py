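"""Synthetic CEA cohort generator.

Produces complete gaze + head + event trial sets for the six-test battery
(egocentric localisation, fixation stability, smooth pursuit, pro/anti
saccades, gaze Stroop, VOR) under per-group generative presets for the
control, mTBI and PPCS populations.  The presets encode the published
group-level outcome distributions (fixation vertical error, pursuit
offset/gain, catch-up saccade rate, VOR gaze stability); quantities the
literature source does not print (e.g. Stroop latencies) are fixed,
field-plausible defaults documented in the methods note.

Every simulated trial records its latent generating parameters in
``Trial.ground_truth`` so extractors can be validated against a known
oracle, and the whole cohort is bit-reproducible from ``CohortSpec.seed``.

Saccade waveforms
-----------------
The battery's detector requires speed > 100 deg/s sustained for >= 50 ms,
which mathematically requires > 5 deg of displacement inside the
suprathreshold run.  Injected saccades therefore use a plateau velocity
profile (raised-cosine ramps) of ~11 deg amplitude and 90 ms duration so
that ground-truth events are recoverable; see docs/methods.md.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

from . import config
from .gaze_core import (
    GazeTrace,
    HeadTrace,
    ScreenGeometry,
    TargetTrajectory,
    Trial,
    deg_to_px,
)

GROUPS = ("control", "mtbi", "ppcs")

TESTS = ("egocentric", "fixation", "pursuit", "saccade", "stroop", "vor")

#: trials per participant per test (battery design)
TRIALS_PER_TEST = {
    "egocentric": 10,
    "fixation": 3,
    "pursuit": 4,
    "saccade": 28,   # 14 pro + 14 anti, randomly interleaved
    "stroop": 30,    # 15 part one + 15 part two
    "vor": 20,       # 10 left + 10 right, alternating
}

STROOP_COLORS = ("red", "blue", "green", "yellow")
#: fixed corner layout: (corner name) -> color
STROOP_CORNER_COLORS = {
    "top_left": "red", "top_right": "blue",
    "bottom_left": "green", "bottom_right": "yellow",
}


# ---------------------------------------------------------------------------
# parameter presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupParams:
    """Per-group generative oculomotor parameters.

    Means/SDs are between-participant unless noted.  ``pursuit_offset``
    describes the magnitude of the participant-constant pursuit error
    vector; ``vor_bcea`` is in log10 minarc^2; rates are events per trial.
    """

    fixation_offset_mean: tuple[float, float]
    fixation_offset_sd: tuple[float, float]
    fixation_jitter_sd: float
    pursuit_offset_mean: float
    pursuit_offset_sd: float
    pursuit_hgain_mean: float
    pursuit_hgain_sd: float
    pursuit_vgain_mean: float
    pursuit_vgain_sd: float
    pursuit_catchup_rate: float
    vor_bcea_mean: float
    vor_bcea_sd: float
    vor_gain_mean: float
    vor_gain_sd: float
    vor_saccade_rate: float
    prosaccade_latency_mean: float
    prosaccade_latency_sd: float
    antisaccade_latency_mean: float
    antisaccade_latency_sd: float
    prosaccade_correct_p: float
    antisaccade_correct_p: float
    stroop_latency_mean: float
    stroop_latency_sd: float
    stroop_correct_p1: float
    stroop_correct_p2: float
    ego_offset_mean: float
    ego_offset_sd: float
    ego_time_mean: float
    ego_time_sd: float

    def __post_init__(self) -> None:
        for name in ("prosaccade_correct_p", "antisaccade_correct_p",
                     "stroop_correct_p1", "stroop_correct_p2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        for name in ("pursuit_catchup_rate", "vor_saccade_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def load_preset(group: str) -> GroupParams:
    """Load the shipped JSON preset for one group."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    text = resources.files("cealab.presets").joinpath(f"{group}.json").read_text()
    d = json.loads(text)
    d["fixation_offset_mean"] = tuple(d["fixation_offset_mean"])
    d["fixation_offset_sd"] = tuple(d["fixation_offset_sd"])
    return GroupParams(**d)


def default_presets() -> dict[str, GroupParams]:
    return {g: load_preset(g) for g in GROUPS}


@dataclass(frozen=True)
class SaccadeWaveformParams:
    """Plateau velocity profile used for every injected saccade.

    ``peak_velocity = amplitude / (plateau_s + ramp_s)``; with the default
    timing an 11.2 deg saccade peaks at 140 deg/s and stays above the
    100 deg/s detection threshold for ~77 ms.
    """

    ramp_s: float = 0.010
    plateau_s: float = 0.070
    amplitude_deg: float = 11.2

    @property
    def duration_s(self) -> float:
        return 2 * self.ramp_s + self.plateau_s

    def peak_velocity(self, amplitude: float | None = None) -> float:
        a = self.amplitude_deg if amplitude is None else amplitude
        return a / (self.plateau_s + self.ramp_s)


WAVEFORM = SaccadeWaveformParams()


def saccade_position(t_rel: np.ndarray, amplitude: float,
                     wf: SaccadeWaveformParams = WAVEFORM) -> np.ndarray:
    """Displacement (0 -> amplitude) of a plateau-profile saccade.

    ``t_rel`` is time since saccade onset; values outside [0, duration]
    clamp to 0 / amplitude.
    """
    r, tp = wf.ramp_s, wf.plateau_s
    vp = amplitude / (tp + r)
    T = wf.duration_s
    t = np.clip(np.asarray(t_rel, dtype=float), 0.0, T)
    pos = np.empty_like(t)
    rise = t < r
    mid = (t >= r) & (t < r + tp)
    fall = t >= r + tp
    # integral of vp*(1-cos(pi t/r))/2
    pos[rise] = vp / 2 * (t[rise] - (r / np.pi) * np.sin(np.pi * t[rise] / r))
    pos[mid] = vp * r / 2 + vp * (t[mid] - r)
    u = T - t[fall]
    pos[fall] = amplitude - vp / 2 * (u - (r / np.pi) * np.sin(np.pi * u / r))
    return pos


def smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3 - 2 * x)


@lru_cache(maxsize=32)
def _gauss_kernel(sigma: float) -> np.ndarray:
    radius = max(1, int(4 * sigma + 0.5))
    k = np.exp(-0.5 * (np.arange(-radius, radius + 1) / sigma) ** 2)
    return k / k.sum()


def smoothed_noise(rng: np.random.Generator, n: int, sd: float,
                   kernel_sigma: float = 3.0) -> np.ndarray:
    """Temporally correlated Gaussian noise with exact marginal SD.

    White noise circularly convolved with a Gaussian kernel and rescaled
    by the kernel's L2 norm, so the sample-to-sample velocity stays small
    while the marginal dispersion equals ``sd``.
    """
    if n == 0:
        return np.zeros(0)
    k = _gauss_kernel(kernel_sigma)
    w = rng.standard_normal(n + len(k))
    sm = np.convolve(w, k, mode="same")[len(k) // 2: len(k) // 2 + n]
    return sm * (sd / np.sqrt(np.sum(k ** 2)))


def window_variance_shrink(n: int, kernel_sigma: float = 3.0) -> float:
    """E[sample variance]/sigma^2 for a length-``n`` window of smoothed noise.

    Short windows of correlated noise under-disperse; generators that must
    realize an exact spatial variance inside a short analysis window (the
    VOR 15-degree window) divide by the square root of this factor.
    """
    k = _gauss_kernel(kernel_sigma)
    # autocorrelation of the kernel, normalized
    ac = np.correlate(k, k, mode="full")
    ac = ac / ac[len(ac) // 2]
    center = len(ac) // 2
    tot = 0.0
    for d in range(1, n):
        rho = ac[center + d] if center + d < len(ac) else 0.0
        tot += (n - d) * rho
    return max(1e-6, 1.0 - 2.0 * tot / (n * (n - 1)))


# ---------------------------------------------------------------------------
# targets
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _lissajous_omega(width: float, height: float, speed: float) -> float:
    """Base angular frequency giving the requested mean path speed."""
    t = np.linspace(0.0, 2 * np.pi, 20001)
    vx = width * np.cos(2 * t)                 # d/dt (w/2) sin(2t)
    vy = 1.5 * height * np.cos(3 * t + np.pi / 2)
    mean_speed_at_unit_omega = float(np.trapezoid(
        np.hypot(vx, vy), t) / (2 * np.pi))
    return speed / mean_speed_at_unit_omega


def lissajous_target(width: float = 11.0, height: float = 6.5,
                     speed: float = 10.0, duration: float = 30.0
                     ) -> TargetTrajectory:
    """Smooth-pursuit stimulus: closed 2:3 Lissajous figure.

    ``x(t) = (width/2) sin(2 w t)``, ``y(t) = (height/2) sin(3 w t + pi/2)``
    with ``w`` calibrated so the time-averaged path speed equals ``speed``
    (a sinusoidal trajectory cannot hold constant speed; the printed
    10 deg/s is read as the mean).
    """
    if min(width, height, speed, duration) <= 0:
        raise ValueError("lissajous parameters must be positive")
    omega = _lissajous_omega(width, height, speed)

    def fn(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return (width / 2 * np.sin(2 * omega * t),
                height / 2 * np.sin(3 * omega * t + np.pi / 2))

    return TargetTrajectory(
        kind="lissajous", onset=0.0, offset=duration,
        params={"width": width, "height": height, "speed": speed,
                "duration": duration, "omega": omega},
        _fn=fn,
    )


def lissajous_velocity(traj: TargetTrajectory, t: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    w = traj.params["width"]
    h = traj.params["height"]
    om = traj.params["omega"]
    return (w * om * np.cos(2 * om * t),
            1.5 * h * om * np.cos(3 * om * t + np.pi / 2))


def point_target(x_deg: float, y_deg: float, duration: float,
                 **extra) -> TargetTrajectory:
    params = {"x": x_deg, "y": y_deg, **extra}

    def fn(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return (np.full_like(t, x_deg, dtype=float),
                np.full_like(t, y_deg, dtype=float))

    return TargetTrajectory(kind="point", onset=0.0, offset=duration,
                            params=params, _fn=fn)


def rebuild_target(kind: str, params: dict) -> TargetTrajectory:
    """Reconstruct a trajectory from its serialized kind + params."""
    if kind == "lissajous":
        return lissajous_target(params["width"], params["height"],
                                params["speed"], params["duration"])
    if kind == "point":
        extra = {k: v for k, v in params.items() if k not in ("x", "y")}
        return point_target(params["x"], params["y"],
                            extra.pop("duration", np.inf), **extra)
    raise ValueError(f"unknown target kind {kind!r}")


# ---------------------------------------------------------------------------
# trace assembly helpers
# ---------------------------------------------------------------------------

def _distance_series(rng: np.random.Generator, n: int, base: float) -> np.ndarray:
    return base + smoothed_noise(rng, n, 3.0, kernel_sigma=30.0)

def _make_trace(t: np.ndarray, x_deg: np.ndarray, y_deg: np.ndarray,
                rng: np.random.Generator, geometry: ScreenGeometry,
                distance_base: float, valid: np.ndarray | None = None,
                ) -> GazeTrace:
    n = len(t)
    distance = _distance_series(rng, n, distance_base)
    x_px, y_px = deg_to_px(x_deg, y_deg, geometry, distance)
    if valid is None:
        valid = np.ones(n, dtype=bool)
    return GazeTrace(t=t, x_px=x_px, y_px=y_px, valid=valid,
                     distance_mm=distance, geometry=geometry)


def _inject_blinks(rng: np.random.Generator, t: np.ndarray,
                   rate_per_s: float = 0.10,
                   protect: list[tuple[float, float]] | None = None,
                   ) -> np.ndarray:
    """Valid-mask with Poisson blink gaps, avoiding protected windows."""
    valid = np.ones(len(t), dtype=bool)
    if len(t) == 0:
        return valid
    duration = t[-1] - t[0]
    for _ in range(rng.poisson(rate_per_s * duration)):
        start = t[0] + rng.uniform(0, duration)
        dur = rng.uniform(0.10, 0.25)
        if protect and any(start < b + 0.1 and start + dur > a - 0.1
                           for a, b in protect):
            continue
        valid &= ~((t >= start) & (t < start + dur))
    return valid


def _gamma_magnitude(rng: np.random.Generator, mean: float, sd: float,
                     clip: float = 5.0) -> float:
    """Nonnegative draw with the requested first two moments (gamma)."""
    if mean <= 0:
        return 0.0
    if sd <= 0:
        return float(mean)
    shape = (mean / sd) ** 2
    scale = sd ** 2 / mean
    return float(min(rng.gamma(shape, scale), clip))


# ---------------------------------------------------------------------------
# per-test simulators
# ---------------------------------------------------------------------------

def draw_latents(params: GroupParams, rng: np.random.Generator) -> dict:
    """Participant-level latent parameters shared by all of their trials."""
    angle = rng.uniform(0, 2 * np.pi)
    return {
        "fix_offset_h": rng.normal(params.fixation_offset_mean[0],
                                   params.fixation_offset_sd[0]),
        "fix_offset_v": rng.normal(params.fixation_offset_mean[1],
                                   params.fixation_offset_sd[1]),
        "pur_offset_mag": _gamma_magnitude(rng, params.pursuit_offset_mean,
                                           params.pursuit_offset_sd),
        "pur_offset_angle": angle,
        "pur_gain_h": rng.normal(params.pursuit_hgain_mean,
                                 params.pursuit_hgain_sd),
        "pur_gain_v": rng.normal(params.pursuit_vgain_mean,
                                 params.pursuit_vgain_sd),
        "vor_bcea_log": rng.normal(params.vor_bcea_mean, params.vor_bcea_sd),
        "vor_gain": float(np.clip(rng.normal(params.vor_gain_mean,
                                             params.vor_gain_sd), 0.5, 1.1)),
        "pro_latency": max(0.12, rng.normal(params.prosaccade_latency_mean,
                                            params.prosaccade_latency_sd)),
        "anti_latency": max(0.12, rng.normal(params.antisaccade_latency_mean,
                                             params.antisaccade_latency_sd)),
        "stroop_latency": max(0.2, rng.normal(params.stroop_latency_mean,
                                              params.stroop_latency_sd)),
        "ego_offset": _gamma_magnitude(rng, params.ego_offset_mean,
                                       params.ego_offset_sd),
        "ego_time": max(0.6, rng.normal(params.ego_time_mean,
                                        params.ego_time_sd)),
        "distance_base": float(np.clip(rng.normal(
            config.NOMINAL_DISTANCE_MM, 30.0), 560.0, 880.0)),
    }


def simulate_fixation_trial(params: GroupParams, latents: dict,
                            rng: np.random.Generator,
                            geometry: ScreenGeometry,
                            duration: float = 10.0) -> dict:
    n = int(round(duration * config.GAZE_HZ))
    t = np.arange(n) / config.GAZE_HZ
    jit = params.fixation_jitter_sd
    x = (latents["fix_offset_h"] + smoothed_noise(rng, n, jit)
         + smoothed_noise(rng, n, 0.08, kernel_sigma=80.0))
    y = (latents["fix_offset_v"] + smoothed_noise(rng, n, jit)
         + smoothed_noise(rng, n, 0.08, kernel_sigma=80.0))
    valid = _inject_blinks(rng, t)
    trace = _make_trace(t, x, y, rng, geometry, latents["distance_base"],
                        valid=valid)
    return {
        "gaze": trace,
        "target": point_target(0.0, 0.0, duration),
        "events": [("target_onset", 0.0)],
        "ground_truth": {
            "true_fix_offset_h": latents["fix_offset_h"],
            "true_fix_offset_v": latents["fix_offset_v"],
        },
    }


def _catchup_event_times(rng: np.random.Generator, n_events: int,
                         duration: float, margin: float = 1.5,
                         min_sep: float = 1.2) -> np.ndarray:
    times: list[float] = []
    for _ in range(200):
        if len(times) == n_events:
            break
        c = rng.uniform(margin, duration - margin)
        if all(abs(c - e) >= min_sep for e in times):
            times.append(c)
    return np.sort(np.array(times))


def simulate_pursuit_trial(params: GroupParams, latents: dict,
                           rng: np.random.Generator,
                           geometry: ScreenGeometry,
                           duration: float = 30.0) -> dict:
    traj = lissajous_target(duration=duration)
    n = int(round(duration * config.GAZE_HZ))
    t = np.arange(n) / config.GAZE_HZ
    tx, ty = traj.position(t)
    off = latents["pur_offset_mag"]
    ang = latents["pur_offset_angle"]
    x = latents["pur_gain_h"] * tx + off * np.cos(ang) + smoothed_noise(rng, n, 0.25)
    y = latents["pur_gain_v"] * ty + off * np.sin(ang) + smoothed_noise(rng, n, 0.25)

    n_catch = rng.poisson(params.pursuit_catchup_rate)
    lag_s = 0.25
    events = _catchup_event_times(rng, n_catch, duration)
    protect = []
    for e in events:
        vx, vy = lissajous_velocity(traj, np.array([e]))
        sp = float(np.hypot(vx[0], vy[0]))
        ux, uy = (-vx[0] / sp, -vy[0] / sp) if sp > 0 else (1.0, 0.0)
        rel = t - e
        lag = WAVEFORM.amplitude_deg * smoothstep(rel / lag_s)
        back = saccade_position(rel - lag_s, WAVEFORM.amplitude_deg)
        disp = lag - back
        x += disp * ux
        y += disp * uy
        protect.append((e, e + lag_s + WAVEFORM.duration_s))
    valid = _inject_blinks(rng, t, protect=protect)
    trace = _make_trace(t, x, y, rng, geometry, latents["distance_base"],
                        valid=valid)
    return {
        "gaze": trace,
        "target": traj,
        "events": [("target_onset", 0.0)],
        "ground_truth": {
            "true_pur_offset": off,
            "true_pur_gain_h": latents["pur_gain_h"],
            "true_pur_gain_v": latents["pur_gain_v"],
            "true_n_catchup": int(len(events)),
            "catchup_times": list(np.round(events, 4)),
        },
    }


def simulate_saccade_trial(params: GroupParams, latents: dict,
                           rng: np.random.Generator,
                           geometry: ScreenGeometry,
                           task: str = "pro") -> dict:
    if task not in ("pro", "anti"):
        raise ValueError("task must be 'pro' or 'anti'")
    duration = 2.2
    n = int(round(duration * config.GAZE_HZ))
    t = np.arange(n) / config.GAZE_HZ
    color_change = rng.uniform(0.5, 1.0)
    secondary_onset = color_change + 0.05
    side = int(rng.integers(0, 2)) * 2 - 1           # -1 left, +1 right
    p = params.prosaccade_correct_p if task == "pro" else params.antisaccade_correct_p
    correct = bool(rng.random() < p)
    lat_mean = latents["pro_latency"] if task == "pro" else latents["anti_latency"]
    latency = max(0.08, rng.normal(lat_mean, 0.02))
    toward = side if task == "pro" else -side
    sign = toward if correct else -toward

    x = smoothed_noise(rng, n, 0.15)
    y = smoothed_noise(rng, n, 0.15)
    onset = secondary_onset + latency
    x += sign * saccade_position(t - onset, WAVEFORM.amplitude_deg)
    trace = _make_trace(t, x, y, rng, geometry, latents["distance_base"])
    side_name = "right" if side > 0 else "left"
    return {
        "gaze": trace,
        "target": point_target(0.0, 0.0, duration, task=task, side=side,
                               secondary_deg=3.0 * side),
        "events": [(f"task={task}", 0.0), ("color_change", color_change),
                   ("secondary_onset", secondary_onset),
                   (f"side={side_name}", secondary_onset)],
        "ground_truth": {"true_latency": latency, "true_correct": correct,
                         "task": task, "side": side},
    }


def _stroop_corner_centers(geometry: ScreenGeometry) -> dict[str, tuple[float, float]]:
    """Corner-block centers in degrees (block = 20% x 20% of the screen)."""
    from .gaze_core import px_to_deg
    frac = config.STROOP_CORNER_ROI_FRAC / 2
    out = {}
    for name, (fx, fy) in {
        "top_left": (frac, frac), "top_right": (1 - frac, frac),
        "bottom_left": (frac, 1 - frac), "bottom_right": (1 - frac, 1 - frac),
    }.items():
        xd, yd = px_to_deg(fx * geometry.width_px, fy * geometry.height_px,
                           geometry)
        out[name] = (float(xd), float(yd))
    return out


def simulate_stroop_trial(params: GroupParams, latents: dict,
                          rng: np.random.Generator,
                          geometry: ScreenGeometry,
                          part: int = 1) -> dict:
    if part not in (1, 2):
        raise ValueError("part must be 1 or 2")
    duration = 3.5
    n = int(round(duration * config.GAZE_HZ))
    t = np.arange(n) / config.GAZE_HZ
    word = STROOP_COLORS[rng.integers(0, 4)]
    font = rng.choice([c for c in STROOP_COLORS if c != word])
    required = word if part == 1 else font
    p = params.stroop_correct_p1 if part == 1 else params.stroop_correct_p2
    correct = bool(rng.random() < p)
    corners = _stroop_corner_centers(geometry)
    color_to_corner = {v: k for k, v in STROOP_CORNER_COLORS.items()}
    final_corner = (color_to_corner[required] if correct else
                    rng.choice([c for c in corners if
                                STROOP_CORNER_COLORS[c] != required]))
    corrected = correct and rng.random() < 0.15
    word_onset = 0.5
    latency = max(0.2, rng.normal(latents["stroop_latency"], 0.08))

    x = smoothed_noise(rng, n, 0.15)
    y = smoothed_noise(rng, n, 0.15)

    def add_saccade(onset: float, frm: tuple[float, float],
                    to: tuple[float, float]) -> None:
        nonlocal x, y
        dx, dy = to[0] - frm[0], to[1] - frm[1]
        amp = float(np.hypot(dx, dy))
        if amp == 0:
            return
        pos = saccade_position(t - onset, amp)
        x += pos * dx / amp
        y += pos * dy / amp

    first_onset = word_onset + latency
    if corrected:
        wrong = rng.choice([c for c in corners if c != final_corner])
        add_saccade(first_onset, (0.0, 0.0), corners[wrong])
        second = first_onset + WAVEFORM.duration_s + 0.15  # brief wrong-corner visit
        add_saccade(second, corners[wrong], corners[final_corner])
    else:
        add_saccade(first_onset, (0.0, 0.0), corners[final_corner])
    trace = _make_trace(t, x, y, rng, geometry, latents["distance_base"])
    return {
        "gaze": trace,
        "target": point_target(0.0, 0.0, duration, part=part, word=word,
                               font_color=font, required_color=required,
                               corner_colors=dict(STROOP_CORNER_COLORS)),
        "events": [(f"part={part}", 0.0), ("word_onset", word_onset)],
        "ground_truth": {"true_latency": latency, "true_correct": correct,
                         "corrected": corrected, "part": part},
    }


def simulate_vor_trial(params: GroupParams, latents: dict,
                       rng: np.random.Generator,
                       geometry: ScreenGeometry,
                       direction: str = "left") -> dict:
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    sign = 1.0 if direction == "right" else -1.0
    pre, rot_T, post = 0.3, 0.55, 0.2
    peak = 80.0                      # deg/s head yaw peak
    excursion = peak * rot_T / 2     # 22 deg total rotation
    duration = pre + rot_T + post
    n = int(round(duration * config.GAZE_HZ))
    t = np.arange(n) / config.GAZE_HZ

    def yaw_of(ts: np.ndarray) -> np.ndarray:
        rel = np.clip((ts - pre) / rot_T, 0.0, 1.0)
        return sign * (peak * rot_T / 2) * (rel - np.sin(2 * np.pi * rel)
                                            / (2 * np.pi))

    t_head = np.arange(int(round(duration * config.HEAD_HZ))) / config.HEAD_HZ
    yaw_head = yaw_of(t_head) + rng.normal(0, 0.05, len(t_head))
    head = HeadTrace(t=t_head, yaw_deg=yaw_head,
                     pitch_deg=rng.normal(0, 0.05, len(t_head)),
                     x_mm=np.zeros(len(t_head)), y_mm=np.zeros(len(t_head)))

    yaw_g = yaw_of(t)
    g = latents["vor_gain"]
    # spatial scatter realizing the participant's latent gaze stability,
    # de-shrunk for the short correlated-noise analysis window
    area = 10.0 ** latents["vor_bcea_log"]
    sigma_deg = np.sqrt(area / (2 * np.pi * config.BCEA_K)) / 60.0
    t15 = pre + rot_T * _tau_at_rotation(15.0 / excursion)
    n_win = max(10, int((t15 - pre) * config.GAZE_HZ))
    shrink = window_variance_shrink(n_win)
    sig = sigma_deg / np.sqrt(shrink)
    x = (1 - g) * yaw_g + smoothed_noise(rng, n, sig)
    y = smoothed_noise(rng, n, sig)

    n_sacc = 0
    if rng.random() < min(1.0, params.vor_saccade_rate / 2.0):
        # out-and-back intrusion inside the 15-degree analysis window
        dwell = 0.06
        span = 2 * WAVEFORM.duration_s + dwell
        lo, hi = pre + 0.01, t15 - span - 0.01
        if hi > lo:
            e = rng.uniform(lo, hi)
            d = rng.choice([-1.0, 1.0])
            out_pos = saccade_position(t - e, WAVEFORM.amplitude_deg)
            back_pos = saccade_position(t - e - WAVEFORM.duration_s - dwell,
                                        WAVEFORM.amplitude_deg)
            x += d * (out_pos - back_pos)
            n_sacc = 2
    trace = _make_trace(t, x, y, rng, geometry, latents["distance_base"])
    return {
        "gaze": trace,
        "head": head,
        "target": point_target(0.0, 0.0, duration, direction=direction),
        "events": [("head_onset", pre), (f"direction={direction}", pre)],
        "ground_truth": {"true_vor_bcea_log": latents["vor_bcea_log"],
                         "true_vor_gain": g, "true_n_saccades": n_sacc,
                         "direction": direction},
    }


@lru_cache(maxsize=64)
def _tau_at_rotation(frac: float) -> float:
    """Normalized time at which a raised-cosine rotation reaches ``frac``."""
    tau = np.linspace(0, 1, 4001)
    cum = tau - np.sin(2 * np.pi * tau) / (2 * np.pi)
    return float(np.interp(frac, cum, tau))


def simulate_egocentric_trial(params: GroupParams, latents: dict,
                              rng: np.random.Generator,
                              geometry: ScreenGeometry) -> dict:
    # target uniform in the padded region (15% top/left/right, 30% bottom)
    fx = rng.uniform(0.15, 0.85)
    fy = rng.uniform(0.15, 0.70)
    tx_px, ty_px = fx * geometry.width_px, fy * geometry.height_px
    from .gaze_core import px_to_deg
    tx_deg, ty_deg = px_to_deg(tx_px, ty_px, geometry)
    d = latents["distance_base"]
    target_mm = np.array([np.tan(np.radians(tx_deg)) * d,
                          np.tan(np.radians(ty_deg)) * d])

    move_T = max(0.5, rng.normal(latents["ego_time"], 0.15))
    offset_deg = max(0.0, latents["ego_offset"] + rng.normal(0, 0.2))
    theta = rng.uniform(0, 2 * np.pi)
    offset_mm = np.tan(np.radians(offset_deg)) * d * np.array(
        [np.cos(theta), np.sin(theta)])
    final_mm = target_mm + offset_mm
    start_mm = rng.normal(0, 15.0, 2)

    duration = move_T + 1.2
    t_head = np.arange(int(round(duration * config.HEAD_HZ))) / config.HEAD_HZ
    frac = smoothstep(t_head / move_T)
    pos = start_mm[None, :] + (final_mm - start_mm)[None, :] * frac[:, None]
    pos += rng.normal(0, 1.0, pos.shape)
    head = HeadTrace(t=t_head, yaw_deg=np.zeros(len(t_head)),
                     pitch_deg=np.zeros(len(t_head)),
                     x_mm=pos[:, 0], y_mm=pos[:, 1])

    n = int(round(duration * config.GAZE_HZ))
    t = np.arange(n) / config.GAZE_HZ
    trace = _make_trace(t, smoothed_noise(rng, n, 0.2),
                        smoothed_noise(rng, n, 0.2), rng, geometry, d)
    return {
        "gaze": trace,
        "head": head,
        "target": point_target(float(tx_deg), float(ty_deg), duration,
                               target_px=[float(tx_px), float(ty_px)]),
        "events": [("target_onset", 0.0)],
        "ground_truth": {"true_ego_offset": offset_deg,
                         "true_ego_time": move_T},
    }


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Cohort composition mirroring the study: 55 control / 20 mTBI / 40 PPCS."""

    n_control: int = 55
    n_mtbi: int = 20
    n_ppcs: int = 40
    seed: int = 0
    sessions: int = 1
    presets: dict[str, GroupParams] | None = None

    def group_sizes(self) -> dict[str, int]:
        return {"control": self.n_control, "mtbi": self.n_mtbi,
                "ppcs": self.n_ppcs}


@dataclass
class Cohort:
    trials: list[Trial]
    ground_truth: pd.DataFrame
    spec: CohortSpec
    geometry: ScreenGeometry


def simulate_participant(participant_id: str, group: str, params: GroupParams,
                         seed_seq: np.random.SeedSequence,
                         geometry: ScreenGeometry,
                         tests: tuple[str, ...] = TESTS,
                         trials_per_test: dict[str, int] | None = None,
                         sessions: int = 1,
                         ) -> tuple[list[Trial], dict]:
    """Simulate one participant's battery (optionally repeated sessions).

    Latents are drawn once and shared across sessions, so repeated
    sessions differ only by trial-level noise — the structure assumed by
    the test–retest reliability analysis.
    """
    counts = dict(TRIALS_PER_TEST)
    if trials_per_test:
        counts.update(trials_per_test)
    # stable stream layout over the canonical test list
    streams = seed_seq.spawn(1 + len(TESTS))
    latents = draw_latents(params, np.random.default_rng(streams[0]))
    trials: list[Trial] = []
    for test in tests:
        idx = TESTS.index(test)
        session_streams = streams[1 + idx].spawn(sessions)
        for session in range(1, sessions + 1):
            rng = np.random.default_rng(session_streams[session - 1])
            n_trials = counts[test]
            if test == "saccade":
                tasks = ["pro"] * (n_trials // 2) + ["anti"] * (n_trials - n_trials // 2)
                rng.shuffle(tasks)
            if test == "vor":
                first = rng.choice(["left", "right"])
                other = "right" if first == "left" else "left"
                dirs = [first if i % 2 == 0 else other for i in range(n_trials)]
            for k in range(n_trials):
                if test == "fixation":
                    parts = simulate_fixation_trial(params, latents, rng, geometry)
                elif test == "pursuit":
                    parts = simulate_pursuit_trial(params, latents, rng, geometry)
                elif test == "saccade":
                    parts = simulate_saccade_trial(params, latents, rng,
                                                   geometry, task=tasks[k])
                elif test == "stroop":
                    parts = simulate_stroop_trial(params, latents, rng, geometry,
                                                  part=1 if k < n_trials // 2 else 2)
                elif test == "vor":
                    parts = simulate_vor_trial(params, latents, rng, geometry,
                                               direction=dirs[k])
                elif test == "egocentric":
                    parts = simulate_egocentric_trial(params, latents, rng,
                                                      geometry)
                else:
                    raise ValueError(f"unknown test {test!r}")
                trials.append(Trial(
                    test_id=test, trial_index=k, participant_id=participant_id,
                    group=group, gaze=parts["gaze"], target=parts["target"],
                    head=parts.get("head"), events=parts["events"],
                    session=session, ground_truth=parts["ground_truth"],
                ))
    return trials, latents


def simulate_cohort(spec: CohortSpec,
                    tests: tuple[str, ...] = TESTS,
                    trials_per_test: dict[str, int] | None = None,
                    geometry: ScreenGeometry | None = None) -> Cohort:
    """Simulate the full cohort; bit-reproducible from ``spec.seed``."""
    geometry = geometry or ScreenGeometry()
    presets = spec.presets or default_presets()
    root = np.random.SeedSequence(spec.seed)
    sizes = spec.group_sizes()
    total = sum(sizes.values())
    children = root.spawn(max(total, 1))
    trials: list[Trial] = []
    gt_rows: list[dict] = []
    i = 0
    prefix = {"control": "C", "mtbi": "M", "ppcs": "P"}
    for group in GROUPS:
        for k in range(sizes[group]):
            pid = f"{prefix[group]}{k + 1:03d}"
            p_trials, latents = simulate_participant(
                pid, group, presets[group], children[i], geometry,
                tests=tests, trials_per_test=trials_per_test,
                sessions=spec.sessions)
            trials.extend(p_trials)
            gt_rows.append({"participant_id": pid, "group": group, **latents})
            i += 1
    gt = pd.DataFrame(gt_rows)
    return Cohort(trials=trials, ground_truth=gt, spec=spec, geometry=geometry)
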
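"""Outcome-measure extraction: raw trials -> participant x outcome table.

Each CEA test contributes a small set of scalar outcomes (the ~25 columns
of :data:`FEATURE_COLUMNS`); per-participant values are means over that
participant's retained trials.  Saccade and blink samples are masked out
of position-based statistics (BCEA, pursuit offset/gain); anticipatory
saccade trials (< 60 ms latency) are removed before averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import config
from .gaze_core import (
    GazeTrace,
    InsufficientDataError,
    Trial,
    compute_velocity,
    detect_saccades,
    preprocess_trial,
    saccade_latency,
    saccade_mask,
)

FEATURE_COLUMNS = [
    "ego_offset", "ego_time",
    "fix_bcea", "fix_err_h", "fix_err_v",
    "pur_offset", "pur_gain_total", "pur_gain_v", "pur_nsacc",
    "sacc_pro_latency", "sacc_pro_velocity", "sacc_pro_correct",
    "sacc_anti_latency", "sacc_anti_velocity", "sacc_anti_correct",
    "stroop1_latency", "stroop1_time", "stroop1_correct",
    "stroop2_latency", "stroop2_time", "stroop2_correct",
    "vor_bcea", "vor_gain", "vor_time_to_max_gain", "vor_nsacc",
]


@dataclass(frozen=True)
class BCEAResult:
    """95% bivariate contour ellipse area of a gaze-sample cloud."""

    area: float          # minarc^2
    log_area: float      # log10 minarc^2
    sigma_h: float       # minarc
    sigma_v: float       # minarc
    rho: float


def bcea95(x_deg: np.ndarray, y_deg: np.ndarray,
           min_points: int = 10) -> BCEAResult:
    """BCEA = 2 k pi sigma_h sigma_v sqrt(1 - rho^2), k = -ln(0.05).

    Sigmas are sample SDs in minutes of arc (deg x 60); the area is
    floored so a degenerate (collinear or constant) cloud still has a
    finite log.
    """
    x = np.asarray(x_deg, dtype=float) * 60.0
    y = np.asarray(y_deg, dtype=float) * 60.0
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < min_points:
        raise InsufficientDataError(
            f"BCEA needs >= {min_points} points, got {len(x)}")
    sh = float(np.std(x, ddof=1))
    sv = float(np.std(y, ddof=1))
    if sh > 0 and sv > 0:
        rho = float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))
    else:
        rho = 0.0
    area = 2.0 * config.BCEA_K * np.pi * sh * sv * np.sqrt(max(0.0, 1 - rho ** 2))
    area = max(area, config.BCEA_AREA_FLOOR_MINARC2)
    return BCEAResult(area=area, log_area=float(np.log10(area)),
                      sigma_h=sh, sigma_v=sv, rho=rho)


def _masked_positions(trial: Trial) -> tuple[np.ndarray, np.ndarray, np.ndarray, list]:
    """Gaze in degrees with the padded-saccade keep-mask applied."""
    trace = trial.gaze
    saccades = detect_saccades(trace)
    keep = saccade_mask(trace, saccades)
    x, y = trace.to_deg()
    return x, y, keep, saccades


def _nanmean(values: Iterable[float]) -> float:
    arr = np.asarray([v for v in values if v is not None], dtype=float)
    if arr.size == 0 or not np.isfinite(arr).any():
        return float("nan")
    return float(np.nanmean(arr))


# ---------------------------------------------------------------------------
# per-test extractors
# ---------------------------------------------------------------------------

def fixation_outcomes(trials: Sequence[Trial]) -> dict[str, float]:
    """BCEA (log10 minarc^2) and mean gaze-error vector, +y above target."""
    bceas, errs_h, errs_v = [], [], []
    for trial in trials:
        x, y, keep, _ = _masked_positions(trial)
        tx, ty = trial.target.position(trial.gaze.t)
        try:
            bceas.append(bcea95(x[keep], y[keep]).log_area)
        except InsufficientDataError:
            pass
        if keep.any():
            errs_h.append(float(np.mean(x[keep] - tx[keep])))
            errs_v.append(float(np.mean(y[keep] - ty[keep])))
    return {"fix_bcea": _nanmean(bceas), "fix_err_h": _nanmean(errs_h),
            "fix_err_v": _nanmean(errs_v)}


def pursuit_outcomes(trials: Sequence[Trial]) -> dict[str, float]:
    """Offset error, per-axis amplitude gains, and catch-up saccade count.

    Offset = magnitude of the time-averaged (gaze - target) vector over
    saccade-free samples.  Per-axis gain is the least-squares slope of eye
    position on target position; total gain averages the two axes.
    """
    offs, gains_h, gains_v, nsaccs = [], [], [], []
    for trial in trials:
        x, y, _, saccades = _masked_positions(trial)
        # also drop the pre-saccadic lag that the catch-up corrects
        keep = saccade_mask(trial.gaze, saccades, pre_pad_s=0.30)
        tx, ty = trial.target.position(trial.gaze.t)
        nsaccs.append(float(len(saccades)))
        if keep.sum() < 10:
            continue
        ex = x[keep] - tx[keep]
        ey = y[keep] - ty[keep]
        offs.append(float(np.hypot(np.mean(ex), np.mean(ey))))

        def slope(eye: np.ndarray, tgt: np.ndarray) -> float:
            tgt_c = tgt - tgt.mean()
            denom = float(np.dot(tgt_c, tgt_c))
            return float(np.dot(eye - eye.mean(), tgt_c) / denom) if denom else np.nan

        gains_h.append(slope(x[keep], tx[keep]))
        gains_v.append(slope(y[keep], ty[keep]))
    gain_h = _nanmean(gains_h)
    gain_v = _nanmean(gains_v)
    return {
        "pur_offset": _nanmean(offs),
        "pur_gain_total": float(np.nanmean([gain_h, gain_v])),
        "pur_gain_v": gain_v,
        "pur_nsacc": _nanmean(nsaccs),
    }


def saccade_outcomes(trials: Sequence[Trial]) -> dict[str, float]:
    """Latency, response peak velocity and proportion correct per task.

    Correctness compares the sign of the first post-cue saccade's
    horizontal direction with the secondary-target side (pro: same sign,
    anti: opposite).  Anticipatory trials (< 60 ms) are removed; trials
    with no response count as incorrect but contribute no latency.
    """
    acc: dict[str, dict[str, list[float]]] = {
        task: {"lat": [], "vel": [], "correct": []} for task in ("pro", "anti")}
    for trial in trials:
        task = trial.target.params.get("task") or trial.event_value("task")
        side = trial.target.params.get("side")
        if task not in acc or side is None:
            continue
        saccades = detect_saccades(trial.gaze)
        latency, flag = saccade_latency(trial, "secondary_onset",
                                        saccades=saccades)
        if flag == "anticipatory":
            continue                      # removed, like a false start
        if flag == "missing":
            acc[task]["correct"].append(0.0)
            continue
        cue_t = trial.event_time("secondary_onset")
        response = next(s for s in saccades if s.onset_t >= cue_t)
        toward = np.sign(response.direction[0]) == np.sign(side)
        correct = toward if task == "pro" else not toward
        acc[task]["lat"].append(latency)
        acc[task]["vel"].append(response.peak_velocity)
        acc[task]["correct"].append(float(correct))
    out = {}
    for task in ("pro", "anti"):
        a = acc[task]
        out[f"sacc_{task}_latency"] = _nanmean(a["lat"])
        out[f"sacc_{task}_velocity"] = _nanmean(a["vel"])
        out[f"sacc_{task}_correct"] = _nanmean(a["correct"])
    return out


def _corner_of(trace: GazeTrace, frac: float = config.STROOP_CORNER_ROI_FRAC
               ) -> np.ndarray:
    """Per-sample corner-block id (pixel-space ROIs), or '' outside."""
    g = trace.geometry
    left = trace.x_px <= frac * g.width_px
    right = trace.x_px >= (1 - frac) * g.width_px
    top = trace.y_px <= frac * g.height_px
    bottom = trace.y_px >= (1 - frac) * g.height_px
    corner = np.full(len(trace), "", dtype=object)
    corner[top & left] = "top_left"
    corner[top & right] = "top_right"
    corner[bottom & left] = "bottom_left"
    corner[bottom & right] = "bottom_right"
    return corner


def _dwell_episodes(trace: GazeTrace, min_dwell: float
                    ) -> list[tuple[str, float]]:
    """(corner, start_time) of sustained same-corner dwells, in order."""
    corner = _corner_of(trace)
    episodes = []
    i = 0
    n = len(trace)
    while i < n:
        if corner[i] == "":
            i += 1
            continue
        j = i
        while j + 1 < n and corner[j + 1] == corner[i]:
            j += 1
        if trace.t[j] - trace.t[i] >= min_dwell:
            episodes.append((str(corner[i]), float(trace.t[i])))
        i = j + 1
    return episodes


def stroop_outcomes(trials: Sequence[Trial], part: int) -> dict[str, float]:
    """Decision latency, total trial time and proportion correct.

    Latency = word onset to first gaze exit from the central region;
    total time = word onset to the first sustained (>= 200 ms) dwell in
    any corner block; a trial is correct when the *final* dwelled corner
    matches the required color, so mid-course corrections still score.
    """
    lats, times, corrects = [], [], []
    for trial in trials:
        if trial.target.params.get("part") != part:
            continue
        t0 = trial.event_time("word_onset")
        required = trial.target.params["required_color"]
        corner_colors = trial.target.params["corner_colors"]
        trace = trial.gaze
        x, y = trace.to_deg()
        r = np.hypot(x, y)
        outside = (trace.t > t0) & (r > config.STROOP_CENTER_ROI_DEG)
        if outside.any():
            lats.append(float(trace.t[np.argmax(outside)] - t0))
        episodes = [(c, s) for c, s in
                    _dwell_episodes(trace, config.STROOP_DWELL_S) if s > t0]
        if episodes:
            times.append(episodes[0][1] - t0)
            final_corner = episodes[-1][0]
            corrects.append(float(corner_colors[final_corner] == required))
        else:
            times.append(float(trace.t[-1] - t0))
            corrects.append(0.0)
    return {
        f"stroop{part}_latency": _nanmean(lats),
        f"stroop{part}_time": _nanmean(times),
        f"stroop{part}_correct": _nanmean(corrects),
    }


def vor_outcomes(trials: Sequence[Trial]) -> dict[str, float]:
    """Gaze stability, velocity gain and saccade count in the VOR window.

    The analysis window runs from head-movement onset to 15 degrees of
    cumulative yaw.  Instantaneous gain = |eye-in-head velocity| / |head
    yaw velocity| with head yaw interpolated onto the gaze clock and
    samples below 20 deg/s head speed excluded; the trial gain is the
    median ratio.
    """
    bceas, gains, tmaxs, nsaccs = [], [], [], []
    for trial in trials:
        if trial.head is None:
            continue
        head = trial.head
        trace = trial.gaze
        if len(trace) < 3:
            continue
        v_head = np.gradient(head.yaw_deg, head.t)
        moving = np.abs(v_head) > 10.0
        if not moving.any():
            continue
        onset_t = float(head.t[np.argmax(moving)])
        yaw_g = head.yaw_at(trace.t)
        yaw0 = float(np.interp(onset_t, head.t, head.yaw_deg))
        cum = np.abs(yaw_g - yaw0)
        reached = (trace.t >= onset_t) & (cum >= config.VOR_WINDOW_DEG)
        if not reached.any():
            continue                      # incomplete rotation
        t15 = float(trace.t[np.argmax(reached)])
        window = (trace.t >= onset_t) & (trace.t <= t15)

        saccades = detect_saccades(trace)
        in_win = [s for s in saccades
                  if onset_t <= s.onset_t <= t15]
        nsaccs.append(float(len(in_win)))
        keep = saccade_mask(trace, saccades)

        x, y = trace.to_deg()
        sel = window & keep
        try:
            bceas.append(bcea95(x[sel], y[sel]).log_area)
        except InsufficientDataError:
            pass

        vx, _vy, _sp = compute_velocity(trace)
        yaw_vel = np.gradient(yaw_g, trace.t)
        ok = (window & keep & np.isfinite(vx)
              & (np.abs(yaw_vel) >= config.VOR_HEAD_SPEED_FLOOR_DEG_S))
        if ok.any():
            ratio = np.abs(vx[ok] - yaw_vel[ok]) / np.abs(yaw_vel[ok])
            gains.append(float(np.median(ratio)))
            tmaxs.append(float(trace.t[ok][np.argmax(ratio)] - onset_t))
    return {"vor_bcea": _nanmean(bceas), "vor_gain": _nanmean(gains),
            "vor_time_to_max_gain": _nanmean(tmaxs),
            "vor_nsacc": _nanmean(nsaccs)}


def egocentric_outcomes(trials: Sequence[Trial]) -> dict[str, float]:
    """Head-alignment offset error (deg) and settling time (s).

    Completion is the first moment the head-center projection stays
    within the settling radius of its final position for >= 500 ms.
    """
    offs, times = [], []
    for trial in trials:
        if trial.head is None:
            continue
        head = trial.head
        d = float(np.median(trial.gaze.distance_mm))
        hx = np.degrees(np.arctan2(head.x_mm, d))
        hy = np.degrees(np.arctan2(head.y_mm, d))
        tx = trial.target.params["x"]
        ty = trial.target.params["y"]
        late = head.t >= head.t[-1] - 0.3
        fx, fy = float(np.median(hx[late])), float(np.median(hy[late]))
        offs.append(float(np.hypot(fx - tx, fy - ty)))
        near = np.hypot(hx - fx, hy - fy) <= config.EGO_SETTLE_RADIUS_DEG
        onset = trial.event_time("target_onset") or 0.0
        settle = None
        i = 0
        n = len(head.t)
        while i < n:
            if not near[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and near[j + 1]:
                j += 1
            if head.t[j] - head.t[i] >= config.EGO_DWELL_S:
                settle = float(head.t[i])
                break
            i = j + 1
        times.append((settle - onset) if settle is not None
                     else float(head.t[-1] - onset))
    return {"ego_offset": _nanmean(offs), "ego_time": _nanmean(times)}


# ---------------------------------------------------------------------------
# table assembly
# ---------------------------------------------------------------------------

def build_feature_table(trials: Sequence[Trial],
                        preprocess: bool = True) -> pd.DataFrame:
    """Assemble the participant x outcome FeatureTable.

    One row per participant (and per session when the input holds repeated
    sessions).  Trials excluded by preprocessing are dropped and counted in
    ``df.attrs['exclusions']``; a participant missing a whole test keeps
    their row with NaN in that test's columns.
    """
    if preprocess:
        trials = [preprocess_trial(tr) for tr in trials]
    excluded = [tr for tr in trials if tr.excluded]
    retained = [tr for tr in trials if not tr.excluded]

    keys = sorted({(tr.participant_id, tr.group, tr.session) for tr in retained})
    by_key: dict[tuple, dict[str, list[Trial]]] = {
        k: {} for k in keys}
    for tr in retained:
        by_key[(tr.participant_id, tr.group, tr.session)].setdefault(
            tr.test_id, []).append(tr)

    rows = []
    for (pid, group, session) in keys:
        tests = by_key[(pid, group, session)]
        row: dict[str, float | str | int] = {
            "participant_id": pid, "group": group, "session": session}
        row.update({c: float("nan") for c in FEATURE_COLUMNS})
        if "egocentric" in tests:
            row.update(egocentric_outcomes(tests["egocentric"]))
        if "fixation" in tests:
            row.update(fixation_outcomes(tests["fixation"]))
        if "pursuit" in tests:
            row.update(pursuit_outcomes(tests["pursuit"]))
        if "saccade" in tests:
            row.update(saccade_outcomes(tests["saccade"]))
        if "stroop" in tests:
            row.update(stroop_outcomes(tests["stroop"], part=1))
            row.update(stroop_outcomes(tests["stroop"], part=2))
        if "vor" in tests:
            row.update(vor_outcomes(tests["vor"]))
        rows.append(row)

    df = pd.DataFrame(rows, columns=["participant_id", "group", "session",
                                     *FEATURE_COLUMNS])
    df.attrs["exclusions"] = [
        {"participant_id": tr.participant_id, "test_id": tr.test_id,
         "trial_index": tr.trial_index, "reason": tr.exclude_reason}
        for tr in excluded]
    return df
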
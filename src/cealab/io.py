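"""CSV/JSON interchange for trials, features and reports.

Formats (UTF-8, "." decimal, header row required):

* ``gaze.csv``   — participant_id, group, test_id, trial_index, session,
  t, x_px, y_px, valid, distance_mm (one row per gaze sample)
* ``head.csv``   — participant_id, test_id, trial_index, session, t,
  yaw_deg, pitch_deg, x_mm, y_mm
* ``events.csv`` — participant_id, test_id, trial_index, session, label, t
* ``trials.csv`` — trial metadata incl. serialized target kind/params
* ``geometry.json`` — the screen geometry used for angular conversion
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .gaze_core import GazeTrace, HeadTrace, ScreenGeometry, Trial
from .synthetic_cohort import rebuild_target


def write_geometry(geometry: ScreenGeometry, path: Path | str) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(geometry), indent=2))


def read_geometry(path: Path | str) -> ScreenGeometry:
    return ScreenGeometry(**json.loads(Path(path).read_text()))


def write_trials(trials: list[Trial], outdir: Path | str,
                 geometry: ScreenGeometry) -> None:
    """Serialize trials to the CSV dialects in ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_geometry(geometry, outdir / "geometry.json")

    gaze_parts, head_parts, event_rows, trial_rows = [], [], [], []
    for tr in trials:
        key = {"participant_id": tr.participant_id, "test_id": tr.test_id,
               "trial_index": tr.trial_index, "session": tr.session}
        g = tr.gaze
        gaze_parts.append(pd.DataFrame({
            **{k: np.repeat(v, len(g)) for k, v in
               {**key, "group": tr.group}.items()},
            "t": g.t, "x_px": g.x_px, "y_px": g.y_px,
            "valid": g.valid.astype(int), "distance_mm": g.distance_mm,
        }))
        if tr.head is not None:
            h = tr.head
            head_parts.append(pd.DataFrame({
                **{k: np.repeat(v, len(h.t)) for k, v in key.items()},
                "t": h.t, "yaw_deg": h.yaw_deg, "pitch_deg": h.pitch_deg,
                "x_mm": h.x_mm, "y_mm": h.y_mm,
            }))
        for label, t in tr.events:
            event_rows.append({**key, "label": label, "t": t})
        trial_rows.append({
            **key, "group": tr.group, "excluded": int(tr.excluded),
            "exclude_reason": tr.exclude_reason or "",
            "target_kind": tr.target.kind,
            "target_params": json.dumps(tr.target.params),
        })

    pd.concat(gaze_parts, ignore_index=True).to_csv(
        outdir / "gaze.csv", index=False)
    if head_parts:
        pd.concat(head_parts, ignore_index=True).to_csv(
            outdir / "head.csv", index=False)
    pd.DataFrame(event_rows).to_csv(outdir / "events.csv", index=False)
    pd.DataFrame(trial_rows).to_csv(outdir / "trials.csv", index=False)


def read_trials(indir: Path | str) -> list[Trial]:
    """Reconstruct Trial objects written by :func:`write_trials`."""
    indir = Path(indir)
    geometry = read_geometry(indir / "geometry.json")
    gaze = pd.read_csv(indir / "gaze.csv")
    head = (pd.read_csv(indir / "head.csv")
            if (indir / "head.csv").exists() else None)
    events = pd.read_csv(indir / "events.csv")
    meta = pd.read_csv(indir / "trials.csv",
                       keep_default_na=False, na_values=[])

    key_cols = ["participant_id", "test_id", "trial_index", "session"]
    gaze_groups = dict(tuple(gaze.groupby(key_cols)))
    head_groups = dict(tuple(head.groupby(key_cols))) if head is not None else {}
    event_groups = dict(tuple(events.groupby(key_cols))) if len(events) else {}

    trials = []
    for _, row in meta.iterrows():
        key = (row["participant_id"], row["test_id"],
               int(row["trial_index"]), int(row["session"]))
        g = gaze_groups[key]
        trace = GazeTrace(
            t=g["t"].to_numpy(), x_px=g["x_px"].to_numpy(),
            y_px=g["y_px"].to_numpy(), valid=g["valid"].to_numpy().astype(bool),
            distance_mm=g["distance_mm"].to_numpy(), geometry=geometry)
        head_trace = None
        if key in head_groups:
            h = head_groups[key]
            head_trace = HeadTrace(
                t=h["t"].to_numpy(), yaw_deg=h["yaw_deg"].to_numpy(),
                pitch_deg=h["pitch_deg"].to_numpy(),
                x_mm=h["x_mm"].to_numpy(), y_mm=h["y_mm"].to_numpy())
        ev = []
        if key in event_groups:
            ev = [(str(r["label"]), float(r["t"]))
                  for _, r in event_groups[key].iterrows()]
        target = rebuild_target(row["target_kind"],
                                json.loads(row["target_params"]))
        trials.append(Trial(
            test_id=row["test_id"], trial_index=int(row["trial_index"]),
            participant_id=row["participant_id"], group=row["group"],
            gaze=trace, head=head_trace, target=target, events=ev,
            excluded=bool(int(row["excluded"])),
            exclude_reason=row["exclude_reason"] or None,
            session=int(row["session"])))
    return trials
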
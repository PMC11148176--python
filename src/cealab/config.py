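"""Protocol constants and pipeline configuration.

All preprocessing thresholds live here so that every stage of the pipeline
reads the same values: the eye-tracker distance acceptance window, the
duration/velocity saccade rule, the anticipatory-latency floor, and the
machine-learning protocol constants (70/30 split, 10-fold CV, 10 seeds).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

# --- signal acquisition -----------------------------------------------------
GAZE_HZ = 133.0          # binocular gaze sampling rate, Hz
HEAD_HZ = 33.0           # head-pose sampling rate, Hz
NOMINAL_DISTANCE_MM = 700.0  # nominal eye-to-screen distance (~70 cm)

# --- trial exclusion --------------------------------------------------------
DISTANCE_MIN_MM = 500.0  # trials with any valid sample closer are excluded
DISTANCE_MAX_MM = 950.0  # ... or farther

# --- saccade detection ------------------------------------------------------
SACCADE_MIN_DURATION_S = 0.050   # run must span at least 50 ms
SACCADE_VELOCITY_DEG_S = 100.0   # samples must exceed 100 deg/s (strict >)
LATENCY_FLOOR_S = 0.060          # latencies below 60 ms are anticipatory

# --- BCEA -------------------------------------------------------------------
# 95% bivariate contour: chi-square quantile for 2 df over 2 == -ln(1-0.95)
BCEA_K = -float(np.log(0.05))
BCEA_AREA_FLOOR_MINARC2 = 1.0

# --- region-of-interest / settling defaults (not protocol-fixed) ------------
STROOP_CORNER_ROI_FRAC = 0.20    # corner ROI = 20% x 20% of the screen
STROOP_DWELL_S = 0.200           # sustained dwell needed to register a corner
STROOP_CENTER_ROI_DEG = 3.0      # leaving this radius marks the decision
EGO_SETTLE_RADIUS_DEG = 1.5
EGO_DWELL_S = 0.500
VOR_WINDOW_DEG = 15.0            # analysis window: first 15 deg of head yaw
VOR_HEAD_SPEED_FLOOR_DEG_S = 20.0
SACCADE_MASK_PAD_S = 0.050       # padding when masking saccade samples

# --- machine-learning protocol ----------------------------------------------
TRAIN_FRACTION = 0.70
CV_FOLDS = 10
N_SEEDS = 10

# --- reliability banding ----------------------------------------------------
ICC_BANDS = ((0.90, "excellent"), (0.75, "good"), (0.50, "moderate"))


@dataclass
class PipelineConfig:
    """Round-trippable configuration for the end-to-end pipeline."""

    out_dir: str = "results/pipeline"
    seed: int = 0
    n_control: int = 55
    n_mtbi: int = 20
    n_ppcs: int = 40
    n_retest: int = 35
    distance_min_mm: float = DISTANCE_MIN_MM
    distance_max_mm: float = DISTANCE_MAX_MM
    saccade_min_duration_s: float = SACCADE_MIN_DURATION_S
    saccade_velocity_deg_s: float = SACCADE_VELOCITY_DEG_S
    latency_floor_s: float = LATENCY_FLOOR_S
    train_fraction: float = TRAIN_FRACTION
    cv_folds: int = CV_FOLDS
    n_seeds: int = N_SEEDS
    tests: tuple[str, ...] = (
        "egocentric", "fixation", "pursuit", "saccade", "stroop", "vor",
    )

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["tests"] = list(d["tests"])
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        d["tests"] = tuple(d.get("tests", cls().tests))
        return cls(**d)

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]
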
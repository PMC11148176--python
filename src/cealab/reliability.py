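"""Test-retest reliability: two-way consistency ICC and Bland-Altman.

The ICC is the two-way mixed, single-measures, consistency form — ICC(3,1)
in Shrout & Fleiss notation:

    ICC = (MS_between - MS_error) / (MS_between + (k - 1) MS_error)

where MS_between is the between-subject mean square and MS_error the
residual mean square of the two-way (subject x session) ANOVA.  The
consistency definition ignores fixed session shifts (a learning or
fatigue offset common to everyone does not lower reliability).  The 95%
CI comes from the F distribution of MS_between/MS_error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import config


@dataclass(frozen=True)
class ICCResult:
    outcome: str
    icc: float
    ci_low: float
    ci_high: float
    band: str
    n_subjects: int
    n_sessions: int


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_difference: float
    sd_diff: float
    loa_low: float
    loa_high: float


def band(icc: float) -> str:
    """Qualitative ICC band: >0.90 excellent, 0.75-0.90 good,
    0.50-0.75 moderate, <0.50 poor (exact thresholds fall to the lower
    band, since 'excellent' requires strictly greater than 0.90)."""
    if not np.isfinite(icc):
        raise ValueError("ICC must be finite")
    for threshold, label in config.ICC_BANDS:
        if icc > threshold:
            return label
    return "poor"


def icc_consistency(session1: np.ndarray, session2: np.ndarray,
                    *more_sessions: np.ndarray,
                    outcome: str = "", alpha: float = 0.05,
                    average_measures: bool = False) -> ICCResult:
    """Two-way consistency ICC over paired sessions.

    ``average_measures=True`` gives the ICC(3,k) variant; the default is
    single measures, matching per-session outcome values.
    """
    data = np.column_stack([session1, session2, *more_sessions]).astype(float)
    ok = np.all(np.isfinite(data), axis=1)
    data = data[ok]
    n, k = data.shape
    if n < 5:
        raise ValueError(f"need >= 5 paired subjects, got {n}")

    grand = data.mean()
    ss_rows = k * np.sum((data.mean(axis=1) - grand) ** 2)
    ss_cols = n * np.sum((data.mean(axis=0) - grand) ** 2)
    ss_tot = np.sum((data - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_rows <= 0:
        raise ValueError("zero between-subject variance; ICC undefined")
    if ms_err <= 1e-12 * ms_rows:   # perfectly consistent sessions
        return ICCResult(outcome=outcome, icc=1.0, ci_low=1.0, ci_high=1.0,
                         band="excellent", n_subjects=n, n_sessions=k)

    if average_measures:
        icc = (ms_rows - ms_err) / ms_rows
    else:
        icc = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)

    # CI from F = MS_between / MS_error  (Shrout & Fleiss)
    df1, df2 = n - 1, (n - 1) * (k - 1)
    f_obs = ms_rows / ms_err
    fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
    fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
    if average_measures:
        ci_low, ci_high = 1 - 1 / fl, 1 - 1 / fu
    else:
        ci_low = (fl - 1) / (fl + k - 1)
        ci_high = (fu - 1) / (fu + k - 1)
    return ICCResult(outcome=outcome, icc=float(icc),
                     ci_low=float(min(ci_low, icc)),
                     ci_high=float(max(ci_high, icc)),
                     band=band(float(icc)), n_subjects=n, n_sessions=k)


def bland_altman(session1: np.ndarray, session2: np.ndarray
                 ) -> BlandAltmanResult:
    """Mean session2-session1 difference with 95% limits of agreement."""
    s1 = np.asarray(session1, dtype=float)
    s2 = np.asarray(session2, dtype=float)
    ok = np.isfinite(s1) & np.isfinite(s2)
    diff = (s2 - s1)[ok]
    if len(diff) < 2:
        raise ValueError("need >= 2 paired values")
    mean = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    return BlandAltmanResult(mean_difference=mean, sd_diff=sd,
                             loa_low=mean - 1.96 * sd,
                             loa_high=mean + 1.96 * sd)


def simulate_retest(n_subjects: int, icc: float, seed: int,
                    mean: float = 0.0, total_sd: float = 1.0
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Paired-session data whose between/total variance ratio equals ``icc``.

    Subject effects ~ N(0, icc * total_sd^2); independent session noise
    carries the remaining variance, so the population consistency ICC of
    the generated pairs is exactly the requested ratio.
    """
    if not 0.0 <= icc < 1.0:
        raise ValueError("icc must be in [0, 1)")
    rng = np.random.default_rng(seed)
    subject = rng.normal(0.0, np.sqrt(icc) * total_sd, n_subjects)
    noise_sd = np.sqrt(1.0 - icc) * total_sd
    s1 = mean + subject + rng.normal(0.0, noise_sd, n_subjects)
    s2 = mean + subject + rng.normal(0.0, noise_sd, n_subjects)
    return s1, s2


def reliability_report(table1: pd.DataFrame, table2: pd.DataFrame,
                       outcomes: list[str] | None = None) -> pd.DataFrame:
    """Per-outcome ICC + Bland-Altman over two session FeatureTables.

    Tables are aligned on ``participant_id``; outcomes where the ICC is
    undefined (zero between-subject variance, too few pairs) get NaN.
    """
    from .features import FEATURE_COLUMNS

    outcomes = outcomes or FEATURE_COLUMNS
    merged = table1.merge(table2, on="participant_id",
                          suffixes=("_s1", "_s2"))
    rows = []
    for outcome in outcomes:
        s1 = merged[f"{outcome}_s1"].to_numpy(dtype=float)
        s2 = merged[f"{outcome}_s2"].to_numpy(dtype=float)
        row: dict[str, object] = {"outcome": outcome}
        try:
            icc = icc_consistency(s1, s2, outcome=outcome)
            row.update(icc=icc.icc, ci_low=icc.ci_low, ci_high=icc.ci_high,
                       band=icc.band, n_subjects=icc.n_subjects)
        except ValueError:
            row.update(icc=np.nan, ci_low=np.nan, ci_high=np.nan,
                       band="undefined", n_subjects=np.sum(
                           np.isfinite(s1) & np.isfinite(s2)))
        try:
            ba = bland_altman(s1, s2)
            row.update(mean_difference=ba.mean_difference, sd_diff=ba.sd_diff,
                       loa_low=ba.loa_low, loa_high=ba.loa_high)
        except ValueError:
            row.update(mean_difference=np.nan, sd_diff=np.nan,
                       loa_low=np.nan, loa_high=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
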
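"""Outcome-extraction tests: BCEA oracle, identities, ground-truth recovery."""

import numpy as np
import pytest

from cealab import config
from cealab.features import (
    FEATURE_COLUMNS,
    bcea95,
    build_feature_table,
    fixation_outcomes,
    pursuit_outcomes,
    saccade_outcomes,
    vor_outcomes,
)
from cealab.gaze_core import (
    HeadTrace,
    InsufficientDataError,
    Trial,
    saccade_mask,
    detect_saccades,
)
from cealab.synthetic_cohort import (
    CohortSpec,
    lissajous_target,
    point_target,
    saccade_position,
    simulate_cohort,
)

from conftest import trace_from_deg

HZ = config.GAZE_HZ


class TestBCEA:
    def test_closed_form_on_large_isotropic_sample(self):
        """Sample estimate converges to 2*k*pi*sh*sv*sqrt(1-rho^2)."""
        rng = np.random.default_rng(1)
        n = 100_000
        sigma_deg = 10.0 / 60.0          # 10 minarc
        x = rng.normal(0, sigma_deg, n)
        y = rng.normal(0, sigma_deg, n)
        res = bcea95(x, y)
        expected = 2 * np.pi * config.BCEA_K * 100.0    # 1882.2 minarc^2
        assert res.area == pytest.approx(expected, rel=0.02)
        assert res.log_area == pytest.approx(3.275, abs=0.01)

    def test_collinear_points_hit_floor(self):
        u = np.linspace(0, 1, 50)
        res = bcea95(u, 2 * u)
        assert res.area == config.BCEA_AREA_FLOOR_MINARC2
        assert res.log_area == 0.0

    def test_constant_cloud_hits_floor(self):
        res = bcea95(np.zeros(20), np.zeros(20))
        assert res.area == config.BCEA_AREA_FLOOR_MINARC2

    def test_too_few_points_raises(self):
        with pytest.raises(InsufficientDataError):
            bcea95(np.zeros(5), np.zeros(5))

    def test_correlation_shrinks_area(self):
        rng = np.random.default_rng(2)
        n = 50_000
        x = rng.normal(0, 1.0, n)
        y = 0.8 * x + rng.normal(0, 0.6, n)
        res = bcea95(x / 60, y / 60)
        rho = 0.8 / np.sqrt(0.64 + 0.36)
        expected = 2 * np.pi * config.BCEA_K * 1.0 * 1.0 * np.sqrt(1 - rho ** 2)
        assert res.area / 3600 == pytest.approx(expected / 3600, rel=0.03)


def _trial(trace, target, test_id="fixation", head=None, events=(),
           ground_truth=None):
    return Trial(test_id=test_id, trial_index=0, participant_id="x",
                 group="control", gaze=trace, target=target, head=head,
                 events=list(events), ground_truth=ground_truth or {})


class TestFixationOutcomes:
    def test_gaze_on_target_zero_error(self):
        rng = np.random.default_rng(3)
        n = 1330
        x = rng.normal(0, 0.01, n)
        y = rng.normal(0, 0.01, n)
        out = fixation_outcomes([_trial(trace_from_deg(x, y),
                                        point_target(0, 0, 10.0))])
        assert out["fix_err_h"] == pytest.approx(0.0, abs=0.005)
        assert out["fix_err_v"] == pytest.approx(0.0, abs=0.005)

    def test_constant_elevation_gives_positive_vertical_error(self):
        n = 1330
        rng = np.random.default_rng(4)
        y = 0.32 + rng.normal(0, 0.05, n)
        out = fixation_outcomes([_trial(trace_from_deg(np.zeros(n), y),
                                        point_target(0, 0, 10.0))])
        assert out["fix_err_v"] == pytest.approx(0.32, abs=0.01)


class TestPursuitOutcomes:
    def _pursuit_trial(self, gain_v=1.0, gain_h=1.0, offset=(0.0, 0.0)):
        traj = lissajous_target()
        n = int(30 * HZ)
        t = np.arange(n) / HZ
        tx, ty = traj.position(t)
        trace = trace_from_deg(gain_h * tx + offset[0],
                               gain_v * ty + offset[1])
        return _trial(trace, traj, test_id="pursuit")

    def test_eye_equals_target_identity(self):
        out = pursuit_outcomes([self._pursuit_trial()])
        assert out["pur_offset"] == pytest.approx(0.0, abs=1e-9)
        assert out["pur_gain_total"] == pytest.approx(1.0, abs=1e-9)
        assert out["pur_nsacc"] == 0.0

    def test_vertical_amplitude_scaling_recovered_as_gain(self):
        out = pursuit_outcomes([self._pursuit_trial(gain_v=1.04)])
        assert out["pur_gain_v"] == pytest.approx(1.04, abs=1e-6)
        assert out["pur_gain_total"] == pytest.approx(1.02, abs=1e-6)

    def test_constant_offset_recovered_as_magnitude(self):
        out = pursuit_outcomes([self._pursuit_trial(offset=(0.3, 0.4))])
        assert out["pur_offset"] == pytest.approx(0.5, abs=1e-3)

    def test_saccade_masking_noop_on_saccade_free_trace(self):
        trial = self._pursuit_trial(offset=(0.2, 0.0))
        sacs = detect_saccades(trial.gaze)
        assert sacs == []
        keep = saccade_mask(trial.gaze, sacs, pre_pad_s=0.30)
        assert keep.all()
        out = pursuit_outcomes([trial])
        assert out["pur_offset"] == pytest.approx(0.2, abs=1e-6)


class TestSaccadeOutcomes:
    def _response_trial(self, task, side, respond_sign, latency=0.25):
        n = int(2 * HZ)
        t = np.arange(n) / HZ
        cue = 0.7
        x = respond_sign * saccade_position(t - cue - latency, 11.2)
        trace = trace_from_deg(x, np.zeros(n))
        return _trial(trace, point_target(0, 0, 2.0, task=task, side=side),
                      test_id="saccade",
                      events=[("secondary_onset", cue)])

    def test_pro_toward_target_correct(self):
        out = saccade_outcomes([self._response_trial("pro", +1, +1)])
        assert out["sacc_pro_correct"] == 1.0
        assert out["sacc_pro_latency"] == pytest.approx(0.25, abs=0.02)

    def test_anti_toward_target_incorrect(self):
        out = saccade_outcomes([self._response_trial("anti", +1, +1)])
        assert out["sacc_anti_correct"] == 0.0

    def test_anti_away_from_target_correct(self):
        out = saccade_outcomes([self._response_trial("anti", +1, -1)])
        assert out["sacc_anti_correct"] == 1.0

    def test_missing_response_counts_incorrect_without_latency(self):
        n = int(2 * HZ)
        quiet = _trial(trace_from_deg(np.zeros(n), np.zeros(n)),
                       point_target(0, 0, 2.0, task="pro", side=1),
                       test_id="saccade", events=[("secondary_onset", 0.7)])
        out = saccade_outcomes([quiet])
        assert out["sacc_pro_correct"] == 0.0
        assert np.isnan(out["sacc_pro_latency"])


class TestVOROutcomes:
    def _vor_trial(self, eye_fraction):
        """Head yaw ramp at 100 deg/s; gaze moves (1-g) * yaw."""
        duration = 0.8
        n = int(duration * HZ)
        t = np.arange(n) / HZ
        yaw = np.clip((t - 0.2) * 100.0, 0.0, None)
        th = np.arange(int(duration * config.HEAD_HZ)) / config.HEAD_HZ
        head = HeadTrace(t=th, yaw_deg=np.interp(th, t, yaw),
                         pitch_deg=np.zeros(len(th)),
                         x_mm=np.zeros(len(th)), y_mm=np.zeros(len(th)))
        rng = np.random.default_rng(5)
        x = (1 - eye_fraction) * yaw + rng.normal(0, 1e-3, n)
        trace = trace_from_deg(x, rng.normal(0, 1e-3, n))
        return _trial(trace, point_target(0, 0, duration), test_id="vor",
                      head=head, events=[("head_onset", 0.2)])

    def test_perfect_counter_rotation_gain_one(self):
        out = vor_outcomes([self._vor_trial(1.0)])
        assert out["vor_gain"] == pytest.approx(1.0, abs=0.02)
        assert out["vor_nsacc"] == 0.0
        assert out["vor_bcea"] <= 1.0   # gaze essentially stationary

    def test_constructed_gain_ratio_recovered(self):
        out = vor_outcomes([self._vor_trial(0.8)])
        assert out["vor_gain"] == pytest.approx(0.8, abs=0.02)

    def test_incomplete_rotation_skipped(self):
        duration = 0.8
        n = int(duration * HZ)
        th = np.arange(int(duration * config.HEAD_HZ)) / config.HEAD_HZ
        yaw = np.clip((th - 0.2) * 40.0, 0.0, 8.0)   # never reaches 15 deg
        head = HeadTrace(t=th, yaw_deg=yaw, pitch_deg=np.zeros(len(th)),
                         x_mm=np.zeros(len(th)), y_mm=np.zeros(len(th)))
        trial = _trial(trace_from_deg(np.zeros(n), np.zeros(n)),
                       point_target(0, 0, duration), test_id="vor", head=head)
        out = vor_outcomes([trial])
        assert np.isnan(out["vor_bcea"]) and np.isnan(out["vor_gain"])

    def test_window_limited_to_first_15_degrees(self):
        # intrusion injected after 15 deg of rotation is not counted
        duration = 0.8
        n = int(duration * HZ)
        t = np.arange(n) / HZ
        yaw = np.clip((t - 0.1) * 100.0, 0.0, None)
        th = np.arange(int(duration * config.HEAD_HZ)) / config.HEAD_HZ
        head = HeadTrace(t=th, yaw_deg=np.interp(th, t, yaw),
                         pitch_deg=np.zeros(len(th)),
                         x_mm=np.zeros(len(th)), y_mm=np.zeros(len(th)))
        # 15 deg reached at t = 0.25; saccade starts well after
        x = np.zeros(n) + saccade_position(t - 0.45, 11.2)
        trial = _trial(trace_from_deg(x, np.zeros(n)),
                       point_target(0, 0, duration), test_id="vor", head=head)
        out = vor_outcomes([trial])
        assert out["vor_nsacc"] == 0.0


@pytest.fixture(scope="module")
def cohort():
    spec = CohortSpec(n_control=10, n_mtbi=10, n_ppcs=10, seed=21)
    return simulate_cohort(spec)


@pytest.fixture(scope="module")
def table(cohort):
    return build_feature_table(cohort.trials)


class TestFeatureTable:
    def test_one_row_per_participant_all_columns(self, table):
        assert len(table) == 30
        assert list(table.columns) == ["participant_id", "group", "session",
                                       *FEATURE_COLUMNS]
        assert table[FEATURE_COLUMNS].notna().all().all()

    def test_proportions_in_unit_interval(self, table):
        for c in ["sacc_pro_correct", "sacc_anti_correct",
                  "stroop1_correct", "stroop2_correct"]:
            assert table[c].between(0, 1).all()

    def test_empty_input_gives_empty_table_with_header(self):
        df = build_feature_table([])
        assert len(df) == 0
        assert list(df.columns) == ["participant_id", "group", "session",
                                    *FEATURE_COLUMNS]

    def test_ground_truth_recovery_correlations(self, cohort, table):
        """Extracted outcomes track the generating latents (r > 0.9)."""
        gt = cohort.ground_truth.set_index("participant_id")
        df = table.set_index("participant_id")
        pairs = [
            ("fix_err_v", "fix_offset_v"),
            ("pur_gain_v", "pur_gain_v"),
            ("pur_offset", "pur_offset_mag"),
            ("vor_bcea", "vor_bcea_log"),
            ("sacc_pro_latency", "pro_latency"),
            ("sacc_anti_latency", "anti_latency"),
            ("stroop1_latency", "stroop_latency"),
            ("ego_offset", "ego_offset"),
        ]
        for feat, latent in pairs:
            r = np.corrcoef(df[feat], gt[latent])[0, 1]
            assert r > 0.9, (feat, latent, r)

    def test_missing_test_keeps_row_with_nan(self, cohort):
        some = [tr for tr in cohort.trials
                if tr.test_id in ("fixation",) and tr.participant_id == "C001"]
        df = build_feature_table(some)
        assert len(df) == 1
        assert np.isfinite(df.loc[0, "fix_bcea"])
        assert np.isnan(df.loc[0, "vor_bcea"])

    def test_out_of_range_trials_logged_as_excluded(self, cohort):
        import dataclasses
        trial = cohort.trials[0]
        bad_trace = dataclasses.replace(
            trial.gaze, distance_mm=np.full(len(trial.gaze), 460.0))
        bad = dataclasses.replace(trial, gaze=bad_trace)
        df = build_feature_table([bad])
        assert len(df) == 0
        assert df.attrs["exclusions"][0]["reason"] == "out_of_range"
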
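import numpy as np
import pytest

import fallwatch as fw
from fallwatch.extract import (activity_parameters, detect_all_steps,
                               detect_steps, detect_transitions,
                               gait_parameters, transition_parameters)
from fallwatch.synthcohort import (ACTIVITY_CODE, LYING, OUT_OF_ROOM, SITTING,
                                   STANDING, WALKING, LabeledTrajectory)

FS = 30.0


def make_traj(z, act, x=None, y=None):
    n = len(z)
    t = np.arange(n) / FS
    x = np.zeros(n) if x is None else np.asarray(x, float)
    y = np.zeros(n) if y is None else np.asarray(y, float)
    return LabeledTrajectory(time=t, x=x, y=y, z=np.asarray(z, float),
                             activity=np.asarray(act, dtype=np.int8))


class TestDetectSteps:
    def test_constant_z_no_steps(self):
        t = np.arange(0, 3, 1 / FS)
        assert detect_steps(t, np.zeros_like(t), np.zeros_like(t),
                            np.full_like(t, 0.9)) == []

    def test_sinusoid_five_cycles_four_steps(self):
        t = np.arange(0, 5, 1 / FS)
        z = 0.9 + 0.05 * np.sin(2 * np.pi * t - np.pi / 2)  # maxima at 0.5+k
        steps = detect_steps(t, np.zeros_like(t), np.zeros_like(t), z)
        assert len(steps) == 4
        assert all(s.duration == pytest.approx(1.0, abs=0.05) for s in steps)

    def test_ten_peak_bout_nine_events(self):
        # ten oscillation cycles, peak spacing 0.55 s, 0.3 m per interval
        t = np.arange(0, 6.5, 1 / FS)
        u = np.clip((t - 0.275) / 0.55, -0.5, 9.5)
        z = 0.95 - 0.02 * (1 - np.cos(2 * np.pi * u))
        x = 0.3 / 0.55 * np.clip(t, 0.275, 0.275 + 9 * 0.55)
        steps = detect_steps(t, x, np.zeros_like(t), z)
        assert len(steps) == 9
        durations = [s.duration for s in steps]
        assert np.mean(durations) == pytest.approx(0.55, abs=0.02)
        lengths = [s.length for s in steps]
        assert np.mean(lengths) == pytest.approx(0.3, abs=0.02)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            detect_steps(np.array([0.0, 0.1]), np.zeros(2), np.zeros(2),
                         np.zeros(2))

    def test_small_oscillation_below_prominence_ignored(self):
        t = np.arange(0, 5, 1 / FS)
        z = 0.9 + 0.003 * np.sin(2 * np.pi * t)  # 3 mm < 1 cm floor
        assert detect_steps(t, t, np.zeros_like(t), z) == []


class TestGaitParameters:
    @staticmethod
    def steps(pairs):
        t = 0.0
        out = []
        for length, dur in pairs:
            out.append(fw.StepEvent(bout_id=0, t_peak_prev=t, t_peak=t + dur,
                                    length=length, duration=dur))
            t += dur
        return out

    def test_identical_steps(self):
        g = gait_parameters(self.steps([(0.5, 0.5)] * 4))
        assert g["mean_step_length_m"] == pytest.approx(0.5)
        assert g["mean_step_duration_s"] == pytest.approx(0.5)
        assert g["cv_step_length"] == 0 and g["cv_step_duration"] == 0
        assert g["cv_pace"] == 0
        assert g["mean_pace_steps_per_s"] == pytest.approx(2.0)
        assert g["mean_gait_speed_mps"] == pytest.approx(1.0)

    def test_two_step_arithmetic(self):
        g = gait_parameters(self.steps([(0.4, 0.5), (0.6, 0.5)]))
        assert g["mean_step_length_m"] == pytest.approx(0.5)
        assert g["mean_gait_speed_mps"] == pytest.approx(1.0)

    def test_fewer_than_two_steps_flagged_missing(self):
        g = gait_parameters(self.steps([(0.5, 0.5)]))
        assert all(np.isnan(v) for v in g.values())

    def test_full_day_recovers_truth_mean(self, subject_day):
        traj, truth = subject_day
        g = gait_parameters(detect_all_steps(traj))
        assert g["mean_step_length_m"] == pytest.approx(
            truth.step_length_m.mean(), abs=0.02)

    def test_step_count_exactness(self, cohort_days):
        """Detected steps == drawn steps minus exactly one boundary loss/bout."""
        for _, traj, truth in cohort_days:
            detected = len(detect_all_steps(traj))
            n_bouts = len(np.unique(truth.step_bout))
            assert detected == len(truth.step_length_m) - n_bouts


class TestActivityParameters:
    def test_half_day_sitting(self):
        act = [SITTING] * 100 + [STANDING] * 100
        p = activity_parameters(act)
        assert p["total_sitting_pct"] == pytest.approx(50.0)
        assert p["n_transitions"] == 1

    def test_run_sequence_transitions(self):
        act = [SITTING] * 10 + [WALKING] * 10 + [SITTING] * 10
        assert activity_parameters(act)["n_transitions"] == 2

    def test_whole_day_out_of_room(self):
        p = activity_parameters([OUT_OF_ROOM] * 50)
        assert p["out_of_room_pct"] == 100.0
        assert p["total_sitting_pct"] == 0.0 and p["total_lying_pct"] == 0.0

    def test_budget_conservation(self, subject_day):
        traj, _ = subject_day
        p = activity_parameters(traj.activity)
        total = (p["total_lying_pct"] + p["total_sitting_pct"] +
                 p["out_of_room_pct"] + p["walking_standing_pct"])
        assert total == pytest.approx(100.0)

    def test_out_of_room_boundary_toggle(self):
        act = [SITTING] * 10 + [OUT_OF_ROOM] * 10 + [SITTING] * 10
        assert activity_parameters(act, include_out_of_room=True)["n_transitions"] == 2
        assert activity_parameters(act, include_out_of_room=False)["n_transitions"] == 0


class TestTransitionParameters:
    def _ramp_traj(self, kind="get_up", dur=2.0, z_lo=0.55, z_hi=0.95):
        hold = int(10 * FS)
        ramp = int(dur * FS)
        if kind == "get_up":
            z = np.concatenate([np.full(hold, z_lo),
                                np.linspace(z_lo, z_hi, ramp),
                                np.full(hold, z_hi)])
            act = [SITTING] * (hold + ramp // 2) + \
                  [STANDING] * (len(z) - hold - ramp // 2)
        else:
            z = np.concatenate([np.full(hold, z_hi),
                                np.linspace(z_hi, z_lo, ramp),
                                np.full(hold, z_lo)])
            act = [STANDING] * (hold + ramp // 2) + \
                  [SITTING] * (len(z) - hold - ramp // 2)
        return make_traj(z, act)

    def test_get_up_ramp_arithmetic(self):
        p = transition_parameters(self._ramp_traj("get_up"))
        assert p["time_to_get_up_s"] == pytest.approx(2.0, abs=0.1)
        assert p["speed_to_get_up_mps"] == pytest.approx(0.2, abs=0.01)
        assert np.isnan(p["time_to_sit_s"])

    def test_symmetry(self):
        up = transition_parameters(self._ramp_traj("get_up"))
        down = transition_parameters(self._ramp_traj("sit_down"))
        assert up["speed_to_get_up_mps"] == pytest.approx(
            down["speed_to_sit_mps"], rel=1e-6)

    def test_no_sitting_flagged_missing(self):
        traj = make_traj(np.full(100, 0.95), [STANDING] * 100)
        p = transition_parameters(traj)
        assert all(np.isnan(v) for v in p.values())

    def test_synthetic_day_get_up_speed(self, cohort_days):
        for _, traj, truth in cohort_days[:5]:
            true_speeds = [t["speed"] for t in truth.transitions
                           if t["kind"] == "get_up"]
            if not true_speeds:
                continue
            p = transition_parameters(traj)
            assert p["speed_to_get_up_mps"] == pytest.approx(
                np.mean(true_speeds), rel=0.15)

    def test_lying_changes_not_scored(self):
        hold = int(5 * FS)
        z = np.concatenate([np.full(hold, 0.55), np.linspace(0.55, 0.30, 60),
                            np.full(hold, 0.30)])
        act = [SITTING] * (hold + 30) + [LYING] * (hold + 30)
        events = detect_transitions(make_traj(z, act))
        assert events == []


class TestExtractParameters:
    def test_all_fifteen_populated(self, subject_day):
        traj, _ = subject_day
        ps = fw.extract_parameters(traj)
        vals = ps.as_dict()
        assert set(vals) == set(fw.PARAMETER_NAMES)
        assert all(np.isfinite(v) for v in vals.values())

    def test_day_without_walking(self):
        hold = int(60 * FS)
        z = np.concatenate([np.full(hold, 0.95), np.linspace(0.95, 0.55, 60),
                            np.full(hold, 0.55)])
        act = [STANDING] * (hold + 30) + [SITTING] * (hold + 30)
        ps = fw.extract_parameters(make_traj(z, act))
        assert np.isnan(ps.mean_step_length_m)
        assert np.isfinite(ps.total_sitting_pct)
        assert ps.total_sitting_pct == pytest.approx(50.0, abs=1.0)

    def test_scale_equivariance(self, subject_day):
        traj, _ = subject_day
        c = 2.0
        scaled = LabeledTrajectory(time=traj.time, x=traj.x * c, y=traj.y * c,
                                   z=traj.z, activity=traj.activity)
        a = fw.extract_parameters(traj)
        b = fw.extract_parameters(scaled)
        assert b.mean_step_length_m == pytest.approx(c * a.mean_step_length_m)
        assert b.mean_gait_speed_mps == pytest.approx(c * a.mean_gait_speed_mps)
        assert b.cv_step_length == pytest.approx(a.cv_step_length)
        assert b.mean_step_duration_s == pytest.approx(a.mean_step_duration_s)

    def test_parameter_recovery_short_cohort(self, cohort_days, cohort_features):
        truth_means = np.array([t.step_length_m.mean() for _, _, t in cohort_days])
        extracted = cohort_features["mean_step_length_m"].to_numpy()
        assert abs((extracted - truth_means).mean()) <= 0.02
        assert np.corrcoef(extracted, truth_means)[0, 1] >= 0.95

    def test_cohort_table_one_row_per_subject(self, cohort_features):
        assert cohort_features.shape == (30, 15)


class TestCentroidFromDepth:
    def test_rendered_blob_centroid(self, small_camera):
        centroid = np.array([2.2, 2.8, 0.9])
        traj = LabeledTrajectory(time=np.array([0.0]),
                                 x=np.array([centroid[0]]),
                                 y=np.array([centroid[1]]),
                                 z=np.array([centroid[2]]),
                                 activity=np.array([WALKING], dtype=np.int8))
        seq = fw.render_depth_sequence(traj, small_camera, noise_sd_mm=0.0)
        series = fw.extract_centroid_series(seq)
        rec = np.array([series.x[0], series.y[0], series.z[0]])
        assert np.linalg.norm(rec - centroid) < 0.01

    def test_pure_background_marked_out_of_room(self, small_camera):
        from fallwatch.synthcohort import DepthSequence
        bg = small_camera.render_background()
        seq = DepthSequence(frames=bg[None, :, :].copy(),
                            timestamps=np.array([0.0]), camera=small_camera,
                            background=bg)
        series = fw.extract_centroid_series(seq)
        assert series.activity[0] == OUT_OF_ROOM
        assert np.isnan(series.x[0])

    def test_two_equal_blobs_midpoint(self, small_camera):
        bg = np.full((72, 96), 8000.0)
        frame = bg.copy()
        frame[30:40, 10:20] = 3000.0
        frame[30:40, 70:80] = 3000.0
        from fallwatch.synthcohort import DepthSequence
        seq = DepthSequence(frames=frame[None], timestamps=np.array([0.0]),
                            camera=small_camera, background=bg)
        series = fw.extract_centroid_series(seq)
        # centroid of the union = midpoint of the two blob centroids
        vv, uu = np.nonzero(np.abs(frame - bg) > 300)
        left = (uu < 50)
        p1 = small_camera.backproject(uu[left], vv[left],
                                      frame[vv[left], uu[left]] / 1000.0).mean(axis=0)
        p2 = small_camera.backproject(uu[~left], vv[~left],
                                      frame[vv[~left], uu[~left]] / 1000.0).mean(axis=0)
        mid = (p1 + p2) / 2
        rec = np.array([series.x[0], series.y[0], series.z[0]])
        np.testing.assert_allclose(rec, mid, atol=1e-9)

    def test_dimension_mismatch_rejected(self, small_camera):
        from fallwatch.synthcohort import DepthSequence
        bg = small_camera.render_background()
        seq = DepthSequence(frames=np.zeros((1, 10, 10)),
                            timestamps=np.array([0.0]), camera=small_camera,
                            background=bg)
        with pytest.raises(ValueError):
            fw.extract_centroid_series(seq)
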
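"""Step detection, anatomical planes, step side, periods and gait phases."""

import numpy as np
import pytest

from gaitlab import (
    KeypointTrajectory,
    StepRecord,
    assign_step_side,
    compute_planes,
    detect_gait_phases,
    detect_step_peaks,
    extract_parameters,
    inter_ankle_distance_series,
    step_periods_and_speeds,
)
from gaitlab.errors import (
    ConfigurationError,
    DegenerateGeometryError,
    NoGaitDetectedError,
    OrderingError,
)
from gaitlab.kinematics import AngularVelocitySeries
from gaitlab.skeleton import JOINT_INDEX, N_JOINTS

from conftest import random_coords


class TestInterAnkleDistance:
    def test_simple_and_coincident(self):
        coords = np.zeros((2, N_JOINTS, 3))
        coords[0, JOINT_INDEX["ankle_right"]] = [300.0, 0.0, 0.0]
        traj = KeypointTrajectory(coords, 30.0)
        d = inter_ankle_distance_series(traj)
        assert d[0] == 300.0
        assert d[1] == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(20)
        traj = KeypointTrajectory(random_coords(rng, 6), 30.0)
        d = inter_ankle_distance_series(traj)
        for f in range(6):
            expected = np.sqrt(
                np.sum(
                    (
                        traj.coords[f, JOINT_INDEX["ankle_left"]]
                        - traj.coords[f, JOINT_INDEX["ankle_right"]]
                    )
                    ** 2
                )
            )
            assert d[f] == pytest.approx(expected, abs=0.0)


class TestStepPeaks:
    def test_constant_series_no_steps(self):
        assert detect_step_peaks(np.full(20, 250.0)) == []

    def test_threshold_filters_small_bump(self):
        peaks = detect_step_peaks(np.array([100.0, 500.0, 100.0, 200.0, 100.0]), 0.5)
        assert peaks == [(1, 500.0)]

    def test_bad_threshold(self):
        with pytest.raises(ConfigurationError):
            detect_step_peaks(np.arange(5.0), threshold_fraction=1.5)

    def test_synthetic_walk_steps(self, walk600):
        _cfg, traj, gt = walk600
        d = inter_ankle_distance_series(traj)
        peaks = detect_step_peaks(d, 0.5, min_separation=9)
        assert len(peaks) == gt.n_steps
        for (_f, value), truth in zip(peaks, gt.step_lengths):
            assert value == pytest.approx(truth, rel=0.01)


class TestPlanes:
    def _spine(self, sv, tv, cv):
        coords = np.zeros((2, N_JOINTS, 3))
        coords[:, JOINT_INDEX["sacrum"]] = sv
        coords[:, JOINT_INDEX["thorax"]] = tv
        coords[:, JOINT_INDEX["neck"]] = cv
        return KeypointTrajectory(coords, 30.0)

    def test_example_normals(self):
        traj = self._spine([0, 0, 1000], [0, 10, 1300], [0, 0, 1500])
        planes = compute_planes(traj, 0)
        assert abs(abs(planes.sagittal_normal[0]) - 1.0) < 1e-9
        assert abs(abs(planes.coronal_normal[1]) - 1.0) < 1e-9

    def test_collinear_spine_error(self):
        traj = self._spine([0, 0, 1000], [0, 0, 1300], [0, 0, 1500])
        with pytest.raises(DegenerateGeometryError, match="frame 0"):
            compute_planes(traj, 0)

    def test_orthogonality_random_frames(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            traj = KeypointTrajectory(random_coords(rng, 2), 30.0)
            try:
                planes = compute_planes(traj, 0)
            except DegenerateGeometryError:
                continue
            sv = traj.coords[0, JOINT_INDEX["sacrum"]]
            cv = traj.coords[0, JOINT_INDEX["neck"]]
            axis = (cv - sv) / np.linalg.norm(cv - sv)
            assert abs(np.dot(planes.coronal_normal, planes.sagittal_normal)) < 1e-9
            assert abs(np.dot(planes.coronal_normal, axis)) < 1e-9
            assert np.linalg.norm(planes.sagittal_normal) == pytest.approx(1.0, abs=1e-12)


class TestStepSide:
    def _walking_frame(self, left_x, right_x):
        """Sacrum advancing along +x; ankles at given x offsets from it."""
        n = 3
        coords = np.zeros((n, N_JOINTS, 3))
        for f in range(n):
            sx = 100.0 * f
            coords[f, JOINT_INDEX["sacrum"]] = [sx, 0, 1000]
            coords[f, JOINT_INDEX["thorax"]] = [sx + 30, 0, 1300]
            coords[f, JOINT_INDEX["neck"]] = [sx, 0, 1500]
            coords[f, JOINT_INDEX["ankle_left"]] = [sx + left_x, 60, 0]
            coords[f, JOINT_INDEX["ankle_right"]] = [sx + right_x, -60, 0]
        return KeypointTrajectory(coords, 30.0)

    def test_anterior_foot_wins(self):
        traj = self._walking_frame(left_x=100.0, right_x=-50.0)
        assert assign_step_side(traj, [(1, 400.0)]) == ["left"]

    def test_mirrored_frame_flips(self):
        traj = self._walking_frame(left_x=-50.0, right_x=100.0)
        assert assign_step_side(traj, [(1, 400.0)]) == ["right"]

    def test_near_tie_warns(self):
        traj = self._walking_frame(left_x=100.0, right_x=99.5)
        with pytest.warns(UserWarning, match="ambiguous"):
            assign_step_side(traj, [(1, 400.0)])

    def test_synthetic_walk_sides_match_truth(self, walk600, profile):
        _cfg, traj, gt = walk600
        result = extract_parameters(traj, profile)
        assert result.steps["side"].tolist() == gt.step_sides


class TestPeriodsAndSpeeds:
    def test_arithmetic(self):
        records = [
            StepRecord(index=0, frame=30, step_length=600.0, time=1.0),
            StepRecord(index=1, frame=48, step_length=600.0, time=1.6),
        ]
        out = step_periods_and_speeds(records)
        assert out[0].step_period is None
        assert out[1].step_period == pytest.approx(0.6)
        assert out[1].walking_speed == pytest.approx(1000.0)

    def test_non_increasing_times_error(self):
        records = [
            StepRecord(index=0, frame=30, step_length=600.0, time=1.0),
            StepRecord(index=1, frame=30, step_length=600.0, time=1.0),
        ]
        with pytest.raises(OrderingError):
            step_periods_and_speeds(records)


class TestGaitPhases:
    def test_constant_omega_no_gait(self):
        omega = AngularVelocitySeries(np.zeros(50), "left", 30.0)
        with pytest.raises(NoGaitDetectedError):
            detect_gait_phases(omega)

    def test_hand_traced_strides(self):
        # per 1 s stride at 50 Hz: min -300 deg/s at t=0.2, max +400 deg/s at
        # t=0.5, first sample below 10 deg/s at t=0.62
        template = np.zeros(50)
        template[1:10] = np.linspace(-300 / 10, -300 * 9 / 10, 9)
        template[9] = -300.0  # t = 0.20, strict minimum
        template[10:24] = np.linspace(-250, 350, 14)
        template[24] = 400.0  # t = 0.50, strict maximum
        template[25:30] = [300.0, 200.0, 100.0, 50.0, 11.0]
        template[30] = 5.0  # t = 0.62, first < 10
        template[31:35] = [4.0, 3.0, 2.0, 1.0]
        omega = AngularVelocitySeries(np.tile(template, 3), "left", 50.0)
        records = detect_gait_phases(omega, heel_strike_threshold=10.0)
        # times property indexes omega sample j at (j+1)/f; the template is
        # laid out so sample j corresponds to t=(j+1)/50
        assert len(records) == 3
        for k, rec in enumerate(records):
            assert rec.toe_off == pytest.approx(k + 0.20, abs=1e-9)
            assert rec.heel_strike == pytest.approx(k + 0.62, abs=1e-9)
            assert rec.swing == pytest.approx(0.42, abs=1e-9)
            if k > 0:
                assert rec.support == pytest.approx(0.58, abs=1e-9)

    def test_walk_events_alternate_and_translate_invariant(self, walk600, profile):
        _cfg, traj, gt = walk600
        result = extract_parameters(traj, profile)
        for side in ("left", "right"):
            sub = result.phases[result.phases["side"] == side]
            splits = sub["t_split_s"].to_numpy()
            touches = sub["t_touch_s"].to_numpy()
            assert np.all(np.diff(splits) > 0)
            assert np.all(np.diff(touches) > 0)
            assert np.all(touches > splits)
            # swing + support of interior cycles ~ one stride (2 steps)
            interior = sub.dropna(subset=["t_support_s"])
            stride = (interior["t_swing_s"] + interior["t_support_s"]).to_numpy()
            assert np.allclose(stride, 1.2, atol=1.0 / 30.0)
        # rigid translation changes nothing
        moved = KeypointTrajectory(traj.coords + np.array([1000.0, -500.0, 250.0]), 30.0)
        again = extract_parameters(moved, profile)
        assert again.steps["T_s"].tolist() == result.steps["T_s"].tolist()
        assert again.steps["side"].tolist() == result.steps["side"].tolist()
        np.testing.assert_allclose(
            again.phases["t_split_s"], result.phases["t_split_s"], atol=1e-9
        )
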
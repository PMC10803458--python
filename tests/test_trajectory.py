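"""Trajectory I/O, centering, scaling, resampling and signal alignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitlab import (
    KeypointTrajectory,
    SubjectProfile,
    align_signals,
    center_keypoints,
    read_trajectory,
    resample_trajectory,
    scale_keypoints,
    write_trajectory,
)
from gaitlab.errors import (
    ConfigurationError,
    DegenerateGeometryError,
    FormatError,
    TrajectoryParseError,
    UndefinedStatisticError,
)
from gaitlab.skeleton import JOINT_INDEX, N_JOINTS

from conftest import random_coords


def make_traj(coords, rate=30.0):
    return KeypointTrajectory(np.asarray(coords, dtype=float), rate)


class TestIO:
    @pytest.mark.parametrize("suffix", ["csv", "json"])
    def test_round_trip(self, walk600, tmp_path, suffix):
        _cfg, traj, _gt = walk600
        path = tmp_path / f"walk.{suffix}"
        write_trajectory(traj, path)
        back = read_trajectory(path, frame_rate=30.0)
        assert back.n_frames == traj.n_frames
        np.testing.assert_allclose(back.coords, traj.coords, atol=1e-6)

    def test_two_frame_csv(self, tmp_path):
        rng = np.random.default_rng(0)
        traj = make_traj(random_coords(rng, 2))
        path = tmp_path / "two.csv"
        write_trajectory(traj, path)
        assert read_trajectory(path, frame_rate=30.0).n_frames == 2

    def test_missing_column_named(self, walk600, tmp_path):
        _cfg, traj, _gt = walk600
        path = tmp_path / "walk.csv"
        write_trajectory(traj, path)
        text = path.read_text().replace("knee_left_z", "knee_left_zz")
        bad = tmp_path / "bad.csv"
        bad.write_text(text)
        with pytest.raises(FormatError, match="knee_left_z"):
            read_trajectory(bad, frame_rate=30.0)

    def test_non_numeric_cell_reports_row(self, tmp_path):
        rng = np.random.default_rng(1)
        traj = make_traj(random_coords(rng, 4))
        path = tmp_path / "walk.csv"
        write_trajectory(traj, path)
        lines = path.read_text().splitlines()
        parts = lines[3].split(",")
        parts[5] = "oops"
        lines[3] = ",".join(parts)
        bad = tmp_path / "bad.csv"
        bad.write_text("\n".join(lines))
        with pytest.raises(TrajectoryParseError, match="row 2"):
            read_trajectory(bad, frame_rate=30.0)


class TestCentering:
    def test_head_example(self):
        coords = np.zeros((2, N_JOINTS, 3))
        coords[:, JOINT_INDEX["sacrum"]] = [100.0, 200.0, 300.0]
        coords[:, JOINT_INDEX["head"]] = [100.0, 200.0, 1800.0]
        out = center_keypoints(make_traj(coords))
        np.testing.assert_allclose(out.joint("head")[0], [0.0, 0.0, 1500.0])
        np.testing.assert_allclose(out.joint("sacrum"), 0.0)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        traj = make_traj(random_coords(rng))
        once = center_keypoints(traj)
        twice = center_keypoints(once)
        np.testing.assert_array_equal(once.coords, twice.coords)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_pairwise_distances_preserved(self, seed):
        rng = np.random.default_rng(seed)
        traj = make_traj(random_coords(rng, 3))
        out = center_keypoints(traj)
        for f in range(traj.n_frames):
            d0 = np.linalg.norm(traj.coords[f, :, None] - traj.coords[f, None, :], axis=-1)
            d1 = np.linalg.norm(out.coords[f, :, None] - out.coords[f, None, :], axis=-1)
            np.testing.assert_allclose(d0, d1, atol=1e-9)


class TestScaling:
    def _legs(self, shank=400.0, sep=100.0, n=3):
        coords = np.zeros((n, N_JOINTS, 3))
        coords[:, JOINT_INDEX["knee_left"]] = [0.0, 0.0, shank]
        coords[:, JOINT_INDEX["ankle_left"]] = [0.0, 0.0, 0.0]
        coords[:, JOINT_INDEX["knee_right"]] = [sep, 0.0, shank]
        coords[:, JOINT_INDEX["ankle_right"]] = [sep, 0.0, 0.0]
        return coords

    def test_half_ratio(self, ):
        # computed shank sum 800 mm, measured 200 + 200 -> every frame halved
        traj = make_traj(self._legs(shank=400.0))
        prof = SubjectProfile(200.0, 200.0, 60.0)
        out = scale_keypoints(traj, prof)
        np.testing.assert_allclose(out.coords, traj.coords * 0.5, atol=1e-9)
        np.testing.assert_allclose(out.joint("knee_left")[0], [0.0, 0.0, 200.0], atol=1e-6)

    def test_identity_when_matched(self):
        traj = make_traj(self._legs(shank=400.0))
        prof = SubjectProfile(400.0, 400.0, 60.0)
        out = scale_keypoints(traj, prof)
        np.testing.assert_allclose(out.coords, traj.coords, atol=1e-9)

    def test_scaled_shank_sum_matches_measured(self):
        rng = np.random.default_rng(3)
        coords = self._legs(shank=350.0) + rng.normal(0, 20, size=(3, N_JOINTS, 3))
        traj = make_traj(coords)
        prof = SubjectProfile(210.0, 230.0, 60.0)
        out = scale_keypoints(traj, prof)
        for f in range(out.n_frames):
            total = np.linalg.norm(
                out.joint("knee_left")[f] - out.joint("ankle_left")[f]
            ) + np.linalg.norm(out.joint("knee_right")[f] - out.joint("ankle_right")[f])
            assert abs(total - 440.0) < 1e-6

    def test_homogeneous_degree_one(self):
        rng = np.random.default_rng(4)
        coords = self._legs() + rng.normal(0, 10, size=(3, N_JOINTS, 3))
        prof = SubjectProfile(300.0, 310.0, 60.0)
        a = scale_keypoints(make_traj(coords), prof)
        b = scale_keypoints(make_traj(coords * 3.7), prof)
        np.testing.assert_allclose(a.coords, b.coords, atol=1e-8)

    def test_degenerate_frame_reported(self):
        coords = self._legs()
        coords[1, JOINT_INDEX["knee_left"]] = coords[1, JOINT_INDEX["ankle_left"]]
        coords[1, JOINT_INDEX["knee_right"]] = coords[1, JOINT_INDEX["ankle_right"]]
        with pytest.raises(DegenerateGeometryError, match="frame 1"):
            scale_keypoints(make_traj(coords), SubjectProfile(400.0, 400.0, 60.0))


class TestResampling:
    def test_identity_rate(self):
        rng = np.random.default_rng(5)
        traj = make_traj(random_coords(rng, 30), rate=30.0)
        out = resample_trajectory(traj, 30.0)
        np.testing.assert_allclose(out.coords, traj.coords, atol=1e-9)

    def test_constant_any_rate(self):
        coords = np.ones((50, N_JOINTS, 3)) * 123.4
        out = resample_trajectory(make_traj(coords, rate=100.0), 30.0)
        np.testing.assert_allclose(out.coords, 123.4, atol=1e-9)
        assert out.frame_rate == 30.0

    def test_sinusoid_closed_form(self):
        # 1 Hz, amplitude 100 mm, sampled at 100 Hz then resampled to 30 Hz
        t_src = np.arange(300) / 100.0
        coords = np.zeros((300, N_JOINTS, 3))
        coords[:, :, 2] = 100.0 * np.sin(2 * np.pi * t_src)[:, None]
        out = resample_trajectory(make_traj(coords, rate=100.0), 30.0)
        expected = 100.0 * np.sin(2 * np.pi * out.times)
        np.testing.assert_allclose(out.coords[:, 0, 2], expected, atol=0.1)

    def test_invalid_rate(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ConfigurationError):
            resample_trajectory(make_traj(random_coords(rng)), 0.0)


class TestAlignment:
    def test_self_alignment(self):
        x = np.sin(np.arange(100) * 0.3)
        assert align_signals(x, x).shift == 0

    def test_delayed_copy(self):
        # y(t) = x(t - 5): y lags x by 5 samples, C(tau)=sum x(t) y(t+tau)
        # peaks at tau = +5 under the implemented convention
        rng = np.random.default_rng(7)
        x = rng.normal(size=200)
        y = np.concatenate([np.zeros(5), x[:-5]])
        assert align_signals(x, y).shift == 5

    def test_impulse_shift_magnitude(self):
        x = np.zeros(40)
        x[10] = 1.0
        y = np.zeros(40)
        y[13] = 1.0
        assert abs(align_signals(x, y).shift) == 3

    @pytest.mark.parametrize("k", [-20, -7, -1, 0, 1, 4, 19])
    def test_shift_recovery_exact(self, k):
        rng = np.random.default_rng(8)
        x = rng.normal(size=80)
        y = np.roll(x, k)  # y(t) = x(t - k)
        # roll wraps, so use a padded copy to emulate a pure delay/advance
        if k >= 0:
            y = np.concatenate([np.zeros(k), x[: x.size - k]])
        else:
            y = np.concatenate([x[-k:], np.zeros(-k)])
        assert align_signals(x, y).shift == k

    def test_all_zero_error(self):
        with pytest.raises(UndefinedStatisticError):
            align_signals(np.zeros(10), np.ones(10))
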
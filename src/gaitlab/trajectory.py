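"""Trajectory data model, file I/O and preprocessing.

A :class:`KeypointTrajectory` is the pipeline's universal currency: an
``(n_frames, 17, 3)`` float array of joint positions in millimetres at a fixed
frame rate, with joints ordered by :data:`gaitlab.skeleton.JOINT_NAMES`.

Preprocessing mirrors the standard markerless workflow:

* ``center_keypoints`` — per-frame translation putting the sacrum at the origin,
  so every downstream measure lives in a body-relative frame;
* ``scale_keypoints`` — metric rescaling of scale-ambiguous monocular poses,
  anchored on the subject's measured shank lengths: each frame is multiplied by
  ``(L_left + L_right) / (||K_l - F_l|| + ||K_r - F_r||)`` computed from that
  frame's knee and ankle keypoints;
* ``resample_trajectory`` — per-coordinate linear interpolation onto a uniform
  grid at a new rate (e.g. optical-lab 100 Hz down to smartphone 30 Hz);
* ``align_signals`` — integer-lag cross-correlation alignment of two scalar
  series (knee-angle series in the validation workflow).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DegenerateGeometryError,
    FormatError,
    TrajectoryParseError,
    UndefinedStatisticError,
)
from .skeleton import AXES, COORDINATE_COLUMNS, JOINT_INDEX, JOINT_NAMES, N_JOINTS


@dataclass
class KeypointTrajectory:
    """Frames x 17 joints x 3 coordinates (mm) at a fixed frame rate."""

    coords: np.ndarray
    frame_rate: float
    joint_names: tuple[str, ...] = JOINT_NAMES
    source_label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (N_JOINTS, 3):
            raise ConfigurationError(
                f"coords must have shape (n, {N_JOINTS}, 3), got {self.coords.shape}"
            )
        if self.coords.shape[0] < 2:
            raise ConfigurationError("a trajectory needs at least 2 frames")
        if not np.all(np.isfinite(self.coords)):
            raise ConfigurationError("coords contain non-finite values")
        if not self.frame_rate > 0:
            raise ConfigurationError(f"frame_rate must be > 0, got {self.frame_rate}")
        if tuple(self.joint_names) != JOINT_NAMES:
            raise ConfigurationError("joint_names must match the shared registry order")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Frame times t_i = i / f in seconds (0-based frames)."""
        return np.arange(self.n_frames) / self.frame_rate

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) / self.frame_rate

    def joint(self, name: str) -> np.ndarray:
        """(n_frames, 3) view of one joint's path."""
        return self.coords[:, JOINT_INDEX[name], :]

    def copy(self) -> "KeypointTrajectory":
        return replace(self, coords=self.coords.copy())


@dataclass(frozen=True)
class SubjectProfile:
    """Measured anthropometry driving metric scaling and COM weighting."""

    shank_length_left: float
    shank_length_right: float
    body_mass: float
    group: str = "healthy"
    subject_id: str = "anonymous"

    def __post_init__(self) -> None:
        if not self.shank_length_left > 0 or not self.shank_length_right > 0:
            raise ConfigurationError("shank lengths must be > 0")
        if not self.body_mass > 0:
            raise ConfigurationError("body_mass must be > 0")


@dataclass(frozen=True)
class AlignmentResult:
    """Integer-frame shift maximising the cross-correlation of two series.

    ``shift`` > 0 means the second series lags the first by that many samples
    (C(tau) = sum_t x(t) * y(t + tau) is maximal at tau = shift).
    """

    shift: int
    peak_correlation: float


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def trajectory_to_frame(traj: KeypointTrajectory) -> pd.DataFrame:
    """Flatten a trajectory into the documented one-row-per-frame CSV layout."""
    flat = traj.coords.reshape(traj.n_frames, N_JOINTS * 3)
    df = pd.DataFrame(flat, columns=list(COORDINATE_COLUMNS))
    df.insert(0, "frame", np.arange(traj.n_frames))
    return df


def write_trajectory(traj: KeypointTrajectory, path: str | Path) -> None:
    """Write a trajectory as CSV or JSON depending on the file suffix."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "frame_rate": traj.frame_rate,
            "source_label": traj.source_label,
            "joints": list(JOINT_NAMES),
            "frames": traj.coords.tolist(),
        }
        path.write_text(json.dumps(payload))
    else:
        trajectory_to_frame(traj).to_csv(path, index=False)


def read_trajectory(path: str | Path, frame_rate: float | None = None) -> KeypointTrajectory:
    """Read a trajectory file (CSV or JSON dialect).

    CSV files carry no frame rate, so ``frame_rate`` is required for them; for
    JSON it overrides the stored value when given.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"trajectory file not found: {path}")
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        joints = tuple(payload.get("joints", ()))
        if joints != JOINT_NAMES:
            missing = sorted(set(JOINT_NAMES) - set(joints))
            raise FormatError(f"JSON trajectory joints do not match registry; missing {missing}")
        coords = np.asarray(payload["frames"], dtype=float)
        rate = frame_rate if frame_rate is not None else payload.get("frame_rate")
        if rate is None:
            raise FormatError(f"{path}: no frame_rate stored and none supplied")
        return KeypointTrajectory(coords, float(rate), source_label=str(path))

    if frame_rate is None:
        raise ConfigurationError("frame_rate is required when reading CSV trajectories")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise TrajectoryParseError(f"{path}: empty trajectory file") from exc
    if df.empty:
        raise TrajectoryParseError(f"{path}: empty trajectory file")
    missing = [c for c in COORDINATE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing coordinate columns {missing}")
    block = df[list(COORDINATE_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    bad = block.isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise TrajectoryParseError(f"{path}: non-numeric coordinate in row {row}")
    coords = block.to_numpy(dtype=float).reshape(len(df), N_JOINTS, 3)
    return KeypointTrajectory(coords, float(frame_rate), source_label=str(path))


def write_profile(profile: SubjectProfile, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "subject_id": profile.subject_id,
                "L_left_mm": profile.shank_length_left,
                "L_right_mm": profile.shank_length_right,
                "mass_kg": profile.body_mass,
                "group": profile.group,
            }
        )
    )


def read_profile(path: str | Path) -> SubjectProfile:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"subject profile not found: {path}")
    try:
        payload = json.loads(path.read_text())
        return SubjectProfile(
            shank_length_left=float(payload["L_left_mm"]),
            shank_length_right=float(payload["L_right_mm"]),
            body_mass=float(payload["mass_kg"]),
            group=str(payload.get("group", "healthy")),
            subject_id=str(payload.get("subject_id", path.stem)),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise FormatError(f"{path}: not a valid subject profile ({exc})") from exc


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def center_keypoints(traj: KeypointTrajectory) -> KeypointTrajectory:
    """Subtract the sacrum from every joint, per frame.

    The sacrum sits at the origin of every output frame; pairwise distances are
    untouched.  Idempotent.
    """
    sacrum = traj.coords[:, JOINT_INDEX["sacrum"], :][:, None, :]
    return replace(traj, coords=traj.coords - sacrum)


def _frame_shank_sums(traj: KeypointTrajectory) -> np.ndarray:
    kl = traj.joint("knee_left")
    fl = traj.joint("ankle_left")
    kr = traj.joint("knee_right")
    fr = traj.joint("ankle_right")
    return np.linalg.norm(kl - fl, axis=1) + np.linalg.norm(kr - fr, axis=1)


def scale_keypoints(
    traj: KeypointTrajectory,
    profile: SubjectProfile,
    mode: str = "per_frame",
) -> KeypointTrajectory:
    """Rescale a scale-ambiguous trajectory to metric units.

    The ratio (measured shank-length sum) / (keypoint shank-length sum) is
    computed from each frame's knees and ankles and applied to that frame
    (``mode='per_frame'``); ``mode='median'`` applies one trajectory-median
    ratio to every frame as a smoother variant.
    """
    if mode not in ("per_frame", "median"):
        raise ConfigurationError(f"mode must be 'per_frame' or 'median', got {mode!r}")
    computed = _frame_shank_sums(traj)
    degenerate = np.flatnonzero(computed <= 0)
    if degenerate.size:
        raise DegenerateGeometryError(
            f"zero shank-length sum at frame {int(degenerate[0])}"
        )
    measured = profile.shank_length_left + profile.shank_length_right
    ratio = measured / computed
    if mode == "median":
        ratio = np.full_like(ratio, np.median(ratio))
    return replace(traj, coords=traj.coords * ratio[:, None, None])


def resample_trajectory(traj: KeypointTrajectory, f_target: float) -> KeypointTrajectory:
    """Linearly interpolate every coordinate onto the grid t = k / f_target."""
    if not f_target > 0:
        raise ConfigurationError(f"f_target must be > 0, got {f_target}")
    t_src = traj.times
    n_out = int(np.floor(t_src[-1] * f_target)) + 1
    t_out = np.arange(n_out) / f_target
    flat = traj.coords.reshape(traj.n_frames, -1)
    out = np.empty((n_out, flat.shape[1]))
    for j in range(flat.shape[1]):
        out[:, j] = np.interp(t_out, t_src, flat[:, j])
    return replace(
        traj,
        coords=out.reshape(n_out, N_JOINTS, 3),
        frame_rate=float(f_target),
    )


def align_signals(x: np.ndarray, y: np.ndarray) -> AlignmentResult:
    """Integer-lag cross-correlation alignment of two same-rate series.

    Both series are mean-removed, then C(tau) = sum_t x(t) * y(t + tau) is
    scanned over every integer lag keeping at least 50% overlap of the shorter
    series; ties break toward the smallest |tau|.  ``shift`` > 0 means y lags x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ConfigurationError("both series need at least 2 samples")
    if not np.any(x) or not np.any(y):
        raise UndefinedStatisticError("alignment is undefined for an all-zero series")
    xc = x - x.mean()
    yc = y - y.mean()
    min_overlap = max(2, int(np.ceil(min(x.size, y.size) / 2)))
    best: tuple[float, int] | None = None
    max_lag_pos = y.size - min_overlap
    max_lag_neg = x.size - min_overlap
    for tau in range(-max_lag_neg, max_lag_pos + 1):
        # overlap of x[t] with y[t + tau]
        t_lo = max(0, -tau)
        t_hi = min(x.size, y.size - tau)
        if t_hi - t_lo < min_overlap:
            continue
        c = float(np.dot(xc[t_lo:t_hi], yc[t_lo + tau : t_hi + tau]))
        if best is None or c > best[0] + 1e-12 or (
            abs(c - best[0]) <= 1e-12 and abs(tau) < abs(best[1])
        ):
            best = (c, tau)
    if best is None:
        raise UndefinedStatisticError("series too short for the requested overlap")
    return AlignmentResult(shift=int(best[1]), peak_correlation=best[0])


def delay_trajectory(traj: KeypointTrajectory, frames: int) -> KeypointTrajectory:
    """Delay a trajectory by an integer number of frames (length preserved).

    The first ``frames`` output frames hold the initial pose.  Used to build
    controlled gold/test pairs for the validation workflow.
    """
    if frames < 0:
        raise ConfigurationError("delay must be non-negative")
    if frames == 0:
        return traj.copy()
    coords = np.concatenate(
        [np.repeat(traj.coords[:1], frames, axis=0), traj.coords[:-frames]], axis=0
    )
    return replace(traj, coords=coords)
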
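"""Knee joint kinematics: the included 3-point knee angle and its velocity.

The knee angle of frame *i* is the included angle at the knee between the
knee->hip and knee->ankle rays,

    theta_i = arccos( (K_i H_i) . (K_i A_i) / (||K_i H_i|| ||K_i A_i||) ),

reported in degrees, so a fully extended leg reads 180 deg.  Angular velocity
is the frame-rate-scaled backward difference omega_i = f * (theta_i -
theta_{i-1}), indexed to the later frame (the series is one sample shorter
than the angle series; no zero-padding).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, EmptyInputError
from .skeleton import side_joints
from .trajectory import KeypointTrajectory


@dataclass(frozen=True)
class AngleSeries:
    """Per-frame joint angle in degrees for one side."""

    values: np.ndarray
    side: str
    frame_rate: float

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.frame_rate


@dataclass(frozen=True)
class AngularVelocitySeries:
    """Signed angular velocity in deg/s, defined for frames i >= 1."""

    values: np.ndarray
    side: str
    frame_rate: float

    @property
    def times(self) -> np.ndarray:
        """Times of the defining (later) frame of each difference."""
        return (1.0 + np.arange(self.values.size)) / self.frame_rate


def included_angle(hip: np.ndarray, knee: np.ndarray, ankle: np.ndarray) -> np.ndarray:
    """Included angle at the knee, in degrees, vectorised over leading axes."""
    u = hip - knee
    v = ankle - knee
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    bad = (nu <= 0) | (nv <= 0)
    if np.any(bad):
        frame = int(np.flatnonzero(np.atleast_1d(bad))[0])
        raise DegenerateGeometryError(f"zero-length thigh or shank segment at frame {frame}")
    cosang = np.sum(u * v, axis=-1) / (nu * nv)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def knee_angle_series(
    traj: KeypointTrajectory,
    side: str,
    smooth_window: int | None = None,
) -> AngleSeries:
    """Knee angle per frame for one leg.

    ``smooth_window`` applies an optional centred moving average (odd window,
    in frames) to the angle series before it is returned.  This is an
    extension for noisy keypoints and is off by default.
    """
    idx = side_joints(side)
    theta = included_angle(
        traj.coords[:, idx["hip"]],
        traj.coords[:, idx["knee"]],
        traj.coords[:, idx["ankle"]],
    )
    if smooth_window is not None and smooth_window > 1:
        if smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd")
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        padded = np.pad(theta, pad, mode="edge")
        theta = np.convolve(padded, kernel, mode="valid")
    return AngleSeries(values=theta, side=side, frame_rate=traj.frame_rate)


def angular_velocity_series(angles: AngleSeries) -> AngularVelocitySeries:
    """omega_i = f * (theta_i - theta_{i-1}) for i >= 1, signed."""
    if angles.values.size < 2:
        raise EmptyInputError("angular velocity needs at least 2 frames")
    omega = angles.frame_rate * np.diff(angles.values)
    return AngularVelocitySeries(values=omega, side=angles.side, frame_rate=angles.frame_rate)


def range_of_motion(series: AngleSeries | AngularVelocitySeries | np.ndarray) -> float:
    """max - min of a series' values (degrees or deg/s)."""
    values = series.values if hasattr(series, "values") else np.asarray(series, dtype=float)
    if values.size == 0:
        raise EmptyInputError("range of an empty series is undefined")
    return float(np.max(values) - np.min(values))
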
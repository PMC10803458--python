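"""Step detection and gait-event labelling.

Spatiotemporal gait parameters come from two complementary signals:

* the inter-ankle distance D_i = ||A_li - A_ri||, whose filtered local maxima
  mark steps — the peak value is the step length S and the peak time its T_i;
* the knee angular velocity omega, whose percentile-filtered extrema mark
  toe-off (retained minima) and anchor the heel-strike search (from each
  retained maximum, the first later sample with omega below a threshold,
  10 deg/s by default).

Step side is resolved against the body's anatomical planes: the sagittal plane
through the sacrum (SV), thoracic (TV) and cervical (CV) markers, and the
coronal plane through SV perpendicular to both the sagittal plane and the
SV->CV axis.  The step belongs to the foot whose ankle is anterior to the
coronal plane, anterior meaning the horizontal direction of sacrum travel over
the enclosing step interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import ConfigurationError, DegenerateGeometryError, NoGaitDetectedError, OrderingError
from .kinematics import AngularVelocitySeries
from .skeleton import JOINT_INDEX
from .trajectory import KeypointTrajectory


@dataclass(frozen=True)
class AnatomicalPlanes:
    """Sagittal and coronal planes of one frame (point + unit normal)."""

    frame: int
    sagittal_point: np.ndarray
    sagittal_normal: np.ndarray
    coronal_point: np.ndarray
    coronal_normal: np.ndarray


@dataclass
class StepRecord:
    """One detected step: length, time, side, and (once known) period/speed."""

    index: int
    frame: int
    step_length: float
    time: float
    side: str | None = None
    step_period: float | None = None
    walking_speed: float | None = None


@dataclass(frozen=True)
class PhaseRecord:
    """One gait cycle's toe-off/heel-strike pair with swing/support durations."""

    side: str
    toe_off: float
    heel_strike: float
    swing: float
    support: float | None


def inter_ankle_distance_series(traj: KeypointTrajectory) -> np.ndarray:
    """D_i = ||A_li - A_ri|| per frame, in mm."""
    al = traj.joint("ankle_left")
    ar = traj.joint("ankle_right")
    return np.linalg.norm(al - ar, axis=1)


def detect_step_peaks(
    distances: np.ndarray,
    threshold_fraction: float = 0.5,
    min_separation: int = 2,
) -> list[tuple[int, float]]:
    """Filtered local maxima of the inter-ankle distance series.

    Strict local maxima with value >= threshold_fraction * max(D) are kept;
    retained peaks closer than ``min_separation`` frames are thinned keeping
    the larger.  A constant series yields no steps (empty list, not an error).
    """
    d = np.asarray(distances, dtype=float)
    if d.size < 3:
        raise ConfigurationError("need at least 3 samples to detect peaks")
    if not 0 < threshold_fraction < 1:
        raise ConfigurationError(
            f"threshold_fraction must be in (0, 1), got {threshold_fraction}"
        )
    dmax = float(np.max(d))
    if dmax <= 0 or np.ptp(d) == 0:
        return []
    idx, _ = find_peaks(d, height=threshold_fraction * dmax, distance=max(2, min_separation))
    return [(int(i), float(d[i])) for i in idx]


def compute_planes(traj: KeypointTrajectory, frame: int) -> AnatomicalPlanes:
    """Sagittal/coronal planes from the spine markers of one frame.

    Sagittal: through SV, TV, CV with normal = unit cross(SV->TV, SV->CV).
    Coronal: through SV with normal = unit cross(sagittal normal, unit SV->CV),
    perpendicular to both the sagittal plane and the SV->CV axis.
    """
    sv = traj.coords[frame, JOINT_INDEX["sacrum"]]
    tv = traj.coords[frame, JOINT_INDEX["thorax"]]
    cv = traj.coords[frame, JOINT_INDEX["neck"]]
    sag = np.cross(tv - sv, cv - sv)
    norm = np.linalg.norm(sag)
    axis = cv - sv
    axis_norm = np.linalg.norm(axis)
    if norm <= 1e-9 * max(1.0, axis_norm**2) or axis_norm <= 0:
        raise DegenerateGeometryError(f"collinear spine points at frame {frame}")
    sag = sag / norm
    axis = axis / axis_norm
    cor = np.cross(sag, axis)
    cor = cor / np.linalg.norm(cor)
    return AnatomicalPlanes(
        frame=int(frame),
        sagittal_point=sv.copy(),
        sagittal_normal=sag,
        coronal_point=sv.copy(),
        coronal_normal=cor,
    )


def point_plane_distance(points: np.ndarray, point_on_plane: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Signed distance of points to a plane along its (unit) normal."""
    return np.dot(np.atleast_2d(points) - point_on_plane, normal)


def _anterior_direction(traj: KeypointTrajectory, lo: int, hi: int) -> np.ndarray:
    """Horizontal unit direction of sacrum travel over frames [lo, hi]."""
    sacrum = traj.joint("sacrum")
    disp = sacrum[hi] - sacrum[lo]
    disp[2] = 0.0
    if np.linalg.norm(disp) < 10.0:  # < 10 mm: fall back to whole-walk travel
        disp = sacrum[-1] - sacrum[0]
        disp[2] = 0.0
    n = np.linalg.norm(disp)
    if n == 0:
        return np.array([1.0, 0.0, 0.0])
    return disp / n


def assign_step_side(
    traj: KeypointTrajectory,
    peaks: list[tuple[int, float]],
) -> list[str]:
    """Label each step with its leading foot.

    At each peak frame the signed ankle-to-coronal-plane distances are taken
    along the anterior unit vector; the foot lying anterior wins.  A near-tie
    (< 1 mm separation) raises a warning and falls back to the larger
    absolute distance.
    """
    sides: list[str] = []
    frames = [f for f, _ in peaks]
    for j, (frame, _s) in enumerate(peaks):
        planes = compute_planes(traj, frame)
        lo = frames[j - 1] if j > 0 else 0
        hi = frames[j + 1] if j + 1 < len(frames) else traj.n_frames - 1
        anterior = _anterior_direction(traj, lo, hi)
        normal = planes.coronal_normal
        if np.dot(normal, anterior) < 0:
            normal = -normal
        d_left = float(point_plane_distance(traj.joint("ankle_left")[frame], planes.coronal_point, normal)[0])
        d_right = float(point_plane_distance(traj.joint("ankle_right")[frame], planes.coronal_point, normal)[0])
        if abs(d_left - d_right) < 1.0:
            warnings.warn(
                f"ambiguous step side at frame {frame}; choosing larger |distance|",
                stacklevel=2,
            )
            sides.append("left" if abs(d_left) >= abs(d_right) else "right")
        else:
            sides.append("left" if d_left > d_right else "right")
    return sides


def step_periods_and_speeds(records: list[StepRecord]) -> list[StepRecord]:
    """Fill step period p_i = T_i - T_{i-1} and speed v_i = (S_i + S_{i-1}) / (2 p_i).

    The first record keeps ``None`` for both (no predecessor).
    """
    if len(records) < 2:
        raise OrderingError("need at least 2 step records")
    times = [r.time for r in records]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise OrderingError("step times must be strictly increasing")
    out = [records[0]]
    for prev, cur in zip(records, records[1:]):
        p = cur.time - prev.time
        v = (cur.step_length + prev.step_length) / (2.0 * p)
        out.append(
            StepRecord(
                index=cur.index,
                frame=cur.frame,
                step_length=cur.step_length,
                time=cur.time,
                side=cur.side,
                step_period=p,
                walking_speed=v,
            )
        )
    return out


def _strict_extrema(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima of a 1-D series."""
    v = values
    interior = np.arange(1, v.size - 1)
    maxima = interior[(v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])]
    minima = interior[(v[1:-1] < v[:-2]) & (v[1:-1] < v[2:])]
    return maxima, minima


def _enforce_alternation(
    events: list[tuple[float, str, float]],
) -> list[tuple[float, str, float]]:
    """Collapse runs of same-type retained extrema to the most extreme one.

    ``events`` are (time, kind, value) sorted by time, kind in {'max', 'min'}.
    A clean stride has exactly one retained maximum between consecutive
    retained minima; noise can split one extremum into several neighbours,
    which this merge removes without inventing any new event.
    """
    out: list[tuple[float, str, float]] = []
    for ev in events:
        if out and out[-1][1] == ev[1]:
            keep_new = ev[2] > out[-1][2] if ev[1] == "max" else ev[2] < out[-1][2]
            if keep_new:
                out[-1] = ev
        else:
            out.append(ev)
    return out


def detect_gait_phases(
    omega: AngularVelocitySeries,
    heel_strike_threshold: float = 10.0,
    percentile_low: float = 20.0,
    percentile_high: float = 80.0,
    signed_threshold: bool = True,
) -> list[PhaseRecord]:
    """Toe-off/heel-strike detection from one leg's knee angular velocity.

    1. find all strict local maxima and minima of omega;
    2. retain maxima >= the ``percentile_high``-th percentile of the sorted
       omega values and minima <= the ``percentile_low``-th percentile
       (linear-interpolation percentiles);
    3. each retained minimum marks a toe-off t_split;
    4. from each retained maximum, scanning forward, the first sample with
       omega < heel_strike_threshold (signed by default; absolute value when
       ``signed_threshold`` is False) marks a heel-strike t_touch;
    5. swing = t_touch minus the preceding t_split; support = t_split minus
       the preceding t_touch.  Cycles lacking a predecessor are omitted.
    """
    v = omega.values
    t = omega.times
    max_idx, min_idx = _strict_extrema(v)
    if max_idx.size == 0 and min_idx.size == 0:
        raise NoGaitDetectedError("no local extrema in the angular velocity series")
    hi = np.percentile(v, percentile_high)
    lo = np.percentile(v, percentile_low)
    kept_max = max_idx[v[max_idx] >= hi]
    kept_min = min_idx[v[min_idx] <= lo]
    if kept_max.size == 0 or kept_min.size == 0:
        raise NoGaitDetectedError("no retained extrema above/below the percentile thresholds")

    events = sorted(
        [(float(t[i]), "min", float(v[i])) for i in kept_min]
        + [(float(t[i]), "max", float(v[i])) for i in kept_max]
    )
    events = _enforce_alternation(events)

    toe_offs = [time for time, kind, _ in events if kind == "min"]
    heel_strikes: list[float] = []
    for time, kind, _val in events:
        if kind != "max":
            continue
        start = int(np.searchsorted(t, time, side="right"))
        crossing = v[start:] < heel_strike_threshold if signed_threshold else np.abs(v[start:]) < heel_strike_threshold
        hits = np.flatnonzero(crossing)
        if hits.size:
            heel_strikes.append(float(t[start + hits[0]]))

    records: list[PhaseRecord] = []
    for split in toe_offs:
        later = [hs for hs in heel_strikes if hs > split]
        prior = [hs for hs in heel_strikes if hs <= split]
        support = split - prior[-1] if prior else None
        if later:
            touch = later[0]
            records.append(
                PhaseRecord(
                    side=omega.side,
                    toe_off=split,
                    heel_strike=touch,
                    swing=touch - split,
                    support=support,
                )
            )
    return records
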
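"""Synthetic 17-joint gait and sit-to-stand trajectories with known ground truth.

This is a parametric kinematic simulator, not a biomechanical model: limbs
follow closed-form trajectories chosen so that every quantity the extraction
pipeline measures has an exact programmed value.

Walking model
-------------
The walker advances along +x (lab frame: +x walking direction, +z up, mm,
frame time t = i/f).  Feet alternate stance and swing with a cosine
swing profile, so consecutive landings are ``step_period`` apart and the
3-D inter-ankle distance at each landing instant equals ``step_length``
exactly (the forward landing separation is sqrt(S^2 - w^2) for stance width
w, and the swing foot's vertical clearance vanishes at landing).  The walk
ends with a closing step (the trailing foot steps beside the leading one)
followed by quiet standing, so the final landing remains an interior
inter-ankle-distance peak.

Each leg's knee angle performs one smooth flexion pulse per stride,

    theta(tau) = 180 - (knee_rom / 2) * (1 - cos(2 pi tau)),  tau in [0, 1],

over a window of length W = (8 p / 3) / (1 + stance_swing_ratio) starting at
that leg's swing onset (p = step period; the window length makes the
angular-velocity-defined swing fraction of the 2p stride match the requested
stance:swing ratio).  The knee is fully extended (180 deg) outside pulses.
Ground-truth toe-off and heel-strike times are the continuous-model
angular-velocity landmarks in closed form: toe-off at the pulse's velocity
minimum (tau = 1/4) and heel-strike where the velocity first falls below
10 deg/s after its maximum, tau = 1 - arcsin(10 / A) / (2 pi) with
A = knee_rom * pi / W the velocity amplitude in deg/s.

Lateral balance motion is imposed on the pelvis and limbs while the trunk
column stays on the corridor midline (y = 0), so the trunk-defined sagittal
plane is exactly the vertical x-z plane.  The limb sway is scaled by the
body model's numerically probed COM attenuation factor so that the whole-body
COM's distance to that plane oscillates with exactly
``lateral_sway_amplitude`` about a 1.5x-amplitude standing offset — making
the unsigned-deviation range equal twice the amplitude by construction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .com import load_segment_table, whole_body_com_series
from .errors import ConfigurationError
from .skeleton import JOINT_INDEX, N_JOINTS
from .trajectory import KeypointTrajectory

HEEL_STRIKE_OMEGA = 10.0  # deg/s, the heel-strike threshold the events module uses
HIP_WIDTH = 160.0
SHOULDER_WIDTH = 360.0
FOOT_CLEARANCE = 40.0
THORAX_FORWARD_BEND = 40.0
UPPER_ARM_DROP = 280.0
FOREARM_DROP = 250.0


@dataclass(frozen=True)
class GaitSimConfig:
    """Parameters of one simulated trial (lengths mm, times s, angles deg)."""

    duration: float = 10.0
    frame_rate: float = 30.0
    step_length: float = 600.0
    step_period: float = 0.6
    knee_rom: float = 60.0
    stance_swing_ratio: float = 1.5
    lateral_sway_amplitude: float = 10.0
    trunk_height: float = 500.0
    shank_length: float = 400.0
    thigh_length: float = 450.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not self.duration > 0:
            raise ConfigurationError(f"duration must be > 0, got {self.duration}")
        if not self.frame_rate > 0:
            raise ConfigurationError(f"frame_rate must be > 0, got {self.frame_rate}")
        if not self.step_period > 0:
            raise ConfigurationError(f"step_period must be > 0, got {self.step_period}")
        if self.step_length < 0:
            raise ConfigurationError(f"step_length must be >= 0, got {self.step_length}")
        if not 0 <= self.knee_rom < 180:
            raise ConfigurationError(f"knee_rom must be in [0, 180), got {self.knee_rom}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not self.stance_swing_ratio > 1.0 / 3.0:
            raise ConfigurationError(
                f"stance_swing_ratio must exceed 1/3, got {self.stance_swing_ratio}"
            )
        for name in ("trunk_height", "shank_length", "thigh_length"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0")


@dataclass
class SyntheticGroundTruth:
    """Everything the simulator programmed, for round-trip validation."""

    frame_rate: float
    n_frames: int
    step_lengths: list[float] = field(default_factory=list)
    step_sides: list[str] = field(default_factory=list)
    step_times: list[float] = field(default_factory=list)
    knee_rom_left: float = 0.0
    knee_rom_right: float = 0.0
    toe_off_times: dict[str, list[float]] = field(default_factory=lambda: {"left": [], "right": []})
    heel_strike_times: dict[str, list[float]] = field(default_factory=lambda: {"left": [], "right": []})
    com_path: np.ndarray | None = None
    sagittal_sway_range: float = 0.0
    rise_onset: float | None = None
    rise_offset: float | None = None

    def __post_init__(self) -> None:
        for seq in (self.step_times, *self.toe_off_times.values(), *self.heel_strike_times.values()):
            if any(b <= a for a, b in zip(seq, seq[1:])):
                raise ConfigurationError("ground-truth event times must be strictly increasing")

    @property
    def n_steps(self) -> int:
        return len(self.step_times)

    @property
    def all_toe_off_times(self) -> list[float]:
        return sorted(self.toe_off_times["left"] + self.toe_off_times["right"])

    @property
    def all_heel_strike_times(self) -> list[float]:
        return sorted(self.heel_strike_times["left"] + self.heel_strike_times["right"])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "frame_rate": self.frame_rate,
            "n_frames": self.n_frames,
            "step_lengths_mm": self.step_lengths,
            "step_sides": self.step_sides,
            "step_times_s": self.step_times,
            "knee_rom_left_deg": self.knee_rom_left,
            "knee_rom_right_deg": self.knee_rom_right,
            "toe_off_times_s": self.toe_off_times,
            "heel_strike_times_s": self.heel_strike_times,
            "sagittal_sway_range_mm": self.sagittal_sway_range,
            "rise_onset_s": self.rise_onset,
            "rise_offset_s": self.rise_offset,
            "com_path_mm": None if self.com_path is None else self.com_path.tolist(),
        }
        Path(path).write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# frame assembly
# ---------------------------------------------------------------------------

def _swing_profile(tau: np.ndarray) -> np.ndarray:
    """Cosine swing: 0 -> 1 with zero endpoint velocity."""
    return 0.5 * (1.0 - np.cos(np.pi * np.clip(tau, 0.0, 1.0)))


def _pulse_angle(t: np.ndarray, starts: list[float], width: float, rom: float) -> np.ndarray:
    """Knee angle series: 180 deg minus one flexion pulse per window."""
    theta = np.full(t.shape, 180.0)
    for s in starts:
        mask = (t >= s) & (t <= s + width)
        tau = (t[mask] - s) / width
        theta[mask] = 180.0 - (rom / 2.0) * (1.0 - np.cos(2.0 * np.pi * tau))
    return theta


def _assemble_frames(
    cfg: GaitSimConfig,
    ankle_x: dict[str, np.ndarray],
    ankle_z: dict[str, np.ndarray],
    theta: dict[str, np.ndarray],
    y_mid: np.ndarray,
    stance_width: float,
) -> np.ndarray:
    """Build the (n, 17, 3) coordinate array from leg state and lateral offset."""
    n = y_mid.shape[0]
    coords = np.zeros((n, N_JOINTS, 3))
    hips = {}
    for side, sign in (("left", 1.0), ("right", -1.0)):
        ankle = np.stack(
            [ankle_x[side], np.full(n, sign * stance_width / 2.0), ankle_z[side]], axis=1
        )
        knee = ankle + np.array([0.0, 0.0, cfg.shank_length])
        beta = np.radians(180.0 - theta[side])
        # hip stays in the leg's vertical x-z plane so the geometric knee
        # angle equals the prescribed theta exactly; lateral balance motion
        # is carried by the upper body instead
        hip = np.stack(
            [
                knee[:, 0] + cfg.thigh_length * np.sin(beta),
                knee[:, 1],
                knee[:, 2] + cfg.thigh_length * np.cos(beta),
            ],
            axis=1,
        )
        coords[:, JOINT_INDEX[f"ankle_{side}"]] = ankle
        coords[:, JOINT_INDEX[f"knee_{side}"]] = knee
        coords[:, JOINT_INDEX[f"hip_{side}"]] = hip
        hips[side] = hip

    sacrum = (hips["left"] + hips["right"]) / 2.0
    sacrum[:, 1] = 0.0  # trunk column stays on the corridor midline
    coords[:, JOINT_INDEX["sacrum"]] = sacrum

    thorax = sacrum + np.array([THORAX_FORWARD_BEND, 0.0, 0.5 * cfg.trunk_height])
    neck = sacrum + np.array([0.0, 0.0, cfg.trunk_height])
    coords[:, JOINT_INDEX["thorax"]] = thorax
    coords[:, JOINT_INDEX["neck"]] = neck

    head = neck.copy()
    head[:, 1] = y_mid
    head[:, 2] += 0.25 * cfg.trunk_height
    coords[:, JOINT_INDEX["head"]] = head

    nose = neck.copy()
    nose[:, 0] += 80.0
    nose[:, 1] = 0.75 * y_mid
    nose[:, 2] += 0.12 * cfg.trunk_height
    coords[:, JOINT_INDEX["nose"]] = nose

    for side, sign in (("left", 1.0), ("right", -1.0)):
        shoulder = neck.copy()
        shoulder[:, 1] = y_mid + sign * SHOULDER_WIDTH / 2.0
        shoulder[:, 2] -= 30.0
        elbow = shoulder + np.array([0.0, 0.0, -UPPER_ARM_DROP])
        wrist = elbow + np.array([0.0, 0.0, -FOREARM_DROP])
        coords[:, JOINT_INDEX[f"shoulder_{side}"]] = shoulder
        coords[:, JOINT_INDEX[f"elbow_{side}"]] = elbow
        coords[:, JOINT_INDEX[f"wrist_{side}"]] = wrist
    return coords


def _com_sway_attenuation(cfg: GaitSimConfig, stance_width: float) -> float:
    """Numerically probe d(COM_y)/d(midline offset) for the standing pose."""
    table = load_segment_table()
    coms = []
    for offset in (0.0, 1.0):
        still = {
            "left": np.zeros(2),
            "right": np.zeros(2),
        }
        coords = _assemble_frames(
            cfg,
            ankle_x={"left": np.zeros(2), "right": np.zeros(2)},
            ankle_z=dict(still),
            theta={"left": np.full(2, 180.0), "right": np.full(2, 180.0)},
            y_mid=np.full(2, offset),
            stance_width=stance_width,
        )
        traj = KeypointTrajectory(coords, cfg.frame_rate, source_label="probe")
        com = whole_body_com_series(traj, table, variant="normalized", reference="none")
        coms.append(com.com[0, 1])
    return float(coms[1] - coms[0])


def _true_com_path(coords: np.ndarray, frame_rate: float) -> np.ndarray:
    traj = KeypointTrajectory(coords, frame_rate, source_label="ground-truth")
    table = load_segment_table()
    return whole_body_com_series(traj, table, variant="normalized", reference="none").com


def add_noise(traj: KeypointTrajectory, sd: float, seed: int) -> KeypointTrajectory:
    """Add isotropic Gaussian keypoint noise; sd = 0 returns an exact copy."""
    if sd < 0:
        raise ConfigurationError(f"noise sd must be >= 0, got {sd}")
    out = traj.copy()
    if sd > 0:
        rng = np.random.default_rng(seed)
        out.coords = out.coords + rng.normal(0.0, sd, size=out.coords.shape)
    return out


def generate_walk(cfg: GaitSimConfig) -> tuple[KeypointTrajectory, SyntheticGroundTruth]:
    """Simulate a straight walk; returns the trajectory and its ground truth."""
    cfg.validate()
    f = cfg.frame_rate
    n = int(round(cfg.duration * f))
    if n < 2:
        raise ConfigurationError("duration too short: fewer than 2 frames")
    t = np.arange(n) / f
    p = cfg.step_period
    S = cfg.step_length

    standing = S < 1.0
    n_steps = 0 if standing else int(math.floor(cfg.duration / p)) - 1
    if not standing and n_steps < 1:
        raise ConfigurationError(
            "duration too short for a single step at the configured step_period"
        )

    stance_width = 0.0 if standing else min(100.0, S / 3.0)
    s_x = 0.0 if standing else math.sqrt(S**2 - stance_width**2)

    # --- ankle paths -------------------------------------------------------
    ankle_x = {"left": np.zeros(n), "right": np.zeros(n)}
    ankle_z = {"left": np.zeros(n), "right": np.zeros(n)}
    swing_starts: dict[str, list[float]] = {"left": [], "right": []}
    if not standing:
        # step k swings foot (left if k odd) during [(k-1)p, kp]
        landings = []
        for k in range(1, n_steps + 1):
            side = "left" if k % 2 == 1 else "right"
            x0 = 0.0 if k <= 2 else (k - 2) * s_x
            x1 = k * s_x
            landings.append((k, side, (k - 1) * p, k * p, x0, x1))
        closing_side = "left" if (n_steps + 1) % 2 == 1 else "right"
        landings.append(
            (
                n_steps + 1,
                closing_side,
                n_steps * p,
                (n_steps + 1) * p,
                (n_steps - 1) * s_x,
                n_steps * s_x,
            )
        )
        # landings are chronological, so each pre-swing plateau is already in
        # place from the previous swing of the same foot (or the initial 0)
        for _k, side, t0, t1, x0, x1 in landings:
            swing_starts[side].append(t0)
            during = (t >= t0) & (t <= t1)
            after = t > t1
            tau = (t[during] - t0) / (t1 - t0)
            ankle_x[side][during] = x0 + (x1 - x0) * _swing_profile(tau)
            ankle_x[side][after] = x1
            ankle_z[side][during] = FOOT_CLEARANCE * np.sin(np.pi * tau)

    # --- knee pulses -------------------------------------------------------
    W = (8.0 * p / 3.0) / (1.0 + cfg.stance_swing_ratio)
    theta = {
        side: _pulse_angle(t, swing_starts[side], W, cfg.knee_rom) for side in ("left", "right")
    }

    # --- lateral sway ------------------------------------------------------
    amp = cfg.lateral_sway_amplitude
    if amp > 0 and not standing:
        attenuation = _com_sway_attenuation(cfg, stance_width)
        y_mid = (1.5 * amp + amp * np.sin(2.0 * np.pi * t / (2.0 * p))) / attenuation
        sway_range = 2.0 * amp
    else:
        y_mid = np.zeros(n)
        sway_range = 0.0

    coords = _assemble_frames(cfg, ankle_x, ankle_z, theta, y_mid, stance_width)
    clean = KeypointTrajectory(coords, f, source_label=f"synthetic-walk seed={cfg.seed}")

    # --- ground truth (closed forms, never from the sampled data) ----------
    gt = SyntheticGroundTruth(frame_rate=f, n_frames=n)
    if not standing:
        gt.step_times = [k * p for k in range(1, n_steps + 1)]
        gt.step_sides = ["left" if k % 2 == 1 else "right" for k in range(1, n_steps + 1)]
        gt.step_lengths = [S] * n_steps
        amp_omega = cfg.knee_rom * math.pi / W  # deg/s velocity amplitude
        for side in ("left", "right"):
            if swing_starts[side] and cfg.knee_rom > 0:
                setattr(gt, f"knee_rom_{side}", cfg.knee_rom)
            if amp_omega > HEEL_STRIKE_OMEGA:
                t_last = (n - 1) / f
                tau_touch = 1.0 - math.asin(HEEL_STRIKE_OMEGA / amp_omega) / (2.0 * math.pi)
                gt.toe_off_times[side] = [
                    s0 + W / 4.0 for s0 in swing_starts[side] if s0 + W / 4.0 <= t_last
                ]
                gt.heel_strike_times[side] = [
                    s0 + W * tau_touch
                    for s0 in swing_starts[side]
                    if s0 + W * tau_touch <= t_last
                ]
    gt.sagittal_sway_range = sway_range
    gt.com_path = _true_com_path(coords, f)

    noisy = add_noise(clean, cfg.noise_sd, cfg.seed)
    return noisy, gt


def generate_sts(cfg: GaitSimConfig) -> tuple[KeypointTrajectory, SyntheticGroundTruth]:
    """Simulate sit(1 s) - rise - stand(1 s) - sit, knees driving the trunk height."""
    cfg.validate()
    f = cfg.frame_rate
    n = int(round(cfg.duration * f))
    if n < 2:
        raise ConfigurationError("duration too short: fewer than 2 frames")
    rise = min(1.5, (cfg.duration - 2.5) / 2.0)
    if rise <= 0.3:
        raise ConfigurationError(
            "duration too short for a sit-to-stand cycle (needs > ~3.1 s)"
        )
    t = np.arange(n) / f

    t_rise0, t_rise1 = 1.0, 1.0 + rise
    t_fall0, t_fall1 = t_rise1 + 1.0, t_rise1 + 1.0 + rise

    theta = np.full(n, 90.0)
    seg = (t >= t_rise0) & (t <= t_rise1)
    theta[seg] = 90.0 + 90.0 * _swing_profile((t[seg] - t_rise0) / rise)
    seg = (t > t_rise1) & (t < t_fall0)
    theta[seg] = 180.0
    seg = (t >= t_fall0) & (t <= t_fall1)
    theta[seg] = 180.0 - 90.0 * _swing_profile((t[seg] - t_fall0) / rise)

    stance_width = 150.0
    zeros = np.zeros(n)
    coords = _assemble_frames(
        cfg,
        ankle_x={"left": zeros.copy(), "right": zeros.copy()},
        ankle_z={"left": zeros.copy(), "right": zeros.copy()},
        theta={"left": theta, "right": theta.copy()},
        y_mid=np.zeros(n),
        stance_width=stance_width,
    )
    clean = KeypointTrajectory(coords, f, source_label=f"synthetic-sts seed={cfg.seed}")
    gt = SyntheticGroundTruth(
        frame_rate=f,
        n_frames=n,
        knee_rom_left=90.0,
        knee_rom_right=90.0,
        rise_onset=t_rise0,
        rise_offset=t_rise1,
    )
    gt.com_path = _true_com_path(coords, f)
    noisy = add_noise(clean, cfg.noise_sd, cfg.seed)
    return noisy, gt
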
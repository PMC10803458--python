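import numpy as np
import pytest

from gaitlab import GaitSimConfig, SubjectProfile, generate_walk
from gaitlab.skeleton import N_JOINTS


@pytest.fixture(scope="session")
def profile() -> SubjectProfile:
    return SubjectProfile(
        shank_length_left=400.0,
        shank_length_right=400.0,
        body_mass=70.0,
        group="healthy",
        subject_id="sim-001",
    )


@pytest.fixture(scope="session")
def walk600():
    """Noise-free reference walk: 600 mm steps at 0.6 s, 10 s at 30 Hz."""
    cfg = GaitSimConfig(
        duration=10.0,
        frame_rate=30.0,
        step_length=600.0,
        step_period=0.6,
        knee_rom=74.0,
        lateral_sway_amplitude=10.0,
        noise_sd=0.0,
        seed=11,
    )
    traj, gt = generate_walk(cfg)
    return cfg, traj, gt


def random_coords(rng: np.random.Generator, n_frames: int = 5) -> np.ndarray:
    """Random finite keypoint block for geometry-invariance tests."""
    return rng.uniform(-1000.0, 1000.0, size=(n_frames, N_JOINTS, 3))


def nearest_errors(detected: list[float], truth: list[float]) -> list[float]:
    """|detected - nearest truth| for every detected event (seconds)."""
    return [min(abs(d - g) for g in truth) for d in detected] if truth else []
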
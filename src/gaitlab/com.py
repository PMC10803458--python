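"""Segmental whole-body centre of mass and balance measures.

An 11-segment kinematic body model (head, upper/lower trunk, bilateral upper
arms, forearms, thighs, shanks; hands and feet excluded as the lightest parts)
places each segment's COM a fixed fraction along its proximal->distal joint
axis and combines them with its mass fraction.  Two combination rules are
available:

* ``variant='normalized'`` (default) — the standard segmental method,
  COM = sum(m_i COM_i) / sum(m_i) over the 11 included segments;
* ``variant='printed'`` — COM = (1/N) sum(COM_i m_i / m_w), a literal
  transcription kept for fidelity testing (with only 11 of the body's
  segments summed it is not a centroid).

Balance measures derived from the COM path:

* RCOMV, the relative COM velocity: f * ||COM_a - COM_{a-1}|| after the COM is
  expressed relative to a reference point (left ankle in the validation
  workflow, where an optical marker sits reliably; the hip/sacrum centre in
  the measurement workflow);
* the range (max - min) of the per-frame unsigned COM distance to the
  sagittal and coronal planes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, DegenerateGeometryError
from .events import AnatomicalPlanes, point_plane_distance
from .skeleton import JOINT_INDEX
from .trajectory import KeypointTrajectory, SubjectProfile

REFERENCE_POINTS = ("hip", "left_foot", "none")


@dataclass(frozen=True)
class BodySegment:
    name: str
    proximal: str
    distal: str
    mass_fraction: float
    com_position_fraction: float


@dataclass(frozen=True)
class SegmentTable:
    """Exactly 11 body segments with mass and COM-position fractions."""

    segments: tuple[BodySegment, ...]

    def __post_init__(self) -> None:
        if len(self.segments) != 11:
            raise ConfigurationError(
                f"the body model uses exactly 11 segments, got {len(self.segments)}"
            )
        for seg in self.segments:
            if not 0 < seg.mass_fraction < 1:
                raise ConfigurationError(f"mass_fraction of {seg.name} must be in (0, 1)")
            if not 0 <= seg.com_position_fraction <= 1:
                raise ConfigurationError(
                    f"com_position_fraction of {seg.name} must be in [0, 1]"
                )
            for joint in (seg.proximal, seg.distal):
                if joint not in JOINT_INDEX:
                    raise ConfigurationError(
                        f"segment {seg.name}: joint {joint!r} not in the registry"
                    )
        if sum(s.mass_fraction for s in self.segments) > 1.0 + 1e-9:
            raise ConfigurationError("segment mass fractions must sum to <= 1")

    @property
    def mass_fractions(self) -> np.ndarray:
        return np.array([s.mass_fraction for s in self.segments])


def load_segment_table(path: str | Path | None = None) -> SegmentTable:
    """Load the segment table from JSON (the bundled default when no path)."""
    if path is None:
        text = resources.files("gaitlab.data").joinpath("segments.json").read_text()
    else:
        text = Path(path).read_text()
    payload = json.loads(text)
    segments = tuple(
        BodySegment(
            name=row["name"],
            proximal=row["proximal"],
            distal=row["distal"],
            mass_fraction=float(row["mass_fraction"]),
            com_position_fraction=float(row["com_position_fraction"]),
        )
        for row in payload["segments"]
    )
    return SegmentTable(segments=segments)


@dataclass
class ComSeries:
    """Whole-body COM path with derived balance series."""

    com: np.ndarray  # (n_frames, 3) mm
    frame_rate: float
    reference: str = "hip"
    rcomv: np.ndarray | None = None  # (n_frames - 1,) mm/s
    sagittal_deviation: np.ndarray | None = None  # (n_frames,) mm, unsigned
    coronal_deviation: np.ndarray | None = None


def segment_com(
    traj: KeypointTrajectory,
    table: SegmentTable,
    frame: int | None = None,
) -> np.ndarray:
    """Per-segment COM positions: proximal + fraction * (distal - proximal).

    Returns (11, 3) for a single frame or (n_frames, 11, 3) when ``frame`` is
    None.
    """
    coords = traj.coords if frame is None else traj.coords[frame : frame + 1]
    out = np.empty((coords.shape[0], 11, 3))
    for s, seg in enumerate(table.segments):
        p = coords[:, JOINT_INDEX[seg.proximal]]
        d = coords[:, JOINT_INDEX[seg.distal]]
        out[:, s] = p + seg.com_position_fraction * (d - p)
    return out[0] if frame is not None else out


def whole_body_com_series(
    traj: KeypointTrajectory,
    table: SegmentTable,
    profile: SubjectProfile | None = None,
    variant: str = "normalized",
    reference: str = "hip",
) -> ComSeries:
    """Whole-body COM per frame, expressed relative to the reference point.

    ``reference='hip'`` subtracts the sacrum path (measurement workflow),
    ``'left_foot'`` the left-ankle path (validation workflow), ``'none'``
    leaves lab coordinates.
    """
    if variant not in ("normalized", "printed"):
        raise ConfigurationError(f"variant must be 'normalized' or 'printed', got {variant!r}")
    if reference not in REFERENCE_POINTS:
        raise ConfigurationError(f"reference must be one of {REFERENCE_POINTS}, got {reference!r}")
    seg_coms = segment_com(traj, table)  # (n, 11, 3)
    m = table.mass_fractions
    total = m.sum()
    if total <= 0:
        raise ConfigurationError("zero total included segment mass")
    if variant == "normalized":
        com = np.einsum("nsk,s->nk", seg_coms, m) / total
    else:
        # literal per-segment weighting with 1/N prefactor and whole-body mass
        n_seg = len(table.segments)
        com = np.einsum("nsk,s->nk", seg_coms, m) / n_seg
    if reference == "hip":
        com = com - traj.joint("sacrum")
    elif reference == "left_foot":
        com = com - traj.joint("ankle_left")
    return ComSeries(com=com, frame_rate=traj.frame_rate, reference=reference)


def rcomv_series(com: ComSeries) -> ComSeries:
    """RCOMV_a = f * ||COM_a - COM_{a-1}||, mm/s, defined for frames a >= 1."""
    if com.com.shape[0] < 2:
        raise ConfigurationError("RCOMV needs at least 2 frames")
    disp = np.diff(com.com, axis=0)
    com.rcomv = com.frame_rate * np.linalg.norm(disp, axis=1)
    return com


def plane_deviation_ranges(
    com: ComSeries,
    planes: list[AnatomicalPlanes],
) -> tuple[float, float]:
    """Range (max - min) of the unsigned COM-to-plane distance series.

    ``planes`` must supply one :class:`AnatomicalPlanes` per COM frame.  The
    per-frame deviation series are stored on ``com`` as a side effect.
    """
    n = com.com.shape[0]
    if len(planes) != n:
        raise DegenerateGeometryError(
            f"need one plane set per frame: {len(planes)} planes for {n} frames"
        )
    sag = np.empty(n)
    cor = np.empty(n)
    for a, pl in enumerate(planes):
        sag[a] = abs(float(point_plane_distance(com.com[a], pl.sagittal_point, pl.sagittal_normal)[0]))
        cor[a] = abs(float(point_plane_distance(com.com[a], pl.coronal_point, pl.coronal_normal)[0]))
    com.sagittal_deviation = sag
    com.coronal_deviation = cor
    return float(np.ptp(sag)), float(np.ptp(cor))
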
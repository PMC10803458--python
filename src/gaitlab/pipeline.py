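"""End-to-end workflows: parameter extraction and system validation.

``extract_parameters`` runs the full measurement chain on one pre-edited gait
segment: sacrum centering, shank-anchored metric scaling, knee kinematics,
step detection and labelling, gait phases, segmental COM and balance series —
returning the canonical parameter set (see
:data:`gaitlab.stats.PARAMETER_COLUMNS`) plus per-step and per-phase tables.

``validate_pairs`` mirrors the gold-standard comparison workflow: the gold
trajectory is resampled to the test rate, the two are temporally aligned by
knee-angle cross-correlation, parameters are extracted from both, and
ICC(2,k) and Pearson r (with their qualitative bands) are computed across
trials for the validation parameter set
(:data:`gaitlab.stats.VALIDATION_PARAMETERS`; step length and the COM
plane-deviation ranges belong to the measurement workflow only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .com import ComSeries, load_segment_table, plane_deviation_ranges, rcomv_series, whole_body_com_series
from .errors import NoGaitDetectedError, PairingError
from .events import (
    PhaseRecord,
    StepRecord,
    assign_step_side,
    compute_planes,
    detect_gait_phases,
    detect_step_peaks,
    inter_ankle_distance_series,
    step_periods_and_speeds,
)
from .kinematics import angular_velocity_series, knee_angle_series, range_of_motion
from .stats import PARAMETER_COLUMNS, VALIDATION_PARAMETERS, icc_2k, pearson_validity
from .trajectory import (
    KeypointTrajectory,
    SubjectProfile,
    align_signals,
    center_keypoints,
    resample_trajectory,
    scale_keypoints,
)

#: a priori physiological cadence bound: no two steps within 0.3 s
MIN_STEP_PERIOD_S = 0.3


@dataclass
class ExtractionResult:
    """Everything one gait segment yields."""

    parameters: dict[str, float]
    steps: pd.DataFrame
    phases: pd.DataFrame
    com: ComSeries
    n_steps: int
    dropped_boundary_steps: int


def _steps_frame(records: list[StepRecord], subject_id: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "index": [r.index for r in records],
            "side": [r.side for r in records],
            "S_mm": [r.step_length for r in records],
            "T_s": [r.time for r in records],
            "p_s": [r.step_period for r in records],
            "v_mm_s": [r.walking_speed for r in records],
        }
    )


def _phases_frame(records: list[PhaseRecord], subject_id: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "side": [r.side for r in records],
            "t_split_s": [r.toe_off for r in records],
            "t_touch_s": [r.heel_strike for r in records],
            "t_swing_s": [r.swing for r in records],
            "t_support_s": [r.support for r in records],
        }
    )


def extract_parameters(
    traj: KeypointTrajectory,
    profile: SubjectProfile,
    threshold_fraction: float = 0.5,
    heel_strike_threshold: float = 10.0,
    com_variant: str = "normalized",
    reference: str = "hip",
    scale_mode: str = "per_frame",
    min_step_period: float = MIN_STEP_PERIOD_S,
) -> ExtractionResult:
    """Run the full measurement chain on one pre-edited gait segment."""
    table = load_segment_table()
    scaled = scale_keypoints(traj, profile, mode=scale_mode)
    centered = center_keypoints(scaled)

    # knee kinematics (per side)
    angles = {s: knee_angle_series(centered, s) for s in ("left", "right")}
    omegas = {s: angular_velocity_series(angles[s]) for s in ("left", "right")}

    # steps from the inter-ankle distance
    distances = inter_ankle_distance_series(scaled)
    min_sep = max(2, int(round(min_step_period * traj.frame_rate)))
    peaks = detect_step_peaks(distances, threshold_fraction, min_separation=min_sep)
    if len(peaks) < 2:
        raise NoGaitDetectedError(
            f"found {len(peaks)} step peak(s); need at least 2 "
            f"(source: {traj.source_label or 'unnamed trajectory'})"
        )
    sides = assign_step_side(scaled, peaks)
    records = [
        StepRecord(
            index=i,
            frame=frame,
            step_length=value,
            time=frame / traj.frame_rate,
            side=side,
        )
        for i, ((frame, value), side) in enumerate(zip(peaks, sides))
    ]
    records = step_periods_and_speeds(records)

    # gait phases per leg
    phase_records: list[PhaseRecord] = []
    for s in ("left", "right"):
        try:
            phase_records.extend(
                detect_gait_phases(omegas[s], heel_strike_threshold=heel_strike_threshold)
            )
        except NoGaitDetectedError:
            pass
    phase_records.sort(key=lambda r: r.toe_off)

    # balance: COM relative to the configured reference, against the trunk planes
    com = whole_body_com_series(
        centered, table, profile, variant=com_variant, reference=reference
    )
    com = rcomv_series(com)
    planes = [compute_planes(centered, a) for a in range(centered.n_frames)]
    sag_range, cor_range = plane_deviation_ranges(com, planes)

    periods = [r.step_period for r in records if r.step_period is not None]
    speeds = [r.walking_speed for r in records if r.walking_speed is not None]
    parameters = {
        "step_period_s": float(np.mean(periods)),
        "step_length_mm": float(np.mean([r.step_length for r in records])),
        "walking_speed_mm_s": float(np.mean(speeds)),
        "knee_rom_right_deg": range_of_motion(angles["right"]),
        "knee_rom_left_deg": range_of_motion(angles["left"]),
        "knee_velocity_range_right_deg_s": range_of_motion(omegas["right"]),
        "knee_velocity_range_left_deg_s": range_of_motion(omegas["left"]),
        "rcomv_mm_s": float(np.mean(com.rcomv)),
        "sagittal_deviation_range_mm": sag_range,
        "coronal_deviation_range_mm": cor_range,
    }
    assert tuple(parameters) == PARAMETER_COLUMNS
    return ExtractionResult(
        parameters=parameters,
        steps=_steps_frame(records, profile.subject_id),
        phases=_phases_frame(phase_records, profile.subject_id),
        com=com,
        n_steps=len(records),
        dropped_boundary_steps=1,  # the first record carries no period/speed
    )


@dataclass
class ValidationReport:
    """Gold-vs-test agreement across trials."""

    table: pd.DataFrame  # per parameter: icc, icc_band, pearson_r, p, r_band
    shifts: list[int] = field(default_factory=list)
    knee_alignment_r: list[float] = field(default_factory=list)
    gold_parameters: pd.DataFrame | None = None
    test_parameters: pd.DataFrame | None = None


def _aligned_crop(
    gold: KeypointTrajectory, test: KeypointTrajectory, shift: int
) -> tuple[KeypointTrajectory, KeypointTrajectory]:
    """Crop both trajectories to their overlap after shifting test by ``shift``."""
    from dataclasses import replace

    if shift >= 0:
        n = min(gold.n_frames, test.n_frames - shift)
        g = gold.coords[:n]
        s = test.coords[shift : shift + n]
    else:
        n = min(gold.n_frames + shift, test.n_frames)
        g = gold.coords[-shift : -shift + n]
        s = test.coords[:n]
    if n < 2:
        raise PairingError("no overlap left after alignment")
    return replace(gold, coords=g.copy()), replace(test, coords=s.copy())


def validate_pairs(
    pairs: list[tuple[KeypointTrajectory, KeypointTrajectory, SubjectProfile]],
    align_side: str = "left",
    reference: str = "left_foot",
    **extract_kwargs,
) -> ValidationReport:
    """Compare gold/test trajectory pairs parameter by parameter.

    The gold trajectory of each pair is resampled to the test frame rate,
    aligned to the test by knee-angle cross-correlation, and both are run
    through :func:`extract_parameters` (COM referenced to the left foot, the
    validation convention).  ICC(2,k) and Pearson r are then computed per
    parameter over the trial series.
    """
    if len(pairs) < 2:
        raise PairingError("validation needs at least 2 gold/test pairs")
    gold_rows, test_rows = [], []
    shifts: list[int] = []
    knee_r: list[float] = []
    for gold, test, profile in pairs:
        if gold.frame_rate != test.frame_rate:
            gold = resample_trajectory(gold, test.frame_rate)
        gold_knee = knee_angle_series(gold, align_side).values
        test_knee = knee_angle_series(test, align_side).values
        alignment = align_signals(gold_knee, test_knee)
        shifts.append(alignment.shift)
        gold_al, test_al = _aligned_crop(gold, test, alignment.shift)
        r, _p, _band = pearson_validity(
            knee_angle_series(gold_al, align_side).values,
            knee_angle_series(test_al, align_side).values,
        )
        knee_r.append(r)
        gold_rows.append(
            extract_parameters(gold_al, profile, reference=reference, **extract_kwargs).parameters
        )
        test_rows.append(
            extract_parameters(test_al, profile, reference=reference, **extract_kwargs).parameters
        )
    gold_df = pd.DataFrame(gold_rows)
    test_df = pd.DataFrame(test_rows)
    out = []
    for col in VALIDATION_PARAMETERS:
        matrix = np.column_stack([gold_df[col], test_df[col]])
        icc, icc_band = icc_2k(matrix)
        r, p, r_band = pearson_validity(gold_df[col], test_df[col])
        out.append(
            {
                "parameter": col,
                "icc": icc,
                "icc_band": icc_band,
                "pearson_r": r,
                "p": p,
                "r_band": r_band,
            }
        )
    return ValidationReport(
        table=pd.DataFrame(out).set_index("parameter"),
        shifts=shifts,
        knee_alignment_r=knee_r,
        gold_parameters=gold_df,
        test_parameters=test_df,
    )
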
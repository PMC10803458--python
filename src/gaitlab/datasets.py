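"""Bundled reference summary tables and the synthetic cohort generator.

Two small summary tables ship with the package:

* :func:`validation_reference` — group-level means (SD) of gait parameters
  measured simultaneously by an optical motion-capture system ("vicon") and a
  smartphone markerless system ("phone") in a validation experiment, with the
  per-system ICC(2,k) and the between-system Pearson r.
* :func:`cohort_reference` — group-level means (SD) of the measurement-
  experiment gait parameters for a healthy-adult cohort (13 subjects) and a
  musculoskeletal-patient cohort (12 subjects, sarcopenia/osteoarthritis),
  each contributing 4 pre-edited gait segments (52 and 48 analysis rows).

These are reference values for benchmarking the statistics layer and for
parameterizing :func:`synthetic_cohort_table`, which draws a per-column
Gaussian cohort at those group statistics — the stand-in for recorded
per-subject data, which the package does not ship.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import GROUP_COLUMN

N_HEALTHY_ROWS = 52  # 13 healthy subjects x 4 gait segments
N_PATIENT_ROWS = 48  # 12 patients x 4 gait segments


def validation_reference() -> pd.DataFrame:
    """Validation-experiment summary: optical system vs smartphone system."""
    rows = [
        # parameter, vicon_mean, vicon_sd, vicon_icc, phone_mean, phone_sd, phone_icc, r
        ("step_period_s", 0.71, 0.05, 0.946, 0.73, 0.06, 0.965, 0.898),
        ("walking_speed_mm_s", 753.0, 68.7, 0.918, 696.0, 68.9, 0.898, 0.942),
        ("knee_rom_right_deg", 55.8, 6.46, 0.982, 56.0, 3.87, 0.937, 0.953),
        ("knee_rom_left_deg", 55.2, 9.38, 0.957, 55.6, 6.74, 0.927, 0.973),
        ("knee_velocity_range_right_deg_s", 518.0, 53.7, 0.942, 525.0, 42.9, 0.975, 0.808),
        ("knee_velocity_range_left_deg_s", 482.0, 103.0, 0.947, 490.0, 100.0, 0.843, 0.934),
        ("rcomv_mm_s", 906.0, 111.0, 0.853, 899.0, 127.0, 0.839, 0.978),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "parameter",
            "vicon_mean",
            "vicon_sd",
            "vicon_icc",
            "phone_mean",
            "phone_sd",
            "phone_icc",
            "pearson_r",
        ],
    ).set_index("parameter")


def cohort_reference() -> pd.DataFrame:
    """Measurement-experiment group summaries: healthy adults vs patients."""
    rows = [
        # parameter, healthy_mean, healthy_sd, patient_mean, patient_sd
        ("step_period_s", 0.54, 0.04, 0.71, 0.12),
        ("step_length_mm", 605.0, 42.2, 416.0, 85.9),
        ("walking_speed_mm_s", 1131.0, 81.4, 644.0, 169.0),
        ("knee_rom_right_deg", 74.2, 4.36, 58.5, 11.1),
        ("knee_rom_left_deg", 73.5, 5.47, 58.1, 12.6),
        ("knee_velocity_range_right_deg_s", 808.0, 87.2, 554.0, 154.0),
        ("knee_velocity_range_left_deg_s", 808.0, 89.8, 585.0, 173.0),
        ("rcomv_mm_s", 6.90, 0.62, 5.77, 1.03),
        ("sagittal_deviation_range_mm", 1.52, 0.24, 2.15, 0.58),
        ("coronal_deviation_range_mm", 3.69, 0.59, 4.51, 0.73),
    ]
    return pd.DataFrame(
        rows,
        columns=["parameter", "healthy_mean", "healthy_sd", "patient_mean", "patient_sd"],
    ).set_index("parameter")


def synthetic_cohort_table(
    seed: int = 0,
    n_healthy: int = N_HEALTHY_ROWS,
    n_patient: int = N_PATIENT_ROWS,
) -> pd.DataFrame:
    """Draw a synthetic per-segment parameter table at the reference statistics.

    Each column is an independent Gaussian at its group's reference mean/SD
    (column correlations of real cohorts are not reproduced).  Rows carry a
    'group' label in {'healthy', 'patient'}.
    """
    rng = np.random.default_rng(seed)
    ref = cohort_reference()
    data: dict[str, np.ndarray] = {}
    for parameter, row in ref.iterrows():
        healthy = rng.normal(row["healthy_mean"], row["healthy_sd"], size=n_healthy)
        patient = rng.normal(row["patient_mean"], row["patient_sd"], size=n_patient)
        data[parameter] = np.concatenate([healthy, patient])
    table = pd.DataFrame(data)
    table[GROUP_COLUMN] = ["healthy"] * n_healthy + ["patient"] * n_patient
    return table
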
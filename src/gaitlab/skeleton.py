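"""The 17-joint skeleton registry shared by every module.

The joint set follows the common monocular 2D-to-3D lifting layout: a spine
column (sacrum, thoracic and cervical vertebrae markers, nose, head top) plus
bilateral hip, knee, ankle, shoulder, elbow and wrist centres.  The order is
frozen here; trajectory files, the simulator and every extractor index joints
through this registry and nothing else.
"""

from __future__ import annotations

JOINT_NAMES: tuple[str, ...] = (
    "sacrum",
    "hip_right",
    "knee_right",
    "ankle_right",
    "hip_left",
    "knee_left",
    "ankle_left",
    "thorax",
    "neck",
    "nose",
    "head",
    "shoulder_left",
    "elbow_left",
    "wrist_left",
    "shoulder_right",
    "elbow_right",
    "wrist_right",
)

N_JOINTS = len(JOINT_NAMES)

JOINT_INDEX: dict[str, int] = {name: i for i, name in enumerate(JOINT_NAMES)}

AXES = ("x", "y", "z")

#: columns of the CSV trajectory dialect, in file order
COORDINATE_COLUMNS: tuple[str, ...] = tuple(
    f"{joint}_{axis}" for joint in JOINT_NAMES for axis in AXES
)

SIDES = ("left", "right")


def side_joints(side: str) -> dict[str, int]:
    """Indices of hip/knee/ankle for one leg.

    Raises ``KeyError`` for a side outside {'left', 'right'}.
    """
    if side not in SIDES:
        raise KeyError(f"side must be 'left' or 'right', got {side!r}")
    return {
        "hip": JOINT_INDEX[f"hip_{side}"],
        "knee": JOINT_INDEX[f"knee_{side}"],
        "ankle": JOINT_INDEX[f"ankle_{side}"],
    }
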
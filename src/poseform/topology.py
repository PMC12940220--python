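"""Canonical 33-landmark full-body pose topology.

The fixed enumeration of named body keypoints emitted per frame by
on-device pose estimators (BlazePose-style full-body topology), in
canonical index order.  All stream I/O and kinematic code addresses
landmarks by these names.
"""

from __future__ import annotations

LANDMARK_NAMES: tuple[str, ...] = (
    "nose",
    "left_eye_inner",
    "left_eye",
    "left_eye_outer",
    "right_eye_inner",
    "right_eye",
    "right_eye_outer",
    "left_ear",
    "right_ear",
    "mouth_left",
    "mouth_right",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_pinky",
    "right_pinky",
    "left_index",
    "right_index",
    "left_thumb",
    "right_thumb",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
    "left_heel",
    "right_heel",
    "left_foot_index",
    "right_foot_index",
)

N_LANDMARKS = len(LANDMARK_NAMES)
assert N_LANDMARKS == 33

LANDMARK_INDEX: dict[str, int] = {name: i for i, name in enumerate(LANDMARK_NAMES)}


def landmark_index(name: str) -> int:
    """Canonical index of a landmark name; raises KeyError for unknown names."""
    try:
        return LANDMARK_INDEX[name]
    except KeyError:
        raise KeyError(
            f"unknown landmark {name!r}; expected one of the 33 canonical names"
        ) from None
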
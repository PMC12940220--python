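"""Joint angles from landmark triplets.

A joint angle is the interior angle at a vertex landmark between the
rays toward a proximal and a distal landmark, computed from the
normalized dot product and clamped into [0, 180] degrees.  Angles are
computed in 3D by default; a planar (x, y) mode is available for
streams whose depth channel is unreliable.

Triplet conventions follow standard sagittal-plane definitions:
hip = shoulder-hip-knee, knee = hip-knee-ankle,
ankle = knee-ankle-foot_index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from pydantic import BaseModel, Field, field_validator

from .pose_io import LandmarkStream
from .topology import LANDMARK_INDEX, landmark_index

Side = Literal["left", "right", "mean"]
AngleMode = Literal["3d", "2d"]


class DegenerateGeometryError(ValueError):
    """A zero-length ray makes the joint angle undefined."""


def joint_angle(a, b, c) -> float:
    """Interior angle (degrees) at vertex ``b`` between rays b->a and b->c.

    Accepts 2- or 3-vectors.  Invariant under rigid rotation, uniform
    scaling and translation of the triplet; symmetric in ``a`` and ``c``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    u = a - b
    v = c - b
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateGeometryError("zero-length ray at joint vertex")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _angle_series(pa: np.ndarray, pb: np.ndarray, pc: np.ndarray) -> np.ndarray:
    """Vectorized joint angle over (n, d) landmark trajectories."""
    u = pa - pb
    v = pc - pb
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    bad = (nu == 0) | (nv == 0)
    denom = np.where(bad, 1.0, nu * nv)
    cosang = np.clip(np.einsum("ij,ij->i", u, v) / denom, -1.0, 1.0)
    out = np.degrees(np.arccos(cosang))
    out[bad] = np.nan
    return out


class JointSpec(BaseModel):
    """One monitored joint: its landmark triplet, reference angle and band.

    ``proximal``/``vertex``/``distal`` are side-less landmark base names
    (e.g. ``shoulder``, ``hip``, ``knee``) resolved to ``left_``/``right_``
    topology names per analyzed side; names without a sided variant
    (e.g. ``nose``) are used as-is.
    """

    joint_name: str
    proximal: str
    vertex: str
    distal: str
    reference_deg: float = Field(gt=0, le=180)
    tolerance_deg: float = Field(gt=0)

    @field_validator("distal")
    @classmethod
    def _distinct(cls, v, info):
        names = {info.data.get("proximal"), info.data.get("vertex"), v}
        if len(names) < 3:
            raise ValueError("proximal, vertex and distal landmarks must be distinct")
        return v


class RepFSMConfig(BaseModel):
    """Thresholds of the repetition-counting state machine (degrees)."""

    descent_threshold: float
    bottom_threshold: float
    hysteresis: float = 5.0

    @field_validator("bottom_threshold")
    @classmethod
    def _ordered(cls, v, info):
        d = info.data.get("descent_threshold")
        if d is not None and v >= d:
            raise ValueError(
                f"bottom_threshold ({v}) must be below descent_threshold ({d})"
            )
        return v


class ExerciseConfig(BaseModel):
    """Per-exercise analysis preset: joints, references, FSM, muscles."""

    name: str
    joints: list[JointSpec]
    primary_joint: str
    fsm: RepFSMConfig
    muscles: list[str] = Field(min_length=2, max_length=3)
    angle_mode: AngleMode = "3d"

    @field_validator("primary_joint")
    @classmethod
    def _primary_known(cls, v, info):
        joints = info.data.get("joints") or []
        if joints and v not in {j.joint_name for j in joints}:
            raise ValueError(f"primary_joint {v!r} not among configured joints")
        return v

    def joint(self, name: str) -> JointSpec:
        for j in self.joints:
            if j.joint_name == name:
                return j
        raise KeyError(name)


@dataclass
class AngleFrame:
    """Joint angles of one frame; missing joints are absent from ``angles``."""

    frame_index: int
    angles: dict[str, float] = field(default_factory=dict)
    imputed: dict[str, bool] = field(default_factory=dict)
    missing: set[str] = field(default_factory=set)


def _resolve(base: str, side: str) -> int:
    sided = f"{side}_{base}"
    if sided in LANDMARK_INDEX:
        return LANDMARK_INDEX[sided]
    return landmark_index(base)


def extract_angles(
    stream: LandmarkStream,
    exercise: ExerciseConfig,
    side: Side = "mean",
    visibility_floor: float = 0.5,
) -> list[AngleFrame]:
    """Per-frame joint angles for every configured joint.

    ``side='mean'`` averages the left and right kinematic chains; a
    joint whose required landmarks fall below ``visibility_floor`` on
    every requested side is flagged missing for that frame.  Angles of
    frames whose triplet includes a gap-filled landmark carry an
    ``imputed`` flag.
    """
    stream.require_nonempty()
    if not exercise.joints:
        raise ValueError("exercise defines no joints")
    sides = ["left", "right"] if side == "mean" else [side]
    dims = slice(0, 3) if exercise.angle_mode == "3d" else slice(0, 2)

    n = stream.n_frames
    out = [AngleFrame(frame_index=int(stream.frame_index[i])) for i in range(n)]
    for spec in exercise.joints:
        per_side_angles = []
        per_side_ok = []
        per_side_imp = []
        for s in sides:
            ia, ib, ic = (_resolve(spec.proximal, s), _resolve(spec.vertex, s),
                          _resolve(spec.distal, s))
            ang = _angle_series(
                stream.coords[:, ia, dims],
                stream.coords[:, ib, dims],
                stream.coords[:, ic, dims],
            )
            ok = (
                (stream.visibility[:, [ia, ib, ic]] >= visibility_floor).all(axis=1)
                & np.isfinite(ang)
            )
            imp = stream.imputed[:, [ia, ib, ic]].any(axis=1)
            per_side_angles.append(ang)
            per_side_ok.append(ok)
            per_side_imp.append(imp)
        A = np.vstack(per_side_angles)
        OK = np.vstack(per_side_ok)
        IMP = np.vstack(per_side_imp)
        for i in range(n):
            usable = OK[:, i]
            if not usable.any():
                out[i].missing.add(spec.joint_name)
                continue
            out[i].angles[spec.joint_name] = float(A[usable, i].mean())
            out[i].imputed[spec.joint_name] = bool(IMP[usable, i].any())
    return out


def knee_valgus_offset(stream: LandmarkStream) -> np.ndarray:
    """Per-frame mediolateral knee offset from the hip-ankle line.

    For each side the offset is the knee's z displacement toward the
    body midline relative to the mean of the hip and ankle z; the
    returned series averages the two sides.  Positive values mean the
    knees cave inward (valgus); units are normalized image units.
    """
    out = np.zeros(stream.n_frames)
    for side, sign in (("left", 1.0), ("right", -1.0)):
        zh = stream.coords[:, LANDMARK_INDEX[f"{side}_hip"], 2]
        zk = stream.coords[:, LANDMARK_INDEX[f"{side}_knee"], 2]
        za = stream.coords[:, LANDMARK_INDEX[f"{side}_ankle"], 2]
        out += sign * ((zh + za) / 2.0 - zk)
    return out / 2.0


def angle_series(
    frames: Sequence[AngleFrame], joint_name: str, fill: float = np.nan
) -> np.ndarray:
    """Dense per-frame series of one joint's angle (``fill`` where missing)."""
    return np.array([f.angles.get(joint_name, fill) for f in frames])
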
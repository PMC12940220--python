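"""Synthetic data with known ground truth.

Two generators make every analysis stage testable without recordings:

* :func:`simulate_squat_stream` — a sagittal four-segment linkage
  (trunk-thigh-shank-foot) driven by a smooth knee-angle trajectory,
  mapped onto the full 33-landmark topology, with controllable form-error
  modes, Gaussian landmark jitter and occlusion spans.  The paired
  :class:`KinematicTruth` carries the noiseless joint-angle series and
  repetition boundaries.
* :func:`simulate_cohort` — paired pre/post outcome tables for a
  single-arm trial with specified per-outcome change distributions,
  dropout categories and missingness.

Geometry notes.  The linkage lives in the image plane (x right, y down,
z mediolateral); segment lengths are fixed round-number fractions of
image height near published anthropometric mean ratios (shank 0.25,
thigh 0.25, trunk 0.30, foot 0.15) — only angles matter downstream.
With the trunk held parallel to the shank (the standard deep-squat cue)
the hip angle equals the knee angle by construction, and the foot pitch
is chosen so a full-depth squat bottoms out at the 90/90/75 deg
hip/knee/ankle reference posture.  Each repetition is a raised-cosine
descent/ascent (continuously differentiable) separated by 0.5 s
standing holds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .pose_io import LandmarkStream
from .topology import LANDMARK_INDEX, N_LANDMARKS

# segment lengths, fractions of normalized image height
L_SHANK = 0.25
L_THIGH = 0.25
L_TRUNK = 0.30
L_FOOT = 0.15
GROUND_Y = 0.92
ANKLE_X = 0.45
HALF_WIDTH = 0.06  # mediolateral half-distance between left/right joints
FOOT_PITCH_DEG = 30.0  # makes the full-depth ankle angle 75 deg
STAND_HOLD_S = 0.5


class SquatSimParams(BaseModel):
    """Parameters of the squat-stream generator."""

    n_reps: int = Field(default=5, ge=0)
    tempo_s: float = Field(default=3.0, gt=0)
    bottom_knee_deg: float = 90.0
    standing_knee_deg: float = 175.0
    fps: float = Field(default=30.0, gt=0)
    jitter_sd: float = Field(default=0.0, ge=0)
    #: error-mode magnitudes; absent key = mode off
    #: insufficient_depth / trunk_lean / heel_rise in degrees,
    #: knee_valgus in normalized mediolateral units
    error_modes: dict[str, float] = Field(default_factory=dict)
    #: (landmark names, (start_frame, end_frame)) dropped to low visibility
    occlusion: tuple[list[str], tuple[int, int]] | None = None
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if not (0 < self.bottom_knee_deg < self.standing_knee_deg <= 180):
            raise ValueError(
                "need 0 < bottom_knee_deg < standing_knee_deg <= 180"
            )
        known = {"insufficient_depth", "knee_valgus", "trunk_lean", "heel_rise"}
        unknown = set(self.error_modes) - known
        if unknown:
            raise ValueError(f"unknown error modes: {sorted(unknown)}")
        return self


@dataclass
class KinematicTruth:
    """Noiseless ground truth retained by the squat generator."""

    knee_deg: np.ndarray
    hip_deg: np.ndarray
    ankle_deg: np.ndarray
    #: per rep: (start_frame, bottom_frame, end_frame) of the descent window
    rep_boundaries: list[tuple[int, int, int]]
    params: SquatSimParams


def _knee_trajectory(p: SquatSimParams) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    """Knee-angle series (degrees) and per-rep frame windows."""
    hold = int(round(STAND_HOLD_S * p.fps))
    rep_frames = int(round(p.tempo_s * p.fps))
    bottom = p.bottom_knee_deg + p.error_modes.get("insufficient_depth", 0.0)
    if bottom >= p.standing_knee_deg:
        raise ValueError("insufficient_depth magnitude leaves no squat at all")
    segments = [np.full(hold, p.standing_knee_deg)]
    boundaries = []
    cursor = hold
    for _ in range(p.n_reps):
        tau = (np.arange(rep_frames) + 0.5) / rep_frames
        theta = p.standing_knee_deg - (p.standing_knee_deg - bottom) * (
            1 - np.cos(2 * np.pi * tau)
        ) / 2.0
        segments.append(theta)
        b = cursor + int(np.argmin(theta))
        boundaries.append((cursor, b, cursor + rep_frames - 1))
        cursor += rep_frames
        segments.append(np.full(hold, p.standing_knee_deg))
        cursor += hold
    return np.concatenate(segments), boundaries


def simulate_squat_stream(
    params: SquatSimParams | None = None,
) -> tuple[LandmarkStream, KinematicTruth]:
    """Generate a squat landmark stream plus its kinematic ground truth."""
    p = params or SquatSimParams()
    rng = np.random.default_rng(p.seed)
    theta, boundaries = _knee_trajectory(p)
    n = len(theta)

    lean = np.radians(p.error_modes.get("trunk_lean", 0.0))
    heel = p.error_modes.get("heel_rise", 0.0)
    valgus = p.error_modes.get("knee_valgus", 0.0)

    phi = np.radians((180.0 - theta) / 2.0)  # shank/thigh angle from vertical
    phi_tr = phi + lean
    # foot pitch grows with shank rotation, reaching FOOT_PITCH_DEG (+ any
    # heel-rise excess) at the full-depth 45-deg shank posture
    delta = np.radians(FOOT_PITCH_DEG + heel) * (phi / np.radians(45.0))

    ankle = np.stack([np.full(n, ANKLE_X), np.full(n, GROUND_Y - 0.04)], axis=1)
    knee = ankle + L_SHANK * np.stack([np.sin(phi), -np.cos(phi)], axis=1)
    hip = knee + L_THIGH * np.stack([-np.sin(phi), -np.cos(phi)], axis=1)
    shoulder = hip + L_TRUNK * np.stack([np.sin(phi_tr), -np.cos(phi_tr)], axis=1)
    foot_index = ankle + L_FOOT * np.stack([np.cos(delta), np.sin(delta)], axis=1)
    heel_pt = ankle + 0.05 * np.stack(
        [-np.cos(delta), np.sin(delta) + heel / 200.0], axis=1
    )

    up = np.stack([np.sin(phi_tr), -np.cos(phi_tr)], axis=1)  # trunk axis
    fwd = np.stack([np.cos(phi_tr), np.sin(phi_tr)], axis=1)  # trunk normal

    def head(off_up: float, off_fwd: float) -> np.ndarray:
        return shoulder + off_up * up + off_fwd * fwd

    coords = np.zeros((n, N_LANDMARKS, 3))
    vis = np.full((n, N_LANDMARKS), 0.95)

    def put(name: str, xy: np.ndarray, z: float) -> None:
        j = LANDMARK_INDEX[name]
        coords[:, j, 0] = xy[:, 0]
        coords[:, j, 1] = xy[:, 1]
        coords[:, j, 2] = z

    # head, rigid with the trunk
    put("nose", head(0.14, 0.05), 0.0)
    for side, zs in (("left", HALF_WIDTH), ("right", -HALF_WIDTH)):
        s = zs / 2.0
        put(f"{side}_eye_inner", head(0.155, 0.045), s * 0.4)
        put(f"{side}_eye", head(0.155, 0.04), s * 0.6)
        put(f"{side}_eye_outer", head(0.155, 0.035), s * 0.8)
        put(f"{side}_ear", head(0.15, 0.0), s * 1.2)
        put(f"mouth_{side}", head(0.125, 0.045), s * 0.5)
        # arms held straight forward at shoulder height
        put(f"{side}_shoulder", shoulder, zs)
        put(f"{side}_elbow", shoulder + 0.15 * fwd, zs)
        put(f"{side}_wrist", shoulder + 0.30 * fwd, zs)
        put(f"{side}_pinky", shoulder + 0.34 * fwd, zs * 1.05)
        put(f"{side}_index", shoulder + 0.345 * fwd, zs * 0.95)
        put(f"{side}_thumb", shoulder + 0.33 * fwd, zs * 0.85)
        put(f"{side}_hip", hip, zs)
        # valgus collapse grows with squat depth, like the real deficiency
        knee_z = np.sign(zs) * np.maximum(
            abs(zs) - valgus * (phi / np.radians(45.0)), 0.0
        )
        j = LANDMARK_INDEX[f"{side}_knee"]
        coords[:, j, 0] = knee[:, 0]
        coords[:, j, 1] = knee[:, 1]
        coords[:, j, 2] = knee_z
        put(f"{side}_ankle", ankle, zs)
        put(f"{side}_heel", heel_pt, zs)
        put(f"{side}_foot_index", foot_index, zs)

    # noiseless truth angles from the planar construction
    hip_deg = 180.0 - np.degrees(phi + phi_tr)
    ankle_deg = 90.0 - np.degrees(phi) + np.degrees(delta)
    truth = KinematicTruth(
        knee_deg=theta.copy(),
        hip_deg=hip_deg,
        ankle_deg=ankle_deg,
        rep_boundaries=boundaries,
        params=p,
    )

    if p.jitter_sd > 0:
        coords = coords + rng.normal(0.0, p.jitter_sd, size=coords.shape)
    if p.occlusion is not None:
        names, (f0, f1) = p.occlusion
        for name in names:
            vis[f0 : f1 + 1, LANDMARK_INDEX[name]] = 0.1

    stream = LandmarkStream(
        coords=coords,
        visibility=vis,
        frame_index=np.arange(n),
        timestamp_ms=np.arange(n) * 1000.0 / p.fps,
        fps_nominal=p.fps,
        metadata={"generator": "poseform.simulate_squat_stream", "seed": p.seed},
    )
    return stream, truth


# ---------------------------------------------------------------------------
# cohort generator


class OutcomeSpec(BaseModel):
    pre_mean: float
    pre_sd: float = Field(gt=0)
    change_mean: float
    change_sd: float = Field(gt=0)
    missing_rate: float = Field(default=0.0, ge=0, le=1)


#: Default effect structure mirroring the validation trial's outcome table.
DEFAULT_OUTCOMES: dict[str, OutcomeSpec] = {
    "1RM squat (kg)": OutcomeSpec(
        pre_mean=34.67, pre_sd=11.34, change_mean=4.39, change_sd=3.85
    ),
    "body fat (%)": OutcomeSpec(
        pre_mean=24.0, pre_sd=4.5, change_mean=-2.92, change_sd=2.13
    ),
    "skeletal muscle mass (%)": OutcomeSpec(
        pre_mean=37.8, pre_sd=2.8, change_mean=2.19, change_sd=1.53
    ),
    "FMS (score)": OutcomeSpec(
        pre_mean=14.0, pre_sd=1.5, change_mean=0.29, change_sd=1.02
    ),
    "VO2max (mL/kg/min)": OutcomeSpec(
        pre_mean=39.2, pre_sd=4.5, change_mean=1.82, change_sd=1.99
    ),
}

#: Default attrition structure: fractions of total enrollment.
DEFAULT_DROPOUT = {
    "voluntary_withdrawal": 0.181,
    "military_conscription": 0.106,
    "academic_status_change": 0.037,
}


class CohortSimParams(BaseModel):
    n_enrolled: int = Field(default=216, ge=1)
    outcomes: dict[str, OutcomeSpec] = Field(
        default_factory=lambda: dict(DEFAULT_OUTCOMES)
    )
    dropout_fractions: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_DROPOUT)
    )
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if any(f < 0 or f > 1 for f in self.dropout_fractions.values()):
            raise ValueError("dropout fractions must be in [0, 1]")
        if sum(self.dropout_fractions.values()) >= 1.0:
            raise ValueError("dropout fractions must sum below 1")
        return self


@dataclass
class CohortTruth:
    params: CohortSimParams
    n_completers: int
    statuses: dict[str, str] = field(default_factory=dict)


def simulate_cohort(
    params: CohortSimParams | None = None,
) -> tuple[pd.DataFrame, CohortTruth]:
    """Paired pre/post outcome table with attrition.

    Per subject and outcome, pre ~ N(pre_mean, pre_sd) and change ~
    N(change_mean, change_sd), post = pre + change.  Dropout counts are
    the rounded category fractions of enrollment (assignment of subjects
    to categories is randomized under the seed); dropouts have missing
    post values, as do completers hit by per-outcome missingness.

    Returns a tidy table (subject_id, status, outcome, pre, post) and a
    truth object with the generating parameters.
    """
    p = params or CohortSimParams()
    rng = np.random.default_rng(p.seed)
    n = p.n_enrolled

    counts = {k: int(round(f * n)) for k, f in p.dropout_fractions.items()}
    if sum(counts.values()) > n:
        raise ValueError("rounded dropout counts exceed enrollment")
    statuses = ["completed"] * (n - sum(counts.values()))
    for cat, c in counts.items():
        statuses += [cat] * c
    order = rng.permutation(n)
    subject_status = {f"S{i + 1:04d}": statuses[order[i]] for i in range(n)}

    rows = []
    for outcome, spec in p.outcomes.items():
        pre = rng.normal(spec.pre_mean, spec.pre_sd, size=n)
        change = rng.normal(spec.change_mean, spec.change_sd, size=n)
        post = pre + change
        miss = rng.random(n) < spec.missing_rate
        for i, (sid, status) in enumerate(subject_status.items()):
            observed_post = post[i]
            if status != "completed" or miss[i]:
                observed_post = np.nan
            rows.append(
                {
                    "subject_id": sid,
                    "status": status,
                    "outcome": outcome,
                    "pre": pre[i],
                    "post": observed_post,
                }
            )
    table = pd.DataFrame(rows)
    truth = CohortTruth(
        params=p,
        n_completers=n - sum(counts.values()),
        statuses=subject_status,
    )
    return table, truth
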
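"""Form assessment: misalignment detection, accuracy scoring, repetition
counting, muscle presentation and corrective-exercise recommendation.

Misalignment is judged per joint against the exercise's reference angle:
a joint is *green* when the absolute deviation (measured minus
reference) lies within the tolerance band, *red* otherwise.

Form accuracy maps deviations to a [0, 100] percentage: each joint
scores ``100 * max(0, 1 - max(0, |dev| - tol) / tol)`` — full credit
inside the band, linearly decaying to zero by twice the tolerance — and
the frame score is the mean over assessed joints.

Repetitions are counted by a three-state hysteretic machine on the
primary joint's angle (standing -> descending -> bottom -> standing);
the hysteresis band rejects estimator chatter around the thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .catalog import corrective_rules, load_exercise
from .kinematics import AngleFrame, ExerciseConfig, JointSpec, RepFSMConfig

Level = Literal["beginner", "intermediate", "advanced"]

DEFICIENCY_CODES = ("insufficient_depth", "knee_valgus", "trunk_lean", "heel_rise")


@dataclass(frozen=True)
class JointAssessment:
    joint_name: str
    measured_deg: float
    reference_deg: float
    deviation_deg: float
    tolerance_deg: float
    status: Literal["green", "red"]


@dataclass
class MisalignmentReport:
    """Per-joint deviation statuses for one frame."""

    frame_index: int
    joints: dict[str, JointAssessment] = field(default_factory=dict)
    unassessed: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class RepSegment:
    """One counted repetition on the primary joint's angle series."""

    start: int
    bottom: int
    end: int
    bottom_angle_deg: float
    form_accuracy: float | None = None

    def __post_init__(self) -> None:
        if not (self.start < self.bottom < self.end):
            raise ValueError("rep segment requires start < bottom < end")


@dataclass(frozen=True)
class Recommendation:
    deficiency_code: str
    exercise_name: str
    level: Level
    description: str
    demo_duration_s: float


def detect_misalignment(
    angles: AngleFrame, specs: Sequence[JointSpec]
) -> MisalignmentReport:
    """Deviation and green/red status per configured joint for one frame."""
    report = MisalignmentReport(frame_index=angles.frame_index)
    for spec in specs:
        measured = angles.angles.get(spec.joint_name)
        if measured is None:
            report.unassessed.add(spec.joint_name)
            continue
        dev = measured - spec.reference_deg
        status = "green" if abs(dev) <= spec.tolerance_deg else "red"
        report.joints[spec.joint_name] = JointAssessment(
            joint_name=spec.joint_name,
            measured_deg=measured,
            reference_deg=spec.reference_deg,
            deviation_deg=dev,
            tolerance_deg=spec.tolerance_deg,
            status=status,
        )
    return report


def form_accuracy(report: MisalignmentReport, specs: Sequence[JointSpec]) -> float:
    """Mean per-joint accuracy percentage in [0, 100] for one frame."""
    scores = []
    for spec in specs:
        a = report.joints.get(spec.joint_name)
        if a is None:
            continue
        excess = max(0.0, abs(a.deviation_deg) - spec.tolerance_deg)
        scores.append(100.0 * max(0.0, 1.0 - excess / spec.tolerance_deg))
    if not scores:
        raise ValueError("form accuracy needs at least one assessed joint")
    return float(np.mean(scores))


def count_repetitions(angle_series, fsm: RepFSMConfig) -> list[RepSegment]:
    """Hysteretic threshold-crossing repetition counter.

    State machine on the primary-joint angle (degrees): from *standing*
    the machine enters *descending* when the angle drops below
    ``descent_threshold``, reaches *bottom* when it drops below
    ``bottom_threshold``, and emits a rep when the angle rises back
    above ``descent_threshold + hysteresis``.  A descent that never
    reaches the bottom threshold is discarded when the angle recovers.
    NaN samples (missing joint) are skipped without changing state.
    """
    theta = np.asarray(angle_series, dtype=float)
    if theta.size < 2:
        raise ValueError("angle series must have at least 2 samples")
    down, bottom, hyst = fsm.descent_threshold, fsm.bottom_threshold, fsm.hysteresis
    up = down + hyst

    reps: list[RepSegment] = []
    state = "standing"
    start = -1
    for i, a in enumerate(theta):
        if not np.isfinite(a):
            continue
        # a single sample may advance several transitions (e.g. an
        # abrupt drop straight past both thresholds)
        if state == "standing" and a < down:
            state = "descending"
            start = i
        if state == "descending":
            if a < bottom:
                state = "bottom"
            elif a > up:
                state = "standing"  # aborted partial rep
        if state == "bottom" and a > up:
            seg = slice(start, i + 1)
            b = start + int(np.nanargmin(theta[seg]))
            s = start if start < b else max(b - 1, 0)  # dip faster than sampling
            reps.append(
                RepSegment(
                    start=s,
                    bottom=max(b, s + 1),
                    end=i,
                    bottom_angle_deg=float(theta[b]),
                )
            )
            state = "standing"
    return reps


def find_descent_attempts(angle_series, fsm: RepFSMConfig) -> list[tuple[int, int, int]]:
    """All descent excursions, completed or aborted, as (start, deepest, end).

    An attempt opens when the angle drops below the descent threshold
    and closes when it recovers above the threshold plus hysteresis (or
    at the end of the series).  Completed repetitions are a subset;
    attempts that never reach the bottom threshold are exactly the
    too-shallow efforts a depth diagnosis must see, since
    :func:`count_repetitions` never emits them.
    """
    theta = np.asarray(angle_series, dtype=float)
    up = fsm.descent_threshold + fsm.hysteresis
    attempts: list[tuple[int, int, int]] = []
    start = None
    for i, a in enumerate(theta):
        if not np.isfinite(a):
            continue
        if start is None:
            if a < fsm.descent_threshold:
                start = i
        elif a > up:
            seg = slice(start, i + 1)
            attempts.append((start, start + int(np.nanargmin(theta[seg])), i))
            start = None
    if start is not None:
        seg = slice(start, len(theta))
        attempts.append((start, start + int(np.nanargmin(theta[seg])), len(theta) - 1))
    return attempts


def associated_muscles(exercise_name: str) -> list[str]:
    """The 2-3 primary target muscles of a catalog exercise, in display order."""
    return list(load_exercise(exercise_name).muscles)


def recommend_corrective(
    deficiencies: Iterable[str], level: Level = "beginner"
) -> list[Recommendation]:
    """One corrective-exercise recommendation per deficiency at a level.

    Deterministic: recommendations come back in the order the codes were
    given, duplicates collapsed to the first occurrence.
    """
    rules = corrective_rules()
    if level not in ("beginner", "intermediate", "advanced"):
        raise ValueError(f"unknown difficulty level {level!r}")
    out: list[Recommendation] = []
    seen: set[str] = set()
    for code in deficiencies:
        if code in seen:
            continue
        seen.add(code)
        if code not in rules:
            raise KeyError(
                f"unknown deficiency code {code!r}; known: {', '.join(sorted(rules))}"
            )
        entry = rules[code][level]
        out.append(
            Recommendation(
                deficiency_code=code,
                exercise_name=entry["exercise_name"],
                level=level,
                description=" ".join(str(entry["description"]).split()),
                demo_duration_s=float(entry["demo_duration_s"]),
            )
        )
    return out


def diagnose_deficiencies(
    report: MisalignmentReport,
    valgus_offset: float | None = None,
    valgus_threshold: float = 0.04,
) -> list[str]:
    """Map a bottom-of-rep misalignment report to deficiency codes.

    Directional rules (squat archetype, evaluated at the deepest frame):

    * knee angle above reference + tolerance -> ``insufficient_depth``
      (the lifter never reached the target depth);
    * hip angle below reference - tolerance -> ``trunk_lean`` (excessive
      forward trunk inclination closes the shoulder-hip-knee angle);
    * ankle angle above reference + tolerance -> ``heel_rise`` (lost
      dorsiflexion, heels leaving the floor);
    * mediolateral knee offset from the hip-ankle line beyond
      ``valgus_threshold`` (normalized units) -> ``knee_valgus``.
    """
    codes: list[str] = []
    knee = report.joints.get("knee")
    if knee is not None and knee.deviation_deg > knee.tolerance_deg:
        codes.append("insufficient_depth")
    if valgus_offset is not None and abs(valgus_offset) > valgus_threshold:
        codes.append("knee_valgus")
    hip = report.joints.get("hip")
    if hip is not None and hip.deviation_deg < -hip.tolerance_deg:
        codes.append("trunk_lean")
    ankle = report.joints.get("ankle")
    if ankle is not None and ankle.deviation_deg > ankle.tolerance_deg:
        codes.append("heel_rise")
    return codes


@dataclass
class SessionReport:
    """End-to-end assessment of one recorded set."""

    exercise: str
    n_reps: int
    reps: list[RepSegment]
    rep_reports: list[MisalignmentReport]
    session_accuracy: float | None
    deficiencies: list[str]
    recommendations: list[Recommendation]
    muscles: list[str]


def assess_session(
    frames: Sequence[AngleFrame],
    exercise: ExerciseConfig,
    level: Level = "beginner",
    valgus_offsets: Sequence[float] | None = None,
) -> SessionReport:
    """Stage 3-5 pipeline on an extracted angle-frame sequence.

    Counts reps on the primary joint, assesses misalignment and form
    accuracy at each rep's bottom frame, pools deficiency codes across
    reps, and attaches corrective recommendations and the exercise's
    muscle presentation list.
    """
    from .kinematics import angle_series

    theta = angle_series(frames, exercise.primary_joint)
    reps = count_repetitions(theta, exercise.fsm) if len(theta) >= 2 else []
    rep_reports: list[MisalignmentReport] = []
    scored: list[RepSegment] = []
    deficiencies: list[str] = []
    for rep in reps:
        report = detect_misalignment(frames[rep.bottom], exercise.joints)
        acc = form_accuracy(report, exercise.joints) if report.joints else None
        rep_reports.append(report)
        scored.append(
            RepSegment(rep.start, rep.bottom, rep.end, rep.bottom_angle_deg, acc)
        )
    # diagnose every descent attempt, so too-shallow efforts that never
    # complete a countable rep still surface as insufficient depth
    attempts = find_descent_attempts(theta, exercise.fsm) if len(theta) >= 2 else []
    for _, deepest, _ in attempts:
        report = detect_misalignment(frames[deepest], exercise.joints)
        voff = valgus_offsets[deepest] if valgus_offsets is not None else None
        for code in diagnose_deficiencies(report, valgus_offset=voff):
            if code not in deficiencies:
                deficiencies.append(code)
    accs = [r.form_accuracy for r in scored if r.form_accuracy is not None]
    return SessionReport(
        exercise=exercise.name,
        n_reps=len(scored),
        reps=scored,
        rep_reports=rep_reports,
        session_accuracy=float(np.mean(accs)) if accs else None,
        deficiencies=deficiencies,
        recommendations=recommend_corrective(deficiencies, level),
        muscles=list(exercise.muscles),
    )
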
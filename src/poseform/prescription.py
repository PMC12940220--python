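"""Periodized 16-week resistance-training prescription.

The plan is 48 sessions: 16 weeks x 3 weekly sessions on a fixed
non-consecutive weekday pattern (mandatory 24 h recovery between
sessions), each 30 min (5 min warm-up + 20 min resistance + 5 min
cool-down) starting within the 09:00-22:00 window.

Intensity follows a three-phase progressive-overload table on the Borg
6-20 RPE scale:

=========  ============  =========  ========
weeks      %1RM          reps       RPE
=========  ============  =========  ========
1-4        60-70         12-15      13-14
5-8        70-80         8-12       15-16
9-16       75-85         6-10       16-17
=========  ============  =========  ========

Initial loads come from the Brzycki relation
``load = 1RM * (37 - reps) / 36`` with the conventional 0.80 * 1RM
anchor at an 8-rep target; progression applies +2% load per completed
set at or beyond the prescription, gated on maintained form quality.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Sequence

SESSION_MINUTES = {"warm_up": 5, "resistance": 20, "cool_down": 5}
N_WEEKS = 16
SESSIONS_PER_WEEK = 3
EARLIEST_START = dt.time(9, 0)
LATEST_END = dt.time(22, 0)

#: (first_week, last_week, %1RM low/high, rep low/high, RPE low/high)
PHASE_TABLE: tuple[tuple[int, int, float, float, int, int, int, int], ...] = (
    (1, 4, 0.60, 0.70, 12, 15, 13, 14),
    (5, 8, 0.70, 0.80, 8, 12, 15, 16),
    (9, 16, 0.75, 0.85, 6, 10, 16, 17),
)

#: Alternative narrative encoding (adaptation / progressive overload /
#: consolidation) usable via ``phase_parameters(..., table=...)``.
PHASE_TABLE_NARRATIVE: tuple[tuple[int, int, float, float, int, int, int, int], ...] = (
    (1, 4, 0.60, 0.70, 12, 15, 13, 14),
    (5, 12, 0.70, 0.80, 8, 12, 15, 16),
    (13, 16, 0.75, 0.85, 6, 10, 16, 17),
)


class ScheduleError(ValueError):
    pass


@dataclass(frozen=True)
class PhaseSpec:
    week_range: tuple[int, int]
    intensity_band: tuple[float, float]  # fraction of 1RM
    rep_range: tuple[int, int]
    rpe_band: tuple[int, int]  # Borg 6-20


@dataclass(frozen=True)
class Session:
    date: dt.date
    start_time: dt.time
    week: int  # 1-based plan week
    components_min: dict = field(default_factory=lambda: dict(SESSION_MINUTES))

    @property
    def total_minutes(self) -> int:
        return sum(self.components_min.values())


@dataclass
class TrainingPlan:
    sessions: list[Session]
    weekday_pattern: tuple[int, ...]
    start_time: dt.time

    def __post_init__(self) -> None:
        if len(self.sessions) != N_WEEKS * SESSIONS_PER_WEEK:
            raise ScheduleError(
                f"plan must hold exactly {N_WEEKS * SESSIONS_PER_WEEK} sessions, "
                f"got {len(self.sessions)}"
            )
        dates = [s.date for s in self.sessions]
        gaps = [(b - a).days for a, b in zip(dates, dates[1:])]
        if any(g < 2 for g in gaps):
            raise ScheduleError("consecutive-day training is prohibited (min gap 2 days)")


def _validate_pattern(weekday_pattern: Sequence[int]) -> tuple[int, ...]:
    pattern = tuple(sorted(set(int(d) for d in weekday_pattern)))
    if len(pattern) != SESSIONS_PER_WEEK:
        raise ScheduleError("weekday pattern must name 3 distinct weekdays (0=Mon)")
    if any(d < 0 or d > 6 for d in pattern):
        raise ScheduleError("weekdays must be 0 (Mon) .. 6 (Sun)")
    # cyclic pairwise gap >= 2 days, including the week wrap-around
    ext = pattern + (pattern[0] + 7,)
    if any(b - a < 2 for a, b in zip(ext, ext[1:])):
        raise ScheduleError(
            f"pattern {pattern} schedules consecutive days; 24 h recovery required"
        )
    return pattern


def _validate_start_time(start_time: dt.time) -> dt.time:
    end = (
        dt.datetime.combine(dt.date(2000, 1, 3), start_time)
        + dt.timedelta(minutes=sum(SESSION_MINUTES.values()))
    ).time()
    if start_time < EARLIEST_START or end > LATEST_END:
        raise ScheduleError(
            f"session {start_time}-{end} falls outside the 09:00-22:00 window"
        )
    return start_time


def build_schedule(
    start_date: dt.date,
    weekday_pattern: Sequence[int] = (0, 2, 4),
    start_time: dt.time = dt.time(18, 0),
) -> TrainingPlan:
    """48 dated sessions over 16 weeks on a non-consecutive weekday pattern.

    ``weekday_pattern`` uses Python weekday numbers (0=Monday); the plan
    starts in the week of ``start_date`` with the first pattern day on
    or after it.
    """
    pattern = _validate_pattern(weekday_pattern)
    start_time = _validate_start_time(start_time)
    # anchor: Monday of the first plan week containing a usable pattern day
    monday = start_date - dt.timedelta(days=start_date.weekday())
    if all(monday + dt.timedelta(days=d) < start_date for d in pattern):
        monday += dt.timedelta(days=7)
    sessions = [
        Session(
            date=monday + dt.timedelta(weeks=w, days=d),
            start_time=start_time,
            week=w + 1,
        )
        for w in range(N_WEEKS)
        for d in pattern
    ]
    return TrainingPlan(sessions=sessions, weekday_pattern=pattern, start_time=start_time)


def phase_parameters(week: int, table=PHASE_TABLE) -> PhaseSpec:
    """The intensity/rep/RPE prescription band for a plan week (1..16)."""
    if not (1 <= int(week) <= N_WEEKS):
        raise ValueError(f"week must be in 1..{N_WEEKS}, got {week}")
    for w0, w1, i0, i1, r0, r1, e0, e1 in table:
        if w0 <= week <= w1:
            return PhaseSpec((w0, w1), (i0, i1), (r0, r1), (e0, e1))
    raise ValueError(f"phase table does not cover week {week}")


def round_to_increment(load_kg: float, increment_kg: float | None) -> float:
    """Round a load to the nearest equipment increment (None disables)."""
    if increment_kg is None or increment_kg <= 0:
        return load_kg
    return round(load_kg / increment_kg) * increment_kg


def initial_load(
    one_rm_kg: float, target_reps: int, increment_kg: float | None = 2.0
) -> float:
    """Brzycki starting load for a rep target.

    Uses the conventional 0.80 * 1RM anchor at 8 reps; other targets use
    the general relation ``1RM * (37 - reps) / 36``.
    """
    if one_rm_kg < 0:
        raise ValueError("one_rm_kg must be >= 0")
    if not (1 <= int(target_reps) <= 15):
        raise ValueError("target_reps must be in 1..15")
    frac = 0.80 if target_reps == 8 else (37 - target_reps) / 36.0
    return round_to_increment(one_rm_kg * frac, increment_kg)


def progress_load(
    prev_load_kg: float,
    prescribed_sets: int,
    completed_sets: int,
    session_form_accuracy: float,
    accuracy_gate: float = 80.0,
    increment_kg: float | None = 2.0,
) -> float:
    """2%-for-1-set progression gated on form quality.

    Each set completed beyond the prescription earns a 2% load increase
    for the next session — ``prev * (1 + 0.02 * (completed -
    prescribed))`` — provided form accuracy held at or above the gate;
    otherwise (or when the prescription was not exceeded) the load is
    unchanged.  Never decreases the load.
    """
    if prev_load_kg < 0:
        raise ValueError("prev_load_kg must be >= 0")
    if completed_sets < 0 or prescribed_sets < 0:
        raise ValueError("set counts must be >= 0")
    if not (0.0 <= session_form_accuracy <= 100.0):
        raise ValueError("session_form_accuracy must be in [0, 100]")
    if session_form_accuracy < accuracy_gate or completed_sets <= prescribed_sets:
        return prev_load_kg
    factor = 1.0 + 0.02 * (completed_sets - prescribed_sets)
    return max(prev_load_kg, round_to_increment(prev_load_kg * factor, increment_kg))
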
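"""IPAQ-SF scoring, FMS composite scoring, and GXT maximal-effort criteria.

IPAQ-SF (7-day recall) converts self-reported activity into MET-min/week
using the standard intensity weights — vigorous 8.0, moderate 4.0,
walking 3.3 METs — via

    class MET-min/week = MET value x active days/week x mean min/day

and totals the three classes.  The standard cleaning rules apply before
scoring: bouts under 10 consecutive minutes are dropped, each day's
summed activity is capped at 960 min (16 h), and the weekly total is
capped at 10,000 MET-min/week.

Activity categories: **High** needs 1500 MET-min/week with vigorous
activity on >= 3 days, or 3000 MET-min/week with any combination on
>= 7 days; **Moderate** needs >= 600 MET-min/week accumulated over
>= 5 active days of any combination; everything else is **Low**.
Residual frequency/duration combinations the source protocol lists only
by example are deliberately not guessed: they fall to Low with a
cleaning-log entry.

FMS: seven movement patterns scored 0-3, best of three attempts per
movement, pain forcing 0; composite is the sum (max 21).  GXT maximal
effort holds when at least two of {VO2 plateau, RER >= 1.10, heart rate
>= 90% of the age-predicted maximum (220 - age)} are met.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

MET_VALUES = {"vigorous": 8.0, "moderate": 4.0, "walking": 3.3}
MIN_BOUT_MINUTES = 10.0
DAY_CAP_MINUTES = 960.0
WEEK_CAP_MET = 10_000.0
MODERATE_MET_THRESHOLD = 600.0
HIGH_VPA_MET = 1500.0
HIGH_ANY_MET = 3000.0

#: truncation priority when the 960-min day cap binds (preserved first)
DAY_CAP_PRIORITY = ("vigorous", "moderate", "walking")

ActivityClass = Literal["vigorous", "moderate", "walking"]
Category = Literal["Low", "Moderate", "High"]

FMS_MOVEMENTS = (
    "Deep Squat",
    "Hurdle Step",
    "Inline Lunge",
    "Shoulder Mobility",
    "Active Straight-Leg Raise",
    "Trunk Stability Push-Up",
    "Rotary Stability",
)


@dataclass
class ActivityDiary:
    """One week of recalled activity bouts.

    Each class maps 7 day slots to a list of bout durations in minutes;
    day alignment is shared across classes so the daily cap can act on
    the summed day.
    """

    vigorous: list[list[float]] = field(default_factory=lambda: [[] for _ in range(7)])
    moderate: list[list[float]] = field(default_factory=lambda: [[] for _ in range(7)])
    walking: list[list[float]] = field(default_factory=lambda: [[] for _ in range(7)])
    cleaned: bool = False

    def __post_init__(self) -> None:
        for cls in MET_VALUES:
            days = getattr(self, cls)
            if len(days) != 7:
                raise ValueError(f"{cls}: diary needs exactly 7 day slots")
            for d, bouts in enumerate(days):
                if any(b < 0 for b in bouts):
                    raise ValueError(f"{cls} day {d}: bout minutes must be >= 0")

    def day_minutes(self, cls: ActivityClass, day: int) -> float:
        return float(sum(getattr(self, cls)[day]))

    def weekly_minutes(self, cls: ActivityClass) -> float:
        return float(sum(self.day_minutes(cls, d) for d in range(7)))

    def active_days(self, cls: ActivityClass) -> int:
        return sum(1 for d in range(7) if self.day_minutes(cls, d) > 0)

    def combined_active_days(self) -> int:
        """Days with any activity of any class."""
        return sum(
            1
            for d in range(7)
            if any(self.day_minutes(cls, d) > 0 for cls in MET_VALUES)
        )


@dataclass
class METSummary:
    vpa_met: float
    mpa_met: float
    walk_met: float
    total_met: float
    category: Category | None = None
    cleaning_log: list[str] = field(default_factory=list)


def clean_diary(diary: ActivityDiary) -> ActivityDiary:
    """Apply the standard IPAQ cleaning rules, logging every action.

    Bouts shorter than 10 consecutive minutes are removed; then each
    day's total minutes across classes is capped at 960, truncating
    walking first, then moderate, preserving vigorous minutes.
    """
    log: list[str] = []
    out = ActivityDiary(
        vigorous=[list(b) for b in diary.vigorous],
        moderate=[list(b) for b in diary.moderate],
        walking=[list(b) for b in diary.walking],
    )
    for cls in MET_VALUES:
        days = getattr(out, cls)
        for d in range(7):
            kept = [b for b in days[d] if b >= MIN_BOUT_MINUTES]
            dropped = len(days[d]) - len(kept)
            if dropped:
                log.append(f"{cls} day {d}: dropped {dropped} bout(s) < 10 min")
            days[d] = kept
    for d in range(7):
        total = sum(out.day_minutes(cls, d) for cls in MET_VALUES)
        if total <= DAY_CAP_MINUTES:
            continue
        log.append(f"day {d}: {total:g} min exceeds 960-min cap, truncated")
        budget = DAY_CAP_MINUTES
        for cls in DAY_CAP_PRIORITY:
            days = getattr(out, cls)
            minutes = out.day_minutes(cls, d)
            if minutes <= budget:
                budget -= minutes
                continue
            # truncate this class's bouts (later bouts first) to fit budget
            kept: list[float] = []
            remaining = budget
            for b in days[d]:
                if remaining <= 0:
                    break
                take = min(b, remaining)
                if take >= MIN_BOUT_MINUTES:
                    kept.append(take)
                remaining -= take
            days[d] = kept
            budget = 0.0
    out.cleaned = True
    out._cleaning_log = log  # type: ignore[attr-defined]
    return out


def met_minutes(diary: ActivityDiary) -> METSummary:
    """MET-min/week per class and capped weekly total for a cleaned diary.

    The per-class score uses active days x mean minutes per active day,
    which equals the class's weekly minutes, weighted by its MET value.
    """
    if not diary.cleaned:
        raise ValueError("diary must pass clean_diary before scoring")
    log = list(getattr(diary, "_cleaning_log", []))
    scores = {cls: MET_VALUES[cls] * diary.weekly_minutes(cls) for cls in MET_VALUES}
    raw_total = sum(scores.values())
    total = raw_total
    if total > WEEK_CAP_MET:
        log.append(
            f"weekly total {raw_total:g} MET-min exceeds 10,000 cap, truncated"
        )
        total = WEEK_CAP_MET
    return METSummary(
        vpa_met=scores["vigorous"],
        mpa_met=scores["moderate"],
        walk_met=scores["walking"],
        total_met=total,
        cleaning_log=log,
    )


_RULE_EPS = 1e-9  # MET thresholds are exact decimals; absorb float accumulation


def categorize(diary: ActivityDiary, summary: METSummary | None = None) -> Category:
    """IPAQ activity category from a cleaned diary and its MET summary."""
    if summary is None:
        summary = met_minutes(diary)
    total = summary.total_met + _RULE_EPS
    if (diary.active_days("vigorous") >= 3 and total >= HIGH_VPA_MET) or (
        diary.combined_active_days() >= 7 and total >= HIGH_ANY_MET
    ):
        return "High"
    if diary.combined_active_days() >= 5 and total >= MODERATE_MET_THRESHOLD:
        return "Moderate"
    return "Low"


def score_diary(diary: ActivityDiary) -> METSummary:
    """clean -> MET-minutes -> category, in one call."""
    cleaned = clean_diary(diary)
    summary = met_minutes(cleaned)
    return replace(summary, category=categorize(cleaned, summary))


# ---------------------------------------------------------------------------
# Functional Movement Screen


@dataclass
class MovementScore:
    attempts: list[int]
    pain: bool = False

    def __post_init__(self) -> None:
        if not self.attempts or len(self.attempts) > 3:
            raise ValueError("each movement needs 1-3 attempt scores")
        if any(a not in (0, 1, 2, 3) for a in self.attempts):
            raise ValueError("attempt scores must be integers 0-3")

    @property
    def best(self) -> int:
        return 0 if self.pain else max(self.attempts)


@dataclass
class FMSSheet:
    movements: dict[str, MovementScore]

    def __post_init__(self) -> None:
        missing = set(FMS_MOVEMENTS) - set(self.movements)
        if missing:
            raise ValueError(f"FMS sheet missing movements: {sorted(missing)}")
        extra = set(self.movements) - set(FMS_MOVEMENTS)
        if extra:
            raise ValueError(f"unknown FMS movements: {sorted(extra)}")


def fms_composite(sheet: FMSSheet) -> tuple[int, dict[str, int]]:
    """Composite 0-21 score and per-movement bests.

    Best of up to three attempts per movement; any reported pain scores
    that movement 0 regardless of attempts.
    """
    bests = {name: sheet.movements[name].best for name in FMS_MOVEMENTS}
    return sum(bests.values()), bests


# ---------------------------------------------------------------------------
# Graded exercise test


@dataclass(frozen=True)
class GXTRecord:
    vo2_plateau: bool
    rer_max: float
    hr_max: float
    age_years: float

    def __post_init__(self) -> None:
        if self.age_years <= 0:
            raise ValueError("age_years must be positive")
        if self.rer_max <= 0 or self.hr_max <= 0:
            raise ValueError("rer_max and hr_max must be positive")


def age_predicted_hr_max(age_years: float) -> float:
    """Conventional 220 - age estimate of maximal heart rate (bpm)."""
    return 220.0 - age_years


def gxt_max_criteria(rec: GXTRecord) -> tuple[list[str], bool]:
    """Which maximal-effort criteria hold, and whether >= 2 do.

    Criteria: VO2 plateau despite increased workload; RER >= 1.10;
    heart rate >= 90% of the age-predicted maximum.
    """
    met: list[str] = []
    if rec.vo2_plateau:
        met.append("vo2_plateau")
    if rec.rer_max >= 1.10:
        met.append("rer_ge_1.10")
    if rec.hr_max >= 0.90 * age_predicted_hr_max(rec.age_years):
        met.append("hr_ge_90pct_max")
    return met, len(met) >= 2
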
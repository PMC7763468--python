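"""Shared domain model for activity-of-daily-living (ADL) monitoring.

The package watches a single elderly person living in a sensor-equipped
home.  Every other module works in terms of the types defined here:

* :class:`ActivityInstance` — one observed occurrence of an ADL (a night
  of sleep, one lunch, one shower, ...) with a start time and a duration.
* :class:`ActivityPattern` — the *usual* way one activity is performed,
  learned from a baseline period: mean start time, mean duration and the
  normal ranges of duration and daily frequency.
* :class:`DailyBehaviorPattern` — the per-person normal behavior: an
  ordered set of activity patterns per label.
* :class:`ToiletFrequencyProfile` — toileting is frequent and irregular
  in time, so it is profiled by counts per time slot rather than by
  start/duration clusters.

Time convention
---------------
All times are seconds since midnight of an *anchor day*; all durations
are seconds.  A behavioral day runs midnight to midnight, except
sleeping, which is anchored to the evening it begins: going to bed at
2:00 a.m. belongs to the previous day's night.  To make this workable
the time axis of a day extends past 86,400 s (up to 172,800 s), and
:func:`linearize_instance` moves pre-dawn instances onto the previous
day's extended axis.  Clock rendering is presentation only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Mapping

SECONDS_PER_DAY = 86_400
#: Upper bound of the extended (linearized) per-day time axis.
AXIS_MAX_S = 2 * SECONDS_PER_DAY
#: Bedtimes after midnight up to this clock time attach to the previous day.
SLEEP_ANCHOR_CUTOFF_S = 12 * 3600


class ActivityLabel(str, Enum):
    """Closed set of monitored ADLs.

    Four basic ADLs (sleeping, eating, showering, toileting — eating is
    split into its three daily meals) plus one instrumental ADL,
    leaving home, which is only meaningful for people who do not always
    stay at home.
    """

    SLEEPING = "sleeping"
    EATING_BREAKFAST = "eating_breakfast"
    EATING_LUNCH = "eating_lunch"
    EATING_DINNER = "eating_dinner"
    TAKING_SHOWER = "taking_shower"
    LEAVING_HOME = "leaving_home"
    GOING_TO_TOILET = "going_to_toilet"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Meal sub-labels, in day order.  They share the generic source label "eating".
MEAL_LABELS: tuple[ActivityLabel, ...] = (
    ActivityLabel.EATING_BREAKFAST,
    ActivityLabel.EATING_LUNCH,
    ActivityLabel.EATING_DINNER,
)

#: Fallback clock windows (start-time based) for assigning a generic eating
#: instance to a meal when no learned meal clusters are available.
MEAL_WINDOWS_S: dict[ActivityLabel, tuple[float, float]] = {
    ActivityLabel.EATING_BREAKFAST: (6 * 3600, 11 * 3600),
    ActivityLabel.EATING_LUNCH: (11 * 3600, 16 * 3600),
    ActivityLabel.EATING_DINNER: (16 * 3600, 22 * 3600),
}


def parse_clock(text: str) -> float:
    """Parse ``"HH:MM"`` or ``"HH:MM:SS"`` to seconds since midnight."""
    parts = text.split(":")
    if len(parts) not in (2, 3):
        raise ValueError(f"not a clock time: {text!r}")
    h, m = int(parts[0]), int(parts[1])
    s = float(parts[2]) if len(parts) == 3 else 0.0
    return h * 3600 + m * 60 + s


def format_clock(seconds: float) -> str:
    """Render seconds-since-midnight as ``HH:MM:SS`` (wraps past 24 h)."""
    s = int(round(seconds)) % SECONDS_PER_DAY
    return f"{s // 3600:02d}:{s % 3600 // 60:02d}:{s % 60:02d}"


@dataclass(frozen=True)
class ActivityInstance:
    """One observed occurrence of an activity.

    Attributes
    ----------
    label:
        Which ADL was performed.
    day_index:
        Observation day the instance is attributed to (0-based).
    start:
        Start time in seconds on the attributed day's extended axis;
        may exceed 86,400 for instances that began after midnight but
        belong to the previous behavioral day.
    duration:
        Length in seconds, strictly positive.
    """

    label: ActivityLabel
    day_index: int
    start: float
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if not (0 <= self.start < AXIS_MAX_S):
            raise ValueError(f"start {self.start} outside [0, {AXIS_MAX_S})")

    @property
    def end(self) -> float:
        """End time on the same axis; ``end == start + duration`` exactly."""
        return self.start + self.duration


def linearize_instance(instance: ActivityInstance, anchor_day: int) -> ActivityInstance:
    """Express *instance* on *anchor_day*'s extended time axis.

    An instance already on the anchor day is returned unchanged.  An
    instance from the following calendar day (e.g. a 2:00 a.m. bedtime)
    is shifted by +86,400 s and re-attributed, so that activities
    crossing or following midnight stay comparable with the evening
    they belong to.  Duration is never altered.

    Raises
    ------
    ValueError
        If the instance starts more than 24 h after the anchor day's
        midnight, or precedes the anchor day.
    """
    if instance.day_index == anchor_day:
        return instance
    if instance.day_index != anchor_day + 1:
        raise ValueError(
            f"instance on day {instance.day_index} cannot be anchored to day {anchor_day}"
        )
    shifted = instance.start + SECONDS_PER_DAY
    if shifted >= AXIS_MAX_S:
        raise ValueError("instance starts more than 24 h after anchor-day midnight")
    return replace(instance, day_index=anchor_day, start=shifted)


def anchor_day_for(label: ActivityLabel, day_index: int, start_clock_s: float) -> int:
    """Behavioral day an instance belongs to.

    Midnight-to-midnight for every activity except sleeping: a sleep
    that starts after midnight but before noon is attributed to the
    previous day's night.
    """
    if label is ActivityLabel.SLEEPING and start_clock_s < SLEEP_ANCHOR_CUTOFF_S:
        return day_index - 1
    return day_index


def assign_meal_label(
    start_s: float,
    meal_starts: Mapping[ActivityLabel, float] | None = None,
) -> ActivityLabel:
    """Assign a generic eating instance to breakfast/lunch/dinner.

    Nearest learned meal cluster (by usual start time) when available,
    otherwise fixed clock windows (breakfast 06:00-11:00, lunch
    11:00-16:00, dinner 16:00-22:00; out-of-window times snap to the
    nearest window edge).
    """
    if meal_starts:
        return min(meal_starts, key=lambda lab: abs(start_s - meal_starts[lab]))
    best, best_d = ActivityLabel.EATING_DINNER, float("inf")
    for label, (lo, hi) in MEAL_WINDOWS_S.items():
        if lo <= start_s < hi:
            return label
        d = min(abs(start_s - lo), abs(start_s - hi))
        if d < best_d:
            best, best_d = label, d
    return best


@dataclass(frozen=True)
class ActivityPattern:
    """Normal pattern of one activity: when it usually happens and for how long.

    ``usual_start``/``usual_duration`` are cluster means over the
    baseline period (noise removed); the intervals and ranges record
    the min/max spread of the same non-noise instances and feed both
    point-anomaly flags and the fuzzy decision-support configuration.
    """

    label: ActivityLabel
    usual_start: float
    usual_duration: float
    start_interval: tuple[float, float]
    duration_range: tuple[float, float]
    frequency_range: tuple[float, float]
    #: baseline instances behind the pattern (cluster size); 0 = unknown
    n_instances: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.start_interval
        if not (lo <= self.usual_start <= hi):
            raise ValueError("usual_start outside start_interval")
        dmin, dmax = self.duration_range
        if not (0 < dmin <= self.usual_duration <= dmax):
            raise ValueError("usual_duration outside duration_range or non-positive")
        fmin, fmax = self.frequency_range
        if fmin < 0 or fmin > fmax:
            raise ValueError("invalid frequency_range")

    @property
    def usual_end(self) -> float:
        return self.usual_start + self.usual_duration


@dataclass(frozen=True)
class ToiletFrequencyProfile:
    """Normal toileting profile: visit counts per n-hour slot plus daily
    totals and the normal range of the longest single visit per day."""

    slot_hours: int
    expected_counts_per_slot: tuple[tuple[float, float], ...]
    daily_count_range: tuple[float, float]
    max_duration_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.slot_hours <= 0 or 24 % self.slot_hours:
            raise ValueError("slot_hours must divide 24")
        if len(self.expected_counts_per_slot) != 24 // self.slot_hours:
            raise ValueError("need one count range per slot")
        for lo, hi in (*self.expected_counts_per_slot, self.daily_count_range, self.max_duration_range):
            if lo > hi:
                raise ValueError(f"range min {lo} exceeds max {hi}")

    @property
    def n_slots(self) -> int:
        return 24 // self.slot_hours


@dataclass
class DailyBehaviorPattern:
    """The learned normal behavior: per-label activity patterns (ordered by
    usual start) and, separately, the toileting frequency profile.

    ``day_of_week`` is a hook for per-weekday variants; the default
    profile is learned across all days of the week.
    """

    patterns: dict[ActivityLabel, list[ActivityPattern]] = field(default_factory=dict)
    toilet_profile: ToiletFrequencyProfile | None = None
    day_of_week: int | None = None

    def __post_init__(self) -> None:
        for label, plist in self.patterns.items():
            starts = [p.usual_start for p in plist]
            if starts != sorted(starts):
                raise ValueError(f"patterns for {label} not ordered by usual_start")

    def expected(self) -> Iterator[ActivityPattern]:
        """All expected pattern occurrences, in stable label order."""
        for label in ActivityLabel:
            yield from self.patterns.get(label, [])

    @property
    def meal_starts(self) -> dict[ActivityLabel, float]:
        return {
            lab: self.patterns[lab][0].usual_start
            for lab in MEAL_LABELS
            if self.patterns.get(lab)
        }

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        doc: dict = {"activities": {}}
        for label in ActivityLabel:
            plist = self.patterns.get(label)
            if not plist:
                continue
            doc["activities"][label.value] = [
                {
                    "usual_start_s": p.usual_start,
                    "usual_duration_s": p.usual_duration,
                    "start_interval": list(p.start_interval),
                    "duration_range": list(p.duration_range),
                    "frequency_range": list(p.frequency_range),
                    "n_instances": p.n_instances,
                }
                for p in plist
            ]
        if self.toilet_profile is not None:
            tp = self.toilet_profile
            doc["going_to_toilet_profile"] = {
                "slot_hours": tp.slot_hours,
                "expected_counts_per_slot": [list(r) for r in tp.expected_counts_per_slot],
                "daily_count_range": list(tp.daily_count_range),
                "max_duration_range": list(tp.max_duration_range),
            }
        if self.day_of_week is not None:
            doc["day_of_week"] = self.day_of_week
        return doc

    @classmethod
    def from_dict(cls, doc: Mapping) -> "DailyBehaviorPattern":
        patterns: dict[ActivityLabel, list[ActivityPattern]] = {}
        for name, plist in doc.get("activities", {}).items():
            label = ActivityLabel(name)
            patterns[label] = [
                ActivityPattern(
                    label=label,
                    usual_start=p["usual_start_s"],
                    usual_duration=p["usual_duration_s"],
                    start_interval=tuple(p["start_interval"]),
                    duration_range=tuple(p["duration_range"]),
                    frequency_range=tuple(p["frequency_range"]),
                    n_instances=p.get("n_instances", 0),
                )
                for p in plist
            ]
        toilet = None
        if "going_to_toilet_profile" in doc:
            tp = doc["going_to_toilet_profile"]
            toilet = ToiletFrequencyProfile(
                slot_hours=tp["slot_hours"],
                expected_counts_per_slot=tuple(tuple(r) for r in tp["expected_counts_per_slot"]),
                daily_count_range=tuple(tp["daily_count_range"]),
                max_duration_range=tuple(tp["max_duration_range"]),
            )
        return cls(patterns=patterns, toilet_profile=toilet, day_of_week=doc.get("day_of_week"))


@dataclass(frozen=True)
class ProfilingConfig:
    """Clustering parameters for routine learning.

    ``eps``/``min_pts`` follow the usual density-clustering heuristic
    (defaults 2 and 4).  ``eps`` lives in *scaled* feature units: start
    times are divided by ``start_unit_s`` and durations by
    ``duration_unit_s`` before clustering, so with the defaults
    (1 h, 10 min) an eps of 2 spans roughly two hours of start-time
    spread or twenty minutes of duration spread.
    """

    eps: float = 2.0
    min_pts: int = 4
    start_unit_s: float = 3600.0
    duration_unit_s: float = 600.0

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        if self.min_pts < 1:
            raise ValueError("min_pts must be >= 1")
        if self.start_unit_s <= 0 or self.duration_unit_s <= 0:
            raise ValueError("feature units must be > 0")

    def scale(self, start_s: float, duration_s: float) -> tuple[float, float]:
        return start_s / self.start_unit_s, duration_s / self.duration_unit_s
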
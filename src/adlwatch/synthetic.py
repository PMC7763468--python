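"""Seeded synthetic activity logs with ground truth.

Emulates a 63-day single-resident smart-home study: per-activity
Gaussian start-time/duration routines (truncated at a 60 s floor,
rounded to whole seconds — sensor resolution), Poisson toileting
counts per 2-hour slot, and injectable anomaly scenarios (skipped
meals, shortened or late sleep, housebound days, elevated toileting)
with per-day normal/abnormal labels.  Every stage of the pipeline is
testable against the generator's ground truth without any download.

The default routine mirrors the reference gastro configuration's
normal ranges (sleep ~36,000 s/night, three meals totalling ~3,960 s,
one ~11,700 s outing, ~11 toilet visits/day), so the decision-support
fixture and the synthetic world describe the same person.  The
``noiseless`` variant zeroes all jitter and fixes the toilet counts:
every un-edited day is then an exact copy of the routine, which is the
regime where min/max-range anomaly flags are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta
from typing import Literal, Mapping, Sequence

import numpy as np

from .casas_io import SensorEvent, Marker
from .core import (
    ActivityInstance,
    ActivityLabel,
    MEAL_LABELS,
    SECONDS_PER_DAY,
    anchor_day_for,
)

DEFAULT_BASE_DATE = date(2012, 8, 1)

#: Source-label and sensor-id dialect used when emitting events.
_EMIT = {
    ActivityLabel.SLEEPING: ("Sleep", "M021"),
    ActivityLabel.EATING_BREAKFAST: ("Eat", "M009"),
    ActivityLabel.EATING_LUNCH: ("Eat", "M009"),
    ActivityLabel.EATING_DINNER: ("Eat", "M009"),
    ActivityLabel.TAKING_SHOWER: ("Bathe", "M014"),
    ActivityLabel.GOING_TO_TOILET: ("Toilet", "MA013"),
}


@dataclass(frozen=True)
class ActivityRoutine:
    """Gaussian routine of one scheduled activity (clock seconds)."""

    start_mean: float
    start_sd: float
    duration_mean: float
    duration_sd: float
    occurrences: int = 1

    def __post_init__(self) -> None:
        if self.start_sd < 0 or self.duration_sd < 0:
            raise ValueError("SDs must be >= 0")
        if self.occurrences < 0:
            raise ValueError("occurrences must be >= 0")


@dataclass(frozen=True)
class RoutineSpec:
    """Study conditions for a synthetic resident."""

    activities: Mapping[ActivityLabel, ActivityRoutine]
    toilet_slot_means: tuple[float, ...]
    toilet_duration_mean: float = 240.0
    toilet_duration_sd: float = 30.0
    slot_hours: int = 2
    days: int = 63
    seed: int = 0
    deterministic_toilet: bool = False
    overlap_tolerance_s: float = 300.0

    def __post_init__(self) -> None:
        if len(self.toilet_slot_means) != 24 // self.slot_hours:
            raise ValueError("need one toilet mean per slot")
        if any(m < 0 for m in self.toilet_slot_means):
            raise ValueError("toilet slot means must be >= 0")
        self._check_feasible()

    def _check_feasible(self) -> None:
        """Mean schedules of daytime activities must not overlap beyond
        tolerance (sleeping is checked against the next morning)."""
        daytime = [
            (r.start_mean, r.start_mean + r.duration_mean, lab)
            for lab, r in self.activities.items()
            if lab is not ActivityLabel.SLEEPING
        ]
        daytime.sort()
        for (s1, e1, l1), (s2, e2, l2) in zip(daytime, daytime[1:]):
            if s2 < e1 - self.overlap_tolerance_s:
                raise ValueError(f"mean schedules of {l1} and {l2} overlap")
        sleep = self.activities.get(ActivityLabel.SLEEPING)
        if sleep is not None and daytime:
            wake = (sleep.start_mean + sleep.duration_mean) % SECONDS_PER_DAY
            first = min(s for s, _, _ in daytime)
            if sleep.start_mean + sleep.duration_mean > SECONDS_PER_DAY and wake > first + self.overlap_tolerance_s:
                raise ValueError("sleep mean schedule overlaps the next morning")


def default_routine(days: int = 63, seed: int = 0, noiseless: bool = False) -> RoutineSpec:
    """The reference resident: regular sleeper, three meals, one shower,
    one afternoon outing, ~11 toilet visits/day in 2-h slots."""
    sd = 0.0 if noiseless else 1.0
    activities = {
        ActivityLabel.SLEEPING: ActivityRoutine(81_000, 1200 * sd, 36_000, 1800 * sd),
        ActivityLabel.TAKING_SHOWER: ActivityRoutine(31_500, 900 * sd, 900, 120 * sd),
        ActivityLabel.EATING_BREAKFAST: ActivityRoutine(35_040, 900 * sd, 1200, 120 * sd),
        ActivityLabel.EATING_LUNCH: ActivityRoutine(45_000, 900 * sd, 1260, 150 * sd),
        ActivityLabel.LEAVING_HOME: ActivityRoutine(48_600, 1800 * sd, 11_700, 900 * sd),
        ActivityLabel.EATING_DINNER: ActivityRoutine(68_400, 900 * sd, 1500, 150 * sd),
    }
    return RoutineSpec(
        activities=activities,
        toilet_slot_means=(0.5, 0.3, 0.5, 0.8, 1.2, 1.2, 1.2, 1.2, 1.2, 1.2, 1.0, 0.7),
        toilet_duration_mean=240.0,
        toilet_duration_sd=0.0 if noiseless else 30.0,
        days=days,
        seed=seed,
        deterministic_toilet=noiseless,
    )


def _deterministic_slot_counts(means: Sequence[float]) -> list[int]:
    """Largest-remainder rounding of per-slot means to integer counts
    preserving the rounded daily total."""
    total = int(round(sum(means)))
    floors = [int(np.floor(m)) for m in means]
    remainder = total - sum(floors)
    order = sorted(range(len(means)), key=lambda i: means[i] - floors[i], reverse=True)
    for i in order[:remainder]:
        floors[i] += 1
    return floors


def _draw(rng: np.random.Generator, mean: float, sd: float, floor: float = 60.0) -> float:
    value = mean if sd == 0 else rng.normal(mean, sd)
    return float(max(floor, round(value)))


def generate_routine_instances(spec: RoutineSpec) -> list[ActivityInstance]:
    """Ground-truth activity instances for every day of the spec.

    Deterministic for a fixed spec+seed.  Sleeping lives on the
    extended day axis (a jittered 00:30 bedtime stays attached to the
    evening's day).
    """
    rng = np.random.default_rng(spec.seed)
    instances: list[ActivityInstance] = []
    slot_s = spec.slot_hours * 3600
    for day in range(spec.days):
        for label, routine in spec.activities.items():
            for _ in range(routine.occurrences):
                start = _draw(rng, routine.start_mean, routine.start_sd, floor=0.0)
                duration = _draw(rng, routine.duration_mean, routine.duration_sd)
                instances.append(
                    ActivityInstance(label=label, day_index=day, start=start, duration=duration)
                )
        for slot, mean in enumerate(spec.toilet_slot_means):
            if spec.deterministic_toilet:
                count = _deterministic_slot_counts(spec.toilet_slot_means)[slot]
            else:
                count = int(rng.poisson(mean))
            if count == 0:
                continue
            if spec.deterministic_toilet:
                offsets = [(k + 1) * slot_s / (count + 1) for k in range(count)]
            else:
                offsets = sorted(rng.uniform(0, slot_s, size=count))
            for off in offsets:
                start = float(slot * slot_s + round(off))
                duration = _draw(rng, spec.toilet_duration_mean, spec.toilet_duration_sd)
                # keep visits inside their slot for exact count recovery
                duration = min(duration, slot_s - (start - slot * slot_s) - 1) or 60.0
                instances.append(
                    ActivityInstance(
                        label=ActivityLabel.GOING_TO_TOILET,
                        day_index=day,
                        start=start,
                        duration=max(60.0, duration),
                    )
                )
    instances.sort(key=lambda i: (i.day_index, i.start))
    return instances


def emit_events(
    instances: Sequence[ActivityInstance],
    base_date: date = DEFAULT_BASE_DATE,
) -> list[SensorEvent]:
    """Render instances as a time-sorted CASAS-style event log.

    Scheduled activities become same-label begin/end pairs; leaving
    home becomes a Leave_Home / Enter_Home event pair.
    """
    events: list[SensorEvent] = []

    def ts(day: int, sec: float) -> datetime:
        extra, clock = divmod(sec, SECONDS_PER_DAY)
        return datetime.combine(base_date, datetime.min.time()) + timedelta(
            days=day + int(extra), seconds=clock
        )

    for inst in instances:
        if inst.label is ActivityLabel.LEAVING_HOME:
            events.append(
                SensorEvent(ts(inst.day_index, inst.start), "D002", "OPEN", "Leave_Home", Marker.BEGIN)
            )
            events.append(
                SensorEvent(ts(inst.day_index, inst.end), "D002", "OPEN", "Enter_Home", Marker.BEGIN)
            )
            continue
        src, sensor = _EMIT[inst.label]
        events.append(SensorEvent(ts(inst.day_index, inst.start), sensor, "ON", src, Marker.BEGIN))
        events.append(SensorEvent(ts(inst.day_index, inst.end), sensor, "OFF", src, Marker.END))
    events.sort(key=lambda e: e.timestamp)
    return events


def generate_routine_log(
    spec: RoutineSpec, base_date: date = DEFAULT_BASE_DATE
) -> tuple[list[SensorEvent], list[ActivityInstance]]:
    """Event log plus ground-truth instances for the routine spec."""
    instances = generate_routine_instances(spec)
    return emit_events(instances, base_date), instances


EditKind = Literal["drop", "scale_duration", "shift_start", "set_toilet_count", "housebound"]


@dataclass(frozen=True)
class Edit:
    """One scenario edit applied to a range of days (inclusive)."""

    kind: EditKind
    first_day: int
    last_day: int
    label: ActivityLabel | None = None
    factor: float = 1.0
    shift_s: float = 0.0
    count: int = 0
    visit_duration_s: float = 240.0

    @property
    def days(self) -> range:
        return range(self.first_day, self.last_day + 1)


@dataclass
class AnomalyScenario:
    """A list of edits with the ground-truth abnormal-day labels they imply."""

    edits: list[Edit] = field(default_factory=list)

    def abnormal_days(self) -> set[int]:
        return {d for e in self.edits for d in e.days}

    def day_labels(self, n_days: int) -> dict[int, bool]:
        """Ground truth for every day: True = abnormal."""
        abnormal = self.abnormal_days()
        return {d: d in abnormal for d in range(n_days)}


def inject_anomaly_scenario(
    instances: Sequence[ActivityInstance],
    scenario: AnomalyScenario,
    seed: int = 0,
) -> tuple[list[ActivityInstance], dict[int, bool]]:
    """Apply scenario edits to ground-truth instances.

    Returns the edited instances and per-day normal/abnormal labels.
    Editing an activity that is absent on a target day is an error
    (the scenario and the log disagree).
    """
    n_days = max((i.day_index for i in instances), default=-1) + 1
    for edit in scenario.edits:
        if edit.first_day < 0 or edit.last_day >= n_days:
            raise ValueError(f"edit days {edit.first_day}-{edit.last_day} outside log span")
    out = list(instances)
    rng = np.random.default_rng(seed)

    for edit in scenario.edits:
        days = set(edit.days)
        if edit.kind == "housebound":
            target = ActivityLabel.LEAVING_HOME
        else:
            target = edit.label
        if edit.kind in ("drop", "scale_duration", "shift_start", "housebound"):
            if target is None:
                raise ValueError(f"{edit.kind} edit needs a label")
            for d in days:
                hits = [i for i in out if i.day_index == d and i.label is target]
                if not hits:
                    raise ValueError(f"no {target.value} instance on day {d} to edit")
                if edit.kind in ("drop", "housebound"):
                    out = [i for i in out if not (i.day_index == d and i.label is target)]
                else:
                    out = [i for i in out if not (i.day_index == d and i.label is target)]
                    for inst in hits:
                        if edit.kind == "scale_duration":
                            new = replace(
                                inst, duration=max(60.0, round(inst.duration * edit.factor))
                            )
                        else:
                            new = replace(inst, start=inst.start + edit.shift_s)
                        out.append(new)
        elif edit.kind == "set_toilet_count":
            for d in days:
                out = [
                    i
                    for i in out
                    if not (i.day_index == d and i.label is ActivityLabel.GOING_TO_TOILET)
                ]
                starts = np.sort(rng.uniform(6 * 3600, 22 * 3600, size=edit.count))
                for s in starts:
                    out.append(
                        ActivityInstance(
                            label=ActivityLabel.GOING_TO_TOILET,
                            day_index=d,
                            start=float(round(s)),
                            duration=edit.visit_duration_s,
                        )
                    )
        else:  # pragma: no cover - Literal guards this
            raise ValueError(f"unknown edit kind {edit.kind!r}")

    out.sort(key=lambda i: (i.day_index, i.start))
    return out, scenario.day_labels(n_days)


def gastro_episode_scenario(
    first_day: int = 43, toilet_visit_s: float = 240.0
) -> AnomalyScenario:
    """Six-day escalating-then-recovering gastrointestinal episode.

    Short (then also late) sleep, a skipped lunch, housebound days and
    elevated toileting, ramping up to a 4+ abnormal-state peak and
    back down — the canonical deviation episode used by the end-to-end
    tests.  ``first_day`` positions the episode in the monitoring part
    of a 63-day log (after a 30-day baseline).
    """
    d = first_day
    sleep = ActivityLabel.SLEEPING
    lunch = ActivityLabel.EATING_LUNCH
    return AnomalyScenario(
        edits=[
            Edit("scale_duration", d, d + 3, label=sleep, factor=0.5),
            Edit("shift_start", d + 1, d + 1, label=sleep, shift_s=14_400),
            Edit("set_toilet_count", d + 1, d + 1, count=14, visit_duration_s=toilet_visit_s),
            Edit("drop", d + 2, d + 3, label=lunch),
            Edit("set_toilet_count", d + 2, d + 3, count=16, visit_duration_s=toilet_visit_s),
            Edit("housebound", d + 3, d + 4),
            Edit("set_toilet_count", d + 4, d + 4, count=14, visit_duration_s=toilet_visit_s),
            Edit("set_toilet_count", d + 5, d + 5, count=13, visit_duration_s=toilet_visit_s),
        ]
    )
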
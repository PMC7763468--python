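"""Reading and writing CASAS-style activity-labeled sensor event logs.

The input dialect is one whitespace-delimited event per line::

    2012-08-01 09:44:00.00 M009 ON Eat begin
    2012-08-01 10:09:30.00 M009 OFF Eat end

i.e. date, time, sensor id, sensor message, activity label and an
optional ``begin``/``end`` marker.  Sensor ids are prefixed ``M``
(infrared motion), ``MA`` (wide-area infrared motion) or ``D``
(magnetic door).  Activity labels are produced upstream by an activity
recognition system; this package never touches raw, unlabeled sensor
streams.

Begin/end markers of the same label are paired into
:class:`~adlwatch.core.ActivityInstance` objects whose duration is the
end-minus-begin difference.  Leaving home is special-cased: its
duration is the time between a *Leave home* and the next *Enter home*
event.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from datetime import date, datetime
from enum import Enum
from typing import IO, Iterable, Mapping, Sequence

from .core import (
    ActivityInstance,
    ActivityLabel,
    MEAL_LABELS,
    SECONDS_PER_DAY,
    anchor_day_for,
    assign_meal_label,
)

logger = logging.getLogger(__name__)

_TS_FORMATS = ("%Y-%m-%d %H:%M:%S.%f", "%Y-%m-%d %H:%M:%S")

#: Generic source-label target for meals; split into breakfast/lunch/dinner
#: at pairing time.
EATING = "eating"

#: Default canonicalization of CASAS AR labels.  Editable: ship your own
#: JSON with the same shape to change it.  Labels in ``ignore`` are read
#: but never paired (the five monitored ADLs only).
DEFAULT_LABEL_MAP: dict = {
    "activities": {
        "Sleep": "sleeping",
        "Eat": EATING,
        "Bathe": "taking_shower",
        "Toilet": "going_to_toilet",
        "Bed_Toilet_Transition": "going_to_toilet",
    },
    "leave_home": "Leave_Home",
    "enter_home": "Enter_Home",
    "ignore": ["Other_Activity", "Relax", "Cook", "Wash_Dishes", "Personal_Hygiene"],
}


class Marker(str, Enum):
    BEGIN = "begin"
    END = "end"
    NONE = "none"


class SensorClass(str, Enum):
    MOTION = "motion"
    WIDE_AREA_MOTION = "wide_area_motion"
    DOOR = "door"
    OTHER = "other"


def sensor_class(sensor_id: str) -> SensorClass:
    """Classify a sensor id by its CASAS prefix (``MA`` before ``M``)."""
    if sensor_id.startswith("MA"):
        return SensorClass.WIDE_AREA_MOTION
    if sensor_id.startswith("M"):
        return SensorClass.MOTION
    if sensor_id.startswith("D"):
        return SensorClass.DOOR
    return SensorClass.OTHER


@dataclass(frozen=True)
class SensorEvent:
    timestamp: datetime
    sensor_id: str
    message: str
    activity_label: str
    marker: Marker = Marker.NONE

    @property
    def sensor_class(self) -> SensorClass:
        return sensor_class(self.sensor_id)


def _parse_timestamp(date_s: str, time_s: str) -> datetime:
    text = f"{date_s} {time_s}"
    for fmt in _TS_FORMATS:
        try:
            return datetime.strptime(text, fmt)
        except ValueError:
            continue
    raise ValueError(f"unparseable timestamp: {text!r}")


def parse_casas_events(lines: Iterable[str]) -> list[SensorEvent]:
    """Parse whitespace-delimited log lines into :class:`SensorEvent` s.

    Malformed lines (bad timestamp, too few fields) are skipped with a
    warning; file order is preserved.  Empty input yields an empty list.
    """
    events: list[SensorEvent] = []
    skipped = 0
    for lineno, line in enumerate(lines, 1):
        fields = line.split()
        if not fields:
            continue
        if len(fields) < 5:
            logger.warning("line %d: expected >= 5 fields, got %d", lineno, len(fields))
            skipped += 1
            continue
        try:
            ts = _parse_timestamp(fields[0], fields[1])
        except ValueError as exc:
            logger.warning("line %d skipped: %s", lineno, exc)
            skipped += 1
            continue
        marker = Marker.NONE
        if fields[-1].lower() in (Marker.BEGIN.value, Marker.END.value):
            marker = Marker(fields[-1].lower())
            label_fields = fields[4:-1]
        else:
            label_fields = fields[4:]
        events.append(
            SensorEvent(
                timestamp=ts,
                sensor_id=fields[2],
                message=fields[3],
                activity_label="_".join(label_fields),
                marker=marker,
            )
        )
    if skipped:
        logger.warning("skipped %d malformed line(s)", skipped)
    return events


def format_casas_event(event: SensorEvent) -> str:
    marker = "" if event.marker is Marker.NONE else f" {event.marker.value}"
    ts = event.timestamp.strftime("%Y-%m-%d %H:%M:%S.%f")[:-4]
    return f"{ts} {event.sensor_id} {event.message} {event.activity_label}{marker}"


def write_casas_events(events: Sequence[SensorEvent], stream: IO[str]) -> None:
    for event in events:
        stream.write(format_casas_event(event) + "\n")


def load_label_map(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _seconds_since_midnight(ts: datetime) -> float:
    return ts.hour * 3600 + ts.minute * 60 + ts.second + ts.microsecond / 1e6


def pair_activity_instances(
    events: Sequence[SensorEvent],
    label_map: Mapping | None = None,
    base_date: date | None = None,
    meal_starts: Mapping[ActivityLabel, float] | None = None,
) -> list[ActivityInstance]:
    """Pair begin/end markers into activity instances.

    Parameters
    ----------
    events:
        Time-sorted sensor events.
    label_map:
        Canonicalization table (see :data:`DEFAULT_LABEL_MAP`).
    base_date:
        Calendar date of observation day 0; defaults to the first
        event's date.
    meal_starts:
        Learned usual start time per meal label; generic eating
        instances are assigned to the nearest meal (fixed clock windows
        when absent).

    Same-label begin/end markers are matched first-begin/first-end;
    begin/end of *different* labels may interleave freely.  A begin
    with no end (or an orphan end) drops the instance with a warning.
    A matched pair whose end precedes its begin is a corrupt log and
    raises.  Sleeping instances that start before noon are attributed
    to the previous behavioral day on its extended time axis.
    """
    label_map = dict(DEFAULT_LABEL_MAP) if label_map is None else label_map
    if not events:
        return []
    base = base_date or events[0].timestamp.date()
    act_map: Mapping[str, str] = label_map.get("activities", {})
    leave_label = label_map.get("leave_home")
    enter_label = label_map.get("enter_home")
    ignored = set(label_map.get("ignore", ()))

    instances: list[ActivityInstance] = []
    open_begins: dict[str, list[SensorEvent]] = {}
    pending_leave: SensorEvent | None = None

    def emit(target: str, begin_ev: SensorEvent, end_ts: datetime) -> None:
        duration = (end_ts - begin_ev.timestamp).total_seconds()
        if duration < 0:
            raise ValueError(
                f"end before begin for {begin_ev.activity_label} at {begin_ev.timestamp}"
            )
        if duration == 0:
            logger.warning("zero-duration %s at %s dropped", target, begin_ev.timestamp)
            return
        day = (begin_ev.timestamp.date() - base).days
        start = _seconds_since_midnight(begin_ev.timestamp)
        if target == EATING:
            label = assign_meal_label(start, meal_starts)
        else:
            label = ActivityLabel(target)
        anchored = anchor_day_for(label, day, start)
        if anchored != day:
            start += SECONDS_PER_DAY
        instances.append(
            ActivityInstance(label=label, day_index=anchored, start=start, duration=duration)
        )

    for ev in events:
        src = ev.activity_label
        if src in ignored:
            continue
        if src == leave_label:
            if ev.marker is Marker.END:
                continue
            if pending_leave is not None:
                logger.warning("leave-home at %s with no return dropped", pending_leave.timestamp)
            pending_leave = ev
            continue
        if src == enter_label:
            if ev.marker is Marker.END:
                continue
            if pending_leave is None:
                logger.warning("enter-home at %s with no prior leave ignored", ev.timestamp)
                continue
            emit(ActivityLabel.LEAVING_HOME.value, pending_leave, ev.timestamp)
            pending_leave = None
            continue
        target = act_map.get(src)
        if target is None:
            continue
        if ev.marker is Marker.BEGIN:
            open_begins.setdefault(src, []).append(ev)
        elif ev.marker is Marker.END:
            queue = open_begins.get(src)
            if not queue:
                logger.warning("orphan end for %s at %s dropped", src, ev.timestamp)
                continue
            emit(target, queue.pop(0), ev.timestamp)

    for src, queue in open_begins.items():
        for ev in queue:
            logger.warning("begin without end for %s at %s dropped", src, ev.timestamp)
    if pending_leave is not None:
        logger.warning("leave-home at %s with no return dropped", pending_leave.timestamp)

    instances.sort(key=lambda i: (i.day_index, i.start))
    return instances


def instances_to_csv(instances: Sequence[ActivityInstance], stream: IO[str]) -> None:
    """Export instances as CSV (day_index, label, start_s, duration_s)."""
    writer = csv.writer(stream)
    writer.writerow(["day_index", "label", "start_s", "duration_s"])
    for inst in instances:
        writer.writerow([inst.day_index, inst.label.value, inst.start, inst.duration])
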
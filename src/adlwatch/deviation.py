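"""Deviation periods and per-day point anomalies.

A *deviation period* is a sustained run of days whose daily scores
depart from the 100% baseline — the early signal that the person's
routine is drifting.  Within (or independently of) such periods,
*point anomalies* pin down what changed on each day: an expected
activity that is missing, an instance with an unusually long or short
duration, or a daily/slot frequency outside the learned range.  The
per-day count of abnormal duration/frequency states feeds the fuzzy
decision-support system.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

from .core import ActivityInstance, ActivityLabel, DailyBehaviorPattern
from .fuzzy import DiseaseConfig, Observation
from .scoring import (
    Flag,
    ScoreSeries,
    frequency_flags,
    match_instances_to_patterns,
    range_flag,
    toilet_slot_counts,
)


class AnomalyKind(str, Enum):
    MISSING = "missing"
    DURATION_ABNORMAL_MINUS = "duration_abnormal_minus"
    DURATION_ABNORMAL_PLUS = "duration_abnormal_plus"
    FREQUENCY_ABNORMAL_MINUS = "frequency_abnormal_minus"
    FREQUENCY_ABNORMAL_PLUS = "frequency_abnormal_plus"


_DURATION_KIND = {
    Flag.ABNORMAL_MINUS: AnomalyKind.DURATION_ABNORMAL_MINUS,
    Flag.ABNORMAL_PLUS: AnomalyKind.DURATION_ABNORMAL_PLUS,
}
_FREQUENCY_KIND = {
    Flag.ABNORMAL_MINUS: AnomalyKind.FREQUENCY_ABNORMAL_MINUS,
    Flag.ABNORMAL_PLUS: AnomalyKind.FREQUENCY_ABNORMAL_PLUS,
}


@dataclass(frozen=True)
class PointAnomaly:
    day_index: int
    label: ActivityLabel
    kind: AnomalyKind
    observed: float
    normal_range: tuple[float, float]
    detail: str = ""

    def to_dict(self) -> dict:
        return {
            "day": self.day_index,
            "label": self.label.value,
            "kind": self.kind.value,
            "observed": self.observed,
            "normal_range": list(self.normal_range),
            "detail": self.detail,
        }


@dataclass(frozen=True)
class DeviationPeriod:
    start_day: int
    end_day: int
    trigger: str

    def __post_init__(self) -> None:
        if self.start_day > self.end_day:
            raise ValueError("start_day after end_day")

    def __contains__(self, day: int) -> bool:
        return self.start_day <= day <= self.end_day


def detect_deviation_periods(
    series: ScoreSeries,
    threshold_pct: float = 80.0,
    min_run: int = 2,
) -> list[DeviationPeriod]:
    """Maximal runs of at least ``min_run`` consecutive deviating days.

    A day deviates when its similarity score falls below
    ``threshold_pct`` or its duration score leaves the symmetric band
    ``[threshold_pct, 200 - threshold_pct]`` around 100%.
    """
    if not len(series):
        raise ValueError("empty score series")
    if not (0 < threshold_pct <= 100):
        raise ValueError("threshold_pct must be in (0, 100]")

    def deviates(d) -> bool:
        return (
            d.similarity_pct < threshold_pct
            or d.duration_pct < threshold_pct
            or d.duration_pct > 200 - threshold_pct
        )

    periods: list[DeviationPeriod] = []
    run: list = []
    for day in list(series) + [None]:
        if day is not None and deviates(day):
            run.append(day)
            continue
        if len(run) >= min_run:
            sims = [d.similarity_pct for d in run]
            periods.append(
                DeviationPeriod(
                    start_day=run[0].day_index,
                    end_day=run[-1].day_index,
                    trigger=(
                        f"{len(run)} consecutive days deviating "
                        f"(min similarity {min(sims):.1f}%)"
                    ),
                )
            )
        run = []
    return periods


def detect_point_anomalies(
    instances: Sequence[ActivityInstance],
    behavior: DailyBehaviorPattern,
    day_index: int | None = None,
) -> list[PointAnomaly]:
    """Per-day point anomalies against the normal behavior pattern.

    For every expected pattern occurrence: missing if no instance was
    assigned to it; otherwise each assigned instance's duration is
    flagged against the pattern's duration range (inclusive bounds).
    Per-label daily counts are flagged against the frequency range,
    and toileting against the slot/daily/max-duration profile.
    """
    if day_index is None:
        day_index = instances[0].day_index if instances else 0
    anomalies: list[PointAnomaly] = []

    for label, patterns in behavior.patterns.items():
        day_insts = [i for i in instances if i.label is label]
        assigned = match_instances_to_patterns(day_insts, patterns)
        for pi, pattern in enumerate(patterns):
            matches = assigned[pi]
            if not matches:
                anomalies.append(
                    PointAnomaly(day_index, label, AnomalyKind.MISSING, 0.0, pattern.duration_range)
                )
                continue
            for inst in matches:
                flag = range_flag(inst.duration, *pattern.duration_range)
                if flag is not Flag.NORMAL:
                    anomalies.append(
                        PointAnomaly(
                            day_index,
                            label,
                            _DURATION_KIND[flag],
                            inst.duration,
                            pattern.duration_range,
                        )
                    )
        if day_insts:
            # label's daily count vs the pooled (summed) cluster ranges
            frange = (
                sum(p.frequency_range[0] for p in patterns),
                sum(p.frequency_range[1] for p in patterns),
            )
            count = len(day_insts)
            flag = range_flag(count, *frange)
            if flag is not Flag.NORMAL:
                anomalies.append(
                    PointAnomaly(day_index, label, _FREQUENCY_KIND[flag], count, frange)
                )

    if behavior.toilet_profile is not None:
        profile = behavior.toilet_profile
        counts, max_dur = toilet_slot_counts(instances, profile)
        flags = frequency_flags(counts, max_dur, profile)
        toilet = ActivityLabel.GOING_TO_TOILET
        for slot, flag in enumerate(flags.per_slot):
            if flag is not Flag.NORMAL:
                anomalies.append(
                    PointAnomaly(
                        day_index,
                        toilet,
                        _FREQUENCY_KIND[flag],
                        counts[slot],
                        profile.expected_counts_per_slot[slot],
                        detail=f"slot_{slot}",
                    )
                )
        if flags.daily is not Flag.NORMAL:
            anomalies.append(
                PointAnomaly(
                    day_index,
                    toilet,
                    _FREQUENCY_KIND[flags.daily],
                    sum(counts),
                    profile.daily_count_range,
                    detail="daily_count",
                )
            )
        if flags.max_duration is not Flag.NORMAL:
            anomalies.append(
                PointAnomaly(
                    day_index,
                    toilet,
                    _DURATION_KIND[flags.max_duration],
                    max_dur,
                    profile.max_duration_range,
                    detail="max_duration",
                )
            )
    return anomalies


def abnormal_days(
    instances: Sequence[ActivityInstance],
    behavior: DailyBehaviorPattern,
    days: Sequence[int],
) -> dict[int, bool]:
    """Classify each day: abnormal iff it has at least one point anomaly."""
    by_day: dict[int, list[ActivityInstance]] = {}
    for inst in instances:
        by_day.setdefault(inst.day_index, []).append(inst)
    return {
        d: bool(detect_point_anomalies(by_day.get(d, []), behavior, day_index=d))
        for d in days
    }


def count_abnormal_states(observation: Observation, config: DiseaseConfig) -> int:
    """Number of configured duration/frequency states strictly outside
    their normal [min, max] range on this day's observation."""
    count = 0
    for var in config.variables:
        try:
            value = observation[var.label][var.aspect]
        except KeyError as exc:
            raise ValueError(f"observation missing {var.label}.{var.aspect}") from exc
        if value < var.normal_min or value > var.normal_max:
            count += 1
    return count
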
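"""Daily activity scores against the learned normal behavior.

Two per-activity scores compare an observed day with the routine:

* **similarity score** — the temporal intersection of the observed
  activity interval with the usual interval, as a percentage of the
  usual duration ``D_an``::

      sim = max(0, min(E_an, E_ad) - max(S_an, S_ad)) * 100 / D_an

  It is 100% when the usual interval is fully covered and 0% for
  disjoint intervals (the raw formula goes negative there; it is
  clamped, since a percentage of intersection cannot be negative).

* **duration score** — ``D_ad * 100 / D_an``, the observed duration as
  a percentage of the usual one.  It exceeds 100% when the person
  takes longer than usual, which matters for gradual-decline trends.

A day's similarity score averages over every *expected* activity
occurrence (a skipped activity contributes 0); the day's duration
score averages per-activity duration scores over activities actually
performed.  Toileting frequency is compared to the learned slot/daily
count ranges instead (inclusive bounds: a count equal to the learned
min or max is Normal).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from typing import Iterator, Mapping, Sequence

import pandas as pd

from .core import (
    ActivityInstance,
    ActivityLabel,
    ActivityPattern,
    DailyBehaviorPattern,
    SECONDS_PER_DAY,
    ToiletFrequencyProfile,
)


def round2(value: float) -> float:
    """Round-half-up to 2 decimals (report convention)."""
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


class Flag(str, Enum):
    ABNORMAL_MINUS = "Abnormal-"
    NORMAL = "Normal"
    ABNORMAL_PLUS = "Abnormal+"


def range_flag(value: float, lo: float, hi: float) -> Flag:
    """Classify a value against an inclusive [lo, hi] normal range."""
    if value < lo:
        return Flag.ABNORMAL_MINUS
    if value > hi:
        return Flag.ABNORMAL_PLUS
    return Flag.NORMAL


def similarity_score(ad: ActivityInstance, an: ActivityPattern) -> float:
    """Temporal-intersection similarity of an observed instance with its
    pattern, in percent of the pattern's usual duration; in [0, 100]."""
    if an.usual_duration <= 0:
        raise ValueError(f"pattern {an.label} has non-positive usual duration")
    overlap = min(an.usual_end, ad.end) - max(an.usual_start, ad.start)
    return max(0.0, min(100.0, overlap * 100.0 / an.usual_duration))


def duration_score(ad: ActivityInstance, an: ActivityPattern) -> float:
    """Observed duration as a percentage of the usual duration (>= 0,
    unbounded above)."""
    if an.usual_duration <= 0:
        raise ValueError(f"pattern {an.label} has non-positive usual duration")
    return ad.duration * 100.0 / an.usual_duration


@dataclass(frozen=True)
class ToiletFlags:
    per_slot: tuple[Flag, ...]
    daily: Flag
    max_duration: Flag

    @property
    def abnormal(self) -> bool:
        return (
            self.daily is not Flag.NORMAL
            or self.max_duration is not Flag.NORMAL
            or any(f is not Flag.NORMAL for f in self.per_slot)
        )


def frequency_flags(
    slot_counts: Sequence[int],
    daily_max_duration: float,
    profile: ToiletFrequencyProfile,
) -> ToiletFlags:
    """Flag a day's toileting counts and max visit duration against the
    profile's inclusive normal ranges."""
    if len(slot_counts) != profile.n_slots:
        raise ValueError(f"expected {profile.n_slots} slot counts, got {len(slot_counts)}")
    if any(c < 0 for c in slot_counts):
        raise ValueError("counts must be non-negative")
    per_slot = tuple(
        range_flag(c, lo, hi)
        for c, (lo, hi) in zip(slot_counts, profile.expected_counts_per_slot)
    )
    daily = range_flag(sum(slot_counts), *profile.daily_count_range)
    max_dur = range_flag(daily_max_duration, *profile.max_duration_range)
    return ToiletFlags(per_slot=per_slot, daily=daily, max_duration=max_dur)


def toilet_slot_counts(
    instances: Sequence[ActivityInstance], profile: ToiletFrequencyProfile
) -> tuple[list[int], float]:
    """A day's toileting per-slot counts and max visit duration."""
    counts = [0] * profile.n_slots
    max_dur = 0.0
    for inst in instances:
        if inst.label is not ActivityLabel.GOING_TO_TOILET:
            continue
        slot = int((inst.start % SECONDS_PER_DAY) // (profile.slot_hours * 3600))
        counts[slot] += 1
        max_dur = max(max_dur, inst.duration)
    return counts, max_dur


@dataclass
class DailyScores:
    """Similarity and duration scores of one observed day."""

    day_index: int
    similarity_pct: float
    duration_pct: float
    per_activity_similarity: dict[ActivityLabel, float] = field(default_factory=dict)
    duration_pct_by_activity: dict[ActivityLabel, float] = field(default_factory=dict)
    toilet_flags: ToiletFlags | None = None


@dataclass
class ScoreSeries:
    """Ordered per-day scores over the monitoring horizon; 100% is the
    baseline reference for both curves."""

    days: list[DailyScores]

    def __post_init__(self) -> None:
        idx = [d.day_index for d in self.days]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("day_index must be strictly increasing")

    def __iter__(self) -> Iterator[DailyScores]:
        return iter(self.days)

    def __len__(self) -> int:
        return len(self.days)

    def to_dataframe(self) -> pd.DataFrame:
        labels = sorted(
            {lab for d in self.days for lab in d.duration_pct_by_activity},
            key=lambda l: l.value,
        )
        rows = []
        for d in self.days:
            row: dict = {
                "day": d.day_index,
                "similarity_pct": round2(d.similarity_pct),
                "duration_pct": round2(d.duration_pct),
            }
            for lab in labels:
                row[f"duration_pct_{lab.value}"] = (
                    round2(d.duration_pct_by_activity[lab])
                    if lab in d.duration_pct_by_activity
                    else None
                )
            if d.toilet_flags is not None:
                row["toilet_daily_flag"] = d.toilet_flags.daily.value
                row["toilet_max_duration_flag"] = d.toilet_flags.max_duration.value
                row["toilet_slot_abnormal"] = sum(
                    f is not Flag.NORMAL for f in d.toilet_flags.per_slot
                )
            rows.append(row)
        return pd.DataFrame(rows)


def match_instances_to_patterns(
    instances: Sequence[ActivityInstance],
    patterns: Sequence[ActivityPattern],
) -> dict[int, list[ActivityInstance]]:
    """Assign each instance to its nearest pattern by start time.

    Returns pattern index -> assigned instances.  Surplus occurrences
    (more instances than patterns) pile onto their nearest pattern;
    they influence frequency flags, not similarity.
    """
    assigned: dict[int, list[ActivityInstance]] = {i: [] for i in range(len(patterns))}
    for inst in instances:
        nearest = min(
            range(len(patterns)),
            key=lambda i: abs(inst.start - patterns[i].usual_start),
        )
        assigned[nearest].append(inst)
    return assigned


def daily_scores(
    instances: Sequence[ActivityInstance],
    behavior: DailyBehaviorPattern,
    day_index: int | None = None,
) -> DailyScores:
    """Score one observed day against the normal behavior pattern."""
    if not behavior.patterns:
        raise ValueError("behavior pattern is empty")
    if day_index is None:
        day_index = instances[0].day_index if instances else 0

    sims: list[float] = []
    per_label_sims: dict[ActivityLabel, list[float]] = {}
    per_label_durs: dict[ActivityLabel, list[float]] = {}

    for label, patterns in behavior.patterns.items():
        day_insts = [i for i in instances if i.label is label]
        assigned = match_instances_to_patterns(day_insts, patterns)
        for pi, pattern in enumerate(patterns):
            matches = assigned[pi]
            sim = max((similarity_score(m, pattern) for m in matches), default=0.0)
            sims.append(sim)
            per_label_sims.setdefault(label, []).append(sim)
            for m in matches:
                per_label_durs.setdefault(label, []).append(duration_score(m, pattern))

    duration_by_activity = {
        lab: sum(v) / len(v) for lab, v in per_label_durs.items()
    }
    present = list(duration_by_activity.values())
    toilet = None
    if behavior.toilet_profile is not None:
        counts, max_dur = toilet_slot_counts(instances, behavior.toilet_profile)
        toilet = frequency_flags(counts, max_dur, behavior.toilet_profile)
    return DailyScores(
        day_index=day_index,
        similarity_pct=sum(sims) / len(sims) if sims else 0.0,
        duration_pct=sum(present) / len(present) if present else 0.0,
        per_activity_similarity={
            lab: sum(v) / len(v) for lab, v in per_label_sims.items()
        },
        duration_pct_by_activity=duration_by_activity,
        toilet_flags=toilet,
    )


def score_series(
    instances: Sequence[ActivityInstance],
    behavior: DailyBehaviorPattern,
    days: Sequence[int] | None = None,
) -> ScoreSeries:
    """Score every day in ``days`` (default: the observed span)."""
    if days is None:
        observed = sorted({i.day_index for i in instances})
        days = list(range(observed[0], observed[-1] + 1)) if observed else []
    by_day: dict[int, list[ActivityInstance]] = {}
    for inst in instances:
        by_day.setdefault(inst.day_index, []).append(inst)
    return ScoreSeries(
        days=[daily_scores(by_day.get(d, []), behavior, day_index=d) for d in days]
    )
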
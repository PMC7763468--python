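"""Learning the normal behavior pattern from a baseline period.

Each activity's observed instances form points in a 2-D feature space
(start time, duration).  Density-based clustering (DBSCAN) groups the
routine occurrences and marks sparse outliers as noise; noise is
discarded and each remaining cluster is summarized into an
:class:`~adlwatch.core.ActivityPattern` (mean start/duration, min/max
ranges).  Eating typically yields three clusters — the three daily
meals.  Toileting, which recurs many times a day at irregular times,
is profiled by visit counts per n-hour slot instead.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.cluster import DBSCAN

from .core import (
    ActivityInstance,
    ActivityLabel,
    ActivityPattern,
    DailyBehaviorPattern,
    MEAL_LABELS,
    ProfilingConfig,
    SECONDS_PER_DAY,
    ToiletFrequencyProfile,
    assign_meal_label,
)

logger = logging.getLogger(__name__)

NOISE = -1


@dataclass(frozen=True)
class ClusterResult:
    """Per-point cluster assignment; ``NOISE`` (-1) marks outliers.

    Cluster ids are contiguous from 0 in order of first appearance.
    """

    assignments: tuple[int, ...]
    n_clusters: int

    def members(self, cluster_id: int) -> list[int]:
        return [i for i, a in enumerate(self.assignments) if a == cluster_id]

    @property
    def noise(self) -> list[int]:
        return self.members(NOISE)


def dbscan(points: Sequence[Sequence[float]], config: ProfilingConfig) -> ClusterResult:
    """Density-based clustering with standard DBSCAN semantics.

    A core point has at least ``min_pts`` neighbors within ``eps``
    (Euclidean, boundary inclusive, the point counting itself);
    clusters are the density-connected components, border points join
    a core's cluster, everything else is noise.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return ClusterResult(assignments=(), n_clusters=0)
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    raw = DBSCAN(eps=config.eps, min_samples=config.min_pts).fit_predict(pts)
    remap: dict[int, int] = {}
    assignments = []
    for lab in raw:
        if lab == NOISE:
            assignments.append(NOISE)
        else:
            assignments.append(remap.setdefault(int(lab), len(remap)))
    return ClusterResult(assignments=tuple(assignments), n_clusters=len(remap))


def _day_span(instances: Sequence[ActivityInstance]) -> range:
    days = [i.day_index for i in instances]
    return range(min(days), max(days) + 1)


def _cluster_frequency_range(
    members: Sequence[ActivityInstance], days: Iterable[int]
) -> tuple[float, float]:
    counts = Counter(i.day_index for i in members)
    per_day = [counts.get(d, 0) for d in days]
    return float(min(per_day)), float(max(per_day))


def build_activity_patterns(
    instances: Sequence[ActivityInstance],
    config: ProfilingConfig,
    days: Iterable[int] | None = None,
    relabel_meals: bool = False,
) -> list[ActivityPattern]:
    """Cluster one activity's instances and summarize each cluster.

    Noise instances are excluded from means and from the min/max
    ranges.  ``days`` is the baseline day span used for daily
    frequency ranges (defaults to the observed span, so days without
    the activity count as frequency 0).  With ``relabel_meals`` the
    clusters of generic eating instances are renamed to
    breakfast/lunch/dinner by their mean start time.

    Returns an empty list (with a warning) when every point is noise.
    """
    if not instances:
        return []
    day_range = list(days) if days is not None else list(_day_span(instances))
    pts = [config.scale(i.start, i.duration) for i in instances]
    result = dbscan(pts, config)
    if result.n_clusters == 0:
        logger.warning("all %d instances marked noise; no pattern built", len(instances))
        return []
    patterns = []
    for cid in range(result.n_clusters):
        members = [instances[i] for i in result.members(cid)]
        starts = np.array([m.start for m in members])
        durations = np.array([m.duration for m in members])
        mean_start = float(starts.mean())
        label = members[0].label
        if relabel_meals:
            label = assign_meal_label(mean_start % SECONDS_PER_DAY)
        patterns.append(
            ActivityPattern(
                label=label,
                usual_start=mean_start,
                usual_duration=float(durations.mean()),
                start_interval=(float(starts.min()), float(starts.max())),
                duration_range=(float(durations.min()), float(durations.max())),
                frequency_range=_cluster_frequency_range(members, day_range),
                n_instances=len(members),
            )
        )
    patterns.sort(key=lambda p: p.usual_start)
    return patterns


def build_toilet_profile(
    instances: Sequence[ActivityInstance],
    slot_hours: int = 2,
    days: Iterable[int] | None = None,
) -> ToiletFrequencyProfile:
    """Build the toileting frequency profile over the baseline days.

    Counts per ``slot_hours``-hour slot and per day, plus the normal
    range of the longest single visit of a day.  Days containing a
    visit whose duration is a gross outlier (beyond 3x the
    median-based spread) are excluded from the max-duration range so a
    single anomalous baseline day cannot stretch it.
    """
    if 24 % slot_hours:
        raise ValueError("slot_hours must divide 24")
    n_slots = 24 // slot_hours
    if not instances:
        empty = ((0.0, 0.0),) * n_slots
        return ToiletFrequencyProfile(slot_hours, empty, (0.0, 0.0), (0.0, 0.0))
    day_range = list(days) if days is not None else list(_day_span(instances))

    slot_counts = {d: [0] * n_slots for d in day_range}
    day_max: dict[int, float] = {}
    for inst in instances:
        if inst.day_index not in slot_counts:
            continue
        slot = int((inst.start % SECONDS_PER_DAY) // (slot_hours * 3600))
        slot_counts[inst.day_index][slot] += 1
        day_max[inst.day_index] = max(day_max.get(inst.day_index, 0.0), inst.duration)

    durations = np.array([i.duration for i in instances if i.day_index in slot_counts])
    med = float(np.median(durations))
    mad = float(np.median(np.abs(durations - med)))
    cutoff = med + 3 * max(mad, 1.0) * 1.4826
    outlier_days = {
        i.day_index
        for i in instances
        if i.day_index in slot_counts and i.duration > cutoff
    }

    per_slot = tuple(
        (
            float(min(slot_counts[d][s] for d in day_range)),
            float(max(slot_counts[d][s] for d in day_range)),
        )
        for s in range(n_slots)
    )
    totals = [sum(slot_counts[d]) for d in day_range]
    max_days = [day_max.get(d, 0.0) for d in day_range if d not in outlier_days]
    if not max_days:  # every day excluded: fall back to all days
        max_days = [day_max.get(d, 0.0) for d in day_range]
    return ToiletFrequencyProfile(
        slot_hours=slot_hours,
        expected_counts_per_slot=per_slot,
        daily_count_range=(float(min(totals)), float(max(totals))),
        max_duration_range=(float(min(max_days)), float(max(max_days))),
    )


def build_normal_behavior(
    instances_by_label: Mapping[ActivityLabel, Sequence[ActivityInstance]],
    config: ProfilingConfig | None = None,
    slot_hours: int = 2,
    days: Iterable[int] | None = None,
) -> DailyBehaviorPattern:
    """Learn the full normal behavior pattern from a baseline window.

    Meal sub-labels are pooled and re-clustered jointly so the three
    daily meals emerge as three clusters; toileting goes through
    :func:`build_toilet_profile`; every other label is clustered on
    its own.  Labels with no instances are simply absent (a housebound
    person has no leaving-home pattern).
    """
    config = config or ProfilingConfig()
    if days is None:
        everything = [i for insts in instances_by_label.values() for i in insts]
        days = _day_span(everything) if everything else []
    days = list(days)

    patterns: dict[ActivityLabel, list[ActivityPattern]] = {}

    eating = [
        i
        for lab in MEAL_LABELS
        for i in instances_by_label.get(lab, ())
    ]
    for p in build_activity_patterns(eating, config, days=days, relabel_meals=True):
        patterns.setdefault(p.label, []).append(p)

    for label in (
        ActivityLabel.SLEEPING,
        ActivityLabel.TAKING_SHOWER,
        ActivityLabel.LEAVING_HOME,
    ):
        insts = list(instances_by_label.get(label, ()))
        if not insts:
            logger.warning("no %s instances in baseline; label omitted", label.value)
            continue
        plist = build_activity_patterns(insts, config, days=days)
        if plist:
            patterns[label] = plist

    toilet_insts = list(instances_by_label.get(ActivityLabel.GOING_TO_TOILET, ()))
    toilet = build_toilet_profile(toilet_insts, slot_hours=slot_hours, days=days) if toilet_insts else None
    return DailyBehaviorPattern(patterns=patterns, toilet_profile=toilet)


def group_by_label(
    instances: Sequence[ActivityInstance],
) -> dict[ActivityLabel, list[ActivityInstance]]:
    grouped: dict[ActivityLabel, list[ActivityInstance]] = {}
    for inst in instances:
        grouped.setdefault(inst.label, []).append(inst)
    return grouped
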
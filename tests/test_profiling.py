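import logging

import numpy as np
import pytest

from adlwatch.core import ActivityInstance, ActivityLabel, ProfilingConfig
from adlwatch.profiling import (
    NOISE,
    build_activity_patterns,
    build_normal_behavior,
    build_toilet_profile,
    dbscan,
    group_by_label,
)
from adlwatch.synthetic import default_routine, generate_routine_instances

from .reference_impls import partition_of, reference_dbscan

CONFIG = ProfilingConfig()  # eps=2, min_pts=4


class TestDbscan:
    def test_empty_input(self):
        result = dbscan([], CONFIG)
        assert result.assignments == () and result.n_clusters == 0

    def test_fewer_points_than_min_pts_all_noise(self):
        result = dbscan([(0, 0), (0.1, 0), (0, 0.1)], CONFIG)
        assert set(result.assignments) == {NOISE}

    def test_dense_clump_plus_far_outlier(self):
        pts = [(1.0, 1.0)] * 5 + [(1.0 + 10 * CONFIG.eps, 1.0)]
        result = dbscan(pts, CONFIG)
        assert result.n_clusters == 1
        assert list(result.assignments[:5]) == [0] * 5
        assert result.assignments[5] == NOISE

    @pytest.mark.parametrize("trial", range(20))
    def test_agrees_with_exhaustive_reference(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(1, 51))
        pts = rng.uniform(0, 10, size=(n, 2))
        ours = dbscan(pts, CONFIG).assignments
        ref = reference_dbscan(pts, CONFIG.eps, CONFIG.min_pts)
        assert partition_of(ours) == partition_of(ref)

    def test_membership_permutation_invariant(self):
        rng = np.random.default_rng(42)
        pts = rng.uniform(0, 8, size=(30, 2))
        perm = rng.permutation(30)
        base = partition_of(dbscan(pts, CONFIG).assignments)
        shuffled = dbscan(pts[perm], CONFIG).assignments
        unshuffled = [None] * 30
        for new_pos, old_pos in enumerate(perm):
            unshuffled[old_pos] = shuffled[new_pos]
        assert partition_of(unshuffled) == base

    def test_removing_noise_point_leaves_others_unchanged(self):
        pts = [(0.0, 0.0), (0.5, 0.0), (0.0, 0.5), (0.5, 0.5), (50.0, 50.0)]
        full = dbscan(pts, CONFIG).assignments
        assert full[4] == NOISE
        trimmed = dbscan(pts[:4], CONFIG).assignments
        assert partition_of(trimmed) == partition_of(full[:4])


def _lunches(n=30, seed=0, outlier=False):
    rng = np.random.default_rng(seed)
    out = [
        ActivityInstance(
            ActivityLabel.EATING_LUNCH,
            d,
            float(round(rng.normal(45_900, 600))),  # ~12:15 +- 10 min
            float(round(rng.normal(2_100, 300))),  # ~35 +- 5 min
        )
        for d in range(n)
    ]
    if outlier:
        out.append(ActivityInstance(ActivityLabel.EATING_LUNCH, n, 45_900, 7_200))
    return out


class TestBuildPatterns:
    def test_outlier_excluded_from_means_and_ranges(self):
        clean = _lunches()
        with_outlier = _lunches(outlier=True)
        [p_clean] = build_activity_patterns(clean, CONFIG, days=range(30))
        [p_dirty] = build_activity_patterns(with_outlier, CONFIG, days=range(30))
        assert p_dirty.duration_range[1] < 7_200
        assert p_dirty.usual_duration == pytest.approx(p_clean.usual_duration)

    def test_noise_removal_shifts_the_mean(self):
        # forgetting noise elimination would drag the mean upward
        with_outlier = _lunches(outlier=True)
        [pattern] = build_activity_patterns(with_outlier, CONFIG, days=range(30))
        naive_mean = np.mean([i.duration for i in with_outlier])
        assert abs(pattern.usual_duration - 2_100) < abs(naive_mean - 2_100)

    def test_three_meal_windows_give_three_patterns(self):
        rng = np.random.default_rng(1)
        instances = []
        for d in range(30):
            for label, start in [
                (ActivityLabel.EATING_BREAKFAST, 35_040),
                (ActivityLabel.EATING_LUNCH, 45_000),
                (ActivityLabel.EATING_DINNER, 68_400),
            ]:
                instances.append(
                    ActivityInstance(
                        label, d,
                        float(round(rng.normal(start, 600))),
                        float(round(rng.normal(1_300, 150))),
                    )
                )
        patterns = build_activity_patterns(
            instances, CONFIG, days=range(30), relabel_meals=True
        )
        assert len(patterns) == 3
        assert [p.label for p in patterns] == [
            ActivityLabel.EATING_BREAKFAST,
            ActivityLabel.EATING_LUNCH,
            ActivityLabel.EATING_DINNER,
        ]

    def test_identical_instances_give_degenerate_pattern(self):
        instances = [
            ActivityInstance(ActivityLabel.TAKING_SHOWER, d, 31_500, 900) for d in range(10)
        ]
        [pattern] = build_activity_patterns(instances, CONFIG, days=range(10))
        assert pattern.usual_start == 31_500
        assert pattern.usual_duration == 900
        assert pattern.duration_range == (900, 900)
        assert pattern.frequency_range == (1, 1)

    def test_all_noise_gives_empty_list_and_warning(self, caplog):
        scattered = [
            ActivityInstance(ActivityLabel.TAKING_SHOWER, d, 3_600.0 * (d % 20), 300.0 + 4_000 * d)
            for d in range(8)
        ]
        with caplog.at_level(logging.WARNING):
            assert build_activity_patterns(scattered, CONFIG) == []
        assert "noise" in caplog.text


class TestToiletProfile:
    def test_controlled_counts_recover_10_12_range(self):
        rng = np.random.default_rng(2)
        instances = []
        for d in range(30):
            count = int(rng.integers(10, 13))  # 10..12 visits/day
            for k in range(count):
                instances.append(
                    ActivityInstance(
                        ActivityLabel.GOING_TO_TOILET,
                        d,
                        6 * 3600 + k * 3_000.0,
                        240.0,
                    )
                )
        profile = build_toilet_profile(instances, slot_hours=2, days=range(30))
        assert profile.daily_count_range == (10, 12)
        assert profile.max_duration_range == (240, 240)

    def test_no_visits_give_zero_ranges(self):
        profile = build_toilet_profile([], slot_hours=2)
        assert profile.daily_count_range == (0, 0)
        assert all(r == (0, 0) for r in profile.expected_counts_per_slot)

    def test_two_hour_slots_give_twelve_ranges(self):
        instances = [ActivityInstance(ActivityLabel.GOING_TO_TOILET, 0, 3_600, 200)]
        assert build_toilet_profile(instances, slot_hours=2).n_slots == 12


class TestNormalBehavior:
    def test_housebound_person_omits_leaving_home(self, caplog):
        spec = default_routine(days=10, seed=0, noiseless=True)
        instances = [
            i
            for i in generate_routine_instances(spec)
            if i.label is not ActivityLabel.LEAVING_HOME
        ]
        with caplog.at_level(logging.WARNING):
            behavior = build_normal_behavior(group_by_label(instances), days=range(10))
        assert ActivityLabel.LEAVING_HOME not in behavior.patterns
        assert ActivityLabel.SLEEPING in behavior.patterns

    def test_identical_days_reproduce_the_day_exactly(self):
        spec = default_routine(days=10, seed=0, noiseless=True)
        instances = generate_routine_instances(spec)
        behavior = build_normal_behavior(group_by_label(instances), days=range(10))
        sleep = behavior.patterns[ActivityLabel.SLEEPING][0]
        assert sleep.usual_start == 81_000
        assert sleep.usual_duration == 36_000
        assert sleep.duration_range == (36_000, 36_000)
        lunch = behavior.patterns[ActivityLabel.EATING_LUNCH][0]
        assert lunch.usual_start == 45_000 and lunch.usual_duration == 1_260

    def test_parameter_recovery_within_3_se(self):
        """Profiling a noisy 30-day baseline recovers the generator's
        sleep-duration mean within 3 standard errors in >= 90% of seeds."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            spec = default_routine(days=30, seed=seed)
            behavior = build_normal_behavior(
                group_by_label(generate_routine_instances(spec)), days=range(30)
            )
            pattern = max(
                behavior.patterns[ActivityLabel.SLEEPING], key=lambda p: p.n_instances
            )
            routine = spec.activities[ActivityLabel.SLEEPING]
            se = routine.duration_sd / np.sqrt(30)
            if abs(pattern.usual_duration - routine.duration_mean) < 3 * se:
                hits += 1
        assert hits >= 18
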
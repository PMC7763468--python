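import json

import numpy as np
import pytest
from scipy.integrate import quad

from adlwatch.fuzzy import (
    ABNORMAL,
    ADLDiseaseVariable,
    DiseaseConfig,
    FuzzyRule,
    FuzzySet,
    assess_disease_day,
    defuzzify_centroid,
    evaluate_rule,
    fuzzify_variable,
    generate_count_rules,
    mamdani_infer,
    trapezoid_membership,
)

INF = float("inf")
LOW = FuzzySet("Low", (0.0, 0.0, 0.2, 0.4))


class TestTrapezoid:
    SET = FuzzySet("Normal", (0.0, 2.0, 4.0, 6.0))

    @pytest.mark.parametrize(
        "x,expected",
        [
            (3.0, 1.0),  # plateau center
            (2.0, 1.0),
            (0.0, 0.0),  # foot
            (1.0, 0.5),  # ramp midpoint
            (5.0, 0.5),
            (6.0, 0.0),
            (-1.0, 0.0),
            (7.0, 0.0),
        ],
    )
    def test_piecewise_linear_shape(self, x, expected):
        assert trapezoid_membership(x, self.SET) == expected

    def test_degenerate_spike(self):
        spike = FuzzySet("crisp", (3.0, 3.0, 3.0, 3.0))
        assert spike.membership(3.0) == 1.0
        assert spike.membership(2.999) == 0.0

    def test_shoulder_sets_with_infinite_corners(self):
        left = FuzzySet("Abnormal-", (-INF, -INF, 1.0, 2.0))
        assert left.membership(-1e9) == 1.0
        assert left.membership(1.5) == 0.5
        assert left.membership(3.0) == 0.0

    def test_unordered_corners_rejected(self):
        with pytest.raises(ValueError):
            FuzzySet("bad", (1.0, 0.0, 2.0, 3.0))


class TestFuzzification:
    def test_plateau_center_is_fully_normal(self, gastro_config):
        var = next(v for v in gastro_config.variables if v.key == ("eating", "duration"))
        degrees = fuzzify_variable((2_880 + 4_500) / 2, var)
        assert degrees == {"Abnormal-": 0.0, "Normal": 1.0, "Abnormal+": 0.0}

    def test_calibrated_sleep_duration_pair(self, gastro_config):
        """30,000 s of sleep is 0.2 Abnormal- and 0.6 Normal."""
        var = next(v for v in gastro_config.variables if v.key == ("sleeping", "duration"))
        degrees = fuzzify_variable(30_000, var)
        assert degrees["Abnormal-"] == pytest.approx(0.2)
        assert degrees["Normal"] == pytest.approx(0.6)

    def test_calibrated_leaving_home_duration(self, gastro_config):
        """4600 s of leaving home is 0.3 Abnormal- (and 0.1 Normal)."""
        var = next(v for v in gastro_config.variables if v.key == ("leaving_home", "duration"))
        degrees = fuzzify_variable(4_600, var)
        assert degrees["Abnormal-"] == pytest.approx(0.3)
        assert degrees["Normal"] == pytest.approx(0.1)

    def test_frequency_at_range_bound_is_fully_normal(self, gastro_config):
        var = next(v for v in gastro_config.variables if v.key == ("leaving_home", "frequency"))
        assert fuzzify_variable(2, var)["Normal"] == 1.0  # max of [1, 2]

    def test_normal_plateau_must_sit_inside_range(self):
        with pytest.raises(ValueError):
            ADLDiseaseVariable.from_range(
                "sleeping", "duration", 10, 20,
                corners={"Normal": (0, 5, 25, 30)},
            )


def _fuzzified(**degrees):
    """Helper: {('v<i>', 'duration'): {subset: degree}} from flat kwargs."""
    out = {}
    for name, (minus, normal, plus) in degrees.items():
        out[(name, "duration")] = {
            "Abnormal-": minus, "Normal": normal, "Abnormal+": plus
        }
    return out


class TestRuleEvaluation:
    def test_and_rule_takes_minimum(self):
        names = ["a"] + [f"v{i}" for i in range(7)]
        fuzz = _fuzzified(a=(0.0, 0.3, 0.0), **{f"v{i}": (0.0, 1.0, 0.0) for i in range(7)})
        rule = FuzzyRule(
            groups=tuple(((name, "duration", "Normal"),) for name in names),
            consequent="Low",
        )
        assert evaluate_rule(rule, fuzz) == 0.3

    def test_zero_clause_absorbs_conjunction(self):
        fuzz = _fuzzified(a=(0.0, 0.0, 0.0), b=(0.0, 1.0, 0.0))
        rule = FuzzyRule(
            groups=((("a", "duration", "Normal"),), (("b", "duration", "Normal"),)),
            consequent="Low",
        )
        assert evaluate_rule(rule, fuzz) == 0.0

    def test_or_groups_inside_and_rule_take_maximum(self):
        fuzz = _fuzzified(a=(0.2, 0.0, 0.0), b=(0.7, 0.0, 0.0))
        rule = FuzzyRule(
            groups=((("a", "duration", "Abnormal-"), ("b", "duration", "Abnormal-")),),
            consequent="High",
        )
        assert evaluate_rule(rule, fuzz) == 0.7

    def test_abnormal_pseudo_subset_takes_either_tail(self):
        fuzz = _fuzzified(a=(0.2, 0.0, 0.9))
        rule = FuzzyRule(groups=((("a", "duration", ABNORMAL),),), consequent="High")
        assert evaluate_rule(rule, fuzz) == 0.9

    def test_unknown_variable_is_error(self):
        rule = FuzzyRule(groups=((("ghost", "duration", "Normal"),),), consequent="Low")
        with pytest.raises(ValueError):
            evaluate_rule(rule, _fuzzified(a=(0, 1, 0)))


OUTPUT_SETS = {
    "Low": FuzzySet("Low", (0.0, 0.0, 0.2, 0.4)),
    "High": FuzzySet("High", (0.2, 0.4, 0.6, 0.8)),
    "Very high": FuzzySet("Very high", (0.6, 0.8, 1.0, 1.0)),
}


class TestInference:
    def test_full_activation_reproduces_consequent_set(self):
        fuzz = _fuzzified(a=(0.0, 1.0, 0.0))
        rule = FuzzyRule(groups=((("a", "duration", "Normal"),),), consequent="Low")
        grid, mu = mamdani_infer([rule], fuzz, OUTPUT_SETS, grid_n=501)
        expected = np.array([OUTPUT_SETS["Low"].membership(y) for y in grid])
        assert np.allclose(mu, expected)

    def test_two_rules_same_set_clip_at_max_activation(self):
        """Two activations 0.3 and 0.1 into one set aggregate at 0.3."""
        fuzz = _fuzzified(a=(0.3, 0.1, 0.0))
        rules = [
            FuzzyRule(groups=((("a", "duration", "Abnormal-"),),), consequent="Low"),
            FuzzyRule(groups=((("a", "duration", "Normal"),),), consequent="Low"),
        ]
        grid, mu = mamdani_infer(rules, fuzz, OUTPUT_SETS, grid_n=1001)
        assert mu.max() == pytest.approx(0.3)
        plateau = (grid >= 0.05) & (grid <= 0.2)
        assert np.allclose(mu[plateau], 0.3)

    def test_no_rule_firing_gives_zero_function(self):
        fuzz = _fuzzified(a=(0.0, 0.0, 1.0))
        rule = FuzzyRule(groups=((("a", "duration", "Normal"),),), consequent="Low")
        _, mu = mamdani_infer([rule], fuzz, OUTPUT_SETS)
        assert not mu.any()


class TestCentroid:
    def test_symmetric_membership_centers_at_half(self):
        grid = np.linspace(0, 1, 1001)
        mu = np.minimum(1.0, np.minimum(grid, 1 - grid) * 4)
        assert defuzzify_centroid(grid, mu) == pytest.approx(0.5)

    def test_two_point_hand_example(self):
        assert defuzzify_centroid(
            np.array([0.2, 0.8]), np.array([1.0, 3.0])
        ) == pytest.approx(0.65)

    def test_all_zero_membership_is_error(self):
        with pytest.raises(ValueError):
            defuzzify_centroid(np.linspace(0, 1, 11), np.zeros(11))

    def test_matches_fine_quadrature_on_clipped_set(self):
        clipped = lambda y: min(LOW.membership(y), 0.3)
        num, _ = quad(lambda y: y * clipped(y), 0, 1, limit=200)
        den, _ = quad(clipped, 0, 1, limit=200)
        grid = np.linspace(0, 1, 1001)
        mu = np.array([clipped(y) for y in grid])
        assert defuzzify_centroid(grid, mu) == pytest.approx(num / den, abs=1e-3)


class TestAssessment:
    def test_worked_day_is_low_with_minor_alert(self, gastro_config, worked_day_observation):
        a = assess_disease_day(worked_day_observation, gastro_config, day_index=11)
        assert a.category == "Low"
        assert a.alert == "Minor"
        assert a.level == pytest.approx(0.185, abs=0.01)  # reported 0.19

    def test_all_normal_day_sits_in_low_plateau(self, gastro_config):
        obs = {}
        for v in gastro_config.variables:
            b, c = v.sets["Normal"].corners[1:3]
            obs.setdefault(v.label, {})[v.aspect] = (b + c) / 2
        a = assess_disease_day(obs, gastro_config)
        assert a.category == "Low"
        # centroid of the full Low set, cross-checked by quadrature
        num, _ = quad(lambda y: y * LOW.membership(y), 0, 1)
        den, _ = quad(LOW.membership, 0, 1)
        assert a.level == pytest.approx(num / den, abs=1e-3)

    def test_everything_deeply_abnormal_is_very_high(self, gastro_config):
        obs = {}
        for v in gastro_config.variables:
            obs.setdefault(v.label, {})[v.aspect] = v.normal_max * 100
        a = assess_disease_day(obs, gastro_config)
        assert a.category == "Very high"
        assert a.alert == "Major"

    @pytest.mark.parametrize(
        "n_abnormal,expected",
        [(0, "Low"), (1, "Low"), (2, "High"), (3, "High"), (4, "Very high"), (5, "Very high")],
    )
    def test_abnormal_state_count_guidance(self, gastro_config, n_abnormal, expected):
        """Fewer than 2 deeply abnormal states assess Low, 2-3 High, >= 4
        Very high (abnormal sets chosen off the expert-rule patterns)."""
        order = [
            ("eating", "duration"),
            ("going_to_toilet", "frequency"),
            ("going_to_toilet", "duration"),
            ("eating", "frequency"),
            ("sleeping", "duration"),
        ]
        abnormal = set(order[:n_abnormal])
        obs = {}
        for v in gastro_config.variables:
            if (v.label, v.aspect) in abnormal:
                value = v.normal_max * 100
            else:
                b, c = v.sets["Normal"].corners[1:3]
                value = (b + c) / 2
            obs.setdefault(v.label, {})[v.aspect] = value
        assert assess_disease_day(obs, gastro_config).category == expected

    def test_level_monotone_as_inputs_leave_their_ranges(self, gastro_config):
        """Pushing sleep duration further below normal never lowers the
        assessed level (with toileting already elevated)."""
        levels = []
        for sleep in np.linspace(36_000, 15_000, 12):
            obs = {
                "leaving_home": {"duration": 11_000, "frequency": 1},
                "going_to_toilet": {"duration": 3_000, "frequency": 14},
                "eating": {"duration": 3_700, "frequency": 3},
                "sleeping": {"duration": float(sleep), "frequency": 1},
            }
            levels.append(assess_disease_day(obs, gastro_config).level)
        assert all(b >= a - 1e-9 for a, b in zip(levels, levels[1:]))

    def test_level_always_inside_aggregate_support(self, gastro_config, worked_day_observation):
        from adlwatch.fuzzy import fuzzify_observation

        fuzz = fuzzify_observation(worked_day_observation, gastro_config)
        grid, mu = mamdani_infer(
            gastro_config.all_rules(), fuzz, gastro_config.output_sets
        )
        level = defuzzify_centroid(grid, mu)
        support = grid[mu > 0]
        assert support.min() <= level <= support.max()


class TestConfig:
    def test_count_rule_base_covers_every_subset(self, gastro_config):
        rules = generate_count_rules(gastro_config.variables)
        assert len(rules) == 2 ** 8
        by_consequent = {c: 0 for c in ("Low", "High", "Very high")}
        for r in rules:
            by_consequent[r.consequent] += 1
        assert by_consequent["Low"] == 1 + 8  # |S| in {0, 1}
        assert by_consequent["High"] == 28 + 56  # |S| in {2, 3}

    def test_json_round_trip(self, gastro_config, tmp_path):
        path = tmp_path / "disease.json"
        path.write_text(json.dumps(gastro_config.to_dict()))
        restored = DiseaseConfig.from_json(path)
        assert restored.disease == gastro_config.disease
        assert len(restored.variables) == len(gastro_config.variables)
        assert restored.rules == gastro_config.rules
        for orig, back in zip(gastro_config.variables, restored.variables):
            assert back.sets == orig.sets
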
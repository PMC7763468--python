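"""Mamdani fuzzy decision-support system for suspected-disease levels.

A suspected disease (e.g. a gastrointestinal problem) is configured as
a set of *ADL-Disease* linguistic variables: activities whose daily
duration or frequency is clinically impacted by the disease.  Each
variable carries a normal range ``[min, max]`` (from a learned profile
or clinician input) and three trapezoidal fuzzy subsets over its value
axis:

* ``Abnormal-`` — below the normal minimum,
* ``Normal``   — inside the normal range,
* ``Abnormal+`` — above the normal maximum.

Assessment of one day is classic Mamdani max-min inference:

1. **fuzzify** each observed duration/frequency into per-subset
   membership degrees via the trapezoids;
2. **infer**: each rule's activation is the MIN of its AND-joined
   clause degrees (MAX for OR); the rule clips its consequent output
   set (Low / High / Very high on [0, 1]) at the activation, and
   clipped sets aggregate by pointwise MAX;
3. **defuzzify** by center of gravity on a uniform grid, giving a
   disease level in [0, 1], mapped to a category (Low / High /
   Very high) and an alert (Minor / Important / Major).

Rule bases are data, not code.  Besides any hand-written expert rules,
a complete rule base is generated from count guidance — fewer than 2
abnormal states is Low, 2-3 is High, 4 or more is Very high — by
enumerating which subset of variables is abnormal (an ``Abnormal``
clause matches either tail), so no input combination is uncovered.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

INF = float("inf")

#: Output linguistic sets on [0, 1].
DEFAULT_OUTPUT_SETS: dict[str, tuple[float, float, float, float]] = {
    "Low": (0.0, 0.0, 0.2, 0.4),
    "High": (0.2, 0.4, 0.6, 0.8),
    "Very high": (0.6, 0.8, 1.0, 1.0),
}
#: Disease level below cutpoint[0] is Low, below cutpoint[1] High, else Very high.
DEFAULT_CUTPOINTS: tuple[float, float] = (1 / 3, 2 / 3)
DEFAULT_ALERTS: dict[str, str] = {
    "Low": "Minor",
    "High": "Important",
    "Very high": "Major",
}

ABNORMAL_MINUS = "Abnormal-"
NORMAL = "Normal"
ABNORMAL_PLUS = "Abnormal+"
#: Pseudo-subset matching either abnormal tail (degree = max of the two).
ABNORMAL = "Abnormal"


@dataclass(frozen=True)
class FuzzySet:
    """Trapezoidal membership function with corners a <= b <= c <= d.

    Membership is 1 on [b, c], 0 outside (a, d), linear on the ramps.
    Corners may be infinite for one-sided (shoulder) sets.
    """

    name: str
    corners: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        a, b, c, d = self.corners
        if not (a <= b <= c <= d):
            raise ValueError(f"corners must be ordered, got {self.corners}")

    def membership(self, x: float) -> float:
        a, b, c, d = self.corners
        if b <= x <= c:
            return 1.0
        if x <= a or x >= d:
            return 0.0
        if x < b:
            return (x - a) / (b - a)
        return (d - x) / (d - c)


def trapezoid_membership(x: float, fset: FuzzySet) -> float:
    """Degree of membership of *x* in a trapezoidal set (total function)."""
    return fset.membership(x)


@dataclass(frozen=True)
class ADLDiseaseVariable:
    """One linguistic input variable: an activity aspect with its normal
    range and Abnormal-/Normal/Abnormal+ subsets.

    ``label`` is the activity group name ("sleeping", "eating",
    "leaving_home", "going_to_toilet"); ``aspect`` is ``duration``
    (seconds per day) or ``frequency`` (occurrences per day).
    """

    label: str
    aspect: str
    normal_min: float
    normal_max: float
    sets: dict[str, FuzzySet]

    def __post_init__(self) -> None:
        if self.aspect not in ("duration", "frequency"):
            raise ValueError(f"aspect must be duration|frequency, got {self.aspect}")
        if self.normal_min > self.normal_max:
            raise ValueError("normal_min exceeds normal_max")
        for name in (ABNORMAL_MINUS, NORMAL, ABNORMAL_PLUS):
            if name not in self.sets:
                raise ValueError(f"missing subset {name}")
        b, c = self.sets[NORMAL].corners[1:3]
        if not (self.normal_min <= b and c <= self.normal_max):
            raise ValueError("Normal plateau must lie inside the normal range")

    @property
    def key(self) -> tuple[str, str]:
        return (self.label, self.aspect)

    @classmethod
    def from_range(
        cls,
        label: str,
        aspect: str,
        normal_min: float,
        normal_max: float,
        alpha: float = 0.25,
        corners: Mapping[str, Sequence[float]] | None = None,
    ) -> "ADLDiseaseVariable":
        """Build the three subsets from a normal range.

        Durations get symmetric transition bands of half-width
        ``alpha * (max - min)`` around each bound.  Frequencies are
        integer counts, so their Normal plateau is exactly the range
        with one-count ramps — a count equal to the bound is fully
        Normal.  ``corners`` overrides individual subsets (used by
        reference fixtures calibrated to published examples).
        """
        m, M = float(normal_min), float(normal_max)
        if aspect == "frequency":
            default = {
                ABNORMAL_MINUS: (-INF, -INF, m - 1, m),
                NORMAL: (m - 1, m, M, M + 1),
                ABNORMAL_PLUS: (M, M + 1, INF, INF),
            }
        else:
            w = alpha * (M - m)
            default = {
                ABNORMAL_MINUS: (-INF, -INF, m - w, m + w),
                NORMAL: (m - w, m + w, M - w, M + w),
                ABNORMAL_PLUS: (M - w, M + w, INF, INF),
            }
        if corners:
            for name, cs in corners.items():
                default[name] = tuple(float(c) for c in cs)
        sets = {name: FuzzySet(name, tuple(cs)) for name, cs in default.items()}
        return cls(label=label, aspect=aspect, normal_min=m, normal_max=M, sets=sets)


def fuzzify_variable(value: float, variable: ADLDiseaseVariable) -> dict[str, float]:
    """Membership degree of *value* in each of the variable's subsets."""
    return {name: fset.membership(value) for name, fset in variable.sets.items()}


Clause = tuple[str, str, str]  # (label, aspect, subset)


@dataclass(frozen=True)
class FuzzyRule:
    """One inference rule.

    ``groups`` is a list of clause groups.  With the ``AND``
    connective the groups are AND-joined and clauses *within* a group
    are OR-alternatives (and vice versa for ``OR``), which is enough
    to express expert rules like "eating frequency is Abnormal- or
    eating duration is Abnormal-, and ...".  A plain conjunction is a
    list of single-clause groups.
    """

    groups: tuple[tuple[Clause, ...], ...]
    consequent: str
    connective: str = "AND"

    def __post_init__(self) -> None:
        if self.connective not in ("AND", "OR"):
            raise ValueError(f"connective must be AND|OR, got {self.connective}")
        if not self.groups:
            raise ValueError("rule needs at least one clause")


def _clause_degree(clause: Clause, fuzzified: Mapping[tuple[str, str], Mapping[str, float]]) -> float:
    label, aspect, subset = clause
    key = (label, aspect)
    if key not in fuzzified:
        raise ValueError(f"rule references unknown variable {key}")
    degrees = fuzzified[key]
    if subset == ABNORMAL:
        return max(degrees[ABNORMAL_MINUS], degrees[ABNORMAL_PLUS])
    if subset not in degrees:
        raise ValueError(f"unknown subset {subset!r} for variable {key}")
    return degrees[subset]


def evaluate_rule(
    rule: FuzzyRule,
    fuzzified: Mapping[tuple[str, str], Mapping[str, float]],
) -> float:
    """Rule activation degree: MIN over AND-joined terms, MAX over OR."""
    inner = max if rule.connective == "AND" else min
    outer = min if rule.connective == "AND" else max
    return outer(
        inner(_clause_degree(c, fuzzified) for c in group) for group in rule.groups
    )


def generate_count_rules(
    variables: Sequence[ADLDiseaseVariable],
    low_below: int = 2,
    very_high_from: int = 4,
) -> list[FuzzyRule]:
    """Complete rule base from abnormal-state count guidance.

    One AND-rule per subset S of variables: the variables in S are
    ``Abnormal`` (either tail) and the rest ``Normal``; the consequent
    is Low for |S| < ``low_below``, Very high for |S| >=
    ``very_high_from``, High in between.  Enumerating abnormal subsets
    is equivalent to the full per-tail enumeration because MIN is
    monotone and aggregation takes the MAX over rules.
    """
    rules = []
    keys = [v.key for v in variables]
    for k in range(len(keys) + 1):
        if k < low_below:
            consequent = "Low"
        elif k < very_high_from:
            consequent = "High"
        else:
            consequent = "Very high"
        for abnormal in combinations(range(len(keys)), k):
            abset = set(abnormal)
            groups = tuple(
                ((label, aspect, ABNORMAL if i in abset else NORMAL),)
                for i, (label, aspect) in enumerate(keys)
            )
            rules.append(FuzzyRule(groups=groups, consequent=consequent))
    return rules


def mamdani_infer(
    rules: Sequence[FuzzyRule],
    fuzzified: Mapping[tuple[str, str], Mapping[str, float]],
    output_sets: Mapping[str, FuzzySet],
    grid_n: int = 1001,
) -> tuple[np.ndarray, np.ndarray]:
    """Max-min (Mamdani) inference.

    Each rule clips its consequent set at its activation degree;
    clipped sets aggregate by pointwise MAX on a uniform grid over
    [0, 1].  Returns ``(grid, membership)``; an all-zero membership
    means no rule fired.
    """
    if grid_n < 2:
        raise ValueError("grid_n must be >= 2")
    grid = np.linspace(0.0, 1.0, grid_n)
    aggregate = np.zeros_like(grid)
    activation_by_set: dict[str, float] = {}
    for rule in rules:
        if rule.consequent not in output_sets:
            raise ValueError(f"rule consequent {rule.consequent!r} has no output set")
        act = evaluate_rule(rule, fuzzified)
        prev = activation_by_set.get(rule.consequent, 0.0)
        activation_by_set[rule.consequent] = max(prev, act)
    for name, act in activation_by_set.items():
        if act <= 0:
            continue
        mu = np.array([output_sets[name].membership(y) for y in grid])
        aggregate = np.maximum(aggregate, np.minimum(mu, act))
    return grid, aggregate


def defuzzify_centroid(grid: np.ndarray, mu: np.ndarray) -> float:
    """Discrete center of gravity ``sum(y*mu) / sum(mu)`` over the grid."""
    total = float(np.sum(mu))
    if total <= 0:
        raise ValueError("all-zero membership: centroid undefined (no assessment)")
    return float(np.sum(np.asarray(grid) * np.asarray(mu)) / total)


@dataclass(frozen=True)
class DiseaseAssessment:
    """Defuzzified disease level of one day with its category and alert."""

    day_index: int
    level: float
    category: str
    alert: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.level <= 1.0):
            raise ValueError(f"level {self.level} outside [0, 1]")


@dataclass
class DiseaseConfig:
    """Full configuration of one suspected disease."""

    disease: str
    variables: list[ADLDiseaseVariable]
    rules: list[FuzzyRule] = field(default_factory=list)
    output_sets: dict[str, FuzzySet] = field(
        default_factory=lambda: {
            name: FuzzySet(name, corners)
            for name, corners in DEFAULT_OUTPUT_SETS.items()
        }
    )
    cutpoints: tuple[float, float] = DEFAULT_CUTPOINTS
    alerts: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_ALERTS))
    generate_count_rules: bool = True
    grid_n: int = 1001

    def __post_init__(self) -> None:
        if not self.variables:
            raise ValueError("disease needs at least one variable")
        if not self.rules and not self.generate_count_rules:
            raise ValueError("no rules and count-rule generation disabled")

    def all_rules(self) -> list[FuzzyRule]:
        rules = list(self.rules)
        if self.generate_count_rules:
            rules.extend(generate_count_rules(self.variables))
        return rules

    def categorize(self, level: float) -> str:
        if level < self.cutpoints[0]:
            return "Low"
        if level < self.cutpoints[1]:
            return "High"
        return "Very high"

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        def cs(corners):
            return [None if math.isinf(c) else c for c in corners]

        return {
            "disease": self.disease,
            "variables": [
                {
                    "label": v.label,
                    "aspect": v.aspect,
                    "normal_min": v.normal_min,
                    "normal_max": v.normal_max,
                    "corners": {n: cs(s.corners) for n, s in v.sets.items()},
                }
                for v in self.variables
            ],
            "rules": [
                {
                    "connective": r.connective,
                    "clauses": [[list(c) for c in g] for g in r.groups],
                    "consequent": r.consequent,
                }
                for r in self.rules
            ],
            "output_sets": {n: list(s.corners) for n, s in self.output_sets.items()},
            "cutpoints": list(self.cutpoints),
            "alerts": dict(self.alerts),
            "generate_count_rules": self.generate_count_rules,
            "grid_n": self.grid_n,
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "DiseaseConfig":
        def uncs(corners):
            out = []
            for i, c in enumerate(corners):
                if c is None:
                    out.append(-INF if i < 2 else INF)
                else:
                    out.append(float(c))
            return tuple(out)

        variables = [
            ADLDiseaseVariable.from_range(
                v["label"],
                v["aspect"],
                v["normal_min"],
                v["normal_max"],
                alpha=v.get("alpha", 0.25),
                corners={n: uncs(c) for n, c in v.get("corners", {}).items()},
            )
            for v in doc["variables"]
        ]
        rules = [
            FuzzyRule(
                groups=tuple(tuple(tuple(c) for c in g) for g in r["clauses"]),
                consequent=r["consequent"],
                connective=r.get("connective", "AND"),
            )
            for r in doc.get("rules", [])
        ]
        kwargs: dict = {}
        if "output_sets" in doc:
            kwargs["output_sets"] = {
                n: FuzzySet(n, tuple(c)) for n, c in doc["output_sets"].items()
            }
        if "cutpoints" in doc:
            kwargs["cutpoints"] = tuple(doc["cutpoints"])
        if "alerts" in doc:
            kwargs["alerts"] = dict(doc["alerts"])
        return cls(
            disease=doc["disease"],
            variables=variables,
            rules=rules,
            generate_count_rules=doc.get("generate_count_rules", True),
            grid_n=doc.get("grid_n", 1001),
            **kwargs,
        )

    @classmethod
    def from_json(cls, path) -> "DiseaseConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


Observation = Mapping[str, Mapping[str, float]]


def fuzzify_observation(
    observation: Observation, config: DiseaseConfig
) -> dict[tuple[str, str], dict[str, float]]:
    fuzzified = {}
    for var in config.variables:
        try:
            value = observation[var.label][var.aspect]
        except KeyError as exc:
            raise ValueError(f"observation missing {var.label}.{var.aspect}") from exc
        fuzzified[var.key] = fuzzify_variable(value, var)
    return fuzzified


def assess_disease_day(
    observation: Observation,
    config: DiseaseConfig,
    day_index: int = 0,
) -> DiseaseAssessment:
    """Fuzzify -> infer -> defuzzify one day's observation.

    ``observation`` maps activity label to its day aggregates, e.g.
    ``{"sleeping": {"duration": 32400, "frequency": 2}, ...}``.
    """
    fuzzified = fuzzify_observation(observation, config)
    grid, mu = mamdani_infer(config.all_rules(), fuzzified, config.output_sets, config.grid_n)
    level = defuzzify_centroid(grid, mu)
    category = config.categorize(level)
    return DiseaseAssessment(
        day_index=day_index,
        level=level,
        category=category,
        alert=config.alerts[category],
    )


def gastro_reference_config() -> DiseaseConfig:
    """Reference configuration for a gastrointestinal problem.

    Four ADL-Disease variables (leaving home, going to toilet, eating,
    sleeping; duration and daily frequency each — 8 states) with
    clinically motivated normal ranges, plus three verbatim expert
    rules and the generated count-based base.  The leaving-home and
    sleeping duration trapezoids are calibrated to published worked
    examples (4600 s fuzzifies to 0.3 Abnormal- / 0.1 Normal; 30,000 s
    of sleep to 0.2 Abnormal- / 0.6 Normal).
    """
    from importlib.resources import files

    return DiseaseConfig.from_dict(
        json.loads(files("adlwatch.data").joinpath("gastro.json").read_text())
    )


def daily_observation(
    instances,
    leaving_home_optional: bool = False,
) -> dict[str, dict[str, float]]:
    """Aggregate one day's instances into DSS observation totals.

    Duration is the summed daily duration per activity group (the
    three meals fold into "eating"); frequency is the daily count.
    Groups with no instance report 0/0 (e.g. a housebound day's
    leaving home) unless ``leaving_home_optional`` drops the group.
    """
    from .core import ActivityLabel, MEAL_LABELS

    group_of = {
        ActivityLabel.SLEEPING: "sleeping",
        ActivityLabel.TAKING_SHOWER: "taking_shower",
        ActivityLabel.LEAVING_HOME: "leaving_home",
        ActivityLabel.GOING_TO_TOILET: "going_to_toilet",
        **{lab: "eating" for lab in MEAL_LABELS},
    }
    obs: dict[str, dict[str, float]] = {
        g: {"duration": 0.0, "frequency": 0.0}
        for g in ("sleeping", "eating", "leaving_home", "going_to_toilet", "taking_shower")
    }
    for inst in instances:
        group = group_of[inst.label]
        obs[group]["duration"] += inst.duration
        obs[group]["frequency"] += 1
    if leaving_home_optional:
        obs.pop("leaving_home")
    return obs
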
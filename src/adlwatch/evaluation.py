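"""Day-level detection metrics: sensitivity and accuracy.

Days are the classification unit; "abnormal" is the positive class.
Sensitivity = Tp / (Tp + Fn) measures the fraction of truly abnormal
days that were caught; accuracy = (Tp + Tn) / N the fraction of all
days classified correctly.  False positives are tracked too, so both
metrics (and any re-reading of published confusion tables that omit
Fp) can be reproduced from the raw counts.

Values are computed at full precision; tables conventionally report
2 decimals, round-half-up (see :func:`adlwatch.scoring.round2`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(
    predicted: Sequence[bool] | Mapping[int, bool],
    truth: Sequence[bool] | Mapping[int, bool],
) -> ConfusionCounts:
    """Tally the 2x2 table over aligned days (True = abnormal)."""
    if isinstance(predicted, Mapping) != isinstance(truth, Mapping):
        raise ValueError("predicted and truth must both be sequences or both mappings")
    if isinstance(predicted, Mapping):
        if set(predicted) != set(truth):
            raise ValueError("predicted and truth cover different days")
        pairs = [(predicted[d], truth[d]) for d in sorted(predicted)]
    else:
        if len(predicted) != len(truth):
            raise ValueError("length mismatch")
        pairs = list(zip(predicted, truth))
    tp = sum(1 for p, t in pairs if p and t)
    tn = sum(1 for p, t in pairs if not p and not t)
    fp = sum(1 for p, t in pairs if p and not t)
    fn = sum(1 for p, t in pairs if not p and t)
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def sensitivity(c: ConfusionCounts) -> float:
    """Tp / (Tp + Fn); undefined without any truly abnormal day."""
    if c.tp + c.fn == 0:
        raise ValueError("sensitivity undefined: no positive days")
    return c.tp / (c.tp + c.fn)


def accuracy(c: ConfusionCounts) -> float:
    """(Tp + Tn) / N over all evaluated days."""
    if c.n == 0:
        raise ValueError("accuracy undefined: no days")
    return (c.tp + c.tn) / c.n
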
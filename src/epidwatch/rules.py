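"""Replan-trigger rules and their sensitivity/specificity evaluation.

A replan-trigger rule fires for a patient when at least
``min_exceeding_fractions`` of the course's GDSA means exceed a
threshold, optionally ignoring the last few fractions (a deviation that
only appears at the very end of a course cannot justify a replan).
Exceedance is signed by default (GDSA > threshold): anatomy loss raises
the transit signal, so positive deviations are the replan-relevant ones;
a magnitude mode is available for sensitivity studies.

Rule predictions are compared against binary replan labels (the
physician's decision as ground truth) in a standard 2x2 contingency
table.  Tabulated proportions are *truncated* (floored) to two decimals
by :func:`truncate`, the convention used for every reproduced value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .errors import IdentityError, UndefinedRateError, ValidationError
from .gdsa import GdsaRecord


@dataclass(frozen=True)
class RuleSpec:
    """One replan-trigger rule."""

    name: str
    threshold_percent: float
    min_exceeding_fractions: int = 1
    exclude_last_n_fractions: int = 0
    signed: bool = True

    def __post_init__(self) -> None:
        if self.threshold_percent <= 0:
            raise ValidationError("threshold must be positive")
        if self.min_exceeding_fractions < 1:
            raise ValidationError("min_exceeding_fractions must be >= 1")
        if self.exclude_last_n_fractions < 0:
            raise ValidationError("exclude_last_n_fractions must be >= 0")


#: The five standard rule variants:
#: A: one fraction > 3 %;  B: one fraction > 2 %;  C: two fractions > 2 %;
#: D: two fractions > 2 % excluding the last five;  E: one fraction > 2 %
#: excluding the last five.
STANDARD_RULES: tuple[RuleSpec, ...] = (
    RuleSpec("A", 3.0, 1, 0),
    RuleSpec("B", 2.0, 1, 0),
    RuleSpec("C", 2.0, 2, 0),
    RuleSpec("D", 2.0, 2, 5),
    RuleSpec("E", 2.0, 1, 5),
)


@dataclass(frozen=True)
class ContingencyTable:
    """TP/FN/FP/TN counts of rule predictions against replan labels."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValidationError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def _trace_values(trace: Sequence) -> list[float]:
    values = []
    for item in trace:
        if isinstance(item, GdsaRecord):
            if item.status != "complete":
                continue
            values.append(item.gdsa_percent)
        else:
            values.append(float(item))
    return values


def apply_rule(trace: Sequence, rule: RuleSpec) -> bool:
    """Decide whether a rule fires on one patient's GDSA trace.

    ``trace`` is a date-ordered sequence of complete-status
    :class:`~epidwatch.gdsa.GdsaRecord` (omitted records are dropped) or
    plain percent values.  The last ``exclude_last_n_fractions`` entries
    are removed before counting; a trace no longer than the exclusion
    window evaluates over an empty window and returns False.
    """
    values = _trace_values(trace)
    if rule.exclude_last_n_fractions:
        values = values[: max(len(values) - rule.exclude_last_n_fractions, 0)]
    if rule.signed:
        count = sum(v > rule.threshold_percent for v in values)
    else:
        count = sum(abs(v) > rule.threshold_percent for v in values)
    return count >= rule.min_exceeding_fractions


def contingency(
    predictions: Mapping[str, bool], labels: Mapping[str, bool]
) -> ContingencyTable:
    """Cross-tabulate per-patient rule predictions against replan labels."""
    if set(predictions) != set(labels):
        raise IdentityError(
            "prediction and label patient sets differ: "
            f"{sorted(set(predictions) ^ set(labels))}"
        )
    tp = fn = fp = tn = 0
    for pid, pred in predictions.items():
        if labels[pid]:
            tp, fn = tp + pred, fn + (not pred)
        else:
            fp, tn = fp + pred, tn + (not pred)
    return ContingencyTable(tp, fn, fp, tn)


def sensitivity(ct: ContingencyTable) -> float:
    """TP / (TP + FN)."""
    if ct.tp + ct.fn == 0:
        raise UndefinedRateError("no positive (replanned) patients")
    return ct.tp / (ct.tp + ct.fn)


def specificity(ct: ContingencyTable) -> float:
    """TN / (TN + FP)."""
    if ct.tn + ct.fp == 0:
        raise UndefinedRateError("no negative (non-replanned) patients")
    return ct.tn / (ct.tn + ct.fp)


def truncate(x: float, decimals: int = 2) -> float:
    """Floor to a fixed number of decimals - the tabulation convention.

    E.g. 105/133 = 0.789... tabulates as 0.78, not 0.79.
    """
    factor = 10**decimals
    return math.floor(x * factor) / factor


def evaluate_rules(
    traces: Mapping[str, Sequence],
    labels: Mapping[str, bool],
    rules: Sequence[RuleSpec] = STANDARD_RULES,
) -> pd.DataFrame:
    """Evaluate every rule against every patient trace.

    Returns one row per rule with the contingency counts and the
    two-decimal-truncated sensitivity and specificity; an undefined rate
    (zero denominator) is reported as NaN.
    """
    if not traces or not labels:
        raise ValidationError("traces and labels must be nonempty")
    rows = []
    for rule in rules:
        predictions = {pid: apply_rule(trace, rule) for pid, trace in traces.items()}
        ct = contingency(predictions, labels)
        try:
            sens = truncate(sensitivity(ct))
        except UndefinedRateError:
            sens = float("nan")
        try:
            spec = truncate(specificity(ct))
        except UndefinedRateError:
            spec = float("nan")
        rows.append(
            {
                "rule": rule.name,
                "tp": ct.tp,
                "fn": ct.fn,
                "fp": ct.fp,
                "tn": ct.tn,
                "sensitivity": sens,
                "specificity": spec,
            }
        )
    return pd.DataFrame(rows)
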
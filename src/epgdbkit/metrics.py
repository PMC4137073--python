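"""Pathway-recovery performance: confusion tables and summary metrics.

Predicted pathway sets are scored against a gold standard over an explicit
pathway *universe* (true negatives are meaningless without one, so the
universe is a required input — typically the full reference pathway
catalogue).  The suite covers sensitivity (recall), specificity, precision,
accuracy, F-measure and Matthews correlation coefficient.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

from .errors import DomainError

logger = logging.getLogger(__name__)

METRIC_NAMES = ("sensitivity", "specificity", "precision", "accuracy", "f_measure", "mcc")


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise DomainError("confusion counts must be non-negative")

    @property
    def universe_size(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_table(
    test: Iterable[str], gold: Iterable[str], universe: Iterable[str]
) -> ConfusionTable:
    """Label every pathway in the universe as TP/FP/FN/TN.

    TP: in both test and gold; FP: test only; FN: gold only; TN: neither.
    Test and gold must be contained in the universe.
    """
    test, gold, universe = frozenset(test), frozenset(gold), frozenset(universe)
    stray = (test | gold) - universe
    if stray:
        raise DomainError(f"pathways outside the universe: {sorted(stray)[:10]}")
    tp = len(test & gold)
    fp = len(test - gold)
    fn = len(gold - test)
    tn = len(universe) - tp - fp - fn
    return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: float, den: float) -> float | None:
    return num / den if den else None


def metric_suite(ct: ConfusionTable) -> dict[str, float | None]:
    """Standard binary-classification metrics from a confusion table.

    Ratios with a zero denominator are reported as ``None`` (undefined), with
    one exception: MCC with a zero marginal is reported as 0.0 per the common
    convention (the prediction carries no signal), with a logged note.
    """
    tp, fp, fn, tn = ct.tp, ct.fp, ct.fn, ct.tn
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    prec = _ratio(tp, tp + fp)
    acc = _ratio(tp + tn, ct.universe_size)
    if prec is None or sens is None or (prec + sens) == 0:
        f = None
    else:
        f = 2 * prec * sens / (prec + sens)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        logger.info("MCC marginal is zero; reporting 0.0 by convention")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "accuracy": acc,
        "f_measure": f,
        "mcc": mcc,
    }


def recovery_fraction(test: Iterable[str], gold: Iterable[str]) -> float:
    """Fraction of gold-standard pathways recovered by the prediction.

    Identical to sensitivity: |test ∩ gold| / |gold|.
    """
    test, gold = frozenset(test), frozenset(gold)
    if not gold:
        raise DomainError("gold-standard pathway set is empty")
    return len(test & gold) / len(gold)
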
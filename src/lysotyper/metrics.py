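"""Confusion matrices, performance scores, confidence stratification.

Conventions (all documented because they change the numbers):

* Confusion-matrix rows are the *true* class, columns the *predicted*
  class, both ordered (virulent, temperate).
* F1 takes **temperate as the positive class** — the choice that
  reproduces published scores of domain-based lifestyle classifiers from
  their confusion matrices.
* Balanced accuracy is *adjusted*: the mean of the per-class recalls is
  rescaled so random guessing scores 0 and a perfect model 1.
* MCC uses the standard 2x2 formula with the convention that a zero
  marginal yields 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .classifier import PredictionResult, classify_probability
from .feature_table import LABELS, TEMPERATE, VIRULENT

CLASS_ORDER = (VIRULENT, TEMPERATE)


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts; rows = true (virulent, temperate), cols = predicted."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (2, 2) or (counts < 0).any():
            raise ValueError("counts must be a 2x2 non-negative integer matrix")
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    @classmethod
    def from_counts(cls, vv: int, vt: int, tv: int, tt: int) -> "ConfusionMatrix":
        """Row-major order: (true virulent pred virulent, true virulent
        pred temperate, true temperate pred virulent, true temperate pred
        temperate)."""
        return cls(np.array([[vv, vt], [tv, tt]]))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=[f"true_{c}" for c in CLASS_ORDER],
            columns=[f"pred_{c}" for c in CLASS_ORDER],
        )

    def swap_classes(self) -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts[::-1, ::-1])


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    balanced_accuracy_adjusted: float
    mcc: float
    f1: float  # positive class = temperate
    n: int

    def rounded(self, ndigits: int = 3) -> "MetricsReport":
        """Values rounded for table reproduction at printing precision."""
        return MetricsReport(
            round(self.accuracy, ndigits),
            round(self.balanced_accuracy_adjusted, ndigits),
            round(self.mcc, ndigits),
            round(self.f1, ndigits),
            self.n,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": ["accuracy", "balanced_accuracy_adjusted", "mcc", "f1"],
                "value": [
                    self.accuracy,
                    self.balanced_accuracy_adjusted,
                    self.mcc,
                    self.f1,
                ],
            }
        )


def _check_labels(labels: Sequence[str]) -> None:
    bad = sorted(set(labels) - set(LABELS))
    if bad:
        raise ValueError(f"unknown label value(s) {bad}; expected {LABELS}")


def confusion(
    true_labels: Sequence[str], predicted_labels: Sequence[str]
) -> ConfusionMatrix:
    if len(true_labels) != len(predicted_labels):
        raise ValueError("true and predicted label lists differ in length")
    _check_labels(true_labels)
    _check_labels(predicted_labels)
    counts = np.zeros((2, 2), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        counts[CLASS_ORDER.index(t), CLASS_ORDER.index(p)] += 1
    return ConfusionMatrix(counts)


def score(matrix: ConfusionMatrix) -> MetricsReport:
    """All four reported scores from a 2x2 confusion matrix.

    With temperate as positive class: TP = true-temperate predicted
    temperate, TN = true-virulent predicted virulent, FP = true-virulent
    predicted temperate, FN = true-temperate predicted virulent.
    """
    if matrix.total == 0:
        raise ValueError("cannot score an empty confusion matrix")
    (tn, fp), (fn, tp) = matrix.counts
    n = matrix.total
    accuracy = (tp + tn) / n
    sensitivity = tp / (tp + fn) if (tp + fn) else 0.0  # temperate recall
    specificity = tn / (tn + fp) if (tn + fp) else 0.0  # virulent recall
    balanced_adjusted = ((sensitivity + specificity) / 2 - 0.5) / 0.5
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return MetricsReport(accuracy, balanced_adjusted, float(mcc), f1, n)


@dataclass(frozen=True)
class ConfidenceStrata:
    """Per-stratum tallies for confident vs non-confident predictions.

    Percentages are reported to 1 decimal place.
    """

    threshold: float
    confident_n: int
    confident_errors: int
    nonconfident_n: int
    nonconfident_errors: int

    @property
    def total(self) -> int:
        return self.confident_n + self.nonconfident_n

    @property
    def confident_fraction_pct(self) -> float:
        return round(100 * self.confident_n / self.total, 1) if self.total else 0.0

    @property
    def confident_pct_correct(self) -> float:
        if not self.confident_n:
            return float("nan")
        return round(100 * (1 - self.confident_errors / self.confident_n), 1)

    @property
    def nonconfident_pct_correct(self) -> float:
        if not self.nonconfident_n:
            return float("nan")
        return round(100 * (1 - self.nonconfident_errors / self.nonconfident_n), 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": ["confident", "not_confident"],
                "n": [self.confident_n, self.nonconfident_n],
                "errors": [self.confident_errors, self.nonconfident_errors],
                "pct_correct": [
                    self.confident_pct_correct,
                    self.nonconfident_pct_correct,
                ],
            }
        )


def confidence_strata(
    results: Sequence[PredictionResult],
    true_labels: Sequence[str],
    threshold: float = 0.95,
) -> ConfidenceStrata:
    """Split predictions at max-probability >= ``threshold`` (inclusive)
    and tally errors per stratum.  The stratum membership is recomputed
    from the probabilities so any threshold can be probed."""
    if len(results) != len(true_labels):
        raise ValueError("one true label per prediction result required")
    _check_labels(true_labels)
    conf_n = conf_err = non_n = non_err = 0
    for res, truth in zip(results, true_labels):
        call, confident = classify_probability(res.p_temperate, threshold)
        wrong = call != truth
        if confident:
            conf_n += 1
            conf_err += wrong
        else:
            non_n += 1
            non_err += wrong
    return ConfidenceStrata(threshold, conf_n, conf_err, non_n, non_err)
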
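"""Multi-label performance metrics.

Let Y and Y-hat be the l x d binary matrices of true and predicted label
indicators. The exact match ratio is the fraction of instances whose entire
predicted label set equals the true set. Per-label F combines precision and
recall for one label column:

    F_j = 2 * sum_i yhat_ij y_ij / (sum_i yhat_ij + sum_i y_ij)

The macro average is the unweighted mean of F_j over labels; the micro
average pools the counts across all labels first. Labels with no true and
no predicted positives have an undefined (0/0) F and are excluded from the
macro average so that labels absent from a small test fold do not distort
the score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

LabelMatrix = np.ndarray  # (l, d) binary


@dataclass
class MetricsReport:
    """The three headline multi-label metrics plus per-label detail."""

    exact_match_ratio: float
    macro_f: float
    micro_f: float
    per_label_f: dict[int, float | None]
    l: int
    d: int


def binarize(labelsets: Sequence[Iterable[int]], d: int) -> LabelMatrix:
    """Encode label sets as an l x d binary indicator matrix (labels 1..d)."""
    Y = np.zeros((len(labelsets), d), dtype=np.uint8)
    for i, labels in enumerate(labelsets):
        for j in labels:
            if not 1 <= j <= d:
                raise ValueError(f"label {j} out of range 1..{d}")
            Y[i, j - 1] = 1
    return Y


def _check_shapes(Y: LabelMatrix, Yhat: LabelMatrix) -> None:
    Y, Yhat = np.asarray(Y), np.asarray(Yhat)
    if Y.shape != Yhat.shape:
        raise ValueError(f"shape mismatch: {Y.shape} vs {Yhat.shape}")
    if Y.ndim != 2:
        raise ValueError("label matrices must be 2-dimensional")


def exact_match_ratio(Y: LabelMatrix, Yhat: LabelMatrix) -> float:
    """Fraction of rows where the predicted indicator row equals the true row."""
    _check_shapes(Y, Yhat)
    Y, Yhat = np.asarray(Y), np.asarray(Yhat)
    return float(np.mean(np.all(Y == Yhat, axis=1)))


def label_f_measure(Y: LabelMatrix, Yhat: LabelMatrix, j: int) -> float | None:
    """F-measure of label ``j`` (1-based); ``None`` in the 0/0 case."""
    _check_shapes(Y, Yhat)
    if not 1 <= j <= np.asarray(Y).shape[1]:
        raise ValueError(f"label {j} out of range")
    y = np.asarray(Y)[:, j - 1].astype(np.int64)
    yhat = np.asarray(Yhat)[:, j - 1].astype(np.int64)
    denom = int(yhat.sum() + y.sum())
    if denom == 0:
        return None
    return float(2 * int((yhat * y).sum()) / denom)


def macro_average_f(Y: LabelMatrix, Yhat: LabelMatrix) -> float:
    """Unweighted mean of per-label F over labels with a defined F."""
    _check_shapes(Y, Yhat)
    d = np.asarray(Y).shape[1]
    values = [f for j in range(1, d + 1) if (f := label_f_measure(Y, Yhat, j)) is not None]
    if not values:
        raise ValueError("macro-average F undefined: every label is a 0/0 case")
    return float(np.mean(values))


def micro_average_f(Y: LabelMatrix, Yhat: LabelMatrix) -> float:
    """F computed from counts pooled across all labels and instances."""
    _check_shapes(Y, Yhat)
    y = np.asarray(Y).astype(np.int64)
    yhat = np.asarray(Yhat).astype(np.int64)
    denom = int(yhat.sum() + y.sum())
    if denom == 0:
        raise ValueError("micro-average F undefined: no positives in truth or prediction")
    return float(2 * int((yhat * y).sum()) / denom)


def compute_report(
    true_sets: Sequence[Iterable[int]],
    pred_sets: Sequence[Iterable[int]],
    d: int,
) -> MetricsReport:
    """All metrics for paired true/predicted label sets over ``1..d``."""
    if len(true_sets) != len(pred_sets):
        raise ValueError("true and predicted collections differ in length")
    Y = binarize(true_sets, d)
    Yhat = binarize(pred_sets, d)
    return MetricsReport(
        exact_match_ratio=exact_match_ratio(Y, Yhat),
        macro_f=macro_average_f(Y, Yhat),
        micro_f=micro_average_f(Y, Yhat),
        per_label_f={j: label_f_measure(Y, Yhat, j) for j in range(1, d + 1)},
        l=Y.shape[0],
        d=d,
    )
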
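"""Operating-point selection and screening metrics.

Sensitivity/specificity at a threshold, ROC-AUC, Youden's index,
expected calibration error (ECE), and the two threshold-selection rules
used in screening deployments: the balanced operating point (sensitivity
equals specificity) and a predefined target specificity.

The decision rule is: predict positive iff score >= threshold.  Candidate
thresholds for the selection rules are the midpoints between adjacent
distinct scores plus the endpoints 0 and 1, which makes the search finite,
exact and reproducible; ties are broken toward the smallest threshold.
All metrics are computed image-wise (one record = one observation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "OperatingPoint",
    "MetricsReport",
    "sen_spc",
    "roc_auc",
    "select_threshold_balanced",
    "select_threshold_at_specificity",
    "youden_index",
    "expected_calibration_error",
    "compute_report",
    "SingleClassError",
]

DEFAULT_ECE_BINS = 10


class SingleClassError(ValueError):
    """Labels contain only one class where both are required."""


def _validate_scored(scores, labels) -> Tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=np.float64).ravel()
    y = np.asarray(labels).ravel()
    if s.size == 0:
        raise ValueError("empty score vector")
    if s.size != y.size:
        raise ValueError("scores and labels differ in length")
    y = y.astype(np.int64)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary {0, 1}")
    return s, y


def _require_both_classes(y: np.ndarray) -> None:
    if not (y == 1).any():
        raise SingleClassError("no positive labels present")
    if not (y == 0).any():
        raise SingleClassError("no negative labels present")


@dataclass(frozen=True)
class OperatingPoint:
    """A calibrated decision threshold plus the rule that produced it."""

    threshold: float
    rule: str  # "balanced" | "target_specificity" | "manual"
    target_value: Optional[float] = None
    achieved_gap: Optional[float] = None  # |SEN - SPC| at selection time
    warning: bool = False  # degenerate-threshold path
    provenance: str = ""

    def __post_init__(self):
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")


@dataclass(frozen=True)
class MetricsReport:
    """Point metrics at a threshold; youden == sensitivity + specificity - 1."""

    sensitivity: float
    specificity: float
    auc: float
    youden: float
    n_pos: int
    n_neg: int
    ece: Optional[float] = None

    def to_dict(self) -> dict:
        d = {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "youden": self.youden,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }
        if self.ece is not None:
            d["ece"] = self.ece
        return d


def _sen_spc_at(
    pos_sorted: np.ndarray, neg_sorted: np.ndarray, thresholds: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorised SEN/SPC over thresholds (positive iff score >= t)."""
    sen = (pos_sorted.size - np.searchsorted(pos_sorted, thresholds, side="left")) / pos_sorted.size
    spc = np.searchsorted(neg_sorted, thresholds, side="left") / neg_sorted.size
    return sen, spc


def sen_spc(scores, labels, threshold: float) -> Tuple[float, float]:
    """Sensitivity TP/(TP+FN) and specificity TN/(TN+FP) at a threshold."""
    s, y = _validate_scored(scores, labels)
    _require_both_classes(y)
    pos = np.sort(s[y == 1])
    neg = np.sort(s[y == 0])
    sen, spc = _sen_spc_at(pos, neg, np.asarray([threshold], dtype=np.float64))
    return float(sen[0]), float(spc[0])


def roc_auc(scores, labels) -> float:
    """Image-wise ROC-AUC (Mann-Whitney concordance, ties counted 1/2)."""
    s, y = _validate_scored(scores, labels)
    _require_both_classes(y)
    return float(roc_auc_score(y, s))


def _candidate_thresholds(s: np.ndarray) -> np.ndarray:
    u = np.unique(s)
    mids = (u[:-1] + u[1:]) / 2.0
    return np.unique(np.concatenate(([0.0], mids, [1.0])))


def select_threshold_balanced(scores, labels) -> OperatingPoint:
    """Threshold minimising |SEN - SPC| over all candidate thresholds.

    Ties are broken toward the smallest threshold; the achieved gap is
    recorded on the returned operating point.
    """
    s, y = _validate_scored(scores, labels)
    _require_both_classes(y)
    cand = _candidate_thresholds(s)
    pos, neg = np.sort(s[y == 1]), np.sort(s[y == 0])
    sen, spc = _sen_spc_at(pos, neg, cand)
    gaps = np.abs(sen - spc)
    i = int(np.argmin(gaps))  # first minimiser = smallest threshold
    return OperatingPoint(
        threshold=float(cand[i]),
        rule="balanced",
        achieved_gap=float(gaps[i]),
        provenance=f"balanced operating point on n={s.size} labelled scores",
    )


def select_threshold_at_specificity(scores, labels, target_spc: float) -> OperatingPoint:
    """Smallest candidate threshold attaining SPC >= ``target_spc``.

    If no non-degenerate threshold reaches the target, the degenerate
    threshold 1 is returned with ``warning=True``.
    """
    if not 0.0 < target_spc < 1.0:
        raise ValueError("target_spc must lie in (0, 1)")
    s, y = _validate_scored(scores, labels)
    _require_both_classes(y)
    cand = _candidate_thresholds(s)
    pos, neg = np.sort(s[y == 1]), np.sort(s[y == 0])
    sen, spc = _sen_spc_at(pos, neg, cand)
    ok = np.flatnonzero(spc >= target_spc)
    if ok.size == 0:
        threshold, warning = 1.0, True
    else:
        threshold = float(cand[ok[0]])
        warning = threshold == 1.0
    i = int(np.searchsorted(cand, threshold))
    return OperatingPoint(
        threshold=threshold,
        rule="target_specificity",
        target_value=float(target_spc),
        achieved_gap=float(abs(sen[i] - spc[i])),
        warning=warning,
        provenance=f"target specificity {target_spc} on n={s.size} labelled scores",
    )


def youden_index(scores, labels, threshold: float) -> float:
    """Youden's J = sensitivity + specificity - 1 at a threshold."""
    sen, spc = sen_spc(scores, labels, threshold)
    return sen + spc - 1.0


def expected_calibration_error(scores, labels, n_bins: int = DEFAULT_ECE_BINS) -> float:
    """ECE over equal-width bins of [0, 1].

    ``ECE = sum_b (n_b / N) * |mean(score in b) - mean(label in b)|`` with
    empty bins contributing 0; the last bin is closed at 1.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    s, y = _validate_scored(scores, labels)
    idx = np.minimum((s * n_bins).astype(np.int64), n_bins - 1)
    ece = 0.0
    for b in range(n_bins):
        mask = idx == b
        nb = int(mask.sum())
        if nb == 0:
            continue
        ece += (nb / s.size) * abs(float(s[mask].mean()) - float(y[mask].mean()))
    return ece


def compute_report(
    scores, labels, threshold: float, n_bins: int = DEFAULT_ECE_BINS
) -> MetricsReport:
    """Full metrics report at a threshold (SEN, SPC, AUC, Youden, ECE)."""
    s, y = _validate_scored(scores, labels)
    sen, spc = sen_spc(s, y, threshold)
    return MetricsReport(
        sensitivity=sen,
        specificity=spc,
        auc=roc_auc(s, y),
        youden=sen + spc - 1.0,
        n_pos=int((y == 1).sum()),
        n_neg=int((y == 0).sum()),
        ece=expected_calibration_error(s, y, n_bins),
    )
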
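"""Unsupervised prediction alignment: piecewise-linear CDF matching.

The transform maps scores from a shifted acquisition domain back onto a
reference score distribution without using any labels.  Fitting proceeds in
two steps: (1) compute the empirical cumulative distribution of the
alignment-set scores; (2) for each distinct alignment score, look up the
reference empirical quantile at the same cumulative level and connect the
resulting knots by straight lines.  Applying the fitted map to new scores
from the shifted domain is then plain piecewise-linear interpolation.

Because the map is monotone non-decreasing it never changes the relative
order of predictions, so ranking metrics such as ROC-AUC are conserved
exactly (up to ties created by flat segments or boundary clipping).

Conventions (the published description leaves them open; fixed here so that
self-alignment is exactly the identity on shared knots):

* ECDF: right-continuous, ``F(x) = #{scores <= x} / n``.
* Quantile: linear interpolation between order statistics, with the i-th of
  n sorted values assigned level ``i / n``; levels below ``1/n`` return the
  minimum.
* Extrapolation: outside the outermost knots the map continues linearly
  along the outermost segment and is clipped to [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.stats import ks_2samp

__all__ = [
    "AlignmentTransform",
    "ShiftReport",
    "empirical_cdf",
    "fit_alignment",
    "apply_alignment",
    "detect_shift",
    "DomainError",
    "FitError",
]

DEFAULT_MIN_FIT_SIZE = 2
DEFAULT_SHIFT_FLAG_THRESHOLD = 0.1


class DomainError(ValueError):
    """Scores outside [0, 1] or otherwise invalid for the transform."""


class FitError(ValueError):
    """Too little (or degenerate) data to fit an alignment transform."""


def _as_scores(x, name: str, allow_empty: bool = False) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64).ravel()
    if arr.size == 0:
        if allow_empty:
            return arr
        raise DomainError(f"{name}: empty score vector")
    if not np.isfinite(arr).all():
        raise DomainError(f"{name}: non-finite score")
    if (arr < 0).any() or (arr > 1).any():
        raise DomainError(f"{name}: scores must lie in [0, 1]")
    return arr


def empirical_cdf(scores) -> Callable[[np.ndarray], np.ndarray]:
    """Return the right-continuous empirical CDF of ``scores``.

    The returned function accepts scalars or arrays and evaluates
    ``#{scores <= x} / n``: 0 below the minimum, 1 at and above the maximum.
    """
    s = np.sort(_as_scores(scores, "scores"))
    n = s.size

    def cdf(x):
        xv = np.asarray(x, dtype=np.float64)
        out = np.searchsorted(s, xv, side="right") / n
        return float(out) if np.isscalar(x) else out

    return cdf


def _reference_quantile(sorted_ref: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Quantiles of a sorted sample at levels ``q`` (order statistic i -> i/n)."""
    m = sorted_ref.size
    levels = np.arange(1, m + 1) / m
    return np.interp(q, levels, sorted_ref)


@dataclass(frozen=True)
class AlignmentTransform:
    """A fitted monotone piecewise-linear map from shifted to reference scores."""

    source_knots: np.ndarray
    target_knots: np.ndarray
    fit_size: int
    reference_size: int

    def __post_init__(self):
        src = np.asarray(self.source_knots, dtype=np.float64)
        tgt = np.asarray(self.target_knots, dtype=np.float64)
        object.__setattr__(self, "source_knots", src)
        object.__setattr__(self, "target_knots", tgt)
        if src.size != tgt.size or src.size < 2:
            raise FitError("knot vectors must have equal length >= 2")
        if not (np.diff(src) > 0).all():
            raise FitError("source knots must be strictly increasing")
        if (np.diff(tgt) < 0).any():
            raise FitError("target knots must be non-decreasing")
        for name, arr in (("source", src), ("target", tgt)):
            if (arr < 0).any() or (arr > 1).any():
                raise DomainError(f"{name} knots must lie in [0, 1]")

    @classmethod
    def identity(cls) -> "AlignmentTransform":
        return cls(np.array([0.0, 1.0]), np.array([0.0, 1.0]), 0, 0)

    def __call__(self, scores) -> np.ndarray:
        x = _as_scores(scores, "scores", allow_empty=True)
        s, t = self.source_knots, self.target_knots
        y = np.interp(x, s, t)
        lo = x < s[0]
        if lo.any():
            slope = (t[1] - t[0]) / (s[1] - s[0])
            y[lo] = t[0] + slope * (x[lo] - s[0])
        hi = x > s[-1]
        if hi.any():
            slope = (t[-1] - t[-2]) / (s[-1] - s[-2])
            y[hi] = t[-1] + slope * (x[hi] - s[-1])
        return np.clip(y, 0.0, 1.0)

    # -- serialisation (for shipping/auditing a fitted transform) -----------

    def to_dict(self) -> dict:
        return {
            "source_knots": self.source_knots.tolist(),
            "target_knots": self.target_knots.tolist(),
            "fit_size": int(self.fit_size),
            "reference_size": int(self.reference_size),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "AlignmentTransform":
        return cls(
            np.asarray(d["source_knots"], dtype=np.float64),
            np.asarray(d["target_knots"], dtype=np.float64),
            int(d["fit_size"]),
            int(d["reference_size"]),
        )

    @classmethod
    def from_json(cls, s: str) -> "AlignmentTransform":
        return cls.from_dict(json.loads(s))


def fit_alignment(
    reference, alignment, min_fit_size: int = DEFAULT_MIN_FIT_SIZE
) -> AlignmentTransform:
    """Fit the piecewise-linear CDF-matching transform.

    ``reference`` are scores from the known domain (the matching target);
    ``alignment`` are unlabelled scores from the shifted domain.  For each
    distinct alignment score ``a`` with ECDF level ``q = #{alignment <= a}/n``
    the transform maps ``a`` to the reference quantile at level ``q``; tied
    alignment scores therefore share one knot placed at the upper tie
    boundary's level.
    """
    ref = _as_scores(reference, "reference")
    ali = _as_scores(alignment, "alignment")
    if ali.size < max(min_fit_size, 2):
        raise FitError(
            f"alignment set has {ali.size} scores; need at least {max(min_fit_size, 2)}"
        )
    src, counts = np.unique(ali, return_counts=True)
    if src.size < 2:
        raise FitError("alignment set has fewer than 2 distinct scores")
    q = np.cumsum(counts) / ali.size
    tgt = _reference_quantile(np.sort(ref), q)
    return AlignmentTransform(src, tgt, fit_size=int(ali.size), reference_size=int(ref.size))


def apply_alignment(transform: AlignmentTransform, scores) -> np.ndarray:
    """Map ``scores`` through a fitted transform (order and length preserved)."""
    return transform(scores)


@dataclass(frozen=True)
class ShiftReport:
    """Two-sample KS distance between reference and window score distributions."""

    statistic: float
    flagged: bool
    threshold: float = DEFAULT_SHIFT_FLAG_THRESHOLD


def detect_shift(
    reference, window, threshold: float = DEFAULT_SHIFT_FLAG_THRESHOLD
) -> ShiftReport:
    """Flag a distribution shift via the two-sample Kolmogorov-Smirnov distance.

    The statistic is ``sup_x |ECDF_ref(x) - ECDF_window(x)|``; the window is
    flagged when it exceeds ``threshold``.
    """
    ref = _as_scores(reference, "reference")
    win = _as_scores(window, "window")
    stat = float(ks_2samp(ref, win, method="asymp").statistic)
    return ShiftReport(statistic=stat, flagged=stat > threshold, threshold=threshold)
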
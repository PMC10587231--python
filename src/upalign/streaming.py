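"""Time-stepped continuous recalibration with per-device running windows.

The engine freezes a balanced operating point on a labelled reference set
at initialisation and never refits it; only the predictions are moved.
Each week, every device's alignment transform is refitted — label-free —
from that device's own running window (the previous ``window_length``
weeks; default two), then applied to the new week's scores, and the
sensitivity/specificity balance is evaluated before and after alignment at
the frozen threshold, per device and pooled.  Devices are fully isolated:
one device's stream never influences another's transform.  The evaluation
week is never part of the fitting window, and a device whose window holds
fewer than ``min_fit_size`` scores runs on raw predictions (cold start).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .align import AlignmentTransform, FitError, fit_alignment
from .metrics import OperatingPoint, select_threshold_balanced
from .records import RecordSet
from .synth import ScenarioSchedule, simulate_week

__all__ = [
    "EngineState",
    "StepReport",
    "RunReport",
    "initialise",
    "step",
    "run",
    "ConfigurationError",
    "SequencingError",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_LENGTH = 2
DEFAULT_STREAM_MIN_FIT = 50


class ConfigurationError(ValueError):
    """Invalid engine configuration (window length, reference set)."""


class SequencingError(ValueError):
    """Weeks fed to the engine out of order or mixed within one step."""


@dataclass
class EngineState:
    """Mutable state of the streaming recalibrator.

    ``reference_scores`` and ``operating_point`` are frozen at
    initialisation.  Buffers hold ``(week, scores, image_ids)`` per device;
    only scores are ever used for fitting (labels never enter the buffers).
    """

    reference_scores: np.ndarray
    operating_point: OperatingPoint
    window_length: int
    min_fit_size: int
    buffers: Dict[str, List[Tuple[int, np.ndarray, np.ndarray]]] = field(
        default_factory=dict
    )
    transforms: Dict[str, Optional[AlignmentTransform]] = field(default_factory=dict)
    last_time: int = -1

    def buffer_scores(self, device_id: str) -> np.ndarray:
        entries = self.buffers.get(device_id, [])
        if not entries:
            return np.empty(0)
        return np.concatenate([s for (_, s, _) in entries])

    def buffer_image_ids(self, device_id: str) -> np.ndarray:
        entries = self.buffers.get(device_id, [])
        if not entries:
            return np.empty(0, dtype=object)
        return np.concatenate([ids for (_, _, ids) in entries])


def _threshold_metrics(scores: np.ndarray, labels: np.ndarray, thr: float) -> dict:
    """SEN/SPC/Youden at a threshold, NaN-tolerant for absent classes."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    sen = float((pos >= thr).mean()) if pos.size else math.nan
    spc = float((neg < thr).mean()) if neg.size else math.nan
    return {
        "sensitivity": sen,
        "specificity": spc,
        "youden": sen + spc - 1.0,
        "sen_minus_spc": sen - spc,
        "n_pos": int(pos.size),
        "n_neg": int(neg.size),
    }


@dataclass
class StepReport:
    """Before/after metrics for one week, per device and pooled."""

    time_index: int
    per_device: Dict[str, Dict[str, dict]]  # device -> {"before": m, "after": m}
    overall: Dict[str, dict]  # {"before": m, "after": m}
    cold_start: List[str]


def initialise(
    reference: RecordSet,
    window_length: int = DEFAULT_WINDOW_LENGTH,
    min_fit_size: int = DEFAULT_STREAM_MIN_FIT,
) -> EngineState:
    """Freeze the operating point on the labelled reference and start empty.

    The balanced threshold is selected on the reference scores; all devices
    begin with empty buffers and identity transforms.
    """
    if window_length < 1:
        raise ConfigurationError("window_length must be >= 1 week")
    if not reference.has_labels:
        raise ConfigurationError("reference set must be fully labelled")
    op = select_threshold_balanced(reference.scores, reference.labels)
    return EngineState(
        reference_scores=reference.scores.copy(),
        operating_point=op,
        window_length=int(window_length),
        min_fit_size=int(min_fit_size),
    )


def step(state: EngineState, week_records: RecordSet) -> StepReport:
    """Advance the engine by one week (state is updated in place).

    Per device: refit the transform from the running window (or fall back
    to raw scores on cold start), align the week's scores, evaluate at the
    frozen threshold before and after, then push the week into the buffer
    and evict weeks older than the window.
    """
    if len(week_records) == 0:
        raise SequencingError("empty week")
    times = week_records.frame["time_index"].unique()
    if len(times) != 1:
        raise SequencingError(f"one step must hold a single week, got {sorted(times)}")
    t = int(times[0])
    if t <= state.last_time:
        raise SequencingError(f"week {t} is not after the last seen week {state.last_time}")
    thr = state.operating_point.threshold

    # evict anything outside [t - window_length, t - 1] before fitting
    for dev in list(state.buffers):
        state.buffers[dev] = [
            e for e in state.buffers[dev] if e[0] >= t - state.window_length
        ]

    per_device: Dict[str, Dict[str, dict]] = {}
    cold: List[str] = []
    raw_all, aligned_all, labels_all = [], [], []
    devices = sorted(week_records.frame["device_id"].unique())
    for dev in devices:
        sub = week_records.for_device(dev)
        raw = sub.scores
        labels = sub.frame["label"].to_numpy()
        buf = state.buffer_scores(dev)
        transform: Optional[AlignmentTransform] = None
        if buf.size >= state.min_fit_size:
            try:
                transform = fit_alignment(state.reference_scores, buf)
            except FitError:
                transform = None
        if transform is None:
            cold.append(dev)
            logger.info("cold start: device %s at week %d uses raw predictions", dev, t)
            aligned = raw.copy()
        else:
            aligned = transform(raw)
        state.transforms[dev] = transform
        per_device[dev] = {
            "before": _threshold_metrics(raw, labels, thr),
            "after": _threshold_metrics(aligned, labels, thr),
        }
        raw_all.append(raw)
        aligned_all.append(aligned)
        labels_all.append(labels)
        image_ids = sub.frame["image_id"].to_numpy()
        state.buffers.setdefault(dev, []).append((t, raw.copy(), image_ids))
        # keep exactly the weeks the next step may fit from
        state.buffers[dev] = [
            e for e in state.buffers[dev] if e[0] >= t + 1 - state.window_length
        ]

    raw_cat = np.concatenate(raw_all)
    lab_cat = np.concatenate(labels_all)
    overall = {
        "before": _threshold_metrics(raw_cat, lab_cat, thr),
        "after": _threshold_metrics(np.concatenate(aligned_all), lab_cat, thr),
    }
    state.last_time = t
    return StepReport(time_index=t, per_device=per_device, overall=overall, cold_start=cold)


# ---------------------------------------------------------------------------
# Repeated scenario runs
# ---------------------------------------------------------------------------


@dataclass
class RunReport:
    """Across-repetition summary of SEN - SPC per week, with/without UPA.

    ``series[key]`` for key in ``{"overall"} | devices`` holds, for each of
    ``"before"`` and ``"after"``, arrays of shape (horizon,) with the mean
    and the 5th/95th percentiles over repetitions (NaN where a device was
    absent or a class was missing in every repetition).
    """

    weeks: np.ndarray
    series: Dict[str, Dict[str, Dict[str, np.ndarray]]]
    n_reps: int

    def to_dict(self) -> dict:
        def arr(a):
            return [None if (isinstance(v, float) and math.isnan(v)) else v for v in a.tolist()]

        return {
            "weeks": self.weeks.tolist(),
            "n_reps": self.n_reps,
            "series": {
                key: {
                    phase: {stat: arr(a) for stat, a in stats.items()}
                    for phase, stats in phases.items()
                }
                for key, phases in self.series.items()
            },
        }


def run(
    schedule: ScenarioSchedule,
    reference: RecordSet,
    n_reps: int = 50,
    seed: int = 0,
    window_length: int = DEFAULT_WINDOW_LENGTH,
    min_fit_size: int = DEFAULT_STREAM_MIN_FIT,
) -> RunReport:
    """Repeat a scenario ``n_reps`` times and summarise SEN - SPC per week.

    Each repetition draws fresh weekly data from the schedule with its own
    child generator (deterministic under ``seed``), runs the streaming
    engine over the horizon, and records the pooled and per-device
    sensitivity-specificity gap before and after alignment.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    keys = ["overall"] + schedule.devices
    gaps = {
        key: {phase: np.full((n_reps, schedule.horizon), np.nan) for phase in ("before", "after")}
        for key in keys
    }
    children = np.random.SeedSequence(seed).spawn(n_reps)
    for r in range(n_reps):
        rng = np.random.default_rng(children[r])
        state = initialise(reference, window_length=window_length, min_fit_size=min_fit_size)
        for week in range(schedule.horizon):
            data = simulate_week(schedule, week, rng)
            if len(data) == 0:
                continue
            report = step(state, data)
            for phase in ("before", "after"):
                gaps["overall"][phase][r, week] = report.overall[phase]["sen_minus_spc"]
                for dev in schedule.devices:
                    if dev in report.per_device:
                        gaps[dev][phase][r, week] = report.per_device[dev][phase][
                            "sen_minus_spc"
                        ]
    series = {}
    for key in keys:
        series[key] = {}
        for phase in ("before", "after"):
            g = gaps[key][phase]
            with warnings.catch_warnings():
                # all-NaN weeks (device absent) legitimately summarise to NaN
                warnings.simplefilter("ignore", RuntimeWarning)
                series[key][phase] = {
                    "mean": np.nanmean(g, axis=0),
                    "p5": np.nanpercentile(g, 5, axis=0),
                    "p95": np.nanpercentile(g, 95, axis=0),
                }
    return RunReport(weeks=np.arange(schedule.horizon), series=series, n_reps=n_reps)
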
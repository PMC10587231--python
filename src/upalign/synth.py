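"""Synthetic prediction-score generator and acquisition-shift scenarios.

The generator emulates the statistical regime the alignment method assumes:
a classifier whose scores separate classes well (stable ROC-AUC) but whose
score *distribution* moves under acquisition shift (new scanner, software
update), so that a pre-calibrated threshold no longer realises the intended
sensitivity/specificity trade-off.

Score model (binormal on the logit scale): each case draws its class from
Bernoulli(prevalence); every image of the case shares that label; each
image draws an independent latent ``z ~ Normal(mu_class, sigma)`` and the
raw score is ``logistic(z)``.  Acquisition shift is a strictly increasing
warp of the score, so the latent-space ROC-AUC,
``Phi((mu_pos - mu_neg) / (sigma * sqrt(2)))``, is untouched by any shift
— exactly the regime the method targets.  The binormal choice gives this
closed form for oracle checks.

Presets mirror two screening regimes: mammography (prevalence 0.02, four
images per case, 250 cases per week) and histopathology patches
(prevalence 0.5, one image per case).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
from scipy.special import expit, logit
from scipy.stats import norm

from .records import RecordSet
import pandas as pd

__all__ = [
    "Warp",
    "identity_warp",
    "affine_latent_warp",
    "power_score_warp",
    "sharpness_update_warp",
    "compose_warps",
    "DomainModel",
    "ScenarioSchedule",
    "generate_records",
    "make_schedule",
    "simulate_week",
    "schedule_from_config",
    "REFERENCE_MODEL",
    "SCANNER_B_MODEL",
    "DEFAULT_UPDATE_STRENGTH",
    "mammography_preset",
    "histopathology_preset",
]


# ---------------------------------------------------------------------------
# Monotone score warps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Warp:
    """A strictly increasing map of [0, 1] onto [0, 1].

    Families:

    * ``identity``
    * ``affine_latent`` (scale, shift): ``s -> logistic(scale * logit(s) + shift)``
    * ``power_score`` (gamma): ``s -> s ** gamma``
    * ``sharpen`` (gamma): symmetric power around 0.5 pushing scores toward
      the extremes, ``0.5 * (2s)^gamma`` below 0.5 and its mirror above
    * ``compose`` (outer, inner): ``s -> outer(inner(s))``
    """

    family: str
    params: tuple = ()

    def __call__(self, s):
        x = np.asarray(s, dtype=np.float64)
        if self.family == "identity":
            out = x.copy()
        elif self.family == "affine_latent":
            a, b = self.params
            with np.errstate(divide="ignore"):
                out = expit(a * logit(x) + b)
            out = np.where(x <= 0.0, 0.0, np.where(x >= 1.0, 1.0, out))
        elif self.family == "power_score":
            (g,) = self.params
            out = x**g
        elif self.family == "sharpen":
            (g,) = self.params
            lo = 0.5 * (2.0 * x) ** g
            hi = 1.0 - 0.5 * (2.0 * (1.0 - x)) ** g
            out = np.where(x <= 0.5, lo, hi)
        elif self.family == "compose":
            outer, inner = self.params
            out = outer(inner(x))
        else:
            raise ValueError(f"unknown warp family {self.family!r}")
        return float(out) if np.isscalar(s) else out

    def inverse(self, s):
        x = np.asarray(s, dtype=np.float64)
        if self.family == "identity":
            out = x.copy()
        elif self.family == "affine_latent":
            a, b = self.params
            with np.errstate(divide="ignore"):
                out = expit((logit(x) - b) / a)
            out = np.where(x <= 0.0, 0.0, np.where(x >= 1.0, 1.0, out))
        elif self.family == "power_score":
            (g,) = self.params
            out = x ** (1.0 / g)
        elif self.family == "sharpen":
            (g,) = self.params
            lo = 0.5 * (2.0 * x) ** (1.0 / g)
            hi = 1.0 - 0.5 * (2.0 * (1.0 - x)) ** (1.0 / g)
            out = np.where(x <= 0.5, lo, hi)
        elif self.family == "compose":
            outer, inner = self.params
            out = inner.inverse(outer.inverse(x))
        else:
            raise ValueError(f"unknown warp family {self.family!r}")
        return float(out) if np.isscalar(s) else out

    def to_dict(self) -> dict:
        if self.family == "compose":
            outer, inner = self.params
            return {
                "family": "compose",
                "outer": outer.to_dict(),
                "inner": inner.to_dict(),
            }
        return {"family": self.family, "params": list(self.params)}

    @classmethod
    def from_dict(cls, d: dict) -> "Warp":
        if d["family"] == "compose":
            return cls(
                "compose",
                (cls.from_dict(d["outer"]), cls.from_dict(d["inner"])),
            )
        return cls(d["family"], tuple(d.get("params", ())))


def identity_warp() -> Warp:
    return Warp("identity")


def affine_latent_warp(scale: float, shift: float) -> Warp:
    if scale <= 0:
        raise ValueError("affine_latent scale must be > 0")
    return Warp("affine_latent", (float(scale), float(shift)))


def power_score_warp(gamma: float) -> Warp:
    if gamma <= 0:
        raise ValueError("power_score gamma must be > 0")
    return Warp("power_score", (float(gamma),))


def sharpness_update_warp(strength: float) -> Warp:
    """Warp emulating a processing-software update that sharpens images.

    Scores are pushed toward 0 and 1 by a symmetric power warp with
    exponent ``1 + strength``; strength 0 is the identity and 0, 0.5, 1 are
    fixed points, so class separability (AUC) is untouched.
    """
    if strength < 0:
        raise ValueError("strength must be >= 0")
    return Warp("sharpen", (1.0 + float(strength),))


def compose_warps(outer: Warp, inner: Warp) -> Warp:
    return Warp("compose", (outer, inner))


# ---------------------------------------------------------------------------
# Domain model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DomainModel:
    """Class-conditional score model for one acquisition domain."""

    mu_neg: float = 0.0
    mu_pos: float = 2.0
    sigma: float = 1.0
    warp: Warp = field(default_factory=identity_warp)

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.mu_pos <= self.mu_neg:
            raise ValueError("mu_pos must exceed mu_neg")

    def latent_auc(self) -> float:
        """Closed-form ROC-AUC, invariant under any strictly increasing warp."""
        return float(norm.cdf((self.mu_pos - self.mu_neg) / (self.sigma * np.sqrt(2.0))))

    def with_warp(self, warp: Warp) -> "DomainModel":
        return replace(self, warp=warp)

    def to_dict(self) -> dict:
        return {
            "mu_neg": self.mu_neg,
            "mu_pos": self.mu_pos,
            "sigma": self.sigma,
            "warp": self.warp.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DomainModel":
        return cls(
            mu_neg=float(d.get("mu_neg", 0.0)),
            mu_pos=float(d.get("mu_pos", 2.0)),
            sigma=float(d.get("sigma", 1.0)),
            warp=Warp.from_dict(d.get("warp", {"family": "identity"})),
        )


#: In-distribution scanner: AUC = Phi(sqrt(2)) ~ 0.921, no warp.
REFERENCE_MODEL = DomainModel()

#: Strong monotone acquisition shift (scanner-B-like): latent affine warp
#: z -> 0.9 z - 1.0.  At the reference balanced threshold this collapses
#: sensitivity while specificity saturates (|SEN - SPC| well above 0.2)
#: although the AUC is unchanged.
SCANNER_B_MODEL = DomainModel(warp=affine_latent_warp(0.9, -1.0))

#: Default strength of the sharpness-update warp (exponent 3 around 0.5).
DEFAULT_UPDATE_STRENGTH = 2.0


def mammography_preset() -> dict:
    """Screening mammography regime: rare positives, four views per case."""
    return {"prevalence": 0.02, "images_per_case": 4, "cases_per_week": 250}


def histopathology_preset() -> dict:
    """Balanced patch-classification regime: one image per case."""
    return {"prevalence": 0.5, "images_per_case": 1, "cases_per_week": 250}


# ---------------------------------------------------------------------------
# Record generation
# ---------------------------------------------------------------------------


def generate_records(
    model: DomainModel,
    n_cases: int,
    prevalence: float,
    images_per_case: int = 1,
    device_id: str = "device",
    time_index: int = 0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> RecordSet:
    """Draw a seeded record set from one domain model.

    The class is drawn once per case; every image of the case carries that
    label with an independent latent draw.  Identical seeds give identical
    record sets.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must lie in [0, 1]")
    if images_per_case < 1:
        raise ValueError("images_per_case must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    case_label = (rng.random(n_cases) < prevalence).astype(np.int64)
    mu = np.where(case_label == 1, model.mu_pos, model.mu_neg)
    n_images = n_cases * images_per_case
    z = rng.normal(loc=np.repeat(mu, images_per_case), scale=model.sigma)
    score = model.warp(expit(z))
    case_ids = np.repeat(
        [f"{device_id}-t{time_index}-c{i:06d}" for i in range(n_cases)],
        images_per_case,
    )
    image_suffix = np.tile([f"-i{j}" for j in range(images_per_case)], n_cases)
    df = pd.DataFrame(
        {
            "score": score,
            "label": np.repeat(case_label, images_per_case).astype(np.float64),
            "case_id": case_ids,
            "image_id": np.char.add(case_ids.astype(str), image_suffix),
            "device_id": device_id,
            "time_index": int(time_index),
        }
    )
    assert len(df) == n_images
    return RecordSet(df)


# ---------------------------------------------------------------------------
# Scenario schedules
# ---------------------------------------------------------------------------


@dataclass
class ScenarioSchedule:
    """Per-week, per-device case counts plus each device's score model.

    ``model_switches`` maps a device to ``(week, post_model)``: from that
    week on (inclusive) the device generates from ``post_model`` — this is
    how a software update is expressed.
    """

    horizon: int
    counts: List[Dict[str, int]]  # one dict per week: device -> case count
    device_models: Dict[str, DomainModel]
    images_per_case: int = 4
    prevalence: float = 0.02
    model_switches: Dict[str, Tuple[int, DomainModel]] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.counts) != self.horizon:
            raise ValueError("counts must have one entry per week")
        for week in self.counts:
            for dev, n in week.items():
                if n < 0:
                    raise ValueError("case counts must be >= 0")
                if dev not in self.device_models:
                    raise ValueError(f"no model for device {dev!r}")

    def model_at(self, device_id: str, week: int) -> DomainModel:
        if device_id in self.model_switches:
            t1, post = self.model_switches[device_id]
            if week >= t1:
                return post
        return self.device_models[device_id]

    def total(self, week: int) -> int:
        return sum(self.counts[week].values())

    @property
    def devices(self) -> List[str]:
        return sorted(self.device_models)

    def to_dict(self) -> dict:
        return {
            "horizon": self.horizon,
            "counts": self.counts,
            "device_models": {d: m.to_dict() for d, m in self.device_models.items()},
            "images_per_case": self.images_per_case,
            "prevalence": self.prevalence,
            "model_switches": {
                d: [t1, m.to_dict()] for d, (t1, m) in self.model_switches.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSchedule":
        return cls(
            horizon=int(d["horizon"]),
            counts=[{k: int(v) for k, v in w.items()} for w in d["counts"]],
            device_models={
                k: DomainModel.from_dict(v) for k, v in d["device_models"].items()
            },
            images_per_case=int(d.get("images_per_case", 4)),
            prevalence=float(d.get("prevalence", 0.02)),
            model_switches={
                k: (int(v[0]), DomainModel.from_dict(v[1]))
                for k, v in d.get("model_switches", {}).items()
            },
        )


def make_schedule(
    scenario: str,
    horizon: int = 20,
    cases_per_week: int = 250,
    images_per_case: int = 4,
    prevalence: float = 0.02,
    device_a: str = "scanner_A",
    device_b: str = "scanner_B",
    model_a: DomainModel = REFERENCE_MODEL,
    model_b: DomainModel = SCANNER_B_MODEL,
    update_week: Optional[int] = None,
    update_strength: float = DEFAULT_UPDATE_STRENGTH,
) -> ScenarioSchedule:
    """Build the weekly schedule for one deployment scenario.

    * ``new_site``: one static week on the shifted device.
    * ``transition``: linear crossover of the weekly counts from device A to
      device B; the total stays constant at ``cases_per_week``.
    * ``addition``: device A constant while device B ramps linearly from 0
      to A's level, doubling the weekly total by the final week.
    * ``software_update``: a single device whose score model switches to a
      sharpened warp at ``update_week`` (default mid-horizon).
    """
    if scenario == "new_site":
        return ScenarioSchedule(
            horizon=1,
            counts=[{device_b: cases_per_week}],
            device_models={device_b: model_b},
            images_per_case=images_per_case,
            prevalence=prevalence,
        )
    if horizon < 4:
        raise ValueError("temporal scenarios need horizon >= 4 weeks")
    if scenario == "transition":
        counts = []
        for w in range(horizon):
            nb = round(cases_per_week * w / (horizon - 1))
            counts.append({device_a: cases_per_week - nb, device_b: nb})
        return ScenarioSchedule(
            horizon=horizon,
            counts=counts,
            device_models={device_a: model_a, device_b: model_b},
            images_per_case=images_per_case,
            prevalence=prevalence,
        )
    if scenario == "addition":
        counts = []
        for w in range(horizon):
            nb = round(cases_per_week * w / (horizon - 1))
            counts.append({device_a: cases_per_week, device_b: nb})
        return ScenarioSchedule(
            horizon=horizon,
            counts=counts,
            device_models={device_a: model_a, device_b: model_b},
            images_per_case=images_per_case,
            prevalence=prevalence,
        )
    if scenario == "software_update":
        t1 = horizon // 2 if update_week is None else int(update_week)
        post = model_a.with_warp(
            compose_warps(sharpness_update_warp(update_strength), model_a.warp)
            if model_a.warp.family != "identity"
            else sharpness_update_warp(update_strength)
        )
        return ScenarioSchedule(
            horizon=horizon,
            counts=[{device_a: cases_per_week} for _ in range(horizon)],
            device_models={device_a: model_a},
            images_per_case=images_per_case,
            prevalence=prevalence,
            model_switches={device_a: (t1, post)},
        )
    raise ValueError(f"unknown scenario {scenario!r}")


def simulate_week(
    schedule: ScenarioSchedule, week: int, rng: np.random.Generator
) -> RecordSet:
    """Generate one week of records according to the schedule (devices in
    sorted order so a given generator state yields a fixed draw)."""
    parts = []
    for dev in sorted(schedule.counts[week]):
        n = schedule.counts[week][dev]
        if n == 0:
            continue
        parts.append(
            generate_records(
                schedule.model_at(dev, week),
                n_cases=n,
                prevalence=schedule.prevalence,
                images_per_case=schedule.images_per_case,
                device_id=dev,
                time_index=week,
                rng=rng,
            )
        )
    return RecordSet.concat(parts) if parts else RecordSet.empty()


def schedule_from_config(cfg: Union[dict, str]) -> ScenarioSchedule:
    """Build a schedule from a JSON config.

    Either a full serialised schedule (``{"horizon": ..., "counts": ...}``)
    or a builder form ``{"scenario": "transition", "params": {...}}`` where
    params are the keyword arguments of :func:`make_schedule` (device
    models given as dicts).
    """
    if isinstance(cfg, str):
        cfg = json.loads(cfg)
    if "scenario" in cfg:
        params = dict(cfg.get("params", {}))
        for key in ("model_a", "model_b"):
            if key in params and isinstance(params[key], dict):
                params[key] = DomainModel.from_dict(params[key])
        return make_schedule(cfg["scenario"], **params)
    return ScenarioSchedule.from_dict(cfg)
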
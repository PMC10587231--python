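"""Bootstrap evaluation of the new-site deployment and dataset-size sweeps.

Each repetition draws an evaluation set and a *disjoint* alignment set
(case-level draws: all images of a drawn case are included; cases may be
reused across repetitions), fits the alignment transform on the alignment
scores against the reference scores, and evaluates sensitivity,
specificity, ROC-AUC and Youden's index at the frozen operating point on
the evaluation images before and after alignment.  Summaries report the
mean, standard deviation and the 5/25/50/75/95 percentiles over
repetitions.

The size-sensitivity sweep mirrors the deployment protocol: the
alignment-set sweep matches against the full reference, the reference-set
sweep fixes the alignment set at 500 cases.  By default the sweeps use
common random numbers — one evaluation draw per repetition shared across
grid sizes, and nested alignment subsets — so that dispersion differences
across sizes reflect the size under study rather than independent
evaluation noise (independent draws via ``common_draws=False``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .align import fit_alignment
from .metrics import OperatingPoint, roc_auc
from .records import RecordSet

__all__ = [
    "BootstrapConfig",
    "BootstrapSummary",
    "scenario1_bootstrap",
    "size_sensitivity",
    "SizingError",
    "check_disjoint",
]

METRICS = ("sensitivity", "specificity", "auc", "youden", "sen_minus_spc")
PERCENTILES = (5, 25, 50, 75, 95)


class SizingError(ValueError):
    """Requested draw sizes exceed the available cases."""


@dataclass(frozen=True)
class BootstrapConfig:
    """Sizes and seed of the repeated evaluation/alignment draws."""

    n_eval_cases: int = 2500
    n_align_cases: int = 1000
    n_reps: int = 500
    seed: int = 0
    unit: str = "case"  # "case" | "image"

    def __post_init__(self):
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.n_eval_cases < 1 or self.n_align_cases < 1:
            raise ValueError("draw sizes must be >= 1")
        if self.unit not in ("case", "image"):
            raise ValueError("unit must be 'case' or 'image'")


def check_disjoint(eval_ids: Sequence, align_ids: Sequence) -> None:
    """Raise if the evaluation and alignment draws share any unit."""
    overlap = set(eval_ids) & set(align_ids)
    if overlap:
        raise AssertionError(
            f"evaluation and alignment draws overlap on {len(overlap)} unit(s)"
        )


@dataclass
class BootstrapSummary:
    """Per-metric draws and summaries, before and after alignment."""

    draws: Dict[str, Dict[str, np.ndarray]]  # metric -> phase -> (n_reps,)
    n_reps: int
    n_eval_cases: int
    n_align_cases: int

    def mean(self, metric: str, phase: str) -> float:
        return float(self.draws[metric][phase].mean())

    def sd(self, metric: str, phase: str) -> float:
        d = self.draws[metric][phase]
        return float(d.std(ddof=1)) if d.size > 1 else 0.0

    def percentile(self, metric: str, phase: str, q: float) -> float:
        return float(np.percentile(self.draws[metric][phase], q))

    def spread(self, metric: str, phase: str) -> float:
        """Inter-percentile (p95 - p5) dispersion across repetitions."""
        return self.percentile(metric, phase, 95) - self.percentile(metric, phase, 5)

    def to_dict(self) -> dict:
        out = {
            "n_reps": self.n_reps,
            "n_eval_cases": self.n_eval_cases,
            "n_align_cases": self.n_align_cases,
            "metrics": {},
        }
        for metric, phases in self.draws.items():
            out["metrics"][metric] = {}
            for phase, d in phases.items():
                out["metrics"][metric][phase] = {
                    "mean": float(d.mean()),
                    "sd": float(d.std(ddof=1)) if d.size > 1 else 0.0,
                    "percentiles": {
                        str(q): float(np.percentile(d, q)) for q in PERCENTILES
                    },
                }
        return out


def _unit_groups(rs: RecordSet, unit: str) -> Tuple[np.ndarray, List[np.ndarray]]:
    """Return unit identifiers and the row indices of each unit."""
    df = rs.frame
    if unit == "image":
        ids = df["image_id"].to_numpy()
        return ids, [np.array([i]) for i in range(len(df))]
    codes, uniques = df["case_id"].factorize(sort=True)
    groups: List[List[int]] = [[] for _ in range(len(uniques))]
    for row, c in enumerate(codes):
        groups[c].append(row)
    return uniques.to_numpy(), [np.asarray(g) for g in groups]


def _phase_metrics(scores: np.ndarray, labels: np.ndarray, thr: float) -> dict:
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    sen = float((pos >= thr).mean())
    spc = float((neg < thr).mean())
    return {
        "sensitivity": sen,
        "specificity": spc,
        "auc": roc_auc(scores, labels),
        "youden": sen + spc - 1.0,
        "sen_minus_spc": sen - spc,
    }


def scenario1_bootstrap(
    target: RecordSet,
    reference: RecordSet,
    op: OperatingPoint,
    cfg: BootstrapConfig = BootstrapConfig(),
) -> BootstrapSummary:
    """Repeated disjoint evaluation/alignment draws on a shifted target set.

    Per repetition: draw ``n_eval_cases`` evaluation cases and a disjoint
    set of ``n_align_cases`` alignment cases from the target, fit the
    transform on the alignment scores against the reference scores, and
    evaluate before/after at the frozen ``op.threshold`` on the evaluation
    images.  Deterministic under ``cfg.seed``.
    """
    ids, groups = _unit_groups(target, cfg.unit)
    need = cfg.n_eval_cases + cfg.n_align_cases
    if need > len(groups):
        raise SizingError(
            f"need {need} {cfg.unit}s per draw but only {len(groups)} available"
        )
    ref_scores = reference.scores
    t_scores = target.scores
    t_labels = target.labels
    rng = np.random.default_rng(cfg.seed)
    draws = {
        m: {ph: np.empty(cfg.n_reps) for ph in ("before", "after")} for m in METRICS
    }
    for r in range(cfg.n_reps):
        perm = rng.permutation(len(groups))
        eval_units = perm[: cfg.n_eval_cases]
        align_units = perm[cfg.n_eval_cases : need]
        check_disjoint(ids[eval_units], ids[align_units])
        eval_rows = np.concatenate([groups[u] for u in eval_units])
        align_rows = np.concatenate([groups[u] for u in align_units])
        transform = fit_alignment(ref_scores, t_scores[align_rows])
        es, el = t_scores[eval_rows], t_labels[eval_rows]
        before = _phase_metrics(es, el, op.threshold)
        after = _phase_metrics(transform(es), el, op.threshold)
        for m in METRICS:
            draws[m]["before"][r] = before[m]
            draws[m]["after"][r] = after[m]
    return BootstrapSummary(
        draws=draws,
        n_reps=cfg.n_reps,
        n_eval_cases=cfg.n_eval_cases,
        n_align_cases=cfg.n_align_cases,
    )


def size_sensitivity(
    target: RecordSet,
    reference: RecordSet,
    op: OperatingPoint,
    align_sizes: Optional[Sequence[int]] = None,
    ref_sizes: Optional[Sequence[int]] = None,
    cfg: BootstrapConfig = BootstrapConfig(),
    align_cases_for_ref_sweep: int = 500,
    common_draws: bool = True,
) -> Dict[str, Dict[int, BootstrapSummary]]:
    """Sweep the alignment-set and reference-set sizes (in cases).

    The alignment sweep matches against the full reference; the reference
    sweep subsamples the reference and fixes the alignment set at
    ``align_cases_for_ref_sweep`` cases.  With ``common_draws`` each
    repetition shares one evaluation draw across all sizes and uses nested
    subsets for the swept set, so dispersion is directly comparable across
    grid points.
    """
    align_sizes = sorted(align_sizes or [])
    ref_sizes = sorted(ref_sizes or [])
    out: Dict[str, Dict[int, BootstrapSummary]] = {"alignment": {}, "reference": {}}
    if align_sizes:
        if not common_draws:
            for size in align_sizes:
                out["alignment"][size] = scenario1_bootstrap(
                    target, reference, op, replace(cfg, n_align_cases=size)
                )
        else:
            out["alignment"] = _nested_align_sweep(target, reference, op, align_sizes, cfg)
    if ref_sizes:
        out["reference"] = _ref_sweep(
            target, reference, op, ref_sizes, cfg, align_cases_for_ref_sweep, common_draws
        )
    return out


def _nested_align_sweep(target, reference, op, align_sizes, cfg):
    ids, groups = _unit_groups(target, cfg.unit)
    max_align = max(align_sizes)
    need = cfg.n_eval_cases + max_align
    if need > len(groups):
        raise SizingError(
            f"need {need} {cfg.unit}s per draw but only {len(groups)} available"
        )
    ref_scores = reference.scores
    t_scores, t_labels = target.scores, target.labels
    rng = np.random.default_rng(cfg.seed)
    draws = {
        size: {m: {ph: np.empty(cfg.n_reps) for ph in ("before", "after")} for m in METRICS}
        for size in align_sizes
    }
    for r in range(cfg.n_reps):
        perm = rng.permutation(len(groups))
        eval_units = perm[: cfg.n_eval_cases]
        align_pool = perm[cfg.n_eval_cases : need]
        eval_rows = np.concatenate([groups[u] for u in eval_units])
        es, el = t_scores[eval_rows], t_labels[eval_rows]
        before = _phase_metrics(es, el, op.threshold)
        for size in align_sizes:
            align_units = align_pool[:size]  # nested subsets
            check_disjoint(ids[eval_units], ids[align_units])
            align_rows = np.concatenate([groups[u] for u in align_units])
            transform = fit_alignment(ref_scores, t_scores[align_rows])
            after = _phase_metrics(transform(es), el, op.threshold)
            for m in METRICS:
                draws[size][m]["before"][r] = before[m]
                draws[size][m]["after"][r] = after[m]
    return {
        size: BootstrapSummary(
            draws=draws[size],
            n_reps=cfg.n_reps,
            n_eval_cases=cfg.n_eval_cases,
            n_align_cases=size,
        )
        for size in align_sizes
    }


def _ref_sweep(target, reference, op, ref_sizes, cfg, n_align, common_draws):
    ids, groups = _unit_groups(target, cfg.unit)
    need = cfg.n_eval_cases + n_align
    if need > len(groups):
        raise SizingError(
            f"need {need} {cfg.unit}s per draw but only {len(groups)} available"
        )
    _, ref_groups = _unit_groups(reference, cfg.unit)
    max_ref = max(ref_sizes)
    if max_ref > len(ref_groups):
        raise SizingError(
            f"reference sweep needs {max_ref} {cfg.unit}s but only {len(ref_groups)} available"
        )
    ref_scores = reference.scores
    t_scores, t_labels = target.scores, target.labels
    rng = np.random.default_rng(cfg.seed + 1)
    draws = {
        size: {m: {ph: np.empty(cfg.n_reps) for ph in ("before", "after")} for m in METRICS}
        for size in ref_sizes
    }
    for r in range(cfg.n_reps):
        perm = rng.permutation(len(groups))
        eval_units = perm[: cfg.n_eval_cases]
        align_units = perm[cfg.n_eval_cases : need]
        check_disjoint(ids[eval_units], ids[align_units])
        eval_rows = np.concatenate([groups[u] for u in eval_units])
        align_rows = np.concatenate([groups[u] for u in align_units])
        es, el = t_scores[eval_rows], t_labels[eval_rows]
        ali = t_scores[align_rows]
        before = _phase_metrics(es, el, op.threshold)
        ref_perm = rng.permutation(len(ref_groups))
        for size in ref_sizes:
            if common_draws:
                ref_units = ref_perm[:size]  # nested reference subsets
            else:
                ref_units = rng.permutation(len(ref_groups))[:size]
            ref_rows = np.concatenate([ref_groups[u] for u in ref_units])
            transform = fit_alignment(ref_scores[ref_rows], ali)
            after = _phase_metrics(transform(es), el, op.threshold)
            for m in METRICS:
                draws[size][m]["before"][r] = before[m]
                draws[size][m]["after"][r] = after[m]
    return {
        size: BootstrapSummary(
            draws=draws[size],
            n_reps=cfg.n_reps,
            n_eval_cases=cfg.n_eval_cases,
            n_align_cases=n_align,
        )
        for size in ref_sizes
    }
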
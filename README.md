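# upalign

Label-free recalibration of classifier output scores under acquisition
shift, for screening and diagnostic imaging AI.

## The problem

A disease-detection model is deployed with a calibrated decision threshold
— an *operating point* realising a chosen sensitivity/specificity (SEN/SPC)
trade-off, e.g. the balanced point where SEN = SPC. When the data
acquisition pipeline changes (a new scanner vendor, a processing-software
update, a different staining protocol), the model's score *distribution*
shifts even when its ability to separate classes (ROC-AUC) is preserved.
The frozen threshold then lands at a different point of the ROC curve:
sensitivity may collapse while specificity saturates, silently, with no
labels available to detect it. This package implements **unsupervised
prediction alignment (UPA)**: a monotone remapping of scores from the
shifted domain back onto the reference score distribution, fitted from a
modest set of *unlabelled* predictions.

## The method

Let $F_{\mathrm{ref}}$ and $F_{\mathrm{align}}$ be the empirical CDFs of
the reference scores and of the (unlabelled) alignment-set scores from the
shifted domain. UPA is piecewise-linear cumulative-distribution matching:

$$\hat T(x) \;=\; \hat F_{\mathrm{ref}}^{-1}\!\big(\hat F_{\mathrm{align}}(x)\big),$$

evaluated by placing one knot at each distinct alignment score (mapped to
the reference quantile at the same cumulative level) and interpolating
linearly between knots. $\hat T$ is monotone non-decreasing, so it never
reorders predictions: ROC-AUC is conserved exactly, and relative
calibration (the shape of the score distribution) is preserved — only the
operating point is restored. No ground-truth labels from the shifted
domain are needed.

Around the core transform the package provides:

- **`records`** — prediction-record tables (score, label, case/image/device
  ids, week index) with CSV/JSON round-trip I/O;
- **`align`** — ECDF, transform fit/apply, JSON serialisation of fitted
  transforms, and a two-sample Kolmogorov–Smirnov shift detector;
- **`metrics`** — SEN/SPC, ROC-AUC, Youden's index $J = \mathrm{SEN} +
  \mathrm{SPC} - 1$, expected calibration error, and threshold selection at
  the balanced point or at a target specificity;
- **`synth`** — a seeded binormal-on-logit score generator with strictly
  monotone acquisition-shift warps and weekly deployment schedules (scanner
  transition, scanner addition, software update);
- **`streaming`** — per-device continuous recalibration from a running
  window of recent weeks, with a frozen threshold;
- **`bootstrap`** — repeated disjoint evaluation/alignment draws for
  new-site deployment and dataset-size sensitivity sweeps.

## Worked example

```python
import numpy as np
from upalign import (REFERENCE_MODEL, SCANNER_B_MODEL, generate_records,
                     select_threshold_balanced, sen_spc, roc_auc, fit_alignment)

# reference site: 3000 screening cases, 4 views each, ~2% prevalence
reference = generate_records(REFERENCE_MODEL, 3000, 0.02, images_per_case=4,
                             device_id="site_ref", seed=7)
op = select_threshold_balanced(reference.scores, reference.labels)
print(f"balanced threshold on reference: {op.threshold:.3f} (|SEN-SPC| = {op.achieved_gap:.4f})")

# new scanner with a strong acquisition shift
new_site = generate_records(SCANNER_B_MODEL, 2000, 0.02, images_per_case=4,
                            device_id="scanner_B", seed=8)
sen, spc = sen_spc(new_site.scores, new_site.labels, op.threshold)
print(f"before alignment: SEN = {sen:.3f}, SPC = {spc:.3f}, "
      f"AUC = {roc_auc(new_site.scores, new_site.labels):.3f}")

# label-free recalibration from 500 unlabelled alignment cases
align_scores = new_site.scores[:2000]   # 500 cases x 4 images
transform = fit_alignment(reference.scores, align_scores)
aligned = transform(new_site.scores)
sen, spc = sen_spc(aligned, new_site.labels, op.threshold)
print(f"after alignment:  SEN = {sen:.3f}, SPC = {spc:.3f}, "
      f"AUC = {roc_auc(aligned, new_site.labels):.3f}")
```

prints

```
balanced threshold on reference: 0.725 (|SEN-SPC| = 0.0000)
before alignment: SEN = 0.517, SPC = 0.988, AUC = 0.932
after alignment:  SEN = 0.836, SPC = 0.851, AUC = 0.932
```

On the shifted scanner the frozen threshold misses half the positives
(SEN 0.52) although the AUC is intact — exactly the silent failure mode.
After fitting the transform on 500 unlabelled cases, the operating point
is back near balance, and the AUC is unchanged to machine precision.

A command-line surface wraps the same operations; see `upalign --help`
(subcommands `fit`, `apply`, `metrics`, `detect-shift`, `simulate`,
`run-scenario`, `evaluate`).

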
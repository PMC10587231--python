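# Methods

## The alignment transform

UPA aligns predictions from a shifted acquisition domain to a reference
score distribution by piecewise-linear cumulative-distribution matching
(the score-space analogue of histogram matching). Fitting uses only two
inputs: reference-domain scores and unlabelled alignment-set scores from
the shifted domain.

Conventions, fixed because the published description leaves them open:

- **ECDF**: right-continuous, `F(x) = #{scores <= x} / n`.
- **Quantile**: linear interpolation between order statistics, with the
  i-th of n sorted values assigned level `i/n`; levels at or below `1/n`
  return the sample minimum. Pairing this convention with the ECDF above
  makes self-alignment *exactly* the identity on shared knots: when the
  alignment set equals the reference set, every knot maps to itself.
- **Knots**: one per distinct alignment score. Tied alignment scores share
  a knot placed at the upper tie boundary's cumulative level, so equal
  inputs always map to equal outputs and the map is deterministic.
- **Extrapolation**: a new test score outside the alignment range follows
  the outermost linear segment and is clipped to [0, 1]. New deployment
  data can legitimately exceed the range seen during fitting; linear
  continuation is the least-structured monotone choice and clipping
  preserves the score-domain invariant. Clipping can create ties at the
  boundaries; the AUC-conservation guarantee is exact whenever the applied
  scores lie inside the knot range (in particular when a domain's own
  scores are aligned), and off by at most the tie mass otherwise.
- **Minimum fit size**: a transform is refused (not fitted badly) below 2
  alignment scores, or below 2 *distinct* scores; the streaming engine
  uses a stricter default of 50 scores before switching off cold start.

Because the map is monotone non-decreasing it cannot reorder predictions:
ROC-AUC is invariant under alignment, and the shape of the score
distribution (hence relative calibration) is transported rather than
destroyed. UPA corrects *threshold shift* only; if class separability
itself degrades across domains (falling AUC), no output remapping can
restore it.

Shift detection uses the two-sample Kolmogorov–Smirnov distance between
the reference and a monitoring window (`scipy.stats.ks_2samp`), flagged
above a configurable threshold (default 0.1, a distribution gap large
enough to move a mid-range operating point noticeably).

## Metrics and operating points

The decision rule is *positive iff score >= threshold*. Candidate
thresholds for selection rules are the midpoints between adjacent distinct
scores plus {0, 1} — a finite, exact, reproducible search space; ties are
broken toward the smallest threshold. The balanced operating point
minimises |SEN − SPC| over candidates; the target-specificity rule takes
the smallest candidate with SPC at or above the target and warns when only
the degenerate threshold 1 attains it. ROC-AUC is the Mann–Whitney
concordance (ties counted 1/2), computed by scikit-learn. Expected
calibration error uses 10 equal-width bins by default (the convention of
the calibration literature); empty bins contribute zero. All metrics are
image-wise; cases are a sampling unit, never an aggregation unit.

## The synthetic generator

The generator emulates the regime the method assumes, not any particular
dataset: a well-separating classifier whose score distribution moves under
acquisition shift while its ROC-AUC does not.

- **Score model**: per case, class ~ Bernoulli(prevalence); all images of
  a case share the class (a malignant study is malignant in every view);
  per image, latent `z ~ Normal(mu_class, sigma)` independently, raw score
  `logistic(z)`. Defaults `mu_neg = 0, mu_pos = 2, sigma = 1` give the
  closed-form AUC `Phi((mu_pos - mu_neg)/(sigma*sqrt(2))) = Phi(sqrt(2)) ≈ 0.921`,
  a realistic screening-model discrimination level, and the closed form
  anchors oracle checks.
- **Acquisition shift** is a strictly increasing warp of the score, so AUC
  preservation holds by construction. Families: latent affine
  (`s -> logistic(a·logit(s) + b)`), score power (`s -> s^g`), and a
  symmetric "sharpening" power warp around 0.5 that pushes scores toward
  the extremes, plus composition.
- **Presets**: mammography-style screening (prevalence 0.02, 4 images per
  case, 250 cases per week) and balanced histopathology patches
  (prevalence 0.5, 1 image per case). The shipped strong-shift scanner
  model uses the latent affine warp `z -> 0.9 z − 1.0`; at the reference
  balanced threshold this collapses sensitivity toward ~0.3 while
  specificity saturates (analytic SEN − SPC ≈ −0.58), mirroring an
  unseen-vendor deployment with intact AUC. The software-update warp ships
  with default strength 2.0 (sharpening exponent 3), chosen once as a
  sudden calibration break of analytic magnitude ≈ +0.30 at the same
  threshold. The image-space sharpening of a real software update is
  represented by this score-space warp; its magnitude has no external
  anchor and is a free parameter.
- What the generator does **not** emulate: population or prevalence shift
  (prevalence is held equal across domains — an assumption of the method,
  enforced rather than relaxed), inter-image correlation within a case
  beyond the shared label, reader effects, or non-monotone score
  distortions (available only behind explicit warp construction for
  negative tests). Passing tests therefore demonstrate behaviour under
  pure monotone acquisition shift, not robustness to other shift types.

**Scenario schedules** map weeks to per-device case counts: `transition`
linearly crosses weekly counts from scanner A to scanner B at constant
total; `addition` keeps A constant while B ramps from 0 to A's level
(total doubles); `software_update` keeps one device whose score model
switches at week T1; `new_site` is a single static week.

## Streaming recalibration

The engine freezes the balanced threshold on a labelled reference set at
initialisation and never refits it. Each week T, per device, a transform
is fitted — label-free — from that device's running window (weeks T−2 and
T−1 by default) against the frozen reference scores, applied to week T's
scores, and SEN/SPC is evaluated before and after at the frozen threshold,
per device and pooled. The evaluation week is never part of the fitting
window (asserted by construction and by id in tests). Devices are fully
isolated: each transform sees only its own device's buffer, so a software
update on one scanner triggers recalibration of that scanner alone. A
device whose window holds fewer than `min_fit_size = 50` scores runs on
raw predictions (cold start) rather than on a badly fitted map. After a
sudden shift at T1 the window is purely pre-shift at T1, mixed at T1+1 and
purely post-shift at T1+2, so recovery completes within the window length.

## Bootstrap evaluation

New-site deployment: per repetition, an evaluation set and a disjoint
alignment set are drawn at case level (all images of a drawn case
included; cases reusable across repetitions — within-repetition
disjointness is the binding requirement), the transform is fitted on the
alignment scores, and metrics are computed before/after at the frozen
threshold on the evaluation images. Summaries report mean, SD and the
5/25/50/75/95 percentiles over repetitions.

The size sweeps follow the deployment protocol: the alignment-size sweep
matches against the full reference; the reference-size sweep subsamples
the reference (nested) with the alignment set fixed at 500 cases. By
default the sweeps use common random numbers — one evaluation draw per
repetition shared across grid sizes, and nested subsets of one draw for
the swept set — so that dispersion comparisons across sizes reflect the
size under study rather than independent evaluation noise; independent
draws are available via `common_draws=False`.

## Problem sizes for desk-scale runs

The test suite and `scripts/acceptance.py` run the pipeline at reduced
scale, chosen as the package's own desk-scale defaults: new-site bootstrap
with a 3000-case reference, 6000-case target pool, 1000-case evaluation /
500-case alignment draws and 100 repetitions; streaming scenarios over 20
weeks of 250 cases at 50 repetitions with a 1200-case reference (the size
used to set the starting threshold in the streaming protocol); size sweeps
over alignment sizes {250, 500, 1000} with 2500-case evaluation draws and
50 repetitions; generator validity at 50 000 images. At screening
prevalence the 1200-case streaming reference contains only ~100 positive
images, so the frozen balanced threshold carries sampling noise of roughly
±0.03 in the population SEN − SPC offset; trajectories should be read
relative to that floor.

## Numerical and degenerate-input choices

- Scores are validated, never silently clamped: inputs outside [0, 1]
  raise; only *outputs* of extrapolation are clipped.
- Full-precision score round-trip in CSV/JSON (shortest-representation
  floats; `float_precision="round_trip"` on read) because the transform is
  sensitive to rank order.
- Empty score vectors, single-class label vectors, out-of-order streaming
  weeks, infeasible draw sizes and unknown scenario names all raise typed
  errors naming the offending quantity.
- All randomness flows through explicit seeds or `numpy` Generators;
  repeated runs under one seed are bit-identical.

## Known limitations

- Corrects threshold shift only; assumes AUC and prevalence transfer
  across domains. Under prevalence shift the matched quantiles no longer
  correspond to the same class mixture and the recovered operating point
  is biased.
- The extrapolation rule beyond the alignment range is a modelling choice;
  with very small alignment sets the tails of the fitted map are poorly
  determined (hence the refusal thresholds).
- Percentile-based dispersion summaries at a few dozen repetitions carry
  sampling jitter of the same order as small true differences between
  adjacent grid sizes; standard deviations are also reported and are the
  more stable dispersion measure at this scale.
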
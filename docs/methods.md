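# Methods

## Data model and stroke segmentation

A recording is an ordered stream of pen samples: page position `(x, y)` in
mm (origin top-left, y increasing downward — the print/scan convention),
an integer millisecond timestamp, a tip-force reading on the 0–1024 sensor
scale, and a pen-contact flag. Invariants: positive pressure implies
contact; an airborne pen reads zero pressure. A contact flag with zero
pressure is tolerated as recording noise (tip switch closed, force below
the sensor threshold). Timestamps are used exactly as recorded — the
nominal rate is 100 samples/s but irregular gaps are not resampled.

A **stroke** is a maximal contiguous run of on-paper samples. Runs of a
single sample are dropped and counted in the log: every per-stroke
kinematic quantity is a finite difference, so a singleton contact carries
no usable information. The segmentation is a partition — stroke samples,
dropped singletons and off-paper samples add up to the stream length. The
in-air interval before stroke *i+1* runs from the last sample of stroke
*i* to the first sample of stroke *i+1*.

I/O uses a plain CSV dialect (one row per sample, columns
`participant_id, task_id, t_ms, x_mm, y_mm, pressure, on_paper`) with a
JSON sidecar for annotations (group, task score, MoCA-BC, MMSE,
demographics), or an equivalent single-file JSON dialect. Floats are
written with shortest round-trip precision and parsed with the
`round_trip` converter, so write∘read is the identity on valid data.

## The 35 per-stroke characteristics

One feature vector per stroke; task-level values (task score, stroke
count) are replicated onto every stroke of the task, because the stroke —
not the participant — is the analysis unit. Conventions that the source
material leaves open, and the choices made:

* **Velocities.** `vx = Δx/Δt`, `vy = Δy/Δt` (Δt in seconds),
  `v = √(vx² + vy²)`; acceleration differences consecutive speeds over the
  spacing of their (interval-end) timestamps. No smoothing by default; a
  centered 3-sample moving average of positions is available behind a
  flag. A stroke of two samples has one velocity and no acceleration; its
  acceleration entropy and slowdown count are 0 by convention.
* **Component statistics** use absolute component velocities |vx|, |vy|
  (means, extrema, dispersions): signed means would cancel on
  back-and-forth strokes.
* **Entropies** are Shannon entropies in bits over equal-width histograms
  spanning [min, max] of the series; default 16 bins, configurable; a
  constant series has zero entropy. The estimator (binning rule, base) is
  a documented package default — only the unit (bits) is fixed by the
  feature definitions.
* **Slowdowns** are deceleration *episodes*: maximal runs of consecutive
  negative first differences. Counting episodes rather than samples
  matches a "number of times" reading.
* **Lengths.** Path length sums Euclidean segment lengths; horizontal and
  vertical lengths sum |Δx| and |Δy|. Their variance/SD are within-stroke
  dispersions of the per-sample absolute displacements (the plausible
  alternative — across-stroke dispersion — would be constant within a
  task and is not used).
* **Tilt** is the signed angle in (−90°, 90°] of the first principal axis
  of the stroke's point cloud against the horizontal, computed after
  negating y (page-down to math convention): a stroke rising to the right
  visually has positive tilt. The 2×2 eigenproblem is solved in closed
  form, θ = ½·atan2(2σxy, σxx − σyy).
* **Moments** are population (divide-by-n) by default; sample moments
  (ddof = 1) behind a flag.

## Synthetic cohorts

The generator emulates the group contrasts reported for AD handwriting:
the AD-like profile writes more slowly (speed 10 vs 15 mm/s, CV 0.5 vs
0.4), presses harder and less steadily (pressure 650 ± 90 vs 580 ± 70
levels), hesitates more (deliberate pauses: rate 3 vs 1.5 per task, mean
1.2 s vs 0.6 s), uses more strokes (7.5 vs 6 per task), shows more tremor
(0.02 vs 0.008 mm positional jitter), scores lower on the tasks, and has
MoCA-BC ≈ 14.9 ± 4.3 vs 28.9 ± 1.6 (means and SDs on the 0–30 scale;
the SDs are the reported standard errors scaled by √n).

Mechanics: strokes trace stylized task templates (a cross and an X for
the point-connection task, two intersecting pentagons, word-like zigzag
groups for the two text tasks — kinematic features depend on trajectory
dynamics, not glyph identity). Template polylines are subdivided so the
writing speed is redrawn from the profile's log-normal roughly every 3 mm
of path; this gives within-stroke speed dynamics that scale
multiplicatively with the profile's speed distribution, so per-stroke
speed maxima and dispersions inherit the group contrast. Positions get
iid N(0, tremor_sd) jitter; tremor defaults are small because at 100 Hz a
jitter of σ mm adds ≈ √2·σ/0.01 mm/s of apparent speed, which must remain
small relative to the writing speed for the intended slower-AD contrast to
survive extraction. Pressure is a clamped rounded normal (≥ 1 on paper).
Stroke counts are rounded normals (≥ 1). Inter-stroke gaps are
exponential: quick transitions (mean 150 ms) or, with probability
pause_rate/n_gaps, deliberate pauses of mean `pause_mean_ms`; off-paper
samples are emitted during gaps so segmentation sees realistic streams.
Log-normal speeds and exponential pauses are chosen for positivity and
memorylessness; everything is configurable per group profile.

Randomness: one PCG64 substream per (seed, group, participant, task), so
cohorts are bit-identical for a fixed seed and independent of generation
order.

What the generator does **not** emulate: glyph shapes, biomechanical
stroke formation, within-subject correlation across tasks (tasks are
drawn independently per participant), pen azimuth/elevation, and any
device artifacts beyond the pressure clamp. Passing tests on synthetic
cohorts therefore demonstrate that the pipeline recovers the injected
statistical structure — not that the specific numeric defaults match any
clinical population.

## Screening

Per feature and task, missing values are imputed with the column mean of
the observed values (which preserves that mean exactly); a feature with no
observed value in one group is reported untestable. The test is chosen by
a gate: pooled-variance Student *t* (df = n₁ + n₂ − 2) when both groups
pass Shapiro–Wilk at α = 0.05 **and** a Levene (median-centered) variance
check passes; otherwise Mann–Whitney *U*. Group summaries follow the
test: mean ± SD for *t*, median + IQR for Mann–Whitney. Each feature is
also Spearman-correlated against MoCA-BC. All tests are two-sided at
α = 0.05; no multiple-testing correction by default (Benjamini–Hochberg
per task behind a flag).

The Mann–Whitney implementation uses midranks, the tie-corrected variance,
and a 0.5 continuity correction; for n₁ + n₂ ≤ 10 the two-sided p-value is
computed by exact enumeration of all group assignments of the pooled
midranks, p = P(|U − n₁n₂/2| ≥ |observed deviation|). Agreement between
the asymptotic and exact p-values, verified by exhaustive enumeration over
all assignments up to 5+5: within 0.01 wherever either p ≤ 0.05 (the
decision-relevant region), within 0.02 globally at 5+5. Mid-range
two-sided p-values on the 26-point U lattice at N = 10 cannot agree more
tightly — deviations up to ≈ 0.017 near p ≈ 0.4 are a property of the
normal approximation itself, not of this implementation.

Strokes are pooled as independent observations by default, mirroring the
stroke-as-sample convention of the underlying study design. Strokes within
a participant are correlated, so the pooled p-values overstate evidence;
`aggregate="participant"` (mean feature per participant) is the
honest-inference mode and is what the package's own type-I simulations
use.

## Diagnostics

ROC, AUC, Youden threshold and confusion metrics are implemented from
first principles (they are the quantities under test; scikit-learn's
versions serve as independent cross-checks in the test suite). The
classification rule is "score ≥ threshold ⇒ AD". ROC thresholds sweep +∞
and every distinct score, collapsing ties into single steps; AUC is the
trapezoidal area and equals the normalized Mann–Whitney statistic
(pairwise wins + half-ties). The Youden threshold maximizes
J = Se + Sp − 1 over all candidate thresholds; ties break toward the lower
threshold, favouring sensitivity in a screening setting. Undefined
confusion ratios (zero denominator) are reported as NaN.

The default roster: logistic regression, k-nearest neighbours, a
Platt-calibrated RBF SVM (monotone calibration, so ranking and AUC match
the raw decision function), Gaussian naive Bayes, random forest, XGBoost,
and AdaBoost, each behind a per-fold standardization step. Evaluation
protocols: stratified 5-fold cross-validation of pooled out-of-fold
probabilities (default), participant-grouped stratified folds
(`cv5_grouped`), and resubstitution. Stroke-level folds leak participant
identity (strokes of one writer appear in both training and test folds),
so the default can overstate generalization on real data; the grouped
protocol is the honest option and is used for the package's null-AUC
checks. Resubstitution is provided because published analyses of this
kind sometimes report training-set ROC. Fold assignment and stochastic
learners are seeded; the seed is recorded in every report.

## Simulation sizes and numerical checks

The package's statistical self-checks (test suite and
`scripts/acceptance.py`) use sizes chosen to make the Monte-Carlo noise
small relative to the asserted bands: type-I calibration uses 1,000 null
cohorts of 20 participants per group (≈33,000 pooled tests; the pooled
rejection rate is asserted within [3.5%, 6.5%] at α = 0.05), null-AUC
soundness uses cohorts of ~500 strokes per group under grouped folds
(single-replicate null AUC has SD ≈ 0.02 there), and effect recovery uses
the default profiles at ~500 strokes per group, where all injected
directional effects are flagged and the best classifier exceeds AUC 0.95.
The null simulations use a lighter-weight writing profile for both groups
(faster, fewer strokes) — exchangeability, not the profile, is what the
null property tests.

## Known limitations

* The stroke-pooled default inference ignores within-participant
  correlation; use the participant-level modes for honest p-values and
  generalization estimates.
* Entropy features depend on the configured bin count; values are
  comparable only at a fixed binning.
* The generator's defaults are plausible, not fitted to any clinical
  dataset; absolute feature values should not be compared against real
  cohorts.
* Exact Mann–Whitney enumeration is limited to n₁ + n₂ ≤ 10; beyond that
  the tie-corrected normal approximation is used.
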
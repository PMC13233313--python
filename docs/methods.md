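# Methods

This note documents the models, parameter choices and numerical conventions
behind `actionsym`, what the synthetic-data generator does and does not
emulate, and the design decisions taken where more than one reading was
defensible.

## Trajectory distance

A stroke enters the metric as positions only. It is rescaled so the
bounding-box diagonal of the resampled points is exactly 1 (aspect ratio
preserved), resampled to N = 70 points equally spaced in cumulative arc
length, and differentiated with the five-point stencil. Two conventions
needed fixing:

* **Velocity time base.** The resampled stroke is treated as spanning unit
  duration (sample step 1/(N−1)), so velocities are in bounding-box
  diagonals per stroke. Any time base would do for comparing two strokes —
  both series share it — but this one makes velocity magnitudes order-1 and
  the metric fully independent of the original sampling rate. Velocity is
  computed directly from the 70 resampled points rather than by re-running
  the 12.5 Hz filtering pipeline of the raw preprocessing; the resampled
  series is already smooth at that scale.
* **Warping penalty.** The regularizer weight λ = 0.045 ⟨|v|⟩ averages the
  per-sample velocity norms of the two inputs being compared, so the metric
  is self-contained (no dataset-level statistics enter a pairwise
  distance).

The DTW recursion uses steps {(1,0), (0,1), (1,1)} with both endpoints
anchored, and the path cost is divided by N (not by path length). The
implementation is an O(N²) dynamic program (numba-accelerated when
available); tests check it against exhaustive path enumeration at N = 6,
where enumeration is tractable, to 1e−12.

Consequences verified as properties: the distance is symmetric, lies in
[0, 1), is invariant to translation, uniform scaling and monotone time
reparameterization, and is monotone non-decreasing in λ.

## Image distance and alignment

The image distance is the outlier-robust modified Hausdorff variant: mean
(not max) of nearest-neighbour distances, averaged over both directions,
after centring each point set on its own centre of mass. It is computed
with a k-d tree and tested against the brute-force double loop exactly.

The primitive alignment a = d1/(d1 + d2) uses the trajectory distance for
drawings, the image distance for stimuli and the plain Euclidean distance
for population activity vectors. When d1 + d2 = 0 the score is defined as
0.5 and flagged degenerate. Alignments of reference trials against their own
set use leave-self-out means so a reference trial does not count its zero
self-distance.

The boundary morph is the level whose trial alignments are bimodal (scores
below 0.35 *and* above 0.65 present), choosing the level with mean closest
to 0.5, ties toward the larger minority class. The two hallmark statistics
are (i) nonlinearity — drawing alignment below the image line at U1 and
above it at U2 — and (ii) switching — boundary trials split by drawn
primitive separate (A2 > A1). Both are tested across morph sets with
one-sided Wilcoxon signed-rank tests; the reported W is the sum of ranks of
opposing sets (0 when every set shows the hallmark).

## Primitive templates and the remixed null

Templates are pointwise means of trajectory vectors over single-shape
trials; D_max,p is the 97.5th percentile of those trials' distances to the
mean. When all source trials are identical the percentile collapses, so the
threshold is floored at 5% of the 97.5th percentile of cross-primitive
nearest distances and flagged. Classification is argmin over templates with
ties broken toward the lowest template index.

Remixed primitives splice the first half (by distance travelled) of one
primitive to the second half of another, offset-aligned and blended over
~10% of arc length around the junction. Candidate filters: no
self-intersection (segment-pair test with a 2-sample adjacency window), and
|curvature| ≤ 0.8 on the inner 80% of the curve. The curvature bound is
applied with the curve at the standard rendered shape size (135 px), where
0.8 px⁻¹ means a turning radius under ~1.3 px — i.e. the splice kinks the
filter exists to catch. On unit-normalized curves the same number would
reject every curve (a unit circle already has |κ| = 2), so a pixel-scale
reading is the only workable one. Set-level constraints: each donor half is
used at most twice, and every remixed–remixed and remixed–actual distance
is at least the minimum actual–actual distance. Thresholds for remixed
primitives are inherited from the actual pool leniently: the largest actual
threshold goes to the remixed primitive with the worst average match to the
character strokes, and so on downward.

## Behavioural scoring

Raw factors: weighted fraction of image points touched within a 20 px
margin (corner/endpoint-like points — top-decile curvature magnitude and the
two endpoints — weighted ×2); negated image distance; efficiency
−max(0, ink_drawn − ink_image)/ink_image (the proportionality constant is
absorbed by the adaptive rescaling); for practised characters, negated
stroke-count mismatch and negated mean stroke-to-shape centroid distance.
Each factor is rescaled linearly to [0, 1] between the 1st and 53rd
percentiles of its last 50 raw values (minimum history 5, neutral 0.5
before that, degenerate equal bounds widened by ε), then aggregated by the
worst weighted factor. Default weights are 1.0 for the image-similarity
factors and 0.5 otherwise; they are configuration, not constants.
Categories: great (> 0.82), good (0.65–0.82], OK (0.15–0.65], fail
(≤ 0.15). Reward is C·m·a·s_scal with m = 1.3/1.0/0.8/0 and
a ~ 0.75 + 0.5·U(0,1); delay maps score 0 → 5 s (+ 0–2.5 s jitter) and
1 → 0 s, ×0.65 unless the trial failed.

## Neural preprocessing

Rates use a 25 ms Gaussian kernel on a 10 ms grid, truncated at ±4 s.d. and
renormalized within the trial window so edge spikes keep unit mass.
Screening: (1) 80th percentile of rates < 1 Hz; (2) drift |m|/u > 0.2 with
m the OLS slope of per-trial mean sqrt-rates versus time in hours and u the
mean sqrt-rate — keeping both numerator and denominator on the sqrt scale
makes the ratio a per-hour fractional drift and lets a 5→20 Hz ramp over
2 h trip the rule, which a raw-Hz denominator would not; (3) fluctuation
rules on disjoint contiguous 50-trial bins ((s_max−s_min)/s_mean > 1.15 on
across-trial s.d. of sqrt-rates, (u_max−u_min)/u_mean > 0.65 on bin means),
skipped and flagged below 100 trials. Normalization is the soft z-score
(sqrt(x) − μ)/(σ + C) with C = min over units of mean rate + 3 Hz; it is
exactly invertible given the parameters.

Time-warping maps each trial's inter-anchor segments linearly onto the
median segment durations; values are resampled, not rescaled, and a 2.5 ms
Gaussian smooths the anchor joints (quarter of a bin — near-invisible on
the 10 ms grid). Trials with missing or disordered anchors are dropped and
logged.

## Population geometry

The neural distance normalizes the per-bin mean pairwise Euclidean distance
by d_max(t), the 98th percentile of all pairwise trial distances in that
bin (an error is raised if it is 0), averages over bins, and subtracts the
average within-condition distances. Within-condition means use distinct
trial pairs only, which makes D* of a condition against itself exactly zero
and the same-distribution expectation zero; negative values are retained
because the debiasing implies small negatives under the null. Encoding
strength averages D* over condition pairs differing only in the target
variable.

Condition-PCA is fitted on train-half condition means (0.15 s bins, 0.02 s
slide, 8 components) over 8 randomized stratified splits, with test-half
trials projected and downstream results split-averaged. The region
comparison fits y = β₀ + β_r X_r + Σ γ_j Z_j + ε per region pair and
variable with condition-pair indicators, Bonferroni-corrects the two-sided
tests on β_r over all variable × pair combinations (56 at 8 regions and 2
variables), and summarizes each region by how many others it beats.

Cross-condition decoding uses a linear one-vs-rest max-margin classifier
(C = 0.1) per time bin, trained at one condition level and tested on the
others, with accuracy rescaled so chance maps to 0; within-condition
(split-half) accuracy is reported alongside. One deliberate choice: the
decoding wrapper fits its condition-PCA on label × condition *conjunction*
means. Fitting it on label means averaged over the generalization condition
would project away any condition-specific component of the code — the
average of per-condition tunings is still label-specific, and trials at
every condition correlate with it — making even a fully condition-specific
code appear invariant. With conjunction conditions the subspace retains the
condition-specific structure and the invariant/specific contrast is
identifiable; the PCA operation itself still accepts any condition key.

The initial-reach correction fits, per unit and bin, an OLS model with
first-stroke, task-type and primitive-class regressors and subtracts only
the first-stroke coefficient from first-stroke trials. The FVAF model fits
f_t = E v_t + b by least squares on all primitives but one and evaluates
FVAF = 1 − SS_err/SS_tot on the held-out primitive, with the *uncentred*
total sum of squares as defined (this differs from a conventional R² on
centred data) and with the intercept included in predictions; lags from
−0.3 to 0.3 s in 0.05 s steps shift neural activity relative to behaviour
(negative = neural leads), and the scalar summary averages −0.15 to
−0.05 s. Fixation-aligned decoding trains a one-vs-rest logistic model on
planning-epoch snippets (0.3 s bins, 0.1 s slide) and excludes fixations
further than 70 px from every shape (count logged).

Default analysis windows are keyword arguments: 0.05–0.6 s after image
onset for planning-epoch analyses, 0.6–1.0 s for time-averaged categorical
analyses, −0.5 to −0.05 s before stroke onset for stroke-aligned analyses
and −0.35 to −0.05 s for non-first strokes.

## Synthetic data

Canonical primitive curves are clamped cubic B-splines whose control-point
coordinates are the named control parameters; the curve is therefore
*linear* in its parameters, so morphing by linear parameter interpolation
moves the image essentially linearly through shape space, and the
image-metric alignment of a morph set is linear in morph fraction (tested
at R² > 0.99). Libraries are rejection-sampled until all pairwise
trajectory distances exceed a floor (default 0.25; empirically,
between-primitive distances run 0.4–0.75 and within-primitive trial
variability 0.05–0.15 at the default noise).

Strokes are drawn at 60 Hz along the placed curve with a minimum-jerk speed
profile, low-pass-filtered Gaussian positional jitter (default s.d. 1.5 px,
smoothed over ~4 samples — chosen to put within-primitive trajectory
distances in the 0.05–0.15 range a practised subject produces) and
lognormal duration variability (σ = 0.15). Stimulus geometry follows the
task: shapes ~135 px (4 cm at 33.6 px/cm), location variation spanning
~320 px, size ratios up to 2.5.

Morph sets default to 5 interior morphs (7 images); the categorical drawing
policy draws each image as the practised primitive on its side of the
boundary, with a 50/50 mixture at the level nearest the boundary fraction,
while the tracing policy draws the interpolated shape itself. Characters
attach 2–6 shapes at sampled arc-length fractions and are rejection-sampled
under the crossing filter (at most one intersection per shape pair, counted
with exact segment intersections).

Population tensors assign every unit independent Gaussian tuning weights
per level of primitive, location, size and task type, scaled by the
respective gains, plus an optional primitive × location interaction gain
that implements a location-*specific* primitive code; a shared smooth
temporal profile modulates the tuned amplitude over the trial. Morph trials
pass through the boundary rule (fraction vs 0.5) before primitive tuning
when the categorical flag is set, and interpolate the two end-point tunings
otherwise. Noise is Gaussian on rates by default (all analyses operate on
smoothed rates); Poisson counts are available. Everything is deterministic
given the design seed.

What the generator does **not** emulate: correlated noise across units or
time, non-stationarity within sessions, realistic eye movements, reach
biomechanics, or the heavy-tailed across-primitive usage frequencies of
real drawing. Passing tests therefore demonstrate that the analysis code
recovers the structure it targets when that structure is present and absent
when it is not — not that real recordings contain it.

## Problem sizes

The test suite and the acceptance script run on deliberately small
instances chosen to estimate each quantity stably: 5–8 primitives,
15–20 trials per primitive for template fitting, 2,000 strokes per
primitive for threshold calibration, 20 morph sets × 8 trials per level for
the hallmark counts, 25–30 units × 8–15 trials per condition for the
population analyses, and 200 resamples for the debiasing null. The
decoder-contrast summary in the acceptance script additionally averages
over 5 independent tuning draws, because with a few dozen units a single
random draw of per-location tunings carries sizeable accidental
correlation.

## Known limitations

* The DTW dynamic program is exact for the stated step set; other step
  patterns (e.g. slope constraints) are not implemented.
* The crossing filter counts polyline intersections; curves that merely
  touch tangentially may count as crossing.
* Unit screening assumes trials of comparable duration when pooling rate
  percentiles.
* `correct_initial_reach` requires both first and non-first strokes and
  assumes the reach effect is additive per unit and bin.
* The fixation decoder expects precomputed fixation events; eye-movement
  segmentation is out of scope.
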
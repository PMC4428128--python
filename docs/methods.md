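# Methods

This note documents the models, conventions and design decisions behind the
package — what is computed, under which assumptions, and what the synthetic
validation does and does not establish.

## Dispersion scores

Two variants of the window dispersion are provided via `metric_mode`:

* `as_printed` (default): average pairwise **squared** Euclidean distance.
  This is the formula the method is defined by, and every downstream default
  uses it. Squared distances make the score decomposable into per-matrix
  moments (mean, mean squared norm), which both the fast sliding-window path
  and the vectorized Monte-Carlo null exploit.
* `euclidean`: the square root is applied to each pairwise coordinate sum
  before averaging, for users who want the score in pixels rather than
  squared pixels. This path assembles matrices window by window and is
  slower.

Because only the *ordering* of dispersion scores relative to the null mean
enters the index, and both variants are strictly monotone transforms of each
other only in special cases, the choice can matter in principle; the
fraction-type index is, however, invariant to any strictly monotone transform
applied to all scores and the threshold together (tested).

Conventions:

* The between-rendition prefactor generalizes from 1/N² to 1/(N_V·N_W) so
  the score remains the mean over all pairs when blink-dropping leaves the
  two renditions with unequal column counts.
* The within-rendition sum runs over ordered pairs n1 ≠ n2 but is normalized
  by N², exactly as defined; no N(N−1) "unbiased" correction is applied. The
  constant factor is immaterial after null thresholding. A single-column
  matrix scores 0.
* Both scores are translation invariant, symmetric (the euclidean path sums
  distances in sorted order so symmetry is exact in floating point), and obey
  the c² / |c| scaling laws.

## Windowing and validity

The grid is 250 ms windows shifted by 50 ms (80% overlap), anchored at video
onset; T = ⌊(duration − 250)/50⌋ + 1. A recording's duration is taken as its
last timestamp plus one nominal sample period, truncated across streams to
the shortest common epoched span (renditions must cover the same segment) and
capped by the marker-derived video duration: the ±1000 ms epoch padding is
retained for inspection but never windowed.

Invalid samples (blinks, track loss, unparseable coordinates) are dropped
from matrices, never zero-filled. A window whose pooled valid-sample
fraction falls below `min_valid_fraction` (default 0.5) in *either*
rendition is flagged unusable: it receives label 0, is excluded from the
index denominator, and its window starts are excluded from the null
randomization pool.

## The Monte-Carlo null

The null hypothesis is that frames do not guide attention in any systematic
pattern. Each of the `n_samples` (default 1000) draws gives **every
contributing stream an independent** uniform-random usable window start of
the same video and viewing pool, then scores the pooled surrogate
renditions. Per-stream (rather than per-surrogate) randomization maximally
destroys cross-subject temporal alignment — exactly the structure the null
must lack — while preserving each stream's marginal gaze distribution.
Thresholds are per-video and per-mode. The "normal fit" is by sample
moments; only the mean D̄_null is consumed by the decision rule, so the fit
method cannot change results. Ties (D_t = D̄_null) are classified divergent.
Degenerate edge: if all gaze is constant, every null sample is 0, σ = 0, and
every usable window ties the threshold — the index saturates at 1. Fewer
than 2 usable windows to randomize over is an error.

## Index variants

The default `fraction` variant is the share of usable windows labeled
divergent, which lies in [0, 1] and is what all group-level results use.
The `weighted` variant, (1/T)·dᵀf over usable windows, is the literal
divergence-weighted sum: it weights each divergent window by its dispersion
and is unit-bearing (squared pixels). Both are reported with the usable
window count.

## Prediction and cross-validation

The preference model y = b₁·iGDI + b₀ is ordinary least squares
(`scipy.stats.linregress` under the hood), reported with r, R², F = R²(n−2)/
(1−R²) on (1, n−2) df and its two-tailed p. A constant response returns
b₁ = 0, r = 0 rather than NaN. Leave-one-out CV refits n times; the report
carries

* RMSE of held-out predictions,
* MAPE = 100·mean(|y−ŷ|/|y|) (absolute percentage; reported absent with a
  warning if any y = 0),
* R²_cv = 1 − SS_res(ŷ)/SS_tot(y) on held-out predictions (the definition
  consistent with shrinkage = R² − R²_cv; the squared-correlation
  alternative is available via `r2_cv_method="corr"`),
* sample SDs of (b₁, b₀) across the n refits.

A negative slope (more divergence → lower preference) is the expected
direction; it is reported, never enforced.

## Heart-rate variability

RMSSD(r) = sqrt( (1/(I−1)) Σ (r(i) − r(i+1))² ) in ms over a video's IBI
series, normalized per subject as percent change from a 5-min resting
baseline. Group analysis pairs each video×viewing's group-mean percent
change with that video's between-viewings index (12 videos × 2 viewings →
24 pairs, df = 22); the first-vs-second-viewing paired t-test is emitted for
transparency before the two viewings are pooled. Pearson r is reported with
Shapiro–Wilk normality checks on both variables (reported, not enforced).

PPG traces are reduced to IBIs by a zero-phase 4th-order Butterworth low-pass
at 7 Hz (the cutoff fixed by the acquisition design; the order is common
physiological practice), peak detection above an adaptive amplitude threshold
(mean + 0.3 SD) with a refractory distance equal to the minimum plausible
interval, and a programmatic sanity filter replacing manual beat editing: a
plausibility band (default 300–2000 ms) plus a running-median spike rule
(interval > 1.3× median flagged), both logged.

## The synthetic generator

The generator exists so every stage is testable against known ground truth;
it emulates the acquisition conditions the analysis targets (10 subjects ×
2 viewings, 30-s spots, 60 Hz, 1024×758 px screen) with a deliberately
parameter-sparse attention model:

* **Guided (storyline) path**: piecewise-constant fixation targets with
  Gaussian jumps (SD 100 px) mean-reverting toward screen center
  (`center_bias` 0.5), exponential fixation durations (mean 300 ms, clipped
  to 80–1500 ms), 40-ms linear saccades. The center bias mimics the strong
  central framing of produced video content.
* **Divergent segments**: inside designed segments each subject-viewing
  follows its own independent exploration path whose targets are uniform
  over the screen — unguided viewing roams. The separation of spatial
  scales between guided and unguided fixations is what makes designed
  divergence identifiable: aligned divergent windows then carry higher
  dispersion than the time-randomized null, whose mean mixes guided and
  unguided samples.
* **Noise and dropout**: per-subject Gaussian jitter (SD 15 px ≈ 0.5° at a
  60-cm viewing distance, the spatial accuracy an ordinary tracker holds),
  coordinates clipped to the screen (clips logged), and a Poisson blink
  process (0.25 blinks/s, 100–400 ms) marking samples invalid with NaN
  coordinates.

A note on saturation: for *any* generator whose divergent paths are
stationary and independent across subjects, the expected dispersion of an
aligned divergent window equals the null expectation once divergence covers
the whole timeline — time randomization changes nothing when no window is
aligned. The index therefore approaches ~0.5, not 1, as coverage → 1; it is
monotone and well separated over the coverage range the validation uses
(0–0.75), which is also the realistic regime.

The full-study fixture maps preference scores monotonically *down* to
divergence coverage (range 0.05–0.7 across the 12 reference scores) and
builds IBI series (AR(1) intervals, mean 850 ms, φ = 0.5, innovation scale
chosen so the expected squared successive difference matches the designed
RMSSD) whose baseline-relative change falls with coverage (intercept +5%,
slope −30%/coverage, subject noise SD 3%). Streams are emitted in recording
time with 1 s of center-fixation pre/post-roll so marker-based epoching is
exercised end to end.

What passing the synthetic validation shows — and what it does not: the
pipeline recovers designed divergence ordering, regression sign and
magnitude, and designed HRV coupling under a model whose gaze statistics are
far cleaner than real data (no smooth pursuit, no saliency structure, no
drift or calibration error, independent-noise subjects, stationary blink
process). Real-data effect sizes will be smaller and noisier; the synthetic
R² values in particular are upper bounds produced by a noiseless
score–coverage linkage, not forecasts.

## Numerical choices and degenerate inputs

* Moment-based dispersion accumulates per-stream prefix sums; round-off can
  produce tiny negative scores on near-constant windows, clamped at −1e−6.
* Monte-Carlo draws whose surrogate rendition ends up with zero valid
  samples (possible when a stream is fully blinked in a pooled-usable
  window) are dropped from the null sample.
* Window membership is the half-open interval [start, start + 250 ms); at
  60 Hz this holds exactly 15 samples per stream.
* Empty matrices, constant predictors, zero baselines, flat PPG signals,
  sub-2 IBI series, and zero usable windows raise typed errors
  (`igdi.errors`) rather than propagating NaNs.
* All simulation and null-sampling randomness flows through
  `numpy.random.Generator` seeded via `SeedSequence`; the CLI derives one
  child generator per video from the run seed, so adding or removing a video
  does not perturb the others.

## Problem sizes used in the shipped validation

Unit and property tests run on reduced cohorts (2–6 subjects, 2–10 s videos,
200–1000 null samples) — the statistics under test are scale-free. The
end-to-end acceptance test and `scripts/acceptance.py` run the reference
study size (12 videos × 10 subjects × 2 viewings, 30 s at 60 Hz, 1000 null
samples); one full pipeline pass takes a few seconds on one CPU.

## Known limitations

* The window-start null randomizes at window granularity only; sub-window
  phase is never shuffled.
* `model_agreement` compares labels over all jointly-usable windows, not
  only divergent ones.
* No frequency-domain HRV (HF/LF power), SDNN or pNN50; RMSSD only.
* No fixation/saccade event detection, scanpath string metrics, heatmap
  rendering or saliency modeling — the index is defined purely on raw gaze
  coordinates, which is the point.
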
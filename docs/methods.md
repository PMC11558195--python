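# Methods

This note documents the statistical model behind `hemospm`, the choices
made where the design was genuinely open, and what the synthetic-cohort
tests do and do not demonstrate about real clinical data.

## Preprocessing

Raw monitor streams are irregularly sampled floats in minutes since the
operation end. They are linearly interpolated onto the integer-minute
grid. Three rules interact:

- **Dropouts.** A maximal span of ≥ `dropout.min_gap` (default 3)
  consecutive minutes containing no raw sample is a dropout; dropout
  minutes are invalid and interpolation never bridges them. Shorter
  silent spans are interpolated. Dropout detection runs *before*
  interpolation so a gap can never be papered over.
- **Edges.** Minutes before the first or after the last raw sample are
  invalid but are reported separately from dropouts (they reflect
  transfer/discharge timing, not sensor failure). The per-sensor
  exclusion rule (invalid > 10 % of the horizon) counts both; excluded
  records are flagged, never silently dropped — the pipeline refuses them
  unless `io.allow_excluded` is set.
- **Hampel identifier.** On the gridded series, each point is compared
  with the median of its centered `hampel.window` = 11-minute window;
  points with |x − med| > t·MAD are replaced by the window median.
  Invalid entries are excluded from window statistics and edge windows
  are truncated (padding would fabricate data at the monitoring start,
  where alarms matter most). MAD = 0 (locally constant window) never
  flags: constant physiologic readings are plausible at 1-minute
  resolution and a zero threshold would flag everything.

**The threshold multiplier t is calibrated, not asymptotic.** The
identifier is parameterized by an allowed misidentification rate
`hampel.alpha` (default 0.05): the probability of flagging an in-control
Gaussian point. The textbook multiplier z₁₋α/₂·1.4826 attains this rate
only as the window grows; at window 11 the window MAD is biased low and
the ratio |x − med|/MAD is far from its asymptotic distribution, so the
asymptotic multiplier flags ≈ 9 % instead of 5 %. The default
(`calibration="simulated"`) therefore uses the (1−α) quantile of
|x − med|/MAD over iid standard-normal windows of the configured length,
computed once per (window, α) by an internally seeded Monte-Carlo
(4×10⁵ windows; deterministic across runs and platforms to Monte-Carlo
resolution ≈ ±0.001 on the rate). `calibration="asymptotic"` restores the
textbook multiplier. Note the calibration is exact for iid data; on
smooth autocorrelated series the studentized ratio has lighter tails and
the realized flag rate runs *below* nominal (≈ 1–2 % on the default
generator) — conservative in the right direction for data cleaning.

The filter is deliberately single-pass. It is not idempotent: replacing a
flagged point shrinks neighbouring windows' MAD, so a second pass can
flag new points (the flag count is non-increasing over passes, which the
tests assert). Iterating to a fixpoint would progressively flatten
genuine physiologic variability.

## Batch-wise normalization

The cohort is an I×J×K array of patients × lag-augmented signals ×
minutes. Each base signal carries `lags.n` = 2 time-lagged copies
(columns are HR, HR−1, HR−2, ABP_SYS, …; minutes k < lag are invalid —
never padded). Each (column, minute) cell is standardized by the training
cohort's mean and sample SD (ddof = 1) across patients, which removes the
shared recovery trajectory and its time-varying variability. Choices:

- **SpO₂ anchor.** SpO₂ columns (all lags) use the fixed reference
  (100 %, 5 %) instead of cohort statistics: saturation has an absolute
  ceiling, and cohort standardization would magnify clinically trivial
  sub-percent dips. Consequently SpO₂ columns may have nonzero mean in
  the unfolded matrix; the PCA re-centers columns and stores the training
  mean.
- **Lagged columns** are standardized with their own (column, minute)
  statistics, which equals lagging the normalized base signal while
  respecting the lag offset — one uniform code path.
- **Degenerate cells.** Cells with < 2 valid patients inherit the nearest
  valid minute's statistics (same column); SDs are floored at
  `normalization.sigma_floor_rel` = 10⁻³ × the column's median SD so a
  degenerate cell can never divide by zero. Both events are cohort-edge
  phenomena at desk scale.

Rows of the variable-wise unfolded (I·K)×J matrix with any invalid entry
are excluded from fitting; a monitored patient's chart shows a gap (not
an alarm) at such minutes.

## Latent-variable models

PCA eigendecomposes the sample covariance B = XcᵀXc/(n−1) = UΛ²Uᵀ via
SVD. The 1/(n−1) scaling (rather than raw XᵀX) makes the score matrix
S = XcUΛ⁻¹ have exactly identity training covariance, which is what makes
the χ² chart distributions below hold. Sign convention: each loading
column's largest-magnitude entry is positive (reproducible across SVD
backends). Singular values below 10⁻⁸ of the largest are excluded from
sphering (their scores are fixed at 0) to keep Λ⁻¹ bounded.

The retained count c defaults to 3 (`pca.c`); with `pca.c: null` it is
chosen per fit as the knee (maximum discrete curvature) of the
(index, log eigenvalue) scree curve, raised if needed to the smallest c
reaching `pca.coverage` = 98 % cumulative variance; a flat spectrum falls
back to the coverage rule directly. The default is fixed rather than
re-selected per fold so all leave-one-out folds share one model order.

SFA sphere-and-rotate: Z = XcUΛ⁻¹, A = ŻᵀŻ/(n_deriv−1) with backward
differences Ż taken only within a patient's contiguous valid minute runs
(differencing across patients or across gaps would fabricate enormous
derivatives). A = PΩPᵀ with eigenpairs ordered by ascending Ω
("slowness" = mean squared derivative of the unit-variance feature: a
unit-variance sinusoid of period T has slowness ≈ (2π/T)²). Scores
XcUΛ⁻¹P keep identity training covariance (P is orthonormal) and preserve
total score energy relative to PCA. The slow-feature count d defaults to
c. Normalizing A by its sample count scales Ω but not the features or
their order.

## Control charts

With identity training-score covariance, the retained-block Hotelling
statistic reduces to a squared norm, and under the null

T² = ‖s₁:c‖² ~ χ²c,  T²,d = ‖s₁:d‖² ~ χ²d,  T²,e = ‖s_d+1:J‖² ~ χ²_{J−d},

monitored against flat (1−α) quantiles with `charts.alpha` = 0.01. The
residual SPE has no χ² form; its per-minute limit uses the Box
moment-matching approximation g·χ²ₕ with g = v/2m, h = 2m²/v from the
training cohort's SPE mean m and variance v at that minute. With small
cohorts those moments are noisy, so the raw training SPE samples are
pooled over a centered `spe.window` = 5-minute window before computing m
and v (pooling the samples is stabler than smoothing m and v
afterwards); h is real-valued, so the non-integer-degree χ² inverse CDF
is used. Minutes with unresolvable moments borrow the nearest resolvable
minute's limit. Alarm sparks are maximal runs of limit crossings;
`alarms.min_duration` defaults to 0 (no debouncing).

**Finite-cohort calibration.** The χ² limits are asymptotic in the number
of training patients I. Two finite-I effects push the held-out
false-alarm rate above α:

1. Per-minute standardization estimated from I patients makes a held-out
   z-value t-distributed with variance (1 + 1/I)(I−1)/(I−3) — ≈ 1.08 at
   I = 40 — independent of the data-generating parameters. This alone
   lifts the T² (c = 3) exceedance from 1.0 % to ≈ 1.5 %.
2. Patient-level baseline offsets persist for a whole stay, so the
   covariance of the between-patient structure is effectively estimated
   from I samples; its eigen-overfit adds a further, seed-dependent
   inflation when offsets carry a substantial variance share.

At the package's calibration conditions (40 training / 20 monitored
patients, 1-day horizon) the measured pooled T² false-alarm fraction is
≈ 0.015–0.03 against the nominal 0.01, and the T²,d percentile coverage
≈ 97.7–98.7 % against the nominal 99 % — reproduce with
`scripts/acceptance.py`. The charts keep the asymptotic χ² limits
because that is the method's standard form; users monitoring against
small cohorts should read the limits as approximate and expect the true
false-alarm rate to sit above α by roughly these factors. (A Hotelling-
style F correction assumes the *entire* score covariance is estimated
from I samples and overcorrects here, where within-patient variation
contributes many more effective samples.)

## Synthetic cohort

The generator emulates a postoperative cohort with known ground truth:

- **Baselines** (monotone-cubic through knots over 7 days): HR
  152→142 bpm mild decline; arterial pressures dip over the first half
  day and recover (e.g., mean ABP 48→42 at hour 12, →52 by hour 36);
  SpO₂ 99.5→97 % slow decline. Values are illustrative clinical
  magnitudes — tests compare generated data against the template's own
  declared parameters, never against any external cohort.
- **Patient-level offsets**: per-signal scalars, correlated across
  signals, scaled by the between-patient SD (HR 6, ABP 4–5, SpO₂ 1).
- **Within-patient noise**: AR(1) with φ = 0.95 (≈ 20-minute correlation
  time) and marginal SD (HR 7, ABP 5–6, SpO₂ 1.2), innovations correlated
  across signals (ABP channels 0.8–0.9, HR–ABP 0.25, SpO₂ 0.1). AR(1) is
  the minimal model that gives the lag structure making 2-lag
  augmentation meaningful.
- **Emission**: samples every 30 s with ±6 s timestamp jitter (exercises
  the resampler); SpO₂ clipped at 100 %.
- **Injection**: mean shifts (in cohort-marginal-SD units — the unit of
  the trajectory-map band), variance inflation, correlation breaks, spike
  trains, and dropout/outlier contamination with full bookkeeping.
  Spikes snap to the sample nearest an integer minute so they survive
  linear re-gridding at full amplitude.

What this generator does **not** emulate: non-Gaussian heavy-tailed
physiologic noise, regime switches (sedation changes, interventions),
slowly drifting per-patient offsets, non-stationary variance, or
sub-minute waveform structure. Passing calibration tests therefore shows
the machinery is correct under its stated assumptions, not that real
postoperative data meets them; in particular real alarm rates will
deviate further from nominal than the finite-cohort analysis above
predicts.

All randomness flows through explicit seeds; there is no global random
state, and regenerating with the same seed is bit-identical.

## Pipeline & evaluation

Leave-one-out cross-validation refits *everything* per fold —
normalization, PCA, SFA, and all limits — on the I−1 training patients,
so a patient's own data never influences the charts that judge it (the
tests assert byte-identical fold models under tampering with the held-out
patient). Trajectory maps (per-minute cross-patient mean ± sample SD) are
computed on raw signals in physical units and are undefined at minutes
with < 2 valid patients. The calibration study sizes (40 + 20 patients,
1440-minute horizon; 10⁵ points for the Hampel rate) were chosen to make
Monte-Carlo error small relative to the rates being measured while the
whole suite stays interactive on a laptop.

## Known limitations

- χ² limits are asymptotic in cohort size (quantified above); no
  finite-I corrected limit is offered by default.
- One global model per cohort: no patient clustering, no multi-phase
  monitoring, no adaptive/recursive updates, no fault
  reconstruction/contribution analysis.
- The Hampel calibration targets iid Gaussian nulls; on smooth series it
  is conservative.
- Coarse clinical-note frames map to fixed 6-hour blocks anchored to
  calendar days offset from the operation end — a convention, since
  note-taking practice varies.
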
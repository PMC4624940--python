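# Methods

`rfdkit` processes isometric force–time recordings from dynamometers —
hand-held devices (HHDs) pressed against a limb, and fixed laboratory
dynamometers used as the criterion reference — into two outcome measures:
**muscle strength** (peak force, kg) and **muscle power** (rate of force
development, RFD, kg/s), and then quantifies how reliable and valid those
outcomes are across sessions, assessors, and devices.

## Signal conditioning

Raw traces arrive on three device profiles: stable 40 Hz, unstable ~100 Hz
(wireless streaming with timestamp jitter), and stable 1000 Hz. Every trace
is brought to a common representation before analysis:

1. **Cubic-spline resampling to 1000 Hz.** A not-a-knot cubic spline is fit
   through the recorded samples and evaluated on a uniform grid starting at
   the first sample time, never extrapolating past the last. Not-a-knot ends
   reproduce cubic polynomials exactly and need no boundary-derivative
   information, which jittered recordings cannot supply. Timestamps are
   trusted as given; no clock correction is attempted.
2. **Zero-phase low-pass Butterworth filtering**, 10 Hz cutoff, order 4
   (the design order; the forward–backward pass squares the magnitude
   response and cancels phase). Edges are padded by odd reflection over
   3× the filter state length, the conventional choice. The double-pass
   response leaves 1 Hz content attenuated by < 0.01% and puts ≥ 110 dB of
   attenuation at 100 Hz, comfortably past the 60 dB the pipeline promises
   at 5× the cutoff.

**Order of operations.** Zero-phase filtering is only well defined on a
uniform grid, and two of the three profiles are not uniform, so the default
pipeline resamples first and filters second; for uniform input the opposite
order (exposed as `filter_first=True`) agrees to within interpolation error
and is verified to ~1e-9 kg in the tests.

**Idempotence.** Literally re-filtering an already-filtered trace would
attenuate residual passband content a second time (~0.01 kg on a typical
contraction), so filtered traces carry a metadata tag and
`preprocess_trace` skips an identical second pass. Re-preprocessing is
therefore exactly idempotent.

## Strength and power

* **Peak force** is the highest force sample over all trials of a trial set
  (typically two maximal contractions), ties broken to the earliest sample
  of the lowest-index trial.
* **RFD** is computed by 14 algorithm variants in three families:
  time-to-peak-force; peak slope between first crossings of two
  percent-of-peak-force thresholds (5–95 … 40–60 %, crossings located
  sub-sample by linear interpolation on the rise to the first peak); and
  the peak chord slope of a fixed-length window (10/20/50/100/200 ms) slid
  sample-by-sample along the whole trace. No contraction-onset detection is
  performed: all searches start from the first recorded sample, which makes
  the moving-window family robust to initial contact artifacts whose slope
  is below the true rise.
* Thresholds in the percent-window family reference the *per-trial* peak
  (each contraction is an independent effort); the across-trials aggregate
  for RFD defaults to the maximum, mirroring the peak-force rule, with
  `mean` and `best_trial` exposed as alternatives. A trial whose thresholds
  are never crossed before its first peak yields a flagged missing value
  (NaN), not an exception, and propagates through the battery.
* Window lengths convert to samples as `round(window_ms * rate / 1000)`;
  exact at 1000 Hz. All ties break to the earliest occurrence, so outputs
  are deterministic.

The percent-window slope is the *endpoint* slope between the two crossings
(consistent with a fixed force position and variable duration); a maximal
sub-slope search between the thresholds would be a different statistic and
is intentionally not the default.

## Agreement statistics

For each (muscle, metric) cell of a long-format measurement table, pairing
one factor (session, rater, or device) with the others held fixed:

* **ICC(2,1)** — two-way random-effects, absolute-agreement,
  single-measures intraclass correlation from the two-way ANOVA mean
  squares, `(MS_R − MS_E) / (MS_R + (k−1)MS_E + (k/n)(MS_C − MS_E))`, k = 2.
  The 95% CI is the Shrout–Fleiss / McGraw–Wong F-based interval with
  Satterthwaite degrees of freedom; estimates may be negative. At n = 50
  the interval is mildly conservative (~96% empirical coverage in the
  acceptance simulations).
* **SEM** = SD₁·√(1 − ICC), with SD₁ the first-session SD, reported
  absolutely and as % of the first-session mean (the reference mean is
  configurable to the pooled mean).
* **MDC** in two first-class variants, because both are in active use:
  `1.96·√2·SEM` (ratio 2.7719) and `1.96·SEM` (ratio 1.96). Every report
  labels which variant it used.
* **Pearson r** (association only) and **Lin's concordance r_c**
  (association plus closeness to the identity line, biased 1/n moments);
  both with Fisher-z 95% CIs. `|r_c| ≤ |r|` holds identically.
* **Bland–Altman 95% limits of agreement.** Differences d = x − y are
  screened against averages a = (x+y)/2; if |corr(d, a)| > 0.50
  (proportional bias, absolute value so negative trends also trigger), the
  regression-based variant is used: the bias line is the OLS fit of d on a
  and the limits are that line ± 1.96·√(π/2) times the OLS fit of
  |residual| on a (half-normal correction). Otherwise mean(d) ± 1.96·SD(d).
* **Interpretation bands** — excellent ≥ 0.90, good 0.75–0.89, moderate
  0.50–0.74, poor < 0.50 — applied after rounding to 2 decimals, half away
  from zero, so classification matches what a report prints.
* **Method comparison** summarises a per-muscle ICC column by median,
  25th/75th percentiles (linear interpolation, quantile type 7), and the
  count of muscles below the 0.75 good-reliability threshold.

Missing outcomes are explicit NaN throughout and are removed
pairwise-complete per cell; cells with fewer than 3 complete pairs are
flagged, never fatal. Rounding for report parity is 2 decimals, half away
from zero, with a decimal-arithmetic guard so binary float representation
(0.785 stored as 0.78499…) cannot flip a tie downward.

## Synthetic data

The generator defines the conditions under which the toolkit is tested.

* **Traces** are logistic contractions
  `F(t) = baseline + f_max / (1 + e^{−k(t−t0)})` over 3–5 s (default 4 s),
  emulating a rapid rise to a steady maximal force. Defaults: f_max 30 kg,
  k 15 /s, t0 1 s — an instantaneous peak RFD of f_max·k/4 = 112.5 kg/s,
  inside the range seen across lower-limb muscle groups. The family has
  closed-form threshold crossings `t0 + ln(p/(1−p))/k` and window chords
  `f_max·tanh(k·w/4)/w`, which the tests use as analytic oracles. Device
  grids: exact 40 Hz and 1000 Hz, and ~100 Hz as 10 ms nominal intervals
  with i.i.d. uniform ±3 ms jitter, sorted. Additive Gaussian measurement
  noise and an optional half-sine initial contact bump are available.
* **Cohorts** follow an additive Gaussian variance-component model per
  muscle: grand mean + subject effect + subject×rater + subject×device +
  subject×session + residual, so the test–retest ICC of the generating
  process is `(σ²_s + σ²_r + σ²_d) / (σ²_s + σ²_r + σ²_d + σ²_sess + σ²_e)`
  in closed form. Defaults (29 subjects, 2 raters, 2 devices, 2 sessions,
  8 muscle groups with means 14–51 kg; variances 9/0.5/0.5/0.5/0.5 kg²,
  theoretical ICC ≈ 0.91) describe a healthy-young-adult protocol with
  good-to-excellent reliability. Heteroscedastic noise (SD ∝ mean) and
  fixed per-device offsets are available to exercise the regression-based
  Bland–Altman branch and the agreement-vs-association distinction.

What the generator does **not** emulate: fatigue across trials,
non-sigmoid force profiles (tremor, double efforts), device saturation, or
non-Gaussian between-subject distributions. Passing tests therefore show
the algorithms are correct on well-behaved contractions and that the
statistics recover known parameters — not that any physical device is
reliable.

## Problem sizes and numerical choices

The simulation-based checks use 10 cohorts of n = 2000 subjects per ICC
level for estimator consistency (single-cohort sampling error of ICC(2,1)
at ICC = 0.5, n = 2000 is ≈ 0.017, so a one-shot ±0.01 check would mostly
measure Monte-Carlo noise; the 10-cohort mean pins it to ≈ 0.005), and
100 replicates per level at n = 50, pooled over the three levels (300
intervals), for CI coverage. Tolerances: analytic-limit recovery 1%,
oracle equivalence exact (moving-window) or 1e-10 (ICC vs variance
components), printed-table MDC arithmetic ±0.02 (propagation of the
2-decimal rounding of published SEM values).

## Known limitations

* The percent-window family is undefined for non-monotone artifacts that
  reach peak before both thresholds; such trials are flagged missing.
* The regression-based limits of agreement assume |residuals| vary
  linearly with the average; strongly nonlinear heteroscedasticity is not
  modelled.
* ICC(2,1) assumes the two-way random-effects model; severe non-normality
  or outliers will distort both the estimate and its F-based interval.
* The spreadsheet reader is a convenience for long-format exports only; it
  does not attempt to parse arbitrary workbook layouts.
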
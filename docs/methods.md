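# Methods

This note documents the models, conventions and design choices behind
`drowsyhrv`, and what the synthetic validation does and does not show.

## Signal model and simulator

The inter-beat-interval (IBI) generator treats the instantaneous interval
as a base level plus sinusoidal modulation at one representative frequency
per classical HRV band:

    ibi(t) = m(t) + a_vlf sin(2π·0.02·t + φ₁) + a_lf(t) sin(2π·0.1·t + φ₂)
                  + a_hf sin(2π·0.3·t + φ₃) + ε,   ε ~ N(0, σ_jitter²)

Beats are placed iteratively (`t_{k+1} = t_k + ibi(t_k)`), so the recorded
ground truth satisfies `ibi[k] = beat_times[k+1] − beat_times[k]` exactly.
Defaults: `m = 0.9 s` (~67 bpm), `a_vlf = 0.01 s`, `a_lf = a_hf = 0.03 s`
(balanced sympathovagal modulation, LF/HF = 1), `σ_jitter = 5 ms`.  The
implied LF/HF of a configuration is the amplitude power ratio
`(a_lf/a_hf)²`.

**Drowsy regime.** Drowsiness is modelled as a *sustained* state, not a
transition: relative to the same subject's alert parameters the mean
interval is raised by 0.1 s (drowsiness slows the heart) and both the mean
interval and the LF amplitude follow seeded piecewise-linear drift
schedules (breakpoints every 120 s; mean wanders ±0.05 s around its raised
level, LF amplitude between 1× and 3× the alert value).  Every 1-minute
window therefore contains genuine within-window drift — the
nonstationarity that motivates wavelet analysis — and the LF/HF ratio is
elevated on average but variable.

**Alert variability.** Perfectly stationary alert sessions would make
LF/HF an artificially perfect discriminator.  Real alert HRV fluctuates,
so simulated subjects get mild alert-state wander: mean ±0.02 s, LF
amplitude 0.6–1.4×, on the same 120 s breakpoint grid.  Both wander
mechanisms are off by default in `SimConfig` so that explicitly configured
amplitudes produce exactly the requested modulation; the experiment
pipeline switches them on.

**PPG rendering.** Each beat contributes an asymmetric raised-cosine pulse
(0.35 s wide, 30 % rise fraction — fast systolic upstroke, slow diastolic
decay) whose maximum falls on the sample nearest the true beat time.
Baseline wander is a slow sinusoid (default 0.05 Hz); motion artifacts are
an even mix of smoothed level steps (~0.5 s transition, a hand shifting
its grip) and triangular ramp bumps (0.4–0.8 s half-width), with heights
0.3–0.8 pulse amplitudes and a configurable Poisson rate.  These are the
additive, low-frequency disturbance classes that first-order differencing
is designed to remove; their severity in the original study population is
unknown, so the artifact parameters are free knobs rather than calibrated
values.

What the simulator does **not** reproduce: realistic pulse morphology
(dicrotic notch, amplitude modulation by respiration), ectopic beats,
sensor saturation, and broadband 1/f interval dynamics.  Passing tests
demonstrate correctness of the processing chain and the *direction* of the
wavelet-vs-FFT comparison under these controlled conditions, not clinical
performance on real drivers.

## Preprocessing

Differencing: `v[x] = (y[x] − y[x−1])·fs`.  A constant offset maps to
zero, a linear drift to a constant — hence its role as artifact removal.

Beat detection runs on the differenced signal by default (a raw-domain
variant is available):

1. smooth with a 0.1 s moving average;
2. subtract a 0.35 s centred moving-average baseline — drift offsets and
   second-scale artifact bumps are removed while the ~0.1 s systolic
   upstroke passes nearly untouched;
3. threshold at 0.5 × the rolling 75th percentile (5 s window) of the
   positive part, floored at 0.25 × the rolling maximum so the threshold
   cannot collapse in quiet stretches;
4. refractory period 0.3 s (caps heart rate at 200 bpm);
5. reject candidates > 4 × the median candidate height (pulse upstrokes
   are homogeneous; an isolated huge detection is a step transient);
6. require a diastolic downstroke: within 0.35 s after the candidate the
   (median-offset-corrected) differenced signal must fall below −0.15 ×
   the candidate height.  A monotone step artifact has no matching
   negative lobe and is rejected; every real pulse does;
7. refine each detection to the raw-waveform maximum within ±0.15 s and
   re-impose the refractory period.

Steps 2, 3 (floor), 5 and 6 extend the minimal quantile-threshold design:
implementing the properties the detector must satisfy (trend invariance,
artifact-count preservation) showed that a bare positive-quantile
threshold is inflated by the constant offset a linear drift leaves after
differencing, and that ~0.5 s artifact bumps cross it.  The added stages
are standard PPG-detector ingredients (slope-sum baselining, amplitude
homogeneity, upstroke/downstroke pairing) and keep the detector
parameter-light.

Interval validation: intervals < 0.3 s drop the extra (false) beat and
merge; intervals > 2.0 s, and intervals differing from the previous valid
interval by more than 75 %, are excluded from the series.  This protects
the spline from ectopic/missed beats that pure differencing cannot fix.

## HRV series

Each valid interval is anchored at the time of the *second* beat of its
pair (the moment the interval becomes known — the common tachogram
convention).  A cubic spline (natural boundary conditions; configurable)
interpolates the (knot, interval) pairs and is evaluated on a uniform 7 Hz
grid from the first to the last knot, never extrapolating.  Spline
overshoot is clipped into (0.3, 2.0) s.  Windows (60/120/180 s) are cut on
the resampled grid, non-overlapping by default; simulated "10-minute"
sessions are generated 615 s long so the knot-to-knot grid spans ten full
1-minute windows.

## Spectral estimation

Mean removal, Hann taper.  Windows shorter than ~2 min use a single-taper
periodogram; longer windows use Welch averaging (64 s segments, 50 %
overlap) to reduce estimator variance.  One-sided density scaling, so the
integrated PSD is an unbiased estimate of the window variance (the suite
verifies this in expectation; a single noise realization fluctuates by
~±15 %).  Band powers integrate the density by the trapezoid rule over
closed bands; a bin landing exactly on a shared edge is credited to the
lower band.  LF/HF is NaN (never infinity) when HF power is zero, and such
windows must be excluded downstream.  Known bias: spline interpolation of
sparse beats attenuates HF power when intervals lengthen (fewer knots per
HF cycle), which inflates LF/HF for slow heart rates; this is inherent to
the spline+FFT method, affects real recordings the same way, and is one
reason the drowsy class separates strongly here.

## Wavelet features

8-level Mallat cascade, Symlet-3, symmetric padding (configurable; tests
pin the mode).  Depth 8 on a 420-sample window deliberately exceeds the
usual boundary-effect heuristic (max "safe" level 6): the coarsest levels
are then boundary-dominated, but they are computed identically for every
window, and the A8 band (0–0.014 Hz) is precisely where sustained mean
shifts and slow trends land.  Features are computed on raw decomposition
coefficients, not reconstructed band signals.

Conventions: entropy is the unnormalised wavelet Shannon entropy
`−Σ c² log₂ c²` in bits — an energy-weighted measure whose magnitude
(~10⁴ for interval-scale inputs) grows with signal energy; for
coefficients with magnitude > 1 it is negative, so its *magnitude* carries
the information and the ROC/SVM stages are direction- and sign-agnostic.
Variance is unbiased (`ddof=1`); kurtosis is the non-excess standardised
fourth moment (Gaussian → 3).  `β` for the pair (D_{j+1}, D_j) is the
local slope of log₂ coefficient variance across one dyadic scale step, a
spectral-exponent surrogate; it is invariant to global rescaling of the
window.  Degenerate zero-variance levels impute kurtosis = 3 and β = 0
with a warning — on realistic data they indicate upstream failure.
Energy conservation holds exactly only for the orthogonal variant
(periodization mode on dyadic lengths), which is how the suite tests it;
symmetric padding introduces boundary redundancy.

## Feature selection and classification

ROC area is the normalised Mann-Whitney statistic (ties credited 0.5),
drowsy as positive class; features are ranked by `|area − 0.5|` because
reliably *low* areas are as informative as high ones, with the 0.7/0.3
acceptability convention.  T-tests default to the pooled-variance variant
(Welch available); no multiple-testing correction by default (a
Benjamini-Hochberg flag is a caller choice).

The SVM backend is scikit-learn's libsvm solver; every fit is verified
against the dual constraints (0 ≤ λ ≤ C, Σλy = 0, tolerance 1e-3) and the
test suite checks decision values against a direct quadratic-programming
solution on small instances.  Features are z-scored on the training fold
only — A8 entropy (~10⁴) and LF/HF (~1) differ by four orders of
magnitude, and leaking the held-out sample into the scaler would bias
leave-one-out.  Grid: linear and RBF kernels, C and γ in {10, 1, 0.1};
best cell by accuracy, ties broken toward the linear kernel, then smaller
C.  A decision value of exactly 0 classifies as drowsy — the fail-safe
direction for an alarm.  Leave-one-out on exactly balanced labels is
pessimistically biased under the null (the training majority votes against
the held-out sample), so permutation tests assert "no better than chance"
rather than "exactly 50 %".

## Labeling and the scaled-down comparison

PERCLOS bands: [0, 0.30) alert, [0.30, 0.40] drowsy (0.30 assigned
drowsy, fail-safe), above 0.40 excluded — the protocol this package
mirrors never produced such windows.

The synthetic-cohort comparison (4 subjects × 20 one-minute windows,
drowsy nonstationary) is evaluated over 20 seeded replications: per seed,
the A8-entropy must match or beat LF/HF in mean ROC distance and in
single-feature leave-one-out accuracy (RBF, γ = 0.1, C = 1).  Success per
seed is "the ≥ holds" (ties count toward ≥, since that is the claim), and
a one-sided binomial sign test across seeds requires p < 0.05.  Problem
sizes throughout the suite (120–615 s sessions, 20-sample cohorts, 20
seeds) were chosen as the smallest scales at which the tested properties
are stable.

## Known limitations

- Sinusoid-plus-drift interval dynamics are a caricature of real HRV;
  broadband and fractal structure is absent, which flatters every
  narrowband estimator.
- The A8/D8 coefficients of a 1-minute window are boundary-dominated at
  depth 8; absolute feature values depend on the padding mode (pinned and
  recorded in the manifest).
- The multiscale β definition (adjacent-pair log-variance slope) is one of
  several in use; it is isolated behind a single function so an
  alternative can be swapped in.
- No probabilistic outputs, multi-class states, or streaming operation.
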
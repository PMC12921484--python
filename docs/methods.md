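# Methods

This note documents the models, rules and numerical choices behind
`greendose`, in the order data flows through the package.

## Session model

A session is 20 min at 128 Hz (256 Hz supported; consumer headsets in this
class typically down-sample 256 → 128 Hz internally) on the 14-channel 10–20
montage AF3, F7, F3, FC5, T7, P7, O1, O2, P8, T8, FC6, F4, F8, AF4, in
microvolts. Minutes 0–4 are the stress-induction phase (arithmetic task,
elevated β); minutes 4–20 are the exposure phase at one of three
environments (UP urban park, RF remnant forest, WP wetland park) under an
open-eyes (OE) or blindfold (BF) condition.

## Synthetic cohort generator

**What it emulates.** The relative band-power composition (θ, α, β fractions
of the 4–32 Hz total) follows a piecewise envelope: constant during stress,
then a logistic relaxation toward a recovered asymptote,

    f_b(t) = L_b + (A_b − L_b) · g(t),
    g(t) = (σ(s(t − t_mid)) − σ₀) / (1 − σ₀),   σ₀ = σ(s(4 − t_mid)),

with σ the standard logistic. Anchoring at the phase boundary makes the
envelope exactly continuous at t = 4 min; all bands share `t_mid` and slope
`s`, so the three fractions sum to one identically. The signal is a sum of
three band-limited Gaussian noise processes — synthesized in the frequency
domain as complex-Gaussian coefficients on the in-band bins, i.e. ideally
filtered white noise — each amplitude-modulated by √f_b(t) and scaled to a
20 μV RMS total.

**Defaults (the simulated study conditions).** Stress fractions
(θ, α, β) = (0.15, 0.25, 0.60) — β-dominated, as after stress induction;
recovered asymptotes (0.20, 0.45, 0.35) — α-dominated relaxation;
`t_mid` = 12 min, `s` = 1 min⁻¹ for a single cohort; the three-environment
demo uses `t_mid` = 8 (UP), 10 (WP), 12 (RF) min, encoding the faster
physiological recovery in the urban park. Between-participant variation:
Gaussian jitter on `t_mid` (SD 1.5 min, clipped to [4.5, 19.5]) and
mean-preserving log-normal jitter on the asymptote triple (SD 0.10,
renormalized to sum to one). Sensor noise: additive white noise, SD 5 μV.
Artifacts: blinks as raised-cosine transients of 0.2–0.5 s and
150–300 μV on AF3/AF4/F7/F8 only at 8/min (blinks are frontal, giving the
ICA a spatially localized target); 50 Hz line noise at 5 μV; spikes of
150 μV (3-sample, polarity matched to the underlying sample so the ±100 μV
threshold is provably exceeded) with probability 0.02 per 30-s window.
These values are field-plausible choices, fixed once; none is prescribed by
a data sheet.

**Determinism.** One master seed; participant `i` uses the substream
`SeedSequence(entropy=seed, spawn_key=(i,))`, so recordings are
bit-reproducible regardless of generation order.

**Ground truth.** `true_thresholds` applies the *same* detection rules as
the estimation path to the analytic envelope on the same 0.5-min dose grid.
Because the estimator averages participants pointwise, its target is the
population-mean trajectory; with t_mid jitter that mean is flatter than any
single participant's logistic, so the ground-truth envelope marginalizes
over the jitter distribution by Gauss–Hermite quadrature (41 nodes, same
clipping as the generator). With zero jitter this reduces to the plain
logistic. Asymptote-level jitter is mean-preserving to second order in its
small SD and is not marginalized. For the β/α index the expectation is taken
of the ratio (matching pointwise-mean aggregation), not the ratio of
expectations.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: non-stationarities other than the recovery
envelope (drowsiness, movement epochs), muscle (EMG) broadband artifacts,
inter-channel correlation structure of real scalp fields (channels are
independent here, except blinks), non-logistic or non-monotone true
recovery shapes, and any dependence of EEG on the actual sensory content of
an environment. Parameter-recovery results certify the estimation chain,
not the field validity of the recovery model.

## Preprocessing

Zero-phase (forward–backward) filtering throughout, so the 30-s grid is
never time-shifted — a causal filter would bias every threshold late.
Band-pass: 4th-order Butterworth, 0.16–43 Hz. Notch: IIR, 50 Hz, Q = 30.
Only the cutoffs are part of the acquisition contract; family, order and Q
are exposed in `FilterConfig`.

Blink removal: FastICA decomposition (unmixing fitted on a 4×-decimated
copy — the mixing is time-invariant — then applied at full rate; 300
iterations, tol 1e-3, fixed random state). Components whose full-rate time
course correlates with |r| ≥ 0.7 against a blink reference (the 1–4 Hz
band-passed mean of the frontal channels) are zeroed before reconstruction.
If nothing is flagged the recording passes through unchanged and a notice is
logged. Amplitude rejection: a 30-s window is flagged iff any channel sample
exceeds ±100 μV; granularity is fixed at the analysis window so rejection
bookkeeping aligns with the feature grid. Stage order is band-pass → notch →
ICA → rejection (rejection counts before ICA are logged too, keeping the
order's effect visible): blinks would otherwise condemn most windows before
the ICA could repair them.

## Spectral features

Per 30-s window: Welch PSD (4-s Hann segments, 50 % overlap, constant
detrend; ≤ 0.25 Hz resolution; a raw single-FFT periodogram is available as
`method="fft"`). Band powers integrate the density over half-open bins
[low, high) — 13 Hz belongs to β, an explicit tie-break — and are averaged
across channels *before* normalization by the 4–32 Hz total. Indices:
rel_α = f_α, rel_β = f_β, β/α = f_β/f_α (the shared denominator cancels, so
the fraction ratio equals the power ratio; f_α = 0 marks the window
invalid), rel_(α+θ) = f_θ + f_α. Under the 4–32 Hz total the last is
identically 1 − rel_β; the identity is asserted in tests rather than
hidden, and widening the total band in `BandDefinition` breaks it
deliberately for anyone wanting an independent (α+θ) index. Invalid windows
are flagged, never dropped, keeping all participants on one rectangular
grid; a participant with > 50 % invalid windows is excluded (logged with a
reason).

## Group curves and thresholds

Aggregation is the pointwise mean over participants with a valid window
(invalid windows excluded per point, not per participant); pointwise SD and
n are kept. Interior points with n = 0 are linearly interpolated and
flagged; an empty boundary point is an error (no extrapolation).

The exposure-phase trajectory is fitted with a cubic smoothing spline whose
penalty is chosen by generalized cross-validation
(`scipy.interpolate.make_smoothing_spline`), overridable by a fixed `lam`.
A spline rather than a parametric family because real group curves can be
non-monotone (e.g. a relative-α decline in a forest), which a logistic
cannot express. Fitted values and the analytic spline derivative are
evaluated on a uniform 0.5-min dose grid over [4, 20] min — thresholds are
reported on that grid, which requires extrapolating the quarter-window from
the first/last 30-s midpoint (4.25, 19.75) to the phase boundaries.

Detection, with gain g(t) = d·(f(t) − f(4)) and direction d from the index
semantics (+1 rel_α, −1 rel_β, −1 β/α, +1 rel_(α+θ)):

- ET = earliest grid point with g′(t) ≥ κ·max g′, default κ = 0.5;
- BT = earliest grid point ≥ ET with g(t) ≥ (1 − δ)·max g, default δ = 0.05;
- no recovery: max g below the detection floor (next paragraph) — no ET/BT
  reported;
- ET at the first grid point sets an `et_at_boundary` flag (recovery already
  under way when exposure starts); a materially negative derivative
  anywhere sets `non_monotone`.

The verbal definitions — "onset of rapid recovery", "begin to plateau" —
admit many formalizations; the κ-fraction-of-max-derivative and
(1−δ)-of-max-gain rules are their minimal quantitative reading, and both
constants are config-exposed and echoed in every output row.

**Detection floor.** On an exactly flat noiseless curve max g ≤ 0 suffices,
but a fitted curve through noisy group means always has a positive maximum
gain somewhere. A recovery is therefore declared only when
max g exceeds the null bound for a flat trajectory:
`t_{0.99, n−1}/z_{0.99} · √2 · √(2 ln m) · median SE`, where SE = sd/√n per
window, m is the number of exposure windows (max over m comparisons), √2
accounts for the difference of two noisy means, and the Student-t ratio
inflates the bound when the SD itself comes from few participants. The
floor is zero for noise-free input, flags flat cohorts reliably at n = 2,
and sits several-fold below the gain of every genuinely recovering cohort
tested.

AUC is the trapezoidal integral of (fitted − baseline) on the dose grid,
baseline = stress-phase mean of the observed group trajectory, so the sign
records whether the index sat above or below its stressed level. Thresholds
are searched only in the exposure phase; a boundary flag records when
recovery appears to precede it.

## Naturalness

Per sampling point: 100 · natural / (natural + man-made); sky and human
pixels excluded before the ratio. Per site: unweighted mean over sampling
points — panoramas differ in resolution and each viewpoint counts equally.
Input is an integer label image plus a code → category map; the built-in
class-name map is a non-normative convenience. All sky/human at a point is
an error naming the point.

## Problem sizes and tolerances

The test suite validates at the following scales, chosen as the smallest
that exercise each claim: envelope round-trips on single 4-channel
recordings (band-power MAE < 0.05 over 40 windows); parameter recovery on
50 cohorts of 20 participants × 3 environments (seeds 1–50, 4 channels, no
artifacts — recovery isolates the estimator, artifact handling is certified
separately) with noise-monotonicity probed at SD 0/2.5/5 μV over 15 seeds
per level; the full artifact-laden structural run at 12 participants per
environment. The acceptance script uses 12 recovery cohorts and the same
12-participant full run. Numerical tolerances: band-fraction identities at
1e−9; oracle threshold equalities exact on the grid; trapezoid values exact
to 1e−12 for polynomials of degree ≤ 1 and bounded by (b−a)h²max|f″|/12
otherwise; filter contracts at the attenuation factors stated in the
preprocessing section.

## Known limitations

- ET/BT are grid quantities (0.5-min resolution); no confidence intervals
  are attached beyond the pointwise SD (none are defined in this design).
- The (α+θ) index is linearly dependent on relative β under the default
  total band; treat its thresholds as a re-expression of the β results
  unless the total band is widened.
- The spline extrapolates 0.25 min at both ends of the exposure phase.
- GCV can under-smooth short, noisy group curves; the detection floor
  guards the no-recovery call, but threshold scatter grows quickly below
  ~8 participants per group.
- EDF files can be read (via the optional `mne` dependency) but not
  written; the native format is delimited text.
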
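# Methods

## The analysis in brief

Sensorimotor beta-band (13–30 Hz) activity is not a sustained oscillation
but a sequence of transient, high-amplitude bursts lasting roughly one to
a few beta cycles. `betabursts` quantifies these bursts in resting-state
region-of-interest (ROI) source time courses and contrasts the
time-domain burst description with the conventional frequency-domain
description of the same signals, in cohorts of patients (e.g. with
Parkinson's disease, off/on medication across two sessions) and healthy
controls.

The processing chain per record is:

1. *(optional)* collapse an n_sources × n_samples ROI matrix to a single
   time course: first right-singular vector of the SVD, scaled by its
   singular value, sign-anchored so that the mean of the first
   left-singular vector times the source-orientation signs is
   non-negative;
2. zero-phase FIR band-pass to 13–30 Hz (windowed-sinc/firwin design with
   transition bandwidths 3.25 Hz below and 7.5 Hz above, group-delay
   compensated);
3. Hilbert envelope (instantaneous beta amplitude), trimming 1 s from
   each end where filter and transform edge artifacts live;
4. burst definition on the envelope by a threshold expressed in multiples
   *k* of the envelope median.

## Data-driven threshold

The multiplier *k* is not fixed a priori. For each candidate on a grid
(1.0 to 5.0 in steps of 0.1) and each subject, the envelope is cut into
consecutive non-overlapping 3.0-s segments; the Pearson correlation
between per-segment mean amplitude and per-segment burst count is
computed, averaged across subjects, and the *k* with the highest mean
correlation is fixed for all subsequent analysis. Intuition: far too low
a threshold counts every wiggle (counts decouple from amplitude), far too
high counts almost nothing; in between, counts track the amplitude
dynamics most faithfully. Subjects whose count variance is zero at some
*k* (typically high thresholds) have an undefined correlation there and
are excluded from that *k*'s average with a warning — treating them as
zero would bias the average downward.

Median-relative thresholds preserve group-level comparability while
adapting to each record's dynamic range. The phrase "k medians above the
median" admits a second reading, T = (1+k)·median; both are implemented
(`threshold.mode = scaled | offset`), the scaled form `T = k·median` is
the default because the sweep then runs literally "from the median to
five times the median". The centering statistic is configurable
(`median | mean | mode`; mode uses the half-sample estimator), median
being the analysed default.

## Burst events and features

Each maximal suprathreshold run contributes one event at its envelope
peak. Onset and offset are found by walking outward from the peak to the
first samples below half the peak amplitude and interpolating linearly to
sub-sample crossing times; duration is offset − onset. Events whose
half-max window is truncated by the record edge are discarded (≤ a
couple per 3-min record); overlapping half-max windows are merged keeping
the larger peak, so events are disjoint and inter-burst intervals
(next onset − current offset) are strictly positive. The four features
are rate (events per analysed minute), duration, inter-burst interval and
peak amplitude. Amplitude units are inherited from the input (for
noise-normalised source estimates they are unit-relative; nothing
downstream depends on absolute scale — detection itself is exactly
scale-invariant).

For an isolated Gaussian envelope bump on a negligible baseline the
measured duration equals the Gaussian FWHM = 2√(2 ln 2)·σ; on a baseline
b with peak p the crossing sits where b + (p−b)·exp(−t²/2σ²) = p/2. Both
closed forms are regression-tested to ~1 ms.

## Frequency-domain counterpart

Welch PSD of the *unfiltered* record: 3-s Hann-tapered segments, 50%
overlap, analysed over 1–48 Hz. Relative beta power is the trapezoidal
band integral (13–30 Hz) over the full-spectrum integral, with band
edges interpolated onto the grid. The 1/f-plus-peaks decomposition
models log10 P(f) = intercept − χ·log10 f plus Gaussians over linear
frequency in log10 power:

1. OLS line in log-log space, refitted excluding the top quartile of
   positive residuals (so band peaks do not drag the line up);
2. iterative peak picking on the flattened spectrum: take the largest
   residual, accept it if it exceeds 2 noise-SDs (noise spread estimated
   from the 25th–50th percentile gap of the residual, which
   strictly-positive peaks cannot inflate) and an absolute floor of 0.01
   log10 units; fit and subtract a Gaussian; at most 8 peaks;
3. joint least-squares refinement of all accepted Gaussians;
4. aperiodic refit on the peak-subtracted spectrum; r² of the combined
   model.

Gaussian SDs are bounded to [0.5, 6] Hz. The exponent is reported
positive for a decaying spectrum; the intercept is log10 power at 1 Hz.
The beta peak is the largest-height Gaussian with center inside 13–30 Hz
and is reported as absent (None) — not zero — when no such peak exists.
Knee-form aperiodic fitting is out of scope; the fixed power-law form is
used throughout.

## Group and symptom statistics

**Burst rate.** Counts per subject/session are modelled by mixed-effects
Poisson regression: Group and Session fixed effects, subject random
intercept, log analysed-minutes exposure offset. The marginal likelihood
is computed by adaptive Gauss–Hermite quadrature (20 nodes, re-centred
per subject at the posterior mode and re-scaled by its curvature), and
maximised over (β, log σ) by L-BFGS-B; standard errors come from the
finite-difference observed information. Estimates agree with
`lme4::glmer(..., nAGQ = 20)` to ≲1e-3 (regression-tested).

**Per-event features.** Duration, inter-burst interval and peak
amplitude are modelled per event on the log scale: lognormal (IBI) or
shifted-lognormal (duration, amplitude) linear mixed models with a
subject random intercept (statsmodels MixedLM, ML). The shift is
profiled on a coarse grid over [0, 0.99·min] on the full additive model
— including the −Σ log(y−shift) change-of-variable term so likelihoods
are comparable on the data scale — then held fixed for all nested fits.
If the random-intercept variance collapses to the boundary the model
degenerates to OLS and is refitted as such (logged). Effects are
reported as percent changes of exp(linear predictor), i.e. of the median
of the shifted component.

**Evidence.** Factor-wise evidence uses Bayes factors approximated from
BIC differences of nested fits, BF ≈ exp((BIC_without − BIC_with)/2),
read on the conventional scale (BF > 3 / < 1/3 conclusive). This is a
deterministic, desk-scale stand-in for full MCMC marginal evidence: the
decision structure (which side of 1 and 3 a BF falls) is what the
package asserts, never exact BF magnitudes. Post-hoc contrasts carry an
exceedance probability — the probability mass on the side of zero
opposite the point estimate — from the Wald tail by default or from a
parametric bootstrap of the fitted model (`stats.bootstrap_n`; the two
agree within 0.02 in the Gaussian case and the bootstrap costs a full
refit per draw, hence Wald as default).

**Symptoms.** Within patients, each of six motor-factor scores (midline
function, rest tremor, rigidity, bradykinesia, postural/kinetic tremor,
lower-limb bradykinesia) is regressed on the burst rate by the same
Poisson machinery, subject random intercept plus a session intercept. A
session *random* intercept with only two levels is weakly identified and
does not fit the single-factor quadrature integrator, so session enters
as a fixed shift — the deterministic equivalent of falling back when the
variance estimate hits zero. The rate effect is transformed to the
percent change of the expected score per +10 bursts/min,
100·(exp(10β)−1); rates are centred before fitting for a stable
intercept (slope unaffected).

**Classification.** Each summary measure (four burst features, relative
beta power, 1/f intercept and exponent, beta peak power) is the single
predictor in a logistic regression of group; the AUC is computed as the
midrank Mann–Whitney statistic of the feature in the orientation of the
fitted slope (exact, tie-robust, and identical to the AUC of the fitted
probabilities). The optimal cut-off maximises Youden's J (accuracy
optionally) over midpoints between consecutive unique feature values,
ties resolved toward the lower value. These are apparent (in-sample)
ROCs — no cross-validation — and are therefore optimistic; under label
shuffling the reported AUC averages ≈0.58, not 0.50, precisely because
the orientation is chosen in-sample.

**Threshold sweep.** The rate model (with its BFs) and the per-session
burst-rate AUC are recomputed at every grid multiplier to show whether
the group inference depends on the chosen threshold.

## Synthetic cohorts

The generator emulates the study conditions so every stage is testable
without recordings. A record is 180 s at 1000 Hz: aperiodic 1/f noise
plus a train of transient beta events.

* **Noise**: white Gaussian noise shaped in the frequency domain with
  amplitude ∝ f^(−χ/2) (DC zeroed), normalised so the expected variance
  equals `scale²`; expected PSD ∝ f^(−χ) exactly. Default exponents 0.8
  (patients) / 0.65 (controls), matching the reported group difference in
  1/f slope.
* **Events**: Gaussian-windowed sinusoids at Poisson onsets. The
  envelope FWHM equals the drawn duration — giving closed-form oracles —
  with durations ~ Normal(75, 30) ms floored at 20 ms (matching the
  reported median of 75 ms and right tail to ~170 ms), carriers uniform
  on 15–29 Hz, peak amplitudes ~ Normal(1.0, 0.25) truncated at 0
  (reported peak amplitudes ≈ 0.99–1.01 units).
* **Subjects**: per-subject rates ~ Normal(group mean, group SD)
  truncated at 0 — 106 (8) bursts/min for patients, 120 (11) for
  controls, 19 subjects each by default. Session 2 regenerates noise and
  event realisations with fresh seeds but keeps the subject's drawn rate
  (plus an optional additive session offset, default 0, since no
  conclusive session effect on rate is expected).
* **Noise scale 1.1** puts the beta-envelope median of the background at
  ≈0.45 units, so default unit-amplitude events sit at ≈2.2× the median
  — right around the optimised threshold, as bursts "just above
  threshold" should.
* **Clinical scores**: Poisson counts with log-mean linear in the
  subject's rate, parameterised as percent change per +10 bursts/min
  (β = ln(1+pct/100)/10). Defaults plant −28% on bradykinesia and −40%
  on postural/kinetic tremor, zero on the other four factors, with
  expected scores 4/3/6/13/3/3 at the 106 bursts/min anchor (summing to
  ≈32, a plausible non-medicated motor-exam total).

What the generator does **not** emulate: multichannel sensor physics and
source leakage, cardiac/ocular artifacts, non-stationary noise floors,
burst waveform asymmetries, and any dependence of burst amplitude or
duration on group. Passing tests therefore demonstrate that the
*pipeline* measures what it claims on signals obeying the stated model —
not that real recordings obey that model.

Two emergent facts are worth knowing when reading results on synthetic
data. First, beta-filtered 1/f noise *alone* produces suprathreshold
envelope excursions whose median half-max duration is an emergent
property of the 17-Hz band (~1/bandwidth), stable across seeds in the
65–80 ms range — the same range the planted events occupy. Second,
measured durations sit ~7% below the planted FWHM at the default SNR:
incoherent noise power inflates the envelope peak (≈√(A²+2σ²)), raising
the half-max level and narrowing the crossing window. Both effects are
properties of the measurement, not bugs, and the second is why the
pooled median on default cohorts reads ≈69–70 ms rather than exactly the
75 ms planted.

## Determinism and problem sizes

All randomness flows from one master seed through named SeedSequence
sub-streams (per stage, group, subject, session), so identical seeds
reproduce cohorts bit-for-bit and stages can be re-run in isolation. The
test suite exercises the full pipeline on reduced cohorts (2×3 subjects,
60-s records, coarsened threshold grids) and the replication checks use
19 records of 180 s for the duration analysis, 200 replicate 19-vs-19
cohorts for the AUC, and 12 replicate 19-patient cohorts for each
symptom-effect recovery; these sizes are the package's chosen desk-scale
defaults and are stated here so they can be scaled up deliberately
rather than discovered in code.

## Known limitations

* BIC-approximated BFs implicitly assume a unit-information prior; they
  match MCMC marginal evidence only in order of magnitude, which is why
  only ordinal conclusions are asserted.
* The shifted-lognormal shift is profiled on a coarse grid, not jointly
  estimated; its uncertainty is not propagated into effect CIs.
* Apparent ROC/AUC (no cross-validation) is optimistic, as in the
  original analysis it mirrors.
* The aperiodic fit assumes a single power law over 1–48 Hz (no knee).
* `combine_roi` exists as the entry point for users with source-space
  matrices; no source reconstruction is performed here.
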
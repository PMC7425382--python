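# betabursts

Transient beta-burst analysis of resting-state sensorimotor cortical
time courses.

Beta-band (13–30 Hz) activity in sensorimotor cortex comes in brief,
high-amplitude bursts — roughly one to a few oscillatory cycles — rather
than as a sustained rhythm, and averaging power spectra over minutes of
signal hides this temporal structure. For clinical electrophysiology
(e.g. Parkinson's disease, where beta dynamics change with disease and
medication state) the burst description carries information the averaged
spectrum does not: how *often* bursts occur, how *long* they last, how
far apart they fall, and how large they are. `betabursts` implements
that analysis for single-channel region-of-interest (ROI) source time
courses, for researchers comparing patient and control cohorts across
sessions.

## What it computes

Given a 3-min, 1-kHz ROI time course per subject/session:

* **Preprocessing** — optional SVD combination of source time courses
  into one ROI course, zero-phase FIR band-pass to 13–30 Hz (transition
  bands 3.25/7.5 Hz), Hilbert envelope `A(t)`.
* **Burst detection** — bursts are excursions of `A(t)` above a
  threshold `T = k · median(A)`. The multiplier `k` is chosen
  data-drivenly: for each candidate `k ∈ {1.0, 1.1, …, 5.0}` the
  envelope is cut into 3-s segments and the correlation between segment
  mean amplitude and segment burst count is averaged across subjects;
  the `k` with the highest mean correlation is fixed. Each burst's
  onset/offset are the half-max crossings around its envelope peak,
  giving the four features: rate (bursts/min), duration, inter-burst
  interval, and peak amplitude.
* **Spectral counterpart** — Welch PSD (3-s Hann segments, 50% overlap,
  1–48 Hz), relative beta power ∫₁₃³⁰P df / ∫₁⁴⁸P df, and an aperiodic
  1/f + Gaussian-peaks decomposition of log₁₀P(f) = b − χ·log₁₀f + Σ
  Gaussians (max 8 peaks), yielding the 1/f intercept and exponent and
  the beta peak frequency/power.
* **Statistics** — mixed-effects Poisson regression of burst counts
  (Group + Session fixed, subject random intercept, exposure offset) via
  an adaptive Gauss–Hermite marginal likelihood; lognormal /
  shifted-lognormal mixed models for the per-event features;
  BIC-approximated Bayes factors for each factor; Poisson regressions of
  six motor-symptom factor scores on burst rate, reported as % change
  per +10 bursts/min.
* **Classification** — per-feature univariate logistic ROC (AUC as the
  exact midrank Mann–Whitney statistic, Youden-optimal cut-offs), and a
  robustness sweep repeating the group model and ROC at every threshold.
* **Synthetic cohorts** — a generator producing 1/f background (planted
  exponent) plus Gaussian-windowed beta events at planted per-subject
  rates, with linked Poisson symptom scores, so the entire pipeline runs
  and is tested without any recording.

## Worked example

```python
from betabursts import (BetaEnvelopeTransformer, BurstDetector, GroupSpec,
                        NoiseGenSpec, gen_subject, summarize_subject,
                        welch_psd, fit_aperiodic_periodic)

group = GroupSpec(label="patient", n_subjects=1, rate_mean=106, rate_sd=8,
                  noise=NoiseGenSpec(exponent=0.8, scale=1.1, duration_s=180.0))
subjects = [gen_subject(group, f"p{i:02d}", 1, seed=i) for i in range(5)]
envelopes = BetaEnvelopeTransformer().fit(None).transform([s.signal for s in subjects])
detector = BurstDetector(k="auto").fit(envelopes)

print(f"optimised threshold k* = {detector.k_:.1f} x median")
for s, env, events in zip(subjects, envelopes, detector.transform(envelopes)):
    summ = summarize_subject(events, env, subject=s.subject_id)
    print(f"{s.subject_id}: rate {summ.rate_per_min:5.1f}/min "
          f"(planted {s.truth_rate:5.1f}), "
          f"median duration {summ.median_duration_ms:4.1f} ms, "
          f"median IBI {summ.median_ibi_ms:5.1f} ms")

fit = fit_aperiodic_periodic(welch_psd(subjects[0].signal))
print(f"p00 spectrum: exponent {fit.exponent:.2f}, "
      f"relative beta power {fit.relative_beta:.2f}, "
      f"beta peak {fit.beta_peak_freq:.1f} Hz")
```

prints

```
optimised threshold k* = 2.1 x median
p00: rate 118.7/min (planted 124.7), median duration 67.5 ms, median IBI 282.8 ms
p01: rate 107.5/min (planted  96.0), median duration 66.8 ms, median IBI 304.6 ms
p02: rate 116.6/min (planted 100.0), median duration 65.7 ms, median IBI 300.5 ms
p03: rate 109.2/min (planted  97.3), median duration 68.2 ms, median IBI 306.1 ms
p04: rate 110.2/min (planted  93.0), median duration 65.9 ms, median IBI 320.7 ms
p00 spectrum: exponent 0.77, relative beta power 0.34, beta peak 26.2 Hz
```

The threshold search lands at ≈2× the envelope median; detected rates
track the planted per-subject rates (the offset comes from bursts that
emerge from the 1/f background itself); median durations sit in the
65–70 ms range — the planted 75-ms events read slightly short because
background power raises each burst's measured peak and hence its
half-max level; and the spectral fit recovers the planted 1/f exponent
(0.8) and a beta-range peak from the same record.

### Command line

```bash
betabursts simulate --seed 0 --out runs/cohort          # write a synthetic cohort
betabursts analyze --manifest runs/cohort --out runs/a  # full analysis -> TSV tables
betabursts report --out runs/a                          # human-readable summary
```

`analyze` emits `burst_summaries.tsv`, `burst_events.tsv`,
`spectral_fits.tsv`, the model `report.txt`, `roc_table.tsv`,
`threshold_sweep.tsv` and `symptom_effects.tsv`; every table is keyed by
subject/group/session. All settings live in a YAML config
(`--config`), and the effective config is copied into each output
directory so a run reproduces from its own artifacts.

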
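"""Frequency-domain measures: Welch PSD, relative beta power, 1/f fit.

The PSD of neural signals is approximately linear in log-log space (the
aperiodic 1/f component) with band-limited peaks superimposed. The
decomposition here mirrors the standard spectral-parameterisation
approach: a robust log-log linear fit is subtracted, Gaussians (in log10
power over linear frequency) are fitted iteratively to the residual
peaks in descending order of height, at most eight in total, then the
aperiodic line is refitted to the peak-subtracted spectrum. Reported
beta quantities are the relative beta power (band integral over the full
1-48 Hz integral) and the largest fitted peak inside 13-30 Hz.
"""

from __future__ import annotations

import numpy as np
import scipy.optimize
import scipy.signal
from sklearn.base import BaseEstimator

from .datatypes import Psd, SpectralFit, TimeSeries

__all__ = [
    "welch_psd",
    "relative_band_power",
    "fit_aperiodic_periodic",
    "SpectralModel",
    "spectral_features",
]


def welch_psd(
    ts: TimeSeries,
    seg_len_s: float = 3.0,
    overlap: float = 0.5,
    taper: str = "hann",
    fmin: float = 1.0,
    fmax: float = 48.0,
) -> Psd:
    """Welch PSD from tapered overlapping segments, cropped to [fmin, fmax]."""
    nperseg = int(round(seg_len_s * ts.fs))
    if ts.n_samples < 2 * nperseg - int(nperseg * overlap):
        raise ValueError("record shorter than two Welch segments")
    freqs, power = scipy.signal.welch(
        ts.samples,
        fs=ts.fs,
        window=taper,
        nperseg=nperseg,
        noverlap=int(nperseg * overlap),
        detrend="constant",
    )
    mask = (freqs >= fmin) & (freqs <= fmax)
    return Psd(freqs[mask], power[mask])


def relative_band_power(psd: Psd, band: tuple[float, float] = (13.0, 30.0)) -> float:
    """Band integral of the PSD divided by the full-spectrum integral.

    Trapezoidal integration, with the band edges interpolated onto the
    frequency grid so the result does not depend on bin alignment.
    """
    lo, hi = band
    if not (lo < hi):
        raise ValueError("empty frequency band")
    if lo < psd.freqs[0] or hi > psd.freqs[-1]:
        raise ValueError("band extends beyond the PSD's frequency range")
    total = np.trapezoid(psd.power, psd.freqs)
    if total <= 0:
        raise ValueError("PSD integrates to zero")
    inner = (psd.freqs > lo) & (psd.freqs < hi)
    f_band = np.concatenate([[lo], psd.freqs[inner], [hi]])
    p_band = np.concatenate(
        [
            [np.interp(lo, psd.freqs, psd.power)],
            psd.power[inner],
            [np.interp(hi, psd.freqs, psd.power)],
        ]
    )
    return float(np.trapezoid(p_band, f_band) / total)


def _gaussian(freqs: np.ndarray, center: float, height: float, sd: float) -> np.ndarray:
    return height * np.exp(-0.5 * ((freqs - center) / sd) ** 2)


def _peaks_model(freqs: np.ndarray, params: np.ndarray) -> np.ndarray:
    model = np.zeros_like(freqs)
    for center, height, sd in params.reshape(-1, 3):
        model += _gaussian(freqs, center, height, sd)
    return model


def _robust_line(log_f: np.ndarray, log_p: np.ndarray) -> tuple[float, float]:
    """OLS line refitted after excluding top-quartile positive residuals.

    The exclusion keeps band peaks from dragging the aperiodic estimate
    upwards. Returns (intercept, slope) of log10 P = intercept + slope *
    log10 f.
    """
    slope, intercept = np.polyfit(log_f, log_p, 1)
    resid = log_p - (intercept + slope * log_f)
    cutoff = np.quantile(resid, 0.75)
    keep = resid <= cutoff
    if keep.sum() >= 3:
        slope, intercept = np.polyfit(log_f[keep], log_p[keep], 1)
    return float(intercept), float(slope)


def fit_aperiodic_periodic(
    psd: Psd,
    max_peaks: int = 8,
    peak_threshold_sd: float = 2.0,
    min_peak_height: float = 0.01,
    min_peak_width_hz: float = 1.0,
    max_peak_width_hz: float = 12.0,
    beta_band: tuple[float, float] = (13.0, 30.0),
) -> SpectralFit:
    """Decompose a PSD into an aperiodic power law plus Gaussian peaks.

    Steps: robust log-log line fit; iterative Gaussian guesses on the
    flattened spectrum (largest residual first, stopping below
    ``peak_threshold_sd`` standard deviations of the current residual or
    at ``max_peaks``); joint refinement of all Gaussians; aperiodic refit
    on the peak-subtracted spectrum; combined-model r^2. Peak widths are
    Gaussian standard deviations in Hz, bounded to
    [min_peak_width_hz/2, max_peak_width_hz/2].
    """
    if np.any(psd.power <= 0):
        raise ValueError("spectral fit requires strictly positive power")
    freqs = psd.freqs
    log_f = np.log10(freqs)
    log_p = np.log10(psd.power)

    intercept, slope = _robust_line(log_f, log_p)
    flat = log_p - (intercept + slope * log_f)

    sd_lo = min_peak_width_hz / 2.0
    sd_hi = max_peak_width_hz / 2.0
    guesses: list[tuple[float, float, float]] = []
    resid = flat.copy()
    for _ in range(max_peaks):
        i_max = int(np.argmax(resid))
        height = resid[i_max]
        # noise spread from the lower half of the residual distribution:
        # peaks are strictly positive excursions, so the 25th-50th
        # percentile gap estimates the noise SD without peak inflation
        q25, q50 = np.quantile(resid, [0.25, 0.5])
        spread = (q50 - q25) / 0.6745
        if height <= max(peak_threshold_sd * spread, min_peak_height):
            break
        center = freqs[i_max]
        # initial width from the half-height extent around the maximum
        half = height / 2.0
        i_left = i_max
        while i_left > 0 and resid[i_left] > half:
            i_left -= 1
        i_right = i_max
        while i_right < resid.size - 1 and resid[i_right] > half:
            i_right += 1
        fwhm = max(freqs[i_right] - freqs[i_left], min_peak_width_hz)
        sd = float(np.clip(fwhm / 2.355, sd_lo, sd_hi))
        guesses.append((float(center), float(height), sd))
        resid = resid - _gaussian(freqs, center, height, sd)

    peak_params = np.array(guesses, dtype=float).reshape(-1, 3)
    if peak_params.size:
        # joint refinement of all Gaussians on the flattened spectrum
        p0 = peak_params.ravel()
        lo_b, hi_b = [], []
        for center, height, sd in peak_params:
            lo_b += [freqs[0], 0.0, sd_lo]
            hi_b += [freqs[-1], np.inf, sd_hi]
        try:
            popt, _ = scipy.optimize.curve_fit(
                lambda f, *p: _peaks_model(f, np.asarray(p)),
                freqs,
                flat,
                p0=p0,
                bounds=(lo_b, hi_b),
                maxfev=5000,
            )
            peak_params = np.asarray(popt).reshape(-1, 3)
        except RuntimeError:
            pass  # keep iterative guesses if the joint fit fails

    peak_model = _peaks_model(freqs, peak_params) if peak_params.size else 0.0
    # final aperiodic fit on the peak-subtracted spectrum
    slope2, intercept2 = np.polyfit(log_f, log_p - peak_model, 1)
    model = intercept2 + slope2 * log_f + peak_model
    ss_res = float(np.sum((log_p - model) ** 2))
    ss_tot = float(np.sum((log_p - log_p.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    peaks = [tuple(map(float, row)) for row in peak_params]
    beta_peaks = [p for p in peaks if beta_band[0] <= p[0] <= beta_band[1]]
    if beta_peaks:
        best = max(beta_peaks, key=lambda p: p[1])
        beta_peak_freq, beta_peak_power = best[0], best[1]
    else:
        beta_peak_freq = beta_peak_power = None

    return SpectralFit(
        intercept=float(intercept2),
        exponent=float(-slope2),
        peaks=peaks,
        r2=r2,
        relative_beta=relative_band_power(psd, beta_band),
        beta_peak_freq=beta_peak_freq,
        beta_peak_power=beta_peak_power,
    )


class SpectralModel(BaseEstimator):
    """Scikit-learn style wrapper around the aperiodic + peaks fit.

    ``fit(psd)`` stores ``intercept_``, ``exponent_``, ``peaks_``,
    ``r2_``, ``relative_beta_``, ``beta_peak_freq_``,
    ``beta_peak_power_`` and the full ``result_`` :class:`SpectralFit`.
    """

    def __init__(
        self,
        max_peaks: int = 8,
        peak_threshold_sd: float = 2.0,
        min_peak_height: float = 0.01,
        min_peak_width_hz: float = 1.0,
        max_peak_width_hz: float = 12.0,
        beta_band: tuple[float, float] = (13.0, 30.0),
    ):
        self.max_peaks = max_peaks
        self.peak_threshold_sd = peak_threshold_sd
        self.min_peak_height = min_peak_height
        self.min_peak_width_hz = min_peak_width_hz
        self.max_peak_width_hz = max_peak_width_hz
        self.beta_band = beta_band

    def fit(self, X: Psd, y=None):
        result = fit_aperiodic_periodic(
            X,
            max_peaks=self.max_peaks,
            peak_threshold_sd=self.peak_threshold_sd,
            min_peak_height=self.min_peak_height,
            min_peak_width_hz=self.min_peak_width_hz,
            max_peak_width_hz=self.max_peak_width_hz,
            beta_band=self.beta_band,
        )
        self.result_ = result
        self.intercept_ = result.intercept
        self.exponent_ = result.exponent
        self.peaks_ = result.peaks
        self.r2_ = result.r2
        self.relative_beta_ = result.relative_beta
        self.beta_peak_freq_ = result.beta_peak_freq
        self.beta_peak_power_ = result.beta_peak_power
        return self


def spectral_features(ts: TimeSeries, **psd_kwargs) -> dict:
    """One record's frequency-domain feature row (PSD + 1/f fit)."""
    psd = welch_psd(ts, **psd_kwargs)
    fit = fit_aperiodic_periodic(psd)
    return {
        "relative_beta_power": fit.relative_beta,
        "aperiodic_intercept": fit.intercept,
        "aperiodic_exponent": fit.exponent,
        "beta_peak_freq": fit.beta_peak_freq,
        "beta_peak_power": fit.beta_peak_power,
        "fit_r2": fit.r2,
    }
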
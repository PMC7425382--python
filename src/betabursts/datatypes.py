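"""Core containers shared across the analysis stages.

The pipeline operates on single-channel region-of-interest (ROI) source
time courses: a real-valued series sampled uniformly (nominally 1000 Hz,
3 minutes). Amplitudes are in arbitrary noise-normalised source units, so
every amplitude-bearing quantity downstream is unit-relative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeries",
    "Envelope",
    "BurstEvent",
    "SubjectBurstSummary",
    "SpectralFit",
    "Psd",
    "CohortDataset",
]


@dataclass
class TimeSeries:
    """A uniformly sampled single-channel signal.

    Parameters
    ----------
    samples : ndarray
        Real-valued signal, arbitrary source units.
    fs : float
        Sampling frequency in Hz. Must be positive.
    t0 : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size < 2:
            raise ValueError("a time series needs at least 2 samples")
        if not np.isfinite(self.samples).all():
            raise ValueError("samples must be finite")
        if not (self.fs > 0):
            raise ValueError(f"fs must be positive, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs


@dataclass
class Envelope:
    """Magnitude of an analytic (Hilbert-transformed) band-filtered signal.

    ``t0`` records the absolute time of the first retained sample so that
    event times remain comparable after edge trimming.
    """

    magnitude: np.ndarray
    fs: float
    band: tuple[float, float]
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=np.float64)
        if self.magnitude.ndim != 1:
            raise ValueError("magnitude must be one-dimensional")
        if self.magnitude.size and self.magnitude.min() < 0:
            raise ValueError("envelope magnitude must be non-negative")
        if not (self.fs > 0):
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return self.magnitude.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class BurstEvent:
    """One suprathreshold envelope excursion.

    Onset and offset are the outward half-max crossings around the peak,
    linearly interpolated to sub-sample resolution; duration is their
    difference.
    """

    onset_s: float
    offset_s: float
    peak_time_s: float
    peak_amp: float

    def __post_init__(self) -> None:
        if not (self.onset_s <= self.peak_time_s <= self.offset_s):
            raise ValueError("peak time must lie within [onset, offset]")
        if not (self.offset_s > self.onset_s):
            raise ValueError("duration must be positive")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class SubjectBurstSummary:
    """Per subject/session burst features.

    Holds the four burst features: rate of occurrence (bursts/min), and
    the per-event duration, inter-burst interval (offset to next onset)
    and envelope peak amplitude vectors together with their medians.
    """

    subject: str
    group: str
    session: int
    n_bursts: int
    analyzed_s: float
    rate_per_min: float
    durations_ms: np.ndarray
    ibis_ms: np.ndarray
    peak_amps: np.ndarray

    @property
    def median_duration_ms(self) -> float:
        return float(np.median(self.durations_ms)) if self.durations_ms.size else np.nan

    @property
    def median_ibi_ms(self) -> float:
        return float(np.median(self.ibis_ms)) if self.ibis_ms.size else np.nan

    @property
    def median_peak_amp(self) -> float:
        return float(np.median(self.peak_amps)) if self.peak_amps.size else np.nan

    def to_row(self) -> dict:
        return {
            "subject": self.subject,
            "group": self.group,
            "session": self.session,
            "n_bursts": self.n_bursts,
            "analyzed_s": self.analyzed_s,
            "rate_per_min": self.rate_per_min,
            "median_duration_ms": self.median_duration_ms,
            "median_ibi_ms": self.median_ibi_ms,
            "median_peak_amp": self.median_peak_amp,
        }


@dataclass
class Psd:
    """Power spectral density restricted to an analysis band (1-48 Hz)."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.power = np.asarray(self.power, dtype=np.float64)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have the same shape")
        if self.freqs.size < 2:
            raise ValueError("a PSD needs at least 2 frequency bins")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


@dataclass
class SpectralFit:
    """Aperiodic (1/f) + Gaussian-peak decomposition of a PSD.

    The aperiodic model is ``log10 P(f) = intercept - exponent * log10 f``
    (exponent stored positive for a decaying spectrum). Peaks are
    ``(center_hz, height_log10, sd_hz)`` Gaussians in log10 power over
    linear frequency. ``beta_peak_freq``/``beta_peak_power`` describe the
    largest peak with center inside the beta band; both are None when no
    beta peak was found (distinct from a zero-height peak).
    """

    intercept: float
    exponent: float
    peaks: list[tuple[float, float, float]]
    r2: float
    relative_beta: float | None = None
    beta_peak_freq: float | None = None
    beta_peak_power: float | None = None

    def aperiodic(self, freqs: np.ndarray) -> np.ndarray:
        """Aperiodic component in log10 power at the given frequencies."""
        return self.intercept - self.exponent * np.log10(np.asarray(freqs, float))


@dataclass
class CohortDataset:
    """A cohort manifest plus in-memory signals and (optional) ground truth.

    ``manifest`` has one row per subject/session with columns
    ``subject, group, session, path, truth_rate`` (path may be empty for
    purely in-memory cohorts). ``signals`` maps ``(subject, session)`` to
    a TimeSeries; ``truth_events`` maps the same key to an array of
    planted events (onset_s, duration_s, amplitude, freq_hz);
    ``clinical_scores`` is a per subject/session table of symptom factor
    scores (may be None).
    """

    manifest: pd.DataFrame
    signals: dict[tuple[str, int], TimeSeries] = field(default_factory=dict)
    truth_events: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)
    clinical_scores: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        required = {"subject", "group", "session"}
        missing = required - set(self.manifest.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        dup = self.manifest.duplicated(subset=["subject", "session"])
        if dup.any():
            raise ValueError("duplicate (subject, session) records in manifest")

    def __len__(self) -> int:
        return len(self.manifest)

    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.manifest["subject"]))

    def iter_records(self):
        """Yield (row, TimeSeries) pairs in manifest order."""
        for _, row in self.manifest.iterrows():
            key = (row["subject"], int(row["session"]))
            yield row, self.signals.get(key)
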
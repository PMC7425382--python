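"""Data-driven burst threshold, event extraction and burst features.

Bursts are defined on the beta-band Hilbert envelope as excursions above
a fixed threshold expressed in multiples ``k`` of the envelope's median
(so the cut adapts to each record's dynamic range while keeping the same
statistical meaning across subjects). ``k`` itself is chosen
data-drivenly: for each candidate ``k`` the envelope is cut into
consecutive 3.0-s segments, and the Pearson correlation between segment
mean amplitude and segment burst count is computed per subject and
averaged; the ``k`` with the highest mean correlation wins.

Each detected event is a maximal suprathreshold run reduced to its peak;
onset and offset are found by walking outward from the peak to the first
half-max crossings (linearly interpolated), which also defines the burst
duration. Events whose half-max window is cut off by the record edge are
discarded, and overlapping half-max windows are merged keeping the
larger peak, so reported events are always disjoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import BurstEvent, CohortDataset, Envelope, SubjectBurstSummary

__all__ = [
    "ThresholdGrid",
    "detect_events",
    "optimize_threshold",
    "summarize_subject",
    "detect_cohort",
    "BurstDetector",
    "default_k_grid",
]


def default_k_grid(k_min: float = 1.0, k_max: float = 5.0, k_step: float = 0.1) -> np.ndarray:
    """Threshold multipliers from the median to five times the median."""
    n = int(round((k_max - k_min) / k_step)) + 1
    return np.round(k_min + k_step * np.arange(n), 10)


@dataclass
class ThresholdGrid:
    """Result of the threshold search across a grid of multipliers."""

    k_values: np.ndarray
    segment_len_s: float
    mean_r: np.ndarray
    n_valid: np.ndarray  # subjects contributing a defined correlation per k
    k_star: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.k_values) <= 0):
            raise ValueError("k_values must be strictly ascending")
        if len(self.mean_r) != len(self.k_values):
            raise ValueError("mean_r must align with k_values")


def _threshold_center(magnitude: np.ndarray, center: str) -> float:
    if center == "median":
        return float(np.median(magnitude))
    if center == "mean":
        return float(np.mean(magnitude))
    if center == "mode":
        return _half_sample_mode(np.sort(magnitude))
    raise ValueError(f"unknown center statistic {center!r}")


def _half_sample_mode(sorted_x: np.ndarray) -> float:
    """Robust mode estimate by recursive half-sample narrowing."""
    x = sorted_x
    while x.size > 3:
        h = x.size // 2
        widths = x[h:] - x[: x.size - h]
        i = int(np.argmin(widths))
        x = x[i : i + h + 1]
    return float(np.mean(x))


def _first_below(mag: np.ndarray, start: int, half: float, direction: int) -> int:
    """Nearest index from ``start`` (exclusive) in ``direction`` with mag < half.

    Returns -1 (left) or len(mag) (right) when no such sample exists.
    """
    n = mag.size
    chunk = 256
    i = start
    if direction < 0:
        while i > 0:
            lo = max(0, i - chunk)
            seg = mag[lo:i]
            below = seg < half
            if below.any():
                return lo + seg.size - 1 - int(np.argmax(below[::-1]))
            i = lo
            chunk *= 2
        return -1
    while i < n - 1:
        hi = min(n, i + 1 + chunk)
        seg = mag[i + 1 : hi]
        below = seg < half
        if below.any():
            return i + 1 + int(np.argmax(below))
        i = hi - 1
        chunk *= 2
    return n


def detect_events(
    env: Envelope,
    k: float,
    center: str = "median",
    threshold_mode: str = "scaled",
) -> list[BurstEvent]:
    """Extract burst events above ``k`` medians from an envelope.

    The threshold is ``T = k * center(magnitude)`` (``threshold_mode=
    'scaled'``, the default) or ``T = (1 + k) * center`` (``'offset'``,
    reading "k medians above the median" literally). Each maximal
    suprathreshold run contributes its peak; the event's onset/offset are
    the outward half-max crossings of that peak, interpolated between
    samples. Edge-truncated events are dropped and overlapping half-max
    windows merged keeping the larger peak.
    """
    if k < 1:
        raise ValueError("threshold multiplier k must be >= 1")
    mag = env.magnitude
    if mag.size == 0:
        raise ValueError("empty envelope")
    center_val = _threshold_center(mag, center)
    if threshold_mode == "scaled":
        threshold = k * center_val
    elif threshold_mode == "offset":
        threshold = (1.0 + k) * center_val
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")

    above = mag > threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1  # exclusive
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [mag.size]])

    candidates: list[BurstEvent] = []
    for s, e in zip(starts, ends):
        p = s + int(np.argmax(mag[s:e]))
        peak = mag[p]
        half = peak / 2.0
        j_left = _first_below(mag, p, half, -1)
        j_right = _first_below(mag, p, half, +1)
        if j_left < 0 or j_right >= mag.size:
            continue  # half-max window truncated by the record edge
        onset_idx = j_left + (half - mag[j_left]) / (mag[j_left + 1] - mag[j_left])
        offset_idx = j_right - (half - mag[j_right]) / (mag[j_right - 1] - mag[j_right])
        candidates.append(
            BurstEvent(
                onset_s=env.t0 + onset_idx / env.fs,
                offset_s=env.t0 + offset_idx / env.fs,
                peak_time_s=env.t0 + p / env.fs,
                peak_amp=float(peak),
            )
        )

    candidates.sort(key=lambda ev: ev.onset_s)
    merged: list[BurstEvent] = []
    for ev in candidates:
        if merged and ev.onset_s < merged[-1].offset_s:
            if ev.peak_amp > merged[-1].peak_amp:
                merged[-1] = ev
        else:
            merged.append(ev)
    return merged


def _segment_correlation(
    env: Envelope,
    events: list[BurstEvent],
    segment_len_s: float,
) -> float:
    """Pearson r between segment mean amplitude and segment burst count.

    Segments are consecutive non-overlapping windows; the trailing
    remainder is dropped. An event belongs to the segment containing its
    peak time. Returns NaN when either series has zero variance.
    """
    seg_n = int(round(segment_len_s * env.fs))
    n_seg = env.n_samples // seg_n
    if n_seg < 2:
        raise ValueError("envelope shorter than two segments")
    trimmed = env.magnitude[: n_seg * seg_n]
    seg_means = trimmed.reshape(n_seg, seg_n).mean(axis=1)
    peak_times = np.array([ev.peak_time_s - env.t0 for ev in events])
    counts, _ = np.histogram(
        peak_times, bins=n_seg, range=(0.0, n_seg * segment_len_s)
    )
    if seg_means.std() == 0 or counts.std() == 0:
        return np.nan
    return float(np.corrcoef(seg_means, counts)[0, 1])


def optimize_threshold(
    envelopes: list[Envelope],
    k_grid: np.ndarray | None = None,
    segment_len_s: float = 3.0,
    center: str = "median",
    threshold_mode: str = "scaled",
) -> ThresholdGrid:
    """Select the burst threshold by the amplitude/count correlation.

    For every multiplier in ``k_grid`` and every subject, correlates the
    per-3-s-segment mean envelope amplitude with the per-segment burst
    count; correlations are averaged across subjects and the multiplier
    with the highest mean correlation becomes ``k_star`` (first maximum
    on ties). Subjects with an undefined correlation at some ``k``
    (zero count variance, typical at high thresholds) are excluded from
    that ``k``'s average with a warning.
    """
    if len(envelopes) < 2:
        raise ValueError("threshold optimisation needs at least 2 subjects")
    if k_grid is None:
        k_grid = default_k_grid()
    k_grid = np.asarray(k_grid, dtype=float)

    mean_r = np.full(k_grid.size, np.nan)
    n_valid = np.zeros(k_grid.size, dtype=int)
    n_excluded = 0
    for i, k in enumerate(k_grid):
        rs = []
        for env in envelopes:
            events = detect_events(env, k, center=center, threshold_mode=threshold_mode)
            r = _segment_correlation(env, events, segment_len_s)
            if np.isnan(r):
                n_excluded += 1
            else:
                rs.append(r)
        n_valid[i] = len(rs)
        if rs:
            mean_r[i] = float(np.mean(rs))
    if n_excluded:
        warnings.warn(
            f"{n_excluded} subject/threshold correlations undefined "
            "(zero count variance) and excluded from the average",
            RuntimeWarning,
            stacklevel=2,
        )
    if np.all(np.isnan(mean_r)):
        raise ValueError("no threshold produced a defined correlation")
    k_star = float(k_grid[np.nanargmax(mean_r)])
    return ThresholdGrid(
        k_values=k_grid,
        segment_len_s=segment_len_s,
        mean_r=mean_r,
        n_valid=n_valid,
        k_star=k_star,
    )


def summarize_subject(
    events: list[BurstEvent],
    env: Envelope,
    subject: str = "",
    group: str = "",
    session: int = 1,
) -> SubjectBurstSummary:
    """The four burst features for one subject/session.

    Rate is events per analysed minute; the inter-burst interval is the
    time from one burst's offset to the next burst's onset (half-max
    boundaries on both sides).
    """
    events = sorted(events, key=lambda ev: ev.onset_s)
    analyzed_s = env.duration_s
    durations_ms = np.array([ev.duration_s * 1000.0 for ev in events])
    peak_amps = np.array([ev.peak_amp for ev in events])
    if len(events) > 1:
        onsets = np.array([ev.onset_s for ev in events])
        offsets = np.array([ev.offset_s for ev in events])
        ibis_ms = (onsets[1:] - offsets[:-1]) * 1000.0
    else:
        ibis_ms = np.empty(0)
    return SubjectBurstSummary(
        subject=subject,
        group=group,
        session=session,
        n_bursts=len(events),
        analyzed_s=analyzed_s,
        rate_per_min=len(events) / (analyzed_s / 60.0),
        durations_ms=durations_ms,
        ibis_ms=ibis_ms,
        peak_amps=peak_amps,
    )


def detect_cohort(
    cohort: CohortDataset,
    k: float,
    transformer=None,
    center: str = "median",
    threshold_mode: str = "scaled",
) -> tuple[list[SubjectBurstSummary], dict[tuple[str, int], list[BurstEvent]], list[str]]:
    """Detect bursts across a cohort at one fixed threshold.

    Returns (summaries, events per record, per-record error messages).
    Records that fail (e.g. missing signal) are collected and skipped so
    one bad file does not abort the run.
    """
    from .preprocess import BetaEnvelopeTransformer

    if transformer is None:
        transformer = BetaEnvelopeTransformer()
    summaries: list[SubjectBurstSummary] = []
    all_events: dict[tuple[str, int], list[BurstEvent]] = {}
    errors: list[str] = []
    for row, ts in cohort.iter_records():
        key = (row["subject"], int(row["session"]))
        try:
            if ts is None:
                raise FileNotFoundError(f"no signal for record {key}")
            env = transformer.fit(None).transform([ts])[0]
            events = detect_events(env, k, center=center, threshold_mode=threshold_mode)
            summaries.append(
                summarize_subject(
                    events, env, subject=key[0], group=row["group"], session=key[1]
                )
            )
            all_events[key] = events
        except Exception as exc:  # noqa: BLE001 - collected, not swallowed
            errors.append(f"{key}: {exc}")
    return summaries, all_events, errors


class BurstDetector(BaseEstimator, TransformerMixin):
    """Scikit-learn style burst detector with a data-driven threshold.

    ``fit`` takes a list of :class:`Envelope` (one per subject) and, when
    ``k='auto'``, runs the segment-correlation threshold search storing
    the chosen multiplier as ``k_`` and the full grid as ``grid_``.
    ``transform`` maps envelopes to per-subject lists of
    :class:`BurstEvent` at the fitted threshold.

    Parameters
    ----------
    k : 'auto' or float
        Fixed threshold multiplier, or 'auto' to optimise it.
    k_min, k_max, k_step : float
        Search grid for ``k='auto'`` (defaults: median to 5x median in
        steps of 0.1).
    segment_len_s : float
        Segment length of the correlation criterion.
    center : {'median', 'mean', 'mode'}
        Envelope center statistic the threshold multiplies.
    threshold_mode : {'scaled', 'offset'}
        ``scaled``: T = k*center; ``offset``: T = (1+k)*center.
    """

    def __init__(
        self,
        k: str | float = "auto",
        k_min: float = 1.0,
        k_max: float = 5.0,
        k_step: float = 0.1,
        segment_len_s: float = 3.0,
        center: str = "median",
        threshold_mode: str = "scaled",
    ):
        self.k = k
        self.k_min = k_min
        self.k_max = k_max
        self.k_step = k_step
        self.segment_len_s = segment_len_s
        self.center = center
        self.threshold_mode = threshold_mode

    def fit(self, X: list[Envelope], y=None):
        if self.k == "auto":
            self.grid_ = optimize_threshold(
                X,
                k_grid=default_k_grid(self.k_min, self.k_max, self.k_step),
                segment_len_s=self.segment_len_s,
                center=self.center,
                threshold_mode=self.threshold_mode,
            )
            self.k_ = self.grid_.k_star
        else:
            self.grid_ = None
            self.k_ = float(self.k)
        return self

    def transform(self, X: list[Envelope]) -> list[list[BurstEvent]]:
        if not hasattr(self, "k_"):
            raise RuntimeError("BurstDetector is not fitted")
        return [
            detect_events(env, self.k_, center=self.center, threshold_mode=self.threshold_mode)
            for env in X
        ]
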
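import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from betabursts.bursts import (
    BurstDetector,
    default_k_grid,
    detect_cohort,
    detect_events,
    optimize_threshold,
    summarize_subject,
)
from betabursts.datatypes import Envelope
from conftest import gaussian_bump_envelope

FS = 1000.0


def random_envelope(seed, duration_s=20.0):
    """Beta-filtered noise magnitude: a realistic random envelope."""
    from betabursts.preprocess import BetaEnvelopeTransformer
    from betabursts.simulate import NoiseGenSpec, gen_aperiodic_noise

    ts = gen_aperiodic_noise(NoiseGenSpec(exponent=0.8, duration_s=duration_s), seed)
    return BetaEnvelopeTransformer().fit([ts]).transform([ts])[0]


class TestDetectEvents:
    def test_constant_envelope_no_events(self):
        env = Envelope(np.ones(5000), fs=FS, band=(13, 30))
        assert detect_events(env, 2.0) == []

    def test_gaussian_bump_half_max_duration_is_fwhm(self):
        # for an isolated Gaussian bump on a negligible baseline, the
        # half-max duration equals the FWHM = 2*sqrt(2 ln 2)*sigma
        sigma = 0.030
        env = gaussian_bump_envelope(baseline=0.01, bumps=((5.0, 3.0, sigma),))
        events = detect_events(env, 2.0)
        assert len(events) == 1
        fwhm_ms = 2 * np.sqrt(2 * np.log(2)) * sigma * 1000.0
        assert events[0].duration_s * 1000.0 == pytest.approx(fwhm_ms, abs=2.0)
        assert events[0].peak_amp == pytest.approx(3.0, rel=1e-6)
        assert events[0].peak_time_s == pytest.approx(5.0, abs=0.002)

    def test_gaussian_bump_on_baseline_closed_form(self):
        # with baseline b and peak p, the half-max level p/2 crosses the
        # bump where b + (p-b) exp(-t^2 / 2 sigma^2) = p/2
        sigma, base, peak = 0.030, 1.0, 3.0
        env = gaussian_bump_envelope(baseline=base, bumps=((5.0, peak, sigma),))
        events = detect_events(env, 2.0)
        assert len(events) == 1
        t_half = sigma * np.sqrt(2 * np.log((peak - base) / (peak / 2 - base)))
        assert events[0].duration_s == pytest.approx(2 * t_half, abs=0.002)

    @pytest.mark.parametrize("seed", range(6))
    def test_count_monotone_nonincreasing_in_k(self, seed):
        env = random_envelope(seed)
        counts = [len(detect_events(env, k)) for k in (1.0, 1.5, 2.0, 3.0, 5.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_scale_invariance_of_detection(self):
        env = random_envelope(10)
        base = detect_events(env, 2.0)
        scaled_env = Envelope(env.magnitude * 7.3, fs=env.fs, band=env.band, t0=env.t0)
        scaled = detect_events(scaled_env, 2.0)
        assert len(base) == len(scaled)
        for a, b in zip(base, scaled):
            assert a.onset_s == pytest.approx(b.onset_s, abs=1e-9)
            assert a.offset_s == pytest.approx(b.offset_s, abs=1e-9)
            assert b.peak_amp == pytest.approx(7.3 * a.peak_amp, rel=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_events_disjoint_and_bounded(self, seed):
        env = random_envelope(seed + 20)
        events = detect_events(env, 1.5)
        for a, b in zip(events, events[1:]):
            assert b.onset_s >= a.offset_s
        total = sum(ev.duration_s for ev in events)
        assert total <= env.duration_s

    def test_offset_mode_is_stricter_than_scaled(self):
        env = random_envelope(30)
        n_scaled = len(detect_events(env, 1.5, threshold_mode="scaled"))
        n_offset = len(detect_events(env, 1.5, threshold_mode="offset"))
        assert n_offset <= n_scaled

    def test_k_below_one_rejected(self):
        env = gaussian_bump_envelope()
        with pytest.raises(ValueError, match="k"):
            detect_events(env, 0.5)

    def test_empty_envelope_rejected(self):
        env = Envelope(np.ones(10), fs=FS, band=(13, 30))
        env.magnitude = np.empty(0)
        with pytest.raises(ValueError, match="empty"):
            detect_events(env, 2.0)

    def test_edge_truncated_event_discarded(self):
        # bump centered at t=0: its half-max window starts before the record
        env = gaussian_bump_envelope(bumps=((0.0, 5.0, 0.05),))
        events = detect_events(env, 2.0)
        assert all(ev.peak_time_s > 0.2 for ev in events)


class TestOptimizeThreshold:
    def test_single_k_grid(self):
        envs = [random_envelope(s) for s in range(2)]
        grid = optimize_threshold(envs, k_grid=np.array([2.0]))
        assert grid.k_star == 2.0

    def test_interior_optimum_with_planted_bursts(self, small_cohort, small_envelopes):
        envs = list(small_envelopes.values())
        grid = optimize_threshold(envs, k_grid=default_k_grid(k_step=0.5))
        i_star = list(grid.k_values).index(grid.k_star)
        assert grid.mean_r[i_star] >= np.nanmax([grid.mean_r[0], grid.mean_r[-1]])

    def test_needs_two_subjects(self):
        with pytest.raises(ValueError, match="2 subjects"):
            optimize_threshold([random_envelope(0)])

    def test_zero_variance_correlations_warn_and_excluded(self):
        # at k=25 the threshold exceeds the bump peak: zero events in every
        # segment, undefined correlation, excluded with a warning
        env = gaussian_bump_envelope(duration_s=12.0, bumps=((6.0, 3.0, 0.02),))
        with pytest.warns(RuntimeWarning, match="undefined"):
            grid = optimize_threshold([env, env], k_grid=np.array([1.0, 25.0]))
        assert grid.k_star == 1.0
        assert np.isnan(grid.mean_r[1])
        assert grid.n_valid[1] == 0


class TestSummaries:
    def test_rate_arithmetic(self):
        from betabursts.datatypes import BurstEvent

        env = Envelope(np.ones(int(180 * FS)), fs=FS, band=(13, 30))
        events = [
            BurstEvent(onset_s=t, offset_s=t + 0.05, peak_time_s=t + 0.02, peak_amp=2.0)
            for t in np.linspace(0.1, 179.0, 360)
        ]
        s = summarize_subject(events, env)
        assert s.rate_per_min == pytest.approx(120.0)

    def test_inter_burst_interval_definition(self):
        from betabursts.datatypes import BurstEvent

        env = Envelope(np.ones(int(10 * FS)), fs=FS, band=(13, 30))
        events = [
            BurstEvent(onset_s=0.900, offset_s=1.000, peak_time_s=0.95, peak_amp=2.0),
            BurstEvent(onset_s=1.199, offset_s=1.300, peak_time_s=1.25, peak_amp=2.0),
        ]
        s = summarize_subject(events, env)
        assert s.ibis_ms.tolist() == pytest.approx([199.0])

    def test_zero_events(self):
        env = Envelope(np.ones(int(10 * FS)), fs=FS, band=(13, 30))
        s = summarize_subject([], env)
        assert s.rate_per_min == 0.0
        assert s.durations_ms.size == 0
        assert np.isnan(s.median_duration_ms)


class TestDetectCohort:
    def test_all_records_summarised(self, small_cohort):
        summaries, events, errors = detect_cohort(small_cohort, k=2.0)
        assert len(summaries) == len(small_cohort)
        assert not errors

    def test_detected_rate_tracks_truth_at_high_snr(self):
        """With strong planted events (amplitude well above the noise
        envelope) and a wide rate spread, detected rates track the
        planted per-subject rates."""
        from betabursts.preprocess import BetaEnvelopeTransformer
        from betabursts.simulate import BurstGenSpec, GroupSpec, NoiseGenSpec, gen_subject

        group = GroupSpec(
            label="patient",
            n_subjects=8,
            rate_mean=110.0,
            rate_sd=30.0,
            noise=NoiseGenSpec(exponent=0.8, scale=1.1, duration_s=120.0),
            burst=BurstGenSpec(amplitude_mean=3.0, amplitude_sd=0.3),
        )
        tr = BetaEnvelopeTransformer()
        det, tru = [], []
        for i in range(8):
            subj = gen_subject(group, f"p{i}", 1, 60 + i)
            env = tr.fit(None).transform([subj.signal])[0]
            summary = summarize_subject(detect_events(env, 2.0), env)
            det.append(summary.rate_per_min)
            tru.append(subj.truth_rate)
        assert np.corrcoef(det, tru)[0, 1] > 0.9

    def test_planted_events_overlap_suprathreshold_intervals(self):
        """High-SNR, band-confined events: essentially every planted event
        coincides with a suprathreshold envelope interval (rare misses
        come from phase cancellation between overlapping events)."""
        from betabursts.preprocess import BetaEnvelopeTransformer
        from betabursts.simulate import BurstGenSpec, GroupSpec, NoiseGenSpec, gen_subject

        group = GroupSpec(
            label="patient",
            n_subjects=4,
            rate_mean=110.0,
            rate_sd=10.0,
            noise=NoiseGenSpec(exponent=0.8, scale=1.1, duration_s=120.0),
            burst=BurstGenSpec(
                amplitude_mean=3.0,
                amplitude_sd=0.0,
                duration_ms_mean=90.0,
                duration_ms_sd=20.0,
                duration_ms_min=60.0,
            ),
        )
        tr = BetaEnvelopeTransformer()
        missed = total = 0
        for i in range(4):
            subj = gen_subject(group, f"p{i}", 1, 60 + i)
            env = tr.fit(None).transform([subj.signal])[0]
            threshold = 2.0 * np.median(env.magnitude)
            for onset, dur, _, _ in subj.truth_events:
                if onset < env.t0 or onset + dur > env.t0 + env.duration_s:
                    continue
                i0 = int((onset - env.t0) * env.fs)
                i1 = int((onset + dur - env.t0) * env.fs)
                total += 1
                if env.magnitude[i0 : i1 + 1].max() <= threshold:
                    missed += 1
        assert missed / total < 0.005

    def test_missing_signal_collected_not_fatal(self, small_cohort):
        import copy

        broken = copy.copy(small_cohort)
        broken.signals = dict(small_cohort.signals)
        key = next(iter(broken.signals))
        broken.signals[key] = None
        summaries, _, errors = detect_cohort(broken, k=2.0)
        assert len(errors) == 1
        assert len(summaries) == len(small_cohort) - 1

    def test_high_threshold_never_more_events(self, small_envelopes):
        for env in small_envelopes.values():
            assert len(detect_events(env, 5.0)) <= len(detect_events(env, 2.0))


class TestEmergentDuration:
    def test_duration_stable_across_noise_seeds(self):
        """Median half-max duration of beta-filtered 1/f noise bursts is an
        emergent property of the band, stable across noise realisations."""
        medians = []
        for seed in range(20):
            env = random_envelope(seed + 100, duration_s=30.0)
            events = detect_events(env, 2.0)
            medians.append(np.median([ev.duration_s for ev in events]) * 1000.0)
        medians = np.array(medians)
        assert medians.std() / medians.mean() < 0.12
        assert 55.0 < medians.mean() < 90.0


class TestBurstDetector:
    def test_fixed_k_no_grid(self, small_envelopes):
        det = BurstDetector(k=2.5).fit(list(small_envelopes.values()))
        assert det.k_ == 2.5
        assert det.grid_ is None

    def test_auto_k_sets_grid(self, small_envelopes):
        det = BurstDetector(k_step=0.5).fit(list(small_envelopes.values()))
        assert det.grid_ is not None
        assert det.k_ == det.grid_.k_star

    def test_transform_before_fit_rejected(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            BurstDetector().transform([gaussian_bump_envelope()])

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        det = BurstDetector(k=3.0, segment_len_s=2.0)
        det2 = clone(det)
        assert det2.get_params() == det.get_params()


@given(st.lists(st.floats(0.1, 10.0), min_size=20, max_size=60), st.floats(1.0, 4.0))
def test_detection_threshold_scale_free(mags, k):
    """Multiplying any envelope by c > 0 never changes the event count."""
    mag = np.repeat(np.asarray(mags), 25)  # smooth-ish steps
    env_a = Envelope(mag, fs=FS, band=(13, 30))
    env_b = Envelope(mag * 3.7, fs=FS, band=(13, 30))
    assert len(detect_events(env_a, k)) == len(detect_events(env_b, k))
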
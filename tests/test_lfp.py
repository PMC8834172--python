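"""Signal chain: filter responses, spectral identities, detection, locking."""

import numpy as np
import pytest

from scnpair.lfp import (
    LfpTrace,
    SpikeEvent,
    TraceError,
    detect_spikes,
    power_spectrum,
    preprocess,
    read_trace_csv,
    robust_sd,
    stimulus_locked_responses,
    write_trace_csv,
)
from scnpair.synthetic import LfpSimSpec, simulate_lfp


def rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.asarray(x) ** 2)))


def sinusoid(freq: float, duration: float = 20.0, fs: float = 1000.0) -> LfpTrace:
    t = np.arange(0, duration, 1 / fs)
    return LfpTrace(fs=fs, samples=np.sin(2 * np.pi * freq * t))


class TestPreprocess:
    def test_mains_frequency_suppressed(self):
        trace = sinusoid(50.0)
        out = preprocess(trace)
        assert rms(out.samples) < 0.05 * rms(trace.samples)

    def test_passband_amplitude_preserved(self):
        trace = sinusoid(10.0)
        out = preprocess(trace)
        assert rms(out.samples) == pytest.approx(rms(trace.samples), rel=0.05)

    def test_dc_offset_removed(self):
        trace = LfpTrace(fs=1000.0, samples=np.full(20_000, 3.7))
        out = preprocess(trace)
        assert rms(out.samples) < 0.05

    def test_length_preserved_without_trim(self):
        trace = sinusoid(10.0)
        assert preprocess(trace).samples.size == trace.samples.size

    def test_lead_trim_drops_placement_time(self):
        trace = sinusoid(10.0, duration=30.0)
        out = preprocess(trace, trim_lead_s=10.0)
        assert out.samples.size == 20_000
        assert out.t0 == pytest.approx(10.0)

    def test_idempotent_on_passband_content(self):
        # pass-band interior tones: a second filter application is a no-op
        t = np.arange(0, 30, 1 / 1000.0)
        x = np.sin(2 * np.pi * 10 * t) + 0.5 * np.sin(2 * np.pi * 30 * t)
        once = preprocess(LfpTrace(fs=1000.0, samples=x))
        twice = preprocess(once)
        assert abs(rms(twice.samples) - rms(once.samples)) < 0.01 * rms(once.samples)

    def test_short_trace_rejected(self):
        with pytest.raises(TraceError, match="warm-up"):
            preprocess(LfpTrace(fs=1000.0, samples=np.zeros(100)))

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(TraceError, match="band edge"):
            preprocess(LfpTrace(fs=150.0, samples=np.zeros(10_000)))


class TestPowerSpectrum:
    def test_sinusoid_peaks_at_its_frequency(self):
        spec = power_spectrum(sinusoid(10.0, duration=40.0), window_s=40.0)
        assert spec.freqs[np.argmax(spec.power)] == pytest.approx(10.0)
        assert spec.freqs[1] - spec.freqs[0] == pytest.approx(1 / 40.0)

    def test_parseval_identity(self):
        trace, _ = simulate_lfp(LfpSimSpec(duration_s=40, seed=2))
        spec = power_spectrum(trace, window_s=40.0)
        from scipy.signal import detrend

        x = detrend(trace.samples, type="linear") * np.hanning(trace.samples.size)
        energy = float(np.sum(x**2))
        assert abs(spec.power.sum() - energy) / energy < 1e-6

    def test_power_non_negative(self):
        trace, _ = simulate_lfp(LfpSimSpec(duration_s=40, noise_model="one_over_f", seed=3))
        spec = power_spectrum(trace, window_s=40.0)
        assert np.all(spec.power >= 0)
        assert spec.freqs[0] == 0.0 and spec.freqs[-1] == pytest.approx(trace.fs / 2)

    def test_short_trace_rejected(self):
        with pytest.raises(TraceError, match="does not fit"):
            power_spectrum(sinusoid(10.0, duration=20.0), window_s=40.0)

    def test_event_traces_enrich_both_bands(self):
        """Injected events raise integrated low- and high-band power vs paired baseline."""
        for seed in range(5):
            on, _ = simulate_lfp(LfpSimSpec(duration_s=40, spont_event_rate_per_min=9, seed=seed))
            off, _ = simulate_lfp(LfpSimSpec(duration_s=40, spont_event_rate_per_min=0, seed=seed))
            ps_on = power_spectrum(preprocess(on), 40.0)
            ps_off = power_spectrum(preprocess(off), 40.0)
            assert ps_on.band_power(2.5, 20) > ps_off.band_power(2.5, 20)
            assert ps_on.band_power(40, 100) > ps_off.band_power(40, 100)


class TestDetectSpikes:
    def test_exact_recovery_of_separated_events(self):
        from scnpair.synthetic import biphasic_template

        fs = 1000.0
        true_onsets = [5.0, 20.0, 40.0]
        x = np.zeros(int(60 * fs))
        template = biphasic_template(fs, 0.030, amplitude=5.0)
        for t in true_onsets:
            i = int(t * fs)
            x[i : i + template.size] += template
        # tiny jitter keeps the robust-SD denominator finite on a silent baseline
        x += np.random.default_rng(0).normal(0, 0.01, x.size)
        events = detect_spikes(LfpTrace(fs=fs, samples=x), k=5.0)
        assert len(events) == 3
        for det, true in zip(events, true_onsets):
            assert abs(det.onset_s - true) < 0.010

    def test_all_zero_trace_warns_and_returns_empty(self):
        trace = LfpTrace(fs=1000.0, samples=np.zeros(1000))
        with pytest.warns(UserWarning, match="zero-variance"):
            assert detect_spikes(trace) == []

    def test_sensitivity_monotone_in_threshold(self):
        trace, _ = simulate_lfp(LfpSimSpec(duration_s=60, spont_event_rate_per_min=10, seed=5))
        clean = preprocess(trace)
        counts = [len(detect_spikes(clean, k=k)) for k in (3, 5, 8, 12)]
        assert counts == sorted(counts, reverse=True)

    def test_false_positive_rate_at_high_threshold(self):
        """Pure Gaussian noise at k=8: well under 1 false positive per 10 min."""
        fp = 0
        for seed in range(5):
            trace, _ = simulate_lfp(
                LfpSimSpec(duration_s=600, spont_event_rate_per_min=0, seed=seed)
            )
            fp += len(detect_spikes(preprocess(trace), k=8.0))
        assert fp / 5 < 1.0

    def test_amplitudes_exceed_threshold(self):
        trace, _ = simulate_lfp(LfpSimSpec(duration_s=60, spont_event_rate_per_min=10, seed=6))
        for ev in detect_spikes(trace, k=5.0):
            assert ev.amplitude_sd >= 5.0

    def test_mutant_wildtype_separation(self):
        """Event counts separate event-bearing from event-free recordings."""
        for seed in range(10):
            mut, _ = simulate_lfp(LfpSimSpec(duration_s=120, spont_event_rate_per_min=6, seed=seed))
            wt, _ = simulate_lfp(LfpSimSpec(duration_s=120, spont_event_rate_per_min=0, seed=seed + 1000))
            n_mut = len(detect_spikes(preprocess(mut)))
            n_wt = len(detect_spikes(preprocess(wt)))
            assert n_mut > n_wt


class TestStimulusLocking:
    def test_saturating_response(self):
        stims = tuple(float(t) for t in np.arange(15.0, 300.0, 30.0))
        trace, _ = simulate_lfp(
            LfpSimSpec(duration_s=300, spont_event_rate_per_min=0,
                       stimulus_times=stims, stimulus_response_prob=1.0, seed=7)
        )
        events = detect_spikes(preprocess(trace))
        table, fraction, events = stimulus_locked_responses(events, stims)
        assert fraction == 1.0
        assert table["hit"].all()
        assert all(e.stimulus_locked is not None for e in events)

    def test_events_between_windows_stay_spontaneous(self):
        events = [SpikeEvent(onset_s=t, peak_s=t, amplitude_sd=6.0, polarity=1)
                  for t in (5.0, 17.0, 29.0)]
        table, fraction, labelled = stimulus_locked_responses(events, [10.0, 20.0], 0.5)
        assert fraction == 0.0
        assert all(e.stimulus_locked is None for e in labelled)

    def test_empty_stimulus_list_gives_undefined_fraction(self):
        events = [SpikeEvent(onset_s=1.0, peak_s=1.0, amplitude_sd=6.0, polarity=1)]
        table, fraction, labelled = stimulus_locked_responses(events, [])
        assert fraction is None
        assert table.empty
        assert labelled[0].stimulus_locked is None

    def test_mean_fraction_tracks_response_probability(self):
        """Binomial oracle at p=0.6 on truth-level events (20-seed subsample)."""
        stims = tuple(float(t) for t in np.arange(15.0, 300.0, 30.0))
        fracs = []
        for seed in range(20):
            trace, _ = simulate_lfp(
                LfpSimSpec(duration_s=300, spont_event_rate_per_min=0,
                           stimulus_times=stims, stimulus_response_prob=0.6, seed=seed)
            )
            events = detect_spikes(preprocess(trace))
            _, frac, _ = stimulus_locked_responses(events, stims)
            fracs.append(frac)
        se = np.sqrt(0.6 * 0.4 / (10 * 20))
        assert abs(np.mean(fracs) - 0.6) < 4 * se


class TestTraceIO:
    def test_round_trip_with_stimuli(self, tmp_path):
        stims = (1.0, 2.5)
        trace, _ = simulate_lfp(LfpSimSpec(duration_s=5, stimulus_times=stims, seed=8))
        csv = tmp_path / "trace.csv"
        stim_file = tmp_path / "stimuli.txt"
        write_trace_csv(trace, csv)
        stim_file.write_text("1.0\n2.5\n")
        back = read_trace_csv(csv, stimulus_path=stim_file)
        assert back.stimulus_times == stims
        np.testing.assert_allclose(back.samples, trace.samples, atol=1e-5)

    def test_single_column_requires_fs(self, tmp_path):
        path = tmp_path / "vals.csv"
        path.write_text("value\n0.0\n1.0\n0.0\n")
        with pytest.raises(TraceError, match="fs"):
            read_trace_csv(path)
        assert read_trace_csv(path, fs=500.0).fs == 500.0

    def test_nonuniform_time_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_s,value\n0.0,0\n0.001,1\n0.005,0\n")
        with pytest.raises(TraceError, match="uniform"):
            read_trace_csv(path)


def test_robust_sd_matches_gaussian_sd():
    rng = np.random.default_rng(9)
    x = rng.normal(0, 2.0, size=100_000)
    assert robust_sd(x) == pytest.approx(2.0, rel=0.02)
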
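"""Spectrogram, sigma trace, thresholding, detection and event metrics."""

import numpy as np
import pytest
from scipy.signal.windows import hann

from spindlepipe import (
    Hypnogram,
    SleepState,
    compute_spectrogram,
    compute_threshold,
    detect_spindle_events,
    detect_spindles,
    sigma_power_trace,
    spindle_density,
    spindle_mean_frequency,
    spindle_rms,
)
from spindlepipe.spindles import SigmaPowerTrace, SpindleEvent
from spindlepipe.synthetic import inject_spindle, pink_noise

from conftest import intervals_match, truth_hypnogram

FS = 250.0


def _nrem_hypnogram(seconds, epoch_length=5.0):
    return Hypnogram(np.full(int(seconds / epoch_length), SleepState.NREM),
                     epoch_length)


def _noise(seconds, seed, rms=15.0):
    return rms * pink_noise(int(seconds * FS), FS, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# compute_spectrogram
# ---------------------------------------------------------------------------

def test_pure_tone_localized_to_its_bin():
    t = np.arange(int(20 * FS)) / FS
    spec = compute_spectrogram(np.sin(2 * np.pi * 13.0 * t), FS)
    mean_spectrum = spec.power.mean(axis=0)
    assert spec.freqs[np.argmax(mean_spectrum)] == pytest.approx(13.0, abs=spec.df)


def test_zero_signal_gives_zero_power():
    spec = compute_spectrogram(np.zeros(int(10 * FS)), FS)
    assert np.all(spec.power == 0.0)


def test_single_window_matches_direct_dft_periodogram():
    """The first spectrogram column equals the direct DFT periodogram of the
    first Hann-tapered segment (one-sided density convention)."""
    rng = np.random.default_rng(4)
    x = rng.standard_normal(int(4 * FS))
    spec = compute_spectrogram(x, FS, window=1.0, step=1.0)
    nperseg = int(FS)
    w = hann(nperseg, sym=False)
    seg = x[:nperseg] * w
    pxx = (np.abs(np.fft.rfft(seg)) ** 2) / (FS * np.sum(w ** 2))
    pxx[1:] *= 2.0
    if nperseg % 2 == 0:
        pxx[-1] /= 2.0
    assert np.allclose(spec.power[0], pxx, rtol=1e-9)


def test_parseval_consistency_on_white_noise():
    """Total spectrogram energy matches the windowed time-domain energy
    within 5% on white noise."""
    rng = np.random.default_rng(5)
    x = rng.standard_normal(int(60 * FS))
    spec = compute_spectrogram(x, FS, window=1.0, step=1.0)
    spectral = np.mean(spec.power.sum(axis=1)) * spec.df
    assert spectral == pytest.approx(np.var(x), rel=0.05)


def test_frequency_grid_at_most_one_hertz():
    spec = compute_spectrogram(np.zeros(int(10 * FS)), FS, window=0.2, step=0.1)
    assert spec.df <= 1.0 + 1e-9
    assert spec.freqs[-1] >= 40.0


def test_window_longer_than_signal_rejected():
    with pytest.raises(ValueError):
        compute_spectrogram(np.zeros(100), FS, window=1.0, step=0.1)


# ---------------------------------------------------------------------------
# sigma_power_trace
# ---------------------------------------------------------------------------

def test_in_band_tone_dominates_sigma_trace():
    t = np.arange(int(20 * FS)) / FS
    spec = compute_spectrogram(np.sin(2 * np.pi * 13.0 * t), FS)
    sigma = sigma_power_trace(spec).sigma_power
    total = spec.power.sum(axis=1) * spec.df
    assert np.all(sigma >= 0.90 * total)


def test_out_of_band_tone_contributes_little():
    t = np.arange(int(20 * FS)) / FS
    spec = compute_spectrogram(np.sin(2 * np.pi * 25.0 * t), FS)
    sigma = sigma_power_trace(spec).sigma_power
    total = spec.power.sum(axis=1) * spec.df
    assert np.all(sigma <= 0.05 * total)


def test_band_sum_equals_column_summation():
    rng = np.random.default_rng(6)
    spec = compute_spectrogram(rng.standard_normal(int(10 * FS)), FS)
    trace = sigma_power_trace(spec, band=(12.0, 20.0))
    cols = (spec.freqs >= 12.0) & (spec.freqs <= 20.0)
    assert np.allclose(trace.sigma_power, spec.power[:, cols].sum(axis=1) * spec.df)


def test_empty_band_intersection_rejected():
    spec = compute_spectrogram(np.zeros(int(10 * FS)), FS)
    with pytest.raises(ValueError):
        sigma_power_trace(spec, band=(500.0, 600.0))


# ---------------------------------------------------------------------------
# compute_threshold
# ---------------------------------------------------------------------------

def _trace(values, step=1.0):
    values = np.asarray(values, dtype=float)
    times = np.arange(values.size) * step + step / 2
    return SigmaPowerTrace(times=times, sigma_power=values, step=step)


def test_constant_trace_threshold_is_the_constant():
    hyp = _nrem_hypnogram(20.0)
    assert compute_threshold(_trace([3.0] * 16), hyp, k_sd=2.5) == 3.0


def test_hand_computed_population_sd_convention():
    """(1,1,1,5) all-NREM, k=1: mean 2, population SD sqrt(3), threshold 2+sqrt(3)."""
    hyp = _nrem_hypnogram(20.0)
    thr = compute_threshold(_trace([1.0, 1.0, 1.0, 5.0]), hyp, k_sd=1.0)
    assert thr == pytest.approx(2.0 + np.sqrt(3.0))


def test_zero_k_gives_nrem_mean():
    hyp = _nrem_hypnogram(20.0)
    assert compute_threshold(_trace([1.0, 3.0]), hyp, k_sd=0.0) == 2.0


def test_no_nrem_requires_explicit_threshold():
    hyp = Hypnogram(np.full(4, SleepState.WAKE))
    with pytest.raises(ValueError, match="explicit threshold"):
        compute_threshold(_trace([1.0, 2.0]), hyp)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def nrem_background():
    """60-s NREM background, its trace threshold, and a quiet injection site."""
    seconds = 60.0
    hyp = _nrem_hypnogram(seconds)
    noise = _noise(seconds, seed=7)
    trace = sigma_power_trace(compute_spectrogram(noise, FS))
    thr = compute_threshold(trace, hyp)
    best_c, best_v = None, np.inf
    for c in np.arange(8.0, seconds - 8.0, 0.5):
        m = (trace.times >= c - 2.5) & (trace.times <= c + 2.5)
        v = trace.sigma_power[m].max()
        if v < best_v:
            best_c, best_v = float(c), v
    return noise, hyp, thr, best_c


def test_injected_one_second_burst_detected_once(nrem_background):
    noise, hyp, thr, c = nrem_background
    sig = inject_spindle(noise, FS, c - 0.5, 1.0, 13.0, 300.0)
    det = detect_spindle_events(sig, FS, hyp, threshold=thr)
    hits = [e for e in det.events
            if intervals_match((e.start, e.end), (c - 0.5, c + 0.5), 0.8)]
    assert len(hits) == 1


@pytest.mark.parametrize("duration", [0.3, 2.5])
def test_out_of_duration_bursts_rejected(nrem_background, duration):
    noise, hyp, thr, c = nrem_background
    sig = inject_spindle(noise, FS, c - duration / 2, duration, 13.0, 300.0)
    det = detect_spindle_events(sig, FS, hyp, threshold=thr)
    hits = [e for e in det.events
            if intervals_match((e.start, e.end), (c - duration / 2, c + duration / 2))]
    assert hits == []


def test_burst_in_wake_epoch_rejected(nrem_background):
    noise, _, thr, c = nrem_background
    states = np.full(12, SleepState.NREM)
    states[int(c // 5)] = SleepState.WAKE
    hyp = Hypnogram(states)
    sig = inject_spindle(noise, FS, c - 0.5, 1.0, 13.0, 300.0)
    det = detect_spindle_events(sig, FS, hyp, threshold=thr)
    hits = [e for e in det.events
            if intervals_match((e.start, e.end), (c - 0.5, c + 0.5))]
    assert hits == []


def test_event_count_monotone_in_threshold(recovery_recording):
    config, rec, truth = recovery_recording
    hyp = truth_hypnogram(config, truth)
    base = detect_spindle_events(rec.eeg, rec.sampling_rate, hyp)
    counts = [
        len(detect_spindle_events(rec.eeg, rec.sampling_rate, hyp,
                                  threshold=base.threshold * m).events)
        for m in (0.5, 1.0, 2.0, 4.0, 8.0, 16.0)
    ]
    assert all(a >= b for a, b in zip(counts, counts[1:])), counts


def test_recovery_recall_precision_and_invariants(recovery_recording):
    """On the high-SNR generator, event recall and precision reach 0.9
    (>= 50% interval overlap); every event respects the duration filter and
    its mean frequency lies in the band."""
    config, rec, truth = recovery_recording
    hyp = truth_hypnogram(config, truth)
    det = detect_spindle_events(rec.eeg, rec.sampling_rate, hyp)
    gt = [(t.start, t.end) for t in truth.spindle_events]
    found = [(e.start, e.end) for e in det.events]
    recall = np.mean([any(intervals_match(t, f) for f in found) for t in gt])
    precision = np.mean([any(intervals_match(f, t) for t in gt) for f in found])
    assert recall >= 0.9
    assert precision >= 0.9
    for e in det.events:
        assert 0.5 <= e.duration <= 2.0
        assert 12.0 <= e.mean_frequency <= 20.0


def test_coarse_run_detector_contract():
    """The coarse run detector keeps only duration-admissible NREM runs."""
    hyp = Hypnogram(np.array([SleepState.NREM] * 2 + [SleepState.WAKE] * 2))
    values = np.zeros(195)
    times = np.arange(195) * 0.1 + 0.05
    values[20:30] = 10.0    # 1.0 s run in NREM
    values[50:52] = 10.0    # 0.2 s run, too short
    values[120:130] = 10.0  # run in WAKE
    trace = SigmaPowerTrace(times=times, sigma_power=values, step=0.1)
    out = detect_spindles(trace, threshold=5.0, hypnogram=hyp)
    assert len(out) == 1
    s, e = out[0]
    assert s == pytest.approx(2.0) and e == pytest.approx(3.0)


# ---------------------------------------------------------------------------
# event metrics
# ---------------------------------------------------------------------------

def test_rms_of_constant_signal():
    assert spindle_rms(np.full(100, -3.0), (0.0, 0.4), FS) == 3.0


def test_rms_of_sinusoid_is_amplitude_over_sqrt2():
    t = np.arange(int(2 * FS)) / FS
    a = 40.0
    rms = spindle_rms(a * np.sin(2 * np.pi * 10.0 * t), (0.0, 2.0), FS)
    assert rms == pytest.approx(a / np.sqrt(2), rel=0.01)


def test_rms_matches_elementwise_oracle():
    x = np.array([1.0, -2.0, 3.0, 0.5, -1.5, 2.5, -0.5, 1.0, -3.0, 2.0])
    assert spindle_rms(x, (0.0, 1.0), 10.0) == pytest.approx(
        np.sqrt(np.sum(x ** 2) / x.size)
    )


def test_empty_interval_rejected():
    with pytest.raises(ValueError):
        spindle_rms(np.zeros(100), (0.2, 0.2), FS)


def test_mean_frequency_of_pure_tone():
    t = np.arange(int(2 * FS)) / FS
    x = np.sin(2 * np.pi * 13.0 * t)
    assert spindle_mean_frequency(x, (0.0, 2.0), FS) == pytest.approx(13.0, abs=0.5)


def test_mean_frequency_of_symmetric_mixture():
    t = np.arange(int(2 * FS)) / FS
    x = np.sin(2 * np.pi * 12.0 * t) + np.sin(2 * np.pi * 14.0 * t)
    assert spindle_mean_frequency(x, (0.0, 2.0), FS) == pytest.approx(13.0, abs=0.5)


def test_mean_frequency_weighted_average_oracle():
    """Powers (1, 2, 1) at (12, 14, 16) Hz average to 14 Hz."""
    t = np.arange(int(2 * FS)) / FS
    x = (np.sin(2 * np.pi * 12.0 * t) + np.sqrt(2) * np.sin(2 * np.pi * 14.0 * t)
         + np.sin(2 * np.pi * 16.0 * t))
    assert spindle_mean_frequency(x, (0.0, 2.0), FS) == pytest.approx(14.0, abs=0.5)


def test_mean_frequency_with_no_in_band_power_is_nan():
    value = spindle_mean_frequency(np.zeros(int(2 * FS)), (0.0, 2.0), FS)
    assert np.isnan(value)


# ---------------------------------------------------------------------------
# spindle_density
# ---------------------------------------------------------------------------

def _event(start, end):
    return SpindleEvent(start=start, end=end, duration=end - start, rms=1.0,
                        mean_frequency=13.0, peak_sigma_power=1.0)


def test_density_counting_oracle():
    hyp = _nrem_hypnogram(20 * 60.0)
    events = [_event(i * 10.0, i * 10.0 + 1.0) for i in range(10)]
    assert spindle_density(events, hyp) == 0.5


def test_density_zero_without_events():
    assert spindle_density([], _nrem_hypnogram(60.0)) == 0.0
    assert spindle_density([], Hypnogram(np.full(4, SleepState.WAKE))) == 0.0


def test_events_without_nrem_is_inconsistent():
    with pytest.raises(ValueError):
        spindle_density([_event(0.0, 1.0)], Hypnogram(np.full(4, SleepState.WAKE)))


def test_density_recovered_from_generator(recovery_recording):
    """Detected density within 25% of the configured rate at high SNR."""
    config, rec, truth = recovery_recording
    hyp = truth_hypnogram(config, truth)
    det = detect_spindle_events(rec.eeg, rec.sampling_rate, hyp)
    assert spindle_density(det.events, hyp) == pytest.approx(
        config.spindle_rate, rel=0.25
    )
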
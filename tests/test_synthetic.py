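"""Generator tests: Markov hypnograms, spindle injection, recordings, behaviour."""

import numpy as np
import pytest

from spindlepipe import (
    SimConfig,
    SleepState,
    inject_spindle,
    simulate_behavior,
    simulate_hypnogram,
    synthesize_recording,
)
from spindlepipe.behavior import allodynia_score, epm_metrics
from spindlepipe.synthetic import ConfigurationError, pink_noise

from conftest import quick_config


# ---------------------------------------------------------------------------
# simulate_hypnogram
# ---------------------------------------------------------------------------

def test_absorbing_start_state_stays_wake():
    config = quick_config(state_transition=np.eye(3))
    states = simulate_hypnogram(config, 10)
    assert np.all(states == SleepState.WAKE)


def test_deterministic_chain_wake_then_nrem():
    P = np.array([[0, 1, 0], [0, 1, 0], [0, 1, 0]], dtype=float)
    config = quick_config(state_transition=P)
    states = simulate_hypnogram(config, 5)
    assert list(states) == [SleepState.WAKE] + [SleepState.NREM] * 4


def test_non_stochastic_matrix_rejected():
    with pytest.raises(ConfigurationError):
        quick_config(state_transition=np.array([[0.5, 0.5, 0.5]] * 3))


def test_state_frequencies_match_stationary_distribution():
    """Empirical occupancies at n=10,000 lie within 3 SE of the stationary
    distribution, with the Markov-chain CLT variance from the fundamental
    matrix (the eigen-decomposition oracle)."""
    config = quick_config()
    P = config.state_transition
    n = 10_000

    # Oracle: stationary distribution by eigen-decomposition of P^T.
    vals, vecs = np.linalg.eig(P.T)
    pi = np.real(vecs[:, np.argmin(np.abs(vals - 1.0))])
    pi = pi / pi.sum()
    # Asymptotic indicator variance via the fundamental matrix.
    Z = np.linalg.inv(np.eye(3) - P + np.tile(pi, (3, 1)))
    sigma2 = pi * (2 * np.diag(Z) - 1 - pi)

    states = simulate_hypnogram(config, n, rng=np.random.default_rng(123))
    for s in SleepState:
        freq = np.mean(states == s)
        se = np.sqrt(sigma2[int(s)] / n)
        assert abs(freq - pi[int(s)]) < 3 * se, (s, freq, pi[int(s)], se)


def test_hypnogram_reproducible():
    config = quick_config(seed=7)
    a = simulate_hypnogram(config, 500)
    b = simulate_hypnogram(config, 500)
    assert np.array_equal(a, b)


# ---------------------------------------------------------------------------
# inject_spindle
# ---------------------------------------------------------------------------

def test_zero_amplitude_leaves_signal_unchanged():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(1000)
    out = inject_spindle(x, 250.0, 1.0, 1.0, 13.0, 0.0)
    assert np.array_equal(out, x)


def test_burst_energy_matches_closed_form_envelope():
    """Energy of a burst on zeros equals the direct sum of the squared
    Hann-enveloped sinusoid, and is close to the analytic 3/16 A^2 d fs."""
    fs, d, f, A = 1000.0, 1.2, 13.0, 40.0
    out = inject_spindle(np.zeros(int(5 * fs)), fs, 2.0, d, f, A)
    # Direct-summation oracle from the closed-form envelope.
    tau = np.arange(int(round(d * fs))) / fs
    oracle = np.sum(
        (A * 0.5 * (1 - np.cos(2 * np.pi * tau / d)) * np.sin(2 * np.pi * f * tau)) ** 2
    )
    assert np.sum(out ** 2) == pytest.approx(oracle, rel=1e-12)
    assert oracle == pytest.approx(3.0 / 16.0 * A ** 2 * d * fs, rel=0.02)


def test_injection_is_linear_and_local():
    rng = np.random.default_rng(1)
    x = rng.standard_normal(3000)
    fs = 250.0
    a = inject_spindle(np.zeros_like(x), fs, 1.0, 1.0, 13.0, 30.0)
    b = inject_spindle(np.zeros_like(x), fs, 6.0, 2.0, 11.0, 20.0)
    both = inject_spindle(inject_spindle(x, fs, 1.0, 1.0, 13.0, 30.0),
                          fs, 6.0, 2.0, 11.0, 20.0)
    assert np.allclose(both, x + a + b)
    # samples outside the burst untouched
    assert np.array_equal(a[: int(1.0 * fs) - 1], np.zeros(int(1.0 * fs) - 1))


def test_burst_outside_signal_rejected():
    with pytest.raises(ValueError):
        inject_spindle(np.zeros(100), 100.0, 0.8, 0.5, 13.0, 10.0)


# ---------------------------------------------------------------------------
# synthesize_recording
# ---------------------------------------------------------------------------

def test_zero_spindle_rate_gives_empty_ground_truth():
    config = quick_config(spindle_rate=0.0, session_minutes=5.0)
    _, truth = synthesize_recording(config, "SHAM", "BASE")
    assert truth.spindle_events == []


def test_noise_free_single_burst_is_windowed_sinusoid():
    """With silent spectra and one NREM epoch, the injected burst dominates
    the spectrum: the DFT peak sits at the burst frequency."""
    silent = {
        s: {"components": (), "noise": 1e-6} for s in SleepState
    }
    config = quick_config(
        session_minutes=0.5,
        state_transition=np.array([[0, 1, 0], [0, 1, 0], [0, 1, 0]], dtype=float),
        state_spectra=silent,
        spindle_rate=0.0,
    )
    rec, _ = synthesize_recording(config, "SHAM", "BASE")
    eeg = inject_spindle(rec.eeg, rec.sampling_rate, 10.0, 1.5, 13.0, 50.0)
    seg = eeg[int(10 * rec.sampling_rate): int(11.5 * rec.sampling_rate)]
    freqs = np.fft.rfftfreq(seg.size, 1 / rec.sampling_rate)
    peak = freqs[np.argmax(np.abs(np.fft.rfft(seg)))]
    assert peak == pytest.approx(13.0, abs=1.0)


def test_injected_count_within_poisson_interval():
    """Injected spindle count lies within 3 SE of rate x NREM minutes under
    the Poisson model (30-min recording, fixed seed)."""
    config = quick_config(session_minutes=30.0)
    _, truth = synthesize_recording(config, "SHAM", "BASE")
    nrem_minutes = np.sum(truth.hypnogram == SleepState.NREM) * config.epoch_length / 60
    lam = config.spindle_rate * nrem_minutes
    assert abs(len(truth.spindle_events) - lam) <= 3 * np.sqrt(lam)


def test_ground_truth_spindles_inside_nrem_and_sorted(quick_recording):
    config, _, truth = quick_recording
    ep = config.epoch_length
    last_end = -np.inf
    for ev in truth.spindle_events:
        assert ev.start >= last_end, "events must be sorted and non-overlapping"
        last_end = ev.end
        lo, hi = config.spindle_duration_range
        assert lo <= ev.end - ev.start <= hi
        span = truth.hypnogram[int(ev.start // ep): int(np.ceil(ev.end / ep))]
        assert np.all(span == SleepState.NREM)


def test_recording_is_bit_reproducible():
    config = quick_config(session_minutes=2.0)
    rec_a, truth_a = synthesize_recording(config, "NRP", "DAY3")
    rec_b, truth_b = synthesize_recording(config, "NRP", "DAY3")
    assert np.array_equal(rec_a.eeg, rec_b.eeg)
    assert np.array_equal(rec_a.emg, rec_b.emg)
    assert truth_a.spindle_events == truth_b.spindle_events


def test_emg_tone_recovered_per_state(quick_recording):
    """Empirical per-state EMG RMS within 10% of the configured tone for
    states occupying at least 10 minutes."""
    config, rec, truth = quick_recording
    spe = int(config.epoch_length * rec.sampling_rate)
    per_sample = np.repeat(truth.hypnogram, spe)
    for state in SleepState:
        mask = per_sample == state
        if mask.sum() < 10 * 60 * rec.sampling_rate:
            continue
        rms = np.sqrt(np.mean(rec.emg[mask] ** 2))
        assert rms == pytest.approx(config.emg_tone[state], rel=0.10)


def test_unknown_group_or_session_rejected():
    config = quick_config(session_minutes=1.0)
    with pytest.raises(ValueError):
        synthesize_recording(config, "CONTROL", "BASE")
    with pytest.raises(ValueError):
        synthesize_recording(config, "SHAM", "DAY9")


def test_pink_noise_is_unit_rms_and_low_frequency_weighted():
    x = pink_noise(2 ** 14, 250.0, np.random.default_rng(3))
    assert np.sqrt(np.mean(x ** 2)) == pytest.approx(1.0, rel=1e-9)
    p = np.abs(np.fft.rfft(x)) ** 2
    f = np.fft.rfftfreq(x.size, 1 / 250.0)
    low = p[(f > 0.5) & (f < 5)].mean()
    high = p[(f > 50) & (f < 100)].mean()
    assert low > 5 * high


# ---------------------------------------------------------------------------
# simulate_behavior
# ---------------------------------------------------------------------------

def test_sham_withdrawals_all_zero():
    config = quick_config()
    table = simulate_behavior(config, "SHAM", "DAY3")
    assert all(allodynia_score(s) == 0 for s in table.acetone)
    table6 = simulate_behavior(config, "SHAM", "DAY6")
    assert all(allodynia_score(s) == 0 for s in table6.acetone)


def test_valerian_day6_withdrawals_zero():
    config = quick_config()
    table = simulate_behavior(config, "VAL_NRP", "DAY6")
    assert np.mean([allodynia_score(s) for s in table.acetone]) == 0.0


def test_epm_occupancy_partitions_session():
    config = quick_config()
    for group in ("SHAM", "NRP", "VAL_NRP"):
        table = simulate_behavior(config, group, "DAY6")
        for session in table.epm:
            m = epm_metrics(session)
            assert m.open_time + m.closed_time + m.center_time == pytest.approx(300.0)


def test_behavior_unknown_day_rejected():
    with pytest.raises(ValueError):
        simulate_behavior(quick_config(), "SHAM", "BASE")


def test_group_sizes_default_to_study_design():
    config = quick_config()
    assert len(simulate_behavior(config, "SHAM", "DAY3").acetone) == 7
    assert len(simulate_behavior(config, "NRP", "DAY3").acetone) == 9
    assert len(simulate_behavior(config, "VAL_NRP", "DAY3").acetone) == 8


# ---------------------------------------------------------------------------
# config round trip
# ---------------------------------------------------------------------------

def test_config_yaml_round_trip(tmp_path):
    config = quick_config(spindle_rate=3.5)
    path = tmp_path / "config.yaml"
    config.to_yaml(path)
    loaded = SimConfig.from_yaml(path)
    assert loaded.spindle_rate == config.spindle_rate
    assert loaded.sampling_rate == config.sampling_rate
    assert np.allclose(loaded.state_transition, config.state_transition)
    assert loaded.state_spectra == config.state_spectra
    assert loaded.group_effects == config.group_effects
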
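import pytest

from spindlepipe import SimConfig, synthesize_recording
from spindlepipe.staging import Hypnogram


def quick_config(**overrides) -> SimConfig:
    """Desk-scale study conditions: 250 Hz keeps every band below Nyquist."""
    base = dict(seed=1, sampling_rate=250.0, session_minutes=20.0)
    base.update(overrides)
    return SimConfig(**base)


def recovery_config(**overrides) -> SimConfig:
    """High-SNR generator whose injected spindles all satisfy the detection
    criteria (12-20 Hz band, 0.5-2 s duration) with margin, for recovery
    tests of the detector."""
    base = dict(
        seed=1,
        sampling_rate=250.0,
        session_minutes=40.0,
        spindle_amplitude=300.0,
        spindle_freq_range=(12.5, 15.0),
        spindle_duration_range=(0.7, 1.8),
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def quick_recording():
    """One 20-min SHAM/BASE recording with ground truth (default spectra)."""
    config = quick_config()
    recording, truth = synthesize_recording(config, "SHAM", "BASE")
    return config, recording, truth


@pytest.fixture(scope="session")
def recovery_recording():
    """40-min high-SNR recording whose spindles are all detector-admissible."""
    config = recovery_config()
    recording, truth = synthesize_recording(config, "SHAM", "BASE")
    return config, recording, truth


def truth_hypnogram(config, truth) -> Hypnogram:
    return Hypnogram(states=truth.hypnogram, epoch_length=config.epoch_length)


def intervals_match(a, b, min_overlap=0.5) -> bool:
    """True when intervals overlap by at least ``min_overlap`` of the shorter."""
    (a0, a1), (b0, b1) = a, b
    return min(a1, b1) - max(a0, b0) >= min_overlap * min(a1 - a0, b1 - b0)
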
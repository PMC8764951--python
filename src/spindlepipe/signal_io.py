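"""Recording containers, file formats, filtering and epoching.

EEG/EMG traces are held in microvolts in a :class:`Recording`.  Two on-disk
formats are supported: a plain CSV dialect (``time_s,eeg_uV,emg_uV``) and EDF
(European Data Format), the de-facto interchange format for polysomnography.
EDF files are read through :mod:`mne`; writing uses a minimal EDF writer
implemented here (16-bit samples, one-second data records).

Filtering follows the acquisition bands of the study design this package
models (EEG 0–40 Hz, EMG 1–400 Hz), applied as zero-phase 4th-order
Butterworth filters so spindle timing is not phase-distorted.  A lower edge of
0 Hz means a pure low-pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "Recording",
    "EpochSet",
    "FormatError",
    "read_recording",
    "write_recording",
    "read_recording_csv",
    "write_recording_csv",
    "read_recording_edf",
    "write_recording_edf",
    "bandpass_filter",
    "filter_recording",
    "epoch_signal",
    "decimate_recording",
]

EEG_BAND = (0.0, 40.0)
EMG_BAND = (1.0, 400.0)


class FormatError(ValueError):
    """A file could not be interpreted as a two-channel recording."""


@dataclass
class Recording:
    """One animal-session's EEG and EMG traces with sampling metadata."""

    eeg: np.ndarray
    emg: np.ndarray
    sampling_rate: float
    animal_id: str = ""
    group: str = ""
    session: str = ""

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=np.float64)
        self.emg = np.asarray(self.emg, dtype=np.float64)
        if self.eeg.ndim != 1 or self.emg.ndim != 1:
            raise ValueError("eeg and emg must be one-dimensional sample vectors")
        if self.eeg.shape != self.emg.shape:
            raise ValueError(
                f"eeg and emg must have equal length, got {self.eeg.size} != {self.emg.size}"
            )
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.eeg.size)

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate


@dataclass
class EpochSet:
    """Fixed-length, consecutive, non-overlapping (eeg, emg) epochs.

    Epochs tile the retained span exactly; a trailing partial epoch is
    discarded.  ``eeg`` and ``emg`` have shape ``(n_epochs, samples_per_epoch)``.
    """

    eeg: np.ndarray
    emg: np.ndarray
    epoch_length: float
    sampling_rate: float

    def __len__(self) -> int:
        return int(self.eeg.shape[0])

    def __iter__(self):
        for i in range(len(self)):
            yield self.eeg[i], self.emg[i]


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

CSV_COLUMNS = ("time_s", "eeg_uV", "emg_uV")


def write_recording_csv(recording: Recording, path) -> None:
    """Write a recording as ``time_s,eeg_uV,emg_uV`` CSV (UTF-8)."""
    t = np.arange(recording.n_samples) / recording.sampling_rate
    frame = pd.DataFrame(
        {"time_s": t, "eeg_uV": recording.eeg, "emg_uV": recording.emg}
    )
    frame.to_csv(path, index=False, float_format="%.6f")


def read_recording_csv(path, sampling_rate: float | None = None, **metadata) -> Recording:
    """Read the CSV dialect written by :func:`write_recording_csv`.

    The sampling rate is inferred from the time column unless given; a
    non-uniform time grid is rejected.
    """
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"could not parse CSV recording {path}: {exc}") from exc
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(
            f"CSV recording {path} is missing columns {missing}; expected {list(CSV_COLUMNS)}"
        )
    t = frame["time_s"].to_numpy(dtype=float)
    if sampling_rate is None:
        if t.size < 2:
            raise FormatError(f"{path}: cannot infer sampling rate from {t.size} samples")
        dt = np.diff(t)
        # tolerate the jitter of decimal-text rounding, reject real gaps
        if np.ptp(dt) > 0.02 * np.median(dt):
            raise FormatError(f"{path}: time column is not uniformly sampled")
        sampling_rate = (t.size - 1) / float(t[-1] - t[0])
        if abs(sampling_rate - round(sampling_rate)) < 1e-3:
            sampling_rate = float(round(sampling_rate))
    return Recording(
        eeg=frame["eeg_uV"].to_numpy(dtype=float),
        emg=frame["emg_uV"].to_numpy(dtype=float),
        sampling_rate=float(sampling_rate),
        **metadata,
    )


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    text = str(value)[:width]
    return text.ljust(width).encode("ascii")


def write_recording_edf(recording: Recording, path, eeg_channel: str = "EEG",
                        emg_channel: str = "EMG") -> None:
    """Write an EDF file with one-second data records and 16-bit samples.

    The sampling rate must be a whole number of samples per second.  The last
    record is zero-padded if the recording does not end on a record boundary;
    amplitudes are quantized to the 16-bit digital range, so round trips are
    exact only to that quantization.
    """
    fs = recording.sampling_rate
    spr = int(round(fs))
    if abs(fs - spr) > 1e-9 or spr <= 0:
        raise FormatError(f"EDF writer needs an integer sampling rate, got {fs}")
    channels = [(eeg_channel, recording.eeg), (emg_channel, recording.emg)]
    n_records = int(np.ceil(recording.n_samples / spr)) if recording.n_samples else 0

    scaled = []
    phys_ranges = []
    for _, x in channels:
        pmax = float(np.max(np.abs(x))) if x.size else 1.0
        if pmax == 0:
            pmax = 1.0
        # EDF mapping: physical = (dig - dmin) * (pmax - pmin)/(dmax - dmin) + pmin
        gain = 2.0 * pmax / 65535.0
        dig = np.clip(np.round((x + pmax) / gain - 32768.0), -32768, 32767)
        dig = dig.astype("<i2")
        zero = np.int16(np.clip(round(pmax / gain - 32768.0), -32768, 32767))
        pad = n_records * spr - dig.size
        if pad:
            dig = np.concatenate([dig, np.full(pad, zero, dtype="<i2")])
        scaled.append(dig)
        phys_ranges.append(pmax)

    ns = len(channels)
    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field(recording.animal_id or "X", 80),
            _edf_field("Startdate X", 80),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(str(256 * (1 + ns)), 8),
            _edf_field("", 44),
            _edf_field(str(n_records), 8),
            _edf_field("1", 8),
            _edf_field(str(ns), 4),
        ]
    )
    labels = [name for name, _ in channels]
    per_signal = [
        b"".join(_edf_field(lab, 16) for lab in labels),
        b"".join(_edf_field("", 80) for _ in labels),
        b"".join(_edf_field("uV", 8) for _ in labels),
        b"".join(_edf_field(f"{-p:.6g}"[:8], 8) for p in phys_ranges),
        b"".join(_edf_field(f"{p:.6g}"[:8], 8) for p in phys_ranges),
        b"".join(_edf_field("-32768", 8) for _ in labels),
        b"".join(_edf_field("32767", 8) for _ in labels),
        b"".join(_edf_field("", 80) for _ in labels),
        b"".join(_edf_field(str(spr), 8) for _ in labels),
        b"".join(_edf_field("", 32) for _ in labels),
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for block in per_signal:
            fh.write(block)
        for r in range(n_records):
            for dig in scaled:
                fh.write(dig[r * spr:(r + 1) * spr].tobytes())


def read_recording_edf(path, eeg_channel: str = "EEG", emg_channel: str = "EMG",
                       **metadata) -> Recording:
    """Read a two-channel EDF recording (channels mapped by name)."""
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise FormatError(f"could not parse EDF recording {path}: {exc}") from exc
    available = list(raw.ch_names)
    missing = [c for c in (eeg_channel, emg_channel) if c not in available]
    if missing:
        raise FormatError(
            f"EDF recording {path} is missing channels {missing}; available: {available}"
        )
    data = raw.get_data(picks=[eeg_channel, emg_channel]) * 1e6  # mne returns volts
    return Recording(
        eeg=data[0],
        emg=data[1],
        sampling_rate=float(raw.info["sfreq"]),
        **metadata,
    )


def read_recording(path, format: str | None = None, **kwargs) -> Recording:
    """Read a recording, dispatching on ``format`` or the file suffix."""
    fmt = (format or Path(path).suffix.lstrip(".")).upper()
    if fmt == "CSV":
        return read_recording_csv(path, **kwargs)
    if fmt == "EDF":
        return read_recording_edf(path, **kwargs)
    raise FormatError(f"unknown recording format {fmt!r} (expected CSV or EDF)")


def write_recording(recording: Recording, path, format: str | None = None, **kwargs) -> None:
    fmt = (format or Path(path).suffix.lstrip(".")).upper()
    if fmt == "CSV":
        return write_recording_csv(recording, path, **kwargs)
    if fmt == "EDF":
        return write_recording_edf(recording, path, **kwargs)
    raise FormatError(f"unknown recording format {fmt!r} (expected CSV or EDF)")


# ---------------------------------------------------------------------------
# Filtering / epoching / decimation
# ---------------------------------------------------------------------------

def bandpass_filter(x: np.ndarray, sampling_rate: float, low: float, high: float,
                    order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth filter; ``low == 0`` means pure low-pass.

    Forward-backward filtering (``sosfiltfilt``) doubles the effective order,
    so a 4th-order design attenuates well over 20 dB one octave beyond the
    band edge while leaving pass-band tones within a few percent.
    """
    x = np.asarray(x, dtype=np.float64)
    nyq = sampling_rate / 2.0
    if not (0 <= low < high < nyq):
        raise ValueError(
            f"invalid band ({low}, {high}) Hz for sampling rate {sampling_rate} Hz"
        )
    if low <= 0:
        sos = sps.butter(order, high, btype="lowpass", fs=sampling_rate, output="sos")
    else:
        sos = sps.butter(order, [low, high], btype="bandpass", fs=sampling_rate,
                         output="sos")
    if x.size == 0:
        return x.copy()
    return sps.sosfiltfilt(sos, x)


def filter_recording(recording: Recording, eeg_band=EEG_BAND, emg_band=EMG_BAND) -> Recording:
    """Apply the acquisition bands to both channels.

    Band edges are clipped to 90% of Nyquist so decimated recordings (where
    400 Hz exceeds Nyquist) remain filterable with the same call.
    """
    nyq = recording.sampling_rate / 2.0
    eeg_hi = min(eeg_band[1], 0.9 * nyq)
    emg_hi = min(emg_band[1], 0.9 * nyq)
    return replace(
        recording,
        eeg=bandpass_filter(recording.eeg, recording.sampling_rate, eeg_band[0], eeg_hi),
        emg=bandpass_filter(recording.emg, recording.sampling_rate, emg_band[0], emg_hi),
    )


def epoch_signal(recording: Recording, epoch_length: float = 5.0) -> EpochSet:
    """Cut a recording into consecutive half-open epochs of ``epoch_length`` s.

    Returns ``floor(duration / epoch_length)`` epochs; a recording shorter
    than one epoch yields an empty :class:`EpochSet`.
    """
    if not epoch_length > 0:
        raise ValueError("epoch_length must be positive")
    k = int(round(epoch_length * recording.sampling_rate))
    n = recording.n_samples // k
    shape = (n, k)
    return EpochSet(
        eeg=recording.eeg[: n * k].reshape(shape).copy(),
        emg=recording.emg[: n * k].reshape(shape).copy(),
        epoch_length=epoch_length,
        sampling_rate=recording.sampling_rate,
    )


def decimate_recording(recording: Recording, target_rate: float = 250.0) -> Recording:
    """Anti-alias resample both channels to ``target_rate`` (polyphase FIR)."""
    if not 0 < target_rate <= recording.sampling_rate:
        raise ValueError("target_rate must be in (0, sampling_rate]")
    frac = Fraction(target_rate / recording.sampling_rate).limit_denominator(10_000)
    up, down = frac.numerator, frac.denominator
    if up == down:
        return replace(recording)
    return replace(
        recording,
        eeg=sps.resample_poly(recording.eeg, up, down),
        emg=sps.resample_poly(recording.emg, up, down),
        sampling_rate=recording.sampling_rate * up / down,
    )
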
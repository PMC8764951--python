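"""Semi-automatic three-state sleep staging.

The scoring scheme mirrors standard rodent polysomnography practice: a human
marks one typical stretch (>= 30 s) of wake, NREM and REM; every 5-s epoch of
the recording is then classified by k-nearest-neighbour similarity of its
EEG/EMG features to the 5-s training epochs cut from those exemplars.

Features per epoch are log band powers (delta 0.5-4, theta 4-9, sigma 12-20,
beta 20-30 Hz), the log theta/delta ratio and log EMG RMS, z-scored against
the training statistics.  Those bands separate the canonical state
signatures: slow-wave-dominated NREM, theta-dominated REM with muscle atonia,
and mixed-frequency wake with high muscle tone.

Vote and distance ties are broken by the fixed state order WAKE < NREM < REM
so predictions are invariant to the ordering of the exemplars.  No post-hoc
hypnogram smoothing is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.spatial.distance import cdist

from .signal_io import EpochSet, Recording, epoch_signal

__all__ = [
    "SleepState",
    "STAGE_BANDS",
    "FEATURE_NAMES",
    "MIN_EXEMPLAR_SECONDS",
    "LabeledExemplar",
    "Hypnogram",
    "StagePercentages",
    "TrainingError",
    "extract_features",
    "SleepStager",
    "fit_stager",
    "score_recording",
    "stage_percentages",
]

from enum import IntEnum


class SleepState(IntEnum):
    """Three-state vigilance alphabet; the integer order is the tie-break order."""

    WAKE = 0
    NREM = 1
    REM = 2

    @classmethod
    def parse(cls, value) -> "SleepState":
        if isinstance(value, cls):
            return value
        if isinstance(value, (int, np.integer)):
            return cls(int(value))
        return cls[str(value).upper()]


STAGE_BANDS = (
    ("delta", 0.5, 4.0),
    ("theta", 4.0, 9.0),
    ("sigma", 12.0, 20.0),
    ("beta", 20.0, 30.0),
)
FEATURE_NAMES = (
    "log_delta", "log_theta", "log_sigma", "log_beta",
    "log_theta_delta_ratio", "log_emg_rms",
)
MIN_EXEMPLAR_SECONDS = 30.0
_POWER_FLOOR = 1e-12


class TrainingError(ValueError):
    """The exemplar set cannot train a three-state stager."""


@dataclass
class LabeledExemplar:
    """A visually identified, state-labelled stretch of EEG+EMG."""

    state: SleepState
    eeg: np.ndarray
    emg: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.state = SleepState.parse(self.state)
        self.eeg = np.asarray(self.eeg, dtype=np.float64)
        self.emg = np.asarray(self.emg, dtype=np.float64)

    @property
    def duration(self) -> float:
        return self.eeg.size / self.sampling_rate


@dataclass
class Hypnogram:
    """Per-epoch sleep-state labels at a fixed epoch length."""

    states: np.ndarray
    epoch_length: float = 5.0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)

    def __len__(self) -> int:
        return int(self.states.size)

    @property
    def epoch_starts(self) -> np.ndarray:
        return np.arange(len(self)) * self.epoch_length

    def state_counts(self) -> dict:
        return {s: int(np.sum(self.states == s)) for s in SleepState}

    def minutes_in(self, state: SleepState) -> float:
        return float(np.sum(self.states == state)) * self.epoch_length / 60.0

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "epoch_index": np.arange(len(self)),
                "start_s": self.epoch_starts,
                "state": [SleepState(s).name for s in self.states],
            }
        ).to_csv(path, sep="\t", index=False, float_format="%.3f")

    @classmethod
    def from_tsv(cls, path, epoch_length: float | None = None) -> "Hypnogram":
        frame = pd.read_csv(path, sep="\t")
        states = [SleepState.parse(s) for s in frame["state"]]
        if epoch_length is None:
            starts = frame["start_s"].to_numpy(dtype=float)
            epoch_length = float(starts[1] - starts[0]) if len(starts) > 1 else 5.0
        return cls(states=np.array(states, dtype=np.int64), epoch_length=epoch_length)


@dataclass
class StagePercentages:
    """Stage shares; NaN marks a share undefined under the chosen denominator."""

    pct_wake: float
    pct_nrem: float
    pct_rem: float
    denominator: str = "TOTAL_RECORDING"


def _band_power(freqs: np.ndarray, pxx: np.ndarray, low: float, high: float) -> float:
    # Half-open [low, high) bins so adjacent bands never double count.
    mask = (freqs >= low) & (freqs < high)
    if not np.any(mask):
        return 0.0
    df = freqs[1] - freqs[0]
    return float(np.sum(pxx[mask]) * df)


def extract_features(eeg_epoch: np.ndarray, emg_epoch: np.ndarray,
                     sampling_rate: float) -> np.ndarray:
    """Raw (un-normalized) feature vector for one epoch.

    Band powers come from the plain (boxcar) periodogram so they equal direct
    DFT band sums; logs are floored so an all-zero epoch still yields a
    defined vector.  Z-scoring against training statistics happens inside the
    stager.
    """
    eeg_epoch = np.asarray(eeg_epoch, dtype=np.float64)
    emg_epoch = np.asarray(emg_epoch, dtype=np.float64)
    freqs, pxx = sps.periodogram(eeg_epoch, fs=sampling_rate, window="boxcar",
                                 detrend=False)
    logs = [
        np.log10(max(_band_power(freqs, pxx, lo, hi), _POWER_FLOOR))
        for _, lo, hi in STAGE_BANDS
    ]
    emg_rms = float(np.sqrt(np.mean(emg_epoch ** 2)))
    return np.array(
        logs + [logs[1] - logs[0], np.log10(max(emg_rms, 1e-9))],
        dtype=np.float64,
    )


class SleepStager:
    """Exemplar-trained KNN epoch classifier (fit via :meth:`fit`)."""

    def __init__(self, features: np.ndarray, labels: np.ndarray, mean: np.ndarray,
                 std: np.ndarray, k: int, epoch_length: float, sampling_rate: float):
        self.features = features          # z-scored training features
        self.labels = labels
        self.mean = mean
        self.std = std
        self.k = k
        self.epoch_length = epoch_length
        self.sampling_rate = sampling_rate

    @classmethod
    def fit(cls, exemplars, k: int = 5, epoch_length: float = 5.0) -> "SleepStager":
        if k < 1:
            raise TrainingError("k must be >= 1")
        exemplars = list(exemplars)
        present = {ex.state for ex in exemplars}
        missing = [s.name for s in SleepState if s not in present]
        if missing:
            raise TrainingError(f"exemplar set is missing state(s): {', '.join(missing)}")
        for ex in exemplars:
            if ex.duration < MIN_EXEMPLAR_SECONDS - 1e-9:
                raise TrainingError(
                    f"{ex.state.name} exemplar is {ex.duration:.1f} s; "
                    f"each exemplar must be at least {MIN_EXEMPLAR_SECONDS:.0f} s"
                )
        rates = {float(ex.sampling_rate) for ex in exemplars}
        if max(rates) - min(rates) > 1e-6 * max(rates):
            raise TrainingError(f"exemplars have inconsistent sampling rates: {sorted(rates)}")
        fs = rates.pop() if len(rates) == 1 else float(np.mean(sorted(rates)))

        feats, labels = [], []
        spe = int(round(epoch_length * fs))
        for ex in exemplars:
            n = ex.eeg.size // spe
            for i in range(n):
                sl = slice(i * spe, (i + 1) * spe)
                feats.append(extract_features(ex.eeg[sl], ex.emg[sl], fs))
                labels.append(int(ex.state))
        X = np.array(feats)
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std[std == 0] = 1.0
        return cls(
            features=(X - mean) / std,
            labels=np.array(labels, dtype=np.int64),
            mean=mean,
            std=std,
            k=int(k),
            epoch_length=epoch_length,
            sampling_rate=fs,
        )

    def classify_features(self, raw_features: np.ndarray) -> np.ndarray:
        """Classify raw feature rows by majority vote among k nearest epochs."""
        raw_features = np.atleast_2d(raw_features)
        if raw_features.shape[0] == 0:
            return np.empty(0, dtype=np.int64)
        z = (raw_features - self.mean) / self.std
        dist = cdist(z, self.features)
        k = min(self.k, self.features.shape[0])
        out = np.empty(z.shape[0], dtype=np.int64)
        for i, row in enumerate(dist):
            # Sort by distance, then by state order, so exemplar ordering and
            # exact distance ties cannot change the prediction.
            order = np.lexsort((self.labels, row))
            votes = np.bincount(self.labels[order[:k]], minlength=len(SleepState))
            out[i] = int(np.argmax(votes))  # argmax tie-break = state order
        return out

    def score_epochs(self, epochs: EpochSet) -> Hypnogram:
        feats = [
            extract_features(e, m, epochs.sampling_rate) for e, m in epochs
        ]
        states = (
            self.classify_features(np.array(feats)) if feats else np.empty(0, np.int64)
        )
        return Hypnogram(states=states, epoch_length=epochs.epoch_length)

    def score_recording(self, recording: Recording) -> Hypnogram:
        if abs(recording.sampling_rate - self.sampling_rate) > 0.01 * self.sampling_rate:
            raise ValueError(
                f"recording sampled at {recording.sampling_rate} Hz is incompatible "
                f"with a stager trained at {self.sampling_rate} Hz"
            )
        return self.score_epochs(epoch_signal(recording, self.epoch_length))


def fit_stager(exemplars, k: int = 5, epoch_length: float = 5.0) -> SleepStager:
    """Train a stager from labelled exemplars (see :meth:`SleepStager.fit`)."""
    return SleepStager.fit(exemplars, k=k, epoch_length=epoch_length)


def score_recording(model: SleepStager, recording: Recording) -> Hypnogram:
    """Score every epoch of ``recording`` with a fitted stager."""
    return model.score_recording(recording)


def stage_percentages(hypnogram: Hypnogram,
                      denominator: str = "TOTAL_RECORDING") -> StagePercentages:
    """Per-state epoch percentages over the recording or over sleep only.

    With the TOTAL_SLEEP denominator only NREM and REM shares are defined
    (they sum to 100); the wake share is reported as NaN.
    """
    if len(hypnogram) == 0:
        raise ValueError("cannot compute stage percentages of an empty hypnogram")
    counts = hypnogram.state_counts()
    denominator = denominator.upper()
    if denominator == "TOTAL_RECORDING":
        total = len(hypnogram)
        return StagePercentages(
            pct_wake=100.0 * counts[SleepState.WAKE] / total,
            pct_nrem=100.0 * counts[SleepState.NREM] / total,
            pct_rem=100.0 * counts[SleepState.REM] / total,
            denominator=denominator,
        )
    if denominator == "TOTAL_SLEEP":
        sleep = counts[SleepState.NREM] + counts[SleepState.REM]
        if sleep == 0:
            raise ValueError("TOTAL_SLEEP denominator is undefined: no sleep epochs")
        return StagePercentages(
            pct_wake=float("nan"),
            pct_nrem=100.0 * counts[SleepState.NREM] / sleep,
            pct_rem=100.0 * counts[SleepState.REM] / sleep,
            denominator=denominator,
        )
    raise ValueError(f"unknown denominator {denominator!r}")
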
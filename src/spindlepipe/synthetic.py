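"""Ground-truth-annotated synthetic rodent polysomnography and behaviour.

The generator emulates the study design this package analyses: three groups
(SHAM, NRP = neuropathic, VAL_NRP = neuropathic + Valerian), three 150-min
recording sessions per animal (BASE, DAY3, DAY6) sampled at 3,000 Hz, plus
acetone (cold allodynia) and elevated-plus-maze sessions on days 3 and 6.

A recording is built from a first-order Markov hypnogram over
{WAKE, NREM, REM} at 5-s epochs.  The EEG is a per-state mixture of sinusoidal
oscillation components over a shared 1/f background (spectrally shaped white
noise, flattened below 0.5 Hz); the EMG is white noise scaled to a per-state
muscle tone.  Sleep spindles — waxing-and-waning 9–15 Hz bursts of 0.5–3 s —
are injected during NREM as a homogeneous Poisson process with non-overlap
rejection, with a raised-cosine (Hann) envelope whose energy has a closed
form.  Group/session effects enter as multiplicative modifiers on spindle
rate and on NREM/REM dwell (self-transition) probabilities; the study this
mirrors reports only the direction of those effects, so the default
magnitudes are qualitative stand-ins and freely configurable.

Every simulated recording returns its :class:`GroundTruth` (true hypnogram
and injected spindle intervals) so downstream stages can be tested as
recovery problems.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

from .behavior import AcetoneSession, EpmSession, N_TRIALS
from .signal_io import Recording
from .staging import LabeledExemplar, SleepState

__all__ = [
    "GROUPS",
    "SESSIONS",
    "BEHAVIOR_DAYS",
    "GroupEffect",
    "StateSpectrum",
    "SimConfig",
    "SpindleGT",
    "GroundTruth",
    "BehaviorTable",
    "ConfigurationError",
    "simulate_hypnogram",
    "synthesize_recording",
    "inject_spindle",
    "simulate_behavior",
    "exemplars_from_ground_truth",
    "pink_noise",
]

GROUPS = ("SHAM", "NRP", "VAL_NRP")
SESSIONS = ("BASE", "DAY3", "DAY6")
BEHAVIOR_DAYS = ("DAY3", "DAY6")


class ConfigurationError(ValueError):
    """The simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class GroupEffect:
    """Multiplicative modifiers applied for one (group, session) cell."""

    spindle_rate: float = 1.0
    rem_dwell: float = 1.0
    nrem_dwell: float = 1.0


@dataclass(frozen=True)
class StateSpectrum:
    """Oscillation components (center Hz, amplitude uV) plus 1/f noise RMS uV."""

    components: tuple = ()
    noise: float = 10.0


def _default_transition() -> np.ndarray:
    # Rows: from WAKE / NREM / REM per 5-s epoch.  Self-transition
    # probabilities give mean bout lengths of ~100 s (wake), ~83 s (NREM)
    # and ~50 s (REM) — light-phase rodent sleep architecture.
    return np.array(
        [
            [0.95, 0.05, 0.00],
            [0.03, 0.94, 0.03],
            [0.08, 0.02, 0.90],
        ]
    )


def _default_spectra() -> dict:
    return {
        SleepState.WAKE: StateSpectrum(components=((7.0, 20.0),), noise=15.0),
        SleepState.NREM: StateSpectrum(components=((1.5, 60.0), (3.0, 20.0)), noise=20.0),
        SleepState.REM: StateSpectrum(components=((7.5, 45.0),), noise=10.0),
    }


def _default_emg_tone() -> dict:
    return {SleepState.WAKE: 30.0, SleepState.NREM: 10.0, SleepState.REM: 5.0}


def _default_group_effects() -> dict:
    # Directions follow the study this package mirrors: Valerian raises
    # spindle density and NREM, REM declines across sessions under treatment.
    return {
        ("VAL_NRP", "BASE"): GroupEffect(spindle_rate=1.5, rem_dwell=1.3),
        ("VAL_NRP", "DAY3"): GroupEffect(spindle_rate=1.5, nrem_dwell=1.2),
        ("VAL_NRP", "DAY6"): GroupEffect(spindle_rate=1.6, rem_dwell=0.75, nrem_dwell=1.25),
        ("NRP", "DAY3"): GroupEffect(spindle_rate=0.9),
        ("NRP", "DAY6"): GroupEffect(spindle_rate=0.95),
    }


def _default_withdrawal_prob() -> dict:
    # Sham animals never withdraw; Valerian abolishes withdrawal by day 6.
    return {
        ("SHAM", "DAY3"): 0.0, ("SHAM", "DAY6"): 0.0,
        ("NRP", "DAY3"): 0.75, ("NRP", "DAY6"): 0.85,
        ("VAL_NRP", "DAY3"): 0.35, ("VAL_NRP", "DAY6"): 0.0,
    }


def _default_epm_closed_pref() -> dict:
    # Probability of choosing the closed arm on leaving the center; anxiety
    # (neuropathy, day 6) raises it.
    return {
        ("SHAM", "DAY3"): 0.60, ("SHAM", "DAY6"): 0.60,
        ("NRP", "DAY3"): 0.70, ("NRP", "DAY6"): 0.85,
        ("VAL_NRP", "DAY3"): 0.65, ("VAL_NRP", "DAY6"): 0.62,
    }


def _default_group_sizes() -> dict:
    return {"SHAM": 7, "NRP": 9, "VAL_NRP": 8}


@dataclass
class SimConfig:
    """All knobs of the synthetic study; defaults are the study conditions."""

    seed: int = 0
    sampling_rate: float = 3000.0
    epoch_length: float = 5.0
    session_minutes: float = 150.0
    state_transition: np.ndarray = field(default_factory=_default_transition)
    state_spectra: dict = field(default_factory=_default_spectra)
    emg_tone: dict = field(default_factory=_default_emg_tone)
    spindle_rate: float = 2.0                       # events per NREM minute
    spindle_freq_range: tuple = (9.0, 15.0)         # Hz
    spindle_duration_range: tuple = (0.5, 3.0)      # s
    spindle_amplitude: float = 50.0                 # uV envelope peak
    group_effects: dict = field(default_factory=_default_group_effects)
    withdrawal_prob: dict = field(default_factory=_default_withdrawal_prob)
    epm_closed_pref: dict = field(default_factory=_default_epm_closed_pref)
    epm_arm_dwell_mean: float = 25.0                # s
    epm_center_dwell_mean: float = 8.0              # s
    group_sizes: dict = field(default_factory=_default_group_sizes)

    def __post_init__(self) -> None:
        self.state_transition = np.asarray(self.state_transition, dtype=float)
        self.state_spectra = {
            SleepState.parse(k): (v if isinstance(v, StateSpectrum) else StateSpectrum(**v))
            for k, v in self.state_spectra.items()
        }
        self.emg_tone = {SleepState.parse(k): float(v) for k, v in self.emg_tone.items()}
        self.validate()

    def validate(self) -> None:
        P = self.state_transition
        if P.shape != (3, 3):
            raise ConfigurationError(f"state_transition must be 3x3, got {P.shape}")
        if np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-9):
            raise ConfigurationError("state_transition rows must be non-negative and sum to 1")
        if not self.sampling_rate > 0 or not self.epoch_length > 0:
            raise ConfigurationError("sampling_rate and epoch_length must be positive")
        if not self.session_minutes > 0:
            raise ConfigurationError("session_minutes must be positive")
        if self.spindle_rate < 0:
            raise ConfigurationError("spindle_rate must be non-negative")
        lo, hi = self.spindle_freq_range
        if not (0 < lo < hi < self.sampling_rate / 2):
            raise ConfigurationError(
                f"spindle_freq_range {self.spindle_freq_range} must lie in (0, Nyquist)"
            )
        dlo, dhi = self.spindle_duration_range
        if not (0 < dlo <= dhi):
            raise ConfigurationError("spindle_duration_range must be positive with lo <= hi")
        if not self.spindle_amplitude >= 0:
            raise ConfigurationError("spindle_amplitude must be non-negative")
        for state in SleepState:
            if state not in self.state_spectra or state not in self.emg_tone:
                raise ConfigurationError(f"missing spectra or EMG tone for {state.name}")
            if self.emg_tone[state] <= 0:
                raise ConfigurationError("emg_tone values must be strictly positive")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "sampling_rate": self.sampling_rate,
            "epoch_length": self.epoch_length,
            "session_minutes": self.session_minutes,
            "state_transition": self.state_transition.tolist(),
            "state_spectra": {
                s.name: {"components": [list(c) for c in v.components], "noise": v.noise}
                for s, v in self.state_spectra.items()
            },
            "emg_tone": {s.name: v for s, v in self.emg_tone.items()},
            "spindle_rate": self.spindle_rate,
            "spindle_freq_range": list(self.spindle_freq_range),
            "spindle_duration_range": list(self.spindle_duration_range),
            "spindle_amplitude": self.spindle_amplitude,
            "group_effects": {
                f"{g}/{s}": dataclasses.asdict(e) for (g, s), e in self.group_effects.items()
            },
            "withdrawal_prob": {f"{g}/{d}": p for (g, d), p in self.withdrawal_prob.items()},
            "epm_closed_pref": {f"{g}/{d}": p for (g, d), p in self.epm_closed_pref.items()},
            "epm_arm_dwell_mean": self.epm_arm_dwell_mean,
            "epm_center_dwell_mean": self.epm_center_dwell_mean,
            "group_sizes": dict(self.group_sizes),
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        data = dict(data)
        for key, factory in (
            ("state_spectra", StateSpectrum),
            ("group_effects", GroupEffect),
        ):
            if key in data:
                parsed = {}
                for k, v in data[key].items():
                    k2 = tuple(k.split("/")) if isinstance(k, str) and "/" in k else k
                    if factory is StateSpectrum and not isinstance(v, StateSpectrum):
                        v = StateSpectrum(
                            components=tuple(tuple(c) for c in v.get("components", ())),
                            noise=float(v.get("noise", 10.0)),
                        )
                    elif factory is GroupEffect and not isinstance(v, GroupEffect):
                        v = GroupEffect(**v)
                    parsed[k2] = v
                data[key] = parsed
        for key in ("withdrawal_prob", "epm_closed_pref"):
            if key in data:
                data[key] = {
                    (tuple(k.split("/")) if isinstance(k, str) and "/" in k else k): float(v)
                    for k, v in data[key].items()
                }
        for key in ("spindle_freq_range", "spindle_duration_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


class SpindleGT(NamedTuple):
    """One injected spindle: half-open interval [start, end) and its frequency."""

    start: float
    end: float
    frequency: float


@dataclass
class GroundTruth:
    """True hypnogram and injected spindle intervals of a synthetic recording."""

    hypnogram: np.ndarray
    spindle_events: list
    epoch_length: float = 5.0

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"start_s": e.start, "end_s": e.end, "freq_hz": e.frequency}
             for e in self.spindle_events]
        )

    def to_tsv(self, path) -> None:
        frame = self.events_frame()
        if frame.empty:
            frame = pd.DataFrame(columns=["start_s", "end_s", "freq_hz"])
        frame.to_csv(path, sep="\t", index=False, float_format="%.4f")


@dataclass
class BehaviorTable:
    """Per-animal acetone and EPM sessions for one (group, day) cell."""

    group: str
    day: str
    acetone: list
    epm: list


# ---------------------------------------------------------------------------
# Hypnogram simulation
# ---------------------------------------------------------------------------

def simulate_hypnogram(config: SimConfig, n_epochs: int,
                       rng: np.random.Generator | None = None,
                       transition: np.ndarray | None = None) -> np.ndarray:
    """Markov-chain state sequence started at WAKE.

    The chain runs at one step per epoch on the configured (or supplied)
    transition matrix; identical seeds give identical output.
    """
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    P = np.asarray(config.state_transition if transition is None else transition,
                   dtype=float)
    if P.shape != (3, 3) or np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1) > 1e-9):
        raise ConfigurationError("transition matrix must be 3x3 row-stochastic")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cum = np.cumsum(P, axis=1)
    states = np.empty(n_epochs, dtype=np.int64)
    state = int(SleepState.WAKE)
    states[0] = state
    u = rng.random(n_epochs)
    for i in range(1, n_epochs):
        state = int(np.searchsorted(cum[state], u[i]))
        states[i] = state
    return states


def _dwell_adjusted(P: np.ndarray, effect: GroupEffect) -> np.ndarray:
    """Scale mean NREM/REM dwell by the effect's multipliers.

    A dwell multiplier m maps the leave probability q = 1 - p_ii to q/m and
    rescales the off-diagonal entries proportionally.
    """
    P = P.copy()
    for state, m in ((SleepState.NREM, effect.nrem_dwell),
                     (SleepState.REM, effect.rem_dwell)):
        if m == 1.0:
            continue
        if m <= 0:
            raise ConfigurationError("dwell multipliers must be positive")
        i = int(state)
        q = 1.0 - P[i, i]
        q_new = min(q / m, 1.0)
        if q > 0:
            P[i] = P[i] * (q_new / q)
        P[i, i] = 1.0 - q_new
    return P


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------

def pink_noise(n: int, sampling_rate: float, rng: np.random.Generator,
               corner_hz: float = 0.5) -> np.ndarray:
    """Unit-RMS 1/f noise via spectral shaping of white noise.

    Power falls as 1/f above ``corner_hz`` and is flat below it, which keeps
    the delta band finite and avoids unbounded drift.
    """
    if n == 0:
        return np.zeros(0)
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    scale = 1.0 / np.sqrt(np.maximum(freqs, corner_hz))
    scale[0] = 0.0
    shaped = np.fft.irfft(spectrum * scale, n=n)
    rms = np.sqrt(np.mean(shaped ** 2))
    return shaped / rms if rms > 0 else shaped


def inject_spindle(signal: np.ndarray, sampling_rate: float, start: float,
                   duration: float, frequency: float, amplitude: float,
                   phase: float = 0.0, _in_place: bool = False) -> np.ndarray:
    """Add a Hann-enveloped sinusoidal burst over [start, start+duration).

    The raised-cosine envelope peaks mid-burst and is zero at both edges
    ("waxing and waning"); samples outside the interval are unchanged.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if duration <= 0:
        raise ValueError("duration must be positive")
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    i0 = int(round(start * sampling_rate))
    n = int(round(duration * sampling_rate))
    if i0 < 0 or i0 + n > signal.size:
        raise ValueError(
            f"burst [{start:g}, {start + duration:g}) s does not fit inside the "
            f"{signal.size / sampling_rate:g} s signal"
        )
    out = signal if _in_place else signal.copy()
    if amplitude == 0 or n == 0:
        return out
    tau = np.arange(n) / sampling_rate
    envelope = 0.5 * (1.0 - np.cos(2.0 * np.pi * tau / duration))
    out[i0:i0 + n] += amplitude * envelope * np.sin(2.0 * np.pi * frequency * tau + phase)
    return out


def _nrem_spans(states: np.ndarray, epoch_length: float):
    """Maximal [start, end) second-spans of contiguous NREM epochs."""
    spans = []
    start = None
    for i, s in enumerate(states):
        if s == SleepState.NREM and start is None:
            start = i
        elif s != SleepState.NREM and start is not None:
            spans.append((start * epoch_length, i * epoch_length))
            start = None
    if start is not None:
        spans.append((start * epoch_length, states.size * epoch_length))
    return spans


def _place_spindles(config: SimConfig, spans, rate: float,
                    rng: np.random.Generator, max_attempts: int = 100):
    """Homogeneous Poisson placement within NREM spans, rejecting overlaps."""
    events = []
    guard = 0.1  # minimum gap between bursts, s
    for t0, t1 in spans:
        lam = rate * (t1 - t0) / 60.0
        k = rng.poisson(lam)
        placed = []
        for _ in range(k):
            for _ in range(max_attempts):
                dur = rng.uniform(*config.spindle_duration_range)
                if t1 - t0 <= dur:
                    continue
                start = rng.uniform(t0, t1 - dur)
                if all(start + dur + guard <= s or start >= e + guard
                       for s, e in placed):
                    freq = rng.uniform(*config.spindle_freq_range)
                    placed.append((start, start + dur))
                    events.append(SpindleGT(start, start + dur, freq))
                    break
    events.sort(key=lambda e: e.start)
    return events


def synthesize_recording(config: SimConfig, group: str, session: str,
                         rng: np.random.Generator | None = None,
                         animal_id: str = "") -> tuple[Recording, GroundTruth]:
    """One animal-session's EEG+EMG traces plus their ground truth.

    The trace is epoch-tiled: ``floor(session_minutes*60/epoch_length)``
    epochs of ``epoch_length * sampling_rate`` samples (equal to
    ``session_minutes*60*sampling_rate`` whenever the epoch length divides
    the session, as with all defaults).
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    if session not in SESSIONS:
        raise ValueError(f"unknown session {session!r}; expected one of {SESSIONS}")
    if rng is None:
        rng = np.random.default_rng(
            [int(config.seed), GROUPS.index(group), SESSIONS.index(session)]
        )
    effect = config.group_effects.get((group, session), GroupEffect())
    fs = config.sampling_rate
    n_epochs = int(config.session_minutes * 60.0 / config.epoch_length)
    spe = int(round(config.epoch_length * fs))
    n = n_epochs * spe

    P = _dwell_adjusted(config.state_transition, effect)
    states = simulate_hypnogram(config, n_epochs, rng=rng, transition=P)
    state_per_sample = np.repeat(states, spe)

    t = np.arange(n) / fs
    eeg = np.zeros(n)
    background = pink_noise(n, fs, rng)
    for state in SleepState:
        mask = state_per_sample == state
        if not np.any(mask):
            continue
        spectrum = config.state_spectra[state]
        for freq, amp in spectrum.components:
            phase = rng.uniform(0, 2 * np.pi)
            eeg[mask] += amp * np.sin(2 * np.pi * freq * t[mask] + phase)
        eeg[mask] += spectrum.noise * background[mask]

    spans = _nrem_spans(states, config.epoch_length)
    rate = config.spindle_rate * effect.spindle_rate
    events = _place_spindles(config, spans, rate, rng) if rate > 0 else []
    for ev in events:
        inject_spindle(eeg, fs, ev.start, ev.end - ev.start, ev.frequency,
                       config.spindle_amplitude, _in_place=True)

    emg = rng.standard_normal(n)
    tone = np.array([config.emg_tone[s] for s in SleepState])
    emg *= tone[state_per_sample]

    recording = Recording(eeg=eeg, emg=emg, sampling_rate=fs,
                          animal_id=animal_id, group=group, session=session)
    truth = GroundTruth(hypnogram=states, spindle_events=events,
                        epoch_length=config.epoch_length)
    return recording, truth


def exemplars_from_ground_truth(recording: Recording, truth: GroundTruth,
                                min_duration: float = 30.0) -> list:
    """Build one labelled exemplar per state from a recording's ground truth.

    Prefers the first contiguous same-state bout of at least ``min_duration``
    (what a visual scorer would mark); if a state has no such bout, falls
    back to concatenating that state's epochs until the duration is reached.
    Raises :class:`ValueError` naming the state if even that fails.
    """
    fs = recording.sampling_rate
    spe = int(round(truth.epoch_length * fs))
    need = int(np.ceil(min_duration / truth.epoch_length))
    exemplars = []
    for state in SleepState:
        idx = np.flatnonzero(truth.hypnogram == state)
        chosen = None
        if idx.size >= need:
            # longest-run scan for a contiguous bout
            run_start = 0
            for j in range(1, idx.size + 1):
                if j == idx.size or idx[j] != idx[j - 1] + 1:
                    if j - run_start >= need:
                        chosen = idx[run_start:run_start + need]
                        break
                    run_start = j
            if chosen is None:
                chosen = idx[:need]  # concatenated fallback
        if chosen is None:
            raise ValueError(
                f"cannot build a {min_duration:g} s exemplar for {state.name}: "
                f"only {idx.size * truth.epoch_length:g} s of that state available"
            )
        eeg = np.concatenate([recording.eeg[i * spe:(i + 1) * spe] for i in chosen])
        emg = np.concatenate([recording.emg[i * spe:(i + 1) * spe] for i in chosen])
        exemplars.append(LabeledExemplar(state=state, eeg=eeg, emg=emg, sampling_rate=fs))
    return exemplars


# ---------------------------------------------------------------------------
# Behaviour simulation
# ---------------------------------------------------------------------------

def simulate_behavior(config: SimConfig, group: str, day: str,
                      n_animals: int | None = None,
                      rng: np.random.Generator | None = None) -> BehaviorTable:
    """Acetone and EPM sessions for every animal of one (group, day) cell.

    Withdrawals are Bernoulli draws per trial at the configured group/day
    probability.  The EPM track alternates center and arm visits with
    exponential dwell times; the closed arm is chosen with the configured
    group/day preference, and the event list is truncated at 300 s.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    if day not in BEHAVIOR_DAYS:
        raise ValueError(f"unknown behaviour day {day!r}; expected one of {BEHAVIOR_DAYS}")
    if n_animals is None:
        n_animals = int(config.group_sizes[group])
    if rng is None:
        rng = np.random.default_rng(
            [int(config.seed), 97, GROUPS.index(group), BEHAVIOR_DAYS.index(day)]
        )
    p_withdraw = float(config.withdrawal_prob[(group, day)])
    p_closed = float(config.epm_closed_pref[(group, day)])

    acetone, epm = [], []
    for a in range(n_animals):
        animal_id = f"{group}-{a + 1:02d}"
        trials = tuple(int(rng.random() < p_withdraw) for _ in range(N_TRIALS))
        acetone.append(AcetoneSession(animal_id=animal_id, day=day, trials=trials))

        events = [(0.0, "CENTER")]
        t = 0.0
        in_center = True
        while True:
            if in_center:
                dwell = rng.exponential(config.epm_center_dwell_mean)
                next_zone = "CLOSED" if rng.random() < p_closed else "OPEN"
            else:
                dwell = max(rng.exponential(config.epm_arm_dwell_mean), 1.0)
                next_zone = "CENTER"
            t += max(dwell, 0.25)
            if t >= EPM_SESSION_LENGTH_GUARD:
                break
            events.append((t, next_zone))
            in_center = next_zone == "CENTER"
        epm.append(EpmSession(animal_id=animal_id, day=day, events=events))
    return BehaviorTable(group=group, day=day, acetone=acetone, epm=epm)


EPM_SESSION_LENGTH_GUARD = 300.0
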
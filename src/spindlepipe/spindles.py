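"""Sigma-band spindle detection from the EEG spectrogram.

Detection follows the classic power-threshold scheme: a short-time
spectrogram of the EEG, the integrated power of the extended sigma band
(12-20 Hz, both edges inclusive), and a data-adaptive threshold of
mean + k.SD (k = 2.5, population SD) over NREM-aligned time bins.
Supra-threshold runs separated by less than 0.3 s are merged, and events are
kept only if their duration lies in [0.5, 2] s and their midpoint falls in a
NREM epoch — spindles are a NREM phenomenon.

Two refinements sharpen the raw run-length rule, whose timing is quantized
by the 1.0-s analysis window:

* event timing is re-estimated on a fine sigma-power trace (0.15-s window,
  0.02-s step) by iterative peak extraction: each supra-threshold power peak
  is measured at quarter peak power (= half peak amplitude), and the event
  duration is twice that width — exact for a raised-cosine ("waxing and
  waning") envelope and independent of the absolute threshold level, so
  measured durations do not shrink or grow with burst amplitude.  Durations
  within +/- 0.05 s (the estimator's resolution) of a duration-criterion
  edge are snapped to the edge before filtering;
* each event must pass a spectral check: the peak frequency of its own
  (Hann-windowed, zero-padded) periodogram, searched over the band widened
  by half a bandwidth, must lie within the detection band with a 0.4 Hz
  edge tolerance — well below the ~2 Hz spectral resolution of the shortest
  admissible event.  This suppresses leakage-driven detections of strong
  just-out-of-band oscillations.

Events are characterized by RMS amplitude, power-weighted mean frequency
over the detection band, and peak sigma power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .staging import Hypnogram, SleepState

__all__ = [
    "SIGMA_BAND",
    "Spectrogram",
    "SigmaPowerTrace",
    "SpindleEvent",
    "SpindleSummary",
    "SpindleDetection",
    "compute_spectrogram",
    "sigma_power_trace",
    "compute_threshold",
    "detect_spindles",
    "detect_spindle_events",
    "spindle_rms",
    "spindle_mean_frequency",
    "spindle_density",
    "summarize_spindles",
    "events_to_tsv",
    "events_from_tsv",
]

SIGMA_BAND = (12.0, 20.0)
MIN_DURATION = 0.5
MAX_DURATION = 2.0
MERGE_GAP = 0.3
DURATION_SNAP = 0.05
_BAND_EDGE_TOL = 1e-9


@dataclass
class Spectrogram:
    """Short-time power spectral density, ``power[time, frequency]`` in uV^2/Hz."""

    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    @property
    def step(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else 0.0


@dataclass
class SigmaPowerTrace:
    """Integrated band power (uV^2) per spectrogram time bin."""

    times: np.ndarray
    sigma_power: np.ndarray
    band: tuple = SIGMA_BAND
    step: float = 0.0
    threshold: float | None = None


@dataclass
class SpindleEvent:
    """One detected spindle: half-open [start, end) interval and metrics."""

    start: float
    end: float
    duration: float
    rms: float
    mean_frequency: float
    peak_sigma_power: float


@dataclass
class SpindleSummary:
    density: float                 # events per NREM minute
    mean_of_mean_frequency: float  # Hz
    mean_rms: float                # uV
    n_events: int


@dataclass
class SpindleDetection:
    """Result bundle of :func:`detect_spindle_events`."""

    events: list
    trace: SigmaPowerTrace
    threshold: float
    band: tuple = SIGMA_BAND

    def summary(self, hypnogram: Hypnogram) -> SpindleSummary:
        return summarize_spindles(self.events, hypnogram)


def compute_spectrogram(signal: np.ndarray, sampling_rate: float,
                        window: float = 1.0, step: float = 0.1) -> Spectrogram:
    """Hann-tapered short-time periodogram (PSD scaling, detrending off).

    The FFT length is zero-padded to at least one second of samples so the
    frequency grid is never coarser than 1 Hz regardless of window length;
    total spectrogram energy stays Parseval-consistent with the windowed
    time-domain energy.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if not 0 < step <= window:
        raise ValueError(f"need 0 < step <= window, got step={step}, window={window}")
    nperseg = int(round(window * sampling_rate))
    hop = max(int(round(step * sampling_rate)), 1)
    if nperseg > signal.size:
        raise ValueError(
            f"window of {window:g} s exceeds the {signal.size / sampling_rate:g} s signal"
        )
    nfft = max(nperseg, int(np.ceil(sampling_rate)))
    freqs, times, pxx = sps.spectrogram(
        signal, fs=sampling_rate, window="hann", nperseg=nperseg,
        noverlap=nperseg - hop, nfft=nfft, detrend=False, scaling="density",
        mode="psd",
    )
    return Spectrogram(times=times, freqs=freqs, power=pxx.T)


def sigma_power_trace(spectrogram: Spectrogram,
                      band: tuple = SIGMA_BAND) -> SigmaPowerTrace:
    """Integrated power over frequency bins whose centers lie in [lo, hi]."""
    lo, hi = band
    mask = (spectrogram.freqs >= lo - _BAND_EDGE_TOL) & \
           (spectrogram.freqs <= hi + _BAND_EDGE_TOL)
    if not np.any(mask):
        raise ValueError(
            f"band {band} Hz selects no spectrogram bins "
            f"(grid spans {spectrogram.freqs[0]:g}-{spectrogram.freqs[-1]:g} Hz)"
        )
    power = spectrogram.power[:, mask].sum(axis=1) * spectrogram.df
    return SigmaPowerTrace(times=spectrogram.times, sigma_power=power,
                           band=(float(lo), float(hi)), step=spectrogram.step)


def _nrem_bin_mask(times: np.ndarray, hypnogram: Hypnogram) -> np.ndarray:
    idx = np.floor(times / hypnogram.epoch_length).astype(int)
    valid = (idx >= 0) & (idx < len(hypnogram))
    mask = np.zeros(times.size, dtype=bool)
    mask[valid] = hypnogram.states[idx[valid]] == SleepState.NREM
    return mask


def compute_threshold(trace: SigmaPowerTrace, hypnogram: Hypnogram,
                      k_sd: float = 2.5) -> float:
    """mean + k_sd x SD of sigma power over NREM-aligned bins (population SD)."""
    mask = _nrem_bin_mask(trace.times, hypnogram)
    if not np.any(mask):
        raise ValueError(
            "hypnogram contains no NREM epochs overlapping the trace; "
            "pass an explicit threshold instead"
        )
    vals = trace.sigma_power[mask]
    return float(np.mean(vals) + k_sd * np.std(vals))


def _runs_above(times: np.ndarray, values: np.ndarray, threshold: float,
                step: float, merge_gap: float):
    """Maximal supra-threshold runs as [start, end) intervals in seconds.

    Bin intervals are the half-open [center - step/2, center + step/2) spans;
    runs separated by less than ``merge_gap`` are merged.
    """
    above = values > threshold
    if not np.any(above):
        return []
    edges = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(above.size)
    intervals = [
        (times[i0] - step / 2.0, times[i1 - 1] + step / 2.0)
        for i0, i1 in zip(starts, ends)
    ]
    merged = [intervals[0]]
    for s, e in intervals[1:]:
        if s - merged[-1][1] < merge_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def _midpoint_is_nrem(start: float, end: float, hypnogram: Hypnogram) -> bool:
    mid = 0.5 * (start + end)
    idx = int(mid // hypnogram.epoch_length)
    return 0 <= idx < len(hypnogram) and hypnogram.states[idx] == SleepState.NREM


def detect_spindles(trace: SigmaPowerTrace, threshold: float,
                    hypnogram: Hypnogram, min_dur: float = MIN_DURATION,
                    max_dur: float = MAX_DURATION,
                    merge_gap: float = MERGE_GAP) -> list:
    """Coarse interval detection on one sigma-power trace.

    Returns the supra-threshold runs (gaps < ``merge_gap`` merged) whose run
    duration lies in [min_dur, max_dur] and whose midpoint falls in a NREM
    epoch.  Timing is quantized by the trace's window and step; use
    :func:`detect_spindle_events` for boundary-refined events.
    """
    if not min_dur < max_dur:
        raise ValueError("min_dur must be smaller than max_dur")
    runs = _runs_above(trace.times, trace.sigma_power, threshold, trace.step, merge_gap)
    return [
        (s, e) for s, e in runs
        if min_dur <= e - s <= max_dur and _midpoint_is_nrem(s, e, hypnogram)
    ]


def _quarter_peak_extent(times, power, peak_idx, floor=0.0, frac=0.25,
                         peak_val=None):
    """[left, right] crossing times of the quarter level around one peak.

    The level sits ``frac`` of the way from the background ``floor`` to the
    peak, so the pedestal of in-band background power does not widen the
    measure.  Crossings are linearly interpolated between bin centers; the
    trace edge is used when the walk runs off the trace.
    """
    peak = power[peak_idx] if peak_val is None else peak_val
    level = floor + frac * (peak - floor)
    i = peak_idx
    while i > 0 and power[i - 1] > level:
        i -= 1
    if i > 0 and power[i] != power[i - 1]:
        f = (level - power[i - 1]) / (power[i] - power[i - 1])
        left = times[i - 1] + np.clip(f, 0.0, 1.0) * (times[i] - times[i - 1])
    else:
        left = times[i]
    j = peak_idx
    while j < power.size - 1 and power[j + 1] > level:
        j += 1
    if j < power.size - 1 and power[j] != power[j + 1]:
        f = (power[j] - level) / (power[j] - power[j + 1])
        right = times[j] + np.clip(f, 0.0, 1.0) * (times[j + 1] - times[j])
    else:
        right = times[j]
    return float(left), float(right)


# Relative level r -> fraction of the duration spanned above it for a
# raised-cosine (cos^2) amplitude envelope: w(r)/d = 1 - (2/pi) asin(r^(1/4)).
_LEVEL_CALIBRATION = tuple(
    (r, 1.0 - (2.0 / np.pi) * np.arcsin(r ** 0.25))
    for r in (0.15, 0.2, 0.25, 0.3, 0.4)
)


def _extract_bursts(times, power, threshold, floor=0.0, max_events=10_000):
    """Iterative peak extraction of burst intervals from a fine power trace.

    While the largest remaining power bin exceeds ``threshold``: measure the
    quarter-peak width w around it (quarter of the way from the background
    ``floor`` to the peak), record the event as the quarter-peak extent
    widened by w/2 on each side (duration 2w — exact for a raised-cosine
    envelope), then suppress those bins and repeat.
    """
    power = power.copy()
    events = []
    step = times[1] - times[0] if times.size > 1 else 0.0
    # Mean of cos^4 over the central +/- 1/16 of a raised-cosine burst: the
    # correction that maps a near-top average back to the profile peak.
    top_correction = 0.9747
    if times.size == 0:
        return events
    for _ in range(max_events):
        peak_idx = int(np.argmax(power))
        peak_val = float(power[peak_idx])
        if peak_val <= threshold:
            break
        left, right = _quarter_peak_extent(times, power, peak_idx, floor=floor)
        # The single-bin maximum rides on top of the noise; re-estimate the
        # peak as the corrected average over the top of the profile, which
        # de-biases the relative levels and with them the width.
        hw = max((right - left) / 8.0, step)
        center_0 = 0.5 * (left + right)
        top = power[(times >= center_0 - hw) & (times <= center_0 + hw)]
        if top.size:
            peak_val = max(float(np.mean(top)) / top_correction, peak_val * 0.5)
        # Width at several relative levels, each mapped to a full duration by
        # the raised-cosine closed form w(r) = d (1 - (2/pi) asin r^(1/4));
        # averaging the level estimates suppresses noise on any one crossing.
        estimates = []
        for fr, cal in _LEVEL_CALIBRATION:
            l_f, r_f = _quarter_peak_extent(times, power, peak_idx, floor=floor,
                                            frac=fr, peak_val=peak_val)
            estimates.append((r_f - l_f) / cal)
        left, right = _quarter_peak_extent(times, power, peak_idx, floor=floor,
                                           peak_val=peak_val)
        w = max(right - left, step)
        duration = max(float(np.mean(estimates)), step)
        center = 0.5 * (left + right)
        events.append((center - duration / 2.0, center + duration / 2.0, peak_val))
        power[(times >= center - duration / 2.0)
              & (times <= center + duration / 2.0)] = 0.0
    events.sort(key=lambda e: e[0])
    return events


def _event_peak_frequency(segment: np.ndarray, sampling_rate: float,
                          search_band: tuple, grid_hz: float = 0.05) -> float:
    """Peak frequency of the Hann-windowed, zero-padded event periodogram.

    The search is confined to ``search_band`` so the slow-wave background
    (delta/theta), which dominates the raw spectrum during NREM, does not
    mask the oscillation that actually triggered the detector.
    """
    segment = np.asarray(segment, dtype=np.float64)
    nfft = max(segment.size, int(np.ceil(sampling_rate / grid_hz)))
    spectrum = np.abs(np.fft.rfft(segment * np.hanning(segment.size), n=nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / sampling_rate)
    mask = (freqs >= search_band[0]) & (freqs <= search_band[1])
    return float(freqs[mask][int(np.argmax(spectrum[mask]))])


def detect_spindle_events(eeg: np.ndarray, sampling_rate: float,
                          hypnogram: Hypnogram, band: tuple = SIGMA_BAND, *,
                          threshold: float | None = None, k_sd: float = 2.5,
                          min_dur: float = MIN_DURATION,
                          max_dur: float = MAX_DURATION,
                          merge_gap: float = MERGE_GAP,
                          window: float = 1.0, step: float = 0.1,
                          refine_window: float = 0.15, refine_step: float = 0.02,
                          duration_snap: float = DURATION_SNAP,
                          spectral_margin: float = 0.4,
                          spectral_check: bool = True) -> SpindleDetection:
    """Full spindle detection on one EEG trace.

    Pipeline: sigma-power trace (1.0 s window, 0.1 s step) -> NREM
    mean + ``k_sd`` SD threshold (unless ``threshold`` is given) -> iterative
    quarter-peak burst extraction on the fine 0.15 s / 0.02 s trace (every
    burst whose fine-trace peak exceeds the threshold) -> merge of bursts
    separated by < ``merge_gap`` -> duration filter [min_dur, max_dur]
    (inclusive, durations within ``duration_snap`` of an edge snapped to it)
    -> NREM-midpoint rule -> spectral peak-in-band check -> event
    characterization.
    """
    eeg = np.asarray(eeg, dtype=np.float64)
    spec = compute_spectrogram(eeg, sampling_rate, window=window, step=step)
    trace = sigma_power_trace(spec, band)
    if threshold is None:
        threshold = compute_threshold(trace, hypnogram, k_sd=k_sd)
    trace.threshold = float(threshold)

    # Candidate zones: supra-threshold runs of the coarse trace.  The fine
    # trace has a much larger background variance (shorter windows), so peak
    # extraction is confined to the zones the coarse trace detects.
    candidates = _runs_above(trace.times, trace.sigma_power, float(threshold),
                             trace.step, merge_gap)
    if not candidates:
        return SpindleDetection(events=[], trace=trace,
                                threshold=float(threshold), band=band)
    fine = sigma_power_trace(
        compute_spectrogram(eeg, sampling_rate, window=refine_window,
                            step=refine_step),
        band,
    )
    pad = 0.25
    zone = np.zeros(fine.times.size, dtype=bool)
    for s, e in candidates:
        zone |= (fine.times >= s - pad) & (fine.times <= e + pad)
    gated = np.where(zone, fine.sigma_power, 0.0)
    # Fine-trace background statistics (NREM bins away from candidates):
    # the fine trace has fewer degrees of freedom per bin than the coarse
    # trace, so its own mean + k_sd.SD is the appropriate peak floor.
    bg_mask = _nrem_bin_mask(fine.times, hypnogram) & ~zone
    if not np.any(bg_mask):
        bg_mask = ~zone
    if np.any(bg_mask):
        bg = fine.sigma_power[bg_mask]
        floor = float(np.mean(bg))
        peak_floor = max(float(threshold), floor + k_sd * float(np.std(bg)))
    else:
        floor, peak_floor = 0.0, float(threshold)
    bursts = _extract_bursts(fine.times, gated, peak_floor, floor=floor)

    # Merge bursts separated by less than merge_gap — but only bursts of
    # comparable peak power.  An envelope dip splits one spindle into two
    # comparable halves; a background bump next to a strong burst is orders
    # of magnitude weaker and must not stretch the event.
    merged = []
    for s, e, pk in bursts:
        if merged:
            ps, pe, ppk = merged[-1]
            if s - pe < merge_gap and min(pk, ppk) >= 0.25 * max(pk, ppk):
                merged[-1] = (ps, max(pe, e), max(ppk, pk))
                continue
            if s < pe:  # overlapping but incomparable: keep the stronger
                if pk > ppk:
                    merged[-1] = (s, e, pk)
                continue
        merged.append((s, e, pk))

    lo, hi = band
    events = []
    for s, e, peak_power in merged:
        dur = e - s
        # The estimator resolves durations no finer than ~refine_window/3;
        # estimates within that resolution of a criterion edge are taken to
        # be at the edge.
        if abs(dur - min_dur) <= duration_snap:
            dur = min_dur
        elif abs(dur - max_dur) <= duration_snap:
            dur = max_dur
        if not (min_dur <= dur <= max_dur):
            continue
        if not _midpoint_is_nrem(s, e, hypnogram):
            continue
        i0 = max(int(round(s * sampling_rate)), 0)
        i1 = min(int(round(e * sampling_rate)), eeg.size)
        if i1 - i0 < 2:
            continue
        segment = eeg[i0:i1]
        if spectral_check:
            # Search one half-bandwidth beyond each edge: wide enough to see a
            # just-out-of-band oscillation win, narrow enough to ignore the
            # slow-wave background.
            half_bw = 0.5 * (hi - lo)
            peak = _event_peak_frequency(
                segment, sampling_rate,
                search_band=(max(lo - half_bw, 0.0), hi + half_bw),
            )
            if not (lo - spectral_margin <= peak <= hi + spectral_margin):
                continue
        interval = (max(s, 0.0), min(e, eeg.size / sampling_rate))
        events.append(
            SpindleEvent(
                start=float(s), end=float(e), duration=float(dur),
                rms=spindle_rms(eeg, interval, sampling_rate),
                mean_frequency=spindle_mean_frequency(eeg, interval,
                                                      sampling_rate, band=band),
                peak_sigma_power=float(peak_power),
            )
        )
    return SpindleDetection(events=events, trace=trace, threshold=float(threshold),
                            band=band)


# ---------------------------------------------------------------------------
# Event characterization
# ---------------------------------------------------------------------------

def _interval_slice(interval, sampling_rate, n):
    start, end = interval
    i0 = int(round(start * sampling_rate))
    i1 = int(round(end * sampling_rate))
    if i0 < 0 or i1 > n or i1 <= i0:
        raise ValueError(f"interval {interval} s is empty or outside the signal")
    return i0, i1


def spindle_rms(eeg: np.ndarray, interval, sampling_rate: float) -> float:
    """Root mean square of the EEG samples over [start, end)."""
    eeg = np.asarray(eeg, dtype=np.float64)
    i0, i1 = _interval_slice(interval, sampling_rate, eeg.size)
    return float(np.sqrt(np.mean(eeg[i0:i1] ** 2)))


def spindle_mean_frequency(eeg: np.ndarray, interval, sampling_rate: float,
                           band: tuple | None = SIGMA_BAND) -> float:
    """Power-weighted mean of the periodogram frequencies of one event.

    f_bar = sum(f_i P(f_i)) / sum(P(f_i)) over components with f_i in
    ``band`` (inclusive edges); ``band=None`` uses the full spectrum.
    Returns NaN when the in-band power is zero.
    """
    eeg = np.asarray(eeg, dtype=np.float64)
    i0, i1 = _interval_slice(interval, sampling_rate, eeg.size)
    if i1 - i0 < 2:
        raise ValueError("interval must contain at least 2 samples")
    freqs, pxx = sps.periodogram(eeg[i0:i1], fs=sampling_rate, window="boxcar",
                                 detrend=False)
    if band is not None:
        lo, hi = band
        mask = (freqs >= lo - _BAND_EDGE_TOL) & (freqs <= hi + _BAND_EDGE_TOL)
        freqs, pxx = freqs[mask], pxx[mask]
    total = float(np.sum(pxx))
    if freqs.size == 0 or total <= 0:
        return float("nan")
    return float(np.sum(freqs * pxx) / total)


def spindle_density(events, hypnogram: Hypnogram) -> float:
    """Detected events per NREM minute (NREM minutes from the hypnogram)."""
    if len(hypnogram) == 0:
        raise ValueError("hypnogram is empty")
    nrem_minutes = hypnogram.minutes_in(SleepState.NREM)
    n = len(events)
    if nrem_minutes == 0:
        if n:
            raise ValueError(f"{n} events but zero NREM minutes in the hypnogram")
        return 0.0
    return n / nrem_minutes


def summarize_spindles(events, hypnogram: Hypnogram) -> SpindleSummary:
    density = spindle_density(events, hypnogram)
    if events:
        mf = [e.mean_frequency for e in events if np.isfinite(e.mean_frequency)]
        mean_mf = float(np.mean(mf)) if mf else float("nan")
        mean_rms = float(np.mean([e.rms for e in events]))
    else:
        mean_mf = float("nan")
        mean_rms = float("nan")
    return SpindleSummary(density=density, mean_of_mean_frequency=mean_mf,
                          mean_rms=mean_rms, n_events=len(events))


def events_to_tsv(events, path) -> None:
    frame = pd.DataFrame(
        [
            {"start_s": e.start, "end_s": e.end, "duration_s": e.duration,
             "rms_uV": e.rms, "mean_freq_hz": e.mean_frequency,
             "peak_sigma_power": e.peak_sigma_power}
            for e in events
        ],
        columns=["start_s", "end_s", "duration_s", "rms_uV", "mean_freq_hz",
                 "peak_sigma_power"],
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.4f")


def events_from_tsv(path):
    frame = pd.read_csv(path, sep="\t")
    return [
        SpindleEvent(
            start=row["start_s"], end=row["end_s"], duration=row["duration_s"],
            rms=row["rms_uV"], mean_frequency=row["mean_freq_hz"],
            peak_sigma_power=row["peak_sigma_power"],
        )
        for _, row in frame.iterrows()
    ]
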
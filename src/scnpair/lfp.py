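"""Local-field-potential analysis: filtering, power spectra, spike detection.

The processing chain mirrors a standard larval-zebrafish LFP workflow:

1. zero-phase 50 Hz notch (mains) then zero-phase 2.5-100 Hz band-pass;
2. magnitude-squared FFT power spectra of 40 s windows (Hann taper,
   detrended), normalised so that the one-sided power sums to the windowed
   signal energy (Parseval);
3. amplitude-threshold spike detection against a robust (MAD-based) estimate
   of the baseline SD, with nearby supra-threshold excursions merged;
4. assignment of detected events to preceding light stimuli within a
   response window, yielding a per-stimulus response table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps


class TraceError(ValueError):
    """Raised for invalid traces or parameters."""


@dataclass(frozen=True)
class LfpTrace:
    """A uniformly sampled voltage trace with optional stimulus times."""

    fs: float
    samples: np.ndarray
    t0: float = 0.0
    stimulus_times: tuple[float, ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise TraceError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise TraceError("trace must be a non-empty 1-D sample array")
        span = (self.t0, self.t0 + self.samples.size / self.fs)
        for t in self.stimulus_times:
            if not span[0] <= t <= span[1]:
                raise TraceError(f"stimulus time {t} s outside trace span {span}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided power spectrum of a single analysis window."""

    freqs: np.ndarray
    power: np.ndarray
    window_s: float
    taper: str = "hann"

    def __post_init__(self) -> None:
        if len(self.freqs) != len(self.power):
            raise TraceError("frequency and power grids differ in length")
        if np.any(np.asarray(self.power) < 0):
            raise TraceError("negative power")

    def band_power(self, lo_hz: float, hi_hz: float) -> float:
        """Total power in [lo_hz, hi_hz] (inclusive bin selection)."""
        sel = (self.freqs >= lo_hz) & (self.freqs <= hi_hz)
        return float(np.sum(self.power[sel]))


@dataclass(frozen=True)
class SpikeEvent:
    """A detected supra-threshold excursion."""

    onset_s: float
    peak_s: float
    amplitude_sd: float  # peak magnitude in units of robust baseline SD
    polarity: int  # sign of the signal at the peak
    stimulus_locked: int | None = None  # index of the triggering stimulus

    def __post_init__(self) -> None:
        if self.peak_s < self.onset_s:
            raise TraceError("event peak precedes onset")


def read_trace_csv(
    path: str | Path,
    fs: float | None = None,
    stimulus_path: str | Path | None = None,
    meta: dict | None = None,
) -> LfpTrace:
    """Read a trace from CSV: two columns (time_s,value) or one (value + fs).

    Stimulus times, when given, are a newline-separated list of seconds.
    """
    df = pd.read_csv(path)
    if df.shape[1] >= 2:
        t = df.iloc[:, 0].to_numpy(dtype=float)
        v = df.iloc[:, 1].to_numpy(dtype=float)
        dt = np.diff(t)
        if len(dt) and (dt.min() <= 0 or not np.allclose(dt, dt[0], rtol=1e-6)):
            raise TraceError(f"{path}: time column is not uniformly sampled")
        fs_eff = 1.0 / dt[0] if len(dt) else (fs or 1.0)
        t0 = float(t[0])
    else:
        if fs is None:
            raise TraceError("single-column trace CSV requires an explicit fs")
        v = df.iloc[:, 0].to_numpy(dtype=float)
        fs_eff, t0 = fs, 0.0
    stimuli: tuple[float, ...] = ()
    if stimulus_path is not None:
        with open(stimulus_path) as fh:
            stimuli = tuple(float(line) for line in fh if line.strip())
    return LfpTrace(fs=fs_eff, samples=v, t0=t0, stimulus_times=stimuli, meta=meta or {})


def write_trace_csv(trace: LfpTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.times, "value": trace.samples}).to_csv(
        path, index=False, float_format="%.6f"
    )


def preprocess(
    trace: LfpTrace,
    notch_hz: float = 50.0,
    notch_bw_hz: float = 2.0,
    band_hz: tuple[float, float] = (2.5, 100.0),
    bandpass_order: int = 4,
    trim_lead_s: float = 0.0,
) -> LfpTrace:
    """Zero-phase notch (mains) then zero-phase band-pass; optional lead trim.

    The notch is a biquad of -3 dB width ``notch_bw_hz``; the band-pass is a
    Butterworth of the given order. Both run forward-backward (filtfilt) so
    event timing is not delayed. ``trim_lead_s`` drops electrode-placement
    time from the start of the recording (used for real 13-min recordings,
    off by default for synthetic traces).
    """
    if trace.fs <= 2 * band_hz[1]:
        raise TraceError(
            f"sampling rate {trace.fs} Hz too low for a {band_hz[1]} Hz band edge"
        )
    x = trace.samples
    # filtfilt needs ~3x the filter's impulse settling; demand a modest minimum
    min_len = int(3 * trace.fs / band_hz[0])
    if x.size < min_len:
        raise TraceError(
            f"trace of {x.size} samples too short for filter warm-up ({min_len})"
        )
    b, a = sps.iirnotch(w0=notch_hz, Q=notch_hz / notch_bw_hz, fs=trace.fs)
    x = sps.filtfilt(b, a, x)
    sos = sps.butter(bandpass_order, band_hz, btype="bandpass", fs=trace.fs, output="sos")
    x = sps.sosfiltfilt(sos, x)
    t0 = trace.t0
    if trim_lead_s > 0:
        n_drop = int(round(trim_lead_s * trace.fs))
        if n_drop >= x.size:
            raise TraceError("lead trim removes the whole trace")
        x = x[n_drop:]
        t0 += trim_lead_s
    stimuli = tuple(t for t in trace.stimulus_times if t >= t0)
    meta = dict(trace.meta)
    meta["preprocessed"] = True
    return LfpTrace(fs=trace.fs, samples=x, t0=t0, stimulus_times=stimuli, meta=meta)


def power_spectrum(
    trace: LfpTrace, window_s: float = 40.0, start_s: float | None = None
) -> PowerSpectrum:
    """One-sided power spectrum of one ``window_s`` window (Hann, detrended).

    Power is |X_k|^2 / N with interior bins doubled, so that
    sum(power) equals the energy sum(w*x)^2 of the tapered, detrended window
    (Parseval). Frequency resolution is 1/window_s Hz.
    """
    n_win = int(round(window_s * trace.fs))
    if n_win < 2:
        raise TraceError("window too short")
    offset = 0 if start_s is None else int(round((start_s - trace.t0) * trace.fs))
    if offset < 0 or offset + n_win > trace.samples.size:
        raise TraceError(
            f"window of {window_s} s at offset {offset} samples does not fit a "
            f"trace of {trace.samples.size} samples"
        )
    x = sps.detrend(trace.samples[offset : offset + n_win], type="linear")
    w = np.hanning(n_win)
    xw = x * w
    spec = np.fft.rfft(xw)
    power = (np.abs(spec) ** 2) / n_win
    power[1:] *= 2.0
    if n_win % 2 == 0:
        power[-1] /= 2.0  # Nyquist bin is not duplicated
    freqs = np.fft.rfftfreq(n_win, d=1.0 / trace.fs)
    return PowerSpectrum(freqs=freqs, power=power, window_s=window_s)


def robust_sd(x: np.ndarray) -> float:
    """1.4826 x median absolute deviation: SD estimate insensitive to spikes."""
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def detect_spikes(
    trace: LfpTrace,
    k: float = 5.0,
    min_separation_ms: float = 100.0,
    edge_guard_s: float = 0.05,
) -> list[SpikeEvent]:
    """Threshold detector: |signal| > k x robust SD, nearby excursions merged.

    Excursions separated by less than ``min_separation_ms`` are merged into
    one event. Excursions starting inside ``edge_guard_s`` of either trace
    boundary are discarded: zero-phase filtering leaves transients there. A
    flat trace yields an empty list with a warning rather than an error.
    """
    x = trace.samples
    sd = robust_sd(x)
    if sd == 0.0:
        if np.any(x != 0):
            sd = float(np.std(x))  # pathological: >50% identical samples
        if sd == 0.0:
            warnings.warn("zero-variance trace: no spikes detectable")
            return []
    thresh = k * sd
    above = np.abs(x) > thresh
    if not np.any(above):
        return []
    # contiguous supra-threshold runs
    edges = np.diff(above.astype(int))
    starts = list(np.where(edges == 1)[0] + 1)
    ends = list(np.where(edges == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(x))
    min_gap = int(min_separation_ms / 1000.0 * trace.fs)
    merged: list[tuple[int, int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < min_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    guard = int(edge_guard_s * trace.fs)
    events = []
    for s, e in merged:
        if s < guard or s > len(x) - guard:
            continue
        seg = x[s:e]
        pk = int(np.argmax(np.abs(seg)))
        events.append(
            SpikeEvent(
                onset_s=trace.t0 + s / trace.fs,
                peak_s=trace.t0 + (s + pk) / trace.fs,
                amplitude_sd=float(abs(seg[pk]) / sd),
                polarity=int(np.sign(seg[pk])) or 1,
            )
        )
    return sorted(events, key=lambda ev: ev.onset_s)


def stimulus_locked_responses(
    events: list[SpikeEvent],
    stimulus_times: list[float] | tuple[float, ...],
    response_window_s: float = 0.5,
) -> tuple[pd.DataFrame, float | None, list[SpikeEvent]]:
    """Assign events to the most recent stimulus within the response window.

    Returns (per-stimulus table with hit/latency, overall response fraction,
    events re-labelled with their stimulus index). With no stimuli the
    fraction is None and every event stays spontaneous.
    """
    stims = sorted(stimulus_times)
    hits: dict[int, float] = {}
    labelled: list[SpikeEvent] = []
    for ev in events:
        locked: int | None = None
        for si in range(len(stims) - 1, -1, -1):
            if stims[si] <= ev.onset_s:
                if ev.onset_s - stims[si] <= response_window_s:
                    locked = si
                break
        if locked is not None and locked not in hits:
            hits[locked] = ev.onset_s - stims[locked]
        labelled.append(replace(ev, stimulus_locked=locked))
    table = pd.DataFrame(
        {
            "stimulus_index": range(len(stims)),
            "stimulus_s": stims,
            "hit": [si in hits for si in range(len(stims))],
            "latency_s": [hits.get(si, math.nan) for si in range(len(stims))],
        }
    )
    fraction = (len(hits) / len(stims)) if stims else None
    return table, fraction, labelled


def events_to_frame(events: list[SpikeEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "onset_s": [e.onset_s for e in events],
            "peak_s": [e.peak_s for e in events],
            "amplitude_sd": [e.amplitude_sd for e in events],
            "polarity": [e.polarity for e in events],
            "stimulus_locked": [
                -1 if e.stimulus_locked is None else e.stimulus_locked for e in events
            ],
        }
    )
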
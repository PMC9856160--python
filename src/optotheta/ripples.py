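"""Sharp-wave ripple detection, event metrics and density contrasts.

Detection pipeline (all stages zero-phase):

1. downsample the CA1 trace to 500 Hz;
2. band-pass 100-250 Hz with a two-way least-squares FIR (0.5 Hz
   transition);
3. rectify and low-pass at 20 Hz (4th-order Butterworth, forward-backward)
   to obtain a smooth envelope;
4. z-score the envelope against the whole trace;
5. events are excursions above 3.5 SD, extended outwards to the nearest
   1 SD crossings; an event starting within 50 ms of the previous event's
   end is merged into it (refractory rule against double detections).

Per-event frequency/amplitude/duration come from a 7-cycle complex Morlet
decomposition over 100-250 Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from . import dsp
from .io_model import Recording, StimProtocol, paired_epochs

__all__ = [
    "RippleEvent",
    "detect_ripples",
    "ripple_metrics",
    "ripple_density",
    "ripple_triggered_profile",
    "DETECT_RATE",
]

DETECT_RATE = 500.0
THRESHOLD_SD = 3.5
EDGE_SD = 1.0
REFRACTORY_S = 0.050


@dataclass
class RippleEvent:
    onset: float
    end: float
    peak_time: float
    amplitude: float  # peak envelope z-score
    duration: float = np.nan  # ms
    peak_freq: float = np.nan  # Hz
    channel_id: int = -1

    def __post_init__(self) -> None:
        if not self.onset <= self.peak_time <= self.end:
            raise ValueError("require onset <= peak_time <= end")


def ripple_envelope(trace: np.ndarray, rate: float) -> tuple[np.ndarray, float]:
    """Z-scored smooth envelope of the 100-250 Hz band; returns (z, rate)."""
    if rate < DETECT_RATE:
        raise ValueError(f"need >= {DETECT_RATE} Hz input for the ripple band")
    x = dsp.resample(np.asarray(trace, dtype=np.float64), rate, DETECT_RATE)
    x = dsp.fir_bandpass(x, DETECT_RATE, dsp.RIPPLE_BAND.lo, dsp.RIPPLE_BAND.hi)
    env = dsp.butter_lowpass(np.abs(x), DETECT_RATE, cutoff=20.0, order=4)
    return dsp.zscore(env), DETECT_RATE


def detect_ripples(trace: np.ndarray, rate: float,
                   channel_id: int = -1) -> list[RippleEvent]:
    """Detect ripple events on one CA1 channel (see module docstring)."""
    trace = np.asarray(trace, dtype=np.float64)
    if trace.size < 2 * rate:
        raise ValueError("need at least 2 s of signal")
    z, fs = ripple_envelope(trace, rate)

    above = z > THRESHOLD_SD
    if not np.any(above):
        events_idx = []
    else:
        edges = np.diff(above.astype(np.int8))
        starts = np.flatnonzero(edges == 1) + 1
        ends = np.flatnonzero(edges == -1) + 1  # exclusive
        if above[0]:
            starts = np.insert(starts, 0, 0)
        if above[-1]:
            ends = np.append(ends, above.size)
        # extend to the surrounding 1 SD crossings
        below = z < EDGE_SD
        events_idx = []
        for s, e in zip(starts, ends):
            prev = np.flatnonzero(below[:s])
            s1 = prev[-1] + 1 if prev.size else 0
            nxt = np.flatnonzero(below[e:])
            e1 = e + nxt[0] if nxt.size else z.size
            events_idx.append([s1, e1])

    # refractory merge: an onset within 50 ms of the previous end joins it
    merged: list[list[int]] = []
    refr = int(round(REFRACTORY_S * fs))
    for s, e in events_idx:
        if merged and s - merged[-1][1] <= refr:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    events = []
    for s, e in merged:
        seg = z[s:e]
        pk = s + int(np.argmax(seg))
        events.append(RippleEvent(
            onset=s / fs, end=e / fs, peak_time=pk / fs,
            amplitude=float(z[pk]),
            duration=(e - s) / fs * 1000.0,
            channel_id=channel_id,
        ))
    return events


def ripple_metrics(events: list[RippleEvent], trace: np.ndarray, rate: float,
                   freq_step: float = 2.0) -> list[RippleEvent]:
    """Fill peak_freq (and refresh duration) via 7-cycle Morlet spectra.

    peak_freq is the frequency of maximal Morlet magnitude averaged over
    the event window, on a 100-250 Hz grid.
    """
    trace = np.asarray(trace, dtype=np.float64)
    x = dsp.resample(trace, rate, DETECT_RATE) if rate != DETECT_RATE else trace
    f_hi = min(dsp.RIPPLE_BAND.hi, 0.98 * DETECT_RATE / 2)
    freqs = np.arange(dsp.RIPPLE_BAND.lo, f_hi, freq_step)
    n = x.size
    out = []
    for ev in events:
        s = int(round(ev.onset * DETECT_RATE))
        e = int(round(ev.end * DETECT_RATE))
        if s < 0 or e > n:
            raise IndexError(f"event [{ev.onset}, {ev.end}] outside trace")
        pad = int(0.05 * DETECT_RATE)
        seg = x[max(s - pad, 0):min(e + pad, n)]
        tfr = dsp.morlet_tfr(seg, DETECT_RATE, freqs, n_cycles=7.0)
        core = tfr[:, min(pad, s):min(pad, s) + (e - s)]
        profile = core.mean(axis=1)
        out.append(replace(ev, peak_freq=float(freqs[int(np.argmax(profile))]),
                           duration=(e - s) / DETECT_RATE * 1000.0))
    return out


def ripple_density(events: list[RippleEvent], protocol: StimProtocol,
                   bin_s: float = 5.0, window_s: float = 15.0):
    """Peri-stimulus ripple density and the paired on/off contrast.

    Returns a dict with the trial-averaged events/s per ``bin_s`` bin
    aligned to pulse onset (from -window_s to +pulse duration), the mean
    on and off densities, and ``contrast = (on - off) / off``.
    """
    pairs = paired_epochs(protocol)
    if not pairs:
        raise ValueError("protocol yields no usable trials")
    peaks = np.sort([ev.peak_time for ev in events])
    dur = protocol.pulse_duration
    edges_rel = np.arange(-window_s, dur + bin_s / 2, bin_s)
    per_trial = []
    for off_ep, on_ep in pairs:
        t0 = on_ep.start
        lo = max(-window_s, -t0)  # clip the pre-pulse window at session start
        counts, _ = np.histogram(peaks, bins=t0 + edges_rel)
        counts = counts.astype(np.float64)
        counts[edges_rel[:-1] < lo] = np.nan
        per_trial.append(counts / bin_s)
    per_trial = np.asarray(per_trial, dtype=np.float64)
    centers = (edges_rel[:-1] + edges_rel[1:]) / 2.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        curve = np.nanmean(per_trial, axis=0)
    # off rate = mean density over the whole pre-pulse window of the curve,
    # on rate = mean density during the pulse
    on_rate = float(curve[(centers > 0) & (centers < dur)].mean())
    off_rate = float(curve[centers < 0].mean())
    if off_rate == 0:
        warnings.warn("no off-epoch events: contrast undefined", stacklevel=2)
        contrast = np.nan
    else:
        contrast = (on_rate - off_rate) / off_rate
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sem = (np.nanstd(per_trial, axis=0, ddof=1) / np.sqrt(len(pairs))
               if len(pairs) > 1 else np.zeros(edges_rel.size - 1))
    return {
        "bin_centers_s": centers,
        "density_mean": curve,
        "density_sem": sem,
        "on_rate": on_rate,
        "off_rate": off_rate,
        "contrast": contrast,
        "n_trials": len(pairs),
    }


def ripple_triggered_profile(events: list[RippleEvent], rec: Recording,
                             half_window_s: float = 0.1,
                             return_band_rms: bool = False):
    """Mean raw LFP around ripple peaks, per channel.

    Returns ``(profile, lags_s)`` with profile of shape channels x window;
    the sharp-wave polarity in it identifies the CA1 laminae.  With
    ``return_band_rms=True`` a third array gives each channel's *induced*
    ripple-band RMS (event-wise RMS of the 100-250 Hz filtered signal,
    averaged over events): ripple cycles are not phase-locked to the
    detected envelope peak, so they largely cancel in the evoked average,
    and the induced quantity is what localizes stratum pyramidale.
    """
    if len(events) < 10:
        warnings.warn(f"only {len(events)} events; laminar profile unreliable",
                      stacklevel=2)
    half = int(round(half_window_s * rec.rate))
    lags = np.arange(-half, half + 1) / rec.rate
    acc = np.zeros((rec.n_channels, lags.size))
    n_used = 0
    windows = []
    for ev in events:
        c = int(round(ev.peak_time * rec.rate))
        if c - half < 0 or c + half + 1 > rec.n_samples:
            continue
        acc += rec.data[:, c - half:c + half + 1]
        # RMS windows cover only the event span, where the band energy is
        windows.append((int(ev.onset * rec.rate), int(ev.end * rec.rate)))
        n_used += 1
    if n_used == 0:
        raise ValueError("no event window fits inside the recording")
    profile = acc / n_used
    if not return_band_rms:
        return profile, lags
    hi = min(dsp.RIPPLE_BAND.hi, 0.95 * rec.rate / 2.0)
    band_rms = np.zeros(rec.n_channels)
    for i in range(rec.n_channels):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bp = dsp.fir_bandpass(rec.data[i], rec.rate, dsp.RIPPLE_BAND.lo,
                                  hi, transition=10.0)
        band_rms[i] = np.sqrt(np.mean(
            [np.mean(bp[s:e] ** 2) for s, e in windows]))
    return profile, lags, band_rms
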
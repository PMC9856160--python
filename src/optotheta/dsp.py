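"""Shared signal-processing primitives.

Every filter in this module is zero-net-phase: the least-squares FIR
band-pass and the Butterworth low-pass are both applied forward and
backward, so a passband sinusoid comes out with no lag.  Phase convention
for :func:`hilbert_phase` is phase 0 at the cosine peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal

__all__ = [
    "BandDef",
    "BANDS",
    "GC_THETA",
    "resample",
    "fir_bandpass",
    "butter_lowpass",
    "hilbert_phase",
    "morlet_tfr",
    "zscore",
    "DegenerateSignalError",
]


class DegenerateSignalError(ValueError):
    """Raised when an operation is undefined on the input (e.g. constant)."""


@dataclass(frozen=True)
class BandDef:
    """A named frequency band [lo, hi] in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 <= self.lo < self.hi:
            raise ValueError(f"invalid band {self.name}: [{self.lo}, {self.hi}]")


#: Band registry for the LFP power contrasts (slow/theta/gamma) and the
#: low-theta band used for the directed-causality contrast.
BANDS = {
    "slow": BandDef("slow", 0.5, 3.0),
    "theta": BandDef("theta", 4.0, 7.0),
    "slow_gamma": BandDef("slow_gamma", 20.0, 40.0),
    "high_gamma": BandDef("high_gamma", 60.0, 140.0),
}
GC_THETA = BandDef("theta", 3.0, 6.0)
RIPPLE_BAND = BandDef("ripple", 100.0, 250.0)


def resample(x: np.ndarray, rate_in: float, rate_out: float) -> np.ndarray:
    """Anti-aliased downsampling via polyphase filtering.

    Output length is ``round(n * rate_out / rate_in)`` up to the polyphase
    ceiling convention (exact for integer decimation of even-length input).
    """
    if rate_out > rate_in:
        raise ValueError("upsampling not supported: rate_out > rate_in")
    if rate_out == rate_in:
        return np.asarray(x, dtype=np.float64).copy()
    from fractions import Fraction

    frac = Fraction(rate_out / rate_in).limit_denominator(10000)
    return signal.resample_poly(np.asarray(x, dtype=np.float64), frac.numerator,
                                frac.denominator)


@lru_cache(maxsize=64)
def _firls_taps(rate: float, lo: float, hi: float, trans: float, numtaps: int) -> np.ndarray:
    nyq = rate / 2.0
    # transition bands shrink near the spectrum edges so the stopbands
    # keep positive width
    f_lo1 = max(lo - trans, lo / 2.0)
    f_hi1 = min(hi + trans, (hi + nyq) / 2.0)
    bands = []
    desired = []
    if lo > 0 and f_lo1 > 0:
        bands += [0.0, f_lo1]
        desired += [0.0, 0.0]
    bands += [lo, hi]
    desired += [1.0, 1.0]
    if f_hi1 < nyq:
        bands += [f_hi1, nyq]
        desired += [0.0, 0.0]
    return signal.firls(numtaps, bands, desired, fs=rate)


def _filtfilt_fft(b: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Forward-backward FIR filtering via FFT convolution.

    Odd-reflection padding (as in ``scipy.signal.filtfilt``) suppresses edge
    transients; FFT convolution keeps long least-squares filters tractable
    on 10-minute traces.
    """
    ntaps = len(b)
    pad = min(3 * ntaps, len(x) - 1)
    xp = np.concatenate([2 * x[0] - x[pad:0:-1], x, 2 * x[-1] - x[-2:-pad - 2:-1]])
    y = signal.fftconvolve(xp, b, mode="same")
    y = signal.fftconvolve(y[::-1], b, mode="same")[::-1]
    return y[pad:pad + len(x)]


def fir_bandpass(x: np.ndarray, rate: float, lo: float, hi: float,
                 transition: float = 0.5) -> np.ndarray:
    """Two-way (zero-phase) least-squares FIR band-pass.

    The filter order targets ``3 * rate / transition`` taps (a 0.5 Hz
    transition width by default) but is capped at one third of the signal
    length, with a warning, so short test fixtures degrade gracefully
    rather than fail.
    """
    x = np.asarray(x, dtype=np.float64)
    nyq = rate / 2.0
    if not 0 <= lo < hi <= nyq:
        raise ValueError(f"band [{lo}, {hi}] outside [0, {nyq}]")
    ntaps = int(3 * rate / transition) | 1
    cap = (len(x) // 3) | 1
    if ntaps > cap:
        ntaps = cap
        eff_trans = 3 * rate / ntaps
        warnings.warn(
            f"signal too short for {transition} Hz transition; "
            f"using {ntaps} taps (~{eff_trans:.2f} Hz)", stacklevel=2)
        transition = eff_trans
    if ntaps < 9:
        raise ValueError("signal too short to filter (need > 3x filter order)")
    b = _firls_taps(float(rate), float(lo), float(hi), float(transition), ntaps)
    return _filtfilt_fft(b, x)


def butter_lowpass(x: np.ndarray, rate: float, cutoff: float = 20.0,
                   order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass (applied forward-backward)."""
    if cutoff >= rate / 2.0:
        raise ValueError(f"cutoff {cutoff} >= Nyquist {rate / 2.0}")
    sos = signal.butter(order, cutoff, btype="low", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=np.float64))


def hilbert_phase(x: np.ndarray) -> np.ndarray:
    """Instantaneous phase of the analytic signal, wrapped to (-pi, pi].

    Phase 0 at the cosine peak: ``cos(2*pi*f*t)`` has phase 0 at t = 0.
    """
    return np.angle(signal.hilbert(np.asarray(x, dtype=np.float64)))


def morlet_tfr(x: np.ndarray, rate: float, freqs: np.ndarray,
               n_cycles: float = 7.0) -> np.ndarray:
    """Morlet wavelet magnitude, freqs x time.

    Each complex wavelet has a Gaussian envelope with temporal SD
    ``n_cycles / (2*pi*f)`` and is normalized so a unit-amplitude sinusoid
    at f yields magnitude ~1 at that frequency row.
    """
    x = np.asarray(x, dtype=np.float64)
    freqs = np.atleast_1d(np.asarray(freqs, dtype=np.float64))
    if np.any(freqs >= rate / 2) or np.any(freqs <= 0):
        raise ValueError("freqs must lie in (0, Nyquist)")
    out = np.empty((freqs.size, x.size))
    for i, f in enumerate(freqs):
        sd_t = n_cycles / (2 * np.pi * f)
        half = int(np.ceil(4 * sd_t * rate))
        t = np.arange(-half, half + 1) / rate
        env = np.exp(-(t ** 2) / (2 * sd_t ** 2))
        w = env * np.exp(2j * np.pi * f * t)
        w /= env.sum() / 2.0  # unit response to a unit-amplitude sinusoid
        out[i] = np.abs(signal.fftconvolve(x, w, mode="same"))
    return out


def zscore(x: np.ndarray) -> np.ndarray:
    """Standardize by the mean and SD of the whole trace."""
    x = np.asarray(x, dtype=np.float64)
    sd = x.std()
    if sd == 0:
        raise DegenerateSignalError("constant signal has no z-score")
    return (x - x.mean()) / sd
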
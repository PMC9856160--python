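"""Multitaper spectral estimation and the band-contrast procedure.

The estimator is the classic Thomson multitaper: average of K Slepian
(DPSS) tapered periodograms with time-bandwidth product TW, giving a
spectral half-bandwidth of TW / T for a window of T seconds.  With the
TW = 3 default the taper count is K = 2*TW - 1 = 5 and a 5-s window has a
0.6 Hz half-bandwidth.

Power is reported as one-sided density (uV^2/Hz for LFP) satisfying the
Parseval contract: the integral over [0, Nyquist] equals the signal
variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats
from scipy.signal import windows

from .dsp import BandDef, BANDS

__all__ = [
    "Spectrum",
    "BandTable",
    "taper_count",
    "half_bandwidth",
    "multitaper_psd",
    "band_power",
    "whiten_1f",
    "spike_psd",
    "compare_bands",
    "InsufficientDataError",
]


class InsufficientDataError(ValueError):
    pass


def taper_count(tw: float) -> int:
    """Number of well-concentrated Slepian tapers for a given TW."""
    return int(2 * tw - 1)


def half_bandwidth(tw: float, window_s: float) -> float:
    """Spectral half-bandwidth (Hz) of a multitaper estimate."""
    return tw / window_s


@dataclass
class Spectrum:
    freqs: np.ndarray
    psd: np.ndarray
    tw: float
    k: int
    window_s: float

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.psd = np.asarray(self.psd, dtype=np.float64)
        if self.freqs.shape != self.psd.shape:
            raise ValueError("freqs and psd must have equal length")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@lru_cache(maxsize=32)
def _dpss(n: int, tw: float, k: int) -> np.ndarray:
    # unit-energy tapers: sum(t**2) == 1 per taper
    tapers = windows.dpss(n, tw, Kmax=k, norm=2)
    return np.asarray(tapers)


def _tapered_fft(seg: np.ndarray, rate: float, tw: float, k: int,
                 nfft: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-taper one-sided FFTs scaled for density estimation.

    Returns (freqs, X) with X of shape (k, n_freqs) such that
    mean(|X|^2, axis=0) is the one-sided PSD.
    """
    n = seg.size
    tapers = _dpss(n, tw, k)
    if nfft is None:
        nfft = n
    X = np.fft.rfft(tapers * seg[None, :], n=nfft, axis=1)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / rate)
    # one-sided density scaling: double all bins except DC (and Nyquist if present)
    scale = np.full(freqs.size, 2.0 / rate)
    scale[0] = 1.0 / rate
    if nfft % 2 == 0:
        scale[-1] = 1.0 / rate
    return freqs, X * np.sqrt(scale)[None, :]


def multitaper_psd(segment: np.ndarray, rate: float, tw: float = 3.0,
                   k: int | None = None, nfft: int | None = None,
                   demean: bool = True) -> Spectrum:
    """Multitaper PSD of one segment.

    Parameters follow the Thomson convention: ``tw`` is the time-bandwidth
    product, ``k`` the taper count (default 2*TW - 1; more would be poorly
    concentrated and is rejected).
    """
    segment = np.asarray(segment, dtype=np.float64)
    kmax = taper_count(tw)
    if k is None:
        k = kmax
    if k > kmax:
        raise ValueError(f"k={k} exceeds 2*TW-1={kmax} well-concentrated tapers")
    if segment.size < 2 * k:
        raise InsufficientDataError(
            f"segment of {segment.size} samples too short for {k} tapers")
    if demean:
        segment = segment - segment.mean()
    freqs, X = _tapered_fft(segment, rate, tw, k, nfft)
    psd = np.mean(np.abs(X) ** 2, axis=0)
    return Spectrum(freqs=freqs, psd=psd, tw=tw, k=k,
                    window_s=segment.size / rate)


def band_power(spectrum: Spectrum, band: BandDef) -> float:
    """Mean power density over a band (uV^2/Hz), matching tabulated units."""
    mask = (spectrum.freqs >= band.lo) & (spectrum.freqs <= band.hi)
    if not np.any(mask):
        raise ValueError(f"band {band.name} empty on this frequency grid")
    return float(spectrum.psd[mask].mean())


def whiten_1f(spectrum: Spectrum) -> Spectrum:
    """Correct the EEG power law by multiplying density by frequency.

    The DC bin (f = 0) is dropped.
    """
    keep = spectrum.freqs > 0
    return Spectrum(
        freqs=spectrum.freqs[keep],
        psd=spectrum.psd[keep] * spectrum.freqs[keep],
        tw=spectrum.tw, k=spectrum.k, window_s=spectrum.window_s,
    )


def spike_psd(times: np.ndarray, epochs, bin_rate: float = 1000.0,
              tw: float = 3.0, k: int | None = None) -> Spectrum:
    """Rate-normalized multitaper spectrum of a spike train.

    Spikes are binned per epoch at ``bin_rate``, mean-subtracted, multitaper
    spectra averaged across epochs, and the result divided by the Poisson
    floor (2 * mean_count * dt) so a homogeneous Poisson train is flat at 1.
    """
    times = np.asarray(times, dtype=np.float64)
    dt = 1.0 / bin_rate
    total = 0
    counts_all = []
    for ep in epochs:
        n_bins = int(round(ep.duration * bin_rate))
        c, _ = np.histogram(times, bins=n_bins, range=(ep.start, ep.start + n_bins * dt))
        counts_all.append(c.astype(np.float64))
        total += int(c.sum())
    if total < 50:
        raise InsufficientDataError(f"only {total} spikes; need >= 50")
    psd = None
    freqs = None
    for c in counts_all:
        sp = multitaper_psd(c - c.mean(), bin_rate, tw=tw, k=k, demean=False)
        psd = sp.psd if psd is None else psd + sp.psd
        freqs = sp.freqs
        kk, win = sp.k, sp.window_s
    psd /= len(counts_all)
    mean_count = total / sum(c.size for c in counts_all)
    floor = 2.0 * mean_count * dt  # one-sided density of Poisson counts
    return Spectrum(freqs=freqs, psd=psd / floor, tw=tw, k=kk, window_s=win)


# ---------------------------------------------------------------------------
# Band contrast tables

@dataclass
class BandTable:
    """Per-band paired on/off contrast with FDR-corrected significance."""

    rows: list[dict]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rows)

    def __getitem__(self, band_name: str) -> dict:
        for r in self.rows:
            if r["band"] == band_name:
                return r
        raise KeyError(band_name)


def _paired_test(off: np.ndarray, on: np.ndarray, alpha_normal: float = 0.05):
    """Paired test with a normality gate on the differences.

    Lilliefors-corrected KS normality on the paired differences selects
    between the paired t-test and the Wilcoxon signed-rank test.
    """
    d = on - off
    if np.allclose(d, 0):
        return 1.0, "degenerate"
    from statsmodels.stats.diagnostic import lilliefors

    try:
        _, p_norm = lilliefors(d, dist="norm")
    except Exception:
        p_norm = 0.0
    if p_norm > alpha_normal:
        _, p = stats.ttest_rel(on, off)
        return float(p), "ttest_rel"
    _, p = stats.wilcoxon(on, off, zero_method="wilcox")
    return float(p), "wilcoxon"


def compare_bands(off_powers: dict[str, np.ndarray], on_powers: dict[str, np.ndarray],
                  bands: dict[str, BandDef] | None = None,
                  alpha: float = 0.05) -> BandTable:
    """Paired per-band on/off contrast with Benjamini-Hochberg correction.

    ``off_powers[band]`` and ``on_powers[band]`` are per-trial band power
    arrays of equal length (paired by trial).
    """
    from statsmodels.stats.multitest import multipletests

    if bands is None:
        bands = BANDS
    rows = []
    pvals = []
    for name, band in bands.items():
        off = np.asarray(off_powers[name], dtype=np.float64)
        on = np.asarray(on_powers[name], dtype=np.float64)
        if off.size != on.size:
            raise ValueError(f"band {name}: unpaired samples")
        if off.size < 6:
            raise InsufficientDataError("need >= 6 trial pairs per band")
        p, test = _paired_test(off, on)
        rows.append({
            "band": name,
            "lo_hz": band.lo,
            "hi_hz": band.hi,
            "mean_off": float(off.mean()),
            "sem_off": float(off.std(ddof=1) / np.sqrt(off.size)),
            "mean_on": float(on.mean()),
            "sem_on": float(on.std(ddof=1) / np.sqrt(on.size)),
            "p_raw": p,
            "test": test,
        })
        pvals.append(p)
    reject, p_fdr, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    for r, pf, rej in zip(rows, p_fdr, reject):
        r["p_fdr"] = float(pf)
        r["significant"] = bool(rej)
    return BandTable(rows=rows)


def per_trial_band_powers(lfp: np.ndarray, rate: float, pairs,
                          bands: dict[str, BandDef] | None = None,
                          tw: float = 3.0, k: int | None = None):
    """Band power per (off, on) epoch pair from one LFP channel.

    Each 5-s epoch is one multitaper window (TW = 3 gives a 0.6 Hz
    half-bandwidth on 5 s).  Returns (off_powers, on_powers) dicts keyed
    by band name.
    """
    if bands is None:
        bands = BANDS
    off_powers = {n: [] for n in bands}
    on_powers = {n: [] for n in bands}
    for off_ep, on_ep in pairs:
        for ep, store in ((off_ep, off_powers), (on_ep, on_powers)):
            seg = lfp[ep.slice(rate)]
            sp = multitaper_psd(seg, rate, tw=tw, k=k)
            for name, band in bands.items():
                store[name].append(band_power(sp, band))
    return ({n: np.asarray(v) for n, v in off_powers.items()},
            {n: np.asarray(v) for n, v in on_powers.items()})
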
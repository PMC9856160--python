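"""Spike-field and LFP-LFP coherence, pairwise phase consistency, and CA1
layer inference from the sharp-wave/ripple laminar profile.

Coherence is magnitude-squared multitaper coherence, with cross- and
auto-spectra averaged over tapers and trials.  The spike "channel" is the
mean-subtracted binned spike count (2 ms bins).

Pairwise phase consistency (PPC) is the mean cosine of the angular
distance over all spike-phase pairs, computed with the exact incoherent-sum
identity PPC = (|sum e^{i theta}|^2 - N) / (N (N - 1)); it is free of the
spike-count bias that afflicts the resultant-length statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import dsp
from .io_model import Recording
from .spectral import _tapered_fft, taper_count

__all__ = [
    "CoherenceCurve",
    "PPCCurve",
    "coherence",
    "spike_field_coherence",
    "ppc",
    "ppc_from_phases",
    "coherence_by_distance",
    "assign_layers",
]

SPIKE_BIN_S = 0.002


@dataclass
class CoherenceCurve:
    freqs: np.ndarray
    coh: np.ndarray
    n_segments: int
    kind: str = "lfp_lfp"  # or "spike_field"

    def band_mean(self, band: dsp.BandDef) -> float:
        mask = (self.freqs >= band.lo) & (self.freqs <= band.hi)
        return float(self.coh[mask].mean())


@dataclass
class PPCCurve:
    freqs: np.ndarray
    ppc: np.ndarray
    n_spikes: int

    def band_mean(self, band: dsp.BandDef) -> float:
        mask = (self.freqs >= band.lo) & (self.freqs <= band.hi) & np.isfinite(self.ppc)
        return float(self.ppc[mask].mean())


def coherence(segs_a, segs_b, rate: float, tw: float = 3.0,
              k: int | None = None, kind: str = "lfp_lfp") -> CoherenceCurve:
    """Multitaper magnitude-squared coherence averaged over trials.

    ``segs_a`` / ``segs_b`` are equal-length lists of paired segments
    (trials).  A single segment is rejected: with one taper-averaged
    segment the estimator degenerates toward 1.
    """
    if k is None:
        k = taper_count(tw)
    segs_a = [np.asarray(s, dtype=np.float64) for s in np.atleast_2d(segs_a)] \
        if isinstance(segs_a, np.ndarray) else [np.asarray(s, float) for s in segs_a]
    segs_b = [np.asarray(s, dtype=np.float64) for s in np.atleast_2d(segs_b)] \
        if isinstance(segs_b, np.ndarray) else [np.asarray(s, float) for s in segs_b]
    if len(segs_a) != len(segs_b):
        raise ValueError("unpaired segment lists")
    if len(segs_a) < 2:
        raise ValueError("coherence needs >= 2 averaging segments")
    saa = sbb = sab = None
    freqs = None
    for a, b in zip(segs_a, segs_b):
        if a.size != b.size:
            raise ValueError("paired segments must have equal length")
        freqs, Xa = _tapered_fft(a - a.mean(), rate, tw, k)
        _, Xb = _tapered_fft(b - b.mean(), rate, tw, k)
        paa = np.sum(np.abs(Xa) ** 2, axis=0)
        pbb = np.sum(np.abs(Xb) ** 2, axis=0)
        pab = np.sum(Xa * np.conj(Xb), axis=0)
        saa = paa if saa is None else saa + paa
        sbb = pbb if sbb is None else sbb + pbb
        sab = pab if sab is None else sab + pab
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(sab) ** 2 / (saa * sbb)
    coh = np.clip(np.nan_to_num(coh), 0.0, 1.0)
    return CoherenceCurve(freqs=freqs, coh=coh, n_segments=len(segs_a), kind=kind)


def bin_spikes(times: np.ndarray, start: float, end: float,
               bin_s: float = SPIKE_BIN_S) -> np.ndarray:
    """Mean-subtracted binned spike counts over [start, end)."""
    n_bins = int(round((end - start) / bin_s))
    c, _ = np.histogram(times, bins=n_bins, range=(start, start + n_bins * bin_s))
    c = c.astype(np.float64)
    return c - c.mean()


def spike_field_coherence(times: np.ndarray, lfp: np.ndarray, rate: float,
                          epochs, tw: float = 3.0, k: int | None = None) -> CoherenceCurve:
    """Coherence between a unit's binned spike train and an LFP channel.

    Both channels are cut per epoch, the LFP resampled onto the 2 ms spike
    bin grid, and coherence averaged across epochs.
    """
    bin_rate = 1.0 / SPIKE_BIN_S
    segs_spk, segs_lfp = [], []
    for ep in epochs:
        seg = lfp[ep.slice(rate)]
        segs_lfp.append(dsp.resample(seg, rate, bin_rate))
        s = bin_spikes(np.asarray(times, float), ep.start, ep.end)
        n = min(s.size, segs_lfp[-1].size)
        segs_lfp[-1] = segs_lfp[-1][:n]
        segs_spk.append(s[:n])
    return coherence(segs_spk, segs_lfp, bin_rate, tw=tw, k=k, kind="spike_field")


# ---------------------------------------------------------------------------
# Pairwise phase consistency

def ppc_from_phases(phases: np.ndarray) -> float:
    """PPC of a phase set via the incoherent-sum identity.

    Equals the O(N^2) mean of cos(theta_j - theta_k) over all pairs.
    """
    phases = np.asarray(phases, dtype=np.float64)
    n = phases.size
    if n < 2:
        return np.nan
    resultant = np.abs(np.exp(1j * phases).sum()) ** 2
    return float((resultant - n) / (n * (n - 1)))


def ppc(times: np.ndarray, lfp: np.ndarray, rate: float,
        freqs: np.ndarray | None = None, half_width: float = 0.5,
        epochs=None) -> PPCCurve:
    """PPC of a spike train against LFP phase on a low-frequency grid.

    For each grid frequency f the LFP is band-passed to
    [f - half_width, f + half_width], the Hilbert phase read out at spike
    times, and the PPC of those phases computed.  The default grid is
    0.25-10 Hz in 0.25 Hz steps (f = 0 is undefined and excluded).
    """
    times = np.asarray(times, dtype=np.float64)
    lfp = np.asarray(lfp, dtype=np.float64)
    if freqs is None:
        freqs = np.arange(0.25, 10.0 + 1e-9, 0.25)
    freqs = np.asarray(freqs, dtype=np.float64)
    if epochs is not None:
        mask = np.zeros(times.size, dtype=bool)
        for ep in epochs:
            mask |= (times >= ep.start) & (times < ep.end)
        times = times[mask]
    idx = np.clip(np.round(times * rate).astype(int), 0, lfp.size - 1)
    vals = np.full(freqs.size, np.nan)
    for i, f in enumerate(freqs):
        lo = max(f - half_width, 0.05)
        hi = f + half_width
        if times.size < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nb = dsp.fir_bandpass(lfp, rate, lo, hi)
        phase = dsp.hilbert_phase(nb)
        vals[i] = ppc_from_phases(phase[idx])
    return PPCCurve(freqs=freqs, ppc=vals, n_spikes=int(times.size))


# ---------------------------------------------------------------------------
# Shank-distance coherence and layer assignment

def coherence_by_distance(rec: Recording, pairs, band: dsp.BandDef | None = None,
                          tw: float = 3.0, k: int | None = None) -> list[dict]:
    """Theta-band coherence for every HP shank pair, on vs off epochs.

    ``pairs`` is the (off, on) epoch-pair list.  One representative channel
    per shank (the median depth_index) is used.  Returns one row per shank
    pair with the inter-shank index distance and band coherence per
    condition.
    """
    if band is None:
        band = dsp.BANDS["theta"]
    hp = rec.by_region("HP")
    shanks = sorted({c.shank for c in hp})
    if len(shanks) < 2:
        raise ValueError("need >= 2 shanks")
    rep = {}
    for s in shanks:
        chans = sorted((c for c in hp if c.shank == s), key=lambda c: c.depth_index)
        rep[s] = chans[len(chans) // 2].id
    rows = []
    for i, sa in enumerate(shanks):
        for sb in shanks[i + 1:]:
            xa = rec.channel_data(rep[sa])
            xb = rec.channel_data(rep[sb])
            row = {"shank_a": sa, "shank_b": sb, "distance": abs(sb - sa)}
            for label, idx in (("off", 0), ("on", 1)):
                segs_a = [xa[p[idx].slice(rec.rate)] for p in pairs]
                segs_b = [xb[p[idx].slice(rec.rate)] for p in pairs]
                c = coherence(segs_a, segs_b, rec.rate, tw=tw, k=k)
                row[f"coh_{label}"] = c.band_mean(band)
            rows.append(row)
    return rows


def assign_layers(profile: np.ndarray, lags: np.ndarray, rec: Recording,
                  band_rms: np.ndarray | None = None,
                  rms_ratio: float = 1.5, sw_window_s: float = 0.05) -> dict[int, str]:
    """Infer CA1 layer per HP channel from the ripple-triggered profile.

    The pyramidal layer is the channel with maximal ripple-band
    (100-250 Hz) RMS (preferably the *induced* per-event RMS from
    :func:`optotheta.ripples.ripple_triggered_profile`, since ripple cycles
    cancel in the evoked average; falls back to the profile's own band
    RMS).  Channels dorsal to it (smaller depth_index) whose sharp-wave
    deflection (mean over +/-sw_window_s) is positive are stratum oriens,
    ventral channels with negative deflection are stratum radiatum.  If no
    channel's ripple RMS exceeds ``rms_ratio`` times the median, the
    profile is ambiguous and every channel is labeled unknown.
    """
    rate = rec.rate
    hp_idx = [i for i, c in enumerate(rec.channels) if c.region == "HP"]
    labels: dict[int, str] = {rec.channels[i].id: "unknown" for i in hp_idx}
    if not hp_idx:
        return labels
    if band_rms is not None:
        rms = np.asarray(band_rms, dtype=np.float64)[hp_idx]
    else:
        nyq = rate / 2.0
        hi = min(dsp.RIPPLE_BAND.hi, 0.95 * nyq)
        rms = np.zeros(len(hp_idx))
        for j, i in enumerate(hp_idx):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rb = dsp.fir_bandpass(profile[i], rate, dsp.RIPPLE_BAND.lo, hi,
                                      transition=10.0)
            rms[j] = np.sqrt(np.mean(rb ** 2))
    med = np.median(rms)
    if med > 0 and rms.max() < rms_ratio * med and len(hp_idx) > 1:
        warnings.warn("ambiguous laminar profile: no ripple RMS peak",
                      stacklevel=2)
        return labels
    pyr_j = int(np.argmax(rms))
    pyr_i = hp_idx[pyr_j]
    pyr_depth = rec.channels[pyr_i].depth_index
    labels[rec.channels[pyr_i].id] = "pyramidale"
    core = np.abs(lags) <= sw_window_s
    defl = {i: float(profile[i, core].mean()) for i in hp_idx if i != pyr_i}
    # orientation from the sharp-wave polarity itself (the positive side of
    # the reversal is stratum oriens), so a flipped probe labels correctly
    lower = [defl[i] for i in defl
             if rec.channels[i].depth_index < pyr_depth]
    upper = [defl[i] for i in defl
             if rec.channels[i].depth_index > pyr_depth]
    if lower and upper:
        orient = 1.0 if np.mean(lower) > np.mean(upper) else -1.0
    elif lower:
        orient = 1.0 if np.mean(lower) > 0 else -1.0
    else:
        orient = -1.0 if (upper and np.mean(upper) > 0) else 1.0
    for i, d in defl.items():
        ch = rec.channels[i]
        side = orient * np.sign(ch.depth_index - pyr_depth)
        if side < 0 and d > 0:
            labels[ch.id] = "oriens"
        elif side > 0 and d < 0:
            labels[ch.id] = "radiatum"
    return labels


def pyramidale_channel(rec: Recording, events, profile=None, lags=None,
                       band_rms=None) -> int:
    """Channel id of the inferred stratum pyramidale contact."""
    from .ripples import ripple_triggered_profile

    if profile is None:
        profile, lags, band_rms = ripple_triggered_profile(
            events, rec, return_band_rms=True)
    labels = assign_layers(profile, lags, rec, band_rms=band_rms)
    for cid, lab in labels.items():
        if lab == "pyramidale":
            return cid
    # fall back: maximal ripple-band RMS even if ambiguous
    hp = rec.by_region("HP")
    if len(hp) == 1:
        return hp[0].id
    raise ValueError("could not identify the pyramidal-layer channel")
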
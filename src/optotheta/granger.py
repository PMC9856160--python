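"""Frequency-domain Wiener-Granger causality for channel pairs.

A two-channel VAR(p) is fitted by ordinary least squares; the Geweke
spectral measure for direction 2 -> 1 is

    f(w) = ln[ S11(w) / (S11(w) - (s22 - s12^2/s11) |H12(w)|^2) ]

where H(w) = (I - sum_k A_k e^{-i w k Dt})^{-1} is the transfer function,
S = H Sigma H* the spectral matrix and Sigma the residual covariance.
The measure is invariant to common rescaling of the channels and is
identically zero for a decoupled (block-diagonal) model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from . import dsp
from .io_model import SpikeTrainSet

__all__ = [
    "VARModel",
    "GCSpectrum",
    "fit_var_ols",
    "simulate_var",
    "gc_spectrum",
    "band_gc",
    "mua_rate_signal",
    "gc_delta_contrast",
]


@dataclass
class VARModel:
    A: np.ndarray  # (p, n_vars, n_vars) coefficient matrices
    sigma: np.ndarray  # residual covariance
    rate: float

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=np.float64)
        self.sigma = np.asarray(self.sigma, dtype=np.float64)
        if self.A.ndim != 3 or self.A.shape[1] != self.A.shape[2]:
            raise ValueError("A must be (p, n, n)")
        if not np.allclose(self.sigma, self.sigma.T):
            raise ValueError("sigma must be symmetric")

    @property
    def order(self) -> int:
        return self.A.shape[0]

    @property
    def n_vars(self) -> int:
        return self.A.shape[1]

    def spectral_radius(self) -> float:
        p, n = self.order, self.n_vars
        comp = np.zeros((n * p, n * p))
        comp[:n, :] = self.A.transpose(1, 0, 2).reshape(n, n * p)
        if p > 1:
            comp[n:, :-n] = np.eye(n * (p - 1))
        return float(np.max(np.abs(np.linalg.eigvals(comp))))

    def is_stable(self) -> bool:
        return self.spectral_radius() < 1.0


@dataclass
class GCSpectrum:
    freqs: np.ndarray
    gc: np.ndarray
    source: str = "x2"
    target: str = "x1"


def fit_var_ols(x: np.ndarray, order: int = 50) -> VARModel:
    """OLS fit of a VAR(order) to an (n_vars, n_samples) series.

    Channels are mean-subtracted internally; the residual covariance uses
    the degrees-of-freedom correction N - n_vars*order.
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    n_vars, n = x.shape
    if n <= 10 * order * n_vars:
        warnings.warn(
            f"{n} samples is short for order {order} with {n_vars} vars",
            stacklevel=2)
    x = x - x.mean(axis=1, keepdims=True)
    # stacked regression: y_t = sum_k A_k y_{t-k} + e_t
    Y = x[:, order:].T  # (N, n_vars)
    N = Y.shape[0]
    X = np.empty((N, n_vars * order))
    for k in range(1, order + 1):
        X[:, (k - 1) * n_vars:k * n_vars] = x[:, order - k:n - k].T
    B, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient VAR design matrix")
    A = B.reshape(order, n_vars, n_vars).transpose(0, 2, 1)
    resid = Y - X @ B
    dof = max(N - n_vars * order, 1)
    sigma = resid.T @ resid / dof
    model = VARModel(A=A, sigma=sigma, rate=np.nan)
    if not model.is_stable():
        warnings.warn("fitted VAR is unstable (spectral radius >= 1)",
                      stacklevel=2)
    return model


def simulate_var(model: VARModel, n_samples: int, rng: np.random.Generator,
                 burn_in: int = 500) -> np.ndarray:
    """Draw a realization from a VAR model (Gaussian innovations)."""
    p, nv = model.order, model.n_vars
    L = np.linalg.cholesky(model.sigma)
    total = n_samples + burn_in + p
    e = rng.standard_normal((total, nv)) @ L.T
    x = np.zeros((total, nv))
    for t in range(p, total):
        acc = e[t].copy()
        for k in range(p):
            acc += model.A[k] @ x[t - 1 - k]
        x[t] = acc
    return x[burn_in + p:].T


def _transfer(model: VARModel, freqs: np.ndarray, rate: float) -> np.ndarray:
    """H(w) on a frequency grid: (n_freq, n, n)."""
    p, nv = model.order, model.n_vars
    w = 2.0 * np.pi * freqs / rate
    ks = np.arange(1, p + 1)
    phase = np.exp(-1j * np.outer(w, ks))  # (n_freq, p)
    Af = np.tensordot(phase, model.A, axes=(1, 0))  # (n_freq, n, n)
    I = np.eye(nv)[None, :, :]
    return np.linalg.inv(I - Af)


def gc_spectrum(model: VARModel, direction: str = "2->1",
                rate: float | None = None, n_freq: int = 1000) -> GCSpectrum:
    """Geweke frequency-domain causality for a 2-variable VAR.

    ``direction`` is "2->1" or "1->2"; frequencies span [0, Nyquist) on an
    ``n_freq``-point grid.
    """
    if model.n_vars != 2:
        raise ValueError("gc_spectrum handles 2-variable models")
    if rate is None:
        rate = model.rate
    if not np.isfinite(rate):
        raise ValueError("sampling rate unknown; pass rate=")
    if direction == "2->1":
        src, tgt = 1, 0
    elif direction == "1->2":
        src, tgt = 0, 1
    else:
        raise ValueError("direction must be '2->1' or '1->2'")
    freqs = np.linspace(0, rate / 2.0, n_freq, endpoint=False)
    H = _transfer(model, freqs, rate)
    sig = model.sigma
    S = H @ sig[None, :, :] @ np.conj(H.transpose(0, 2, 1))
    s_tt = np.real(S[:, tgt, tgt])
    # partial innovation variance of the source given the target
    sigma_cond = sig[src, src] - sig[tgt, src] ** 2 / sig[tgt, tgt]
    h_ts = np.abs(H[:, tgt, src]) ** 2
    denom = s_tt - sigma_cond * h_ts
    bad = denom <= 0
    if np.any(bad):
        denom = np.where(bad, np.finfo(float).tiny, denom)
    gc = np.log(s_tt / denom)
    gc = np.maximum(gc, 0.0)
    if not np.all(np.isfinite(gc)):
        iw = int(np.flatnonzero(~np.isfinite(gc))[0])
        raise FloatingPointError(f"gc singular at {freqs[iw]:.3f} Hz")
    labels = {0: "x1", 1: "x2"}
    return GCSpectrum(freqs=freqs, gc=gc, source=labels[src], target=labels[tgt])


def band_gc(spec: GCSpectrum, band: dsp.BandDef | None = None) -> float:
    """Mean causality over a band (low theta, 3-6 Hz, by default)."""
    if band is None:
        band = dsp.GC_THETA
    mask = (spec.freqs >= band.lo) & (spec.freqs <= band.hi)
    if not np.any(mask):
        raise ValueError(f"band {band.name} empty on the gc frequency grid")
    return float(spec.gc[mask].mean())


def mua_rate_signal(spikes: SpikeTrainSet, session_length: float,
                    rate_out: float = 500.0, smooth_sigma_s: float = 0.010) -> np.ndarray:
    """Multiunit-activity rate signal: pooled 2 ms counts, Gaussian-smoothed
    (sigma 10 ms), mean-subtracted, at ``rate_out``."""
    if len(spikes) == 0:
        raise ValueError("empty spike set")
    bin_s = 0.002
    n_bins = int(round(session_length / bin_s))
    pooled = np.zeros(n_bins)
    for _, _, times in spikes:
        c, _ = np.histogram(times, bins=n_bins, range=(0, n_bins * bin_s))
        pooled += c
    sm = ndimage.gaussian_filter1d(pooled, sigma=smooth_sigma_s / bin_s)
    if rate_out != 1.0 / bin_s:
        sm = dsp.resample(sm, 1.0 / bin_s, rate_out)
    return sm - sm.mean()


def gc_delta_contrast(gc_values: np.ndarray, slow_power: np.ndarray,
                      trial_lfp_hp: list[np.ndarray] | None = None,
                      trial_lfp_ms: list[np.ndarray] | None = None,
                      rate: float | None = None,
                      percentile: float = 5.0) -> dict:
    """Trial-wise theta-causality vs slow-wave power contrast.

    Spearman rank correlation between per-trial theta-band causality and
    slow-band (0.5-3 Hz) power, plus the two 5th-percentile trial subsets
    (lowest causality / highest slow power).  When per-trial LFP segments
    are supplied, also returns their average normalized PSDs and the
    z-scored theta-filtered amplitudes aligned to the hippocampal theta
    peak (peak at t = 0; the MS average is read out at the HP peak times).
    """
    gc_values = np.asarray(gc_values, dtype=np.float64)
    slow_power = np.asarray(slow_power, dtype=np.float64)
    if gc_values.size != slow_power.size:
        raise ValueError("unpaired trial vectors")
    n = gc_values.size
    if n < 40:
        raise ValueError(f"need >= 40 trials for {percentile}% subsets; got {n}")
    n_ties = n - np.unique(gc_values).size
    if n_ties > n // 2:
        warnings.warn("more than half of the causality ranks are tied",
                      stacklevel=2)
    r, p = stats.spearmanr(gc_values, slow_power)
    k = max(int(np.ceil(n * percentile / 100.0)), 2)
    low_gc_idx = np.argsort(gc_values)[:k]
    high_delta_idx = np.argsort(slow_power)[-k:]
    out = {
        "spearman_r": float(r),
        "p": float(p),
        "n_trials": n,
        "low_gc_idx": low_gc_idx,
        "high_delta_idx": high_delta_idx,
    }
    if trial_lfp_hp is not None and rate is not None:
        from .spectral import multitaper_psd

        def _avg_psd(idx):
            acc = None
            for i in idx:
                sp = multitaper_psd(trial_lfp_hp[i], rate)
                acc = sp.psd if acc is None else acc + sp.psd
            return sp.freqs, acc / len(idx) / max((acc / len(idx)).max(), 1e-30)

        f, psd_low = _avg_psd(low_gc_idx)
        _, psd_high = _avg_psd(high_delta_idx)
        out["psd_freqs"] = f
        out["psd_low_gc"] = psd_low
        out["psd_high_delta"] = psd_high

        theta = dsp.BANDS["theta"]
        half = int(0.5 * rate)

        def _theta_triggered(idx):
            hp_acc, ms_acc, used = None, None, 0
            for i in idx:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    th = dsp.fir_bandpass(trial_lfp_hp[i], rate, theta.lo, theta.hi,
                                          transition=1.0)
                thz = (th - th.mean()) / (th.std() or 1.0)
                pk = int(np.argmax(thz))
                if pk - half < 0 or pk + half + 1 > thz.size:
                    continue
                w = thz[pk - half:pk + half + 1]
                hp_acc = w if hp_acc is None else hp_acc + w
                if trial_lfp_ms is not None:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        tm = dsp.fir_bandpass(trial_lfp_ms[i], rate, theta.lo,
                                              theta.hi, transition=1.0)
                    tmz = (tm - tm.mean()) / (tm.std() or 1.0)
                    wm = tmz[pk - half:pk + half + 1]
                    ms_acc = wm if ms_acc is None else ms_acc + wm
                used += 1
            hp = hp_acc / used if used else None
            ms = ms_acc / used if (used and ms_acc is not None) else None
            return hp, ms, used

        hp_lo, ms_lo, _ = _theta_triggered(low_gc_idx)
        hp_hi, ms_hi, _ = _theta_triggered(high_delta_idx)
        out["theta_lags_s"] = np.arange(-half, half + 1) / rate
        out["theta_hp_low_gc"] = hp_lo
        out["theta_ms_low_gc"] = ms_lo
        out["theta_hp_high_delta"] = hp_hi
        out["theta_ms_high_delta"] = ms_hi
    return out
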
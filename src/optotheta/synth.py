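"""Seeded generator of synthetic septo-hippocampal sessions.

The generator emulates the statistical structure the analyses assume for a
urethane-state optogenetic session: a 10-min recording with 5-s light
pulses every 20 s, hippocampal LFP with slow (0.5-3 Hz), theta (4-7 Hz,
slowly drifting) and gamma components over a 1/f background, sharp-wave
ripple events with laminar polarity, septal channels whose theta leads the
hippocampal theta (MS -> HP directionality), and septal/hippocampal units
with excited/inhibited subpopulations and von Mises theta phase locking.

Default effect sizes mirror the study conditions being emulated: +14.8%
theta power during light, -17.3% ripple density, 21.5%/7.3% of septal
units excited (+53.2%) / inhibited (-45.5%), 20.2%/4.7% of hippocampal
units excited (+34.1%) / inhibited (-19.4%), and a negative coupling
between slow-wave amplitude and the MS -> HP theta transfer.

All randomness flows from ``SynthConfig.seed`` through a single
``numpy.random.Generator``; the same seed reproduces the session exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy import signal

from . import dsp
from .io_model import (ChannelMeta, Recording, SpikeTrainSet, StimProtocol,
                       write_protocol, write_recording, write_spikes)

__all__ = [
    "SynthConfig",
    "SessionGroundTruth",
    "generate_lfp",
    "generate_spikes",
    "generate_session",
    "inject_ripple_bursts",
]


@dataclass
class SynthConfig:
    """Knobs of the synthetic session; defaults are the emulated study
    conditions, not free tuning parameters."""

    seed: int = 0
    session_length: float = 600.0  # s
    rate: float = 1000.0  # Hz
    n_hp_channels: int = 8  # per shank, spanning oriens -> radiatum
    n_hp_shanks: int = 1
    n_ms_channels: int = 2
    theta_freq: float = 5.5  # Hz, drift center
    theta_power_gain_on: float = 1.148  # theta band power ratio on/off
    ripple_rate_off: float = 0.3  # events/s
    ripple_rate_gain_on: float = 0.827
    frac_hp_excited: float = 0.202
    hp_excited_gain: float = 1.341
    frac_hp_inhibited: float = 0.047
    hp_inhibited_gain: float = 0.806
    frac_ms_excited: float = 0.215
    ms_excited_gain: float = 1.532
    frac_ms_inhibited: float = 0.073
    ms_inhibited_gain: float = 0.545
    theta_stochastic_share: float = 0.10  # power share of the AR(2) component
    theta_ar_bandwidth: float = 3.0  # Hz, full width of the AR(2) resonance
    theta_coupling_cv: float = 0.5  # block-to-block CV of the MS->HP transfer
    kappa_theta_locking: float = 1.0
    kappa_gain_on: float = 1.5  # locking concentration multiplier during light
    ms_to_hp_lag: float = 0.02  # s, septal theta lead
    delta_gc_coupling: float = -0.3  # in [-1, 0]
    n_units_per_region: int = 40
    gain_cv: float = 0.10  # within-class log-normal CV of unit gains
    # amplitudes (uV)
    theta_amp_hp: float = 50.0
    theta_amp_ms: float = 60.0
    slow_amp_hp: float = 80.0
    slow_amp_ms: float = 60.0
    gamma_slow_amp: float = 10.0
    gamma_fast_amp: float = 5.0
    pink_density_at_1hz: float = 66.0  # uV^2/Hz of the 1/f background
    ripple_burst_z: float = 6.0  # calibrated against the detection envelope
    ripple_freq_hz: tuple = (140.0, 160.0)
    ripple_duration_s: tuple = (0.050, 0.080)
    sharp_wave_amp: float = 60.0
    blockade_time_s: float | None = None  # cholinergic blockade: theta gain -> 1 after this time

    def __post_init__(self) -> None:
        if self.rate < 500:
            raise ValueError("rate must be >= 500 Hz (ripple band Nyquist)")
        if self.frac_hp_excited + self.frac_hp_inhibited > 1:
            raise ValueError("HP class fractions exceed 1")
        if self.frac_ms_excited + self.frac_ms_inhibited > 1:
            raise ValueError("MS class fractions exceed 1")
        for g in (self.hp_excited_gain, self.hp_inhibited_gain,
                  self.ms_excited_gain, self.ms_inhibited_gain):
            if g <= 0:
                raise ValueError("gains must be > 0")
        if not -1.0 <= self.delta_gc_coupling <= 0.0:
            raise ValueError("delta_gc_coupling must lie in [-1, 0]")

    @property
    def pyr_depth_index(self) -> int:
        return self.n_hp_channels // 2


@dataclass
class SessionGroundTruth:
    """What the generator injected; used to score the analyses."""

    theta_phase_hp: np.ndarray  # radians at LFP rate
    theta_phase_ms: np.ndarray
    on_mask: np.ndarray  # bool at LFP rate
    theta_gain_trace: np.ndarray  # amplitude gain applied to HP theta
    ripple_times: np.ndarray  # burst centers, s
    ripple_onsets: np.ndarray  # burst support starts, s
    ripple_durations: np.ndarray  # s
    block_coupling: np.ndarray  # per-20-s-block MS->HP theta transfer factor
    unit_info: list = field(default_factory=list)


def _default_protocol(cfg: SynthConfig) -> StimProtocol:
    return StimProtocol.default(session_length=cfg.session_length)


def _on_mask(cfg: SynthConfig, protocol: StimProtocol, n: int) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for t in protocol.onsets:
        mask[int(t * cfg.rate):int((t + protocol.pulse_duration) * cfg.rate)] = True
    return mask


def _pink_noise(n: int, rate: float, density_1hz: float,
                rng: np.random.Generator, f_floor: float = 0.5) -> np.ndarray:
    """Background with one-sided PSD ~ density_1hz / f (flat below f_floor)."""
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    shape = np.zeros(freqs.size)
    nz = freqs > 0
    shape[nz] = np.sqrt(density_1hz / np.maximum(freqs[nz], f_floor))
    spec = shape * (rng.standard_normal(freqs.size) +
                    1j * rng.standard_normal(freqs.size)) / np.sqrt(2)
    spec[0] = 0.0
    # scale so the one-sided density integrates to the variance
    x = np.fft.irfft(spec, n=n)
    return x * np.sqrt(n * rate) / np.sqrt(2)


def _narrowband_noise(n: int, rate: float, lo: float, hi: float, amp: float,
                      rng: np.random.Generator, order: int = 2) -> np.ndarray:
    """Band-limited Gaussian noise with RMS ``amp / sqrt(2)`` (sinusoid-
    equivalent amplitude ``amp``)."""
    w = rng.standard_normal(n)
    sos = signal.butter(order, [lo, hi], btype="band", fs=rate, output="sos")
    x = signal.sosfiltfilt(sos, w)
    sd = x.std()
    if sd == 0:
        return x
    return x * (amp / np.sqrt(2)) / sd

def _theta_drive(cfg: SynthConfig, n: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Common theta drive: drifting sinusoid plus a causal AR(2) resonance.

    The deterministic part is a sinusoid whose frequency wanders slowly
    within 4-7 Hz; it keeps the theta power of a 5-s epoch stable, which is
    what makes the paired on/off power contrast detectable at 30 trials.
    The stochastic part (power share ``theta_stochastic_share``) is a
    *causally* driven AR(2) resonance centred on ``theta_freq``: the
    hippocampal copy must inherit the septal drive's innovations for the
    MS -> HP direction to carry Wiener-Granger-detectable information, and
    an anticausally smoothed process would let the target anticipate them.
    Total RMS is 1/sqrt(2) (unit sinusoid-equivalent amplitude).
    """
    # deterministic drifting sinusoid; the drift is slow (~1 min coherence)
    # so the frequency is stable across an off/on epoch pair, and its range
    # keeps the spectral peak (+/- the 0.6 Hz multitaper half-bandwidth)
    # inside the 4-7 Hz measurement band
    drift = signal.sosfiltfilt(
        signal.butter(2, 0.02, btype="low", fs=cfg.rate, output="sos"),
        rng.standard_normal(n))
    drift *= 0.4 / max(drift.std(), 1e-12)
    freq = np.clip(cfg.theta_freq + drift, 4.7, 6.3)
    det = np.cos(2 * np.pi * np.cumsum(freq) / cfg.rate
                 + rng.uniform(0, 2 * np.pi))
    # causal stochastic resonance
    w = rng.standard_normal(n)
    r = np.exp(-np.pi * (cfg.theta_ar_bandwidth / 2.0) / cfg.rate)
    a = [1.0, -2 * r * np.cos(2 * np.pi * cfg.theta_freq / cfg.rate), r ** 2]
    ar = signal.lfilter([1.0], a, w)
    ar /= ar.std() * np.sqrt(2)
    s = cfg.theta_stochastic_share
    return np.sqrt(1 - s) * det / np.sqrt(2) + np.sqrt(s) * ar


def _block_factors(cfg: SynthConfig, protocol: StimProtocol,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-20-s-block theta-transfer and slow-amplitude factors.

    The slow-wave amplitude co-varies inversely with the MS -> HP theta
    transfer with strength ``|delta_gc_coupling|``, so trials of high
    slow-wave power have weak theta causality.
    """
    n_blocks = int(np.ceil(cfg.session_length / protocol.period))
    z = rng.standard_normal(n_blocks)
    coupling = np.exp(cfg.theta_coupling_cv * z)  # theta transfer, log-normal
    slow = np.exp(-abs(cfg.delta_gc_coupling) * z)
    return coupling, slow


def _expand_blocks(factors: np.ndarray, period: float, rate: float,
                   n: int) -> np.ndarray:
    block_len = int(round(period * rate))
    out = np.repeat(factors, block_len)[:n]
    if out.size < n:
        out = np.pad(out, (0, n - out.size), mode="edge")
    return out


def _ripple_waveform(dur: float, freq: float, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-windowed ripple burst of unit peak amplitude and its
    sharp-wave window (unit amplitude)."""
    half = dur / 2.0
    t = np.arange(-half, half + 1.0 / rate / 2, 1.0 / rate)
    sd = dur / 4.0
    env = np.exp(-(t ** 2) / (2 * sd ** 2))
    burst = env * np.sin(2 * np.pi * freq * t)
    sw = np.exp(-(t ** 2) / (2 * (dur / 3.0) ** 2))
    return burst, sw


def _bg_envelope_stats(bg: np.ndarray, rate: float) -> tuple[float, float]:
    """(mean, SD) of the detection envelope of a background-only trace.

    Mirrors the detection pipeline (500 Hz, 100-250 Hz FIR, rectify,
    20 Hz Butterworth) so injected burst amplitudes can be expressed in
    background-envelope SD units.
    """
    import warnings as _w

    x = dsp.resample(bg, rate, 500.0)
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        band = dsp.fir_bandpass(x, 500.0, 100.0, 250.0)
    env = dsp.butter_lowpass(np.abs(band), 500.0, 20.0)
    return float(env.mean()), float(env.std())


@lru_cache(maxsize=64)
def _probe_peak(dur_ms: int, freq: float = 150.0) -> float:
    """Detection-envelope peak response to a unit-amplitude burst.

    The 20 Hz envelope smoothing attenuates short bursts more, so the
    response is duration-dependent and cached per ms of duration.
    """
    import warnings as _w

    probe = np.zeros(int(4 * 500))
    b, _ = _ripple_waveform(dur_ms / 1000.0, freq, 500.0)
    i0 = len(probe) // 2 - b.size // 2
    probe[i0:i0 + b.size] = b
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        pb = dsp.fir_bandpass(probe, 500.0, 100.0, 250.0)
    penv = dsp.butter_lowpass(np.abs(pb), 500.0, 20.0)
    return float(penv.max())


def calibrate_burst_amplitudes(bg: np.ndarray, rate: float, z: float,
                               centers, durations, freqs,
                               n_iter: int = 2) -> np.ndarray:
    """Per-burst peak amplitudes (uV) whose detection-envelope peaks sit at
    ``z`` in the detector's own z units.

    The detector z-scores the envelope of the *whole* trace, so the events
    themselves inflate the normalizing SD; the calibration therefore
    iterates: amplitudes are first set against the background-only envelope
    statistics, the bursts are provisionally injected, and the amplitudes
    rescaled against the envelope statistics of the composed trace.
    """
    durations = np.atleast_1d(durations)
    freqs = np.atleast_1d(freqs)
    peaks = np.array([_probe_peak(int(round(d * 1000)), float(np.round(f, -1)))
                      for d, f in zip(durations, freqs)])
    mu, sd = _bg_envelope_stats(bg, rate)
    amps = (mu + z * sd) / peaks
    for _ in range(n_iter - 1):
        probe = inject_ripple_bursts(bg, rate, centers, durations, freqs, amps)
        mu, sd = _bg_envelope_stats(probe, rate)
        amps = (mu + z * sd) / peaks
    return amps


def _draw_ripples(cfg: SynthConfig, protocol: StimProtocol,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Poisson ripple times: base rate off, thinned by the on-epoch gain."""
    t = 0.0
    centers = []
    margin = max(cfg.ripple_duration_s) / 2 + 0.05
    if cfg.ripple_rate_off <= 0:
        return np.empty(0), np.empty(0), np.empty(0)
    while True:
        t += rng.exponential(1.0 / cfg.ripple_rate_off)
        if t >= cfg.session_length - margin:
            break
        if t < margin:
            continue
        in_on = np.any((protocol.onsets <= t) &
                       (t < protocol.onsets + protocol.pulse_duration))
        if in_on and rng.uniform() > cfg.ripple_rate_gain_on:
            continue
        centers.append(t)
    centers = np.asarray(centers)
    durs = rng.uniform(*cfg.ripple_duration_s, size=centers.size)
    freqs = rng.uniform(*cfg.ripple_freq_hz, size=centers.size)
    return centers, durs, freqs


def inject_ripple_bursts(trace: np.ndarray, rate: float, centers, durations,
                         freqs, amplitude_uv) -> np.ndarray:
    """Add Gaussian-windowed ripple bursts (peak ``amplitude_uv``, scalar or
    per-burst array) to a trace."""
    out = np.asarray(trace, dtype=np.float64).copy()
    amps = np.broadcast_to(np.asarray(amplitude_uv, dtype=np.float64),
                           np.atleast_1d(centers).shape)
    for tc, dur, f, amplitude_uv in zip(np.atleast_1d(centers),
                                        np.atleast_1d(durations),
                                        np.atleast_1d(freqs), amps):
        burst, _ = _ripple_waveform(dur, f, rate)
        i0 = int(round((tc - dur / 2.0) * rate))
        if i0 < 0 or i0 + burst.size > out.size:
            continue
        out[i0:i0 + burst.size] += amplitude_uv * burst
    return out


def generate_lfp(cfg: SynthConfig,
                 protocol: StimProtocol | None = None) -> Recording:
    """Generate the multichannel LFP of one synthetic session.

    The returned Recording carries the injected ground truth in its
    ``ground_truth`` attribute (a :class:`SessionGroundTruth`).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    if protocol is None:
        protocol = _default_protocol(cfg)
    n = int(round(cfg.session_length * cfg.rate))
    on = _on_mask(cfg, protocol, n)

    # common drives
    drive_ms = _theta_drive(cfg, n, rng)
    lag = int(round(cfg.ms_to_hp_lag * cfg.rate))
    drive_hp = np.roll(drive_ms, lag)  # HP theta lags the septal drive
    phase_ms = np.angle(signal.hilbert(drive_ms))
    phase_hp = np.angle(signal.hilbert(drive_hp))
    coupling_blk, slow_blk = _block_factors(cfg, protocol, rng)
    coupling = _expand_blocks(coupling_blk, protocol.period, cfg.rate, n)
    slow_gain = _expand_blocks(slow_blk, protocol.period, cfg.rate, n)
    amp_gain = np.where(on, np.sqrt(cfg.theta_power_gain_on), 1.0)
    if cfg.blockade_time_s is not None:
        amp_gain[int(cfg.blockade_time_s * cfg.rate):] = 1.0
    # order-4 skirts keep the slow band out of the theta measurement band
    slow_common = _narrowband_noise(n, cfg.rate, 0.5, 3.0, 1.0, rng, order=4)

    theta_hp = cfg.theta_amp_hp * coupling * amp_gain * drive_hp
    slow_hp = cfg.slow_amp_hp * slow_gain * slow_common

    centers, durs, rip_freqs = _draw_ripples(cfg, protocol, rng)

    channels: list[ChannelMeta] = []
    data_rows: list[np.ndarray] = []
    pyr = cfg.pyr_depth_index
    ripple_amp_uv = None
    cid = 0
    for shank in range(cfg.n_hp_shanks):
        for depth in range(cfg.n_hp_channels):
            bg = (_pink_noise(n, cfg.rate, cfg.pink_density_at_1hz, rng)
                  + _narrowband_noise(n, cfg.rate, 20.0, 40.0,
                                      cfg.gamma_slow_amp, rng)
                  + _narrowband_noise(n, cfg.rate, 60.0, 140.0,
                                      cfg.gamma_fast_amp, rng))
            x = theta_hp + slow_hp + bg
            if ripple_amp_uv is None:
                # calibrate burst amplitudes on the first (reference)
                # channel so envelope peaks land at ripple_burst_z in the
                # detector's whole-trace z units
                if centers.size:
                    ripple_amp_uv = calibrate_burst_amplitudes(
                        bg, cfg.rate, cfg.ripple_burst_z, centers, durs,
                        rip_freqs)
                else:
                    ripple_amp_uv = np.empty(0)
            depth_fall = np.exp(-abs(depth - pyr) / 1.5)
            if depth < pyr:
                sw_pol = 1.0
            elif depth > pyr:
                sw_pol = -1.0
            else:
                sw_pol = 0.2
            for tc, dur, f, amp in zip(centers, durs, rip_freqs, ripple_amp_uv):
                burst, sw = _ripple_waveform(dur, f, cfg.rate)
                i0 = int(round((tc - dur / 2.0) * cfg.rate))
                if i0 < 0 or i0 + burst.size > n:
                    continue
                x[i0:i0 + burst.size] += (amp * depth_fall * burst
                                          + cfg.sharp_wave_amp * sw_pol * sw)
            layer = ("pyramidale" if depth == pyr
                     else "oriens" if depth < pyr else "radiatum")
            channels.append(ChannelMeta(id=cid, region="HP", shank=shank,
                                        depth_index=depth, layer=layer))
            data_rows.append(x)
            cid += 1

    theta_ms = cfg.theta_amp_ms * drive_ms
    for i in range(cfg.n_ms_channels):
        bg = _pink_noise(n, cfg.rate, cfg.pink_density_at_1hz, rng)
        slow_ms = cfg.slow_amp_ms * _narrowband_noise(n, cfg.rate, 0.5, 3.0,
                                                      1.0, rng, order=4)
        channels.append(ChannelMeta(id=cid, region="MS", shank=0,
                                    depth_index=i, layer="unknown"))
        data_rows.append(theta_ms + slow_ms + bg)
        cid += 1

    rec = Recording(data=np.asarray(data_rows), rate=cfg.rate,
                    channels=channels, session_id=f"synth-{cfg.seed}")
    rec.ground_truth = SessionGroundTruth(
        theta_phase_hp=phase_hp,
        theta_phase_ms=phase_ms,
        on_mask=on,
        theta_gain_trace=amp_gain,
        ripple_times=centers,
        ripple_onsets=centers - durs / 2.0,
        ripple_durations=durs,
        block_coupling=coupling_blk,
    )
    return rec


_CLASS_RATE_LOGMEAN = {  # baseline rate draws (Hz), log-normal
    ("HP", "excited"): (1.5, 0.4),   # putative pyramidal: low rate
    ("HP", "inhibited"): (8.0, 0.3),  # putative interneuron: high rate
    ("HP", "none"): (3.0, 0.5),
    ("MS", "excited"): (4.0, 0.4),
    ("MS", "inhibited"): (4.0, 0.4),
    ("MS", "none"): (4.0, 0.5),
}


def _unit_classes(cfg: SynthConfig, region: str) -> list[str]:
    n = cfg.n_units_per_region
    if region == "HP":
        n_exc = int(round(cfg.frac_hp_excited * n))
        n_inh = int(round(cfg.frac_hp_inhibited * n))
    else:
        n_exc = int(round(cfg.frac_ms_excited * n))
        n_inh = int(round(cfg.frac_ms_inhibited * n))
    return (["excited"] * n_exc + ["inhibited"] * n_inh
            + ["none"] * (n - n_exc - n_inh))


def generate_spikes(cfg: SynthConfig, rec: Recording) -> SpikeTrainSet:
    """Inhomogeneous point-process units sharing the recording's theta phase.

    Each unit has a log-normal baseline rate, von Mises theta phase
    modulation (normalized so the mean rate is phase-independent), its
    class gain during light-on epochs, and -- for hippocampal putative
    pyramidal (excited-class) units -- a modest rate boost during ripple
    events.
    """
    gt: SessionGroundTruth = rec.ground_truth
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))
    n = gt.on_mask.size
    kappa_on = cfg.kappa_theta_locking * cfg.kappa_gain_on

    ripple_mask = np.zeros(n, dtype=bool)
    for tc, dur in zip(gt.ripple_times, gt.ripple_durations):
        ripple_mask[int((tc - dur / 2) * cfg.rate):
                    int((tc + dur / 2) * cfg.rate)] = True

    gains = {
        ("HP", "excited"): cfg.hp_excited_gain,
        ("HP", "inhibited"): cfg.hp_inhibited_gain,
        ("MS", "excited"): cfg.ms_excited_gain,
        ("MS", "inhibited"): cfg.ms_inhibited_gain,
    }
    units = []
    info = []
    from scipy.special import i0

    for region, phase in (("MS", gt.theta_phase_ms), ("HP", gt.theta_phase_hp)):
        classes = _unit_classes(cfg, region)
        for j, cls in enumerate(classes):
            mean_rate, log_sd = _CLASS_RATE_LOGMEAN[(region, cls)]
            r0 = mean_rate * rng.lognormal(-log_sd ** 2 / 2, log_sd)
            base_gain = gains.get((region, cls), 1.0)
            gain = (base_gain * rng.lognormal(-cfg.gain_cv ** 2 / 2, cfg.gain_cv)
                    if cls != "none" else 1.0)
            phi = rng.uniform(-np.pi, np.pi)
            kappa = cfg.kappa_theta_locking
            boost = 2.0 if (region == "HP" and cls == "excited") else 1.0
            lam_max = (r0 * max(gain, 1.0) * np.exp(max(kappa, kappa_on))
                       / i0(max(kappa, kappa_on)) * boost * 1.05)
            n_cand = rng.poisson(lam_max * cfg.session_length)
            cand = np.sort(rng.uniform(0, cfg.session_length, n_cand))
            idx = np.minimum((cand * cfg.rate).astype(int), n - 1)
            k_t = np.where(gt.on_mask[idx], kappa_on, kappa)
            lam = (r0
                   * np.where(gt.on_mask[idx], gain, 1.0)
                   * np.exp(k_t * np.cos(phase[idx] - phi)) / i0(k_t))
            if boost != 1.0:
                lam = lam * np.where(ripple_mask[idx], boost, 1.0)
            keep = rng.uniform(size=n_cand) < lam / lam_max
            times = cand[keep]
            uid = f"{region.lower()}{j:03d}"
            units.append((uid, region, times))
            info.append({"unit_id": uid, "region": region, "cls": cls,
                         "gain": gain if cls != "none" else 1.0,
                         "base_rate": r0, "kappa": kappa, "phase_pref": phi})
    gt.unit_info = info
    return SpikeTrainSet(units=units)


def generate_session(cfg: SynthConfig, out_dir: str | Path | None = None
                     ) -> tuple[Recording, SpikeTrainSet, StimProtocol]:
    """Full synthetic session: LFP + spikes + 15 s off / 5 s on protocol.

    If ``out_dir`` is given, writes ``lfp.dat``/``lfp.json``,
    ``spikes.csv`` and ``protocol.csv`` there.
    """
    protocol = _default_protocol(cfg)
    rec = generate_lfp(cfg, protocol)
    spikes = generate_spikes(cfg, rec)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        amax = np.abs(rec.data).max()
        scale = max(amax / 32000.0, 0.195)
        write_recording(rec, out_dir / "lfp.dat", scale_uv_per_bit=scale)
        write_spikes(spikes, out_dir / "spikes.csv")
        write_protocol(protocol, out_dir / "protocol.csv")
    return rec, spikes, protocol
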
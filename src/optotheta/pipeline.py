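"""Config-driven end-to-end orchestration of the session analyses.

``run_pipeline`` sequences, on one conforming session: epoching ->
ripple detection and laminar assignment -> per-band power contrasts ->
unit-response classification -> coherence / PPC -> directed causality ->
the slow-wave/causality contrast, writing every result as CSV/JSON plus a
run log (version, seed, parameters).  ``make_report`` renders a markdown
summary with tables and figures from a result bundle.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, dsp, granger, ripples, spectral, synchrony, unit_response
from .io_model import (SpikeTrainSet, paired_epochs, read_protocol,
                       read_recording, read_spikes)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "make_report"]

_STAGES = ("ripples", "bands", "units", "synchrony", "granger")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    lfp_path: str | None = None
    spikes_path: str | None = None
    protocol_path: str | None = None
    out_dir: str = "results"
    seed: int = 0
    n_shuffles: int = 1000
    tw: float = 3.0
    analysis_rate: float = 500.0
    var_order: int = 20
    gc_n_freq: int = 1000
    ppc_step_hz: float = 0.25
    ppc_max_hz: float = 10.0
    session_length: float = 600.0
    stages: dict = field(default_factory=lambda: {s: True for s in _STAGES})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.stages = {s: cfg.stages.get(s, True) for s in _STAGES}
        return cfg


def _load_session(cfg: PipelineConfig):
    rec = read_recording(cfg.lfp_path)
    spikes = read_spikes(cfg.spikes_path) if cfg.spikes_path else SpikeTrainSet([])
    protocol = read_protocol(cfg.protocol_path,
                             session_length=rec.duration)
    return rec, spikes, protocol


def _fmt_float(df: pd.DataFrame) -> str:
    return df.to_csv(index=False, float_format="%.6g")


def run_pipeline(cfg: PipelineConfig, session=None) -> dict:
    """Execute the analysis stages; returns the result bundle.

    ``session`` may be a pre-built (Recording, SpikeTrainSet, StimProtocol)
    tuple (e.g. from :func:`optotheta.synth.generate_session`); otherwise
    the files referenced by the config are read.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if session is None:
        session = _load_session(cfg)
    rec, spikes, protocol = session
    pairs = paired_epochs(protocol)
    bundle: dict = {"config": dataclasses.asdict(cfg), "n_trials": len(pairs)}
    fs = cfg.analysis_rate

    hp_chans = rec.by_region("HP")
    ms_chans = rec.by_region("MS")
    hp500 = {c.id: dsp.resample(rec.channel_data(c.id), rec.rate, fs)
             for c in hp_chans}

    stage = "ripples"
    try:
        if cfg.stages.get("ripples", True) and hp_chans:
            # detection channel: maximal ripple-band RMS (stratum pyramidale)
            rms = {}
            for cid, x in hp500.items():
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rb = dsp.fir_bandpass(x, fs, dsp.RIPPLE_BAND.lo,
                                          min(dsp.RIPPLE_BAND.hi, 0.95 * fs / 2))
                rms[cid] = float(np.sqrt(np.mean(rb ** 2)))
            det_chan = max(rms, key=rms.get)
            events = ripples.detect_ripples(rec.channel_data(det_chan), rec.rate,
                                            channel_id=det_chan)
            events = ripples.ripple_metrics(events, rec.channel_data(det_chan),
                                            rec.rate)
            density = ripples.ripple_density(events, protocol)
            profile = lags = band_rms = None
            if len(events) >= 10:
                profile, lags, band_rms = ripples.ripple_triggered_profile(
                    events, rec, return_band_rms=True)
            layers = (synchrony.assign_layers(profile, lags, rec,
                                              band_rms=band_rms)
                      if profile is not None else {})
            pd.DataFrame([{
                "onset_s": e.onset, "end_s": e.end, "peak_time_s": e.peak_time,
                "duration_ms": e.duration, "peak_freq_hz": e.peak_freq,
                "amplitude_z": e.amplitude, "channel_id": e.channel_id,
            } for e in events]).to_csv(out / "events.csv", index=False,
                                       float_format="%.6f")
            bundle["ripples"] = {
                "detect_channel": det_chan, "n_events": len(events),
                "density": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                            for k, v in density.items()},
                "layers": layers, "events": events,
                "profile": profile, "profile_lags": lags,
            }

        stage = "bands"
        if cfg.stages.get("bands", True) and hp_chans:
            chan = bundle.get("ripples", {}).get("detect_channel",
                                                 hp_chans[0].id)
            off_p, on_p = spectral.per_trial_band_powers(
                hp500[chan], fs, pairs, tw=cfg.tw)
            table = spectral.compare_bands(off_p, on_p)
            df = table.to_frame()
            (out / "band_table.csv").write_text(_fmt_float(df))
            # paired geometric-mean ratio (band powers are ~log-normal
            # across trials, so the log scale is the natural pairing)
            bundle["bands"] = {"table": table, "channel": chan,
                               "theta_ratio": float(np.exp(np.mean(
                                   np.log(on_p["theta"] / off_p["theta"]))))}

        stage = "units"
        if cfg.stages.get("units", True) and len(spikes):
            cls = unit_response.classify_all(
                spikes, protocol, n_shuffles=cfg.n_shuffles, seed=cfg.seed)
            region_of = {uid: reg for uid, reg, _ in spikes}
            rows = [{
                "unit_id": c.unit_id, "region": region_of.get(c.unit_id, "?"),
                "label": c.label, "effect_pct": c.effect_pct,
                "p_like": c.p_like, "off_rate_hz": c.off_rate,
                "on_rate_hz": c.on_rate,
            } for c in cls]
            (out / "units_summary.csv").write_text(
                _fmt_float(pd.DataFrame(rows)))
            summaries = {}
            for reg in ("MS", "HP"):
                sub = [c for c in cls if region_of.get(c.unit_id) == reg]
                if len(sub) >= 10:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        summaries[reg] = unit_response.population_summary(sub)
            (out / "population_summary.json").write_text(
                json.dumps(summaries, indent=1, default=float))
            bundle["units"] = {"classifications": cls, "summary": summaries,
                               "region_of": region_of}

        stage = "synchrony"
        if cfg.stages.get("synchrony", True) and hp_chans and len(spikes):
            chan = bundle.get("ripples", {}).get("detect_channel",
                                                 hp_chans[0].id)
            lfp = hp500[chan]
            theta = dsp.BANDS["theta"]
            off_eps = [p[0] for p in pairs]
            on_eps = [p[1] for p in pairs]
            ppc_freqs = np.arange(cfg.ppc_step_hz, cfg.ppc_max_hz + 1e-9,
                                  cfg.ppc_step_hz)
            phases = _phase_bank(lfp, fs, ppc_freqs)
            coh_rows, ppc_rows = [], []
            for uid, reg, times in spikes.by_region("HP"):
                for cond, eps in (("off", off_eps), ("on", on_eps)):
                    try:
                        c = synchrony.spike_field_coherence(
                            times, lfp, fs, eps, tw=cfg.tw)
                        for f, v in zip(c.freqs, c.coh):
                            if f <= 20:
                                coh_rows.append({"unit_id": uid, "freq_hz": f,
                                                 "condition": cond, "coherence": v})
                    except ValueError:
                        continue
                    pv = _ppc_from_bank(times, phases, fs, eps)
                    for f, v in zip(ppc_freqs, pv):
                        ppc_rows.append({"unit_id": uid, "freq_hz": f,
                                         "condition": cond, "ppc": v})
            (out / "coherence.csv").write_text(
                _fmt_float(pd.DataFrame(coh_rows)))
            (out / "ppc.csv").write_text(_fmt_float(pd.DataFrame(ppc_rows)))
            # LFP-LFP coherence between extreme depths of the pyramidale shank
            lfp_coh = {}
            if len(hp_chans) >= 2:
                by_depth = sorted(hp_chans, key=lambda c: c.depth_index)
                xa = hp500[by_depth[0].id]
                xb = hp500[by_depth[-1].id]
                for cond, eps in (("off", off_eps), ("on", on_eps)):
                    c = synchrony.coherence([xa[e.slice(fs)] for e in eps],
                                            [xb[e.slice(fs)] for e in eps],
                                            fs, tw=cfg.tw)
                    lfp_coh[cond] = c.band_mean(theta)
            shank_rows = []
            if len({c.shank for c in hp_chans}) >= 2:
                shank_rows = synchrony.coherence_by_distance(rec, pairs)
            bundle["synchrony"] = {"coh_rows": coh_rows, "ppc_rows": ppc_rows,
                                   "lfp_lfp_theta": lfp_coh,
                                   "by_distance": shank_rows}

        stage = "granger"
        if cfg.stages.get("granger", True) and hp_chans and ms_chans:
            chan = bundle.get("ripples", {}).get("detect_channel",
                                                 hp_chans[0].id)
            hp = hp500[chan]
            ms = dsp.resample(rec.channel_data(ms_chans[0].id), rec.rate, fs)
            ms_mua = None
            if len(spikes.by_region("MS")):
                ms_mua = granger.mua_rate_signal(spikes.by_region("MS"),
                                                 protocol.session_length,
                                                 rate_out=fs)
            gc_rows, spectra, trial_gc, trial_slow = _gc_stage(
                cfg, hp, ms, ms_mua, fs, pairs)
            (out / "gc.csv").write_text(_fmt_float(pd.DataFrame(gc_rows)))
            contrast = None
            if len(trial_gc) >= 40:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    contrast = granger.gc_delta_contrast(
                        np.asarray(trial_gc), np.asarray(trial_slow))
                (out / "gc_contrast.json").write_text(json.dumps(
                    {k: v for k, v in contrast.items()
                     if np.isscalar(v)}, indent=1, default=float))
            bundle["granger"] = {"rows": gc_rows, "spectra": spectra,
                                 "contrast": contrast}
    except Exception as exc:  # partial outputs stay on disk
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc

    log = {
        "optotheta_version": __version__,
        "seed": cfg.seed,
        "n_trials": len(pairs),
        "parameters": dataclasses.asdict(cfg),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1, default=str))
    bundle["out_dir"] = str(out)
    return bundle


def _phase_bank(lfp: np.ndarray, rate: float, freqs: np.ndarray) -> dict:
    """Hilbert phase of the LFP band-passed around each grid frequency."""
    bank = {}
    for f in freqs:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nb = dsp.fir_bandpass(lfp, rate, max(f - 0.5, 0.05), f + 0.5)
        bank[float(f)] = dsp.hilbert_phase(nb)
    return bank


def _ppc_from_bank(times: np.ndarray, phase_bank: dict, rate: float,
                   epochs) -> np.ndarray:
    mask = np.zeros(times.size, dtype=bool)
    for ep in epochs:
        mask |= (times >= ep.start) & (times < ep.end)
    t = times[mask]
    vals = np.full(len(phase_bank), np.nan)
    if t.size < 2:
        return vals
    for i, (f, phase) in enumerate(phase_bank.items()):
        idx = np.clip(np.round(t * rate).astype(int), 0, phase.size - 1)
        vals[i] = synchrony.ppc_from_phases(phase[idx])
    return vals


def _gc_stage(cfg: PipelineConfig, hp, ms, ms_mua, fs, pairs):
    """Per-trial VAR/Geweke causality per condition; trial-averaged spectra."""
    theta = dsp.GC_THETA
    slow = dsp.BANDS["slow"]
    gc_rows = []
    spectra: dict = {}
    trial_gc, trial_slow = [], []
    pair_signals = {"MS_LFP->HP_LFP": (ms, hp), "HP_LFP->MS_LFP": (hp, ms)}
    if ms_mua is not None:
        pair_signals["HP_LFP->MS_MUA"] = (hp, ms_mua)
        pair_signals["MS_MUA->HP_LFP"] = (ms_mua, hp)
    for name, (src, tgt) in pair_signals.items():
        for cond_idx, cond in ((0, "off"), (1, "on")):
            acc = None
            for ti, pair in enumerate(pairs):
                ep = pair[cond_idx]
                sl = ep.slice(fs)
                x = np.vstack([tgt[sl], src[sl]])
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = granger.fit_var_ols(x, order=cfg.var_order)
                spec = granger.gc_spectrum(model, "2->1", rate=fs,
                                           n_freq=cfg.gc_n_freq)
                bgc = granger.band_gc(spec, theta)
                gc_rows.append({"trial": ti, "direction": name,
                                "condition": cond, "band": "theta_3_6",
                                "gc": bgc})
                acc = spec.gc if acc is None else acc + spec.gc
                if name == "MS_LFP->HP_LFP" and cond == "on":
                    trial_gc.append(bgc)
                    sp = spectral.multitaper_psd(hp[sl], fs, tw=cfg.tw)
                    trial_slow.append(spectral.band_power(sp, slow))
            spectra[(name, cond)] = granger.GCSpectrum(
                freqs=spec.freqs, gc=acc / len(pairs), source=name, target="")
    return gc_rows, spectra, trial_gc, trial_slow


# ---------------------------------------------------------------------------
# Reporting

def make_report(bundle: dict, out_dir: str | Path | None = None) -> Path:
    """Render a markdown report (tables + figure panels) from a bundle."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir or bundle.get("out_dir", "results"))
    fig_dir = out / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)
    lines = ["# Session analysis report", ""]
    missing = []

    def _panel(name: str, plot_fn) -> None:
        fig, ax = plt.subplots(figsize=(4.2, 3.0))
        plot_fn(ax)
        fig.tight_layout()
        path = fig_dir / f"{name}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        lines.append(f"![{name}](figures/{name}.png)")
        lines.append("")

    bands = bundle.get("bands")
    if bands:
        lines.append("## Band power (light off vs on)\n")
        df = bands["table"].to_frame()
        lines.append(df.to_markdown(index=False, floatfmt=".4g"))
        lines.append("")
        _panel("band_power", lambda ax: _plot_bands(ax, df))
    else:
        missing.append("bands")

    rip = bundle.get("ripples")
    if rip:
        lines.append("## Sharp-wave ripples\n")
        if rip["n_events"] == 0:
            lines.append("*no events detected*\n")
        else:
            d = rip["density"]
            lines.append(
                f"{rip['n_events']} events on channel {rip['detect_channel']}; "
                f"density off {d['off_rate']:.3f}/s, on {d['on_rate']:.3f}/s "
                f"(contrast {100 * d['contrast']:+.1f}%)\n")
            _panel("ripple_density", lambda ax: _plot_density(ax, d))
            if rip.get("profile") is not None:
                _panel("laminar_profile",
                       lambda ax: _plot_profile(ax, rip))
    else:
        missing.append("ripples")

    units = bundle.get("units")
    if units:
        lines.append("## Unit responses\n")
        for reg, s in units["summary"].items():
            lines.append(
                f"- {reg}: {100 * s['frac_excited']:.1f}% excited "
                f"({s['excited_effect_mean_pct']:+.1f}%), "
                f"{100 * s['frac_inhibited']:.1f}% inhibited "
                f"({s['inhibited_effect_mean_pct']:+.1f}%), global rate change "
                f"{s['global_rate_change_pct']:+.1f}%")
        lines.append("")
        _panel("unit_effects", lambda ax: _plot_units(ax, units))
    else:
        missing.append("units")

    sync = bundle.get("synchrony")
    if sync:
        lines.append("## Synchrony\n")
        if sync["lfp_lfp_theta"]:
            lines.append(
                f"LFP-LFP theta coherence off {sync['lfp_lfp_theta'].get('off', float('nan')):.3f} "
                f"vs on {sync['lfp_lfp_theta'].get('on', float('nan')):.3f}\n")
        _panel("spike_field_coherence", lambda ax: _plot_curves(
            ax, sync["coh_rows"], "coherence"))
        _panel("ppc", lambda ax: _plot_curves(ax, sync["ppc_rows"], "ppc"))
    else:
        missing.append("synchrony")

    gc = bundle.get("granger")
    if gc:
        lines.append("## Directed causality\n")
        df = pd.DataFrame(gc["rows"])
        tab = (df.groupby(["direction", "condition"])["gc"]
               .agg(["mean", "sem"]).reset_index())
        lines.append(tab.to_markdown(index=False, floatfmt=".4g"))
        lines.append("")
        _panel("gc_spectra", lambda ax: _plot_gc(ax, gc["spectra"]))
        if gc.get("contrast"):
            c = gc["contrast"]
            lines.append(
                f"Theta causality vs slow-wave power: Spearman r = "
                f"{c['spearman_r']:.3f} (p = {c['p']:.2g}, n = {c['n_trials']})\n")
    else:
        missing.append("granger")

    if missing:
        lines.append(f"\n*Missing sections: {', '.join(missing)}*\n")
    path = out / "report.md"
    path.write_text("\n".join(lines))
    return path


def _plot_bands(ax, df):
    x = np.arange(len(df))
    ax.bar(x - 0.2, df["mean_off"], 0.4, yerr=df["sem_off"], label="off",
           color="k", alpha=0.7)
    ax.bar(x + 0.2, df["mean_on"], 0.4, yerr=df["sem_on"], label="on",
           color="g", alpha=0.7)
    ax.set_xticks(x, df["band"], rotation=30)
    ax.set_ylabel("power (uV$^2$/Hz)")
    ax.legend()


def _plot_density(ax, d):
    ax.bar(d["bin_centers_s"], d["density_mean"], width=4.5,
           yerr=d["density_sem"], color="0.4")
    ax.axvspan(0, 5, color="g", alpha=0.2)
    ax.set_xlabel("time from pulse onset (s)")
    ax.set_ylabel("ripples / s")


def _plot_profile(ax, rip):
    prof = np.asarray(rip["profile"])
    lags = np.asarray(rip["profile_lags"])
    off = 1.2 * np.abs(prof).max()
    for i, row in enumerate(prof):
        ax.plot(lags * 1000, row - i * off, "k", lw=0.8)
    ax.set_xlabel("lag (ms)")
    ax.set_yticks([])


def _plot_units(ax, units):
    effects = [c.effect_pct for c in units["classifications"]
               if np.isfinite(c.effect_pct)]
    colors = {"excited": "r", "inhibited": "b", "none": "0.6"}
    cs = [colors[c.label] for c in units["classifications"]
          if np.isfinite(c.effect_pct)]
    ax.bar(range(len(effects)), sorted(effects),
           color=[c for _, c in sorted(zip(effects, cs))])
    ax.set_xlabel("unit (sorted)")
    ax.set_ylabel("rate change (%)")


def _plot_curves(ax, rows, value):
    if not rows:
        return
    df = pd.DataFrame(rows)
    for cond, color in (("off", "k"), ("on", "g")):
        sub = df[df["condition"] == cond]
        m = sub.groupby("freq_hz")[value].mean()
        ax.plot(m.index, m.values, color=color, label=cond)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel(value)
    ax.legend()


def _plot_gc(ax, spectra):
    for (name, cond), spec in spectra.items():
        if name.endswith("MUA") or name.startswith("MS_MUA"):
            continue
        style = "-" if cond == "off" else "--"
        color = "C0" if name.startswith("MS") else "C1"
        keep = spec.freqs <= 40
        ax.plot(spec.freqs[keep], spec.gc[keep], style, color=color,
                lw=1.0, label=f"{name} {cond}")
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("Granger causality")
    ax.legend(fontsize=6)
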
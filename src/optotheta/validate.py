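"""Parameter-recovery validation of the analysis chain on the generator.

Each function regenerates synthetic sessions from scratch, runs the
corresponding analysis, and scores it against the injected ground truth.
They are shared by the acceptance test suite and ``scripts/acceptance.py``;
all randomness derives from the ``base_seed`` argument.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np

from . import dsp, granger, ripples, spectral, synchrony, unit_response
from .io_model import StimProtocol, paired_epochs
from .synth import (SynthConfig, calibrate_burst_amplitudes, generate_lfp,
                    generate_session, inject_ripple_bursts)

GC_CONTRAST_BAND = dsp.BandDef("theta_gc", 3.0, 7.0)


def _seeds(base_seed: int, n: int, stream: int) -> list[int]:
    """Distinct per-run seeds below 2**31 derived from the base seed."""
    ss = np.random.SeedSequence([int(base_seed), stream])
    return [int(s) for s in ss.generate_state(n) % (2 ** 31)]


# ---------------------------------------------------------------------------
# multitaper configuration (analytic)

def multitaper_config(tw: float = 3.0, window_s: float = 5.0) -> dict:
    return {
        "taper_count": spectral.taper_count(tw),
        "half_bandwidth_hz": spectral.half_bandwidth(tw, window_s),
    }


# ---------------------------------------------------------------------------
# theta power contrast recovery

def theta_power_recovery(base_seed: int = 0, n_seeds: int = 20) -> dict:
    """Per-seed on/off band powers on default sessions; pooled theta test.

    Returns per-seed theta ratios, the pooled band table, and per-seed
    significance flags for every band.
    """
    protocol = StimProtocol.default()
    pairs = paired_epochs(protocol)
    ratios = []
    flags = {name: [] for name in dsp.BANDS}
    pooled_off = {name: [] for name in dsp.BANDS}
    pooled_on = {name: [] for name in dsp.BANDS}
    for seed in _seeds(base_seed, n_seeds, 1):
        cfg = SynthConfig(seed=seed, n_hp_channels=1, n_ms_channels=0)
        rec = generate_lfp(cfg, protocol)
        x = dsp.resample(rec.data[0], cfg.rate, 500.0)
        off_p, on_p = spectral.per_trial_band_powers(x, 500.0, pairs)
        # paired (geometric-mean) ratio: robust to the heavy-tailed
        # trial-to-trial theta amplitude
        ratios.append(float(np.exp(np.mean(
            np.log(on_p["theta"] / off_p["theta"])))))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = spectral.compare_bands(off_p, on_p)
        for name in dsp.BANDS:
            flags[name].append(table[name]["significant"])
            pooled_off[name].append(off_p[name])
            pooled_on[name].append(on_p[name])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pooled_table = spectral.compare_bands(
            {n: np.concatenate(v) for n, v in pooled_off.items()},
            {n: np.concatenate(v) for n, v in pooled_on.items()})
    return {
        "ratios": np.asarray(ratios),
        "mean_ratio": float(np.mean(ratios)),
        "pooled_table": pooled_table,
        "per_seed_flags": {n: int(np.sum(v)) for n, v in flags.items()},
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# ripple detection

def _match_events(events, true_centers, true_onsets, margin: float = 0.025):
    """Coverage matching: a true burst is recalled if a detection's span
    (padded by ``margin``) contains its centre; detections covering no
    burst are false positives."""
    spans = np.array([[e.onset - margin, e.end + margin] for e in events]) \
        if events else np.empty((0, 2))
    matched_det = np.zeros(len(events), dtype=bool)
    hits = 0
    onset_errors = []
    for tc, to in zip(true_centers, true_onsets):
        inside = (spans[:, 0] <= tc) & (tc < spans[:, 1])
        if inside.any():
            hits += 1
            matched_det |= inside
            j = int(np.argmax(inside))
            onset_errors.append(abs(events[j].onset - to))
    return hits, int(matched_det.sum()), onset_errors


def ripple_detection_scores(base_seed: int = 0, n_seeds: int = 20,
                            trace_s: float = 120.0) -> dict:
    """Recall/precision of the detector on default-rate traces."""
    n_true = n_hit = n_det = n_tp = 0
    for seed in _seeds(base_seed, n_seeds, 2):
        cfg = SynthConfig(seed=seed, n_hp_channels=1, n_ms_channels=0,
                          session_length=trace_s)
        rec = generate_lfp(cfg)
        gt = rec.ground_truth
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            events = ripples.detect_ripples(rec.data[0], cfg.rate)
        hits, tp, _ = _match_events(events, gt.ripple_times, gt.ripple_onsets)
        n_true += gt.ripple_times.size
        n_hit += hits
        n_det += len(events)
        n_tp += tp
    return {
        "recall": n_hit / n_true,
        "precision": n_tp / n_det,
        "n_true": n_true,
        "n_detections": n_det,
    }


def ripple_onset_error(base_seed: int = 0, n_seeds: int = 20) -> dict:
    """Mean |detected - true| onset error on isolated 60-ms 6-z bursts."""
    errors = []
    for seed in _seeds(base_seed, n_seeds, 3):
        cfg = SynthConfig(seed=seed, n_hp_channels=1, n_ms_channels=0,
                          session_length=120.0, ripple_rate_off=0.0)
        rec = generate_lfp(cfg)
        bg = rec.data[0]
        centers = 3.0 + 6.0 * np.arange(20)
        durs = np.full(20, 0.060)
        freqs = np.full(20, 150.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            amps = calibrate_burst_amplitudes(bg, cfg.rate, 6.0, centers,
                                              durs, freqs)
            trace = inject_ripple_bursts(bg, cfg.rate, centers, durs, freqs,
                                         amps)
            events = ripples.detect_ripples(trace, cfg.rate)
        _, _, errs = _match_events(events, centers, centers - 0.030)
        errors.extend(errs)
    errors = np.asarray(errors) * 1000.0
    return {"mean_onset_error_ms": float(errors.mean()),
            "median_onset_error_ms": float(np.median(errors)),
            "n_matched": errors.size}


def ripple_density_recovery(base_seed: int = 0, n_seeds: int = 20) -> dict:
    """Recovered on/off ripple-density contrast on default sessions."""
    contrasts = []
    on_rates, off_rates = [], []
    protocol = StimProtocol.default()
    for seed in _seeds(base_seed, n_seeds, 4):
        cfg = SynthConfig(seed=seed, n_hp_channels=1, n_ms_channels=0)
        rec = generate_lfp(cfg, protocol)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            events = ripples.detect_ripples(rec.data[0], cfg.rate)
            d = ripples.ripple_density(events, protocol)
        contrasts.append(d["contrast"])
        on_rates.append(d["on_rate"])
        off_rates.append(d["off_rate"])
    pooled = float(np.mean(on_rates) / np.mean(off_rates) - 1.0)
    return {"contrasts": np.asarray(contrasts),
            "mean_contrast": float(np.mean(contrasts)),
            "pooled_contrast": pooled}


# ---------------------------------------------------------------------------
# unit classification

def unit_classification_recovery(base_seed: int = 0, n_seeds: int = 20,
                                 n_shuffles: int = 1000) -> dict:
    """Classification on default sessions, scored against ground truth."""
    counts = {("MS", "excited"): [0, 0], ("MS", "inhibited"): [0, 0],
              ("HP", "excited"): [0, 0], ("HP", "inhibited"): [0, 0]}
    n_none = n_none_correct = 0
    n_units = {"MS": 0, "HP": 0}
    flagged = {("MS", "excited"): 0, ("MS", "inhibited"): 0,
               ("HP", "excited"): 0, ("HP", "inhibited"): 0}
    effects = {k: [] for k in counts}
    injected = {k: [] for k in counts}
    for seed in _seeds(base_seed, n_seeds, 5):
        cfg = SynthConfig(seed=seed, n_hp_channels=1, n_ms_channels=0,
                          ripple_rate_off=0.0)
        rec, spikes, protocol = generate_session(cfg)
        info = {u["unit_id"]: u for u in rec.ground_truth.unit_info}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cls = unit_response.classify_all(spikes, protocol,
                                             n_shuffles=n_shuffles, seed=seed)
        for c in cls:
            u = info[c.unit_id]
            region, true = u["region"], u["cls"]
            n_units[region] += 1
            if true == "none":
                n_none += 1
                n_none_correct += c.label == "none"
            else:
                key = (region, true)
                counts[key][1] += 1
                counts[key][0] += c.label == true
                if np.isfinite(c.effect_pct):
                    effects[key].append(c.effect_pct)
                    injected[key].append(100.0 * (u["gain"] - 1.0))
            if c.label in ("excited", "inhibited"):
                flagged[(region, c.label)] += 1
    out = {
        "specificity": n_none_correct / n_none,
        "n_units": n_units,
        "fractions": {f"{r.lower()}_{lab}": flagged[(r, lab)] / n_units[r]
                      for r, lab in flagged},
        "sensitivity": {f"{r.lower()}_{lab}":
                        (counts[(r, lab)][0] / counts[(r, lab)][1]
                         if counts[(r, lab)][1] else np.nan)
                        for r, lab in counts},
        "mean_effect": {f"{r.lower()}_{lab}": float(np.mean(effects[(r, lab)]))
                        for r, lab in effects},
        "mean_injected_effect": {f"{r.lower()}_{lab}":
                                 float(np.mean(injected[(r, lab)]))
                                 for r, lab in injected},
    }
    return out


def unit_sensitivity_at_gain(base_seed: int = 0, n_seeds: int = 20,
                             gain_exc: float = 1.5, gain_inh: float = 0.5,
                             n_shuffles: int = 1000) -> dict:
    """Sensitivity at strong injected gains (half excited, quarter inhibited)."""
    hits = {"excited": [0, 0], "inhibited": [0, 0]}
    eff_err = []
    for seed in _seeds(base_seed, n_seeds, 6):
        cfg = SynthConfig(seed=seed, n_hp_channels=1, n_ms_channels=0,
                          ripple_rate_off=0.0, n_units_per_region=10,
                          frac_hp_excited=0.5, hp_excited_gain=gain_exc,
                          frac_hp_inhibited=0.3, hp_inhibited_gain=gain_inh,
                          frac_ms_excited=0.5, ms_excited_gain=gain_exc,
                          frac_ms_inhibited=0.3, ms_inhibited_gain=gain_inh)
        rec, spikes, protocol = generate_session(cfg)
        info = {u["unit_id"]: u for u in rec.ground_truth.unit_info}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cls = unit_response.classify_all(spikes, protocol,
                                             n_shuffles=n_shuffles, seed=seed)
        for c in cls:
            u = info[c.unit_id]
            if u["cls"] == "none":
                continue
            hits[u["cls"]][1] += 1
            hits[u["cls"]][0] += c.label == u["cls"]
            if np.isfinite(c.effect_pct):
                eff_err.append(c.effect_pct - 100.0 * (u["gain"] - 1.0))
    return {
        "sensitivity_excited": hits["excited"][0] / hits["excited"][1],
        "sensitivity_inhibited": hits["inhibited"][0] / hits["inhibited"][1],
        "mean_effect_error_pct": float(np.mean(eff_err)),
    }


# ---------------------------------------------------------------------------
# PPC and coherence oracles

def ppc_oracle_check(base_seed: int = 0, n_sets: int = 100,
                     max_n: int = 500) -> dict:
    """Identity-formula PPC vs the O(N^2) pairwise brute force."""
    rng = np.random.default_rng(np.random.SeedSequence([base_seed, 7]))
    max_diff = 0.0
    uniform_means = []
    for _ in range(n_sets):
        n = int(rng.integers(2, max_n + 1))
        phases = rng.uniform(-np.pi, np.pi, n)
        brute = 0.0
        for j in range(n - 1):
            brute += np.cos(phases[j] - phases[j + 1:]).sum()
        brute *= 2.0 / (n * (n - 1))
        max_diff = max(max_diff,
                       abs(synchrony.ppc_from_phases(phases) - brute))
        uniform_means.append(synchrony.ppc_from_phases(phases))
    return {
        "max_diff_vs_bruteforce": max_diff,
        "equal_phases": synchrony.ppc_from_phases(np.full(17, 0.83)),
        "antipodal_pair": synchrony.ppc_from_phases(np.array([0.0, np.pi])),
        "uniform_mean": float(np.mean(uniform_means)),
    }


def coherence_checks(base_seed: int = 0, n_trials: int = 60,
                     snr_a: float = 1.0, snr_b: float = 0.5) -> dict:
    rng = np.random.default_rng(np.random.SeedSequence([base_seed, 8]))
    n = 2500
    segs = [rng.standard_normal(n) for _ in range(10)]
    self_coh = synchrony.coherence(segs, [s.copy() for s in segs], 500.0)
    segs_a, segs_b = [], []
    for _ in range(n_trials):
        common = rng.standard_normal(n)
        segs_a.append(np.sqrt(snr_a) * common + rng.standard_normal(n))
        segs_b.append(np.sqrt(snr_b) * common + rng.standard_normal(n))
    shared = synchrony.coherence(segs_a, segs_b, 500.0)
    closed_form = snr_a * snr_b / ((1 + snr_a) * (1 + snr_b))
    indep = synchrony.coherence([rng.standard_normal(n) for _ in range(30)],
                                [rng.standard_normal(n) for _ in range(30)],
                                500.0)
    return {
        "self_coherence_min": float(self_coh.coh.min()),
        "shared_signal_coh": float(shared.coh[5:-5].mean()),
        "closed_form": closed_form,
        "independent_mean_coh": float(indep.coh.mean()),
    }


# ---------------------------------------------------------------------------
# Granger causality

def _unidirectional_model(c: float = 0.4) -> granger.VARModel:
    A = np.zeros((1, 2, 2))
    A[0, 0, 0] = 0.5
    A[0, 1, 1] = 0.4
    A[0, 1, 0] = c  # x1 drives x2
    return granger.VARModel(A=A, sigma=np.eye(2), rate=500.0)


def granger_checks(base_seed: int = 0, n_trials: int = 15,
                   n_reps: int = 20, n_per_trial: int = 2500) -> dict:
    rng = np.random.default_rng(np.random.SeedSequence([base_seed, 9]))
    # decoupled model
    A = np.zeros((1, 2, 2))
    np.fill_diagonal(A[0], [0.5, -0.3])
    dec = granger.VARModel(A=A, sigma=np.diag([1.0, 2.0]), rate=500.0)
    dec_max = max(granger.gc_spectrum(dec, d, n_freq=500).gc.max()
                  for d in ("1->2", "2->1"))

    model = _unidirectional_model()
    # direction recovery on per-trial fits
    correct = total = 0
    band = dsp.BandDef("low", 0.0, 20.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_reps):
            for _ in range(n_trials):
                x = granger.simulate_var(model, n_per_trial, rng)
                fit = granger.fit_var_ols(x, order=5)
                fwd = granger.band_gc(granger.gc_spectrum(
                    fit, "1->2", rate=500.0, n_freq=500), band)
                rev = granger.band_gc(granger.gc_spectrum(
                    fit, "2->1", rate=500.0, n_freq=500), band)
                correct += fwd > rev
                total += 1
        # fitted vs true spectrum at the peak (large n)
        x = granger.simulate_var(model, 50_000, rng)
        fit = granger.fit_var_ols(x, order=5)
    true_spec = granger.gc_spectrum(model, "1->2", n_freq=1000)
    fit_spec = granger.gc_spectrum(fit, "1->2", rate=500.0, n_freq=1000)
    ipk = int(np.argmax(true_spec.gc))
    peak_rel_err = abs(fit_spec.gc[ipk] - true_spec.gc[ipk]) / true_spec.gc[ipk]
    # gain invariance: common rescaling of both channels
    scaled = granger.VARModel(A=model.A, sigma=model.sigma * 13.7 ** 2,
                              rate=500.0)
    gain_diff = float(np.max(np.abs(
        granger.gc_spectrum(model, "1->2", n_freq=500).gc
        - granger.gc_spectrum(scaled, "1->2", n_freq=500).gc)))
    return {
        "decoupled_max_gc": float(dec_max),
        "direction_recovery": correct / total,
        "peak_rel_err": float(peak_rel_err),
        "gain_invariance_diff": gain_diff,
    }


def gc_direction_on_generator(base_seed: int = 0, n_seeds: int = 20,
                              order: int = 20) -> dict:
    """Theta-band MS->HP vs HP->MS causality on default generator sessions."""
    wins = 0
    fwd_all, rev_all = [], []
    protocol = StimProtocol.default()
    pairs = paired_epochs(protocol)
    for seed in _seeds(base_seed, n_seeds, 10):
        cfg = SynthConfig(seed=seed, n_hp_channels=1, n_ms_channels=1,
                          ripple_rate_off=0.0)
        rec = generate_lfp(cfg, protocol)
        hp = dsp.resample(rec.data[0], cfg.rate, 500.0)
        ms = dsp.resample(rec.data[1], cfg.rate, 500.0)
        fwd, rev = [], []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for off_ep, _ in pairs:
                sl = off_ep.slice(500.0)
                model = granger.fit_var_ols(np.vstack([hp[sl], ms[sl]]),
                                            order=order)
                fwd.append(granger.band_gc(granger.gc_spectrum(
                    model, "2->1", rate=500.0, n_freq=500)))
                rev.append(granger.band_gc(granger.gc_spectrum(
                    model, "1->2", rate=500.0, n_freq=500)))
        fwd_all.append(np.mean(fwd))
        rev_all.append(np.mean(rev))
        wins += np.mean(fwd) > np.mean(rev)
    return {
        "direction_win_fraction": wins / n_seeds,
        "mean_gc_ms_to_hp": float(np.mean(fwd_all)),
        "mean_gc_hp_to_ms": float(np.mean(rev_all)),
    }


def gc_delta_recovery(base_seed: int = 0, n_seeds: int = 20,
                      session_length: float = 2020.0, order: int = 20) -> dict:
    """Sign recovery of the slow-wave/causality anticorrelation."""
    rs = []
    protocol = StimProtocol.default(session_length=session_length)
    pairs = paired_epochs(protocol)
    for seed in _seeds(base_seed, n_seeds, 11):
        cfg = SynthConfig(seed=seed, n_hp_channels=1, n_ms_channels=1,
                          ripple_rate_off=0.0, session_length=session_length)
        rec = generate_lfp(cfg, protocol)
        hp = dsp.resample(rec.data[0], cfg.rate, 500.0)
        ms = dsp.resample(rec.data[1], cfg.rate, 500.0)
        gcs, slows = [], []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _, on_ep in pairs:
                sl = on_ep.slice(500.0)
                model = granger.fit_var_ols(np.vstack([hp[sl], ms[sl]]),
                                            order=order)
                gcs.append(granger.band_gc(granger.gc_spectrum(
                    model, "2->1", rate=500.0, n_freq=500), GC_CONTRAST_BAND))
                sp = spectral.multitaper_psd(hp[sl], 500.0)
                slows.append(spectral.band_power(sp, dsp.BANDS["slow"]))
            out = granger.gc_delta_contrast(np.asarray(gcs),
                                            np.asarray(slows))
        rs.append(out["spearman_r"])
    rs = np.asarray(rs)
    return {"spearman_rs": rs, "n_negative": int(np.sum(rs < 0)),
            "mean_r": float(rs.mean()), "n_trials": len(pairs)}


def gc_delta_null(base_seed: int = 0, n_seeds: int = 100,
                  n_trials: int = 100) -> dict:
    """Null calibration: independent causality and power columns."""
    rng = np.random.default_rng(np.random.SeedSequence([base_seed, 12]))
    rs = []
    for _ in range(n_seeds):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = granger.gc_delta_contrast(
                rng.lognormal(0, 0.5, n_trials),
                rng.lognormal(0, 0.5, n_trials))
        rs.append(out["spearman_r"])
    rs = np.asarray(rs)
    return {"frac_small": float(np.mean(np.abs(rs) < 0.2)),
            "max_abs_r": float(np.abs(rs).max())}


# ---------------------------------------------------------------------------
# end-to-end determinism

def determinism_check(base_seed: int = 0, out_root=None) -> dict:
    """Identical config + seed must give byte-identical pipeline outputs."""
    import hashlib
    import tempfile
    from pathlib import Path

    from .pipeline import PipelineConfig, run_pipeline

    seed = _seeds(base_seed, 1, 13)[0]
    cfg = SynthConfig(seed=seed, n_hp_channels=4, n_units_per_region=8,
                      session_length=200.0)
    digests = []
    with tempfile.TemporaryDirectory(dir=out_root) as tmp:
        for rep in ("a", "b"):
            session = generate_session(replace(cfg))
            pcfg = PipelineConfig(out_dir=str(Path(tmp) / rep), seed=seed,
                                  n_shuffles=200, session_length=200.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                run_pipeline(pcfg, session=session)
            d = {}
            for f in sorted(Path(tmp, rep).glob("*")):
                # run_log.json records the out_dir path, which necessarily
                # differs between the two replicate directories
                if f.is_file() and f.name != "run_log.json":
                    d[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
            digests.append(d)
    return {"identical": digests[0] == digests[1],
            "files": sorted(digests[0])}
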
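import warnings

import numpy as np
import pytest

from optotheta import ripples, synth
from optotheta.io_model import StimProtocol


def _background(seed=0, length=120.0):
    cfg = synth.SynthConfig(seed=seed, n_hp_channels=1, n_ms_channels=0,
                            session_length=length, ripple_rate_off=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rec = synth.generate_lfp(cfg)
    return cfg, rec.data[0]


def _inject(bg, rate, centers, dur=0.060, freq=150.0, z=6.0):
    durs = np.full(len(centers), dur)
    freqs = np.full(len(centers), freq)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        amps = synth.calibrate_burst_amplitudes(bg, rate, z, centers, durs,
                                                freqs)
        return synth.inject_ripple_bursts(bg, rate, centers, durs, freqs,
                                          amps)


class TestDetectRipples:
    def test_injected_bursts_recovered_with_accurate_onsets(self):
        cfg, bg = _background(seed=3)
        centers = 3.0 + 6.0 * np.arange(20)
        trace = _inject(bg, cfg.rate, centers)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            events = ripples.detect_ripples(trace, cfg.rate)
        hits = 0
        errs = []
        for tc in centers:
            for e in events:
                if e.onset - 0.025 <= tc < e.end + 0.025:
                    hits += 1
                    errs.append(abs(e.onset - (tc - 0.030)))
                    break
        assert hits >= 19
        assert np.mean(errs) <= 0.010

    def test_noise_false_positive_rate_bounded(self):
        # envelope exceedances of pure background; the 3.5 SD threshold on
        # this pipeline admits some noise events -- rate must stay low
        n_fp, total_s = 0, 0.0
        for seed in range(3):
            cfg, bg = _background(seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                n_fp += len(ripples.detect_ripples(bg, cfg.rate))
            total_s += cfg.session_length
        assert n_fp / total_s < 0.15

    def test_nearby_bursts_merge_into_one_event(self):
        cfg, bg = _background(seed=5)
        trace = _inject(bg, cfg.rate, np.array([60.0, 60.08]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            events = ripples.detect_ripples(trace, cfg.rate)
        near = [e for e in events if 59.5 < e.peak_time < 60.6]
        assert len(near) == 1
        assert near[0].duration >= 80.0  # spans both bursts, ms

    def test_gain_invariance_of_detection(self):
        cfg, bg = _background(seed=1)
        trace = _inject(bg, cfg.rate, 5.0 + 10.0 * np.arange(10))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = ripples.detect_ripples(trace, cfg.rate)
            b = ripples.detect_ripples(trace * 7.3, cfg.rate)
        assert [(e.onset, e.end) for e in a] == [(e.onset, e.end) for e in b]

    def test_constant_trace_rejected(self):
        from optotheta.dsp import DegenerateSignalError

        with pytest.raises(DegenerateSignalError):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ripples.detect_ripples(np.zeros(10_000), 1000.0)


class TestRippleMetrics:
    def test_peak_frequency_recovered(self):
        cfg, bg = _background(seed=7)
        centers = 5.0 + 10.0 * np.arange(11)
        trace = _inject(bg, cfg.rate, centers, freq=150.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            events = ripples.detect_ripples(trace, cfg.rate)
            events = ripples.ripple_metrics(events, trace, cfg.rate)
        matched = [e for e in events
                   if any(abs(e.peak_time - tc) < 0.05 for tc in centers)]
        assert len(matched) >= 9
        freqs = np.array([e.peak_freq for e in matched])
        assert abs(np.median(freqs) - 150.0) <= 4.0
        assert np.mean(np.abs(freqs - 150.0) <= 6.0) >= 0.8

    def test_duration_within_envelope_crossing_bounds(self):
        cfg, bg = _background(seed=8)
        centers = 5.0 + 10.0 * np.arange(11)
        trace = _inject(bg, cfg.rate, centers, dur=0.060)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            events = ripples.detect_ripples(trace, cfg.rate)
        durs = [e.duration for e in events
                if any(abs(e.peak_time - tc) < 0.05 for tc in centers)]
        assert np.all((np.array(durs) >= 40.0) & (np.array(durs) <= 110.0))

    def test_amplitude_monotone_in_burst_gain(self):
        cfg, bg = _background(seed=9)
        amps_meas = []
        for z in (4.5, 6.0, 8.0):
            trace = _inject(bg, cfg.rate, np.array([60.0]), z=z)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                events = ripples.detect_ripples(trace, cfg.rate)
            ev = max((e for e in events if abs(e.peak_time - 60) < 0.05),
                     key=lambda e: e.amplitude)
            amps_meas.append(ev.amplitude)
        assert amps_meas[0] < amps_meas[1] < amps_meas[2]


class TestRippleDensity:
    def test_null_gain_gives_zero_contrast(self, rng):
        protocol = StimProtocol.default()
        events = [ripples.RippleEvent(t, t + 0.05, t + 0.02, 5.0)
                  for t in np.sort(rng.uniform(1, 599, 400))]
        d = ripples.ripple_density(events, protocol)
        assert abs(d["contrast"]) < 0.25  # Poisson noise scale at n=400

    def test_empty_on_epochs_give_minus_100pct(self, rng):
        protocol = StimProtocol.default()
        times = np.sort(rng.uniform(1, 599, 500))
        keep = ~np.any((times[:, None] >= protocol.onsets[None, :])
                       & (times[:, None] < protocol.onsets[None, :] + 5.0),
                       axis=1)
        events = [ripples.RippleEvent(t - 0.03, t + 0.02, t, 5.0)
                  for t in times[keep]]
        d = ripples.ripple_density(events, protocol)
        assert d["contrast"] == pytest.approx(-1.0)

    def test_density_curve_shape(self, rng):
        protocol = StimProtocol.default()
        events = [ripples.RippleEvent(t, t + 0.05, t + 0.02, 5.0)
                  for t in np.sort(rng.uniform(1, 599, 600))]
        d = ripples.ripple_density(events, protocol)
        assert d["bin_centers_s"].size == 4  # -15..0 in 5 s bins + pulse bin
        assert d["n_trials"] == 30


class TestTriggeredProfile:
    def test_identical_events_reproduce_template(self):
        rate = 1000.0
        n = 60_000
        data = np.zeros((2, n))
        template = np.sin(2 * np.pi * 150 * np.arange(-100, 101) / rate)
        centers = (5000 + 4000 * np.arange(12))
        for c in centers:
            data[0, c - 100:c + 101] += template
            data[1, c - 100:c + 101] -= 0.5 * template
        from optotheta.io_model import ChannelMeta, Recording

        rec = Recording(data=data, rate=rate, channels=[
            ChannelMeta(id=0, depth_index=0), ChannelMeta(id=1, depth_index=1)])
        events = [ripples.RippleEvent(c / rate - 0.03, c / rate + 0.03,
                                      c / rate, 5.0) for c in centers]
        prof, lags = ripples.ripple_triggered_profile(events, rec)
        np.testing.assert_allclose(prof[0], template, atol=1e-12)
        np.testing.assert_allclose(prof[1], -0.5 * template, atol=1e-12)

    def test_laminar_polarity_and_rms_peak(self, small_session):
        cfg, rec, _, _ = small_session
        pyr = cfg.pyr_depth_index
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            events = ripples.detect_ripples(rec.data[pyr], rec.rate)
            prof, lags, band_rms = ripples.ripple_triggered_profile(
                events, rec, return_band_rms=True)
        hp = [i for i, c in enumerate(rec.channels) if c.region == "HP"]
        core = np.abs(lags) <= 0.05
        sw = prof[hp][:, core].mean(axis=1)
        assert np.all(sw[:pyr] > 0)  # dorsal to pyramidale: positive
        assert np.all(sw[pyr + 1:] < 0)  # ventral: negative
        assert np.argmax(band_rms[: len(hp)]) == pyr

    def test_few_events_warn(self, small_session):
        _, rec, _, _ = small_session
        events = [ripples.RippleEvent(1.0, 1.05, 1.02, 5.0)]
        with pytest.warns(UserWarning, match="events"):
            ripples.ripple_triggered_profile(events, rec)
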
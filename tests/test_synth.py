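import warnings

import numpy as np
import pytest

from optotheta import dsp, spectral, synth
from optotheta.io_model import paired_epochs


class TestDeterminism:
    def test_same_seed_identical_session(self):
        cfg = synth.SynthConfig(seed=5, n_hp_channels=2, n_units_per_region=4,
                                session_length=100.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec1, spk1, p1 = synth.generate_session(cfg)
            rec2, spk2, p2 = synth.generate_session(cfg)
        np.testing.assert_array_equal(rec1.data, rec2.data)
        np.testing.assert_array_equal(p1.onsets, p2.onsets)
        for (a, _, ta), (b, _, tb) in zip(spk1, spk2):
            assert a == b
            np.testing.assert_array_equal(ta, tb)

    def test_seed_change_changes_spikes_not_protocol(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, spk1, p1 = synth.generate_session(synth.SynthConfig(
                seed=1, n_hp_channels=1, n_units_per_region=4,
                session_length=100.0))
            _, spk2, p2 = synth.generate_session(synth.SynthConfig(
                seed=2, n_hp_channels=1, n_units_per_region=4,
                session_length=100.0))
        np.testing.assert_array_equal(p1.onsets, p2.onsets)
        assert not np.array_equal(spk1.units[0][2], spk2.units[0][2])


class TestProtocol:
    def test_default_session_has_30_pulses(self):
        _, _, protocol = synth.generate_session(
            synth.SynthConfig(seed=0, n_hp_channels=1, n_units_per_region=2,
                              ripple_rate_off=0.0))
        np.testing.assert_allclose(protocol.onsets,
                                   np.arange(15.0, 596.0, 20.0))


class TestLFPComposition:
    def test_null_theta_gain_gives_unit_ratio(self):
        cfg = synth.SynthConfig(seed=3, n_hp_channels=1, n_ms_channels=0,
                                ripple_rate_off=0.0, theta_power_gain_on=1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = synth.generate_lfp(cfg)
        x = dsp.resample(rec.data[0], cfg.rate, 500.0)
        from optotheta.io_model import StimProtocol

        pairs = paired_epochs(StimProtocol.default())
        off_p, on_p = spectral.per_trial_band_powers(x, 500.0, pairs)
        ratio = on_p["theta"].mean() / off_p["theta"].mean()
        assert ratio == pytest.approx(1.0, abs=0.15)

    def test_ms_theta_leads_hp_theta(self):
        cfg = synth.SynthConfig(seed=4, n_hp_channels=1, n_ms_channels=1,
                                ripple_rate_off=0.0, session_length=120.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = synth.generate_lfp(cfg)
            hp = dsp.fir_bandpass(rec.data[0], cfg.rate, 4, 7, transition=1.0)
            ms = dsp.fir_bandpass(rec.data[1], cfg.rate, 4, 7, transition=1.0)
        lags = np.arange(-60, 61)
        # corr(ms[t], hp[t+l]) peaks at l = +lag when hp lags the MS drive
        xc = [np.corrcoef(ms[1000:-1000],
                          np.roll(hp, -l)[1000:-1000])[0, 1] for l in lags]
        best = lags[int(np.argmax(xc))]
        assert best == pytest.approx(int(cfg.ms_to_hp_lag * cfg.rate), abs=3)

    def test_ripple_amplitudes_calibrated_in_detector_units(self):
        from optotheta import ripples

        cfg = synth.SynthConfig(seed=6, n_hp_channels=1, n_ms_channels=0,
                                session_length=300.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = synth.generate_lfp(cfg)
            z, fs = ripples.ripple_envelope(rec.data[0], cfg.rate)
        gt = rec.ground_truth
        idx = np.minimum((gt.ripple_times * fs).astype(int), z.size - 1)
        peaks = [z[max(i - 12, 0):i + 12].max() for i in idx]
        assert np.median(peaks) == pytest.approx(cfg.ripple_burst_z, abs=1.0)

    def test_blockade_mode_cancels_theta_gain(self):
        from optotheta.io_model import StimProtocol

        cfg = synth.SynthConfig(seed=8, n_hp_channels=1, n_ms_channels=0,
                                ripple_rate_off=0.0, blockade_time_s=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = synth.generate_lfp(cfg)
        assert np.all(rec.ground_truth.theta_gain_trace == 1.0)
        x = dsp.resample(rec.data[0], cfg.rate, 500.0)
        pairs = paired_epochs(StimProtocol.default())
        off_p, on_p = spectral.per_trial_band_powers(x, 500.0, pairs)
        assert on_p["theta"].mean() / off_p["theta"].mean() == pytest.approx(
            1.0, abs=0.15)


class TestSpikes:
    def test_class_counts_match_configured_fractions(self, small_session):
        cfg, rec, spikes, _ = small_session
        info = rec.ground_truth.unit_info
        ms = [u for u in info if u["region"] == "MS"]
        n = cfg.n_units_per_region
        assert sum(u["cls"] == "excited" for u in ms) == round(
            cfg.frac_ms_excited * n)
        assert sum(u["cls"] == "inhibited" for u in ms) == round(
            cfg.frac_ms_inhibited * n)
        assert len(spikes) == 2 * n

    def test_excited_unit_rate_ratio_recovers_gain(self):
        cfg = synth.SynthConfig(seed=13, n_hp_channels=1, n_ms_channels=0,
                                ripple_rate_off=0.0, n_units_per_region=40)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec, spikes, protocol = synth.generate_session(cfg)
        info = {u["unit_id"]: u for u in rec.ground_truth.unit_info}
        on_t = protocol.onsets.size * protocol.pulse_duration
        off_t = protocol.session_length - on_t
        ratios = []
        injected = []
        for uid, region, times in spikes:
            if info[uid]["cls"] != "excited" or region != "HP":
                continue
            in_on = np.any((times[:, None] >= protocol.onsets[None, :])
                           & (times[:, None] < protocol.onsets[None, :] + 5),
                           axis=1)
            n_on = in_on.sum()
            ratios.append((n_on / on_t) / ((times.size - n_on) / off_t))
            injected.append(info[uid]["gain"])
        assert np.mean(ratios) == pytest.approx(np.mean(injected), abs=0.08)

    def test_theta_locking_concentration(self, small_session):
        # spikes should cluster at each unit's preferred phase
        cfg, rec, spikes, _ = small_session
        info = {u["unit_id"]: u for u in rec.ground_truth.unit_info}
        phase = rec.ground_truth.theta_phase_hp
        resultants = []
        for uid, region, times in spikes:
            if region != "HP" or times.size < 200:
                continue
            idx = np.minimum((times * cfg.rate).astype(int), phase.size - 1)
            d = phase[idx] - info[uid]["phase_pref"]
            resultants.append(np.abs(np.mean(np.exp(1j * d))))
            assert np.abs(np.angle(np.mean(np.exp(1j * d)))) < 0.5
        # kappa = 1 -> resultant ~ I1(1)/I0(1) ~ 0.45 (off), higher during on
        assert np.mean(resultants) == pytest.approx(0.47, abs=0.12)
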
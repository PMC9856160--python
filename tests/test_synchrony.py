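import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from optotheta import dsp, ripples, synchrony
from optotheta.io_model import ChannelMeta, Recording


class TestCoherence:
    def test_self_coherence_is_one(self, rng):
        segs = [rng.standard_normal(2500) for _ in range(5)]
        c = synchrony.coherence(segs, [s.copy() for s in segs], 500)
        np.testing.assert_allclose(c.coh, 1.0, atol=1e-9)

    def test_independent_noise_floor(self, rng):
        c = synchrony.coherence(
            [rng.standard_normal(2500) for _ in range(30)],
            [rng.standard_normal(2500) for _ in range(30)], 500)
        assert c.coh.mean() < 0.1
        assert np.all((c.coh >= 0) & (c.coh <= 1))

    def test_shared_signal_matches_snr_closed_form(self, rng):
        snr_a, snr_b = 2.0, 0.8
        segs_a, segs_b = [], []
        for _ in range(80):
            common = rng.standard_normal(2500)
            segs_a.append(np.sqrt(snr_a) * common
                          + rng.standard_normal(2500))
            segs_b.append(np.sqrt(snr_b) * common
                          + rng.standard_normal(2500))
        c = synchrony.coherence(segs_a, segs_b, 500)
        expect = snr_a * snr_b / ((1 + snr_a) * (1 + snr_b))
        assert c.coh[5:-5].mean() == pytest.approx(expect, abs=0.05)

    def test_symmetry_in_arguments(self, rng):
        a = [rng.standard_normal(1000) for _ in range(4)]
        b = [rng.standard_normal(1000) for _ in range(4)]
        cab = synchrony.coherence(a, b, 500)
        cba = synchrony.coherence(b, a, 500)
        np.testing.assert_allclose(cab.coh, cba.coh, atol=1e-12)

    def test_single_segment_rejected(self, rng):
        with pytest.raises(ValueError):
            synchrony.coherence([rng.standard_normal(1000)],
                                [rng.standard_normal(1000)], 500)


class TestPPC:
    def test_equal_phases_give_one(self):
        assert synchrony.ppc_from_phases(np.full(9, 1.3)) == pytest.approx(1.0)

    def test_antipodal_pair_gives_minus_one(self):
        assert synchrony.ppc_from_phases(
            np.array([0.4, 0.4 + np.pi])) == pytest.approx(-1.0)

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 2 ** 20), n=st.integers(2, 300))
    def test_identity_equals_pairwise_bruteforce(self, seed, n):
        phases = np.random.default_rng(seed).uniform(-np.pi, np.pi, n)
        brute = 0.0
        for j in range(n - 1):
            brute += np.cos(phases[j] - phases[j + 1:]).sum()
        brute *= 2.0 / (n * (n - 1))
        assert synchrony.ppc_from_phases(phases) == pytest.approx(
            brute, abs=1e-10)

    def test_uniform_phases_unbiased_near_zero(self, rng):
        vals = [synchrony.ppc_from_phases(rng.uniform(-np.pi, np.pi, 500))
                for _ in range(500)]
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se + 1e-4

    def test_locked_spikes_yield_high_theta_ppc(self, rng):
        rate = 500.0
        t = np.arange(int(60 * rate)) / rate
        lfp = 50 * np.cos(2 * np.pi * 5.5 * t) + rng.normal(0, 5, t.size)
        # spikes at the cosine peaks (phase 0)
        spikes = np.arange(1.0, 59.0, 1 / 5.5)
        curve = synchrony.ppc(spikes, lfp, rate,
                              freqs=np.arange(4.0, 7.25, 0.25))
        i = np.argmin(np.abs(curve.freqs - 5.5))
        assert curve.ppc[i] > 0.8

    def test_fewer_than_two_spikes_undefined(self, rng):
        lfp = rng.standard_normal(5000)
        curve = synchrony.ppc(np.array([1.0]), lfp, 500,
                              freqs=np.array([5.0]))
        assert np.isnan(curve.ppc).all()


class TestCoherenceByDistance:
    def _two_shank_recording(self, rng, common_gain=1.0):
        rate = 500.0
        n = int(200 * rate)
        t = np.arange(n) / rate
        common = np.cos(2 * np.pi * 5.5 * t)
        data = []
        chans = []
        for shank in range(3):
            for depth in range(2):
                data.append(common_gain * common
                            + 0.5 * rng.standard_normal(n))
                chans.append(ChannelMeta(id=len(chans), region="HP",
                                         shank=shank, depth_index=depth))
        return Recording(data=np.asarray(data), rate=rate, channels=chans)

    def test_common_drive_gives_high_theta_coherence_all_pairs(self, rng):
        from optotheta.io_model import Epoch

        rec = self._two_shank_recording(rng)
        pairs = [(Epoch(10 * k, 10 * k + 5), Epoch(10 * k + 5, 10 * k + 10))
                 for k in range(15)]
        rows = synchrony.coherence_by_distance(rec, pairs)
        assert len(rows) == 3  # 3 shank pairs
        for r in rows:
            assert r["coh_off"] > 0.5 and r["coh_on"] > 0.5

    def test_single_shank_rejected(self, rng, small_session):
        _, rec, _, _ = small_session
        with pytest.raises(ValueError):
            synchrony.coherence_by_distance(rec, [])


class TestAssignLayers:
    def test_generator_layout_recovered_exactly(self, small_session):
        cfg, rec, _, _ = small_session
        pyr = cfg.pyr_depth_index
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            events = ripples.detect_ripples(rec.data[pyr], rec.rate)
            prof, lags, band_rms = ripples.ripple_triggered_profile(
                events, rec, return_band_rms=True)
            labels = synchrony.assign_layers(prof, lags, rec,
                                             band_rms=band_rms)
        truth = {c.id: c.layer for c in rec.channels if c.region == "HP"}
        assert labels == truth

    def test_flat_profile_is_ambiguous(self, rng):
        rate = 1000.0
        rec = Recording(
            data=rng.standard_normal((4, 2000)), rate=rate,
            channels=[ChannelMeta(id=i, region="HP", depth_index=i)
                      for i in range(4)])
        prof = np.ones((4, 201)) * 0.1
        lags = np.arange(-100, 101) / rate
        with pytest.warns(UserWarning, match="ambiguous"):
            labels = synchrony.assign_layers(
                prof, lags, rec, band_rms=np.ones(4))
        assert set(labels.values()) == {"unknown"}

    def test_probe_flip_swaps_oriens_and_radiatum(self, small_session):
        # a physically flipped probe sees the same waveforms on contacts in
        # reversed depth order: reverse the profile rows, keep the metadata
        cfg, rec, _, _ = small_session
        pyr = cfg.pyr_depth_index
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            events = ripples.detect_ripples(rec.data[pyr], rec.rate)
            prof, lags, band_rms = ripples.ripple_triggered_profile(
                events, rec, return_band_rms=True)
            orig = synchrony.assign_layers(prof, lags, rec, band_rms=band_rms)
            n = cfg.n_hp_channels
            prof_f = prof.copy()
            prof_f[:n] = prof[n - 1::-1]  # HP contacts in reversed depth order
            rms_f = band_rms.copy()
            rms_f[:n] = band_rms[n - 1::-1]
            flip = synchrony.assign_layers(prof_f, lags, rec, band_rms=rms_f)
        # orientation is inferred from sharp-wave polarity, so the physical
        # labels travel with the waveforms: contact n-1-i (which now records
        # what contact i recorded) keeps i's label, i.e. the oriens and
        # radiatum ends of the probe swap consistently
        for cid, lab in orig.items():
            assert flip[n - 1 - cid] == lab


class TestSpikeFieldCoherence:
    def test_locked_unit_shows_theta_coherence(self, rng):
        from optotheta.io_model import Epoch

        rate = 500.0
        t = np.arange(int(300 * rate)) / rate
        lfp = 50 * np.cos(2 * np.pi * 5.5 * t) + rng.normal(0, 20, t.size)
        lam = 4.0 * np.exp(np.cos(2 * np.pi * 5.5 * t)) / 1.2661
        cand = np.sort(rng.uniform(0, 300, rng.poisson(4.0 * np.e * 300)))
        idx = np.minimum((cand * rate).astype(int), t.size - 1)
        spikes = cand[rng.uniform(size=cand.size) < lam[idx] / (4.0 * np.e)]
        eps = [Epoch(5 * k, 5 * (k + 1)) for k in range(60)]
        c = synchrony.spike_field_coherence(spikes, lfp, rate, eps)
        theta = dsp.BANDS["theta"]
        hf = dsp.BandDef("hf", 40, 100)
        assert c.band_mean(theta) > 5 * c.band_mean(hf)
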
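"""Simplified cochlear model: filterbank, IHC low-pass, rate-level, spikes."""

import numpy as np
import pytest

from phaselock.binaural import BinauralWaveform
from phaselock.manipulations import gammatone_ir
from phaselock.periphery import (
    DEFAULT_FIBER_TYPES,
    NerveResponse,
    PeripheryConfig,
    gammatone_subbands,
    ihc_fir,
    ihc_lowpass,
    load_response,
    make_cf_axis,
    periphery_response,
    rate_level,
    sample_spikes,
    save_response,
    vector_strength,
)
from phaselock.stimuli import Waveform, apply_ramp, erb_number, synth_tone


class TestCfAxis:
    def test_endpoints_inclusive(self):
        cfs = make_cf_axis(50, 125, 8000)
        assert cfs[0] == 125 and cfs[-1] == 8000 and cfs.size == 50

    def test_constant_erb_step(self):
        steps = np.diff(erb_number(make_cf_axis(50, 125, 16000)))
        assert np.allclose(steps, steps[0], atol=1e-9)

    def test_degenerate_two_points(self):
        assert np.allclose(make_cf_axis(2, 125, 8000), [125, 8000])


class TestGammatoneFilterbank:
    def test_on_cf_channel_has_maximal_rms(self):
        cfs = make_cf_axis(20, 125, 8000)
        w = synth_tone(cfs[8], 0.2, 40000, 60)
        sub = gammatone_subbands(w, cfs)
        assert np.argmax(np.sqrt(np.mean(sub**2, axis=1))) == 8

    def test_linearity_sample_exact(self):
        cfs = make_cf_axis(5, 500, 4000)
        a = synth_tone(800, 0.1, 40000, 60)
        b = synth_tone(1700, 0.1, 40000, 55)
        sub_sum = gammatone_subbands(Waveform(a.samples + b.samples, 40000.0), cfs)
        sub_a = gammatone_subbands(a, cfs)
        sub_b = gammatone_subbands(b, cfs)
        assert np.allclose(sub_sum, sub_a + sub_b, atol=1e-12)

    def test_impulse_returns_truncated_ir(self):
        cfs = np.array([1000.0])
        x = np.zeros(4000)
        x[0] = 1.0
        sub = gammatone_subbands(Waveform(x, 40000.0), cfs)
        ir = gammatone_ir(1000.0, 40000.0)
        assert np.allclose(sub[0, : ir.size], ir)
        assert np.allclose(sub[0, ir.size :], 0)

    def test_cf_above_nyquist_rejected(self):
        w = synth_tone(500, 0.1, 10000)
        with pytest.raises(ValueError):
            gammatone_subbands(w, np.array([6000.0]))


class TestIhcLowpass:
    def test_unit_dc_gain_constant_passes(self):
        x = np.full((1, 5000), 0.3)
        y = ihc_lowpass(x, 3000.0, 40000.0)
        assert y[0, -1] == pytest.approx(0.3, rel=1e-6)

    @pytest.mark.parametrize("fc", [320.0, 1000.0, 3000.0])
    def test_magnitude_at_cutoff_near_analytic(self, fc):
        # 7 cascaded identical first-order sections: -3.01 dB each at fc
        h = ihc_fir(fc, 40000.0)
        H = np.fft.rfft(h, 2**17)
        f = np.fft.rfftfreq(2**17, 1 / 40000.0)
        mag_db = 20 * np.log10(np.abs(H[np.argmin(np.abs(f - fc))]))
        assert mag_db == pytest.approx(-21.07, abs=0.5)

    def test_monotone_nonincreasing_magnitude(self):
        h = ihc_fir(1000.0, 40000.0)
        mag = np.abs(np.fft.rfft(h, 2**15))
        # smooth magnitude response decays monotonically (tiny FIR ripple allowed)
        assert np.all(np.diff(mag) <= 1e-6)

    def test_low_cutoff_leaves_only_envelope(self):
        # 2 kHz subband through a 50 Hz cutoff: AC power at 2 kHz crushed
        fs = 40000.0
        t = np.arange(8000) / fs
        x = np.maximum(np.sin(2 * np.pi * 2000 * t), 0)[None, :]
        y = ihc_lowpass(x, 50.0, fs)[:, 4000:]
        spec = np.abs(np.fft.rfft(y[0] - y[0].mean()))
        f = np.fft.rfftfreq(y.shape[1], 1 / fs)
        ac_2k = spec[np.argmin(np.abs(f - 2000))]
        dc = y[0].mean() * y.shape[1]
        assert 20 * np.log10(ac_2k / dc) < -60

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            ihc_lowpass(np.ones((1, 100)), 6000.0, 10000.0)


class TestRateLevel:
    def test_silence_near_zero_rate(self):
        for ft in DEFAULT_FIBER_TYPES:
            assert rate_level(np.zeros(10), ft).max() < 0.05 * ft.max_rate

    def test_95_percent_at_threshold_plus_dynamic_range(self):
        from phaselock.stimuli import P_REF

        for ft in DEFAULT_FIBER_TYPES:
            amp = P_REF * 10 ** ((ft.threshold + ft.dynamic_range) / 20)
            rate = rate_level(np.array([amp]), ft)[0]
            assert rate == pytest.approx(0.95 * 250.0, rel=1e-9)

    def test_high_sr_saturates_before_low_sr(self):
        from phaselock.stimuli import P_REF

        amp = np.array([P_REF * 10 ** (30 / 20)])  # 30 dB SPL drive
        high = rate_level(amp, DEFAULT_FIBER_TYPES[0])[0] / 250
        low = rate_level(amp, DEFAULT_FIBER_TYPES[2])[0] / 250
        assert high > low

    def test_monotone_in_amplitude(self):
        x = np.linspace(0, 1.0, 200)
        r = rate_level(x, DEFAULT_FIBER_TYPES[1])
        assert np.all(np.diff(r) >= 0)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            rate_level(np.array([-0.1]), DEFAULT_FIBER_TYPES[0])


class TestPeripheryResponse:
    def test_silence_gives_near_zero_rates(self, small_periphery):
        w = Waveform(np.zeros(8000), 40000.0)
        resp = periphery_response(w, small_periphery)
        assert resp.rates.max() < 1.0

    def test_shapes_and_bounds(self, small_periphery):
        w = synth_tone(1000, 0.1, 40000, 60)
        resp = periphery_response(w, small_periphery)
        assert resp.shape == (10, 1000, 3)
        assert resp.rates.min() >= 0 and resp.rates.max() <= 250.0

    def test_binaural_input_gives_pair(self, small_periphery):
        w = synth_tone(500, 0.05, 40000, 60)
        pair = periphery_response(BinauralWaveform(w, w.copy()), small_periphery)
        assert len(pair) == 2
        assert np.allclose(pair[0].rates, pair[1].rates)

    def test_phase_locked_oscillation_present_then_absent(self):
        # 1 kHz 60 dB tone: rates oscillate at 1 kHz with a 3000 Hz cutoff,
        # not with a 50 Hz cutoff, yet excitation patterns stay put
        fs = 40000
        tone = apply_ramp(synth_tone(1000, 0.2, fs, 60), "hanning", 0.01)
        profiles = {}
        vs = {}
        for cutoff in (3000.0, 50.0):
            cfg = PeripheryConfig(ihc_cutoff=cutoff)
            resp = periphery_response(tone, cfg)
            ch = np.argmin(np.abs(cfg.cf_axis - 1000))
            vs[cutoff] = vector_strength(resp.rates[ch, 300:, 2], 1000, cfg.fs_out)
            profiles[cutoff] = resp.time_averaged().mean(axis=1)
        assert vs[3000.0] > 0.3
        assert vs[50.0] < 0.05
        assert np.corrcoef(profiles[3000.0], profiles[50.0])[0, 1] > 0.95


class TestSampleSpikes:
    def test_fiber_counts_per_bin(self):
        cfg = PeripheryConfig()
        assert [cfg.n_per_bin(ft) for ft in cfg.fiber_types] == [384, 160, 96]

    def test_zero_rate_zero_counts(self, small_periphery):
        r = NerveResponse(
            np.zeros((10, 500, 3)), small_periphery.cf_axis, 10000.0
        )
        spk = sample_spikes(r, small_periphery, seed=0)
        assert spk.counts.sum() == 0

    def test_counts_within_bounds_and_integer(self, small_periphery):
        rates = np.full((10, 2000, 3), 200.0)
        r = NerveResponse(rates, small_periphery.cf_axis, 10000.0)
        spk = sample_spikes(r, small_periphery, seed=1)
        assert spk.counts.dtype.kind == "i"
        for s, ft in enumerate(small_periphery.fiber_types):
            n = small_periphery.n_per_bin(ft)
            assert spk.counts[:, :, s].min() >= 0
            assert spk.counts[:, :, s].max() <= n

    def test_binomial_moments(self):
        # rate 100 sp/s at 10 kHz, n = 384: mean 3.84, var 3.8016
        cfg = PeripheryConfig()
        rates = np.full((1, 100000, 3), 100.0)
        r = NerveResponse(rates, cfg.cf_axis[:1], 10000.0)
        c = sample_spikes(r, cfg, seed=0).counts[0, :, 0]
        assert c.mean() == pytest.approx(3.84, rel=0.02)
        assert c.var() == pytest.approx(384 * 0.01 * 0.99, rel=0.02)

    def test_identical_seed_bit_identical(self, small_periphery):
        rates = np.full((10, 300, 3), 120.0)
        r = NerveResponse(rates, small_periphery.cf_axis, 10000.0)
        a = sample_spikes(r, small_periphery, seed=7)
        b = sample_spikes(r, small_periphery, seed=7)
        assert np.array_equal(a.counts, b.counts)

    def test_rate_above_sampling_rate_rejected(self, small_periphery):
        rates = np.full((10, 10, 3), 20000.0)
        r = NerveResponse(rates, small_periphery.cf_axis, 10000.0)
        with pytest.raises(ValueError):
            sample_spikes(r, small_periphery, seed=0)

    def test_refractory_reduces_spikes_preserves_shape(self, small_periphery):
        w = synth_tone(500, 0.05, 40000, 60)
        nerve = periphery_response(w, small_periphery)
        g = sample_spikes(nerve, small_periphery, seed=2)
        f = sample_spikes(nerve, small_periphery, seed=2, refractory=True)
        assert f.counts.sum() < g.counts.sum()
        assert f.counts.shape == g.counts.shape


class TestVectorStrength:
    def test_constant_rate_zero(self):
        assert vector_strength(np.ones(10000), 100.0, 10000.0) < 1e-12

    def test_halfwave_rectified_sine_pi_over_4(self):
        fs, f = 100000.0, 100.0
        t = np.arange(int(fs)) / fs
        vs = vector_strength(np.maximum(np.sin(2 * np.pi * f * t), 0), f, fs)
        assert vs == pytest.approx(np.pi / 4, abs=1e-3)

    def test_raised_cosine_half(self):
        fs, f = 100000.0, 100.0
        t = np.arange(int(fs)) / fs
        vs = vector_strength(1 + np.cos(2 * np.pi * f * t), f, fs)
        assert vs == pytest.approx(0.5, abs=1e-3)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            vector_strength(np.zeros(100), 10.0, 1000.0)


def test_hdf5_round_trip(tmp_path, small_periphery):
    w = synth_tone(800, 0.05, 40000, 60)
    nerve = periphery_response(w, small_periphery)
    spk = sample_spikes(nerve, small_periphery, seed=3)
    p1, p2 = tmp_path / "rates.h5", tmp_path / "counts.h5"
    save_response(p1, nerve)
    save_response(p2, spk)
    nerve2 = load_response(p1)
    spk2 = load_response(p2)
    assert np.allclose(nerve2.rates, nerve.rates)
    assert nerve2.ihc_cutoff == small_periphery.ihc_cutoff
    assert np.array_equal(spk2.counts, spk.counts)
    assert spk2.seed == 3
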
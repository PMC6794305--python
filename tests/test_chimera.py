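"""Band-wise decomposition, chimera synthesis and WAV plumbing."""

import numpy as np
import pytest
from scipy.signal import butter, sosfiltfilt, welch

from emocert import chimera as ch

RATE = 44100


def _tone(freq, dur=1.0, amp=0.5, rate=RATE):
    t = np.arange(int(rate * dur)) / rate
    return ch.AudioExcerpt(amp * np.sin(2 * np.pi * freq * t), rate)


def _am_tone(carrier=1000.0, fm=4.0, depth=0.8, dur=3.0, amp=0.5, rate=RATE):
    t = np.arange(int(rate * dur)) / rate
    mod = (1 + depth * np.cos(2 * np.pi * fm * t)) / (1 + depth)
    return ch.AudioExcerpt(amp * mod * np.cos(2 * np.pi * carrier * t), rate), amp * mod


def _interior(n, frac=0.8):
    cut = int(n * (1 - frac) / 2)
    return slice(cut, n - cut)


class TestFilterbank:
    def test_single_band_spans_range(self):
        fb = ch.design_filterbank(1, 80, 4400, 44100)
        assert np.allclose(fb.edges, [80, 4400])

    def test_two_band_edge_is_geometric_midpoint(self):
        fb = ch.design_filterbank(2, 80, 4400, 44100)
        assert fb.edges[1] == pytest.approx(np.sqrt(80 * 4400), abs=1e-9)
        assert fb.edges[1] == pytest.approx(593.30, abs=0.01)

    def test_log_spacing_constant_ratio(self):
        fb = ch.design_filterbank(64, 80, 4400, 44100)
        assert fb.edges.size == 65
        ratios = fb.edges[1:] / fb.edges[:-1]
        assert np.allclose(ratios, (4400 / 80) ** (1 / 64))
        assert np.all(np.diff(fb.edges) > 0)

    def test_invalid_parameters(self):
        with pytest.raises(ch.InvalidFilterbankError):
            ch.design_filterbank(4, 80, 23000, 44100)  # beyond Nyquist
        with pytest.raises(ValueError):
            ch.design_filterbank(0, 80, 4400, 44100)
        with pytest.raises(ch.InvalidFilterbankError):
            ch.design_filterbank(4, 4400, 80, 44100)


class TestDecompose:
    def test_pure_tone_envelope_and_carrier(self):
        x = _tone(1000.0, dur=1.0, amp=0.5)
        dec = ch.decompose(x, ch.design_filterbank(1))
        sl = _interior(x.samples.size)
        assert np.allclose(dec.env[0][sl], 0.5, atol=1e-3)
        # fine structure is a unit-amplitude sinusoid at the carrier frequency
        assert np.max(np.abs(dec.fis[0][sl])) == pytest.approx(1.0, abs=1e-3)
        report = ch.stimulus_report(ch.AudioExcerpt(dec.fis[0], RATE))
        assert report["peak_freq"] == pytest.approx(1000.0, abs=2.0)

    def test_am_tone_envelope_matches_rectify_lowpass_oracle(self):
        x, _ = _am_tone()
        dec = ch.decompose(x, ch.design_filterbank(1))
        # independent oracle: full-wave rectification + 50 Hz low-pass
        sos = butter(4, 50 / (RATE / 2), btype="low", output="sos")
        oracle = sosfiltfilt(sos, np.abs(x.samples)) * np.pi / 2
        sl = _interior(x.samples.size)
        err = np.sqrt(np.mean((dec.env[0][sl] - oracle[sl]) ** 2))
        assert err / np.sqrt(np.mean(oracle[sl] ** 2)) < 0.05
        assert np.corrcoef(dec.env[0][sl], oracle[sl])[0, 1] > 0.99

    def test_full_scale_decomposition_shapes(self):
        t = np.arange(int(RATE * 3.0)) / RATE
        x = ch.AudioExcerpt(0.3 * np.sin(2 * np.pi * 440 * t), RATE)
        dec = ch.decompose(x, ch.design_filterbank(64))
        assert dec.env.shape == dec.fis.shape == (64, 132300)
        assert np.all(dec.env >= 0)

    def test_silent_input_rejected(self):
        with pytest.raises(ch.EmptySignalError):
            ch.decompose(ch.AudioExcerpt(np.zeros(1000), RATE), ch.design_filterbank(2))
        with pytest.raises(ch.EmptySignalError):
            ch.decompose(ch.AudioExcerpt(np.array([]), RATE), ch.design_filterbank(2))

    def test_band_products_sum_to_bandlimited_signal(self, rng):
        # |z| cos(arg z) = Re z per band, and the complementary band windows
        # telescope to the band-limit window, so the identity is exact
        x = ch.AudioExcerpt(0.2 * rng.standard_normal(RATE // 4), RATE)
        fb = ch.design_filterbank(4)
        dec = ch.decompose(x, fb)
        ref = ch.bandlimit(x)
        assert np.allclose(dec.reconstruct(), ref.samples, atol=1e-12)


class TestBandlimit:
    def test_stopband_attenuation_on_white_noise(self, rng):
        x = ch.AudioExcerpt(0.1 * rng.standard_normal(RATE * 3), RATE)
        y = ch.bandlimit(x)
        f, p_in = welch(x.samples, RATE, nperseg=16384)
        _, p_out = welch(y.samples, RATE, nperseg=16384)
        inband = np.mean(p_out[(f > 200) & (f < 4000)]) / np.mean(p_in[(f > 200) & (f < 4000)])
        for f0 in (40.0, 8800.0):
            i = np.argmin(np.abs(f - f0))
            assert 10 * np.log10(p_out[i] / p_in[i] / inband) <= -40.0

    def test_inband_tone_passthrough(self):
        x = _tone(1000.0, dur=1.0)
        y = ch.bandlimit(x)
        sl = _interior(x.samples.size)
        gain = np.sqrt(np.mean(y.samples[sl] ** 2) / np.mean(x.samples[sl] ** 2))
        assert gain == pytest.approx(1.0, abs=0.05)

    def test_stopband_tone_suppressed(self):
        x = _tone(10.0, dur=2.0)
        y = ch.bandlimit(x)
        assert y.rms < 0.01 * x.rms

    def test_invalid_band(self):
        x = _tone(1000.0, dur=0.2)
        with pytest.raises(ValueError):
            ch.bandlimit(x, 4400, 80)


class TestChimera:
    @pytest.mark.parametrize("nb", [1, 2, 4, 8, 16])
    def test_self_chimera_reconstruction(self, nb, rng):
        # short excerpt keeps the property test cheap (the full 3-s, 64-band
        # run lives in the acceptance suite); pre-filtering well inside the
        # 80-4400 Hz range avoids edge-energy ambiguity in the reference
        x = ch.AudioExcerpt(0.2 * rng.standard_normal(RATE), RATE, emotion="happy")
        x = ch.bandlimit(x, 150, 3500)
        out = ch.synthesize_chimera(x, x, ch.ChimeraSpec("FIS", nb=nb))
        ref = ch.bandlimit(x)
        sl = _interior(x.samples.size)
        err = np.sqrt(np.mean((out.samples[sl] - ref.samples[sl]) ** 2))
        assert err / np.sqrt(np.mean(ref.samples[sl] ** 2)) < 0.02

    def test_cross_chimera_carrier_and_envelope(self):
        am, modulator = _am_tone(carrier=1000.0)
        steady = _tone(2000.0, dur=3.0, amp=0.5)
        steady.emotion = "sad"
        am.emotion = "happy"
        # envelopes from the AM tone, fine structure from the steady tone
        out = ch.synthesize_chimera(am, steady, ch.ChimeraSpec("ENV", nb=1))
        assert out.emotion == "happy"
        assert ch.stimulus_report(out)["peak_freq"] == pytest.approx(2000.0, abs=5.0)
        env = np.abs(out.samples)
        sos = butter(4, 50 / (RATE / 2), btype="low", output="sos")
        env = sosfiltfilt(sos, env)
        sl = _interior(out.samples.size)
        assert np.corrcoef(env[sl], modulator[sl])[0, 1] > 0.9

    def test_swap_sources_with_flipped_carrier_is_identical(self, rng):
        a = ch.bandlimit(ch.AudioExcerpt(0.2 * rng.standard_normal(RATE // 2), RATE))
        b = ch.bandlimit(ch.AudioExcerpt(0.2 * rng.standard_normal(RATE // 2), RATE))
        out1 = ch.synthesize_chimera(a, b, ch.ChimeraSpec("FIS", nb=4))
        out2 = ch.synthesize_chimera(b, a, ch.ChimeraSpec("ENV", nb=4))
        assert np.allclose(out1.samples, out2.samples)

    def test_mismatched_inputs_rejected(self):
        a = _tone(440.0, dur=1.0)
        b = _tone(440.0, dur=0.5)
        with pytest.raises(ValueError):
            ch.synthesize_chimera(a, b, ch.ChimeraSpec("FIS", nb=2))


class TestStimulusReport:
    def test_tone_peak_within_one_bin(self):
        rep = ch.stimulus_report(_tone(1000.0, dur=1.0))
        assert abs(rep["peak_freq"] - 1000.0) <= 1.1  # 1 Hz bins for 1 s signal
        ridge = rep["freqs"][np.argmax(rep["sxx"], axis=0)]
        assert np.allclose(ridge, 1000.0, atol=rep["freqs"][1] - rep["freqs"][0])

    def test_linear_sweep_monotone_ridge(self):
        t = np.arange(int(RATE * 3.0)) / RATE
        sweep = np.sin(2 * np.pi * (440 * t + (7040 - 440) / (2 * 3.0) * t**2))
        rep = ch.stimulus_report(ch.AudioExcerpt(0.5 * sweep, RATE), nperseg=2048)
        ridge = rep["freqs"][np.argmax(rep["sxx"], axis=0)]
        assert np.all(np.diff(ridge[2:-2]) >= 0)

    def test_silence_all_zero(self):
        rep = ch.stimulus_report(ch.AudioExcerpt(np.zeros(4096), RATE))
        assert not np.any(rep["sxx"]) and not np.any(rep["spectrum"])
        assert rep["peak_freq"] == 0.0


class TestWavIO:
    @pytest.mark.parametrize("subtype,atol", [("pcm16", 1e-4), ("float32", 1e-7)])
    def test_roundtrip(self, tmp_path, subtype, atol):
        x = _tone(440.0, dur=0.1)
        x.emotion = "happy"
        p = tmp_path / "t.wav"
        ch.write_wav(p, x, subtype=subtype)
        y = ch.read_wav(p, emotion="happy")
        assert y.rate == RATE and y.emotion == "happy"
        assert np.allclose(y.samples, x.samples, atol=atol)

    def test_config_roundtrip(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("filterbank:\n  nb: 8\n  f_lo: 80\n  f_hi: 4400\n")
        cfg = ch.load_config(p)
        assert cfg["filterbank"]["nb"] == 8
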
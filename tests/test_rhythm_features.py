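"""Envelope, envelope spectrum, EMD, IMF statistics and modulation spectra."""

from __future__ import annotations

import numpy as np
import pytest

from prosodyml.corpus_io import Utterance
from prosodyml.rhythm_features import (
    EnvelopeSignal,
    FeatureError,
    RhythmConfig,
    emd,
    env_spectrum_features,
    extract_envelope,
    imf_features,
    rhythm_vector,
    tms_features,
)
from prosodyml.synthetic_speech import SynthesisParams

CFG = RhythmConfig()


def _am_tone(mod_hz=4.0, carrier=1000.0, duration=2.0, sr=16000, depth=1.0):
    t = np.arange(int(duration * sr)) / sr
    x = (1 + depth * np.sin(2 * np.pi * mod_hz * t)) * np.sin(2 * np.pi * carrier * t)
    return Utterance("am", 0.4 * x / np.max(np.abs(x)), sr)


class TestExtractEnvelope:
    def test_pure_tone_constant_envelope(self):
        t = np.arange(16000) / 16000
        utt = Utterance("tone", 0.5 * np.sin(2 * np.pi * 1000 * t), 16000)
        env = extract_envelope(utt, CFG).values
        core = env[20:-20]  # away from filter edges
        assert np.max(np.abs(core - 0.5)) / 0.5 < 0.02

    def test_am_tone_has_four_maxima_per_second(self):
        env = extract_envelope(_am_tone(), CFG).values
        interior = env[1:-1]
        peaks = np.sum((interior > env[:-2]) & (interior > env[2:])
                       & (interior > 0.5 * env.max()))
        assert abs(peaks / 2.0 - 4.0) <= 1.0  # 4 maxima/s over 2 s

    def test_silence_maps_to_zero(self):
        env = extract_envelope(Utterance("sil", np.zeros(8000), 16000), CFG).values
        assert np.allclose(env, 0.0)

    def test_envelope_rate_and_nonnegativity(self):
        env = extract_envelope(_am_tone(duration=1.7), CFG)
        assert env.env_rate == CFG.env_rate
        assert env.values.size == pytest.approx(1.7 * CFG.env_rate, abs=2)
        assert np.all(env.values >= 0)


class TestEnvSpectrum:
    def test_sinusoid_peaks_in_4hz_bin(self):
        t = np.arange(300) / 100.0
        env = EnvelopeSignal(values=1.0 + 0.8 * np.sin(2 * np.pi * 4.0 * t), env_rate=100.0)
        feats = env_spectrum_features(env, CFG)
        # 0.25 Hz bins: 4 Hz lies on the bin 15/16 boundary
        assert int(np.argmax(feats)) in (15, 16)

    def test_constant_envelope_all_floor(self):
        env = EnvelopeSignal(values=np.full(200, 3.3), env_rate=100.0)
        feats = env_spectrum_features(env, CFG)
        assert np.allclose(feats, np.log10(1e-12))

    def test_log_scaling_identity(self):
        t = np.arange(400) / 100.0
        base = 1.0 + 0.5 * np.sin(2 * np.pi * 3.1 * t)
        f1 = env_spectrum_features(EnvelopeSignal(base, 100.0), CFG)
        f10 = env_spectrum_features(EnvelopeSignal(10 * base, 100.0), CFG)
        strong = f1 > -6  # bins clearly above the floor
        np.testing.assert_allclose(f10[strong] - f1[strong], 2.0, atol=1e-6)


class TestEMD:
    def test_two_component_separation(self):
        t = np.arange(300) / 100.0
        x = np.sin(2 * np.pi * 6 * t) + np.sin(2 * np.pi * 1 * t)
        imfs, residual = emd(x, CFG)
        assert len(imfs) >= 2

        def dom_freq(m):
            spec = np.abs(np.fft.rfft(m)) ** 2
            freqs = np.fft.rfftfreq(m.size, d=0.01)
            return freqs[1 + np.argmax(spec[1:])]

        assert abs(dom_freq(imfs[0]) - 6.0) / 6.0 < 0.2
        assert abs(dom_freq(imfs[1]) - 1.0) / 1.0 < 0.2

    def test_monotone_ramp_no_imfs(self):
        imfs, residual = emd(np.linspace(0, 1, 100), CFG)
        assert imfs == []
        np.testing.assert_array_equal(residual, np.linspace(0, 1, 100))

    def test_reconstruction_identity_random_envelopes(self):
        rng = np.random.default_rng(42)
        from scipy.signal import sosfiltfilt, butter
        sos = butter(4, 0.2, output="sos")
        for _ in range(100):
            x = sosfiltfilt(sos, rng.standard_normal(rng.integers(150, 350)))
            imfs, residual = emd(x, CFG)
            recon = residual + (np.sum(imfs, axis=0) if imfs else 0.0)
            err = np.linalg.norm(recon - x) / (np.linalg.norm(x) + 1e-30)
            assert err < 1e-6

    def test_nan_rejected(self):
        with pytest.raises(FeatureError):
            emd(np.array([0.0, np.nan, 1.0, 0.0]), CFG)


class TestIMFFeatures:
    def test_pure_sinusoid_statistics(self):
        t = np.arange(300) / 100.0
        m = np.sin(2 * np.pi * 4.0 * t)
        feats = imf_features([m], np.zeros_like(m), CFG)
        mean_if, dom, zcr = feats[4], feats[6], feats[7]
        assert 3.6 <= mean_if <= 4.4
        assert abs(dom - 4.0) < 0.5
        assert 7.2 <= zcr <= 8.8

    def test_missing_imfs_padded_with_zeros(self):
        t = np.arange(200) / 100.0
        imfs = [np.sin(2 * np.pi * 5 * t), np.sin(2 * np.pi * 1 * t)]
        feats = imf_features(imfs, np.ones(200), CFG)
        assert feats.shape == (48,)
        assert np.allclose(feats[16:], 0.0)

    def test_energy_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        x = EnvelopeSignal(np.abs(np.cumsum(rng.standard_normal(250)) + 10), 100.0)
        imfs, residual = emd(x, CFG)
        feats = imf_features(imfs, residual, CFG)
        fracs = feats[1::8][: len(imfs)]
        res_frac = float(np.sum(residual**2)) / (
            sum(float(np.sum(m**2)) for m in imfs) + float(np.sum(residual**2)) + 1e-30
        )
        assert np.sum(fracs) + res_frac == pytest.approx(1.0, abs=1e-9)


class TestTMS:
    def _am_noise(self, seed=0, mod_hz=4.0, duration=2.0, sr=16000):
        rng = np.random.default_rng(seed)
        t = np.arange(int(duration * sr)) / sr
        x = (1 + np.sin(2 * np.pi * mod_hz * t)) * rng.standard_normal(t.size)
        return Utterance("amn", 0.3 * x / np.max(np.abs(x)), sr)

    def test_am_noise_peaks_at_modulation_rate(self):
        feats = tms_features(self._am_noise(), CFG).reshape(CFG.tms_bands, CFG.tms_mod_bins)
        for band in range(CFG.tms_bands):
            # 1 Hz bins: 4 Hz lies on the bin 3/4 boundary
            assert int(np.argmax(feats[band])) in (3, 4)

    def test_unit_sum_and_gain_invariance(self):
        utt = self._am_noise(seed=3)
        f1 = tms_features(utt, CFG)
        assert np.sum(f1) == pytest.approx(1.0, abs=1e-9)
        half = Utterance("half", 0.5 * utt.samples, utt.sample_rate)
        np.testing.assert_allclose(tms_features(half, CFG), f1, atol=1e-9)

    def test_low_sample_rate_rejected(self):
        utt = Utterance("lowsr", np.random.default_rng(0).standard_normal(4000), 8000)
        with pytest.raises(FeatureError, match="band edge"):
            tms_features(utt, CFG)


class TestRhythmVector:
    def test_dimensionality_contract(self, en_speaker):
        vec = rhythm_vector(en_speaker, CFG)
        assert vec.values.shape == (8640,)
        assert CFG.per_utterance_dim == 432
        assert vec.layout["blocks"] == {"ENV": 64, "IMF": 48, "TMS": 320}

    def test_determinism(self, en_speaker):
        a = rhythm_vector(en_speaker, CFG).values
        b = rhythm_vector(en_speaker, CFG).values
        np.testing.assert_array_equal(a, b)

    def test_wrong_utterance_count_rejected(self, en_speaker):
        import dataclasses
        broken = dataclasses.replace(en_speaker)
        broken.utterances = en_speaker.utterances[:19]
        with pytest.raises(Exception):
            rhythm_vector(broken, CFG)

    def test_env_argmax_tracks_syllable_rate(self):
        """Faster speech shifts the speaker-level envelope-spectrum peak upward."""
        from prosodyml.synthetic_speech import generate_speaker

        hits = total = 0
        band = slice(8, 64)  # >= 2 Hz, away from the utterance-scale bins
        for seed in range(10):
            peaks = {}
            for rate in (4.0, 5.0):
                params = SynthesisParams(base_syllable_rate=rate)
                spk = generate_speaker(f"s{seed}", "TD", "YUE", params=params,
                                       seed=seed)
                spec = np.mean(
                    [env_spectrum_features(extract_envelope(u, CFG), CFG)
                     for u in spk.utterances], axis=0)
                peaks[rate] = np.argmax(spec[band])
            total += 1
            hits += peaks[5.0] > peaks[4.0]
        assert hits / total >= 0.9
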
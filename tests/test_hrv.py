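import numpy as np
import pytest

from apneascreen.hrv import (
    HRV_FEATURE_NAMES,
    cepstrum20,
    dfa,
    filterbank,
    hrv_features,
    hrv_spectral_features,
    periodogram,
    real_cepstrum,
)
from apneascreen.rqa import RQA_FEATURE_NAMES

from conftest import modulated_frame
from oracles import dft_power_direct, real_cepstrum_direct


class TestPeriodogram:
    def test_constant_sequence_is_dc_only(self):
        p = periodogram(np.full(16, 3.0))
        assert p.power[0] == pytest.approx(16 * 9.0)
        np.testing.assert_allclose(p.power[1:], 0.0, atol=1e-12)

    def test_unit_impulse_flat_spectrum(self):
        x = np.zeros(8)
        x[0] = 1.0
        np.testing.assert_allclose(periodogram(x).power, 1 / 8)

    def test_cosine_matches_direct_dft(self):
        n = 200
        x = np.cos(2 * np.pi * 0.1 * np.arange(n))
        p = periodogram(x)
        direct = dft_power_direct(x)
        np.testing.assert_allclose(p.power, direct, rtol=1e-9, atol=1e-9)
        assert np.argmax(p.power) == 20  # 0.1 cycles/sample

    def test_empty_input_fails(self):
        with pytest.raises(ValueError):
            periodogram(np.array([]))

    @pytest.mark.parametrize("seed", range(3))
    def test_parseval(self, seed):
        """Sum of S(k) over the full DFT equals the signal energy / N."""
        x = np.random.default_rng(seed).standard_normal(128)
        p = periodogram(x)
        # full-spectrum sum: double the positive bins except DC and Nyquist
        full = p.power[0] + p.power[-1] + 2 * p.power[1:-1].sum()
        np.testing.assert_allclose(full, (x**2).sum(), rtol=1e-9)


class TestFilterbank:
    def test_flat_spectrum_uniform_bands(self):
        x = np.zeros(400)
        x[0] = 1.0  # impulse -> white spectrum
        fb = filterbank(periodogram(x), 20)
        np.testing.assert_allclose(fb.values, np.log(1 / 20), atol=0.02)

    def test_all_power_in_first_band(self):
        p = periodogram(np.sin(2 * np.pi * 0.01 * np.arange(500)))
        fb = filterbank(p, 10)  # band 1 = (0, 0.05] cycles/sample
        assert fb.values[0] == pytest.approx(0.0, abs=1e-6)
        assert (fb.values[1:] < np.log(1e-6)).all()

    def test_tone_lands_in_its_band(self):
        # band 7 of 34 over (0, 0.5]: center ~ (6.5/34)*0.5
        f = 6.5 / 34 * 0.5
        x = np.sin(2 * np.pi * f * np.arange(600))
        fb = filterbank(periodogram(x), 34)
        assert int(np.argmax(fb.values)) == 6

    @pytest.mark.parametrize("seed", range(3))
    def test_exp_values_sum_to_one(self, seed):
        x = np.random.default_rng(seed).standard_normal(300)
        fb = filterbank(periodogram(x), 17)
        assert np.exp(fb.values).sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_power_fails(self):
        with pytest.raises(ValueError, match="zero-power"):
            filterbank(periodogram(np.full(64, 5.0)), 10)  # DC only


class TestHrvSpectral:
    def test_cvhr_oscillation_dominates_low_bands(self, cvhr_frame):
        v = hrv_spectral_features(cvhr_frame).values
        assert v[:2].max() > v[4:].max() + 5

    def test_rsa_modulation_peaks_at_band_17(self):
        frame = modulated_frame(0.25, depth=0.05)
        v = hrv_spectral_features(frame).values
        assert int(np.argmax(v)) + 1 == 17

    def test_output_length_34(self, cvhr_frame):
        assert hrv_spectral_features(cvhr_frame).values.size == 34

    def test_too_few_beats_flagged(self):
        frame = modulated_frame(0.02)
        frame.rr_segment.intervals = frame.rr_segment.intervals[:10]
        frame.rr_segment.beat_times = frame.rr_segment.beat_times[:10]
        with pytest.raises(ValueError, match="fewer than 64"):
            hrv_spectral_features(frame)


class TestCepstrum:
    def test_impulse_has_zero_cepstrum(self):
        x = np.zeros(64)
        x[0] = 1.0
        np.testing.assert_allclose(real_cepstrum(x), 0.0, atol=1e-12)

    def test_gain_only_moves_quefrency_zero(self):
        x = np.random.default_rng(1).standard_normal(256)
        c1, c2 = real_cepstrum(x), real_cepstrum(2 * x)
        assert c2[0] - c1[0] == pytest.approx(np.log(2), abs=1e-12)
        np.testing.assert_allclose(c1[1:20], c2[1:20], atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_transform_oracle(self, seed):
        x = np.random.default_rng(seed).standard_normal(48)
        np.testing.assert_allclose(
            real_cepstrum(x), real_cepstrum_direct(x), rtol=1e-9, atol=1e-9
        )

    def test_frame_cepstrum_has_20_coefficients(self, cvhr_frame):
        assert cepstrum20(cvhr_frame).size == 20


class TestDfa:
    def test_white_noise_alpha_half(self):
        rng = np.random.default_rng(0)
        alphas = [dfa(rng.standard_normal(5000)).alpha1 for _ in range(20)]
        assert np.mean(alphas) == pytest.approx(0.5, abs=0.08)

    def test_brownian_alpha_three_halves(self):
        rng = np.random.default_rng(1)
        alphas = [
            dfa(np.cumsum(rng.standard_normal(5000)),
                short_range=(10, 194), long_range=None).alpha1
            for _ in range(10)
        ]
        assert np.mean(alphas) == pytest.approx(1.5, abs=0.1)

    def test_pink_noise_alpha_one(self):
        rng = np.random.default_rng(2)

        def pink(n):
            f = np.fft.rfftfreq(n, 1.0)
            f[0] = np.inf
            amp = 1 / np.sqrt(f)
            ph = rng.uniform(0, 2 * np.pi, f.size)
            return np.fft.irfft(amp * np.exp(1j * ph), n)

        alphas = [
            dfa(pink(5000), short_range=(10, 194), long_range=None).alpha1
            for _ in range(10)
        ]
        assert np.mean(alphas) == pytest.approx(1.0, abs=0.1)

    @pytest.mark.parametrize("a,b", [(3.0, 0.0), (0.5, 2.0), (-1.0, 0.1)])
    def test_affine_invariance(self, a, b):
        x = np.random.default_rng(3).standard_normal(2000)
        d0, d1 = dfa(x), dfa(a * x + b)
        assert d1.alpha1 == pytest.approx(d0.alpha1, abs=1e-9)
        assert d1.alpha2 == pytest.approx(d0.alpha2, abs=1e-9)

    def test_alpha2_absent_for_short_series(self):
        x = np.random.default_rng(4).standard_normal(120)
        assert dfa(x).alpha2 is None

    def test_too_short_series_fails(self):
        with pytest.raises(ValueError, match="100"):
            dfa(np.random.default_rng(5).standard_normal(50))


def test_frame_yields_73_named_hrv_features(cvhr_frame):
    from apneascreen.rqa import rqa_features

    rqa_vals = rqa_features(cvhr_frame, m=8, tau=5)
    feats = hrv_features(cvhr_frame, rqa_values=np.array(
        [rqa_vals[n] for n in RQA_FEATURE_NAMES]))
    assert len(feats) == 73
    assert set(feats) == set(HRV_FEATURE_NAMES) | set(RQA_FEATURE_NAMES)
    assert all(np.isfinite(v) for v in feats.values())
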
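import numpy as np
import pytest
import pywt

from vfshock.exceptions import BandError, LengthError
from vfshock.predictor_bank import (
    FEATURE_NAMES,
    HOMOGENEITY_DEGREE,
    Spectrum,
    amplitude_features,
    compute_all,
    compute_spectrum,
    nonlinear_features,
    slope_features,
    sneo,
    spectral_entropy,
    spectral_features,
    wavelet_energy_distribution,
    wavelet_entropy,
)
from vfshock.signal_io import AnalysisWindow, extract_preshock_window
from vfshock.synthetic_vf import VfGenParams, generate_vf

FS = 250.0


def _tone(freq, duration=5.0, amplitude=1.0, fs=FS):
    t = np.arange(int(round(duration * fs))) / fs
    return amplitude * np.sin(2 * np.pi * freq * t)


def _bin_centred_tone(bin_index, duration=5.0, amplitude=1.0, fs=FS,
                      nfft=2048):
    return _tone(bin_index * fs / nfft, duration, amplitude, fs)


@pytest.fixture(scope="module")
def vf_window():
    record = generate_vf(VfGenParams(seed=3, amplitude=220, irregularity=0.6))
    return extract_preshock_window(record, record.shocks[0], 5.0)


class TestAmplitudeFeatures:
    def test_square_wave(self):
        x = 50.0 * np.where(_tone(2.0) >= 0, 1.0, -1.0)
        f = amplitude_features(x, FS)
        assert f["AR"] == pytest.approx(100.0)
        assert f["MA"] == pytest.approx(50.0)

    def test_sine_rms(self):
        f = amplitude_features(_tone(5.0, amplitude=100.0), FS)
        assert f["RMS1"] == pytest.approx(100.0 / np.sqrt(2), rel=1e-3)
        assert f["RMS2"] == pytest.approx(f["RMS1"], rel=1e-6)

    def test_constant_zero(self):
        f = amplitude_features(np.zeros(500), FS)
        assert all(v == 0.0 for v in f.values())

    def test_ppa_subwindow_average(self):
        # 1st second swings ±50 µV, 2nd second ±25 µV
        x = np.concatenate([50 * np.sign(_tone(5.0, 1.0)),
                            25 * np.sign(_tone(5.0, 1.0))])
        f = amplitude_features(x, FS)
        assert f["PPA"] == pytest.approx(75.0)
        assert f["AR"] == pytest.approx(100.0)

    def test_signint_units(self):
        x = np.full(500, 10.0)
        f = amplitude_features(x, FS)
        assert f["SignInt"] == pytest.approx(10.0 * 500 / FS)

    def test_empty_window(self):
        with pytest.raises(LengthError):
            amplitude_features(np.array([]), FS)


class TestSlopeFeatures:
    def test_ramp(self):
        x = np.arange(500, dtype=float)  # 1 µV per sample
        f = slope_features(x, FS)
        assert f["MS"] == pytest.approx(250.0)
        assert f["MdS"] == pytest.approx(250.0)

    def test_constant(self):
        f = slope_features(np.full(100, 3.0), FS)
        assert f["MS"] == 0.0 and f["MdS"] == 0.0

    def test_sine_mean_slope_identity(self):
        # mean |dx/dt| of A·sin(2πft) is 4fA
        freq, amp = 4.0, 100.0
        f = slope_features(_tone(freq, duration=10.0, amplitude=amp), FS)
        assert f["MS"] == pytest.approx(4 * freq * amp, rel=0.02)


class TestSneo:
    def test_constant(self):
        assert sneo(np.full(100, 7.0), FS) == pytest.approx(0.0)

    def test_tone_energy_identity(self):
        # psi of a tone is exactly A² sin²(2πf/fs)
        freq, amp = 5.0, 100.0
        got = sneo(_tone(freq, amplitude=amp), FS)
        assert got == pytest.approx(amp**2 * np.sin(2 * np.pi * freq / FS) ** 2,
                                    rel=0.01)

    def test_white_noise_variance(self):
        x = np.random.default_rng(0).normal(0, 30.0, 50_000)
        assert sneo(x, FS) == pytest.approx(30.0**2, rel=0.05)

    def test_too_short(self):
        with pytest.raises(LengthError):
            sneo(np.array([1.0, 2.0]), FS)


class TestSpectrum:
    def test_tone_peak_amplitude_and_location(self):
        amp = 200.0
        x = _bin_centred_tone(41, amplitude=amp)  # ≈ 5.005 Hz
        s = compute_spectrum(x, FS)
        k = np.argmax(s.power)
        assert k == 41
        assert s.amplitude[k] == pytest.approx(amp, rel=0.05)

    def test_two_tones(self):
        x = _bin_centred_tone(33) + _bin_centred_tone(66)  # ≈ 4 and 8 Hz
        s = compute_spectrum(x, FS)
        top2 = np.argsort(s.power)[-2:]
        assert set(top2) == {33, 66}

    def test_power_is_amplitude_squared(self, vf_window):
        s = compute_spectrum(vf_window.samples, FS)
        assert np.allclose(s.power, s.amplitude**2)

    def test_too_long_window(self):
        with pytest.raises(LengthError):
            compute_spectrum(np.zeros(3000), FS)


def _flat_spectrum(band=(2.0, 30.0), fs=FS, level=10.0):
    freqs = np.fft.rfftfreq(2048, 1 / fs)
    amplitude = np.where((freqs >= band[0]) & (freqs <= band[1]), level, 0.0)
    return Spectrum(freqs=freqs, amplitude=amplitude, power=amplitude**2,
                    fs=fs)


class TestSpectralFeatures:
    def test_single_tone(self):
        amp, k = 150.0, 41
        f0 = k * FS / 2048
        s = compute_spectrum(_bin_centred_tone(k, amplitude=amp), FS)
        f = spectral_features(s)
        assert f["PF"] == pytest.approx(f0, abs=FS / 2048)
        assert f["CF"] == pytest.approx(f0, abs=0.25)
        assert f["SFM"] < 0.1
        assert f["MP"] == pytest.approx(amp**2, rel=0.1)
        # AMSA is the window-leakage-weighted A·f0; proportionality in A and
        # f0 is the invariant the spectral sum must satisfy
        f2 = spectral_features(
            compute_spectrum(_bin_centred_tone(k, amplitude=2 * amp), FS))
        assert f2["AMSA"] == pytest.approx(2 * f["AMSA"], rel=1e-6)
        f8 = spectral_features(
            compute_spectrum(_bin_centred_tone(2 * k, amplitude=amp), FS))
        assert f8["AMSA"] == pytest.approx(2 * f["AMSA"], rel=0.05)

    def test_flat_spectrum(self):
        s = _flat_spectrum()
        f = spectral_features(s)
        freqs, _, _ = s.band()
        assert f["SFM"] == pytest.approx(1.0)
        assert f["CF"] == pytest.approx(freqs.mean())
        assert spectral_entropy(s) == pytest.approx(1.0)

    def test_dc_only_input(self):
        # the band starts above 0 Hz, so only window-leakage skirts remain:
        # negligible next to any in-band tone of the same amplitude
        s = compute_spectrum(np.full(1250, 100.0), FS)
        f = spectral_features(s)
        tone = spectral_features(
            compute_spectrum(_bin_centred_tone(41, amplitude=100.0), FS))
        assert f["AMSA"] < 0.01 * tone["AMSA"]
        assert f["ENRG"] < 0.01 * tone["ENRG"]

    def test_empty_band(self):
        with pytest.raises(BandError):
            _flat_spectrum().band((40.0, 30.0))


class TestSpectralEntropy:
    def test_single_bin(self):
        freqs = np.fft.rfftfreq(2048, 1 / FS)
        amp = np.zeros_like(freqs)
        amp[41] = 100.0
        s = Spectrum(freqs=freqs, amplitude=amp, power=amp**2, fs=FS)
        assert spectral_entropy(s) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_in_tone_snr(self, rng):
        noise = rng.normal(0, 1.0, 1250)
        sens = []
        for tone_amp in (0.0, 5.0, 50.0):
            s = compute_spectrum(noise + _tone(6.0, amplitude=tone_amp), FS)
            sens.append(spectral_entropy(s))
        assert sens[0] > sens[1] > sens[2] > 0.0


class TestNonlinearFeatures:
    def test_white_noise_scaling(self):
        x = np.random.default_rng(2).standard_normal(10_000)
        f = nonlinear_features(x, FS)
        assert f["Hu"] == pytest.approx(0.5, abs=0.05)
        assert f["DFA1"] == pytest.approx(0.5, abs=0.05)
        assert f["DFA2"] == pytest.approx(0.5, abs=0.05)

    def test_random_walk_dfa(self):
        x = np.cumsum(np.random.default_rng(3).standard_normal(10_000))
        f = nonlinear_features(x, FS)
        assert f["DFA1"] == pytest.approx(1.5, abs=0.1)

    def test_constant_flagged(self):
        f = nonlinear_features(np.full(1000, 5.0), FS)
        assert f["MSI"] == 0.0
        assert np.isnan(f["Hu"]) and np.isnan(f["DFA1"])

    def test_msi_is_median_poincare_step(self):
        x = np.array([0.0, 1.0, 0.0, 1.0, 0.0])
        f = nonlinear_features(x, FS)
        # every consecutive Poincaré step is sqrt(1² + 1²)
        assert f["MSI"] == pytest.approx(np.sqrt(2.0))


class TestWaveletEntropy:
    def test_energy_in_one_band(self):
        # build a signal whose decomposition has energy in one band only
        # (periodization mode makes the transform exactly orthogonal)
        rng = np.random.default_rng(4)
        template = pywt.wavedec(np.zeros(1024), "db4", level=5,
                                mode="periodization")
        coeffs = [np.zeros_like(c) for c in template]
        coeffs[2] = rng.normal(size=template[2].size)
        x = pywt.waverec(coeffs, "db4", mode="periodization")
        assert wavelet_entropy(x) == pytest.approx(0.0, abs=1e-10)

    def test_equal_energy_bands(self):
        rng = np.random.default_rng(5)
        template = pywt.wavedec(np.zeros(1024), "db4", level=5,
                                mode="periodization")
        coeffs = []
        for c in template:
            v = rng.normal(size=c.size)
            coeffs.append(v / np.linalg.norm(v))  # unit energy per band
        x = pywt.waverec(coeffs, "db4", mode="periodization")
        assert wavelet_entropy(x) == pytest.approx(np.log(6), abs=1e-10)

    def test_broadband_vf_between_bounds(self, vf_window):
        we = wavelet_entropy(vf_window.samples)
        assert 0.0 < we < np.log(6)

    def test_distribution_sums_to_one(self, vf_window):
        p = wavelet_energy_distribution(vf_window.samples)
        assert p.sum() == pytest.approx(1.0)

    def test_too_short(self):
        with pytest.raises(LengthError):
            wavelet_entropy(np.zeros(16))


class TestComputeAll:
    def test_all_features_present_and_finite(self, vf_window):
        fv = compute_all(vf_window)
        assert fv.complete()
        assert fv.flags() == []

    def test_constant_window(self):
        w = AnalysisWindow(samples=np.zeros(1250), fs=FS, duration=5.0)
        fv = compute_all(w)
        assert fv["AR"] == fv["MA"] == fv["RMS1"] == 0.0
        assert fv["SampEn"] == fv["FuzzyEn"] == 0.0
        assert "Hu" in fv.flags()  # scale-free features flagged, not dropped

    def test_amplitude_doubling(self, vf_window):
        fv1 = compute_all(vf_window)
        w2 = AnalysisWindow(samples=2 * vf_window.samples, fs=FS, duration=5.0)
        fv2 = compute_all(w2)
        assert fv2["AMSA"] == pytest.approx(2 * fv1["AMSA"], rel=1e-9)
        assert fv2["SEN"] == pytest.approx(fv1["SEN"], abs=1e-9)
        # entropies must NOT be scale-invariant at fixed absolute r
        assert abs(fv2["FuzzyEn"] - fv1["FuzzyEn"]) > 0.01


@pytest.mark.parametrize("name", sorted(HOMOGENEITY_DEGREE))
def test_homogeneity_degree(name, vf_window):
    """feature(k·x) == k**degree · feature(x) for every literature feature."""
    k = 3.0
    fv1 = compute_all(vf_window)
    w2 = AnalysisWindow(samples=k * vf_window.samples, fs=FS, duration=5.0)
    fv2 = compute_all(w2)
    degree = HOMOGENEITY_DEGREE[name]
    assert fv2[name] == pytest.approx(k**degree * fv1[name], rel=1e-6,
                                      abs=1e-9)


def test_feature_name_registry_consistent():
    assert len(FEATURE_NAMES) == 27
    assert set(HOMOGENEITY_DEGREE) | {"SampEn", "FuzzyEn"} == set(FEATURE_NAMES)
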
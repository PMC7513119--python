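"""The literature bank of 25 VF-waveform shock-outcome predictors.

Covers the time-domain amplitude and slope family (AR, PPA, MA, SignInt,
RMS1, RMS2, MS, MdS, SNEO), the spectral family computed from a 2048-point
Hamming-windowed FFT (AMSA, CF, PF, ENRG, SFM, CP, MP, PSA), the
non-linear-dynamics family (Hu, ScE, LAC, DFA1, DFA2, MSI) and two
distributional entropies (WE, SEN).  :func:`compute_all` adds the
regularity entropies SampEn and FuzzyEn on top, for a 27-entry feature
vector per shock.

Several of the literature features (CP, PSA, LAC, ScE, MSI, WE and the PPA
sub-windowing) are only pinned down in their original references; the
definitions used here are documented in each function and chosen to match
the feature's name and its amplitude-scaling degree.  All have parameters
exposed so alternative conventions can be swapped in.

Units: inputs are µV at the stated sampling rate; each feature's unit is
recorded in :data:`FEATURE_UNITS`.  Spectral features are computed on the
band-passed 250 Hz signal, the entropies at the 60 Hz working rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import stats as spstats

from .entropy_core import (
    EntropyParams,
    QRS_FUZZYEN,
    QRS_SAMPEN,
    fuzzyen,
    prepare_series,
    sampen,
)
from .exceptions import BandError, LengthError
from .signal_io import AnalysisWindow

__all__ = [
    "Spectrum",
    "FeatureVector",
    "FEATURE_NAMES",
    "FEATURE_UNITS",
    "HOMOGENEITY_DEGREE",
    "amplitude_features",
    "slope_features",
    "sneo",
    "compute_spectrum",
    "spectral_features",
    "nonlinear_features",
    "wavelet_energy_distribution",
    "wavelet_entropy",
    "spectral_entropy",
    "compute_all",
]

#: Default spectral analysis band (Hz): above drift, below the AED filter edge.
DEFAULT_BAND = (2.0, 30.0)
NFFT = 2048

LITERATURE_FEATURES = (
    "AR", "PPA", "MA", "SignInt", "RMS1", "RMS2", "MS", "MdS", "SNEO",
    "AMSA", "CF", "PF", "ENRG", "SFM", "CP", "MP", "PSA",
    "Hu", "ScE", "LAC", "DFA1", "DFA2", "MSI", "WE", "SEN",
)
FEATURE_NAMES = LITERATURE_FEATURES + ("SampEn", "FuzzyEn")

FEATURE_UNITS = {
    "AR": "µV", "PPA": "µV", "MA": "µV", "SignInt": "µV·s",
    "RMS1": "µV", "RMS2": "µV", "MS": "µV/s", "MdS": "µV/s", "SNEO": "µV²",
    "AMSA": "µV·Hz", "CF": "Hz", "PF": "Hz", "ENRG": "µV²", "SFM": "",
    "CP": "Hz", "MP": "µV²", "PSA": "µV·Hz²",
    "Hu": "", "ScE": "", "LAC": "", "DFA1": "", "DFA2": "", "MSI": "µV",
    "WE": "nats", "SEN": "", "SampEn": "nats", "FuzzyEn": "nats",
}

#: Amplitude-scaling degree of every literature feature: feature(k·x) equals
#: k**degree · feature(x).  The entropies are deliberately *not* homogeneous
#: (absolute tolerance) and are excluded.
HOMOGENEITY_DEGREE = {
    "AR": 1, "PPA": 1, "MA": 1, "SignInt": 1, "RMS1": 1, "RMS2": 1,
    "MS": 1, "MdS": 1, "SNEO": 2,
    "AMSA": 1, "CF": 0, "PF": 0, "ENRG": 2, "SFM": 0, "CP": 0, "MP": 2,
    "PSA": 1,
    "Hu": 0, "ScE": 0, "LAC": 0, "DFA1": 0, "DFA2": 0, "MSI": 1,
    "WE": 0, "SEN": 0,
}


@dataclass(frozen=True)
class Spectrum:
    """Amplitude/power spectrum from a 2048-point Hamming-windowed FFT.

    ``amplitude`` is coherent-gain compensated so a tone of amplitude A µV
    shows a peak bin of ≈ A µV; ``power = amplitude**2``.
    """

    freqs: np.ndarray
    amplitude: np.ndarray
    power: np.ndarray
    fs: float

    def band(self, band: tuple[float, float] = DEFAULT_BAND):
        """Return (freqs, amplitude, power) restricted to ``band``."""
        lo, hi = band
        if hi <= lo:
            raise BandError(f"empty band {band}")
        mask = (self.freqs >= lo) & (self.freqs <= hi)
        if not mask.any():
            raise BandError(f"no FFT bins inside band {band}")
        return self.freqs[mask], self.amplitude[mask], self.power[mask]


@dataclass
class FeatureVector:
    """Named map of the 27 predictor values for one shock."""

    values: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def flags(self) -> list[str]:
        """Names of features whose value is non-finite (kept, not dropped)."""
        return [k for k, v in self.values.items() if not np.isfinite(v)]

    def complete(self) -> bool:
        return all(name in self.values for name in FEATURE_NAMES)


def _as_window(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise LengthError("empty window")
    return x


# ---------------------------------------------------------------- time domain

def amplitude_features(x, fs: float) -> dict[str, float]:
    """AR, PPA, MA, SignInt, RMS1, RMS2.

    PPA averages the peak-to-peak excursion over non-overlapping 1 s
    sub-windows (any trailing partial second is included as its own
    sub-window).
    """
    x = _as_window(x)
    n1 = max(1, int(round(fs)))
    edges = list(range(0, x.size, n1))
    ptp = [np.ptp(x[i:i + n1]) for i in edges]
    return {
        "AR": float(np.ptp(x)),
        "PPA": float(np.mean(ptp)),
        "MA": float(np.mean(np.abs(x))),
        "SignInt": float(np.sum(np.abs(x)) / fs),
        "RMS1": float(np.sqrt(np.mean(x ** 2))),
        "RMS2": float(np.sqrt(np.mean((x - x.mean()) ** 2))),
    }


def slope_features(x, fs: float) -> dict[str, float]:
    """Mean and median absolute slope, µV/s."""
    x = _as_window(x)
    if x.size < 2:
        raise LengthError("need >= 2 samples for slopes")
    s = np.abs(np.diff(x)) * fs
    return {"MS": float(np.mean(s)), "MdS": float(np.median(s))}


def sneo(x, fs: float, smooth_len: int = 7) -> float:
    """Smoothed non-linear (Teager–Kaiser) energy operator, µV².

    ``psi(n) = x(n)^2 - x(n-1) x(n+1)`` smoothed by a Bartlett window of
    ``smooth_len`` points (unit DC gain), then averaged.
    """
    x = _as_window(x)
    if x.size < 3:
        raise LengthError("need >= 3 samples for the energy operator")
    psi = x[1:-1] ** 2 - x[:-2] * x[2:]
    if smooth_len > 1:
        w = np.bartlett(smooth_len)
        w = w / w.sum()
        psi = np.convolve(psi, w, mode="same")
    return float(np.mean(psi))


# ------------------------------------------------------------ spectral domain

def compute_spectrum(x, fs: float = 250.0, nfft: int = NFFT) -> Spectrum:
    """Hamming-windowed ``nfft``-point amplitude/power spectrum.

    The window is applied to the analysis interval and the product is
    zero-padded to ``nfft``.  Amplitude is scaled by ``2 / sum(window)`` so
    a bin-centred tone of amplitude A µV peaks at ≈ A µV.  The interval
    mean is removed first: a residual DC offset would otherwise leak
    through the window side lobes into the analysis band (post-band-pass
    signals have near-zero mean anyway).
    """
    x = _as_window(x)
    if x.size > nfft:
        raise LengthError(f"window of {x.size} samples exceeds the "
                          f"{nfft}-point transform")
    w = np.hamming(x.size)
    spec = np.fft.rfft((x - x.mean()) * w, nfft)
    amplitude = 2.0 * np.abs(spec) / w.sum()
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return Spectrum(freqs=freqs, amplitude=amplitude,
                    power=amplitude ** 2, fs=fs)


def spectral_features(
    spectrum: Spectrum,
    band: tuple[float, float] = DEFAULT_BAND,
) -> dict[str, float]:
    """AMSA, CF, PF, ENRG, SFM, CP, MP, PSA over the analysis band.

    AMSA is the frequency-weighted sum of band amplitudes Σ|A(f)|·f; PSA
    weights amplitudes by f²; CF/CP are power- and squared-power-weighted
    centroid frequencies; SFM is the geometric/arithmetic power-mean ratio.
    """
    f, a, p = spectrum.band(band)
    p_sum = p.sum()
    if p_sum <= 0:
        return {k: (0.0 if k in ("AMSA", "ENRG", "MP", "PSA") else np.nan)
                for k in ("AMSA", "CF", "PF", "ENRG", "SFM", "CP", "MP", "PSA")}
    return {
        "AMSA": float(np.sum(a * f)),
        "CF": float(np.sum(f * p) / p_sum),
        "PF": float(f[np.argmax(p)]),
        "ENRG": float(p_sum),
        "SFM": float(spstats.gmean(p) / np.mean(p)) if np.all(p > 0)
        else 0.0,
        "CP": float(np.sum(f * p ** 2) / np.sum(p ** 2)),
        "MP": float(p.max()),
        "PSA": float(np.sum(a * f ** 2)),
    }


def spectral_entropy(
    spectrum: Spectrum,
    band: tuple[float, float] = DEFAULT_BAND,
) -> float:
    """Normalised Shannon entropy of the band power distribution, in [0, 1]."""
    _, _, p = spectrum.band(band)
    total = p.sum()
    if total <= 0 or p.size < 2:
        return float("nan")
    q = p / total
    q = q[q > 0]
    return float(-(q * np.log(q)).sum() / np.log(p.size))


# ------------------------------------------------------- non-linear dynamics

def _rs_expected(n: int) -> float:
    """Anis–Lloyd–Peters expectation of R/S for an i.i.d. series of length n."""
    i = np.arange(1, n)
    coef = np.sum(np.sqrt((n - i) / i))
    if n <= 340:
        from math import gamma as _g
        front = _g((n - 1) / 2.0) / (np.sqrt(np.pi) * _g(n / 2.0))
    else:
        front = 1.0 / np.sqrt(n * np.pi / 2.0)
    return float(((n - 0.5) / n) * front * coef)


def hurst_exponent(x, min_block: int = 16) -> float:
    """Rescaled-range Hurst exponent with the Anis–Lloyd small-sample
    correction (so white noise centres on 0.5).

    The slope of ``log(R/S) - log(E[R/S])`` vs ``log(n)`` over dyadic block
    sizes is added to 0.5.
    """
    x = _as_window(x)
    n = x.size
    sizes = []
    size = min_block
    while size <= n // 2:
        sizes.append(size)
        size *= 2
    if len(sizes) < 2:
        return float("nan")
    log_n, log_rs = [], []
    for s in sizes:
        n_blocks = n // s
        rs_vals = []
        for b in range(n_blocks):
            seg = x[b * s:(b + 1) * s]
            dev = seg - seg.mean()
            z = np.cumsum(dev)
            r = z.max() - z.min()
            sd = seg.std()
            if sd > 0 and r > 0:
                rs_vals.append(r / sd)
        if rs_vals:
            log_n.append(np.log(s))
            log_rs.append(np.log(np.mean(rs_vals)) - np.log(_rs_expected(s)))
    if len(log_n) < 2:
        return float("nan")
    slope = np.polyfit(log_n, log_rs, 1)[0]
    return float(0.5 + slope)


def scaling_exponent(x, max_lag: int = 10) -> float:
    """Curve-length scaling exponent: slope of log L(τ) vs log τ.

    ``L(τ)`` is the mean absolute increment at lag τ; smooth signals give
    slopes near 1, white noise near 0.  Amplitude-invariant by construction.
    """
    x = _as_window(x)
    lags = np.arange(1, max_lag + 1)
    lengths = []
    for lag in lags:
        if x.size <= lag:
            return float("nan")
        lengths.append(np.mean(np.abs(x[lag:] - x[:-lag])))
    lengths = np.asarray(lengths)
    if np.any(lengths <= 0):
        return float("nan")
    return float(np.polyfit(np.log(lags), np.log(lengths), 1)[0])


def log_absolute_correlations(x, lags: tuple[int, ...] = tuple(range(1, 26))
                              ) -> float:
    """Log of the mean absolute autocorrelation over a fixed lag set."""
    x = _as_window(x)
    x = x - x.mean()
    var = np.dot(x, x)
    if var <= 0:
        return float("nan")
    acf = [np.dot(x[lag:], x[:-lag]) / var for lag in lags if lag < x.size]
    if not acf:
        return float("nan")
    mean_abs = np.mean(np.abs(acf))
    return float(np.log(mean_abs)) if mean_abs > 0 else float("nan")


def dfa_exponent(x, scales) -> float:
    """Detrended fluctuation analysis slope over the given box sizes.

    The profile (cumulative sum of the mean-subtracted series) is split
    into non-overlapping boxes, linearly detrended per box; the slope of
    ``log F(s)`` vs ``log s`` is returned.
    """
    x = _as_window(x)
    y = np.cumsum(x - x.mean())
    log_s, log_f = [], []
    for s in scales:
        s = int(s)
        n_boxes = y.size // s
        if n_boxes < 2:
            continue
        segs = y[:n_boxes * s].reshape(n_boxes, s)
        t = np.arange(s)
        # per-box linear detrend via least squares on the shared time axis
        t_mean = t.mean()
        t_dev = t - t_mean
        denom = np.dot(t_dev, t_dev)
        slopes = segs @ t_dev / denom
        resid = segs - segs.mean(axis=1, keepdims=True) - slopes[:, None] * t_dev
        f = np.sqrt(np.mean(resid ** 2))
        if f > 0:
            log_s.append(np.log(s))
            log_f.append(np.log(f))
    if len(log_s) < 2:
        return float("nan")
    return float(np.polyfit(log_s, log_f, 1)[0])


def median_stepping_increment(x) -> float:
    """Median Euclidean step between successive Poincaré-plot points (µV)."""
    x = _as_window(x)
    if x.size < 3:
        raise LengthError("need >= 3 samples for the Poincaré step")
    d1 = np.diff(x)
    steps = np.sqrt(d1[:-1] ** 2 + d1[1:] ** 2)
    return float(np.median(steps))


def nonlinear_features(
    x,
    fs: float,
    dfa1_scales=(8, 11, 16, 23, 32),
    dfa2_scales=(32, 45, 64, 91, 128),
) -> dict[str, float]:
    """Hu, ScE, LAC, DFA1, DFA2, MSI.

    DFA scale ranges default to 8–32 samples (short) and 32–128 samples
    (long) at 250 Hz; box sizes below ~8 samples were avoided because
    first-order DFA is biased high there (white noise would read ≈ 0.6
    instead of 0.5).  Degenerate (constant) inputs yield NaN for the
    scale-free features and 0 for MSI.
    """
    x = _as_window(x)
    if np.ptp(x) == 0:
        return {"Hu": float("nan"), "ScE": float("nan"), "LAC": float("nan"),
                "DFA1": float("nan"), "DFA2": float("nan"), "MSI": 0.0}
    return {
        "Hu": hurst_exponent(x),
        "ScE": scaling_exponent(x),
        "LAC": log_absolute_correlations(x),
        "DFA1": dfa_exponent(x, dfa1_scales),
        "DFA2": dfa_exponent(x, dfa2_scales),
        "MSI": median_stepping_increment(x),
    }


# ------------------------------------------------------------------ entropies

def wavelet_energy_distribution(x, wavelet: str = "db4", level: int = 5,
                                mode: str = "periodization") -> np.ndarray:
    """Relative energies of the ``level + 1`` wavelet sub-bands.

    Periodization boundary handling keeps the transform exactly orthogonal,
    so sub-band energies sum to the signal energy.
    """
    x = _as_window(x)
    if x.size < 2 ** level:
        raise LengthError(f"need >= {2 ** level} samples for a "
                          f"{level}-level decomposition")
    coeffs = pywt.wavedec(x, wavelet, level=level, mode=mode)
    energies = np.array([np.sum(c ** 2) for c in coeffs])
    total = energies.sum()
    if total <= 0:
        return np.full(energies.size, np.nan)
    return energies / total


def wavelet_entropy(x, wavelet: str = "db4", level: int = 5,
                    mode: str = "periodization") -> float:
    """Shannon entropy (nats) of the wavelet sub-band energy distribution.

    Zero when all energy sits in one sub-band; ``ln(level + 1)`` when the
    energy is spread evenly.
    """
    p = wavelet_energy_distribution(x, wavelet=wavelet, level=level, mode=mode)
    if not np.all(np.isfinite(p)):
        return float("nan")
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


# ------------------------------------------------------------------- assembly

def compute_all(
    window: AnalysisWindow,
    sampen_params: EntropyParams = QRS_SAMPEN,
    fuzzyen_params: EntropyParams = QRS_FUZZYEN,
    band: tuple[float, float] = DEFAULT_BAND,
) -> FeatureVector:
    """All 27 predictors for one pre-shock window.

    The window must already be band-passed at its native rate; the 25
    literature features are computed at that rate (250 Hz by design) and
    the two entropies after resampling to their working rate.
    Per-feature failures are carried as NaN flags, never dropped.
    """
    x, fs = window.samples, window.fs
    values: dict[str, float] = {}
    values.update(amplitude_features(x, fs))
    values.update(slope_features(x, fs))
    values["SNEO"] = sneo(x, fs)
    spectrum = compute_spectrum(x, fs)
    values.update(spectral_features(spectrum, band))
    values.update(nonlinear_features(x, fs))
    values["WE"] = wavelet_entropy(x)
    values["SEN"] = spectral_entropy(spectrum, band)

    if np.ptp(x) == 0:
        values["SampEn"] = 0.0
        values["FuzzyEn"] = 0.0
    else:
        x60_s = prepare_series(x, fs, sampen_params.fs_star)
        x60_f = (x60_s if fuzzyen_params.fs_star == sampen_params.fs_star
                 else prepare_series(x, fs, fuzzyen_params.fs_star))
        values["SampEn"] = float(sampen(x60_s, sampen_params).value)
        values["FuzzyEn"] = float(fuzzyen(x60_f, fuzzyen_params).value)
    return FeatureVector(values=values)
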
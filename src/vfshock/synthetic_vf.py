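"""Synthetic VF-like cohorts with outcome-linked waveform properties.

No public dataset of pre-shock OHCA recordings exists, so every pipeline
in this package is exercised on synthetic signals.  The generator makes no
claim of biophysical VF realism: it targets the three statistical handles
the prediction method responds to — amplitude (tens to hundreds of µV),
dominant frequency (3–7 Hz, where human VF concentrates), and waveform
irregularity — which is sufficient to test every contract.

A signal is a frequency-modulated sinusoidal carrier at the dominant
frequency whose phase is jittered by an Ornstein–Uhlenbeck process scaled
by the ``irregularity`` knob, under a slowly modulated amplitude envelope,
plus band-limited Gaussian noise whose level also grows with
``irregularity``.  An optional exponential amplitude decay emulates
waveform deterioration across a pre-shock pause.

Cohorts draw per-class amplitude/irregularity parameters so that outcome
labels are statistically linked to the waveform; each record's random
stream is derived by stable hashing of (cohort seed, record index), making
the cohort a pure function of its spec.  iAAFT surrogates are provided for
nonlinearity (rank) testing of the entropy statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, LengthError, SpecError
from .signal_io import EcgRecord, ShockEvent

__all__ = [
    "VfGenParams",
    "ClassParams",
    "CohortSpec",
    "generate_vf",
    "generate_cohort",
    "make_surrogates",
    "surrogate_rank_test",
]


@dataclass(frozen=True)
class VfGenParams:
    """Knobs of one synthetic VF record.

    ``irregularity`` in [0, 1] jointly scales the phase jitter and the
    broadband admixture; ``decay_rate`` (min^-1) applies an exponential
    amplitude decay across the record, emulating deterioration during a
    long pause.  ``pause_s`` seconds before the shock (placed at the end of
    the record) are compression-free.
    """

    duration: float = 30.0
    fs: float = 250.0
    amplitude: float = 200.0      # µV envelope scale
    dominant_freq: float = 5.0    # Hz
    irregularity: float = 0.5
    decay_rate: float = 0.0       # min^-1
    pause_s: float = 22.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.fs <= 0:
            raise DomainError("duration and fs must be positive")
        if self.amplitude <= 0:
            raise DomainError("amplitude must be positive µV")
        if not (3.0 <= self.dominant_freq <= 7.0):
            raise DomainError("dominant_freq must lie in [3, 7] Hz")
        if not (0.0 <= self.irregularity <= 1.0):
            raise DomainError("irregularity must lie in [0, 1]")
        if not (0.0 < self.pause_s < self.duration):
            raise DomainError("pause_s must lie in (0, duration)")


def _ou_process(rng, n: int, dt: float, theta: float, sigma: float
                ) -> np.ndarray:
    """Ornstein–Uhlenbeck path (zero mean, starts at 0), Euler–Maruyama.

    The AR(1) recursion z[k] = (1 - theta*dt) z[k-1] + sigma*sqrt(dt) w[k]
    is evaluated with a single-pole IIR filter for speed.
    """
    from scipy.signal import lfilter

    noise = rng.standard_normal(n - 1)
    a = 1.0 - theta * dt
    z = lfilter([sigma * np.sqrt(dt)], [1.0, -a], noise)
    return np.concatenate([[0.0], z])


def _bandlimited_noise(rng, n: int, fs: float, band=(2.0, 12.0)) -> np.ndarray:
    """Unit-RMS Gaussian noise restricted to ``band`` (FFT masking)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spec[(freqs < band[0]) | (freqs > band[1])] = 0.0
    x = np.fft.irfft(spec, n)
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def generate_vf(
    params: VfGenParams,
    qrs_success: bool = False,
    survival: bool = False,
) -> EcgRecord:
    """One synthetic VF record with a single annotated shock at its end.

    Identical ``params`` (including seed) give bit-identical output.
    """
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    fs, dur = params.fs, params.duration
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    irr = params.irregularity

    # phase jitter: OU process, sd grows with irregularity
    phase_jitter = _ou_process(rng, n, 1.0 / fs, theta=1.0,
                               sigma=6.0 * irr)
    phase = 2.0 * np.pi * params.dominant_freq * t + phase_jitter
    carrier = np.sin(phase) + 0.25 * np.sin(2.0 * phase + rng.uniform(0, 2 * np.pi))

    # slow multiplicative envelope + optional pause decay
    env_phase = rng.uniform(0, 2 * np.pi)
    envelope = 1.0 + 0.25 * np.sin(2.0 * np.pi * 0.3 * t + env_phase)
    envelope *= np.exp(-params.decay_rate * t / 60.0)

    noise = _bandlimited_noise(rng, n, fs)
    x = params.amplitude * envelope * (carrier / 1.03 + 0.6 * irr * noise)

    shock = ShockEvent(shock_time=dur, pause_start=dur - params.pause_s,
                       qrs_success=qrs_success, survival=survival)
    return EcgRecord(record_id=f"synthetic-vf-{params.seed}", fs=fs,
                     samples=x, shocks=(shock,))


@dataclass(frozen=True)
class ClassParams:
    """Per-class distribution of generator parameters.

    Amplitude is log-normal around ``amplitude_median`` with log-sd
    ``amplitude_logsd``; irregularity is normal, clipped to [0.05, 0.95];
    the dominant frequency is uniform over ``freq_range``.
    """

    amplitude_median: float = 200.0
    amplitude_logsd: float = 0.3
    irregularity_mean: float = 0.5
    irregularity_sd: float = 0.1
    freq_range: tuple[float, float] = (3.5, 6.5)


#: Default class-conditional parameters: successful shocks come from larger,
#: more irregular VF (the waveform signature of defibrillation amenability).
SUCCESS_CLASS = ClassParams(amplitude_median=300.0, amplitude_logsd=0.25,
                            irregularity_mean=0.70, irregularity_sd=0.10)
FAILURE_CLASS = ClassParams(amplitude_median=110.0, amplitude_logsd=0.25,
                            irregularity_mean=0.35, irregularity_sd=0.10)


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a two-class synthetic shock cohort.

    ``label_noise`` flips each outcome label independently with the given
    probability.  With ``null=True`` both classes draw from the *success*
    distribution, so labels carry no waveform information (for calibration
    checks).
    """

    n_success: int = 100
    n_failure: int = 100
    success: ClassParams = SUCCESS_CLASS
    failure: ClassParams = FAILURE_CLASS
    label_noise: float = 0.0
    null: bool = False
    duration: float = 30.0
    fs: float = 250.0
    pause_s: float = 22.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_success < 2 or self.n_failure < 2:
            raise SpecError("need at least 2 shocks per class")
        if not (0.0 <= self.label_noise < 0.5):
            raise SpecError("label_noise must lie in [0, 0.5)")
        if not (0.0 < self.pause_s < self.duration):
            raise SpecError("pause_s must lie in (0, duration)")


def _record_seed(cohort_seed: int, index: int) -> int:
    """Stable per-record seed from (cohort seed, record index)."""
    ss = np.random.SeedSequence(entropy=cohort_seed, spawn_key=(index,))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def generate_cohort(spec: CohortSpec):
    """List of (EcgRecord, labels) with class-conditional waveforms.

    ``labels`` maps ``"qrs"`` and ``"survival"`` to booleans; both
    criteria share the class assignment (independently noise-flipped when
    ``label_noise > 0``).
    """
    out = []
    n_total = spec.n_success + spec.n_failure
    for idx in range(n_total):
        is_success = idx < spec.n_success
        cls = spec.success if (is_success or spec.null) else spec.failure
        seed = _record_seed(spec.seed, idx)
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=spec.seed, spawn_key=(idx, 1)))
        amplitude = cls.amplitude_median * np.exp(
            cls.amplitude_logsd * rng.standard_normal())
        irregularity = float(np.clip(
            rng.normal(cls.irregularity_mean, cls.irregularity_sd),
            0.05, 0.95))
        freq = rng.uniform(*cls.freq_range)
        labels = {}
        for criterion in ("qrs", "survival"):
            lab = is_success
            if spec.label_noise > 0 and rng.random() < spec.label_noise:
                lab = not lab
            labels[criterion] = lab
        params = VfGenParams(duration=spec.duration, fs=spec.fs,
                             amplitude=float(amplitude),
                             dominant_freq=float(freq),
                             irregularity=irregularity,
                             pause_s=spec.pause_s, seed=seed)
        record = generate_vf(params, qrs_success=labels["qrs"],
                             survival=labels["survival"])
        out.append((record, labels))
    return out


def make_surrogates(x, n_surr: int = 19, seed: int | None = None,
                    n_iter: int = 100, tol: float = 1e-8):
    """iAAFT surrogates of *x*: rank-exact amplitudes, matched spectrum.

    Each surrogate has exactly the original's sorted sample values and a
    power spectrum matching the original's within the iteration tolerance;
    phases are randomised, so any nonlinearity of the original generating
    process is destroyed while its linear correlations are kept.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 128:
        raise LengthError("need at least 128 samples for surrogate testing")
    rng = np.random.default_rng(seed)
    sorted_x = np.sort(x)
    target_amp = np.abs(np.fft.rfft(x))
    surrogates = []
    for _ in range(n_surr):
        y = rng.permutation(x)
        prev_err = np.inf
        for _ in range(n_iter):
            spec = np.fft.rfft(y)
            phases = np.angle(spec)
            y = np.fft.irfft(target_amp * np.exp(1j * phases), x.size)
            # restore exact amplitude distribution by rank
            ranks = np.argsort(np.argsort(y))
            y = sorted_x[ranks]
            err = np.linalg.norm(np.abs(np.fft.rfft(y)) - target_amp)
            if abs(prev_err - err) < tol * np.linalg.norm(target_amp):
                break
            prev_err = err
        surrogates.append(y)
    return surrogates


def surrogate_rank_test(original_stat: float, surrogate_stats,
                        alternative: str = "two-sided") -> dict:
    """Rank test of the original statistic against its surrogate null.

    With ``n`` surrogates the attainable one-sided level is
    ``1 / (n + 1)`` (0.05 for the default 19).  Returns the rank of the
    original, the p-value and a significance flag at that level.
    """
    stats = np.asarray(surrogate_stats, dtype=float)
    n = stats.size
    greater = int(np.sum(stats >= original_stat))
    less = int(np.sum(stats <= original_stat))
    if alternative == "greater":
        p = (greater + 1) / (n + 1)
    elif alternative == "less":
        p = (less + 1) / (n + 1)
    elif alternative == "two-sided":
        p = min(1.0, 2.0 * (min(greater, less) + 1) / (n + 1))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return {"rank": greater, "n_surrogates": n, "p": float(p),
            "significant": bool(p <= 0.05)}
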
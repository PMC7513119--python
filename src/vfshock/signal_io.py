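"""ECG record handling for pre-shock VF analysis.

Houses the raw single-channel ECG (microvolts) together with its shock
annotations, the AED-bandwidth band-pass filter, rational-factor
resampling, and extraction of the pre-shock analysis window that every
predictor is computed from.

Conventions
-----------
* Amplitudes are in µV throughout; times in seconds from record start.
* Filtering is causal by default (single forward pass), mirroring how an
  AED would process the signal in real time; zero-phase filtering is
  available behind a flag for offline work.
* The analysis window of length ``wl`` ends exactly 1 s before the shock
  (guard interval), i.e. it covers ``[shock_time - 1 - wl, shock_time - 1)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .exceptions import (
    DataError,
    DomainError,
    InvalidRateError,
    LengthError,
    WindowError,
)

__all__ = [
    "ShockEvent",
    "EcgRecord",
    "AnalysisWindow",
    "bandpass_filter",
    "resample_signal",
    "extract_preshock_window",
    "quantize",
    "read_record",
    "write_record",
    "GUARD_S",
    "AED_BAND_HZ",
    "LSB_UV",
]

#: Guard interval between the end of the analysis window and the shock (s).
GUARD_S = 1.0
#: Emulated AED acquisition band (Hz).
AED_BAND_HZ = (0.5, 30.0)
#: Amplitude resolution of the recording device (µV per least significant bit).
LSB_UV = 4.8


@dataclass(frozen=True)
class ShockEvent:
    """One defibrillation attempt with its two outcome labels.

    ``qrs_success`` is the electrical criterion (post-shock rhythm with
    sustained QRS complexes at >= 30 bpm within a minute); ``survival`` is
    the clinical criterion (discharged alive with CPC 1-3).
    """

    shock_time: float
    pause_start: float
    qrs_success: bool
    survival: bool

    def __post_init__(self) -> None:
        if not (self.pause_start < self.shock_time):
            raise WindowError(
                f"pause_start ({self.pause_start} s) must precede "
                f"shock_time ({self.shock_time} s)"
            )
        if self.qrs_success is None or self.survival is None:
            raise DataError("both outcome labels must be present")

    @property
    def pause_duration(self) -> float:
        """Length of the pre-shock compression-free interval (s)."""
        return self.shock_time - self.pause_start

    def label(self, criterion: str) -> bool:
        if criterion == "qrs":
            return self.qrs_success
        if criterion == "survival":
            return self.survival
        raise KeyError(f"unknown success criterion {criterion!r}")


@dataclass(frozen=True)
class EcgRecord:
    """Single-channel ECG in µV with its sampling rate and shock events."""

    record_id: str
    fs: float
    samples: np.ndarray
    shocks: tuple[ShockEvent, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        object.__setattr__(self, "shocks", tuple(self.shocks))
        if self.fs <= 0:
            raise InvalidRateError(f"fs must be > 0, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise LengthError("samples must be a 1-D sequence of length >= 2")
        if not np.all(np.isfinite(self.samples)):
            raise DataError("samples contain non-finite values")
        for shock in self.shocks:
            if not (0.0 <= shock.shock_time <= self.duration):
                raise WindowError(
                    f"shock at {shock.shock_time} s outside record "
                    f"[0, {self.duration:.3f}] s"
                )

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class AnalysisWindow:
    """A ``wl``-second pre-shock slice of an :class:`EcgRecord`."""

    samples: np.ndarray
    fs: float
    duration: float
    source_shock: ShockEvent | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        expected = int(round(self.fs * self.duration))
        if self.samples.size != expected:
            raise LengthError(
                f"window has {self.samples.size} samples, expected "
                f"round(fs*duration) = {expected}"
            )


def bandpass_filter(
    x,
    fs: float,
    band: tuple[float, float] = AED_BAND_HZ,
    order: int = 8,
    rp_db: float = 1.0,
    rs_db: float = 30.0,
    zero_phase: bool = False,
):
    """Band-pass *x* to the AED acquisition band.

    Elliptic band-pass of total order ``order`` (second-order sections),
    1 dB pass-band ripple and 30 dB stop-band attenuation by default.
    Causal (single forward pass) unless ``zero_phase`` is set.
    """
    x = np.asarray(x, dtype=float)
    if fs < 2.0 * band[1]:
        raise InvalidRateError(
            f"fs = {fs} Hz too low: band edge {band[1]} Hz must lie below Nyquist"
        )
    if not np.all(np.isfinite(x)):
        raise DataError("input contains non-finite samples")
    if x.size < 2:
        raise LengthError("input too short to filter")
    if order % 2:
        raise ValueError("band-pass order must be even")
    sos = sps.ellip(order // 2, rp_db, rs_db, band, btype="bandpass", fs=fs,
                    output="sos")
    if zero_phase:
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def resample_signal(x, fs_in: float, fs_out: float):
    """Resample *x* from ``fs_in`` to ``fs_out`` Hz.

    Polyphase FIR resampling at the rational factor ``fs_out/fs_in`` with a
    Kaiser anti-aliasing design; output length is exactly
    ``round(len(x) * fs_out / fs_in)``.
    """
    if fs_in <= 0 or fs_out <= 0:
        raise InvalidRateError("sampling rates must be positive")
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise DataError("input contains non-finite samples")
    if fs_in == fs_out:
        return x.copy()
    ratio = Fraction(fs_out / fs_in).limit_denominator(10_000)
    y = sps.resample_poly(x, ratio.numerator, ratio.denominator,
                          window=("kaiser", 5.0))
    target = int(round(x.size * fs_out / fs_in))
    if y.size > target:
        y = y[:target]
    elif y.size < target:
        y = np.pad(y, (0, target - y.size), mode="edge")
    return y


def extract_preshock_window(
    record: EcgRecord,
    shock: ShockEvent,
    wl: float,
    guard: float = GUARD_S,
) -> AnalysisWindow:
    """Cut the ``wl``-second analysis window ending ``guard`` s pre-shock.

    The window covers ``[shock_time - guard - wl, shock_time - guard)`` and
    must fit inside the annotated compression-free pause, so that chest
    compressions never contaminate the analysed VF.
    """
    if wl <= 0:
        raise WindowError("window length must be positive")
    end = shock.shock_time - guard
    start = end - wl
    if start < 0:
        raise WindowError(
            f"insufficient pre-shock signal: window would start at "
            f"{start:.3f} s (needs {wl + guard:.1f} s before the shock at "
            f"{shock.shock_time:.1f} s)"
        )
    if start < shock.pause_start - 1e-9:
        raise WindowError(
            f"window start {start:.3f} s precedes the pause start "
            f"{shock.pause_start:.3f} s: only "
            f"{shock.pause_duration - guard:.2f} s of compression-free "
            f"signal available for a {wl:.1f} s window"
        )
    n = int(round(record.fs * wl))
    i0 = int(round(start * record.fs))
    samples = record.samples[i0:i0 + n]
    if samples.size < n:
        raise WindowError("record ends before the analysis window is complete")
    return AnalysisWindow(samples=samples, fs=record.fs, duration=wl,
                          source_shock=shock)


def quantize(x, lsb_uv: float = LSB_UV):
    """Re-quantize *x* to the device amplitude resolution (robustness tool).

    Off by default everywhere; provided to reproduce the recorder's
    ``lsb_uv`` µV/LSB staircase for sensitivity experiments.
    """
    if lsb_uv <= 0:
        raise DomainError("lsb_uv must be positive")
    return lsb_uv * np.round(np.asarray(x, dtype=float) / lsb_uv)


def write_record(record: EcgRecord, csv_path, sidecar_path) -> None:
    """Write a record as ``t_s,ecg_uV`` CSV plus a JSON shock sidecar."""
    t = np.arange(record.samples.size) / record.fs
    pd.DataFrame({"t_s": t, "ecg_uV": record.samples}).to_csv(
        csv_path, index=False, float_format="%.6f"
    )
    meta = {
        "record_id": record.record_id,
        "fs": record.fs,
        "shocks": [
            {
                "shock_time_s": s.shock_time,
                "pause_start_s": s.pause_start,
                "qrs_success": bool(s.qrs_success),
                "survival": bool(s.survival),
            }
            for s in record.shocks
        ],
    }
    Path(sidecar_path).write_text(json.dumps(meta, indent=1))


def read_record(csv_path, sidecar_path) -> EcgRecord:
    """Read a record written by :func:`write_record`."""
    csv_path, sidecar_path = Path(csv_path), Path(sidecar_path)
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing shock sidecar: {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    df = pd.read_csv(csv_path)
    if "ecg_uV" not in df.columns:
        raise DataError(f"{csv_path} lacks an 'ecg_uV' column")
    shocks = tuple(
        ShockEvent(
            shock_time=s["shock_time_s"],
            pause_start=s["pause_start_s"],
            qrs_success=bool(s["qrs_success"]),
            survival=bool(s["survival"]),
        )
        for s in meta.get("shocks", [])
    )
    return EcgRecord(
        record_id=str(meta.get("record_id", csv_path.stem)),
        fs=float(meta["fs"]),
        samples=df["ecg_uV"].to_numpy(dtype=float),
        shocks=shocks,
    )
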
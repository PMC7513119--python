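"""Entropy evolution across the pre-shock chest-compression pause.

During the pause before a shock no compressions re-oxygenate the
myocardium, so the VF waveform might deteriorate; if entropy predicts
shock outcome, its drift across the pause measures that deterioration.
This module slides a 3 s entropy window (0.5 s hop) across the pause,
pools the resulting (time, entropy) points per outcome group, fits an
ordinary least-squares line (slope reported per minute), compares the
two groups' lines with the pooled-variance extension of the t-test for
regression coefficients (Weaver–Wuensch), and extrapolates how long the
fitted decay would take to carry the successful-shock mean entropy down
to the unsuccessful-shock mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats

from .entropy_core import EntropyParams, fuzzyen, prepare_series, sampen
from .exceptions import DomainError, FitError, TrajectoryError
from .signal_io import EcgRecord, ShockEvent, bandpass_filter, resample_signal

__all__ = [
    "EntropyTrajectory",
    "RegressionFit",
    "CoefComparison",
    "entropy_trajectory",
    "fit_group_regression",
    "fit_points",
    "compare_regressions",
    "time_to_cross",
    "TRAJECTORY_WINDOW_S",
    "TRAJECTORY_HOP_S",
    "TRAJECTORY_HORIZON_S",
]

#: Entropy window length inside the pause (s).
TRAJECTORY_WINDOW_S = 3.0
#: Hop between successive trajectory values (s).
TRAJECTORY_HOP_S = 0.5
#: Latest window start considered, relative to pause onset (s).
TRAJECTORY_HORIZON_S = 16.0


@dataclass(frozen=True)
class EntropyTrajectory:
    """Entropy values on the 0.5 s grid across one pre-shock pause.

    ``times`` are window *start* times in seconds since pause onset; each
    value is the entropy of the 3 s window starting there.
    """

    times: np.ndarray
    values: np.ndarray
    params: EntropyParams
    kind: str
    shock: ShockEvent | None = None

    def points(self):
        """(time_min, value) pairs with time converted to minutes."""
        return np.column_stack([self.times / 60.0, self.values])


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of entropy on pause time (time in minutes).

    Carries the sufficient statistics (``x_mean``, ``sxx``, ``sse``) needed
    for the pooled-variance coefficient comparison.
    """

    intercept: float
    slope: float            # nats per minute
    se_intercept: float
    se_slope: float
    n: int
    resid_var: float
    x_mean: float
    sxx: float
    sse: float

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        t = spstats.t.ppf(0.5 + level / 2.0, self.n - 2)
        return (self.slope - t * self.se_slope, self.slope + t * self.se_slope)


@dataclass(frozen=True)
class CoefComparison:
    """t statistics and p-values for intercept and slope differences."""

    t_intercept: float
    p_intercept: float
    t_slope: float
    p_slope: float
    df: int


def entropy_trajectory(
    record: EcgRecord,
    shock: ShockEvent,
    params: EntropyParams,
    kind: str = "fuzzyen",
    window_s: float = TRAJECTORY_WINDOW_S,
    hop_s: float = TRAJECTORY_HOP_S,
    horizon_s: float = TRAJECTORY_HORIZON_S,
) -> EntropyTrajectory:
    """Sliding-window entropy across the pre-shock pause.

    Windows of ``window_s`` start every ``hop_s`` from the pause onset;
    the last start time is ``min(pause_duration - window_s, horizon_s)``.
    The record is band-passed once at its native rate, then each window is
    resampled to the entropy working rate.
    """
    pause = shock.pause_duration
    if pause < window_s:
        raise TrajectoryError(
            f"pause of {pause:.2f} s is shorter than the {window_s:.1f} s "
            "entropy window"
        )
    t_max = min(pause - window_s, horizon_s)
    times = np.arange(0.0, t_max + 1e-9, hop_s)
    fs = record.fs
    filtered = (bandpass_filter(record.samples, fs)
                if fs >= 60.0 else record.samples)
    n_win = int(round(window_s * fs))
    values = np.empty(times.size)
    estimator = fuzzyen if kind == "fuzzyen" else sampen
    if kind not in ("fuzzyen", "sampen"):
        raise ValueError(f"unknown entropy kind {kind!r}")
    for k, t in enumerate(times):
        i0 = int(round((shock.pause_start + t) * fs))
        seg = filtered[i0:i0 + n_win]
        y = resample_signal(seg, fs, params.fs_star)
        values[k] = float(estimator(y, params).value)
    return EntropyTrajectory(times=times, values=values, params=params,
                             kind=kind, shock=shock)


def fit_points(t_min, values) -> RegressionFit:
    """OLS of entropy on time (minutes) from raw pooled points."""
    t = np.asarray(t_min, dtype=float)
    y = np.asarray(values, dtype=float)
    mask = np.isfinite(t) & np.isfinite(y)
    t, y = t[mask], y[mask]
    n = t.size
    if n < 3 or np.unique(t).size < 2:
        raise FitError("need >= 3 points at >= 2 distinct times")
    x_mean = t.mean()
    sxx = float(np.sum((t - x_mean) ** 2))
    slope = float(np.sum((t - x_mean) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x_mean)
    resid = y - (intercept + slope * t)
    sse = float(np.sum(resid ** 2))
    resid_var = sse / (n - 2)
    se_slope = float(np.sqrt(resid_var / sxx))
    se_intercept = float(np.sqrt(resid_var * (1.0 / n + x_mean ** 2 / sxx)))
    return RegressionFit(intercept=intercept, slope=slope,
                         se_intercept=se_intercept, se_slope=se_slope,
                         n=n, resid_var=resid_var, x_mean=float(x_mean),
                         sxx=sxx, sse=sse)


def fit_group_regression(
    trajectories,
    outcome_filter=None,
    pooling: str = "points",
) -> RegressionFit:
    """Fit one regression line to a group of trajectories.

    ``pooling="points"`` (default) pools every (time, value) pair of every
    selected trajectory into one OLS fit — the population-level trend.
    ``pooling="per_shock"`` fits each trajectory separately and combines
    the per-shock coefficients (mean, with between-shock standard errors),
    a hierarchical alternative for strongly unbalanced pauses.
    ``outcome_filter`` is an optional predicate on the trajectory's shock.
    """
    selected = [tr for tr in trajectories
                if outcome_filter is None or outcome_filter(tr.shock)]
    if not selected:
        raise FitError("no trajectories selected")
    if pooling == "points":
        pts = np.vstack([tr.points() for tr in selected])
        return fit_points(pts[:, 0], pts[:, 1])
    if pooling == "per_shock":
        fits = [fit_points(*tr.points().T) for tr in selected]
        k = len(fits)
        if k < 2:
            raise FitError("per-shock pooling needs >= 2 trajectories")
        slopes = np.array([f.slope for f in fits])
        icepts = np.array([f.intercept for f in fits])
        n_tot = int(sum(f.n for f in fits))
        return RegressionFit(
            intercept=float(icepts.mean()), slope=float(slopes.mean()),
            se_intercept=float(icepts.std(ddof=1) / np.sqrt(k)),
            se_slope=float(slopes.std(ddof=1) / np.sqrt(k)),
            n=n_tot, resid_var=float(np.mean([f.resid_var for f in fits])),
            x_mean=float(np.mean([f.x_mean for f in fits])),
            sxx=float(np.sum([f.sxx for f in fits])),
            sse=float(np.sum([f.sse for f in fits])),
        )
    raise ValueError(f"unknown pooling {pooling!r}")


def compare_regressions(fit_a: RegressionFit, fit_b: RegressionFit
                        ) -> CoefComparison:
    """Pooled-variance t-tests for slope and intercept differences.

    The residual variance is pooled across the two fits,
    ``s2 = (SSE_a + SSE_b) / (n_a + n_b - 4)``, giving the Weaver–Wuensch
    extension of the two-sample t-test; the slope test is algebraically the
    interaction term of a dummy-coded joint regression and the intercept
    test the group main effect (both at ``df = n_a + n_b - 4``).
    """
    df = fit_a.n + fit_b.n - 4
    if df < 1:
        raise FitError("not enough points to compare regressions")
    s2 = (fit_a.sse + fit_b.sse) / df
    se_slope = np.sqrt(s2 * (1.0 / fit_a.sxx + 1.0 / fit_b.sxx))
    t_slope = (fit_a.slope - fit_b.slope) / se_slope
    se_icept = np.sqrt(s2 * (1.0 / fit_a.n + fit_a.x_mean ** 2 / fit_a.sxx
                             + 1.0 / fit_b.n + fit_b.x_mean ** 2 / fit_b.sxx))
    t_icept = (fit_a.intercept - fit_b.intercept) / se_icept
    p_slope = float(2.0 * spstats.t.sf(abs(t_slope), df))
    p_icept = float(2.0 * spstats.t.sf(abs(t_icept), df))
    return CoefComparison(t_intercept=float(t_icept), p_intercept=p_icept,
                          t_slope=float(t_slope), p_slope=p_slope, df=df)


def time_to_cross(intercept_hi: float, intercept_lo: float,
                  slope_per_min: float) -> float:
    """Seconds for a linear entropy decay to fall from one level to another.

    With the successful-group intercept ``intercept_hi`` (nats), the
    unsuccessful-group intercept ``intercept_lo`` and a negative decay
    ``slope_per_min`` (nats/min), returns
    ``60 * (intercept_hi - intercept_lo) / |slope|``.
    """
    if slope_per_min >= 0:
        raise DomainError("decay slope must be negative")
    if intercept_hi < intercept_lo:
        raise DomainError("intercept_hi must be >= intercept_lo")
    return 60.0 * (intercept_hi - intercept_lo) / abs(slope_per_min)
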
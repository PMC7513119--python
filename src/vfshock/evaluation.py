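"""ROC-based evaluation of shock-outcome predictors.

Shock-outcome prediction is a binary decision problem with *shock success*
as the positive class.  Sweeping the decision threshold over a predictor
yields a receiver operating characteristic (ROC); the area under it (AUC)
summarises predictive power, and four critical operating points are
reported per curve: sensitivity at 90% specificity, specificity at 90%
sensitivity, the balanced-accuracy (Youden) optimum BAC = (Se + Sp) / 2,
and the vertex closest to the ideal (0, 1) corner.

Also here: the Mann–Whitney rank comparison of predictor values between
outcome groups, the (m, r) grid search for the entropy parameters, and the
window-length sweep (2–5 s) that probes robustness to short analysis
intervals.

Convention: success corresponds to the *larger* predictor value.  For
predictors negatively associated with success, pass
``larger_is_success=False`` and the scores are negated internally (the sign
is recorded on the curve).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as spstats

from .entropy_core import EntropyParams
from .exceptions import ClassError, DomainError, WindowError
from .signal_io import EcgRecord, ShockEvent, extract_preshock_window

__all__ = [
    "RocCurve",
    "CutoffReport",
    "GridResult",
    "roc_curve",
    "balanced_accuracy",
    "critical_cutoffs",
    "mann_whitney",
    "grid_search",
    "window_length_sweep",
    "DEFAULT_M_VALUES",
    "DEFAULT_R_VALUES",
]

#: Entropy parameter search grid: 3 embedding dimensions x 20 tolerances (µV).
DEFAULT_M_VALUES = (1, 2, 3)
DEFAULT_R_VALUES = tuple(float(r) for r in range(5, 105, 5))


@dataclass(frozen=True)
class RocCurve:
    """ROC vertices (thresholds with Se/Sp in %) plus trapezoidal AUC."""

    thresholds: np.ndarray
    se: np.ndarray
    sp: np.ndarray
    auc: float
    positive_label: str = "success"
    larger_is_success: bool = True

    def vertices(self):
        return list(zip(self.thresholds, self.se, self.sp))


@dataclass(frozen=True)
class CutoffReport:
    """Four critical ROC operating points (percent scales)."""

    se_at_sp90: float
    sp_at_se90: float
    youden: tuple[float, float, float]     # (se, sp, threshold)
    closest01: tuple[float, float, float]  # (se, sp, threshold)

    @property
    def bac(self) -> float:
        return balanced_accuracy(self.youden[0], self.youden[1])


@dataclass(frozen=True)
class GridResult:
    """AUC surface over the (m, r) grid, per success criterion."""

    m_values: tuple[int, ...]
    r_values: tuple[float, ...]
    auc: dict[str, np.ndarray]               # criterion -> (len(m), len(r))
    median_success: dict[str, np.ndarray]
    median_failure: dict[str, np.ndarray]
    optimum: dict[str, tuple[int, float, float]]  # criterion -> (m, r, auc)
    entropies: np.ndarray = field(repr=False, default=None)


def _check_binary(labels) -> np.ndarray:
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or (~labels).all():
        raise ClassError("need at least one success and one failure")
    return labels


def roc_curve(scores, labels, larger_is_success: bool = True,
              positive_label: str = "success") -> RocCurve:
    """ROC curve with one vertex per distinct score plus both endpoints.

    Ties share a single vertex, which makes the trapezoidal AUC equal to
    the tie-corrected rank statistic U / (n1 · n2).
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    s = scores if larger_is_success else -scores
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos

    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = labels[order]
    # cumulative counts at each distinct threshold (predict success if >= t)
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(~y_sorted)[distinct]
    thr = s_sorted[distinct]
    # prepend the "predict nothing" endpoint
    tp = np.r_[0, tp]
    fp = np.r_[0, fp]
    thr = np.r_[np.inf, thr]
    se = 100.0 * tp / n_pos
    sp = 100.0 * (n_neg - fp) / n_neg
    auc = float(np.trapezoid(tp / n_pos, fp / n_neg))
    return RocCurve(thresholds=thr, se=se, sp=sp, auc=auc,
                    positive_label=positive_label,
                    larger_is_success=larger_is_success)


def balanced_accuracy(se: float, sp: float) -> float:
    """Balanced accuracy (Se + Sp) / 2, all in percent."""
    if not (0.0 <= se <= 100.0 and 0.0 <= sp <= 100.0):
        raise DomainError(f"Se/Sp must be in [0, 100], got {se}, {sp}")
    return (se + sp) / 2.0


def _interp_along(x, y, x0):
    """Linear interpolation of y at x0 along the ROC's upper envelope.

    Several vertices can share the same x (e.g. Sp = 100 at multiple
    thresholds); the attainable operating point is the best y among them,
    so duplicates are collapsed to their maximum before interpolating.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    xu = np.unique(x)
    yu = np.array([y[x == v].max() for v in xu])
    return float(np.interp(x0, xu, yu))


def critical_cutoffs(roc: RocCurve) -> CutoffReport:
    """The four Se/Sp operating points reported for every predictor.

    Se-at-Sp90 and Sp-at-Se90 are linearly interpolated between adjacent
    ROC vertices; the Youden and closest-to-(0,1) points are exact vertices
    with their thresholds.
    """
    se, sp, thr = roc.se, roc.sp, roc.thresholds
    se_at_sp90 = _interp_along(sp, se, 90.0)
    sp_at_se90 = _interp_along(se, sp, 90.0)

    bac = (se + sp) / 2.0
    i = int(np.argmax(bac))
    youden = (float(se[i]), float(sp[i]), float(thr[i]))
    dist2 = (1.0 - se / 100.0) ** 2 + (1.0 - sp / 100.0) ** 2
    j = int(np.argmin(dist2))
    closest01 = (float(se[j]), float(sp[j]), float(thr[j]))
    return CutoffReport(se_at_sp90=se_at_sp90, sp_at_se90=sp_at_se90,
                        youden=youden, closest01=closest01)


def mann_whitney(a, b, exact_max_n: int = 20) -> float:
    """Two-sided Mann–Whitney p-value with tie correction.

    Exact null distribution when both samples are small and tie-free,
    normal approximation (tie-corrected, no continuity correction)
    otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ClassError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if has_ties and np.unique(pooled).size == 1:
        return 1.0  # all values identical: no evidence either way
    method = ("exact" if not has_ties and max(a.size, b.size) <= exact_max_n
              else "asymptotic")
    res = spstats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                               use_continuity=False)
    return float(min(res.pvalue, 1.0))


def grid_search(
    cohort,
    entropy_fn,
    m_values=DEFAULT_M_VALUES,
    r_values=DEFAULT_R_VALUES,
    criteria=("qrs", "survival"),
) -> GridResult:
    """AUC of an entropy statistic over the (m, r) grid, per criterion.

    ``cohort`` is a list of ``(x, labels)`` pairs where ``x`` is the
    preprocessed analysis window at the working rate and ``labels`` maps
    criterion name to a boolean outcome.  ``entropy_fn(x, params)`` must
    return a float (NaN-free; undefined values should be substituted by the
    caller, e.g. with 0 matches mapped to a small floor).

    Ties in AUC are broken toward smaller r, then smaller m.  Per-cell
    per-class median entropies are retained for tolerance-sweep plots.
    """
    if not m_values or not r_values:
        raise ValueError("grid must be non-empty")
    cohort = list(cohort)
    if len(cohort) < 2:
        raise ClassError("cohort must contain at least two shocks")
    label_arrays = {
        c: _check_binary([labels[c] for _, labels in cohort]) for c in criteria
    }
    shape = (len(m_values), len(r_values))
    auc = {c: np.zeros(shape) for c in criteria}
    med_s = {c: np.zeros(shape) for c in criteria}
    med_f = {c: np.zeros(shape) for c in criteria}
    entropies = np.zeros(shape + (len(cohort),))
    for i, m in enumerate(m_values):
        for j, r in enumerate(r_values):
            params = EntropyParams(m=m, r=r)
            vals = np.array([float(entropy_fn(x, params)) for x, _ in cohort])
            entropies[i, j] = vals
            for c in criteria:
                y = label_arrays[c]
                auc[c][i, j] = roc_curve(vals, y).auc
                med_s[c][i, j] = np.median(vals[y])
                med_f[c][i, j] = np.median(vals[~y])
    optimum = {}
    for c in criteria:
        best = None
        for j, r in enumerate(r_values):      # smaller r wins ties
            for i, m in enumerate(m_values):  # then smaller m
                cell = auc[c][i, j]
                if best is None or cell > best[2] + 1e-12:
                    best = (m, float(r), float(cell))
        optimum[c] = best
    return GridResult(m_values=tuple(m_values),
                      r_values=tuple(float(r) for r in r_values),
                      auc=auc, median_success=med_s, median_failure=med_f,
                      optimum=optimum, entropies=entropies)


def window_length_sweep(
    cases,
    wl_values,
    feature_fns,
    criteria=("qrs", "survival"),
):
    """Re-extract windows at each length and tabulate AUC per feature.

    ``cases`` is a list of ``(EcgRecord, ShockEvent)`` pairs;
    ``feature_fns`` maps feature name to a callable taking an
    :class:`~vfshock.signal_io.AnalysisWindow` and returning a float.
    Shocks whose record cannot supply a window at some length are dropped
    for that length and reported in the returned ``dropped`` dict.

    Returns ``(auc, dropped)`` with ``auc[(wl, feature, criterion)]``.
    """
    auc: dict[tuple[float, str, str], float] = {}
    dropped: dict[float, int] = {}
    for wl in wl_values:
        windows, labels = [], []
        n_drop = 0
        for record, shock in cases:
            try:
                windows.append(extract_preshock_window(record, shock, wl))
                labels.append({c: shock.label(c) for c in criteria})
            except WindowError:
                n_drop += 1
        dropped[float(wl)] = n_drop
        if not windows:
            continue
        for name, fn in feature_fns.items():
            vals = np.array([float(fn(w)) for w in windows])
            for c in criteria:
                y = np.asarray([lab[c] for lab in labels], dtype=bool)
                auc[(float(wl), name, c)] = roc_curve(vals, y).auc
    return auc, dropped
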
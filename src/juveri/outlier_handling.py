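"""Three-criterion outlier procedure: fence, retain-if-fixable, Cook's.

The screen flags suspect points with a wide Tukey fence (Q1 - 3 IQR,
Q3 + 3 IQR).  Flagged points are *retained* when the full sample already
has an acceptable distribution after the best power transform (criterion
b); otherwise they are removed and the sample re-tested (criterion a); if
the distribution still fails, observations with outsized influence on a
normal-scores regression are deleted by Cook's distance (criterion c).
Every step is recorded in an audit trail — points are never dropped
silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.outliers_influence import OLSInfluence

from .distribution_diagnostics import (
    DegenerateSampleError,
    DiagnosticsReport,
    InsufficientSampleError,
    TransformSpec,
    apply_transform,
    diagnostics_report,
    fit_power_transform,
)

DEFAULT_FENCE_K = 3.0


@dataclass
class OutlierReport:
    """Audit trail of the outlier decision for one sample.

    ``criterion_applied`` is one of ``b_retained`` (flagged points kept),
    ``a_removed`` (fence outliers removed) or ``c_cook`` (Cook's-distance
    deletions on top of fence removal).
    """

    q1: float
    q3: float
    iqr: float
    lower_fence: float
    upper_fence: float
    fence_flagged: tuple[int, ...]
    cook_flagged: tuple[int, ...] = ()
    retained: bool = True
    criterion_applied: str = "b_retained"
    transform: TransformSpec | None = None
    diagnostics_initial: DiagnosticsReport | None = None
    diagnostics_final: DiagnosticsReport | None = None
    removed_indices: tuple[int, ...] = ()
    notes: list[str] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return len(self.removed_indices)

    def to_dict(self) -> dict:
        def diag(d: DiagnosticsReport | None):
            if d is None:
                return None
            return {
                "ad_statistic": d.ad_statistic,
                "ad_p": d.ad_p,
                "symmetry_statistic": d.symmetry_statistic,
                "symmetry_p": d.symmetry_p,
                "normal_ok": d.normal_ok,
                "symmetric_ok": d.symmetric_ok,
            }

        return {
            "q1": self.q1,
            "q3": self.q3,
            "iqr": self.iqr,
            "lower_fence": self.lower_fence,
            "upper_fence": self.upper_fence,
            "fence_flagged": list(self.fence_flagged),
            "cook_flagged": list(self.cook_flagged),
            "retained": self.retained,
            "criterion_applied": self.criterion_applied,
            "transform": None
            if self.transform is None
            else {"lambda": self.transform.lambda_, "offset": self.transform.offset},
            "diagnostics_initial": diag(self.diagnostics_initial),
            "diagnostics_final": diag(self.diagnostics_final),
            "removed_indices": list(self.removed_indices),
            "notes": list(self.notes),
        }


def iqr_fence_outliers(values, k: float = DEFAULT_FENCE_K) -> OutlierReport:
    """Flag values strictly outside the Tukey fence at ``k`` IQR.

    Quartiles use linear interpolation of order statistics (position
    ``p (n - 1) + 1``), so fences are reproducible across conventions.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        raise InsufficientSampleError(f"fence needs n >= 4, got {arr.size}")
    q1, q3 = np.percentile(arr, [25.0, 75.0], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    flagged = tuple(int(i) for i in np.flatnonzero((arr < lo) | (arr > hi)))
    return OutlierReport(
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        lower_fence=float(lo),
        upper_fence=float(hi),
        fence_flagged=flagged,
    )


def cooks_outliers(values, threshold_rule: Callable[[int], float] | None = None) -> tuple[int, ...]:
    """Influential observations of a normal-scores regression.

    Sorted values are regressed (OLS) on normal quantile scores at Blom
    plotting positions ``(i - 3/8) / (n + 1/4)``; observations with Cook's
    distance above ``4 / n`` (default rule) are flagged.  Leverage here
    measures departure from straightness of the normal Q-Q relationship,
    i.e. the points preventing normality.
    """
    arr = np.asarray(values, dtype=float)
    n = arr.size
    if n < 10:
        raise InsufficientSampleError(f"Cook's screen needs n >= 10, got {n}")
    if np.ptp(arr) == 0:
        raise DegenerateSampleError("zero-variance sample")
    order = np.argsort(arr, kind="stable")
    scores = stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    model = sm.OLS(arr[order], sm.add_constant(scores)).fit()
    if model.mse_resid <= 1e-24 * float(np.var(arr)):
        return ()  # exact fit: no observation is influential
    cooks = OLSInfluence(model).cooks_distance[0]
    cutoff = (threshold_rule or (lambda m: 4.0 / m))(n)
    flagged_sorted = np.flatnonzero(cooks > cutoff)
    return tuple(sorted(int(order[j]) for j in flagged_sorted))


def _default_diagnostics(values: np.ndarray) -> tuple[bool, TransformSpec, DiagnosticsReport]:
    """Retention test: is any estimator still valid with every point in?

    Acceptable when the best Box-Cox transform achieves normality (a
    transformed standard interval is computable) or the raw sample is
    symmetric (a robust interval is computable).  This is the "good
    distribution and/or symmetricity" retention rule, phrased in terms of
    the methods the selection tree can actually choose.
    """
    tf = fit_power_transform(values)
    report = diagnostics_report(apply_transform(values, tf))
    _, raw_sym_p = stats.skewtest(values) if np.ptp(values) > 0 else (0.0, 0.0)
    ok = report.normal_ok or raw_sym_p >= report.symmetry_alpha
    return ok, tf, report


def outlier_decision(
    values,
    diagnostics_fn: Callable[[np.ndarray], tuple[bool, TransformSpec, DiagnosticsReport]] | None = None,
    *,
    fence_k: float = DEFAULT_FENCE_K,
    cook_threshold_rule: Callable[[int], float] | None = None,
) -> tuple[np.ndarray, OutlierReport]:
    """Run the full three-criterion outlier procedure.

    Parameters
    ----------
    values : array-like
        Raw cell values, n >= 10.
    diagnostics_fn : callable, optional
        Maps a sample to ``(acceptable, transform, report)``.  The default
        fits the best Box-Cox transform and requires the transformed
        sample to be normal and/or symmetric (the study's "fixable"
        condition).  Cook's screening runs on this best-transformed scale.

    Returns
    -------
    (cleaned, report)
        Cleaned values (original order preserved) and the audit trail;
        ``len(cleaned) + len(report.removed_indices) == len(values)``
        always holds.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 10:
        raise InsufficientSampleError(f"outlier decision needs n >= 10, got {arr.size}")
    fn = diagnostics_fn or _default_diagnostics
    report = iqr_fence_outliers(arr, k=fence_k)

    ok, tf, diag = fn(arr)
    report.transform = tf
    report.diagnostics_initial = diag
    if ok:
        # Criterion b: distribution acceptable with every point in place.
        report.retained = True
        report.criterion_applied = "b_retained"
        report.diagnostics_final = diag
        if report.fence_flagged:
            report.notes.append(
                f"{len(report.fence_flagged)} fence-flagged point(s) retained"
            )
        return arr.copy(), report

    # Criterion a: remove fence outliers and re-test.
    keep_mask = np.ones(arr.size, dtype=bool)
    keep_mask[list(report.fence_flagged)] = False
    trimmed = arr[keep_mask]
    removed = list(report.fence_flagged)
    if report.fence_flagged and trimmed.size >= 10:
        ok2, tf2, diag2 = fn(trimmed)
        if ok2:
            report.retained = False
            report.criterion_applied = "a_removed"
            report.transform = tf2
            report.diagnostics_final = diag2
            report.removed_indices = tuple(sorted(removed))
            report.notes.append(
                f"removed {len(removed)} fence outlier(s); distribution acceptable after removal"
            )
            return trimmed, report

    # Criterion c: Cook's-distance deletion on the best-transformed scale.
    base = trimmed if (report.fence_flagged and trimmed.size >= 10) else arr
    base_removed = removed if base is trimmed else []
    tf3 = fit_power_transform(base)
    cook_local = cooks_outliers(
        apply_transform(base, tf3), threshold_rule=cook_threshold_rule
    )
    base_orig_idx = np.flatnonzero(keep_mask) if base is trimmed else np.arange(arr.size)
    cook_orig = sorted(int(base_orig_idx[j]) for j in cook_local)
    keep2 = np.ones(base.size, dtype=bool)
    keep2[list(cook_local)] = False
    cleaned = base[keep2]
    report.retained = False
    report.criterion_applied = "c_cook"
    report.cook_flagged = tuple(cook_orig)
    report.removed_indices = tuple(sorted(set(base_removed) | set(cook_orig)))
    if cleaned.size >= 10:
        ok4, tf4, diag4 = fn(cleaned)
        report.transform = tf4
        report.diagnostics_final = diag4
        if not ok4:
            report.notes.append(
                "distribution still unacceptable after Cook's deletions (unfixable)"
            )
    report.notes.append(
        f"Cook's deletions: {len(cook_orig)} point(s) on transformed scale"
    )
    return cleaned, report
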
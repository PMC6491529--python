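"""Reference-interval estimators and the N-driven method-selection tree.

Three estimators of the central 95% reference interval:

* **non-parametric** (NP): rank interpolation at positions ``p (n + 1)``
  (CLSI convention), the preferred method at n >= 120;
* **parametric standard**: ``mean +/- z sd`` on the raw or Box-Cox
  transformed scale, back-transformed to analyte units;
* **robust**: iterated Tukey-biweight location and scale (Horn-style),
  limits at ``location +/- t(1 - alpha/2, n - 1) * scale``.

90% confidence intervals on each limit come from distribution-free
binomial rank bounds (NP at large n) or a seeded percentile bootstrap.
``select_method`` reproduces the study's decision tree: outlier handling
first, NP at n >= 120, otherwise parametric on the first scale that looks
normal, the robust method for symmetric-but-non-normal samples, and an NP
forced fallback when the distribution is unfixable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy import stats

from .distribution_diagnostics import (
    DiagnosticsReport,
    TransformSpec,
    apply_transform,
    diagnostics_report,
    fit_power_transform,
    invert_transform,
)
from .outlier_handling import OutlierReport, outlier_decision


class SmallSampleError(ValueError):
    """Too few reference individuals for any estimator."""


class UnfixableDistributionError(ValueError):
    """Diagnostics failed on the working scale of a parametric fit."""


class ConvergenceError(RuntimeError):
    """Iterative robust estimator failed to converge."""


class MethodLabel(str, enum.Enum):
    """RI estimation method vocabulary, matching the study's table labels."""

    NP = "NP"
    UNTRANSFORMED_STANDARD = "Untrans. Std."
    TRANSFORMED_STANDARD = "Trans. Std."
    UNTRANSFORMED_ROBUST = "Untrans. Rob."
    TRANSFORMED_ROBUST = "Trans. Rob."

    @property
    def is_parametric(self) -> bool:
        return self in (MethodLabel.UNTRANSFORMED_STANDARD, MethodLabel.TRANSFORMED_STANDARD)

    @property
    def is_robust(self) -> bool:
        return self in (MethodLabel.UNTRANSFORMED_ROBUST, MethodLabel.TRANSFORMED_ROBUST)


@dataclass(frozen=True)
class ReferenceInterval:
    """A reference interval with its provenance.

    ``ci90_lower`` / ``ci90_upper`` are (low, high) 90% confidence bounds
    on the lower and upper reference limits, or None when not computed.
    """

    lower: float
    upper: float
    method: MethodLabel
    n: int
    coverage: float = 0.95
    transform: TransformSpec | None = None
    ci90_lower: tuple[float, float] | None = None
    ci90_upper: tuple[float, float] | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError(f"RI lower {self.lower} exceeds upper {self.upper}")

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass
class MethodDecision:
    """Trace of the method-selection tree for one sample."""

    chosen: MethodLabel
    n: int
    diagnostics_raw: DiagnosticsReport | None
    diagnostics_transformed: DiagnosticsReport | None
    transform: TransformSpec | None
    outlier_report: OutlierReport
    note: str = ""

    def to_dict(self) -> dict:
        def diag(d):
            if d is None:
                return None
            return {
                "ad_p": d.ad_p,
                "symmetry_p": d.symmetry_p,
                "normal_ok": d.normal_ok,
                "symmetric_ok": d.symmetric_ok,
            }

        return {
            "chosen": self.chosen.value,
            "n": self.n,
            "diagnostics_raw": diag(self.diagnostics_raw),
            "diagnostics_transformed": diag(self.diagnostics_transformed),
            "transform": None
            if self.transform is None
            else {"lambda": self.transform.lambda_, "offset": self.transform.offset},
            "outliers": self.outlier_report.to_dict(),
            "note": self.note,
        }


@dataclass(frozen=True)
class RIConfig:
    """Tunable constants of the pipeline, with study defaults."""

    coverage: float = 0.95
    np_min_n: int = 120  # NP preferred at and above this n
    hard_min_n: int = 20  # refuse below this n (ASVCP floor)
    bootstrap_B: int = 5000
    fence_k: float = 3.0
    ad_alpha: float = 0.05
    symmetry_alpha: float = 0.01
    overlap_alpha: float = 0.05
    #: Bonferroni factor across the analyte panel for post-hoc p-values;
    #: None means "use the panel size" in the pipeline, 1 means plain Tukey.
    bonferroni_analytes: int | None = None
    biweight_c_location: float = 3.7
    biweight_c_scale: float = 9.0
    adult_comparable_jaccard: float = 0.5
    seed: int = 0


def _tail_p(coverage: float) -> float:
    return (1.0 - coverage) / 2.0


def _rank_interpolate(sorted_rows: np.ndarray, p: float) -> np.ndarray:
    """Limit at rank ``p (n + 1)`` with linear interpolation, rowwise.

    ``sorted_rows`` is (m, n) with each row sorted ascending; ranks falling
    outside [1, n] clamp to the sample minimum / maximum.
    """
    n = sorted_rows.shape[-1]
    r = p * (n + 1)
    if r <= 1:
        return sorted_rows[..., 0]
    if r >= n:
        return sorted_rows[..., -1]
    lo = int(np.floor(r))
    frac = r - lo
    return sorted_rows[..., lo - 1] + frac * (sorted_rows[..., lo] - sorted_rows[..., lo - 1])


def nonparametric_ri(values, coverage: float = 0.95, *, np_min_n: int = 120) -> ReferenceInterval:
    """Non-parametric (percentile) reference interval.

    Limits at ranks ``p (n + 1)``; preferred at n >= ``np_min_n``, accepted
    down to n = 20 with a forced-fallback note (the small-sample NP
    interval is imprecise but assumption-free).
    """
    arr = np.sort(np.asarray(values, dtype=float))
    n = arr.size
    if n < 20:
        raise SmallSampleError(f"non-parametric RI refused at n={n} < 20")
    note = "" if n >= np_min_n else f"forced NP at n={n} < {np_min_n}"
    p = _tail_p(coverage)
    lower = float(_rank_interpolate(arr, p))
    upper = float(_rank_interpolate(arr, 1.0 - p))
    return ReferenceInterval(
        lower=lower, upper=upper, method=MethodLabel.NP, n=n, coverage=coverage, note=note
    )


def parametric_ri(
    values,
    transform: TransformSpec | None = None,
    coverage: float = 0.95,
    *,
    check_diagnostics: bool = False,
    ad_alpha: float = 0.05,
) -> ReferenceInterval:
    """Parametric standard reference interval, optionally on a transformed scale.

    On the working scale the limits are ``mean +/- z sd`` with z the
    standard normal quantile (1.95996 for 95% coverage, not the rounded
    2.0), back-transformed to analyte units when a transform is given.
    With ``check_diagnostics`` the working-scale sample must pass the
    Anderson-Darling screen, otherwise the fit is refused.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 20:
        raise SmallSampleError(f"parametric RI refused at n={arr.size} < 20")
    work = apply_transform(arr, transform) if transform is not None else arr
    if check_diagnostics:
        report = diagnostics_report(work, ad_alpha=ad_alpha)
        if not report.normal_ok:
            raise UnfixableDistributionError(
                f"normality rejected on working scale (AD p={report.ad_p:.4g})"
            )
    z = stats.norm.ppf(1.0 - _tail_p(coverage))
    m, s = float(np.mean(work)), float(np.std(work, ddof=1))
    lo_w, hi_w = m - z * s, m + z * s
    if transform is not None:
        # Back-transform; a working-scale limit beyond the power-family
        # branch maps to the closed end of the support.
        try:
            lo = float(invert_transform(np.array([lo_w]), transform)[0])
        except ValueError:
            lo = 0.0
        try:
            hi = float(invert_transform(np.array([hi_w]), transform)[0])
        except ValueError as exc:
            raise UnfixableDistributionError(
                f"upper limit outside transform domain: {exc}"
            ) from exc
        label = MethodLabel.TRANSFORMED_STANDARD
    else:
        lo, hi = lo_w, hi_w
        label = MethodLabel.UNTRANSFORMED_STANDARD
    return ReferenceInterval(
        lower=max(0.0, lo),
        upper=hi,
        method=label,
        n=arr.size,
        coverage=coverage,
        transform=transform,
    )


def biweight_location_scale(
    values: np.ndarray,
    *,
    c_location: float = 3.7,
    c_scale: float = 9.0,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterated Tukey-biweight location and biweight-midvariance scale.

    Works rowwise on a (m, n) matrix (or a single 1-D sample).  Location
    starts at the median and iterates the biweight mean (tuning
    ``c_location`` in MAD units) until the relative change drops below
    ``tol``; the scale is the biweight midvariance (tuning ``c_scale``),
    consistent for the SD under normality.

    Raises :class:`ConvergenceError` if any row fails to converge within
    ``max_iter`` iterations.
    """
    x = np.atleast_2d(np.asarray(values, dtype=float))
    med = np.median(x, axis=1, keepdims=True)
    mad = np.median(np.abs(x - med), axis=1, keepdims=True)
    fallback = np.std(x, axis=1, keepdims=True)
    mad = np.where(mad > 0, mad, fallback)
    if np.any(mad <= 0):
        raise ConvergenceError("degenerate sample: zero spread")
    t = med.copy()
    converged = np.zeros(x.shape[0], dtype=bool)
    for _ in range(max_iter):
        u = (x - t) / (c_location * mad)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        t_new = np.sum(w * x, axis=1, keepdims=True) / np.sum(w, axis=1, keepdims=True)
        step = np.abs(t_new - t) / np.maximum(1.0, np.abs(t))
        converged |= (step <= tol).ravel()
        t = t_new
        if converged.all():
            break
    if not converged.all():
        bad = int(np.flatnonzero(~converged)[0])
        raise ConvergenceError(
            f"biweight location did not converge in {max_iter} iterations "
            f"(row {bad}, last step {float(step.ravel()[bad]):.3g})"
        )
    n = x.shape[1]
    u = (x - t) / (c_scale * mad)
    inside = np.abs(u) < 1
    num_terms = np.where(inside, (x - t) ** 2 * (1 - u**2) ** 4, 0.0)
    den_terms = np.where(inside, (1 - u**2) * (1 - 5 * u**2), 0.0)
    s = np.sqrt(n * np.sum(num_terms, axis=1)) / np.abs(np.sum(den_terms, axis=1))
    return t.ravel(), s


def robust_ri(
    values,
    coverage: float = 0.95,
    transform: TransformSpec | None = None,
    *,
    c_location: float = 3.7,
    c_scale: float = 9.0,
) -> ReferenceInterval:
    """Horn-style robust reference interval (biweight location/scale).

    Limits on the working scale are ``T +/- t(1 - alpha/2, n - 1) * s``
    with T the iterated biweight location and s the biweight midvariance
    scale; back-transformed when a transform is given.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 20:
        raise SmallSampleError(f"robust RI refused at n={arr.size} < 20")
    work = apply_transform(arr, transform) if transform is not None else arr
    t_loc, s = biweight_location_scale(work, c_location=c_location, c_scale=c_scale)
    tq = stats.t.ppf(1.0 - _tail_p(coverage), arr.size - 1)
    lo_w, hi_w = float(t_loc[0] - tq * s[0]), float(t_loc[0] + tq * s[0])
    if transform is not None:
        try:
            lo = float(invert_transform(np.array([lo_w]), transform)[0])
        except ValueError:
            lo = 0.0
        hi = float(invert_transform(np.array([hi_w]), transform)[0])
        label = MethodLabel.TRANSFORMED_ROBUST
    else:
        lo, hi = lo_w, hi_w
        label = MethodLabel.UNTRANSFORMED_ROBUST
    return ReferenceInterval(
        lower=max(0.0, lo),
        upper=hi,
        method=label,
        n=arr.size,
        coverage=coverage,
        transform=transform,
    )


def _binomial_rank_ci(
    sorted_values: np.ndarray, p: float, level: float = 0.90
) -> tuple[float, float]:
    """Distribution-free CI for the p-th population quantile.

    Order-statistic bounds (X_(l), X_(u)) with l the largest rank whose
    lower tail stays within (1 - level)/2 and u the smallest rank whose
    cumulative binomial probability reaches 1 - (1 - level)/2.
    """
    n = sorted_values.size
    tail = (1.0 - level) / 2.0
    k = np.arange(1, n + 1)
    cdf_below = stats.binom.cdf(k - 1, n, p)  # P(fewer than k values below quantile)
    l_candidates = k[cdf_below <= tail]
    l = int(l_candidates[-1]) if l_candidates.size else 1
    u_candidates = k[cdf_below >= 1.0 - tail]
    u = int(u_candidates[0]) if u_candidates.size else n
    return float(sorted_values[l - 1]), float(sorted_values[u - 1])


def limit_confidence_intervals(
    values,
    method: MethodLabel,
    *,
    coverage: float = 0.95,
    level: float = 0.90,
    B: int = 5000,
    seed: int | np.random.SeedSequence | None = None,
    transform: TransformSpec | None = None,
    np_min_n: int = 120,
    c_location: float = 3.7,
    c_scale: float = 9.0,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """90% confidence intervals on the lower and upper reference limits.

    NP intervals at n >= ``np_min_n`` get exact distribution-free binomial
    rank CIs; every other case uses a seeded percentile bootstrap of the
    limit (``B`` resamples, B >= 100).  For transformed fits the transform
    is held fixed across resamples (refitting the exponent per resample
    changes the estimand, not just its uncertainty).
    """
    if B < 100:
        raise ValueError(f"bootstrap B={B} < 100 refused")
    arr = np.asarray(values, dtype=float)
    n = arr.size
    p = _tail_p(coverage)
    if method is MethodLabel.NP and n >= np_min_n:
        srt = np.sort(arr)
        return _binomial_rank_ci(srt, p, level), _binomial_rank_ci(srt, 1 - p, level)

    rng = np.random.default_rng(seed)
    work = apply_transform(arr, transform) if transform is not None else arr
    idx = rng.integers(0, n, size=(B, n))
    res = work[idx]
    if method is MethodLabel.NP:
        res.sort(axis=1)
        lows = _rank_interpolate(res, p)
        highs = _rank_interpolate(res, 1 - p)
    elif method.is_parametric:
        z = stats.norm.ppf(1 - p)
        m = res.mean(axis=1)
        s = res.std(axis=1, ddof=1)
        lows, highs = m - z * s, m + z * s
    elif method.is_robust:
        t_loc, s = biweight_location_scale(res, c_location=c_location, c_scale=c_scale)
        tq = stats.t.ppf(1 - p, n - 1)
        lows, highs = t_loc - tq * s, t_loc + tq * s
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unknown method {method}")

    def back(v: np.ndarray) -> np.ndarray:
        if transform is None:
            return v
        base = (
            np.exp(v) - transform.offset
            if transform.is_log
            else np.where(transform.lambda_ * v + 1 > 0, transform.lambda_ * v + 1, np.nan)
            ** (1 / transform.lambda_ if transform.lambda_ != 0 else 1)
            - transform.offset
        )
        return base

    lows, highs = back(lows), back(highs)
    tail_pct = 100 * (1.0 - level) / 2.0
    ci_lower = tuple(float(q) for q in np.nanpercentile(lows, [tail_pct, 100 - tail_pct]))
    ci_upper = tuple(float(q) for q in np.nanpercentile(highs, [tail_pct, 100 - tail_pct]))
    return ci_lower, ci_upper


def select_method(
    values,
    config: RIConfig | None = None,
    *,
    compute_cis: bool = False,
    seed: int | np.random.SeedSequence | None = None,
    diagnostics_fn: Callable | None = None,
) -> tuple[ReferenceInterval, MethodDecision]:
    """Outlier handling plus the N-driven method-selection decision tree.

    Order of preference after cleaning: non-parametric at n >= 120;
    parametric standard on the raw scale when it already looks normal;
    parametric standard after the best Box-Cox transform; robust on the
    raw scale when symmetric but not normalisable; otherwise the NP forced
    fallback (the "unfixable distribution" route: normality rejected on
    both scales and symmetry rejected on the raw scale).
    """
    cfg = config or RIConfig()
    arr = np.asarray(values, dtype=float)
    cleaned, outlier_report = outlier_decision(
        arr, diagnostics_fn, fence_k=cfg.fence_k
    )
    n = cleaned.size
    if n < cfg.hard_min_n:
        raise SmallSampleError(
            f"n={n} after outlier handling is below the floor of {cfg.hard_min_n}; "
            "recruit more reference individuals"
        )
    diag_raw = diagnostics_report(
        cleaned, ad_alpha=cfg.ad_alpha, symmetry_alpha=cfg.symmetry_alpha
    )
    diag_t: DiagnosticsReport | None = None
    tf: TransformSpec | None = None
    note = ""

    if n >= cfg.np_min_n:
        ri = nonparametric_ri(cleaned, cfg.coverage, np_min_n=cfg.np_min_n)
    elif diag_raw.normal_ok:
        ri = parametric_ri(cleaned, None, cfg.coverage)
    else:
        tf = fit_power_transform(cleaned)
        diag_t = diagnostics_report(
            apply_transform(cleaned, tf),
            ad_alpha=cfg.ad_alpha,
            symmetry_alpha=cfg.symmetry_alpha,
        )
        if diag_t.normal_ok:
            ri = parametric_ri(cleaned, tf, cfg.coverage)
        elif diag_raw.symmetric_ok:
            ri = robust_ri(
                cleaned,
                cfg.coverage,
                c_location=cfg.biweight_c_location,
                c_scale=cfg.biweight_c_scale,
            )
        else:
            note = (
                "unfixable distribution (normality rejected on the raw and "
                "transformed scales, symmetry rejected); non-parametric fallback"
            )
            ri = nonparametric_ri(cleaned, cfg.coverage, np_min_n=cfg.np_min_n)
            ri = replace(ri, note=note)

    if compute_cis:
        ci_lo, ci_hi = limit_confidence_intervals(
            cleaned,
            ri.method,
            coverage=cfg.coverage,
            B=cfg.bootstrap_B,
            seed=seed if seed is not None else cfg.seed,
            transform=ri.transform,
            np_min_n=cfg.np_min_n,
            c_location=cfg.biweight_c_location,
            c_scale=cfg.biweight_c_scale,
        )
        ri = replace(ri, ci90_lower=ci_lo, ci90_upper=ci_hi)

    decision = MethodDecision(
        chosen=ri.method,
        n=n,
        diagnostics_raw=diag_raw,
        diagnostics_transformed=diag_t,
        transform=ri.transform,
        outlier_report=outlier_report,
        note=note or ri.note,
    )
    return ri, decision
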
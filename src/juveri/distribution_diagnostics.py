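"""Normality and symmetry diagnostics, power transformation, overlap screen.

These are the gatekeepers of the method-selection tree: a cell's data must
look normal (Anderson-Darling) on some Box-Cox scale before a parametric
standard interval is allowed, must at least be symmetric (D'Agostino
skewness test) before the robust interval is allowed, and subgroup
distributions (trials, sexes) must overlap before pooling.

Thresholds follow the study conventions: Anderson-Darling at alpha 0.05,
symmetry at alpha 0.01, subgroup overlap (pairwise two-sample
Kolmogorov-Smirnov, Bonferroni-adjusted) at family-wise alpha 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import optimize, stats

MIN_DIAGNOSTIC_N = 8
#: |lambda| below this is collapsed to an exact log transform.
LOG_LAMBDA_TOL = 0.01


class InsufficientSampleError(ValueError):
    """Sample too small for the requested diagnostic."""


class DegenerateSampleError(ValueError):
    """Sample has zero variance; diagnostics are undefined."""


@dataclass(frozen=True)
class TransformSpec:
    """A Box-Cox power transform with a positivity offset.

    ``y = ((x + offset)^lambda - 1) / lambda`` for lambda != 0 and
    ``y = log(x + offset)`` at lambda == 0.  The offset is 0 when all
    values are positive, else ``1 - min(x)``, which guarantees the shifted
    data start at 1.
    """

    lambda_: float
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError("transform offset must be >= 0")

    @property
    def is_log(self) -> bool:
        return self.lambda_ == 0.0

    @property
    def is_identity_like(self) -> bool:
        """True when the transform is the affine map x - 1 (lambda = 1)."""
        return self.lambda_ == 1.0 and self.offset == 0.0


IDENTITY_TRANSFORM = TransformSpec(lambda_=1.0, offset=0.0)


@dataclass(frozen=True)
class DiagnosticsReport:
    """Anderson-Darling + symmetry test results with threshold flags."""

    ad_statistic: float
    ad_p: float
    symmetry_statistic: float
    symmetry_p: float
    ad_alpha: float = 0.05
    symmetry_alpha: float = 0.01

    @property
    def normal_ok(self) -> bool:
        return self.ad_p >= self.ad_alpha

    @property
    def symmetric_ok(self) -> bool:
        return self.symmetry_p >= self.symmetry_alpha

    @property
    def fixable(self) -> bool:
        """Acceptable distribution: normal and/or symmetric.

        The converse — both tests rejecting — is the study's "unfixable
        distribution" condition that forces the non-parametric fallback.
        """
        return self.normal_ok or self.symmetric_ok


@dataclass(frozen=True)
class OverlapReport:
    """Pairwise subgroup-distribution comparison for pooling decisions."""

    pairwise_p: dict[tuple[str, str], float]
    adjusted_p: dict[tuple[str, str], float]
    pooled_ok: bool
    offending_pairs: tuple[tuple[str, str], ...]
    note: str = ""


def _check_sample(values: np.ndarray, min_n: int = MIN_DIAGNOSTIC_N) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.size < min_n:
        raise InsufficientSampleError(f"need n >= {min_n}, got {arr.size}")
    if np.ptp(arr) == 0:
        raise DegenerateSampleError("zero-variance sample")
    return arr


def anderson_darling(values) -> tuple[float, float]:
    """Anderson-Darling test of normality with estimated mean and SD.

    Returns ``(A2, p)`` where ``A2`` is the uncorrected statistic and the
    p-value comes from the small-sample-corrected statistic
    ``A* = A2 (1 + 0.75/n + 2.25/n^2)`` via the standard piecewise
    exponential approximation for the estimated-parameters case.
    """
    arr = _check_sample(values)
    n = arr.size
    z = np.sort((arr - arr.mean()) / arr.std(ddof=1))
    cdf = np.clip(stats.norm.cdf(z), 1e-300, 1 - 1e-16)
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (np.log(cdf) + np.log1p(-cdf[::-1])))
    a_star = a2 * (1 + 0.75 / n + 2.25 / n**2)
    if a_star >= 0.6:
        p = math.exp(1.2937 - 5.709 * a_star + 0.0186 * a_star**2)
    elif a_star > 0.34:
        p = math.exp(0.9177 - 4.279 * a_star - 1.38 * a_star**2)
    elif a_star > 0.2:
        p = 1 - math.exp(-8.318 + 42.796 * a_star - 59.938 * a_star**2)
    else:
        p = 1 - math.exp(-13.436 + 101.14 * a_star - 223.73 * a_star**2)
    return float(a2), float(min(max(p, 0.0), 1.0))


def symmetry_test(values) -> tuple[float, float]:
    """D'Agostino skewness test: two-sided test of zero skewness.

    Sample skewness is mapped to an approximately standard normal deviate;
    an exactly symmetric sample gives statistic 0 and p = 1.
    """
    arr = _check_sample(values)
    if stats.skew(arr) == 0.0:
        # exactly symmetric sample: the normal deviate is 0 by definition
        # (scipy substitutes a non-zero placeholder at b1 == 0)
        return 0.0, 1.0
    statistic, p = stats.skewtest(arr)
    return float(statistic), float(p)


def diagnostics_report(
    values, *, ad_alpha: float = 0.05, symmetry_alpha: float = 0.01
) -> DiagnosticsReport:
    """Run both diagnostics and package the threshold flags."""
    ad_stat, ad_p = anderson_darling(values)
    sym_stat, sym_p = symmetry_test(values)
    return DiagnosticsReport(
        ad_statistic=ad_stat,
        ad_p=ad_p,
        symmetry_statistic=sym_stat,
        symmetry_p=sym_p,
        ad_alpha=ad_alpha,
        symmetry_alpha=symmetry_alpha,
    )


def fit_power_transform(values, *, lambda_bounds: tuple[float, float] = (-3.0, 3.0)) -> TransformSpec:
    """Fit the Box-Cox exponent by profile maximum likelihood.

    The offset is 0 when all values are positive, else ``1 - min`` (the
    simplest rule guaranteeing positivity).  lambda maximizes the Box-Cox
    profile log-likelihood over ``lambda_bounds``; fitted values with
    ``|lambda| < 0.01`` collapse to an exact log transform to avoid
    numerical blow-up near zero.
    """
    arr = _check_sample(values)
    mn = float(arr.min())
    offset = 0.0 if mn > 0 else 1.0 - mn
    shifted = arr + offset
    res = optimize.minimize_scalar(
        lambda lam: -stats.boxcox_llf(lam, shifted),
        bounds=lambda_bounds,
        method="bounded",
        options={"xatol": 1e-5},
    )
    lam = float(res.x)
    if abs(lam) < LOG_LAMBDA_TOL:
        lam = 0.0
    return TransformSpec(lambda_=lam, offset=offset)


def apply_transform(values, spec: TransformSpec) -> np.ndarray:
    """Apply a Box-Cox transform elementwise."""
    arr = np.asarray(values, dtype=float) + spec.offset
    if np.any(arr <= 0):
        raise ValueError("transform requires values + offset > 0")
    if spec.is_log or abs(spec.lambda_) < 1e-12:
        return np.log(arr)
    # expm1 formulation degrades smoothly to log as lambda -> 0
    return np.expm1(spec.lambda_ * np.log(arr)) / spec.lambda_


def invert_transform(values, spec: TransformSpec) -> np.ndarray:
    """Invert :func:`apply_transform`; raises on out-of-domain values.

    For lambda != 0 the inverse is ``(lambda y + 1)^(1/lambda) - offset``,
    defined only where ``lambda y + 1 > 0`` (the branch limit of the power
    family).
    """
    arr = np.asarray(values, dtype=float)
    if spec.is_log or abs(spec.lambda_) < 1e-12:
        return np.exp(arr) - spec.offset
    base = spec.lambda_ * arr + 1.0
    if np.any(base <= 0):
        raise ValueError(
            f"value outside the branch domain of lambda={spec.lambda_:g} transform"
        )
    # log1p formulation degrades smoothly to exp as lambda -> 0
    return np.exp(np.log1p(spec.lambda_ * arr) / spec.lambda_) - spec.offset


def subgroup_overlap(
    groups: dict[str, np.ndarray], *, alpha: float = 0.05, min_n: int = MIN_DIAGNOSTIC_N
) -> OverlapReport:
    """Screen whether subgroup distributions overlap enough to pool.

    Pairwise two-sample Kolmogorov-Smirnov tests with Bonferroni
    adjustment over the pairs; ``pooled_ok`` is true iff every adjusted
    p-value is at least ``alpha``.  The study made this call visually from
    histograms; the KS screen is its quantitative stand-in.

    A single subgroup is trivially poolable (with a note).  Subgroups
    smaller than ``min_n`` are excluded from testing and named in the note.
    """
    usable = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    small = sorted(k for k, v in usable.items() if v.size < min_n)
    usable = {k: v for k, v in usable.items() if v.size >= min_n}
    note = f"subgroups below n={min_n} excluded: {small}" if small else ""
    if len(usable) < 2:
        return OverlapReport(
            pairwise_p={},
            adjusted_p={},
            pooled_ok=True,
            offending_pairs=(),
            note=(note + "; " if note else "") + "fewer than 2 testable subgroups",
        )
    pairs = list(combinations(sorted(usable), 2))
    raw = {
        pair: float(stats.ks_2samp(usable[pair[0]], usable[pair[1]]).pvalue)
        for pair in pairs
    }
    m = len(pairs)
    adjusted = {pair: min(1.0, p * m) for pair, p in raw.items()}
    offending = tuple(pair for pair, p in adjusted.items() if p < alpha)
    return OverlapReport(
        pairwise_p=raw,
        adjusted_p=adjusted,
        pooled_ok=not offending,
        offending_pairs=offending,
        note=note,
    )
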
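"""Age-group comparison, fold-change relevance screen, adult comparison.

Statistical comparison across age groups follows the study's recipe:
fence-cleaned (3 IQR) one-way ANOVA, Tukey HSD pairwise p-values (with an
optional Bonferroni factor across the analyte panel), and a compact
letter display for figure annotation.  Statistical significance is then
tempered by a biological relevance screen: pairwise median fold changes
inside [0.85, 1.15] are not considered major differences.  Finally each
juvenile interval is classified against the adult literature interval by
plain interval arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

from .core_model import AdultRI
from .ri_estimation import ReferenceInterval


@dataclass
class ComparisonResult:
    """ANOVA + post-hoc comparison of one analyte across age groups."""

    group_labels: tuple[str, ...]
    f_statistic: float
    anova_p: float
    pairwise: np.ndarray  # adjusted p-values, symmetric, diag = 1
    letters: tuple[str, ...]
    fold_changes: dict[tuple[str, str], float]
    relevance_flags: tuple[tuple[str, str], ...]


@dataclass(frozen=True)
class AdultComparison:
    """Interval-arithmetic relation of a juvenile RI to the adult RI."""

    relation: str  # within_adult | contains_adult | overlapping | disjoint_below | disjoint_above
    overlap_fraction: float  # Jaccard |intersection| / |union|
    comparable: bool


def one_way_anova(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA F test across groups.

    Degenerate inputs follow fixed conventions: zero within-group variance
    with equal means gives (0, 1); zero within-group variance with unequal
    means gives (inf, 0).
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")
    grand = np.concatenate(arrays)
    ssw = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    means = [a.mean() for a in arrays]
    if ssw == 0.0:
        if np.ptp(means) == 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def tukey_bonferroni(
    groups: Sequence[np.ndarray], *, analyte_multiplier: int = 1
) -> np.ndarray:
    """Tukey HSD pairwise adjusted p-values, Bonferroni-scaled across analytes.

    The studentized-range p-values (Tukey-Kramer for unbalanced groups) are
    multiplied by ``analyte_multiplier`` — the number of analytes in the
    panel when the comparison is part of a panel-wide screen — and capped
    at 1.  The default multiplier 1 gives plain Tukey HSD for standalone
    use.
    """
    if analyte_multiplier < 1:
        raise ValueError("analyte_multiplier must be >= 1")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with n >= 2 each")
    k = len(arrays)
    if all(np.ptp(a) == 0 for a in arrays) and np.ptp([a.mean() for a in arrays]) == 0:
        return np.ones((k, k))
    res = stats.tukey_hsd(*arrays)
    p = np.asarray(res.pvalue, dtype=float)
    adj = np.minimum(1.0, p * analyte_multiplier)
    np.fill_diagonal(adj, 1.0)
    return adj


def compact_letters(pairwise: np.ndarray, alpha: float = 0.05) -> tuple[str, ...]:
    """Compact letter display by the insert-and-absorb algorithm.

    Groups connected by adjusted p >= alpha share a letter; any pair with
    adjusted p < alpha never shares one.  Letter sets that are subsets of
    another are absorbed, and letters are ordered by the first group they
    contain, so the output is deterministic given the input order.
    """
    p = np.asarray(pairwise, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("pairwise must be a square matrix")
    if not np.allclose(p, p.T, equal_nan=True):
        raise ValueError("pairwise matrix must be symmetric")
    k = p.shape[0]
    letter_sets: list[set[int]] = [set(range(k))]
    for i, j in combinations(range(k), 2):
        if p[i, j] >= alpha:
            continue
        for s in [s for s in letter_sets if i in s and j in s]:
            letter_sets.remove(s)
            s_i = s - {j}
            s_j = s - {i}
            for cand in (s_i, s_j):
                if not any(cand <= other for other in letter_sets):
                    letter_sets.append(cand)
            letter_sets = [
                s1
                for s1 in letter_sets
                if not any(s1 < s2 for s2 in letter_sets)
            ]
    letter_sets.sort(key=lambda s: (min(s), sorted(s)))
    labels = "abcdefghijklmnopqrstuvwxyz"
    out = ["" for _ in range(k)]
    for letter, s in zip(labels, letter_sets):
        for g in s:
            out[g] += letter
    return tuple("".join(sorted(x)) for x in out)


def fold_change_screen(
    medians: Sequence[float], labels: Sequence[str] | None = None
) -> tuple[dict[tuple[str, str], float], tuple[tuple[str, str], ...]]:
    """Directional median fold changes with the biological relevance screen.

    For every chronologically ordered pair (earlier, later) the fold is
    ``median_later / median_earlier``; pairs outside [0.85, 1.15] are
    flagged as biologically relevant differences.
    """
    med = [float(m) for m in medians]
    if len(med) < 2:
        raise ValueError("need medians for >= 2 groups")
    if any(m <= 0 for m in med):
        raise ValueError("fold changes require positive medians")
    labs = tuple(labels) if labels is not None else tuple(str(i) for i in range(len(med)))
    folds: dict[tuple[str, str], float] = {}
    flags: list[tuple[str, str]] = []
    for i, j in combinations(range(len(med)), 2):
        fold = med[j] / med[i]
        pair = (labs[i], labs[j])
        folds[pair] = fold
        if fold > 1.15 or fold < 0.85:
            flags.append(pair)
    return folds, tuple(flags)


def compare_to_adult(
    juvenile: ReferenceInterval | tuple[float, float],
    adult: AdultRI,
    *,
    comparable_jaccard: float = 0.5,
) -> AdultComparison:
    """Classify a juvenile RI against the adult RI by interval arithmetic.

    ``overlap_fraction`` is the Jaccard index of the two intervals;
    ``comparable`` is true at Jaccard >= ``comparable_jaccard``.  An exact
    match resolves the within/contains tie as ``within_adult``.
    """
    jl, ju = (
        (juvenile.lower, juvenile.upper)
        if isinstance(juvenile, ReferenceInterval)
        else (float(juvenile[0]), float(juvenile[1]))
    )
    al, au = adult.lower, adult.upper
    inter = max(0.0, min(ju, au) - max(jl, al))
    union = max(ju, au) - min(jl, al)
    jaccard = inter / union if union > 0 else 1.0
    if ju < al:
        relation = "disjoint_below"
    elif jl > au:
        relation = "disjoint_above"
    elif al <= jl and ju <= au:
        relation = "within_adult"
    elif jl < al and au < ju:
        relation = "contains_adult"
    else:
        relation = "overlapping"
    return AdultComparison(
        relation=relation,
        overlap_fraction=float(jaccard),
        comparable=bool(jaccard >= comparable_jaccard),
    )


def compare_age_groups(
    groups: dict[str, np.ndarray],
    *,
    alpha: float = 0.05,
    analyte_multiplier: int = 1,
    fence_k: float = 3.0,
) -> ComparisonResult:
    """Full comparison chain for one analyte across ordered age groups.

    Each group is fence-cleaned (values outside Q1 - k IQR, Q3 + k IQR
    dropped) before ANOVA and Tukey HSD, mirroring the study's boxplot
    convention; medians for the fold-change screen come from the cleaned
    groups.
    """
    from .outlier_handling import iqr_fence_outliers

    labels = tuple(groups)
    cleaned = []
    for lab in labels:
        arr = np.asarray(groups[lab], dtype=float)
        if arr.size >= 4:
            rep = iqr_fence_outliers(arr, k=fence_k)
            keep = np.ones(arr.size, dtype=bool)
            keep[list(rep.fence_flagged)] = False
            arr = arr[keep]
        cleaned.append(arr)
    f, p = one_way_anova(cleaned)
    pairwise = tukey_bonferroni(cleaned, analyte_multiplier=analyte_multiplier)
    letters = compact_letters(pairwise, alpha=alpha)
    medians = [float(np.median(a)) for a in cleaned]
    folds, flags = fold_change_screen(medians, labels)
    return ComparisonResult(
        group_labels=labels,
        f_statistic=f,
        anova_p=p,
        pairwise=pairwise,
        letters=letters,
        fold_changes=folds,
        relevance_flags=flags,
    )
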
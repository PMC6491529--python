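# Methods

This note documents the statistical procedures implemented in `juveri`,
the assumptions behind the synthetic-cohort generator, and the design
choices made where the underlying guideline practice leaves room.

## Reference-interval estimators

All estimators target the central 95% of the reference distribution
(`coverage` configurable in `RIConfig`). Lower limits are clamped at 0:
every analyte in the panels is a non-negative concentration or activity.

**Non-parametric (NP).** Limits at ranks `r = p(n+1)` for
`p = (1−coverage)/2` and its complement, with linear interpolation
between order statistics and clamping to the sample extremes when `r`
falls outside `[1, n]`. This rank convention matters at desk scale —
alternatives (e.g. `p(n−1)+1`) differ by fractions of an order-statistic
gap — so the same convention is used everywhere, including the test
oracles. NP is preferred at `n ≥ 120` (the smallest n at which the 2.5th
and 97.5th percentile estimates stop depending on the extreme one or two
observations) and accepted down to `n = 20` only as a forced fallback,
with a note recorded in the interval.

**Parametric standard.** `mean ± z·sd` with `z = Φ⁻¹(0.975) = 1.95996`
(not the rounded 2.0), computed on the raw scale or after a Box-Cox
transform and back-transformed. A working-scale lower limit that falls
beyond the branch point of a negative-λ transform maps to the closed end
of the support (0); an upper limit beyond it is an error, surfaced as an
unfixable-distribution signal.

**Robust (Horn-style).** Iterated Tukey-biweight location (tuning 3.7 in
MAD units, iterated to relative change < 1e-6, max 100 iterations with a
convergence error otherwise) and biweight-midvariance scale; limits at
`T ± t(0.975, n−1)·s`. The scale tuning constant is 9, the standard
choice that makes the biweight midvariance a consistent estimator of σ
under normality — at tuning 3.7 the scale would be biased low and the
robust limits could not coincide with the parametric ones on clean normal
data (they agree within ~2% at n = 200, which the tests assert). Both
constants are exposed in `RIConfig`.

**Confidence intervals on limits.** 90% CIs per limit: exact
distribution-free binomial rank bounds for NP at `n ≥ 120` (order
statistics `X₍ₗ₎, X₍ᵤ₎` with `l` the largest rank whose binomial lower
tail stays within 5% and `u` the smallest reaching 95%); otherwise a
seeded percentile bootstrap (B = 5000 by default, refused below 100).
For transformed fits the fitted exponent is held fixed across resamples —
refitting λ per resample changes the estimand rather than measuring its
uncertainty. The percentile bootstrap of a reference limit mildly
undercovers (measured ≈ 87% for the nominal 90% at n = 60 under normal
truth; the reverse-percentile variant measured worse), a known property
of percentile intervals for location-scale functionals at moderate n.

## Distribution diagnostics

**Normality**: Anderson–Darling with estimated mean/SD, small-sample
correction `A* = A²(1 + 0.75/n + 2.25/n²)`, p-value from the standard
piecewise-exponential approximation for the estimated-parameters case
(the statistic is cross-checked against `scipy.stats.anderson`, which
reports no closed-form p). Threshold α = 0.05.

**Symmetry**: D'Agostino skewness test (`scipy.stats.skewtest`), two
sided, threshold α = 0.01. The guideline software behind the published
panels names only "symmetry test"; the skewness test is the documented
stand-in. An exactly zero-skew sample returns statistic 0, p = 1 (scipy
internally substitutes a placeholder at b₁ = 0, which would misreport the
exact-symmetry case).

**Box-Cox transform**: offset 0 when all values are positive, else
`1 − min` (the simplest rule guaranteeing positivity, recorded in the
transform for reproducibility); λ maximises the profile log-likelihood
over [−3, 3]; |λ| < 0.01 collapses to an exact log. Apply/invert use
`expm1`/`log1p` formulations so tiny non-zero λ degrades smoothly to the
log branch instead of losing precision.

λ is only estimable when the data carry enough relative spread: at
CV ≈ 0.05 the profile likelihood is nearly flat and the MLE scatters
widely around 1 (sd ≈ 0.4 at n = 1000); at a typical analyte CV of
0.15–0.25 it concentrates. Tests assert per-seed recovery where λ is
identified and mean-over-seeds recovery where it is not.

**Subgroup overlap**: the published panels pooled trials and sexes after
a visual histogram-overlap judgment; the quantitative stand-in is
pairwise two-sample Kolmogorov–Smirnov with Bonferroni adjustment over
the pairs, family-wise α = 0.05. Subgroups below n = 8 are excluded and
named in the report; a single subgroup pools trivially.

## Outlier handling

The three-criterion procedure records a full audit trail; points are
never dropped silently, and `|cleaned| + |removed| = n` always holds.
Retention under criterion (b) means "some selectable estimator remains
valid with every point in place": normality after the best transform
(standard interval computable) or raw-scale symmetry (robust interval
computable). Cook's screening (criterion c) regresses sorted values on
normal quantile scores at Blom plotting positions and deletes points with
`Dᵢ > 4/n` — the guideline source names the statistic but not the model,
so this design makes departure from Q-Q straightness the leverage being
measured, consistent with its role as a normality-fixing deletion step;
it runs on the best-transformed scale (recorded in the audit) and is
swappable via the `diagnostics_fn`/threshold-rule hooks. An exact
regression fit (zero residual variance) flags nothing.

## Method-selection tree

After outlier handling (hard floor n ≥ 20): NP at n ≥ 120; else
untransformed standard if the raw scale passes Anderson–Darling; else
transformed standard if the Box-Cox scale passes; else robust if the raw
scale is symmetric; else the NP forced fallback with an
"unfixable distribution" note. The tree deliberately does not offer a
transformed-robust branch: the Box-Cox MLE symmetrises almost any
one-sided shape, so gating the fallback on post-transform symmetry would
make it unreachable, and the published panels never report a transformed
robust fit. `MethodLabel.TRANSFORMED_ROBUST` exists in the vocabulary and
`robust_ri(transform=...)` supports it for standalone use.

## Synthetic cohorts

The generator stands in for unreleased per-animal data. Each analyte ×
age cell is a two-parameter family chosen from the printed mean/median
ratio: lognormal (`μ = ln median`, `σ = √(2 ln(mean/median))` — exact
moment matching of a lognormal's mean and median) when the ratio exceeds
1.05, the smallest ratio in the panels that visibly implies right skew;
normal (mean, SD) otherwise; left-skewed rows fall back to normal with a
warning (one cholesterol row, ratio 0.91). Printed minima/maxima are
order statistics, not parameters, and serve only as sanity bands.

On top of the base family: a contamination process (rate 0.01,
multiplier uniform on (3, 6)) reproducing the magnitude of the rare
extreme maxima seen in acute-phase proteins without moving medians; and
per-trial location offsets (default 0.1 × scale for one of three calf
trials) giving overlapping-but-not-identical seasonal trials. A 0.5-scale
offset scenario (`trial_shift_scenario`) reproduces the two reported
non-overlapping trial distributions (AST and cholesterol at 2 weeks), and
`unfixable_skew_spec` expresses a 68/32 bimodal lognormal mixture through
the same offset machinery to reproduce the one published
unfixable-distribution cell (piglet AST at 7 days): the second mode sits
5 log-scale units up — still inside the 3·IQR fence and largely immune to
Cook's deletion — so no power transform can normalise or symmetrise it.

Determinism: each cell draws from its own child of one `SeedSequence`, so
identical (spec, seed) give byte-identical cohorts and cells are
independent of one another.

What the generator does **not** emulate: cross-analyte correlation within
an animal, longitudinal correlation of the same animal across ages,
assay imprecision structure, and any left-skewed family. Passing tests
therefore validate the estimation pipeline under realistic marginal
distributions, not the joint structure of real cohorts.

## Group and adult comparison

Age comparison runs on fence-cleaned (3·IQR) samples, mirroring the
boxplot convention of the source figures: classical one-way ANOVA
(convention: zero within-variance with equal means → p = 1, with unequal
means → p = 0), Tukey HSD pairwise p-values (Tukey–Kramer for unbalanced
groups) multiplied by a Bonferroni factor across the analyte panel
(defaulting to the panel size inside the pipeline, 1 standalone) and
capped at 1, then a compact letter display via insert-and-absorb
(deterministic given group order; significant pairs never share a letter,
non-significant pairs always do). Statistical significance is tempered by
the fold-change relevance screen: directional median ratios for every
chronologically ordered pair, flagged outside [0.85, 1.15].

Adult comparison is plain interval arithmetic (within / contains /
overlapping / disjoint below / disjoint above) plus the Jaccard index of
the two intervals; "comparable" means Jaccard ≥ 0.5 (configurable — the
guideline literature gives no numeric criterion). The comparison reports
what the intervals say, even where a verbal claim in the source
literature disagrees with its own printed limits (calf urea at 7 weeks is
disjoint below the adult range).

## Problem sizes

Defaults throughout are the study conditions: published per-cell N
(28–193), coverage 0.95, B = 5000 bootstrap resamples. Simulation-based
checks use 100–1000 seeded replicates (coverage: 200 fits × 10,000
evaluation draws; contamination resistance: 30–50 pairs; null overlap:
100 seeds), sizes at which the asserted tolerances are comfortably
resolvable.

## Known limitations

- The synthetic marginals cannot validate rank correlations or
  repeated-measures structure; the source analysis itself used one-way
  ANOVA despite sampling the same animals longitudinally, and `juveri`
  replicates that choice rather than fitting mixed models.
- The Anderson–Darling p-value approximation is accurate for n ≥ ~8 but
  is an approximation; decisions near the 0.05 boundary can differ from
  table-interpolated implementations by a hair.
- Percentile-bootstrap CIs on limits undercover slightly at small n (see
  above); binomial rank CIs are exact but only available for NP at large n.
- `below_detection` rows are discarded, not imputed; panels with heavy
  censoring would need a different strategy.
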
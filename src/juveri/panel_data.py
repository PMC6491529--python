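"""Reference panel data for the calf and piglet serum biochemistry studies.

Per-analyte, per-age summary statistics (mean, median, SD, minimum, maximum,
N) for two juvenile cohorts:

* unweaned male Holstein calves sampled at 24 h (after colostrum intake)
  and at 2, 5 and 7 weeks of age, pooled over three seasonal trials;
* commercial crossbred piglets weaned at 21 days and sampled at 0, 7 and
  14 days post-weaning.

These summaries calibrate the synthetic cohort generator
(:mod:`juveri.synthetic_cohort`), which stands in for the unreleased
per-animal data.  Adult reference intervals collected from the veterinary
literature are included for juvenile-vs-adult comparison, together with the
study-design bookkeeping (trial enrolment, pen structure).
"""

from __future__ import annotations

CALF_AGE_GROUPS: tuple[str, ...] = ("24h", "2w", "5w", "7w")
PIGLET_AGE_GROUPS: tuple[str, ...] = ("0d", "7d", "14d")

# Trial enrolment for the calf study (three seasonal trials) and the pen
# structure of the piglet study (single trial; 3 piglets sampled per pen).
CALF_TRIAL_ENROLMENT: dict[str, int] = {"T1": 60, "T2": 76, "T3": 57}
PIGLET_N_PENS = 24
PIGLET_PIGLETS_PER_PEN = 14
PIGLET_SAMPLED_PER_PEN = 3

# Which trials contributed animals at each calf sampling age: only trial T1
# sampled newborns at 24 h; trial T1 ended before the 7-week bleed.
CALF_TRIALS_BY_AGE: dict[str, tuple[str, ...]] = {
    "24h": ("T1",),
    "2w": ("T1", "T2", "T3"),
    "5w": ("T1", "T2", "T3"),
    "7w": ("T2", "T3"),
}
PIGLET_TRIALS_BY_AGE: dict[str, tuple[str, ...]] = {
    "0d": ("single",),
    "7d": ("single",),
    "14d": ("single",),
}


def total_calves_enrolled() -> int:
    """Total calves across the three trials (60 + 76 + 57 = 193)."""
    return sum(CALF_TRIAL_ENROLMENT.values())


def piglets_weaned() -> int:
    """Total piglets weaned into the nursery (24 pens x 14 per pen)."""
    return PIGLET_N_PENS * PIGLET_PIGLETS_PER_PEN


def piglets_sampled() -> int:
    """Piglets bled at each sampling day (3 per pen x 24 pens)."""
    return PIGLET_SAMPLED_PER_PEN * PIGLET_N_PENS


# Analyte metadata: measurement unit, reporting decimals for RI tables, and
# (where the literature provides one) an adult reference interval.
# adult = (lower, upper, source) or None.
CALF_ANALYTE_META: dict[str, dict] = {
    "ALT": {"unit": "U/L", "decimals": 1, "adult": (11.0, 40.0, "adult cattle literature")},
    "AST": {"unit": "U/L", "decimals": 1, "adult": (78.0, 132.0, "adult cattle literature")},
    "Cholesterol": {"unit": "mg/dL", "decimals": 1, "adult": (80.0, 120.0, "adult cattle literature")},
    "Creatinine": {"unit": "mg/dL", "decimals": 2, "adult": (1.0, 2.0, "adult cattle literature")},
    "GGT": {"unit": "U/L", "decimals": 1, "adult": (6.1, 17.4, "adult cattle literature")},
    "Glucose": {"unit": "mg/dL", "decimals": 1, "adult": (45.0, 75.0, "adult cattle literature")},
    "GPx": {"unit": "U/L", "decimals": 1, "adult": None},
    "Haptoglobin": {"unit": "mg/mL", "decimals": 2, "adult": (0.0, 1.0, "healthy adult cattle (upper bound)")},
    "NEFAs": {"unit": "mmol/L", "decimals": 2, "adult": (0.07, 0.46, "adult cattle literature")},
    "TGs": {"unit": "mg/dL", "decimals": 1, "adult": (0.0, 14.0, "adult cattle literature")},
    "TP": {"unit": "g/dL", "decimals": 2, "adult": (6.74, 7.46, "adult cattle literature")},
    "SOD": {"unit": "U/mL", "decimals": 2, "adult": None},
    "Urea": {"unit": "mg/dL", "decimals": 1, "adult": (20.0, 30.0, "adult cattle literature")},
}

PIGLET_ANALYTE_META: dict[str, dict] = {
    "ALT": {"unit": "U/L", "decimals": 1, "adult": (31.0, 58.0, "adult pig literature")},
    "AST": {"unit": "U/L", "decimals": 1, "adult": (32.0, 84.0, "adult pig literature")},
    "Cholesterol": {"unit": "mg/dL", "decimals": 1, "adult": (36.0, 54.0, "adult pig literature")},
    "Cortisol": {"unit": "ng/mL", "decimals": 1, "adult": None},
    "Creatinine": {"unit": "mg/dL", "decimals": 2, "adult": (1.0, 2.7, "adult pig literature")},
    "GGT": {"unit": "U/L", "decimals": 1, "adult": (10.0, 60.0, "adult pig literature")},
    "Glucose": {"unit": "mg/dL", "decimals": 1, "adult": (85.0, 150.0, "adult pig literature")},
    "Haptoglobin": {"unit": "mg/mL", "decimals": 2, "adult": (0.02, 3.00, "mixed-age pigs, commercial farms")},
    "NEFAs": {"unit": "mmol/L", "decimals": 2, "adult": None},
    "PigMAP": {"unit": "g/L", "decimals": 2, "adult": (0.46, 2.36, "mixed-age pigs, commercial farms")},
    "TGs": {"unit": "mg/dL", "decimals": 1, "adult": None},
    "TNF-alpha": {"unit": "pg/mL", "decimals": 1, "adult": None},
    "TP": {"unit": "g/dL", "decimals": 2, "adult": (7.90, 8.90, "adult pig literature")},
    "Urea": {"unit": "mg/dL", "decimals": 1, "adult": (10.0, 30.0, "adult pig literature")},
}

# Summary rows: (mean, median, sd, minimum, maximum, n) per analyte per age.
CALF_SUMMARY: dict[str, dict[str, tuple]] = {
    "ALT": {
        "24h": (12.1, 10.8, 4.4, 6.8, 22.3, 29),
        "2w": (6.8, 6.6, 1.7, 3.3, 12.1, 188),
        "5w": (8.3, 8.1, 2.1, 4.3, 19.5, 193),
        "7w": (9.5, 9.4, 2.4, 4.7, 19.0, 134),
    },
    "AST": {
        "24h": (87.5, 85.0, 20.4, 53.0, 134.0, 30),
        "2w": (36.6, 38.0, 9.3, 0.0, 60.0, 188),
        "5w": (42.2, 42.0, 15.0, 19.0, 178.0, 193),
        "7w": (37.5, 36.5, 10.8, 16.0, 77.0, 134),
    },
    "Cholesterol": {
        "24h": (36.1, 33.6, 11.1, 20.6, 67.4, 30),
        "2w": (71.5, 78.3, 29.3, 11.5, 145.0, 188),
        "5w": (82.1, 77.0, 29.4, 30.6, 187.7, 193),
        "7w": (65.5, 64.9, 23.0, 18.8, 133.4, 134),
    },
    "Creatinine": {
        "24h": (1.22, 1.20, 0.17, 0.96, 1.64, 30),
        "2w": (1.00, 0.99, 0.20, 0.54, 1.71, 188),
        "5w": (0.83, 0.82, 0.16, 0.50, 1.40, 193),
        "7w": (0.67, 0.66, 0.12, 0.43, 1.03, 134),
    },
    "GGT": {
        "24h": (1459.8, 1303.0, 831.3, 288.0, 3170.0, 28),
        "2w": (100.8, 76.0, 70.6, 12.0, 348.0, 188),
        "5w": (24.5, 23.0, 9.5, 7.0, 54.0, 193),
        "7w": (16.8, 16.0, 4.4, 8.0, 31.0, 134),
    },
    "Glucose": {
        "24h": (125.8, 119.4, 28.5, 68.5, 211.1, 30),
        "2w": (110.6, 110.6, 22.1, 65.4, 222.5, 188),
        "5w": (101.8, 101.4, 18.4, 43.8, 157.9, 193),
        "7w": (93.0, 93.3, 15.3, 59.2, 147.8, 134),
    },
    "GPx": {
        "24h": (737.1, 632.0, 347.4, 343.1, 1650.4, 28),
        "2w": (505.0, 452.4, 194.0, 231.6, 1610.7, 186),
        "5w": (421.1, 383.0, 157.6, 242.2, 1525.3, 192),
        "7w": (437.1, 413.2, 128.0, 262.4, 1330.8, 133),
    },
    "Haptoglobin": {
        "24h": (0.16, 0.14, 0.05, 0.09, 0.32, 28),
        "2w": (0.14, 0.13, 0.12, 0.06, 1.48, 190),
        "5w": (0.14, 0.12, 0.18, 0.06, 2.21, 193),
        "7w": (0.13, 0.12, 0.06, 0.07, 0.56, 134),
    },
    "NEFAs": {
        "24h": (0.41, 0.40, 0.15, 0.19, 0.77, 30),
        "2w": (0.10, 0.09, 0.06, 0.03, 0.31, 188),
        "5w": (0.15, 0.14, 0.06, 0.05, 0.30, 193),
        "7w": (0.18, 0.17, 0.07, 0.05, 0.40, 134),
    },
    "TGs": {
        "24h": (39.1, 38.2, 19.7, 13.5, 87.0, 30),
        "2w": (19.6, 16.0, 12.1, 5.5, 81.8, 188),
        "5w": (21.9, 18.1, 12.0, 7.4, 71.7, 193),
        "7w": (24.1, 21.5, 14.3, 6.1, 101.9, 134),
    },
    "TP": {
        "24h": (6.02, 6.15, 0.71, 4.42, 7.43, 30),
        "2w": (5.11, 5.10, 0.63, 3.75, 7.14, 188),
        "5w": (4.99, 4.99, 0.50, 3.77, 6.49, 193),
        "7w": (4.80, 4.70, 0.54, 3.66, 6.47, 134),
    },
    "SOD": {
        "24h": (0.90, 0.53, 0.89, 0.05, 2.79, 30),
        "2w": (0.31, 0.25, 0.21, 0.02, 1.33, 185),
        "5w": (0.23, 0.20, 0.14, 0.02, 0.94, 191),
        "7w": (0.23, 0.20, 0.13, 0.01, 0.66, 130),
    },
    "Urea": {
        "24h": (19.4, 19.3, 5.6, 8.7, 34.9, 30),
        "2w": (15.2, 13.9, 7.9, 6.3, 92.7, 188),
        "5w": (13.9, 13.7, 3.9, 6.3, 27.3, 193),
        "7w": (11.2, 10.9, 2.9, 5.8, 18.8, 134),
    },
}

PIGLET_SUMMARY: dict[str, dict[str, tuple]] = {
    "ALT": {
        "0d": (32.8, 31.3, 9.4, 10.2, 63.7, 66),
        "7d": (24.8, 22.8, 8.8, 8.2, 53.3, 67),
        "14d": (35.5, 28.7, 23.6, 11.4, 177.9, 64),
    },
    "AST": {
        "0d": (78.4, 63.0, 47.5, 20.0, 242.0, 68),
        "7d": (45.8, 37.0, 22.3, 15.0, 125.0, 67),
        "14d": (65.6, 48.0, 45.7, 23.0, 260.0, 62),
    },
    "Cholesterol": {
        "0d": (125.5, 122.0, 41.8, 51.4, 272.2, 61),
        "7d": (53.1, 52.0, 14.3, 27.0, 95.5, 65),
        "14d": (69.7, 62.4, 36.9, 37.5, 303.9, 62),
    },
    "Cortisol": {
        "0d": (74.9, 60.2, 50.1, 2.0, 202.2, 71),
        "7d": (19.0, 15.6, 12.4, 1.1, 52.5, 68),
        "14d": (21.2, 18.9, 16.7, 1.6, 83.8, 65),
    },
    "Creatinine": {
        "0d": (0.80, 0.79, 0.15, 0.57, 1.16, 54),
        "7d": (0.94, 0.93, 0.16, 0.66, 1.51, 65),
        "14d": (0.85, 0.82, 0.17, 0.53, 1.26, 57),
    },
    "GGT": {
        "0d": (46.0, 41.0, 16.5, 11.0, 89.0, 65),
        "7d": (40.9, 40.0, 13.9, 13.0, 74.0, 67),
        "14d": (50.9, 49.0, 17.4, 17.0, 112.0, 66),
    },
    "Glucose": {
        "0d": (84.9, 80.8, 17.8, 49.0, 141.4, 57),
        "7d": (79.1, 78.9, 12.4, 55.3, 107.6, 64),
        "14d": (83.0, 85.8, 16.5, 34.5, 126.9, 60),
    },
    "Haptoglobin": {
        "0d": (0.50, 0.41, 0.39, 0.05, 1.68, 61),
        "7d": (0.62, 0.49, 0.52, 0.07, 2.39, 66),
        "14d": (0.57, 0.30, 0.66, 0.05, 3.05, 61),
    },
    "NEFAs": {
        "0d": (0.40, 0.40, 0.14, 0.15, 0.76, 61),
        "7d": (0.18, 0.15, 0.11, 0.04, 0.58, 62),
        "14d": (0.11, 0.10, 0.03, 0.05, 0.21, 55),
    },
    "PigMAP": {
        "0d": (3.26, 2.88, 1.22, 1.22, 5.88, 71),
        "7d": (0.99, 0.94, 0.31, 0.43, 2.24, 69),
        "14d": (0.74, 0.70, 0.28, 0.32, 2.13, 63),
    },
    "TGs": {
        "0d": (43.2, 40.9, 13.1, 22.6, 85.0, 59),
        "7d": (35.5, 31.7, 11.2, 18.8, 73.3, 65),
        "14d": (38.8, 38.0, 10.0, 20.2, 68.3, 60),
    },
    "TNF-alpha": {
        "0d": (54.3, 48.8, 22.3, 23.1, 110.6, 67),
        "7d": (103.2, 101.7, 27.7, 41.4, 165.7, 72),
        "14d": (98.1, 92.5, 42.8, 43.6, 292.0, 71),
    },
    "TP": {
        "0d": (3.78, 3.68, 0.64, 2.34, 5.42, 58),
        "7d": (3.49, 3.46, 0.48, 2.39, 4.57, 65),
        "14d": (3.84, 3.74, 0.69, 2.76, 6.36, 59),
    },
    "Urea": {
        "0d": (12.1, 11.7, 3.6, 6.7, 25.2, 57),
        "7d": (18.2, 17.2, 6.9, 4.3, 41.3, 64),
        "14d": (14.7, 12.9, 7.5, 4.6, 38.5, 57),
    },
}

# Estimation method reported for each cell in the source RI tables,
# kept as reference metadata for qualitative comparison (not used by the
# estimators themselves).  "NP" = non-parametric percentile method.
CALF_REPORTED_METHOD: dict[str, dict[str, str]] = {
    analyte: {
        "24h": ("Untrans. Std." if analyte in ("Glucose", "NEFAs") else "Trans. Std."),
        "2w": "NP",
        "5w": "NP",
        "7w": "NP",
    }
    for analyte in CALF_SUMMARY
}

PIGLET_REPORTED_METHOD: dict[str, dict[str, str]] = {
    analyte: {
        "0d": ("Untrans. Rob." if analyte in ("Creatinine", "Glucose") else "Trans. Std."),
        "7d": ("NP" if analyte == "AST" else "Trans. Std."),
        "14d": "Trans. Std.",
    }
    for analyte in PIGLET_SUMMARY
}


def summary_table(species: str) -> dict[str, dict[str, tuple]]:
    """Return the summary-statistics table for ``species`` (calf/piglet)."""
    if species == "calf":
        return CALF_SUMMARY
    if species == "piglet":
        return PIGLET_SUMMARY
    raise ValueError(f"unknown species {species!r}; expected 'calf' or 'piglet'")


def analyte_meta(species: str) -> dict[str, dict]:
    if species == "calf":
        return CALF_ANALYTE_META
    if species == "piglet":
        return PIGLET_ANALYTE_META
    raise ValueError(f"unknown species {species!r}; expected 'calf' or 'piglet'")


def age_groups(species: str) -> tuple[str, ...]:
    if species == "calf":
        return CALF_AGE_GROUPS
    if species == "piglet":
        return PIGLET_AGE_GROUPS
    raise ValueError(f"unknown species {species!r}; expected 'calf' or 'piglet'")
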
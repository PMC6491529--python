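"""Classify juvenile reference intervals against adult literature RIs.

Interval arithmetic with a Jaccard overlap index: a juvenile RI is
"comparable" to the adult RI at overlap >= 0.5.  Shows calf creatinine
converging towards (then leaving) the adult range and urea ending below it.
"""

import warnings

import juveri as jv

warnings.filterwarnings("ignore", category=UserWarning)

cohort = jv.simulate_cohort(jv.packaged_specs("calf", seed=42))
result = jv.run_pipeline(cohort, jv.RIConfig(seed=42), compute_cis=False)

for analyte in ("Creatinine", "Urea"):
    adult = cohort.analyte_meta[analyte].adult
    print(f"{analyte} (adult RI [{adult.lower}, {adult.upper}] {cohort.analyte_meta[analyte].unit}):")
    for age in cohort.age_order:
        ri = result.interval(analyte, age)
        cmp_ = result.adult[(analyte, age)]
        print(
            f"  {age:>3}: [{ri.lower:6.2f}, {ri.upper:6.2f}] -> {cmp_.relation:<14}"
            f" Jaccard {cmp_.overlap_fraction:.2f}"
            f"{'  (comparable)' if cmp_.comparable else ''}"
        )
# Juvenile values drift with age: applying adult RIs to young animals
# would misclassify healthy individuals wherever the relation is not
# "within_adult" or "overlapping" with high Jaccard.
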
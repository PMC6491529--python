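"""End-to-end orchestration of the RI establishment analysis.

For every analyte x age cell: subgroup-overlap screen (trials, sexes),
three-criterion outlier handling, method selection, reference limits with
90% CIs.  For every analyte across ages: fence-cleaned ANOVA, Tukey HSD
with the panel-wide Bonferroni factor, compact letters and the fold-change
relevance screen; juvenile-vs-adult classification where an adult RI is
configured.  All randomness derives from the single config seed, and a
rerun with the same seed writes byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_model import CohortTable, write_ri_table
from .distribution_diagnostics import OverlapReport, subgroup_overlap
from .group_comparison import (
    AdultComparison,
    ComparisonResult,
    compare_age_groups,
    compare_to_adult,
)
from .ri_estimation import (
    MethodDecision,
    ReferenceInterval,
    RIConfig,
    SmallSampleError,
    select_method,
)

log = logging.getLogger("juveri")


@dataclass
class PipelineResult:
    """Everything the pipeline computed, ready for serialization."""

    species: str
    ri_results: list[tuple[str, str, ReferenceInterval]]
    decisions: dict[tuple[str, str], MethodDecision]
    overlap: dict[tuple[str, str], dict[str, OverlapReport]]
    comparisons: dict[str, ComparisonResult]
    adult: dict[tuple[str, str], AdultComparison]
    failures: dict[tuple[str, str], str] = field(default_factory=dict)

    def interval(self, analyte: str, age_group: str) -> ReferenceInterval:
        for a, g, ri in self.ri_results:
            if a == analyte and g == age_group:
                return ri
        raise KeyError((analyte, age_group))

    def audit_dict(self) -> dict:
        """JSON-serializable audit trail (deterministic key order)."""

        def overlap_dict(rep: OverlapReport) -> dict:
            return {
                "pooled_ok": rep.pooled_ok,
                "adjusted_p": {" vs ".join(k): v for k, v in sorted(rep.adjusted_p.items())},
                "offending_pairs": [" vs ".join(p) for p in rep.offending_pairs],
                "note": rep.note,
            }

        cells = {}
        for (analyte, age), dec in sorted(self.decisions.items()):
            key = f"{analyte}|{age}"
            cells[key] = {
                "decision": dec.to_dict(),
                "overlap": {
                    by: overlap_dict(rep)
                    for by, rep in sorted(self.overlap.get((analyte, age), {}).items())
                },
            }
        comparisons = {}
        for analyte, comp in sorted(self.comparisons.items()):
            comparisons[analyte] = {
                "groups": list(comp.group_labels),
                "f_statistic": comp.f_statistic,
                "anova_p": comp.anova_p,
                "letters": list(comp.letters),
                "fold_changes": {" -> ".join(k): v for k, v in sorted(comp.fold_changes.items())},
                "relevance_flags": [" -> ".join(p) for p in comp.relevance_flags],
            }
        adult = {
            f"{analyte}|{age}": {
                "relation": ac.relation,
                "overlap_fraction": ac.overlap_fraction,
                "comparable": ac.comparable,
            }
            for (analyte, age), ac in sorted(self.adult.items())
        }
        return {
            "species": self.species,
            "cells": cells,
            "comparisons": comparisons,
            "adult_comparison": adult,
            "failures": {f"{a}|{g}": msg for (a, g), msg in sorted(self.failures.items())},
        }


def run_pipeline(
    cohort: CohortTable,
    config: RIConfig | None = None,
    *,
    compute_cis: bool = True,
) -> PipelineResult:
    """Run the full RI establishment analysis on a validated cohort.

    Cells whose sample is too small for any estimator are recorded under
    ``failures`` (never dropped silently).  Bootstrap seeds are spawned
    per cell from ``config.seed`` in a fixed (analyte, age) order, so the
    result is a pure function of (cohort, config).
    """
    cfg = config or RIConfig()
    analytes = [a for a in sorted(cohort.analyte_meta) if (cohort.data["analyte"] == a).any()]
    ages = [g for g in cohort.age_order]
    cell_keys = [(a, g) for a in analytes for g in ages]
    ss = np.random.SeedSequence(cfg.seed)
    children = dict(zip(cell_keys, ss.spawn(len(cell_keys))))

    ri_results: list[tuple[str, str, ReferenceInterval]] = []
    decisions: dict[tuple[str, str], MethodDecision] = {}
    overlap: dict[tuple[str, str], dict[str, OverlapReport]] = {}
    adult: dict[tuple[str, str], AdultComparison] = {}
    failures: dict[tuple[str, str], str] = {}

    for analyte, age in cell_keys:
        values = cohort.values(analyte, age)
        if values.size == 0:
            failures[(analyte, age)] = "no measured values"
            continue
        reps: dict[str, OverlapReport] = {}
        for by in ("trial", "sex"):
            groups = cohort.subgroup_values(analyte, age, by)
            groups = {k: v for k, v in groups.items() if k != "unknown"}
            if len(groups) >= 2:
                reps[by] = subgroup_overlap(groups, alpha=cfg.overlap_alpha)
                if not reps[by].pooled_ok:
                    log.info(
                        "%s %s: non-overlapping %s distributions: %s",
                        analyte,
                        age,
                        by,
                        reps[by].offending_pairs,
                    )
        overlap[(analyte, age)] = reps
        try:
            ri, decision = select_method(
                values, cfg, compute_cis=compute_cis, seed=children[(analyte, age)]
            )
        except SmallSampleError as exc:
            failures[(analyte, age)] = str(exc)
            log.warning("%s %s: %s", analyte, age, exc)
            continue
        if decision.note:
            log.info("%s %s: %s", analyte, age, decision.note)
        ri_results.append((analyte, age, ri))
        decisions[(analyte, age)] = decision
        meta = cohort.analyte_meta.get(analyte)
        if meta is not None and meta.adult is not None:
            adult[(analyte, age)] = compare_to_adult(
                ri, meta.adult, comparable_jaccard=cfg.adult_comparable_jaccard
            )

    multiplier = cfg.bonferroni_analytes or max(1, len(analytes))
    comparisons: dict[str, ComparisonResult] = {}
    for analyte in analytes:
        groups = {
            age: cohort.values(analyte, age)
            for age in ages
            if cohort.values(analyte, age).size >= 4
        }
        if len(groups) < 2:
            continue
        comparisons[analyte] = compare_age_groups(
            groups,
            alpha=0.05,
            analyte_multiplier=multiplier,
            fence_k=cfg.fence_k,
        )

    return PipelineResult(
        species=cohort.species,
        ri_results=ri_results,
        decisions=decisions,
        overlap=overlap,
        comparisons=comparisons,
        adult=adult,
        failures=failures,
    )


def write_outputs(
    result: PipelineResult,
    cohort: CohortTable,
    ri_path: str | Path,
    audit_path: str | Path | None = None,
) -> None:
    """Write the RI CSV and (optionally) the JSON audit trail."""
    write_ri_table(result.ri_results, ri_path, cohort.analyte_meta)
    if audit_path is not None:
        with open(audit_path, "w") as fh:
            json.dump(result.audit_dict(), fh, indent=2, sort_keys=True, default=_np_default)
            fh.write("\n")


def _np_default(obj):
    """Coerce stray numpy scalars to JSON-native types."""
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)!r}")
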
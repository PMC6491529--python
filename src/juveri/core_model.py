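"""Domain types, cohort ingestion/validation, summaries and RI table I/O.

A cohort is held in long format: one row per animal x sampling age x
analyte.  Ingestion enforces the study's handling of incomplete data —
missing and below-detection results are discarded (never imputed) and the
discard counts are logged — and validates values (non-negative reals) and
age-group labels against the species' declared ordered set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("juveri")

DEFAULT_LOD_TOKEN = "<LOD"

RI_TABLE_COLUMNS = [
    "analyte",
    "unit",
    "age_group",
    "n",
    "method",
    "lower",
    "upper",
    "lower_ci90_low",
    "lower_ci90_high",
    "upper_ci90_low",
    "upper_ci90_high",
]


class ValidationError(ValueError):
    """Raised when input data violate the cohort contract."""


class EmptySampleError(ValueError):
    """Raised when a statistic is requested on an empty sample."""


@dataclass(frozen=True)
class AdultRI:
    """Adult reference interval from the literature, for comparison."""

    lower: float
    upper: float
    source: str = ""

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValidationError(
                f"adult RI requires lower < upper, got [{self.lower}, {self.upper}]"
            )

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class AnalyteMeta:
    """Reporting metadata for one analyte: unit, decimals, optional adult RI."""

    unit: str
    decimals: int = 2
    adult: AdultRI | None = None


@dataclass(frozen=True)
class SummaryStats:
    """Descriptive summary of one analyte x age cell (sample SD, n-1)."""

    mean: float
    median: float
    sd: float
    minimum: float
    maximum: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise EmptySampleError("summary requires n >= 1")
        # tolerate float rounding at the boundaries (mean of a constant
        # vector can differ from it by an ulp)
        tol = 1e-9 * max(1.0, abs(self.minimum), abs(self.maximum))
        if not (self.minimum - tol <= self.median <= self.maximum + tol):
            raise ValidationError("median must lie within [minimum, maximum]")
        if not (self.minimum - tol <= self.mean <= self.maximum + tol):
            raise ValidationError("mean must lie within [minimum, maximum]")
        if self.sd < 0:
            raise ValidationError("sd must be non-negative")


@dataclass
class DiscardLog:
    """Bookkeeping of rows dropped during ingestion."""

    missing: int = 0
    below_detection: int = 0
    retained: int = 0

    @property
    def discarded(self) -> int:
        return self.missing + self.below_detection

    @property
    def total(self) -> int:
        return self.discarded + self.retained


@dataclass
class CohortTable:
    """Validated long-format cohort of measured values.

    After ingestion the table contains only rows with an actual measured
    value; the :class:`DiscardLog` accounts for everything dropped.

    Attributes
    ----------
    species : str
        ``"calf"`` or ``"piglet"`` (or any label for custom panels).
    data : pandas.DataFrame
        Columns ``animal_id, analyte, value, age_group, trial, sex``.
    analyte_meta : dict
        Per-analyte :class:`AnalyteMeta`.
    age_order : tuple of str
        The species' ordered age-group labels.
    """

    species: str
    data: pd.DataFrame
    analyte_meta: dict[str, AnalyteMeta]
    age_order: tuple[str, ...]
    discard_log: DiscardLog = field(default_factory=DiscardLog)

    def __post_init__(self) -> None:
        required = {"animal_id", "analyte", "value", "age_group"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"cohort data missing columns: {sorted(missing)}")
        for col in ("trial", "sex"):
            if col not in self.data.columns:
                self.data[col] = "unknown"

    def values(self, analyte: str, age_group: str) -> np.ndarray:
        """Measured values for one analyte x age cell, as a float array."""
        mask = (self.data["analyte"] == analyte) & (self.data["age_group"] == age_group)
        return self.data.loc[mask, "value"].to_numpy(dtype=float)

    def subgroup_values(
        self, analyte: str, age_group: str, by: str
    ) -> dict[str, np.ndarray]:
        """Values split by a partition column (``trial`` or ``sex``)."""
        mask = (self.data["analyte"] == analyte) & (self.data["age_group"] == age_group)
        sub = self.data.loc[mask]
        return {
            str(label): grp["value"].to_numpy(dtype=float)
            for label, grp in sub.groupby(by, sort=True)
        }

    @property
    def analytes(self) -> list[str]:
        return sorted(self.analyte_meta)

    def cell_sizes(self) -> pd.DataFrame:
        """n per (analyte, age_group), including explicit zeros."""
        counts = (
            self.data.groupby(["analyte", "age_group"], observed=True)
            .size()
            .rename("n")
            .reset_index()
        )
        return counts

    def to_csv(self, path: str | Path) -> None:
        cols = ["animal_id", "analyte", "value", "age_group", "trial", "sex"]
        self.data[cols].to_csv(path, index=False)


def summarize(values: Sequence[float] | np.ndarray) -> SummaryStats:
    """Mean / median / sample SD / min / max / n of a value vector.

    The SD uses the n-1 denominator; the median of an even-length sample is
    the midpoint of the two central order statistics.  A single observation
    has SD 0 by convention (there is no dispersion to report).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise EmptySampleError("cannot summarize an empty sample")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return SummaryStats(
        mean=float(np.mean(arr)),
        median=float(np.median(arr)),
        sd=sd,
        minimum=float(np.min(arr)),
        maximum=float(np.max(arr)),
        n=int(arr.size),
    )


def _parse_meta_mapping(schema: Mapping) -> dict[str, AnalyteMeta]:
    meta: dict[str, AnalyteMeta] = {}
    for name, entry in schema.items():
        if isinstance(entry, AnalyteMeta):
            meta[name] = entry
            continue
        adult = None
        if entry.get("adult_lower") is not None and entry.get("adult_upper") is not None:
            adult = AdultRI(
                lower=float(entry["adult_lower"]),
                upper=float(entry["adult_upper"]),
                source=str(entry.get("adult_source", "")),
            )
        elif entry.get("adult") is not None:
            a = entry["adult"]
            adult = a if isinstance(a, AdultRI) else AdultRI(float(a[0]), float(a[1]), str(a[2]) if len(a) > 2 else "")
        meta[name] = AnalyteMeta(
            unit=str(entry.get("unit", "")),
            decimals=int(entry.get("decimals", 2)),
            adult=adult,
        )
    return meta


def load_analyte_meta(path: str | Path) -> dict[str, AnalyteMeta]:
    """Load per-analyte metadata from a YAML file.

    Layout: ``{analyte: {unit, decimals, adult_lower, adult_upper,
    adult_source}}``; the adult fields are optional.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ValidationError(f"analyte metadata in {path} must be a mapping")
    return _parse_meta_mapping(raw)


def read_measurements(
    path: str | Path,
    schema: Mapping[str, AnalyteMeta] | Mapping[str, Mapping],
    *,
    species: str = "custom",
    age_order: Sequence[str] | None = None,
    lod_token: str = DEFAULT_LOD_TOKEN,
) -> CohortTable:
    """Read a long-format measurement CSV into a validated :class:`CohortTable`.

    Rows with an empty value are counted as missing; rows whose value equals
    ``lod_token`` (default ``"<LOD"``) are counted as below detection.  Both
    are discarded, mirroring the study's stated handling of missing and
    undetectable samples.  Remaining values must parse as non-negative
    reals; unknown analytes and age-group labels are rejected.

    Parameters
    ----------
    path : path
        CSV with header ``animal_id, analyte, value, age_group`` and
        optional ``trial`` and ``sex`` columns.
    schema : mapping
        Per-analyte metadata (:class:`AnalyteMeta` or plain dicts).
    age_order : sequence of str, optional
        Declared ordered age labels.  Defaults to the order of first
        appearance in the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = _parse_meta_mapping(schema)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"malformed CSV {path}: {exc}") from exc
    required = {"animal_id", "analyte", "value", "age_group"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValidationError(f"{path}: missing required columns {sorted(missing_cols)}")

    unknown = set(df["analyte"]) - set(meta)
    if unknown:
        raise ValidationError(f"{path}: unknown analytes {sorted(unknown)}")

    value_str = df["value"].str.strip()
    missing_mask = value_str == ""
    lod_mask = value_str == lod_token
    keep = ~(missing_mask | lod_mask)
    kept = df.loc[keep].copy()
    try:
        kept["value"] = kept["value"].astype(float)
    except ValueError as exc:
        bad = kept.loc[pd.to_numeric(kept["value"], errors="coerce").isna()]
        line = int(bad.index[0]) + 2 if len(bad) else "?"
        raise ValidationError(f"{path}: non-numeric value near line {line}: {exc}") from exc
    if (kept["value"] < 0).any():
        bad = kept.loc[kept["value"] < 0].iloc[0]
        raise ValidationError(
            f"{path}: negative value {bad['value']} for analyte {bad['analyte']}"
        )

    if age_order is None:
        age_order = tuple(dict.fromkeys(df["age_group"]))
    bad_ages = set(kept["age_group"]) - set(age_order)
    if bad_ages:
        raise ValidationError(f"{path}: unknown age_group labels {sorted(bad_ages)}")

    dlog = DiscardLog(
        missing=int(missing_mask.sum()),
        below_detection=int(lod_mask.sum()),
        retained=int(keep.sum()),
    )
    log.info(
        "%s: retained %d rows; discarded %d (missing %d, below detection %d)",
        path.name,
        dlog.retained,
        dlog.discarded,
        dlog.missing,
        dlog.below_detection,
    )
    kept = kept.reset_index(drop=True)
    return CohortTable(
        species=species,
        data=kept,
        analyte_meta=meta,
        age_order=tuple(age_order),
        discard_log=dlog,
    )


def write_ri_table(
    results: Iterable[tuple[str, str, "ReferenceInterval"]],  # noqa: F821
    path: str | Path,
    analyte_meta: Mapping[str, AnalyteMeta],
) -> pd.DataFrame:
    """Serialize reference intervals to the standard RI CSV layout.

    One row per (analyte, age_group); limits and their 90% confidence
    bounds are rounded to the analyte's reporting decimals.  Returns the
    frame that was written.
    """
    rows = []
    for analyte, age_group, ri in results:
        meta = analyte_meta.get(analyte, AnalyteMeta(unit=""))
        d = meta.decimals

        def r(x):
            return None if x is None else round(float(x), d)

        ci_lo = ri.ci90_lower or (None, None)
        ci_hi = ri.ci90_upper or (None, None)
        rows.append(
            {
                "analyte": analyte,
                "unit": meta.unit,
                "age_group": age_group,
                "n": ri.n,
                "method": ri.method.value,
                "lower": r(ri.lower),
                "upper": r(ri.upper),
                "lower_ci90_low": r(ci_lo[0]),
                "lower_ci90_high": r(ci_lo[1]),
                "upper_ci90_low": r(ci_hi[0]),
                "upper_ci90_high": r(ci_hi[1]),
            }
        )
    if not rows:
        raise ValidationError("write_ri_table: no results to write")
    frame = pd.DataFrame(rows, columns=RI_TABLE_COLUMNS)
    try:
        frame.to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"failed writing RI table to {path}: {exc}") from exc
    return frame


def read_ri_table(path: str | Path) -> pd.DataFrame:
    """Read back an RI CSV produced by :func:`write_ri_table`."""
    frame = pd.read_csv(path)
    missing = set(RI_TABLE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: not an RI table, missing {sorted(missing)}")
    return frame
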
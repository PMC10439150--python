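"""Domain types, pipeline configuration and tabular I/O.

Measurement tables are delimiter-separated text with a header row, one row
per routine measurement: numeric result (analyte units), age in days, a sex
code and a pseudonymous subject identifier.  Percentile tables are written
one row per day of life with one column per percentile (plus confidence
bounds when present).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_PROBS = (0.025, 0.10, 0.25, 0.50, 0.75, 0.90, 0.975)
_DELIMITERS = (",", ";", "\t")


class ValidationError(ValueError):
    """Input data violates a pipeline precondition."""


class FittingError(RuntimeError):
    """A model fit failed or the data cannot support one."""


class ExtrapolationError(ValueError):
    """Prediction requested outside the fitted age range."""


class PipelineError(RuntimeError):
    """A pipeline stage failed fatally."""


@dataclass(frozen=True)
class Measurement:
    """A single routine measurement."""

    value: float
    age_days: int
    sex: str
    subject_id: str

    def __post_init__(self) -> None:
        if not (self.value > 0 and math.isfinite(self.value)):
            raise ValidationError(f"value must be positive and finite, got {self.value}")
        if self.age_days < 0:
            raise ValidationError(f"age_days must be >= 0, got {self.age_days}")
        if not self.subject_id:
            raise ValidationError("subject_id must be non-empty")


class MeasurementSet:
    """An ordered collection of measurements backed by a DataFrame.

    Columns: ``value`` (float, > 0), ``age_days`` (int, >= 0), ``sex`` (str),
    ``subject_id`` (str).  The row order is the measurement order; downstream
    stages refer to measurements by positional index.
    """

    COLUMNS = ("value", "age_days", "sex", "subject_id")

    def __init__(self, df: pd.DataFrame, analyte_label: str = "analyte",
                 unit_label: str = "a.u.") -> None:
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"missing columns: {missing}")
        df = df.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        df["value"] = df["value"].astype(float)
        df["age_days"] = df["age_days"].astype(np.int64)
        df["sex"] = df["sex"].astype(str)
        df["subject_id"] = df["subject_id"].astype(str)
        if len(df) == 0:
            raise ValidationError("MeasurementSet may not be empty")
        if not np.all(np.isfinite(df["value"].to_numpy())) or np.any(df["value"].to_numpy() <= 0):
            raise ValidationError("all values must be positive and finite")
        if np.any(df["age_days"].to_numpy() < 0):
            raise ValidationError("all ages must be >= 0 days")
        if (df["subject_id"] == "").any():
            raise ValidationError("subject ids must be non-empty")
        self._df = df
        self.analyte_label = analyte_label
        self.unit_label = unit_label

    # -- accessors ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self._df)

    @property
    def values(self) -> np.ndarray:
        return self._df["value"].to_numpy()

    @property
    def age_days(self) -> np.ndarray:
        return self._df["age_days"].to_numpy()

    @property
    def sex(self) -> np.ndarray:
        return self._df["sex"].to_numpy()

    @property
    def subject_id(self) -> np.ndarray:
        return self._df["subject_id"].to_numpy()

    def to_dataframe(self) -> pd.DataFrame:
        return self._df.copy()

    def subject_sample_counts(self) -> np.ndarray:
        """Per-row count of samples its subject contributes to the whole set."""
        return self._df.groupby("subject_id")["subject_id"].transform("size").to_numpy()

    def take(self, indices) -> "MeasurementSet":
        """A new set of the rows at ``indices`` (duplicates allowed: used by
        bootstrap resampling; subject counts are recomputed on the new set)."""
        return MeasurementSet(
            self._df.iloc[np.asarray(indices)].reset_index(drop=True),
            analyte_label=self.analyte_label,
            unit_label=self.unit_label,
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, MeasurementSet)
            and self._df.equals(other._df)
            and self.analyte_label == other.analyte_label
            and self.unit_label == other.unit_label
        )


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable settings of the four-step pipeline.

    ``n_min`` is the minimum number of (per-subject deduplicated) samples an
    age group must reach by symmetric expansion; ``width_growth`` the
    fractional growth of group width with age (1% of the age in days by
    default); ``bootstrap_B`` the number of bootstrap pipeline executions for
    confidence bands at level ``ci_level``.
    """

    n_min: int = 1000
    width_growth: float = 0.01
    percentile_probs: tuple = DEFAULT_PROBS
    bootstrap_B: int = 100
    ci_level: float = 0.95
    rng_seed: int = 0
    max_age_days: int = 6570
    families: tuple = ("BCCG", "BCPE", "BCT")

    def __post_init__(self) -> None:
        if self.n_min < 1:
            raise ValidationError("n_min must be >= 1")
        if not 0 < self.width_growth < 1:
            raise ValidationError("width_growth must lie in (0, 1)")
        probs = tuple(self.percentile_probs)
        if any(not 0 < p < 1 for p in probs) or any(
            b <= a for a, b in zip(probs, probs[1:])
        ):
            raise ValidationError("percentile_probs must be strictly increasing in (0, 1)")
        if self.bootstrap_B < 1:
            raise ValidationError("bootstrap_B must be >= 1")
        if not 0 < self.ci_level < 1:
            raise ValidationError("ci_level must lie in (0, 1)")
        if self.max_age_days < 1:
            raise ValidationError("max_age_days must be >= 1")
        bad = [f for f in self.families if f not in ("BCCG", "BCPE", "BCT")]
        if bad or not self.families:
            raise ValidationError(f"families must be a non-empty subset of BCCG/BCPE/BCT, got {self.families}")
        object.__setattr__(self, "percentile_probs", probs)
        object.__setattr__(self, "families", tuple(self.families))

    def with_(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)


@dataclass
class PercentileTable:
    """Percentile estimates on an age grid, optionally with CI bounds."""

    ages: np.ndarray          # integer days, sorted
    probs: tuple              # strictly increasing in (0, 1)
    values: np.ndarray        # [n_ages, n_probs]
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=np.int64)
        self.probs = tuple(float(p) for p in self.probs)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ages), len(self.probs)):
            raise ValidationError("values shape must be [n_ages, n_probs]")
        if np.any(np.diff(self.ages) < 0):
            raise ValidationError("ages must be sorted")
        for name in ("ci_lower", "ci_upper"):
            m = getattr(self, name)
            if m is not None:
                m = np.asarray(m, dtype=float)
                if m.shape != self.values.shape:
                    raise ValidationError(f"{name} shape mismatch")
                setattr(self, name, m)

    @property
    def has_ci(self) -> bool:
        return self.ci_lower is not None and self.ci_upper is not None


def _prob_label(p: float) -> str:
    return f"p{100 * p:g}"


def detect_delimiter(first_line: str) -> str:
    counts = {d: first_line.count(d) for d in _DELIMITERS}
    best = max(counts.values())
    if best == 0:
        raise ValidationError("could not detect a delimiter (comma/semicolon/tab)")
    for d in _DELIMITERS:  # priority order on ties
        if counts[d] == best:
            return d
    raise AssertionError("unreachable")


def read_measurements(
    path,
    column_map: Mapping[str, str] | None = None,
    sex_filter: str | None = None,
    analyte_label: str = "analyte",
    unit_label: str = "a.u.",
) -> MeasurementSet:
    """Read a delimiter-separated measurement table with validation.

    ``column_map`` maps canonical names (``value``, ``age_days``, ``sex``,
    ``subject_id``) to the file's column names.  Rows with non-numeric or
    non-positive values, or missing/negative ages, or empty subject ids are
    dropped with a logged count; fractional ages are floored with a warning.
    ``sex_filter`` retains a single sex stratum (the pipeline runs per sex).
    """
    path = Path(path)
    try:
        with open(path, "r", encoding="utf-8") as fh:
            first = fh.readline()
    except OSError as exc:
        raise OSError(f"cannot read {path}: {exc}") from exc
    delim = detect_delimiter(first)
    df = pd.read_csv(path, sep=delim, dtype=str)

    cmap = dict(column_map or {})
    rename = {}
    for canon in MeasurementSet.COLUMNS:
        src = cmap.get(canon, canon)
        if src not in df.columns:
            raise ValidationError(f"column {src!r} (for {canon!r}) not found in {path.name}")
        rename[src] = canon
    df = df.rename(columns=rename)[list(MeasurementSet.COLUMNS)]

    n0 = len(df)
    value = pd.to_numeric(df["value"], errors="coerce")
    age = pd.to_numeric(df["age_days"], errors="coerce")
    frac = age.notna() & (age != np.floor(age))
    if frac.any():
        logger.warning("%d fractional ages floored to whole days", int(frac.sum()))
    age = np.floor(age)
    subject = df["subject_id"].fillna("").astype(str).str.strip()
    keep = (
        value.notna()
        & np.isfinite(value.fillna(np.nan))
        & (value > 0)
        & age.notna()
        & (age >= 0)
        & (subject != "")
    )
    dropped = n0 - int(keep.sum())
    if dropped:
        logger.info("dropped %d of %d rows failing validation", dropped, n0)
    out = pd.DataFrame(
        {
            "value": value[keep].astype(float),
            "age_days": age[keep].astype(np.int64),
            "sex": df.loc[keep, "sex"].astype(str).str.strip(),
            "subject_id": subject[keep],
        }
    )
    if sex_filter is not None:
        out = out[out["sex"] == sex_filter]
        logger.info("sex filter %r retained %d rows", sex_filter, len(out))
    if len(out) == 0:
        raise ValidationError(f"no valid measurement rows survive in {path.name}")
    return MeasurementSet(out.reset_index(drop=True), analyte_label, unit_label)


def write_measurements(ms: MeasurementSet, path, delimiter: str = "\t") -> None:
    ms.to_dataframe().to_csv(path, sep=delimiter, index=False)


def percentile_table_to_frame(table: PercentileTable) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {"age_days": table.ages}
    for j, p in enumerate(table.probs):
        lab = _prob_label(p)
        cols[lab] = table.values[:, j]
        if table.has_ci:
            cols[lab + "_lo"] = table.ci_lower[:, j]
            cols[lab + "_hi"] = table.ci_upper[:, j]
    return pd.DataFrame(cols)


def write_percentile_table(table: PercentileTable, path, delimiter: str = "\t") -> None:
    """Write one row per age with percentile (and CI) columns; 12 significant
    digits so a read-back round-trips to well below 1e-9 relative error."""
    if len(table.ages) == 0:
        raise ValidationError("refusing to write an empty percentile table")
    frame = percentile_table_to_frame(table)
    try:
        frame.to_csv(path, sep=delimiter, index=False, float_format="%.12g")
    except OSError as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


def read_percentile_table(path) -> PercentileTable:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    delim = detect_delimiter(first)
    df = pd.read_csv(path, sep=delim)
    plabs = [c for c in df.columns if c.startswith("p") and not c.endswith(("_lo", "_hi"))]
    probs = [float(c[1:]) / 100.0 for c in plabs]
    values = df[plabs].to_numpy()
    has_ci = all(c + "_lo" in df.columns and c + "_hi" in df.columns for c in plabs)
    ci_lo = df[[c + "_lo" for c in plabs]].to_numpy() if has_ci and plabs else None
    ci_hi = df[[c + "_hi" for c in plabs]].to_numpy() if has_ci and plabs else None
    return PercentileTable(
        ages=df["age_days"].to_numpy(), probs=tuple(probs), values=values,
        ci_lower=ci_lo, ci_upper=ci_hi,
    )
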
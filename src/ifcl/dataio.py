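"""Loading and preprocessing of continuous observational tables.

The preprocessing pipeline mirrors common practice for the Pima-style
diabetes files: drop the class/outcome column, treat biologically
impossible zeros as missing, mean-impute, Z-score standardize, and
replace extreme values by the column mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, InputError

__all__ = [
    "RawTable",
    "Dataset",
    "PreprocessReport",
    "load_table",
    "impute_missing",
    "zscore_standardize",
    "replace_abnormal",
    "preprocess",
]


@dataclass(frozen=True)
class RawTable:
    """A raw numeric table, possibly with missing entries (NaN).

    Attributes
    ----------
    variables : list of column names (unique).
    values : (m, p) float array; missing cells are NaN.
    """

    variables: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "variables", tuple(self.variables))
        if vals.ndim != 2:
            raise InputError("table values must be a 2-D matrix")
        if vals.shape[0] < 2:
            raise InputError(f"need at least 2 rows, got {vals.shape[0]}")
        if vals.shape[1] < 2:
            raise InputError(f"need at least 2 columns, got {vals.shape[1]}")
        if len(self.variables) != vals.shape[1]:
            raise InputError("number of variable names must match column count")
        if len(set(self.variables)) != len(self.variables):
            raise InputError("variable names must be unique")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class Dataset:
    """A complete (no missing values) m x n observation matrix O.

    Rows are observations o_j; columns are the analyzed variables.
    ``standardized`` records that each column was Z-scored (zero mean,
    unit sample standard deviation) at the time of standardization;
    subsequent abnormal-value replacement may perturb the moments
    slightly and is tracked in the preprocessing report.
    """

    variables: tuple[str, ...]
    O: np.ndarray
    standardized: bool = False

    def __post_init__(self) -> None:
        vals = np.asarray(self.O, dtype=float)
        object.__setattr__(self, "O", vals)
        object.__setattr__(self, "variables", tuple(self.variables))
        if vals.ndim != 2:
            raise InputError("O must be a 2-D matrix")
        if np.isnan(vals).any():
            raise DataError("Dataset may not contain missing values")
        if len(self.variables) != vals.shape[1]:
            raise InputError("number of variable names must match column count")

    @property
    def m(self) -> int:
        return self.O.shape[0]

    @property
    def n(self) -> int:
        return self.O.shape[1]

    def column(self, i: int) -> np.ndarray:
        return self.O[:, i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.O, columns=list(self.variables))


@dataclass
class PreprocessReport:
    """Per-column bookkeeping of the preprocessing pipeline."""

    imputed: dict[str, int] = field(default_factory=dict)
    replaced_abnormal: dict[str, int] = field(default_factory=dict)
    dropped_columns: list[str] = field(default_factory=list)
    zero_as_missing: list[str] = field(default_factory=list)
    zmax: float | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "imputed": self.imputed,
                "replaced_abnormal": self.replaced_abnormal,
                "dropped_columns": self.dropped_columns,
                "zero_as_missing": self.zero_as_missing,
                "zmax": self.zmax,
            },
            indent=2,
        )


def load_table(
    path: str | Path,
    drop_columns: Sequence[str] = (),
    zero_as_missing: Sequence[str] = (),
    delimiter: str = ",",
) -> RawTable:
    """Read a delimited numeric table with a header row.

    Non-numeric cells are mapped to missing. Columns listed in
    ``zero_as_missing`` have exact zeros recoded as missing — the
    convention for Pima-style files where 0 encodes a measurement
    that was not taken (glucose, blood pressure, skinfold, insulin, BMI).

    Parameters
    ----------
    path : CSV file with a header row.
    drop_columns : names removed before analysis (e.g. the class label).
    zero_as_missing : columns whose zeros are sentinel codes for missing.
    delimiter : field separator, default comma.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=delimiter)
    except (OSError, pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise InputError(f"cannot read table {path}: {exc}") from exc
    if frame.shape[0] == 0:
        raise InputError(f"{path} has a header but no data rows")
    for col in drop_columns:
        if col not in frame.columns:
            raise ConfigurationError(f"drop column {col!r} not present in {path}")
    frame = frame.drop(columns=list(drop_columns))
    if frame.shape[1] < 2:
        raise InputError("fewer than 2 variables remain after dropping columns")
    frame = frame.apply(pd.to_numeric, errors="coerce")
    for col in zero_as_missing:
        if col not in frame.columns:
            raise ConfigurationError(f"zero-as-missing column {col!r} not present")
        frame.loc[frame[col] == 0, col] = np.nan
    return RawTable(tuple(str(c) for c in frame.columns), frame.to_numpy(dtype=float))


def impute_missing(table: RawTable, report: PreprocessReport | None = None) -> RawTable:
    """Replace each missing cell by its column's arithmetic mean.

    Means are computed over the observed values only; observed cells are
    unchanged. A fully missing column is a :class:`DataError`.
    """
    values = table.values.copy()
    for k, name in enumerate(table.variables):
        col = values[:, k]
        miss = np.isnan(col)
        if miss.all():
            raise DataError(f"column {name!r} has no observed values to impute from")
        if miss.any():
            col[miss] = np.nanmean(col)
        if report is not None:
            report.imputed[name] = int(miss.sum())
    return RawTable(table.variables, values)


def zscore_standardize(table: RawTable) -> Dataset:
    """Z-score each column: (x - mean) / sd with sample sd (ddof=1).

    Requires complete data and non-constant columns.
    """
    values = np.asarray(table.values, dtype=float)
    if np.isnan(values).any():
        raise DataError("standardization requires complete data; impute first")
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=1)
    for k, name in enumerate(table.variables):
        if sds[k] == 0.0 or not np.isfinite(sds[k]):
            raise DataError(f"column {name!r} is constant; cannot standardize")
    return Dataset(table.variables, (values - means) / sds, standardized=True)


def replace_abnormal(
    data: Dataset, zmax: float = 3.0, report: PreprocessReport | None = None
) -> Dataset:
    """Replace cells with |z| > zmax by the column mean (0 after Z-scoring).

    Counts of replacements per column are recorded in ``report``.
    """
    if zmax <= 0:
        raise ConfigurationError(f"zmax must be positive, got {zmax}")
    if not data.standardized:
        raise DataError("replace_abnormal expects standardized data")
    values = data.O.copy()
    abnormal = np.abs(values) > zmax
    values[abnormal] = 0.0
    if report is not None:
        report.zmax = zmax
        for k, name in enumerate(data.variables):
            report.replaced_abnormal[name] = int(abnormal[:, k].sum())
    return replace(data, O=values)


def preprocess(
    path: str | Path,
    drop_columns: Sequence[str] = (),
    zero_as_missing: Sequence[str] = (),
    zmax: float = 3.0,
    delimiter: str = ",",
) -> tuple[Dataset, PreprocessReport]:
    """Full pipeline: load -> zeros-as-missing -> impute -> Z-score -> clip.

    Returns the analysis-ready Dataset together with a report of what
    was imputed and replaced.
    """
    report = PreprocessReport(
        dropped_columns=list(drop_columns), zero_as_missing=list(zero_as_missing)
    )
    raw = load_table(path, drop_columns, zero_as_missing, delimiter)
    raw = impute_missing(raw, report)
    data = zscore_standardize(raw)
    data = replace_abnormal(data, zmax=zmax, report=report)
    return data, report
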
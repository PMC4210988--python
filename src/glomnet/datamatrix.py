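"""Units x variables data matrices: loading, validation, pre-filtering.

The raw-data stage of the toolchain.  Rows are observational units (counties
or county equivalents in the motivating application), columns are variables
(economic, health-care, physical and social indicators), and one column may
be flagged as the outcome under study.  Missing values are allowed and kept
as NaN throughout.

Conventions fixed here and used everywhere downstream:

* sample standard deviation (n-1 denominator) for both variance filtering
  and z-scoring;
* accepted missing-value tokens in delimited files: empty string, "NA",
  "NaN" (case-insensitive);
* variance filtering operates on the raw scale and precedes normalization.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataMatrix",
    "load_data_matrix",
    "write_data_matrix",
    "filter_low_variance",
    "zscore_normalize",
]

log = logging.getLogger(__name__)

NA_TOKENS = {"", "na", "nan"}
MIN_UNITS = 3  # fewer rows cannot support a meaningful correlation

DEFAULT_VARIANCE_EPSILON = 1e-8


@dataclass
class DataMatrix:
    """A validated units x variables real matrix.

    ``values`` is float64 with NaN for missing entries; identifiers are
    unique within each axis and ``outcome_id``, when set, names a column.
    """

    unit_ids: list[str]
    variable_ids: list[str]
    values: np.ndarray
    outcome_id: str | None = None

    def __post_init__(self) -> None:
        self.unit_ids = [str(u) for u in self.unit_ids]
        self.variable_ids = [str(v) for v in self.variable_ids]
        self.values = np.asarray(self.values, dtype=np.float64)
        n, p = len(self.unit_ids), len(self.variable_ids)
        if self.values.shape != (n, p):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{n} units x {p} variables"
            )
        if n < MIN_UNITS:
            raise ValueError(f"need at least {MIN_UNITS} units, got {n}")
        for axis_name, ids in (("unit", self.unit_ids), ("variable", self.variable_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise ValueError(f"duplicate {axis_name} id: {dup!r}")
        if self.outcome_id is not None and self.outcome_id not in self.variable_ids:
            raise ValueError(f"outcome variable {self.outcome_id!r} not in variable_ids")

    # -- accessors ---------------------------------------------------------

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def n_variables(self) -> int:
        return len(self.variable_ids)

    def column(self, variable: str) -> np.ndarray:
        try:
            j = self.variable_ids.index(variable)
        except ValueError:
            raise KeyError(f"unknown variable: {variable!r}") from None
        return self.values[:, j]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.unit_ids, columns=self.variable_ids)

    def subset_variables(self, keep: Sequence[str]) -> "DataMatrix":
        keep_set = set(keep)
        cols = [j for j, v in enumerate(self.variable_ids) if v in keep_set]
        new_outcome = self.outcome_id if self.outcome_id in keep_set else None
        return DataMatrix(
            unit_ids=list(self.unit_ids),
            variable_ids=[self.variable_ids[j] for j in cols],
            values=self.values[:, cols].copy(),
            outcome_id=new_outcome,
        )

    def drop_variables(self, drop: Sequence[str]) -> "DataMatrix":
        drop_set = set(drop)
        return self.subset_variables([v for v in self.variable_ids if v not in drop_set])

    def with_column(self, variable: str, column: np.ndarray, outcome: bool = False) -> "DataMatrix":
        """Return a copy with one extra variable appended."""
        col = np.asarray(column, dtype=np.float64).reshape(-1, 1)
        return DataMatrix(
            unit_ids=list(self.unit_ids),
            variable_ids=self.variable_ids + [variable],
            values=np.hstack([self.values, col]),
            outcome_id=variable if outcome else self.outcome_id,
        )

    def sample_sd(self) -> np.ndarray:
        """Per-variable sample SD (ddof=1) over non-missing entries."""
        with np.errstate(invalid="ignore"):
            return _nan_sd(self.values)


def _nan_sd(values: np.ndarray) -> np.ndarray:
    counts = np.sum(~np.isnan(values), axis=0)
    sd = np.full(values.shape[1], np.nan)
    ok = counts >= 2
    if ok.any():
        sd[ok] = np.nanstd(values[:, ok], axis=0, ddof=1)
    sd[counts < 2] = 0.0
    return sd


def _first_duplicate(ids: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


def _infer_delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def load_data_matrix(
    path,
    outcome: str | None = None,
    delimiter: str | None = None,
) -> DataMatrix:
    """Read a delimited text matrix: header row of variable names, first
    column of unit identifiers, numeric or NA cells.

    The delimiter is inferred from the extension (.tsv/.tab/.txt -> tab,
    otherwise comma) unless given explicitly.  Errors name duplicates and the
    (unit, variable) coordinates of non-numeric cells.
    """
    path = Path(path)
    sep = delimiter if delimiter is not None else _infer_delimiter(path)
    with open(path, encoding="utf-8", newline="") as fh:
        rows = [row for row in csv.reader(fh, delimiter=sep) if row]
    if not rows:
        raise ValueError(f"{path}: empty file")
    header = rows[0]
    if len(header) < 2:
        raise ValueError(f"{path}: header must contain a unit-id column plus variables")
    variable_ids = [h.strip() for h in header[1:]]
    dup = _first_duplicate(variable_ids)
    if dup is not None:
        raise ValueError(f"{path}: duplicate variable id: {dup!r}")
    unit_ids: list[str] = []
    data = np.full((len(rows) - 1, len(variable_ids)), np.nan)
    for i, row in enumerate(rows[1:]):
        if len(row) != len(header):
            raise ValueError(
                f"{path}: row {i + 2} has {len(row)} fields, expected {len(header)}"
            )
        unit_ids.append(row[0].strip())
        for j, cell in enumerate(row[1:]):
            token = cell.strip()
            if token.lower() in NA_TOKENS:
                continue
            try:
                data[i, j] = float(token)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} at unit "
                    f"{row[0].strip()!r} (row {i + 2}), variable "
                    f"{variable_ids[j]!r} (column {j + 2})"
                ) from None
    dup = _first_duplicate(unit_ids)
    if dup is not None:
        raise ValueError(f"{path}: duplicate unit id: {dup!r}")
    if outcome is not None and outcome not in variable_ids:
        raise ValueError(f"{path}: outcome variable {outcome!r} not found in header")
    return DataMatrix(unit_ids, variable_ids, data, outcome_id=outcome)


def write_data_matrix(dm: DataMatrix, path, delimiter: str | None = None) -> None:
    """Write in the same dialect ``load_data_matrix`` reads (NaN -> "NA").

    Finite values round-trip bit-for-bit (repr-based float formatting).
    """
    path = Path(path)
    sep = delimiter if delimiter is not None else _infer_delimiter(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep, lineterminator="\n")
        writer.writerow(["unit_id"] + dm.variable_ids)
        for i, uid in enumerate(dm.unit_ids):
            row = [uid] + [
                "NA" if np.isnan(x) else repr(float(x)) for x in dm.values[i]
            ]
            writer.writerow(row)


def filter_low_variance(
    dm: DataMatrix, epsilon: float = DEFAULT_VARIANCE_EPSILON
) -> DataMatrix:
    """Drop variables whose sample SD (non-missing entries) is <= ``epsilon``.

    The outcome variable is always retained; if its SD fails the cut a
    warning is logged instead.  Dropped variable ids are logged.
    """
    if epsilon < 0:
        raise ValueError(f"epsilon must be nonnegative, got {epsilon}")
    sd = dm.sample_sd()
    keep: list[str] = []
    dropped: list[str] = []
    for j, v in enumerate(dm.variable_ids):
        if sd[j] > epsilon:
            keep.append(v)
        elif v == dm.outcome_id:
            keep.append(v)
            log.warning(
                "outcome variable %r has SD %.3g <= epsilon %.3g; retained anyway",
                v, sd[j], epsilon,
            )
        else:
            dropped.append(v)
    if dropped:
        log.info("filter_low_variance dropped %d variable(s): %s", len(dropped), dropped)
    return dm.subset_variables(keep)


def zscore_normalize(dm: DataMatrix) -> DataMatrix:
    """Standardize each variable to mean 0, sample SD 1 over non-missing
    entries; missing entries stay missing.

    Zero-variance variables are rejected with a pointer to
    :func:`filter_low_variance`.
    """
    sd = dm.sample_sd()
    bad = [v for j, v in enumerate(dm.variable_ids) if not sd[j] > 0]
    if bad:
        raise ValueError(
            f"zero-variance variable(s) {bad}; apply filter_low_variance first"
        )
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(dm.values, axis=0)
    out = (dm.values - mean) / sd
    return replace(dm, values=out)
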
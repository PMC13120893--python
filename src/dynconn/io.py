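"""Cohort and time-series input/output.

Subjects enter the pipeline as plain-text matrices (tab-delimited, one row
per time point, one column per node/IC) plus a cohort table (CSV) carrying
BMI, age, gender and optionally mean frame-wise displacement.  This module
reads and validates both, applies the tabular exclusion filters used for
resting-state cohorts (missing demographics, excessive head motion), and
assigns WHO-style BMI group labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SubjectTimeSeries",
    "BMI_GROUPS",
    "assign_bmi_group",
    "validate_cohort",
    "apply_exclusions",
    "read_timeseries",
    "write_matrix",
    "read_cohort",
]

#: Default repetition time in seconds (multiband HCP-style acquisition).
DEFAULT_TR = 0.72

#: Group labels in ascending BMI order.
BMI_GROUPS = ("underweight", "healthy", "overweight", "obese")


@dataclass
class SubjectTimeSeries:
    """One subject's node-by-time matrix of IC time courses.

    Parameters
    ----------
    subject_id : str
        Unique subject identifier.
    data : ndarray of shape (n_nodes, n_timepoints)
        Real-valued IC time courses; rows are nodes.
    tr_seconds : float
        Repetition time (sampling interval) in seconds.
    """

    subject_id: str
    data: np.ndarray
    tr_seconds: float = DEFAULT_TR

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be a 2-D matrix")
        if not np.isfinite(self.data).all():
            raise ValueError(
                f"subject {self.subject_id}: non-finite values in time series"
            )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


def assign_bmi_group(bmi: float) -> str:
    """Map a BMI value (kg/m^2) to a weight-group label.

    Half-open intervals make the assignment a total function of BMI:
    underweight (0, 18.5), healthy [18.5, 25), overweight [25, 30),
    obese [30, inf).
    """
    if not np.isfinite(bmi) or bmi <= 0:
        raise ValueError(f"BMI must be positive and finite, got {bmi!r}")
    if bmi < 18.5:
        return "underweight"
    if bmi < 25.0:
        return "healthy"
    if bmi < 30.0:
        return "overweight"
    return "obese"


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort table; returns a copy with normalized dtypes.

    Required columns: ``subject_id, bmi, age, gender``; optional
    ``mean_fd``.  Gender is normalized to the strings 'male'/'female'
    (missing stays missing).
    """
    required = ["subject_id", "bmi", "age", "gender"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    out = table.copy()
    out["subject_id"] = out["subject_id"].astype(str)
    if out["subject_id"].duplicated().any():
        dups = out.loc[out["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject_id values: {dups}")
    out["bmi"] = pd.to_numeric(out["bmi"], errors="coerce")
    out["age"] = pd.to_numeric(out["age"], errors="coerce")
    gender = out["gender"].astype("string").str.strip().str.lower()
    gender = gender.where(gender.isin(["male", "female"]))
    out["gender"] = gender
    if (out["bmi"].dropna() <= 0).any():
        raise ValueError("BMI values must be positive")
    if (out["age"].dropna() <= 0).any():
        raise ValueError("age values must be positive")
    if "mean_fd" in out.columns:
        out["mean_fd"] = pd.to_numeric(out["mean_fd"], errors="coerce")
    return out


def apply_exclusions(
    table: pd.DataFrame, fd_threshold: float = 0.25
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply tabular exclusion filters to a cohort table.

    Removes subjects with missing BMI, age or gender, and subjects whose
    mean frame-wise displacement exceeds ``fd_threshold`` (head motion).
    Filters on scanning-history columns (``endocrine_disorder``,
    ``recent_birth``, 0/1 indicators) are applied only when those columns
    exist; otherwise they are recorded in the log as not evaluable.

    Returns
    -------
    (retained, log) : tuple of DataFrame
        ``retained`` is the filtered table; ``log`` has columns
        ``subject_id, reason`` with one row per exclusion event (a subject
        can appear more than once), plus rows with subject_id '*' for
        filters that could not be evaluated.
    """
    table = validate_cohort(table)
    reasons: list[tuple[str, str]] = []
    drop = pd.Series(False, index=table.index)

    incomplete = table["bmi"].isna() | table["age"].isna() | table["gender"].isna()
    for sid in table.loc[incomplete, "subject_id"]:
        reasons.append((sid, "missing BMI or demographic data"))
    drop |= incomplete

    if "mean_fd" in table.columns:
        motion = table["mean_fd"].notna() & (table["mean_fd"] > fd_threshold)
        for sid in table.loc[motion, "subject_id"]:
            reasons.append((sid, "head motion"))
        drop |= motion
    else:
        reasons.append(("*", "head-motion filter not evaluable: no mean_fd column"))

    for col, reason in [
        ("endocrine_disorder", "endocrine disorder history"),
        ("recent_birth", "recent childbirth"),
    ]:
        if col in table.columns:
            flagged = pd.to_numeric(table[col], errors="coerce").fillna(0) > 0
            for sid in table.loc[flagged, "subject_id"]:
                reasons.append((sid, reason))
            drop |= flagged
        else:
            reasons.append(("*", f"{reason} filter not evaluable: no {col} column"))

    retained = table.loc[~drop].reset_index(drop=True)
    if retained.empty:
        warnings.warn("all subjects excluded", stacklevel=2)
    log = pd.DataFrame(reasons, columns=["subject_id", "reason"])
    return retained, log


def read_timeseries(
    path: str | Path,
    subject_id: Optional[str] = None,
    tr_seconds: float = DEFAULT_TR,
    rows: str = "time",
) -> SubjectTimeSeries:
    """Read a tab-delimited time-series matrix.

    On disk rows are time points and columns are nodes (``rows='time'``,
    the default); pass ``rows='node'`` for transposed files.  Ragged rows
    and non-numeric cells raise ``ValueError`` naming the offending row
    and column (1-based).
    """
    path = Path(path)
    if rows not in ("time", "node"):
        raise ValueError("rows must be 'time' or 'node'")
    values: list[list[float]] = []
    width: Optional[int] = None
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cells = line.split("\t")
            if width is None:
                width = len(cells)
            elif len(cells) != width:
                raise ValueError(
                    f"{path}: ragged row {i}: expected {width} columns, "
                    f"got {len(cells)}"
                )
            row = []
            for j, cell in enumerate(cells, start=1):
                try:
                    row.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric cell at row {i}, column {j}: "
                        f"{cell!r}"
                    ) from None
            values.append(row)
    if not values:
        raise ValueError(f"{path}: empty time-series file")
    mat = np.array(values, dtype=float)
    if rows == "time":
        mat = mat.T
    return SubjectTimeSeries(
        subject_id=subject_id or path.stem, data=mat, tr_seconds=tr_seconds
    )


def write_matrix(path: str | Path, matrix: np.ndarray, rows: str = "time") -> None:
    """Write a node-by-time matrix as a tab-delimited text file.

    With ``rows='time'`` (default) the file stores one row per time point.
    Values round-trip exactly through :func:`read_timeseries` (written with
    repr-precision).
    """
    matrix = np.asarray(matrix, dtype=float)
    if rows == "time":
        matrix = matrix.T
    np.savetxt(path, matrix, delimiter="\t", fmt="%.17g")


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV (``subject_id,bmi,age,gender[,mean_fd]``)."""
    return validate_cohort(pd.read_csv(path))
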
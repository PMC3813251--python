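"""CSV input/output for calibration tables and degradation time courses.

Schemas (header rows are required, extra columns are rejected by name):

* calibration table: ``day, replicate, conc_ugml, area``
* time-course table: ``condition, temperature_C, time_h, percent_remaining``

Numeric values round-trip at full precision; display rounding happens only in
rendered report tables.  Unix and Windows line endings are both accepted.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataParseError, SchemaError
from .kinetics import TimeCourse

__all__ = [
    "CALIBRATION_COLUMNS",
    "TIMECOURSE_COLUMNS",
    "read_calibration_csv",
    "write_calibration_csv",
    "read_timecourse_csv",
    "write_timecourse_csv",
]

CALIBRATION_COLUMNS = ("day", "replicate", "conc_ugml", "area")
TIMECOURSE_COLUMNS = ("condition", "temperature_C", "time_h", "percent_remaining")


def _check_schema(df: pd.DataFrame, expected: Sequence[str], path) -> None:
    missing = [c for c in expected if c not in df.columns]
    unknown = [c for c in df.columns if c not in expected]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    if unknown:
        raise SchemaError(f"{path}: unknown column(s) {unknown}")


def _numeric(df: pd.DataFrame, columns: Iterable[str], path) -> pd.DataFrame:
    df = df.copy()
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataParseError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} "
                f"in column {col!r} at row {row}"
            )
        df[col] = coerced
    return df


def read_calibration_csv(path) -> pd.DataFrame:
    """Read a calibration table, validating schema and numeric cells."""
    df = pd.read_csv(path)
    _check_schema(df, CALIBRATION_COLUMNS, path)
    return _numeric(df, CALIBRATION_COLUMNS, path)


def write_calibration_csv(table: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, columns=list(CALIBRATION_COLUMNS))


def read_timecourse_csv(path) -> list[TimeCourse]:
    """Read a time-course table into one :class:`TimeCourse` per (condition, temperature)."""
    df = pd.read_csv(path)
    _check_schema(df, TIMECOURSE_COLUMNS, path)
    df = _numeric(df, [c for c in TIMECOURSE_COLUMNS if c != "condition"], path)
    out = []
    for (cond, temp), grp in df.groupby(["condition", "temperature_C"], sort=True):
        grp = grp.sort_values("time_h")
        out.append(
            TimeCourse(
                condition=str(cond),
                temperature_c=float(temp),
                times_h=grp["time_h"].to_numpy(dtype=float),
                percent_remaining=grp["percent_remaining"].to_numpy(dtype=float),
            )
        )
    return out


def write_timecourse_csv(timecourses: Sequence[TimeCourse], path) -> None:
    """Write time courses to one long-format CSV (full numeric precision)."""
    frames = [
        pd.DataFrame(
            {
                "condition": tc.condition,
                "temperature_C": tc.temperature_c,
                "time_h": tc.times_h,
                "percent_remaining": tc.percent_remaining,
            }
        )
        for tc in timecourses
    ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
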
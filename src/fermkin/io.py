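"""CSV reading/writing for time courses, content tables and fit reports.

Tabular format: RFC-4180 CSV, UTF-8, "." decimal.  Time-course columns:
``time_days``, then any of ``biomass_g_L``, ``sugar_g_L``, ``ga``
(product titer; unit declared at read time, mg/L converted to g/L),
``replicate``, ``strain``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Union

import numpy as np
import pandas as pd

from .comparison import ContentRecord
from .errors import TimeCourseParseError
from .fitting import FitResult
from .kinetics import TimeCourse

__all__ = [
    "read_timecourse",
    "write_timecourse",
    "read_contents",
    "write_fit_report",
    "GA_UNITS",
]

GA_UNITS = ("g_L", "mg_L")

_OPTIONAL_NUMERIC = {"biomass_g_L": "X", "sugar_g_L": "S", "ga": "P"}


def read_timecourse(path: Union[str, Path], ga_unit: str = "g_L") -> TimeCourse:
    """Read and validate a time-course CSV.

    ``ga_unit`` declares the unit of the ``ga`` column; ``mg_L`` values are
    converted to g/L on ingestion.  Rows are sorted by (time, replicate).
    Errors name the offending row (1-based, counting the header as row 1).
    """
    if ga_unit not in GA_UNITS:
        raise TimeCourseParseError(f"ga_unit must be one of {GA_UNITS}, got {ga_unit!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError as exc:
        raise TimeCourseParseError(f"{path}: file is empty") from exc
    if "time_days" not in df.columns:
        raise TimeCourseParseError(f"{path}: missing required column 'time_days'")
    if df.empty:
        raise TimeCourseParseError(f"{path}: no data rows (header only)")

    def numeric(col: str, required_nonneg: bool = True) -> np.ndarray:
        # float() is correctly rounded, so write->read round-trips exactly
        vals = np.empty(len(df), dtype=float)
        for i, cell in enumerate(df[col].tolist()):
            if cell is None or (isinstance(cell, float) and pd.isna(cell)) \
                    or (isinstance(cell, str) and not cell.strip()):
                vals[i] = np.nan
                continue
            try:
                vals[i] = float(cell)
            except (TypeError, ValueError) as exc:
                raise TimeCourseParseError(
                    f"{path}: non-numeric value {cell!r} in column {col!r} "
                    f"at row {i + 2}"  # +1 header, +1 zero-based
                ) from exc
        if required_nonneg and np.any(vals[np.isfinite(vals)] < 0):
            row = int(np.flatnonzero(np.nan_to_num(vals, nan=0.0) < 0)[0]) + 2
            raise TimeCourseParseError(
                f"{path}: negative value in column {col!r} at row {row}"
            )
        return vals

    times = numeric("time_days")
    if np.any(~np.isfinite(times)):
        row = int(np.flatnonzero(~np.isfinite(times))[0]) + 2
        raise TimeCourseParseError(f"{path}: missing time value at row {row}")

    replicate = None
    if "replicate" in df.columns:
        rep_vals = numeric("replicate")
        if np.any(~np.isfinite(rep_vals)):
            row = int(np.flatnonzero(~np.isfinite(rep_vals))[0]) + 2
            raise TimeCourseParseError(f"{path}: missing replicate value at row {row}")
        replicate = rep_vals.astype(int)
        pairs = list(zip(times.tolist(), replicate.tolist()))
        seen: dict = {}
        for i, pair in enumerate(pairs):
            if pair in seen:
                raise TimeCourseParseError(
                    f"{path}: duplicate (time, replicate) pair {pair} at row {i + 2}"
                )
            seen[pair] = i
    else:
        seen_t: dict = {}
        for i, t in enumerate(times.tolist()):
            if t in seen_t:
                raise TimeCourseParseError(
                    f"{path}: duplicate time {t} at row {i + 2} "
                    "(add a 'replicate' column for repeated measurements)"
                )
            seen_t[t] = i

    series = {}
    for col, attr in _OPTIONAL_NUMERIC.items():
        if col in df.columns:
            vals = numeric(col)
            if attr == "P" and ga_unit == "mg_L":
                vals = vals / 1000.0
            series[attr] = vals

    strain = ""
    if "strain" in df.columns:
        labels = df["strain"].dropna().unique()
        if len(labels) > 1:
            raise TimeCourseParseError(
                f"{path}: multiple strain labels in one file: {sorted(labels)}"
            )
        if len(labels) == 1:
            strain = str(labels[0])

    order = np.lexsort((replicate if replicate is not None else np.zeros_like(times), times))
    return TimeCourse(
        times=times[order],
        X=series.get("X", None)[order] if "X" in series else None,
        S=series.get("S", None)[order] if "S" in series else None,
        P=series.get("P", None)[order] if "P" in series else None,
        replicate=replicate[order] if replicate is not None else None,
        strain_label=strain,
    )


def write_timecourse(tc: TimeCourse, path: Union[str, Path], ga_unit: str = "g_L") -> None:
    """Write a time course as CSV, round-trip exact with ``read_timecourse``."""
    if ga_unit not in GA_UNITS:
        raise TimeCourseParseError(f"ga_unit must be one of {GA_UNITS}, got {ga_unit!r}")
    data = {"time_days": tc.times}
    if tc.X is not None:
        data["biomass_g_L"] = tc.X
    if tc.S is not None:
        data["sugar_g_L"] = tc.S
    if tc.P is not None:
        data["ga"] = tc.P * 1000.0 if ga_unit == "mg_L" else tc.P
    if tc.replicate is not None:
        data["replicate"] = tc.replicate
    if tc.strain_label:
        data["strain"] = [tc.strain_label] * len(tc)
    pd.DataFrame(data).to_csv(path, index=False)


def read_contents(path: Union[str, Path]) -> List[ContentRecord]:
    """Read a metabolite-content table (strain, analyte, mean, sd, n, unit)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, skipinitialspace=True)
    except pd.errors.EmptyDataError as exc:
        raise TimeCourseParseError(f"{path}: file is empty") from exc
    required = {"strain", "analyte", "mean", "sd"}
    missing = required - set(df.columns)
    if missing:
        raise TimeCourseParseError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                ContentRecord(
                    strain=str(row["strain"]),
                    analyte=str(row["analyte"]),
                    mean=float(row["mean"]),
                    sd=float(row["sd"]),
                    n=int(row["n"]) if "n" in df.columns and not pd.isna(row["n"]) else 3,
                    unit=str(row["unit"]) if "unit" in df.columns and not pd.isna(row["unit"]) else "",
                )
            )
        except (ValueError, TypeError) as exc:
            raise TimeCourseParseError(f"{path}: bad content record at row {i + 2}: {exc}") from exc
    return records


def write_fit_report(result: FitResult, path: Union[str, Path]) -> None:
    """Serialize a fit result as a JSON report."""
    Path(path).write_text(result.to_json() + "\n", encoding="utf-8")


def write_json(obj: dict, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(obj, indent=2) + "\n", encoding="utf-8")
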
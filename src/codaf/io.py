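"""Reading and writing age-share tables and forecast reports.

Input tables follow the layout of published share data: either *wide*
(a ``year`` column plus one column per age group) or *long*
(``year, group, value``).  Values may be percentages or proportions;
``unit="auto"`` infers the scale from row sums (within 2% of 100 or of 1)
and rejects anything else, naming the offending row.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .pipeline import ForecastResult
from .simplex import CompositionSeries

logger = logging.getLogger("codaf")


class TableFormatError(ValueError):
    pass


def _infer_unit(row_sums: np.ndarray, unit: str) -> float:
    """Return the divisor converting table values to proportions."""
    if unit == "percent":
        lo, hi, div = 98.0, 102.0, 100.0
    elif unit == "proportion":
        lo, hi, div = 0.98, 1.02, 1.0
    elif unit == "auto":
        if np.all((row_sums >= 98.0) & (row_sums <= 102.0)):
            return 100.0
        if np.all((row_sums >= 0.98) & (row_sums <= 1.02)):
            return 1.0
        # pick the scale most rows agree with, then name the offender
        as_pct = (row_sums >= 98.0) & (row_sums <= 102.0)
        as_prop = (row_sums >= 0.98) & (row_sums <= 1.02)
        mask = as_pct if as_pct.sum() >= as_prop.sum() else as_prop
        bad = int(np.argmax(~mask))
        raise TableFormatError(
            f"cannot infer unit: row {bad} sums to {row_sums[bad]:g} "
            "(neither ~100 nor ~1)"
        )
    else:
        raise ValueError(f"unknown unit {unit!r}")
    bad = (row_sums < lo) | (row_sums > hi)
    if bad.any():
        i = int(np.argmax(bad))
        raise TableFormatError(
            f"row {i} sums to {row_sums[i]:g}, outside the {unit} tolerance "
            f"[{lo}, {hi}]"
        )
    return div


def read_series_csv(
    path: str | Path,
    layout: str = "wide",
    unit: str = "auto",
) -> CompositionSeries:
    """Read an age-share table into a CompositionSeries.

    Rows are re-closed to exact unit sum (logged when the deviation
    exceeds 1e-6); years are sorted ascending and duplicates rejected.
    """
    df = pd.read_csv(path)
    if layout == "long":
        if not {"year", "group", "value"}.issubset(df.columns):
            raise TableFormatError("long layout needs columns year, group, value")
        df = df.pivot(index="year", columns="group", values="value")
        # preserve first-appearance group order rather than alphabetical
        order = pd.read_csv(path)["group"].drop_duplicates().tolist()
        df = df[order].reset_index()
    elif layout != "wide":
        raise ValueError(f"unknown layout {layout!r}")
    cols = list(df.columns)
    ycol = next((c for c in cols if str(c).lower() == "year"), None)
    if ycol is None:
        raise TableFormatError("missing 'year' column")
    groups = [c for c in cols if c != ycol]
    if len(groups) < 2:
        raise TableFormatError("need at least two group columns")
    try:
        years = df[ycol].astype(int).to_numpy()
    except (TypeError, ValueError) as exc:
        raise TableFormatError(f"years do not parse as integers: {exc}") from exc
    if len(np.unique(years)) != len(years):
        raise TableFormatError("duplicate years in table")
    order = np.argsort(years)
    years = years[order]
    values = df[groups].to_numpy(dtype=float)[order]
    if np.any(values < 0):
        raise TableFormatError("negative share values")
    div = _infer_unit(values.sum(axis=1), unit)
    props = values / div
    drift = np.abs(props.sum(axis=1) - 1.0)
    if np.any(drift > 1e-6):
        logger.warning(
            "renormalised %d row(s) with unit-sum deviation up to %.2g",
            int(np.sum(drift > 1e-6)), float(drift.max()),
        )
    rows = props / props.sum(axis=1, keepdims=True)
    return CompositionSeries.from_matrix(years, rows, tuple(map(str, groups)))


def write_series_csv(
    series: CompositionSeries, path: str | Path, unit: str = "percent"
) -> None:
    """Write a series in the wide dialect the reader consumes."""
    labels = series.labels or tuple(f"part{i + 1}" for i in range(series.D))
    scale = 100.0 if unit == "percent" else 1.0
    df = pd.DataFrame(series.as_matrix() * scale, columns=list(labels))
    df.insert(0, "year", list(series.years))
    df.to_csv(path, index=False)


def write_forecast_table(
    result: ForecastResult, path: str | Path, json_path: str | Path | None = None
) -> None:
    """Write forecast compositions as a percent table (2 decimals).

    The CSV mirrors the printed layout: a Year column, one percent column
    per group, and — when any LCC row leaves the simplex — a ``valid``
    flag column.  Unrounded values and full provenance go to the
    companion JSON report (default: same path with a .json suffix).
    """
    labels = result.labels or tuple(f"part{i + 1}" for i in range(result.parts.shape[1]))
    df = pd.DataFrame(
        np.round(result.parts * 100.0, 2), columns=[str(l) for l in labels]
    )
    df.insert(0, "Year", list(result.years))
    if not all(result.valid):
        df["valid"] = list(result.valid)
    df.to_csv(path, index=False, float_format="%.2f")
    report = {
        "transform": result.transform,
        "model": result.family,
        "horizon": result.horizon,
        "years": list(result.years),
        "parts": result.parts.tolist(),
        "valid": list(result.valid),
        "labels": list(labels),
        "config": {
            k: v for k, v in dataclasses.asdict(result.config).items()
            if v is not None
        },
    }
    jp = Path(json_path) if json_path else Path(path).with_suffix(".json")
    jp.write_text(json.dumps(report, indent=2))


def report_to_dict(report) -> dict:
    """JSON-serialisable view of an EvaluationReport."""
    return {
        "train_years": list(report.train_years),
        "test_years": list(report.test_years),
        "seed": report.seed,
        "cells": [
            {
                "transform": t,
                "model": f,
                "coda_rmse": c.coda_rmse,
                "coda_mape": c.coda_mape,
                "warnings": list(c.warnings),
                "error": c.error,
            }
            for (t, f), c in sorted(report.entries.items())
        ],
        "nnetts_grid": [
            {
                "transform": t,
                "lags": m,
                "hidden": h,
                "coda_rmse": c.coda_rmse,
                "coda_mape": c.coda_mape,
                "error": c.error,
            }
            for (t, m, h), c in sorted(report.nnetts_grid.items())
        ],
    }
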
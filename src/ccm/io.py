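"""Delimited-text input and tidy output tables.

Input is CSV/TSV with one column per variable, an optional header row and
an optional leading time column (recognized as a monotone arithmetic
progression). Outputs are tidy TSVs so that every figure has a table twin
carrying the exact plotted numbers.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .crossmap import ConvergenceSummary, CrossMapResult
from .embedding import TimeSeries
from .optimize import ParamSurface

__all__ = [
    "read_series",
    "write_result_tsv",
    "write_summary_tsv",
    "write_surface_tsv",
]


def _sniff_delimiter(path: Path) -> str:
    sample = path.read_text().splitlines()[0]
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t; ").delimiter
    except csv.Error:
        return ","


def _is_arithmetic(values: np.ndarray) -> bool:
    if values.size < 3 or not np.issubdtype(values.dtype, np.number):
        return False
    diffs = np.diff(values.astype(float))
    return bool(
        np.all(np.isfinite(diffs))
        and diffs[0] != 0
        and np.allclose(diffs, diffs[0], rtol=1e-9, atol=1e-12)
    )


def read_series(
    path,
    columns: tuple | None = None,
    delimiter: str | None = None,
) -> list[TimeSeries]:
    """Read time series from a delimited text file.

    Parameters
    ----------
    path : str or Path
        CSV/TSV file, one column per variable, optional header row.
    columns : tuple of (str or int), optional
        Two or more columns to load, by header name or 0-based position
        (positions count data columns after time-column removal). Default:
        all data columns.
    delimiter : str, optional
        Field separator; sniffed from the first line when omitted.

    Notes
    -----
    A leading column forming a monotone arithmetic progression is treated
    as a time axis: it sets the sampling step but is not returned as data.
    Missing or non-finite values are a hard error — interpolate upstream.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delimiter)
    # a file without a header yields numeric-looking column names; reload
    first_row_numeric = all(_parses_float(c) for c in df.columns)
    if first_row_numeric:
        df = pd.read_csv(path, sep=delimiter, header=None)
        df.columns = [f"col{i}" for i in range(df.shape[1])]
    if df.shape[1] < 1:
        raise ValueError(f"{path}: no columns found")

    # a leading arithmetic progression is a time axis, but only when at
    # least two data columns remain after dropping it
    step = 1.0
    first = df.iloc[:, 0].to_numpy()
    if df.shape[1] >= 3 and _is_arithmetic(first):
        step = float(np.diff(first.astype(float))[0])
        df = df.iloc[:, 1:]

    if columns is not None:
        selected = []
        for c in columns:
            if isinstance(c, int) or (isinstance(c, str) and c.isdigit()):
                selected.append(df.columns[int(c)])
            elif c in df.columns:
                selected.append(c)
            else:
                raise ValueError(
                    f"{path}: column {c!r} not found among {list(df.columns)}"
                )
        df = df[selected]

    out = []
    for name in df.columns:
        vals = pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)):
            raise ValueError(
                f"{path}: column {name!r} has missing or non-numeric values; "
                "interpolate or filter upstream"
            )
        out.append(TimeSeries(vals, name=str(name), step=step))
    return out


def result_frame(results: list[CrossMapResult]) -> pd.DataFrame:
    """Long-format table: one row per (direction, L, window)."""
    rows = []
    for res in results:
        p = res.params
        for L, rhos in zip(res.lib_sizes, res.rho_windows):
            for start, rho in enumerate(rhos):
                rows.append(
                    dict(
                        direction=res.direction,
                        E=p.E,
                        tau=p.tau,
                        tau_p=p.tau_p,
                        L=int(L),
                        window_start=start,
                        rho=rho,
                    )
                )
    return pd.DataFrame(rows)


def write_result_tsv(results: list[CrossMapResult], path) -> None:
    result_frame(results).to_csv(path, sep="\t", index=False, float_format="%.10g")


def summary_frame(
    results: list[CrossMapResult],
    convergences: list[ConvergenceSummary],
) -> pd.DataFrame:
    """One row per direction: the convergence curve means plus the verdict."""
    rows = []
    for res, conv in zip(results, convergences):
        for L, rho in zip(res.lib_sizes, res.rho_mean):
            rows.append(
                dict(
                    direction=res.direction,
                    E=res.params.E,
                    tau=res.params.tau,
                    tau_p=res.params.tau_p,
                    L=int(L),
                    mean_rho=rho,
                    delta_rho=conv.delta_rho,
                    converged=conv.converged,
                )
            )
    return pd.DataFrame(rows)


def write_summary_tsv(results, convergences, path) -> None:
    summary_frame(results, convergences).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def surface_frame(surfaces: list[ParamSurface]) -> pd.DataFrame:
    """Tidy (direction, E, tau_p, max_rho) rows; infeasible cells stay NaN."""
    rows = []
    for surf in surfaces:
        for i, E in enumerate(surf.e_values):
            for j, tp in enumerate(surf.tau_p_values):
                rows.append(
                    dict(
                        direction=surf.direction,
                        E=int(E),
                        tau_p=int(tp),
                        max_rho=surf.values[i, j],
                    )
                )
    return pd.DataFrame(rows)


def write_surface_tsv(surfaces, path) -> None:
    surface_frame(surfaces).to_csv(path, sep="\t", index=False, float_format="%.10g")


def _parses_float(text) -> bool:
    try:
        float(text)
        return True
    except (TypeError, ValueError):
        return False
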
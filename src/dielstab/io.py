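"""Tabular I/O for spectra, single-frequency scans and composition tables.

All files are long-format CSV with unit-suffixed headers:

* wide-band spectra: ``temperature_K[, time_s], frequency_Hz, eps_real[, eps_imag]``
* single-frequency scans: ``temperature_K, eps_real``
* composition tables: ``w2, tg_K[, method]``
* relaxation maps: ``temperature_K, tau_alpha_s``

Reading and writing round-trip exactly (pandas emits shortest-repr floats).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import CompositionPoint, DielectricSpectrum, SpectrumSeries
from .errors import EmptyInputError, FormatError, ValidationError

#: temperatures closer than this (kelvin) are treated as one measurement
DEFAULT_TEMPERATURE_TOLERANCE = 0.01


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: file is empty") from None
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")
    return df

def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    for col in columns:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")


def _cluster_keys(values: np.ndarray, tolerance: float) -> np.ndarray:
    """Map raw grouping keys to cluster representatives.

    Greedy one-pass clustering of the sorted unique values: a new cluster
    starts whenever a value lies more than ``tolerance`` from the current
    cluster's first member, so values differing by more than the tolerance
    are never merged.
    """
    uniq = np.unique(values)
    reps = {}
    cluster_start = None
    members: list[float] = []
    for v in uniq:
        if cluster_start is None or v - cluster_start > tolerance:
            for m in members:
                reps[m] = float(np.mean(members))
            cluster_start = v
            members = [v]
        else:
            members.append(v)
    for m in members:
        reps[m] = float(np.mean(members))
    return np.array([reps[v] for v in values])


def read_spectrum_series(
    path,
    dialect: str = "wide_band",
    axis: str = "temperature",
    fixed_frequency: float = 1.0e3,
    temperature_tolerance: float = DEFAULT_TEMPERATURE_TOLERANCE,
) -> SpectrumSeries:
    """Read a spectra CSV into a validated :class:`SpectrumSeries`.

    ``dialect='wide_band'`` expects ``temperature_K, frequency_Hz, eps_real``
    (``eps_imag`` and ``time_s`` optional); rows are grouped by temperature
    (or time) into spectra, groups sorted ascending.

    ``dialect='single_frequency'`` expects ``temperature_K, eps_real`` — one
    real-permittivity reading per temperature at ``fixed_frequency``.
    """
    df = _read_csv(path)
    if dialect == "single_frequency":
        _require_columns(df, ["temperature_K", "eps_real"], path)
        df = df.sort_values("temperature_K", kind="stable")
        spectra = tuple(
            DielectricSpectrum(
                temperature=float(row.temperature_K),
                frequencies=np.array([fixed_frequency]),
                eps_real=np.array([row.eps_real]),
            )
            for row in df.itertuples()
        )
        return SpectrumSeries(spectra=spectra, axis="temperature",
                              fixed_frequency=fixed_frequency)

    if dialect != "wide_band":
        raise FormatError(f"unknown dialect {dialect!r}")
    _require_columns(df, ["temperature_K", "frequency_Hz", "eps_real"], path)
    has_imag = "eps_imag" in df.columns
    has_time = "time_s" in df.columns
    if axis == "time" and not has_time:
        raise FormatError(f"{path}: axis='time' requires a time_s column")

    key_col = "time_s" if axis == "time" else "temperature_K"
    keys = df[key_col].to_numpy(dtype=float)
    tol = temperature_tolerance if axis == "temperature" else 0.0
    group_keys = _cluster_keys(keys, tol) if tol > 0 else keys

    spectra = []
    for key in np.unique(group_keys):
        sub = df[group_keys == key]
        freq = sub["frequency_Hz"].to_numpy(dtype=float)
        order = np.arange(freq.size)
        if np.any(np.diff(freq) <= 0):
            raise ValidationError(
                f"{path}: non-monotone frequency grid within the group at {key_col}={key}"
            )
        spectra.append(
            DielectricSpectrum(
                temperature=float(sub["temperature_K"].iloc[0]) if axis == "time"
                else float(key),
                time=float(sub["time_s"].iloc[0]) if has_time else None,
                frequencies=freq[order],
                eps_real=sub["eps_real"].to_numpy(dtype=float)[order],
                eps_imag=sub["eps_imag"].to_numpy(dtype=float)[order] if has_imag else None,
            )
        )
    return SpectrumSeries(spectra=tuple(spectra), axis=axis)


def write_spectrum_series(series: SpectrumSeries, path) -> None:
    """Write a series as long-format CSV re-readable by :func:`read_spectrum_series`."""
    rows = []
    has_time = any(s.time is not None for s in series)
    single = series.fixed_frequency is not None
    for s in series:
        for j in range(s.n_points):
            row = {"temperature_K": s.temperature}
            if has_time:
                row["time_s"] = s.time
            if not single:
                row["frequency_Hz"] = s.frequencies[j]
            if s.eps_real is not None:
                row["eps_real"] = s.eps_real[j]
            if s.eps_imag is not None:
                row["eps_imag"] = s.eps_imag[j]
            rows.append(row)
    if rows:
        df = pd.DataFrame(rows)
    else:
        cols = ["temperature_K", "frequency_Hz", "eps_real", "eps_imag"]
        if single:
            cols = ["temperature_K", "eps_real"]
        df = pd.DataFrame(columns=cols)
    df.to_csv(path, index=False)


def read_composition_table(path) -> list[CompositionPoint]:
    """Read ``w2, tg_K[, method]`` rows, validated and sorted by ``w2``.

    Duplicate ``w2`` rows (replicates) are preserved.
    """
    df = _read_csv(path)
    _require_columns(df, ["w2", "tg_K"], path)
    points = []
    for i, row in enumerate(df.itertuples()):
        w2 = float(row.w2)
        if not 0.0 <= w2 <= 1.0:
            raise ValidationError(f"{path}: row {i}: w2={w2} outside [0, 1]")
        method = getattr(row, "method", None)
        if method is not None and not isinstance(method, str) and pd.isna(method):
            method = None
        points.append(CompositionPoint(w2=w2, tg=float(row.tg_K), method=method))
    return sorted(points, key=lambda p: p.w2)


def write_composition_table(points: Sequence[CompositionPoint], path) -> None:
    df = pd.DataFrame(
        {"w2": [p.w2 for p in points],
         "tg_K": [p.tg for p in points],
         "method": [p.method for p in points]}
    )
    if df["method"].isna().all():
        df = df.drop(columns=["method"])
    df.to_csv(path, index=False)


def read_trace(path, axis: str = "time"):
    """Read a fixed-frequency ε′ trace CSV (``time_s`` or ``temperature_K`` + ``eps_real``)."""
    from .crystallization import CrystallizationTrace

    df = _read_csv(path)
    col = "time_s" if axis == "time" else "temperature_K"
    _require_columns(df, [col, "eps_real"], path)
    df = df.sort_values(col, kind="stable")
    return CrystallizationTrace(
        axis=axis,
        axis_values=df[col].to_numpy(dtype=float),
        eps_real=df["eps_real"].to_numpy(dtype=float),
    )


def write_trace(trace, path) -> None:
    col = "time_s" if trace.axis == "time" else "temperature_K"
    pd.DataFrame({col: trace.axis_values, "eps_real": trace.eps_real}).to_csv(
        path, index=False
    )


def read_relaxation_map(path) -> pd.DataFrame:
    """Read a ``temperature_K, tau_alpha_s`` table."""
    df = _read_csv(path)
    _require_columns(df, ["temperature_K", "tau_alpha_s"], path)
    if (df["tau_alpha_s"] <= 0).any():
        raise ValidationError(f"{path}: tau_alpha_s must be positive")
    return df


def write_relaxation_map(points, path) -> None:
    """Write relaxation points (objects with .temperature/.tau_alpha) as CSV."""
    pd.DataFrame(
        {"temperature_K": [p.temperature for p in points],
         "tau_alpha_s": [p.tau_alpha for p in points]}
    ).to_csv(path, index=False)
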
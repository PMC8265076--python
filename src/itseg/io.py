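"""Data ingestion: CSV/TSV reading, grid validation, missing-value
interpolation, cross-unit overlap restriction, and candidate-set
construction from calendar date ranges.

The expected layout is wide: a first timestamp column followed by one
outcome column per unit.  Timestamps are ISO-8601 dates (a custom
``date_format`` is accepted) or plain numeric ticks.  A long layout
(unit, date, value) is accepted as a dialect and pivoted to wide.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .model import MIN_SEGMENT, CandidateSet, ITSDataset, UnitSeries

__all__ = [
    "read_table",
    "restrict_overlap",
    "interpolate_missing",
    "candidates_from_range",
    "load_dataset",
    "to_grid_index",
]


def read_table(path, dialect: str | None = None, date_format: str | None = None) -> pd.DataFrame:
    """Read a wide CSV/TSV into a typed frame.

    Returns a frame whose first column (named ``date``) holds parsed
    timestamps (datetime64 or float ticks) and whose remaining columns are
    float outcome series with missing cells as NaN (flagged, never dropped).

    Raises descriptive errors for unparseable timestamps or values (with row
    numbers) and duplicated timestamps (naming the date).
    """
    if dialect is None:
        dialect = "tsv" if str(path).lower().endswith((".tsv", ".tab", ".txt")) else "csv"
    if dialect not in ("csv", "tsv"):
        raise ValueError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
    sep = "," if dialect == "csv" else "\t"
    raw = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    if raw.shape[1] < 2:
        raise ValueError(
            f"{path}: need at least a timestamp column and one unit column, "
            f"found {raw.shape[1]} column(s)"
        )
    # long dialect: (unit, date, value) in any of the obvious column namings
    lowered = [c.strip().lower() for c in raw.columns]
    if raw.shape[1] == 3 and set(lowered) == {"unit", "date", "value"}:
        raw.columns = lowered
        raw = raw.pivot_table(
            index="date", columns="unit", values="value", aggfunc="first"
        ).reset_index()
        raw.columns.name = None

    date_col = raw.columns[0]
    dates_str = raw[date_col].astype(str).str.strip()
    try:
        if date_format is not None:
            dates = pd.to_datetime(dates_str, format=date_format)
        else:
            dates = pd.to_datetime(dates_str, format="ISO8601")
        times = dates.to_numpy().astype("datetime64[ns]")
    except (ValueError, TypeError):
        numeric = pd.to_numeric(dates_str, errors="coerce")
        bad = np.nonzero(numeric.isna().to_numpy())[0]
        if len(bad):
            raise ValueError(
                f"{path}: unparseable timestamp {dates_str.iloc[bad[0]]!r} "
                f"in data row {bad[0] + 1}"
            ) from None
        times = numeric.to_numpy(dtype=float)
    dup = pd.Series(times).duplicated()
    if dup.any():
        first = np.nonzero(dup.to_numpy())[0][0]
        raise ValueError(f"{path}: duplicated timestamp {dates_str.iloc[first]!r}")

    out = pd.DataFrame({"date": times})
    for col in raw.columns[1:]:
        cell = raw[col].astype("string").str.strip()
        cell = cell.replace({"": None, "NA": None, "NaN": None, "nan": None})
        vals = pd.to_numeric(cell, errors="coerce")
        bad = np.nonzero((vals.isna() & cell.notna()).to_numpy())[0]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric value {cell.iloc[bad[0]]!r} for unit "
                f"{col!r} in data row {bad[0] + 1}"
            )
        out[str(col).strip()] = vals.to_numpy(dtype=float)
    order = np.argsort(out["date"].to_numpy(), kind="stable")
    return out.iloc[order].reset_index(drop=True)


def _trim_edges(times: np.ndarray, values: np.ndarray, unit_id: str):
    """Drop leading/trailing missing cells (cannot be interpolated)."""
    finite = np.isfinite(values)
    if not finite.any():
        raise ValueError(f"unit {unit_id!r}: all values are missing")
    first, last = np.nonzero(finite)[0][[0, -1]]
    if first > 0 or last < len(values) - 1:
        warnings.warn(
            f"unit {unit_id!r}: trimming {first + (len(values) - 1 - last)} "
            "edge time point(s) with missing values",
            UserWarning,
        )
    return times[first : last + 1], values[first : last + 1]


def interpolate_missing(times: np.ndarray, values: np.ndarray, unit_id: str = "?"):
    """Linearly interpolate interior missing values on the time grid.

    Returns ``(times, values, imputed)`` where ``imputed`` holds the 0-based
    positions that were filled (relative to the returned, edge-trimmed
    arrays).  Imputation can bias parameter estimates slightly, so any
    filled-in points trigger a warning; series without missing data are
    preferred.
    """
    times = np.asarray(times)
    values = np.asarray(values, dtype=float)
    times, values = _trim_edges(times, values, unit_id)
    missing = ~np.isfinite(values)
    imputed = np.nonzero(missing)[0]
    if len(imputed):
        pos = (
            times.astype("datetime64[s]").astype(float)
            if np.issubdtype(times.dtype, np.datetime64)
            else times.astype(float)
        )
        values = values.copy()
        values[missing] = np.interp(pos[missing], pos[~missing], values[~missing])
        warnings.warn(
            f"unit {unit_id!r}: linearly interpolated {len(imputed)} missing "
            "value(s); estimates may be slightly biased",
            UserWarning,
        )
    return times, values, imputed


def restrict_overlap(units):
    """Restrict every unit to the timestamps present in all units.

    Accepts ``(unit_id, times, values)`` triples or :class:`UnitSeries`; a
    unit observed only in 2015 against others covering 2015-2016 truncates
    everyone to 2015.  Raises on an empty intersection.
    """
    triples = [
        (u.unit_id, u.times, u.values) if isinstance(u, UnitSeries) else u for u in units
    ]
    if not triples:
        raise ValueError("no units to restrict")
    common = triples[0][1]
    for _, t, _ in triples[1:]:
        common = np.intersect1d(common, t)
    if len(common) == 0:
        raise ValueError("units share no overlapping time points")
    out = []
    for uid, t, v in triples:
        keep = np.isin(t, common)
        out.append((uid, np.asarray(t)[keep], np.asarray(v, dtype=float)[keep]))
    return out


def to_grid_index(times: np.ndarray, when) -> int:
    """1-based tick of the grid point nearest to ``when``."""
    if np.issubdtype(np.asarray(times).dtype, np.datetime64):
        when = np.datetime64(when)
        deltas = np.abs((times - when).astype("timedelta64[s]").astype(float))
    else:
        deltas = np.abs(times.astype(float) - float(when))
    return int(np.argmin(deltas)) + 1


def candidates_from_range(
    dataset: ITSDataset, start, end, min_segment: int = MIN_SEGMENT
) -> CandidateSet:
    """Candidate change-points: every measurement time inside [start, end],
    restricted to ticks leaving at least ``min_segment`` observations in each
    phase.  Two ranges whose endpoints fall between the same measurement
    dates yield identical candidate sets.
    """
    times = dataset.times
    if np.issubdtype(times.dtype, np.datetime64):
        start, end = np.datetime64(start), np.datetime64(end)
    if end < start:
        raise ValueError("candidate range end precedes start")
    inside = np.nonzero((times >= start) & (times <= end))[0] + 1
    n = dataset.n
    lo, hi = min_segment + 1, n - min_segment + 1
    admissible = inside[(inside >= lo) & (inside <= hi)]
    if len(admissible) == 0:
        raise ValueError(
            "no admissible change-point candidates in the requested range "
            f"[{start}, {end}] (admissible ticks are [{lo}, {hi}])"
        )
    theo = (
        to_grid_index(times, dataset.intervention_time)
        if dataset.intervention_time is not None
        else None
    )
    return CandidateSet(indices=admissible, theoretical_index=theo)


def load_dataset(
    source,
    dialect: str | None = None,
    date_format: str | None = None,
    intervention_time=None,
    analysis_start=None,
    analysis_end=None,
) -> ITSDataset:
    """Full ingestion pipeline: read (or accept) a wide table, trim edge
    missing cells, restrict to the cross-unit overlapping grid, interpolate
    interior gaps, and assemble the dataset.

    ``analysis_start``/``analysis_end`` clip the series to a study window
    before any fitting, so only the visible part of the series is processed.
    """
    df = source if isinstance(source, pd.DataFrame) else read_table(source, dialect, date_format)
    times = df.iloc[:, 0].to_numpy()
    if analysis_start is not None or analysis_end is not None:
        lo = times.min() if analysis_start is None else np.asarray(analysis_start).astype(times.dtype)
        hi = times.max() if analysis_end is None else np.asarray(analysis_end).astype(times.dtype)
        keep = (times >= lo) & (times <= hi)
        df = df.loc[keep]
        times = times[keep]
    raw_units = []
    for col in df.columns[1:]:
        t, v = _trim_edges(times, df[col].to_numpy(dtype=float), str(col))
        raw_units.append((str(col), t, v))
    units = []
    for uid, t, v in restrict_overlap(raw_units):
        t, v, _ = interpolate_missing(t, v, uid)
        units.append(UnitSeries(unit_id=uid, times=t, values=v))
    return ITSDataset(units=tuple(units), intervention_time=intervention_time)
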
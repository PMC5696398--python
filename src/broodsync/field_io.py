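"""Reading, validation and pairing of the four CSV inputs.

All tables are tidy :class:`pandas.DataFrame` objects with documented column
schemas.  Dates are integer day-of-year (1-based); clock time is the integer
minute of the day (0-1439), so a reading's timestamp is the pair
``(day, minute)``.  Coordinates are planar metres (already projected).

Schemas
-------
ambient.csv      logger_id, x, y, day, minute, temp
nest_traces.csv  nest_id, x, y, placement_date, day, minute, temp
nest_records.csv nest_id, year, x, y, initiation_date, clutch_size,
                 completion_date, hatch_date, fledglings, section
caterpillar.csv  year, peak_date

``hatch_date`` and ``fledglings`` may be empty (nest failed or unchecked).
A ``date`` column in ISO format may replace ``day`` in any file and is
converted to day-of-year on read.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

AMBIENT_COLUMNS = ["logger_id", "x", "y", "day", "minute", "temp"]
TRACE_COLUMNS = ["nest_id", "x", "y", "placement_date", "day", "minute", "temp"]
RECORD_COLUMNS = [
    "nest_id", "year", "x", "y", "initiation_date", "clutch_size",
    "completion_date", "hatch_date", "fledglings", "section",
]
CATERPILLAR_COLUMNS = ["year", "peak_date"]


class SchemaError(ValueError):
    """A required column is missing or has the wrong type."""


class ValidationError(ValueError):
    """Row-level invariant violated; message carries row numbers."""


class CoverageError(ValueError):
    """An ambient series does not cover the span it is asked for."""


def _require_columns(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing required column(s) {missing}")


def _convert_iso_dates(df: pd.DataFrame, day_col: str) -> pd.DataFrame:
    """Accept an ISO ``date`` column in place of an integer day column."""
    if day_col not in df.columns and "date" in df.columns:
        df = df.copy()
        df[day_col] = pd.to_datetime(df["date"]).dt.dayofyear
        df = df.drop(columns=["date"])
    return df


def read_ambient(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df = _convert_iso_dates(df, "day")
    _require_columns(df, AMBIENT_COLUMNS, "ambient")
    df = df[AMBIENT_COLUMNS].copy()
    df["logger_id"] = df["logger_id"].astype(str)
    # timestamps strictly increasing at constant spacing within each logger
    for lid, grp in df.groupby("logger_id", sort=False):
        t = grp["day"].to_numpy() * 1440 + grp["minute"].to_numpy()
        dt = np.diff(t)
        if len(dt) and (dt <= 0).any():
            row = int(grp.index[1:][dt <= 0][0])
            raise ValidationError(
                f"ambient: non-monotone timestamps for logger {lid} at row {row}"
            )
        if len(dt) and len(np.unique(dt)) > 1:
            raise ValidationError(
                f"ambient: irregular sampling interval for logger {lid}"
            )
    return df


def read_traces(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df = _convert_iso_dates(df, "day")
    _require_columns(df, TRACE_COLUMNS, "nest_traces")
    df = df[TRACE_COLUMNS].copy()
    df["nest_id"] = df["nest_id"].astype(str)
    for nid, grp in df.groupby("nest_id", sort=False):
        t = grp["day"].to_numpy() * 1440 + grp["minute"].to_numpy()
        if len(t) > 1 and (np.diff(t) <= 0).any():
            row = int(grp.index[1:][np.diff(t) <= 0][0])
            raise ValidationError(
                f"nest_traces: non-monotone timestamps for nest {nid} at row {row}"
            )
        if int(grp["placement_date"].iloc[0]) > int(grp["day"].iloc[0]):
            raise ValidationError(
                f"nest_traces: nest {nid} placement_date after first reading"
            )
    return df


def read_records(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, RECORD_COLUMNS, "nest_records")
    df = df[RECORD_COLUMNS].copy()
    df["nest_id"] = df["nest_id"].astype(str)
    bad = df["clutch_size"] < 1
    if bad.any():
        raise ValidationError(
            f"nest_records: clutch_size < 1 at rows {list(df.index[bad])}"
        )
    expected = df["initiation_date"] + df["clutch_size"] - 1
    bad = df["completion_date"] != expected
    if bad.any():
        raise ValidationError(
            "nest_records: completion_date != initiation_date + clutch_size - 1 "
            f"at rows {list(df.index[bad])}"
        )
    hatched = df["hatch_date"].notna()
    bad = hatched & (df.loc[hatched, "hatch_date"] <= df.loc[hatched, "completion_date"])
    if bad.any():
        raise ValidationError(
            f"nest_records: hatch_date <= completion_date at rows {list(df.index[bad])}"
        )
    return df


def read_caterpillar(path, years_required=None) -> pd.DataFrame:
    df = pd.read_csv(path)
    df = _convert_iso_dates(df, "peak_date")
    _require_columns(df, CATERPILLAR_COLUMNS, "caterpillar")
    df = df[CATERPILLAR_COLUMNS].copy()
    if years_required is not None:
        missing = sorted(set(years_required) - set(df["year"]))
        if missing:
            raise ValidationError(
                f"caterpillar: no peak date for year(s) {missing}"
            )
    if df.empty:
        raise ValidationError("caterpillar: table is empty")
    return df


def read_inputs(ambient_path, traces_path, records_path, caterpillar_path):
    """Read and validate all four inputs; caterpillar years are checked
    against the years present in the nest records."""
    ambient = read_ambient(ambient_path)
    traces = read_traces(traces_path)
    records = read_records(records_path)
    caterpillar = read_caterpillar(
        caterpillar_path, years_required=records["year"].unique()
    )
    return ambient, traces, records, caterpillar


# ---------------------------------------------------------------------------
# Nest-to-logger pairing
# ---------------------------------------------------------------------------

def pair_nearest_logger(x: float, y: float, loggers: pd.DataFrame) -> str:
    """Return the id of the ambient logger nearest (Euclidean) to ``(x, y)``.

    ``loggers`` needs columns ``logger_id, x, y`` (one row per logger).
    Exact distance ties go to the lexicographically smaller logger_id.
    """
    if loggers.empty:
        raise ValueError("no ambient loggers available")
    d2 = (loggers["x"].to_numpy() - x) ** 2 + (loggers["y"].to_numpy() - y) ** 2
    best = d2.min()
    candidates = loggers["logger_id"].to_numpy()[d2 == best]
    return str(min(candidates))


def pair_all_nests(nests: pd.DataFrame, loggers: pd.DataFrame) -> pd.Series:
    """Vectorised nearest-logger pairing; index follows ``nests``."""
    if loggers.empty:
        raise ValueError("no ambient loggers available")
    lg = loggers.sort_values("logger_id").reset_index(drop=True)
    dx = nests["x"].to_numpy()[:, None] - lg["x"].to_numpy()[None, :]
    dy = nests["y"].to_numpy()[:, None] - lg["y"].to_numpy()[None, :]
    # argmin returns the first (lexicographically smallest id) on ties
    idx = np.argmin(dx**2 + dy**2, axis=1)
    return pd.Series(lg["logger_id"].to_numpy()[idx], index=nests.index)


def logger_positions(ambient: pd.DataFrame) -> pd.DataFrame:
    """One row per logger with its coordinates."""
    return (
        ambient.groupby("logger_id", as_index=False)[["x", "y"]].first()
    )


# ---------------------------------------------------------------------------
# Hourly alignment
# ---------------------------------------------------------------------------

def hourly_ambient(ambient: pd.DataFrame) -> pd.DataFrame:
    """Clock-hour bucket means of ambient readings per logger.

    Columns of the result: logger_id, day, hour, ambient_temp.
    """
    df = ambient.copy()
    df["hour"] = df["minute"] // 60
    out = (
        df.groupby(["logger_id", "day", "hour"], as_index=False)["temp"]
        .mean()
        .rename(columns={"temp": "ambient_temp"})
    )
    return out


def _fill_nearest(values: np.ndarray, limit: int) -> np.ndarray:
    """Fill NaN entries from the nearest non-NaN neighbour within ``limit``
    index positions (earlier neighbour wins ties)."""
    s = pd.Series(values)
    fwd = s.ffill(limit=limit)
    bwd = s.bfill(limit=limit)
    pos = np.arange(len(s))
    valid = s.notna()
    idx_prev = pd.Series(np.where(valid, pos, np.nan)).ffill().to_numpy()
    idx_next = pd.Series(np.where(valid, pos, np.nan)).bfill().to_numpy()
    dist_prev = np.where(np.isnan(idx_prev), np.inf, pos - idx_prev)
    dist_next = np.where(np.isnan(idx_next), np.inf, idx_next - pos)
    out = np.where(dist_prev <= dist_next, fwd.to_numpy(), bwd.to_numpy())
    return out


def align_hourly(
    trace: pd.DataFrame,
    ambient: pd.DataFrame,
    logger_id: str | None = None,
    max_gap_hours: int = 2,
) -> pd.DataFrame:
    """Pair each 20-min in-nest reading with same-clock-hour mean ambient.

    ``trace`` is one nest's readings (columns day, minute, temp, and
    optionally nest_id/x/y); ``ambient`` is either the full ambient table
    (then ``logger_id`` selects the paired logger) or a single logger's
    readings.  Hours with no ambient reading are filled from the nearest
    hour within ``max_gap_hours``; beyond that the row is flagged missing
    (``ambient_temp`` NaN).

    Returns the trace with ``hour``, ``ambient_temp`` and
    ``delta = temp - ambient_temp`` columns appended.
    """
    if logger_id is not None:
        ambient = ambient[ambient["logger_id"] == str(logger_id)]
    if ambient.empty:
        raise CoverageError("no ambient readings for the paired logger")
    ha = hourly_ambient(ambient.assign(logger_id="_"))
    ha["t"] = ha["day"] * 24 + ha["hour"]
    t0 = int(trace["day"].min() * 24 + trace["minute"].min() // 60)
    t1 = int(trace["day"].max() * 24 + trace["minute"].max() // 60)
    if t0 < ha["t"].min() or t1 > ha["t"].max():
        raise CoverageError(
            "ambient series does not cover the span of the nest trace"
        )
    full = np.arange(ha["t"].min(), ha["t"].max() + 1)
    series = pd.Series(np.nan, index=full)
    series.loc[ha["t"].to_numpy()] = ha["ambient_temp"].to_numpy()
    filled = _fill_nearest(series.to_numpy(), max_gap_hours)
    lookup = pd.Series(filled, index=full)

    out = trace.copy()
    out["hour"] = out["minute"] // 60
    out["ambient_temp"] = lookup.reindex(
        out["day"].to_numpy() * 24 + out["hour"].to_numpy()
    ).to_numpy()
    out["delta"] = out["temp"] - out["ambient_temp"]
    return out


def align_all(
    traces: pd.DataFrame,
    ambient: pd.DataFrame,
    pairing: pd.Series | dict,
    max_gap_hours: int = 2,
) -> pd.DataFrame:
    """Vectorised hourly alignment for many nests at once.

    ``pairing`` maps nest_id -> logger_id.  Assumes the ambient grid has no
    gaps (the common case for generated data); per-nest coverage is still
    checked.  Returns the paired long table for all nests.
    """
    ha = hourly_ambient(ambient)
    pairing = pd.Series(pairing)
    out = traces.copy()
    out["hour"] = out["minute"] // 60
    out["logger_id"] = out["nest_id"].map(pairing)
    if out["logger_id"].isna().any():
        bad = sorted(out.loc[out["logger_id"].isna(), "nest_id"].unique())
        raise ValueError(f"no paired logger for nest(s) {bad}")
    merged = out.merge(ha, on=["logger_id", "day", "hour"], how="left")
    if merged["ambient_temp"].isna().any():
        # fall back to the per-nest gap-filling path
        parts = []
        for nid, grp in out.groupby("nest_id", sort=False):
            parts.append(
                align_hourly(
                    grp.drop(columns=["logger_id", "hour"]),
                    ambient,
                    logger_id=pairing[nid],
                    max_gap_hours=max_gap_hours,
                ).assign(nest_id=nid)
            )
        merged = pd.concat(parts, ignore_index=True)
    merged["delta"] = merged["temp"] - merged["ambient_temp"]
    return merged
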
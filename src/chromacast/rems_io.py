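"""Ingestion of greenhouse sensor logs onto a uniform per-minute grid.

Sensor loggers emit per-parameter CSV files (``timestamp,value``) at an
arbitrary, possibly irregular cadence.  Everything downstream consumes a
canonical representation: one value per minute with an explicit missing
mask.  This module reads the raw logs, resolves duplicates, bins readings
onto the minute grid, and reports gaps.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Parameter",
    "CHANNEL_ORDER",
    "SensorSeries",
    "read_sensor_log",
    "read_manifest",
    "resample_to_minutes",
    "detect_gaps",
    "write_store",
    "read_store",
]


class Parameter(str, enum.Enum):
    """Environmental parameter measured by one sensor channel."""

    TEMPERATURE = "temperature"      # °C
    HUMIDITY = "humidity"            # %RH
    LIGHT = "light"                  # lux
    SOIL_MOISTURE = "soil_moisture"  # unitless index
    SOIL_PH = "soil_ph"              # pH units


#: Fixed channel order used whenever the five parameters are stacked.
CHANNEL_ORDER: tuple[Parameter, ...] = (
    Parameter.TEMPERATURE,
    Parameter.HUMIDITY,
    Parameter.LIGHT,
    Parameter.SOIL_MOISTURE,
    Parameter.SOIL_PH,
)


@dataclass
class SensorSeries:
    """One environmental parameter's timestamped values.

    ``timestamps`` are minutes since the series start.  Before
    regularization they may be fractional and irregular; after
    :func:`resample_to_minutes` they are the integers ``0..N-1``.
    ``missing_mask`` is ``True`` exactly where no value is available.
    """

    parameter: Parameter
    timestamps: np.ndarray
    values: np.ndarray
    missing_mask: np.ndarray
    start_time: datetime | None = None
    regular: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.timestamps.ndim != 1:
            raise ValueError("timestamps must be one-dimensional")
        if not (len(self.timestamps) == len(self.values) == len(self.missing_mask)):
            raise ValueError("timestamps, values and missing_mask must align")
        if self.n_points < 2:
            raise ValueError("a sensor series needs at least 2 points")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(~np.isnan(self.values) & self.missing_mask):
            # normalize: masked cells carry NaN so they can never leak
            self.values = self.values.copy()
            self.values[self.missing_mask] = np.nan

    @property
    def n_points(self) -> int:
        return len(self.timestamps)

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    def observed_values(self) -> np.ndarray:
        return self.values[~self.missing_mask]


def _parse_timestamp(token: str) -> float:
    """Parse an ISO-8601 or epoch-seconds timestamp to epoch seconds."""
    try:
        return float(token)
    except ValueError:
        pass
    ts = pd.Timestamp(token)
    if ts.tzinfo is None:
        ts = ts.tz_localize("UTC")
    return ts.timestamp()


def read_sensor_log(path: str | Path, parameter: Parameter | str) -> SensorSeries:
    """Read a raw ``timestamp,value`` CSV into an (irregular) SensorSeries.

    Rows are sorted by time and duplicate timestamps are resolved by
    keeping the last record.  No regularization is performed here.
    """
    parameter = Parameter(parameter)
    path = Path(path)
    rows: list[tuple[float, float]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or (lineno == 1 and row[0].strip().lower() == "timestamp"):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 'timestamp,value'")
            try:
                t = _parse_timestamp(row[0].strip())
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}: line {lineno}: bad timestamp {row[0]!r}") from exc
            val_token = row[1].strip()
            if val_token == "" or val_token.lower() == "nan":
                val, missing = math.nan, True
            else:
                try:
                    val, missing = float(val_token), False
                except ValueError as exc:
                    raise ValueError(f"{path}: line {lineno}: bad value {row[1]!r}") from exc
            rows.append((t, val if not missing else math.nan))
    if not rows:
        raise ValueError(f"{path}: empty sensor log")
    if len(rows) < 2:
        raise ValueError(f"{path}: a sensor log needs at least 2 readings")
    # stable sort, then keep the LAST record for duplicated timestamps
    order = np.argsort([r[0] for r in rows], kind="stable")
    t_sorted = np.array([rows[i][0] for i in order])
    v_sorted = np.array([rows[i][1] for i in order])
    keep = np.ones(len(t_sorted), dtype=bool)
    keep[:-1] = np.diff(t_sorted) > 0
    t_sorted, v_sorted = t_sorted[keep], v_sorted[keep]
    start = datetime.fromtimestamp(t_sorted[0], tz=timezone.utc)
    minutes = (t_sorted - t_sorted[0]) / 60.0
    return SensorSeries(
        parameter=parameter,
        timestamps=minutes,
        values=v_sorted,
        missing_mask=np.isnan(v_sorted),
        start_time=start,
        regular=False,
        provenance={"path": str(path)},
    )


def read_manifest(path: str | Path) -> dict[Parameter, SensorSeries]:
    """Read a YAML manifest mapping parameter name -> CSV path."""
    path = Path(path)
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, dict):
        raise ValueError(f"{path}: manifest must map parameter -> file")
    out = {}
    for key, rel in mapping.items():
        param = Parameter(key)
        csv_path = Path(rel)
        if not csv_path.is_absolute():
            csv_path = path.parent / csv_path
        out[param] = read_sensor_log(csv_path, param)
    return out


def resample_to_minutes(s: SensorSeries) -> SensorSeries:
    """Regularize a series onto the uniform 1-minute grid.

    Each grid cell takes the arithmetic mean of the raw readings falling
    inside it; cells without readings are marked missing.  Already-regular
    per-minute input is returned unchanged (bit-exact values).  Spans
    shorter than 2 minutes are padded so the output always has >= 2 cells.
    """
    if s.regular:
        return s
    t = s.timestamps - s.timestamps[0]
    if np.allclose(t, np.round(t)) and np.all(np.diff(np.round(t)) == 1):
        # already on the minute grid: identity, values preserved bit-exactly
        return replace(s, timestamps=np.round(t), regular=True)
    n_cells = max(2, int(math.floor(t[-1] + 1e-9)) + 1)
    idx = np.minimum(t.astype(int), n_cells - 1)
    obs = ~s.missing_mask
    counts = np.bincount(idx[obs], minlength=n_cells)
    sums = np.bincount(idx[obs], weights=s.values[obs], minlength=n_cells)
    values = np.full(n_cells, np.nan)
    filled = counts > 0
    values[filled] = sums[filled] / counts[filled]
    return SensorSeries(
        parameter=s.parameter,
        timestamps=np.arange(n_cells, dtype=float),
        values=values,
        missing_mask=~filled,
        start_time=s.start_time,
        regular=True,
        provenance=dict(s.provenance),
    )


def detect_gaps(s: SensorSeries) -> list[tuple[int, int]]:
    """Return maximal runs of missing cells as half-open minute intervals."""
    if not s.regular:
        raise ValueError("detect_gaps requires a regularized series")
    m = s.missing_mask
    if not m.any():
        return []
    padded = np.concatenate([[False], m, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2]
    return list(zip(starts.tolist(), ends.tolist()))


def write_store(series: dict[Parameter, SensorSeries], path: str | Path) -> None:
    """Write regularized channels to a CSV store; missing cells are empty fields."""
    series = {Parameter(k): v for k, v in series.items()}
    n = max(s.n_points for s in series.values())
    frame = pd.DataFrame({"minute": np.arange(n)})
    for param, s in series.items():
        if not s.regular:
            raise ValueError(f"{param.value}: store requires regularized series")
        col = np.full(n, np.nan)
        col[: s.n_points] = s.values
        frame[param.value] = col
    frame.to_csv(path, index=False, na_rep="")


def read_store(path: str | Path) -> dict[Parameter, SensorSeries]:
    """Read a CSV store written by :func:`write_store`."""
    frame = pd.read_csv(path)
    out = {}
    for col in frame.columns:
        if col == "minute":
            continue
        param = Parameter(col)
        values = frame[col].to_numpy(dtype=float)
        out[param] = SensorSeries(
            parameter=param,
            timestamps=frame["minute"].to_numpy(dtype=float),
            values=values,
            missing_mask=np.isnan(values),
            regular=True,
        )
    return out
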
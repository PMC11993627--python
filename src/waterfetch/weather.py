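"""Gridded daily weather and household exposure linkage.

A :class:`WeatherGrid` holds daily precipitation (cm/day) and daily maximum
temperature (degC) on a regular lon/lat lattice with edge-aligned cell
registration: cell ``(row, col)`` spans
``[lon0 + col*s, lon0 + (col+1)*s) x [lat0 + row*s, lat0 + (row+1)*s)``
with ``s = cell_size`` in degrees.

Exposure variables are built per household and lag window (7/30/90/180/365
days preceding the survey date): precipitation is summed over the window and
divided by the window length in weeks (``window_days / 7``) to give cm/week;
temperature is the arithmetic mean of daily maxima over the same window. By
default the window ends the day *before* the survey date, so exposure
strictly precedes the outcome; ``include_survey_day=True`` shifts the window
to end on the survey date instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

#: Lag windows (days) used throughout the analysis.
WINDOWS: tuple[int, ...] = (7, 30, 90, 180, 365)

#: Exposure column names produced by :func:`link_all`.
EXPOSURE_COLUMNS: tuple[str, str] = ("precip_cm_per_week", "tmax_mean_c")


@dataclass
class WeatherGrid:
    """Daily precipitation and maximum temperature on a regular lattice.

    Parameters
    ----------
    lon0, lat0 : float
        Coordinates of the grid origin (south-west cell *edge*), degrees.
    cell_size : float
        Cell edge length in degrees (0.5 for the analysis lattice).
    dates : pandas.DatetimeIndex
        Strictly consecutive daily calendar index.
    precip : ndarray, shape (n_dates, n_lat, n_lon)
        Daily precipitation, cm/day, non-negative.
    tmax : ndarray, shape (n_dates, n_lat, n_lon)
        Daily maximum temperature, degC.
    """

    lon0: float
    lat0: float
    cell_size: float
    dates: pd.DatetimeIndex
    precip: np.ndarray
    tmax: np.ndarray
    _cum_precip: np.ndarray = field(init=False, repr=False, default=None)
    _cum_tmax: np.ndarray = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        self.precip = np.asarray(self.precip, dtype=float)
        self.tmax = np.asarray(self.tmax, dtype=float)
        self.dates = pd.DatetimeIndex(self.dates)
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.precip.ndim != 3 or self.precip.shape != self.tmax.shape:
            raise ValueError("precip and tmax must be 3-D arrays of equal shape")
        if len(self.dates) != self.precip.shape[0]:
            raise ValueError("date index length does not match array time axis")
        if self.n_lat == 0 or self.n_lon == 0:
            raise ValueError("grid has zero cells")
        if len(self.dates) > 1:
            steps = np.diff(self.dates.values).astype("timedelta64[D]")
            if not (steps == np.timedelta64(1, "D")).all():
                raise ValueError("dates must be strictly consecutive daily")
        if np.nanmin(self.precip) < 0:
            raise ValueError("precipitation must be non-negative")

    # -- geometry -----------------------------------------------------------
    @property
    def n_lat(self) -> int:
        return self.precip.shape[1]

    @property
    def n_lon(self) -> int:
        return self.precip.shape[2]

    @property
    def lon_max(self) -> float:
        return self.lon0 + self.n_lon * self.cell_size

    @property
    def lat_max(self) -> float:
        return self.lat0 + self.n_lat * self.cell_size

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Return (lon, lat) of the center of cell ``(row, col)``."""
        return (
            self.lon0 + (col + 0.5) * self.cell_size,
            self.lat0 + (row + 0.5) * self.cell_size,
        )

    # -- window sums (cached cumulative arrays) -----------------------------
    def _cumsums(self) -> tuple[np.ndarray, np.ndarray]:
        if self._cum_precip is None:
            zero = np.zeros((1,) + self.precip.shape[1:])
            self._cum_precip = np.concatenate(
                [zero, np.cumsum(self.precip, axis=0)], axis=0
            )
            self._cum_tmax = np.concatenate(
                [zero, np.cumsum(self.tmax, axis=0)], axis=0
            )
        return self._cum_precip, self._cum_tmax

    # -- I/O ----------------------------------------------------------------
    def to_xarray(self) -> xr.Dataset:
        lat = self.lat0 + (np.arange(self.n_lat) + 0.5) * self.cell_size
        lon = self.lon0 + (np.arange(self.n_lon) + 0.5) * self.cell_size
        ds = xr.Dataset(
            {
                "precip_cm": (("time", "lat", "lon"), self.precip),
                "tmax_c": (("time", "lat", "lon"), self.tmax),
            },
            coords={"time": self.dates, "lat": lat, "lon": lon},
            attrs={
                "lon0": self.lon0,
                "lat0": self.lat0,
                "cell_size": self.cell_size,
            },
        )
        return ds

    @classmethod
    def from_xarray(cls, ds: xr.Dataset) -> "WeatherGrid":
        return cls(
            lon0=float(ds.attrs["lon0"]),
            lat0=float(ds.attrs["lat0"]),
            cell_size=float(ds.attrs["cell_size"]),
            dates=pd.DatetimeIndex(ds["time"].values),
            precip=ds["precip_cm"].values,
            tmax=ds["tmax_c"].values,
        )

    def to_netcdf(self, path) -> None:
        self.to_xarray().to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "WeatherGrid":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_xarray(ds.load())


def locate_cell(lon: float, lat: float, grid: WeatherGrid) -> tuple[int, int]:
    """Map a point to its (row, col) grid cell.

    Half-open edge convention: ``col = floor((lon - lon0)/cell_size)``; a point
    exactly on a shared edge belongs to the higher-index cell. Points outside
    the grid extent raise ``ValueError`` carrying the offending coordinates.
    """
    col = int(np.floor((lon - grid.lon0) / grid.cell_size))
    row = int(np.floor((lat - grid.lat0) / grid.cell_size))
    if not (0 <= col < grid.n_lon and 0 <= row < grid.n_lat):
        raise ValueError(
            f"point (lon={lon}, lat={lat}) is outside the grid extent "
            f"[{grid.lon0}, {grid.lon_max}) x [{grid.lat0}, {grid.lat_max})"
        )
    return row, col


def aggregate_to_coarser(fine: np.ndarray, factor: int = 2) -> np.ndarray:
    """Block-average a (time, lat, lon) array by ``factor`` in both spatial axes.

    Used in real mode to area-average 0.25-degree precipitation onto the
    0.5-degree temperature lattice so one cell indexing serves both variables.
    """
    t, nlat, nlon = fine.shape
    if nlat % factor or nlon % factor:
        raise ValueError("spatial dimensions not divisible by the aggregation factor")
    return fine.reshape(t, nlat // factor, factor, nlon // factor, factor).mean(
        axis=(2, 4)
    )


def _window_slice(
    grid: WeatherGrid, survey_date, window_days: int, include_survey_day: bool
) -> tuple[int, int]:
    """Return (start, stop) time indices (stop exclusive) of the lag window."""
    d = (pd.Timestamp(survey_date) - grid.dates[0]).days
    stop = d + 1 if include_survey_day else d  # exclusive
    start = stop - window_days
    if start < 0:
        raise ValueError(
            f"{window_days}-day window before {pd.Timestamp(survey_date).date()} "
            f"extends before the grid start {grid.dates[0].date()}"
        )
    if stop > len(grid.dates):
        raise ValueError(
            f"{window_days}-day window before {pd.Timestamp(survey_date).date()} "
            f"extends past the grid end {grid.dates[-1].date()}"
        )
    return start, stop


def lagged_precip(
    grid: WeatherGrid,
    cell: tuple[int, int],
    survey_date,
    window_days: int,
    include_survey_day: bool = False,
) -> float:
    """Window precipitation total converted to cm/week.

    Sums daily precipitation over the ``window_days`` days ending the day
    before ``survey_date`` and divides by ``window_days / 7`` weeks.
    """
    start, stop = _window_slice(grid, survey_date, window_days, include_survey_day)
    row, col = cell
    total = float(grid.precip[start:stop, row, col].sum())
    return total / (window_days / 7.0)


def lagged_tmax(
    grid: WeatherGrid,
    cell: tuple[int, int],
    survey_date,
    window_days: int,
    include_survey_day: bool = False,
) -> float:
    """Mean daily maximum temperature (degC) over the same lag window."""
    start, stop = _window_slice(grid, survey_date, window_days, include_survey_day)
    row, col = cell
    return float(grid.tmax[start:stop, row, col].mean())


def link_all(
    records: pd.DataFrame,
    grid: WeatherGrid,
    windows=WINDOWS,
    include_survey_day: bool = False,
) -> pd.DataFrame:
    """Build the lagged-exposure table: one row per record x window.

    All households of a cluster share coordinates and survey date, so
    exposures are computed once per cluster and broadcast. The cell indices
    are recorded on each row for the spatial-first-differences stage.

    Returns a DataFrame with columns ``cluster_id, household_id, window_days,
    precip_cm_per_week, tmax_mean_c, cell_row, cell_col``.
    """
    windows = tuple(int(w) for w in windows)
    if len(records) == 0:
        return pd.DataFrame(
            columns=[
                "cluster_id",
                "household_id",
                "window_days",
                *EXPOSURE_COLUMNS,
                "cell_row",
                "cell_col",
            ]
        )
    cum_p, cum_t = grid._cumsums()
    clusters = records.drop_duplicates("cluster_id")[
        ["cluster_id", "lon", "lat", "survey_date"]
    ]
    per_cluster = {}
    for rec in clusters.itertuples(index=False):
        try:
            row, col = locate_cell(rec.lon, rec.lat, grid)
            vals = {}
            for w in windows:
                start, stop = _window_slice(
                    grid, rec.survey_date, w, include_survey_day
                )
                psum = cum_p[stop, row, col] - cum_p[start, row, col]
                tsum = cum_t[stop, row, col] - cum_t[start, row, col]
                vals[w] = (psum / (w / 7.0), tsum / w)
        except ValueError as err:
            raise ValueError(f"cluster {rec.cluster_id}: {err}") from err
        per_cluster[rec.cluster_id] = (row, col, vals)

    out = {
        "cluster_id": [],
        "household_id": [],
        "window_days": [],
        "precip_cm_per_week": [],
        "tmax_mean_c": [],
        "cell_row": [],
        "cell_col": [],
    }
    for rec in records.itertuples(index=False):
        row, col, vals = per_cluster[rec.cluster_id]
        for w in windows:
            p, t = vals[w]
            out["cluster_id"].append(rec.cluster_id)
            out["household_id"].append(rec.household_id)
            out["window_days"].append(w)
            out["precip_cm_per_week"].append(p)
            out["tmax_mean_c"].append(t)
            out["cell_row"].append(row)
            out["cell_col"].append(col)
    return pd.DataFrame(out)
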
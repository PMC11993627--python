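"""Synthetic weather, household surveys, walk times and source choices.

The generator emulates the statistical structure the spatial-first-differences
(SFD) analysis assumes, with known ground truth so every downstream stage is
testable without any downloads:

* daily weather fields on a 0.5-degree lattice, built as a time-constant
  spatially smooth climatology (Gaussian-kernel-smoothed white noise) plus a
  seasonal sinusoid plus smooth daily noise; precipitation is rectified at 0;
* clustered household locations (one GPS coordinate per cluster, as household
  surveys publish) with survey dates uniform in a collection window;
* one-way walk times from a linear model in the lagged weather exposures plus
  a spatially smooth unobserved confounder plus Gaussian noise;
* weather-dependent source-type choice through a multinomial logit.

The confounder surface is smooth at scales well above the cell size and is
statistically independent of the weather fields; an optional violation mode
mixes the weather climatology into the confounder to demonstrate when SFD
fails. Everything is bit-reproducible from ``SimulationConfig.seed``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .weather import WINDOWS, WeatherGrid, link_all

SOURCE_TYPES_DEFAULT = ("piped", "borehole", "surface", "unprotected_well")

COLLECTOR_PROBS_DEFAULT = {
    # Shares among reporting households mirror the published breakdown
    # (woman 67%, girl 10%, man 14%, boy 4%, other 5%); the collector is
    # reported for ~15% of observations.
    "woman": 0.67 * 0.15,
    "girl": 0.10 * 0.15,
    "man": 0.14 * 0.15,
    "boy": 0.04 * 0.15,
    "other": 0.05 * 0.15,
    "missing": 0.85,
}

CLIMATE_ZONE_PROBS_DEFAULT = {"arid": 0.3, "temperate": 0.3, "tropical": 0.4}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic pipeline.

    Spatial extent defaults to a 5 x 5 degree region gridded at 0.5 degrees
    (10 x 10 cells); weather spans 380 days so the 365-day lag window is
    defined for surveys in the final fortnight. Effect sizes default to the
    365-day-window values the SFD analysis targets: -3.5 min per (cm/week)
    of precipitation and +0.76 min per degC of mean daily maximum
    temperature.
    """

    # extent and lattice
    lon_min: float = 30.0
    lon_max: float = 35.0
    lat_min: float = -5.0
    lat_max: float = 0.0
    cell_size: float = 0.5
    # weather calendar
    date_start: str = "2015-01-01"
    date_end: str = "2016-01-15"
    # survey design
    n_clusters: int = 100
    households_per_cluster: int = 25
    survey_start: str = "2016-01-01"
    survey_end: str = "2016-01-15"
    n_countries: int = 1
    max_lag_days: int = 365
    # true outcome model
    alpha: float = 30.0
    beta_precip: float = -3.5
    beta_temp: float = 0.76
    effect_window_days: int = 365
    confounder_amplitude: float = 10.0
    confounder_length_scale: float = 1.5
    confounder_trend_share: float = 0.8  # variance share in a regional gradient
    confounder_weather_mix: float = 0.0  # violation mode: >0 correlates C with tmax
    noise_sd: float = 12.0
    # weather field: climatologies carry a random-direction regional gradient
    # (trend) plus short-scale smooth structure, like real climate surfaces
    weather_length_scale: float = 0.5
    weather_trend_share: float = 0.5
    tmax_mean: float = 31.0
    tmax_spatial_sd: float = 2.0
    tmax_seasonal_amplitude: float = 2.5
    tmax_daily_sd: float = 1.5
    precip_mean: float = 0.30
    precip_spatial_sd: float = 0.15
    precip_seasonal_amplitude: float = 0.15
    precip_daily_sd: float = 0.25
    seasonal_phase_doy: float = 15.0
    # household covariates
    p_urban: float = 0.3
    p_electricity_urban: float = 0.7
    p_electricity_rural: float = 0.25
    climate_zone_probs: dict = field(
        default_factory=lambda: dict(CLIMATE_ZONE_PROBS_DEFAULT)
    )
    collector_probs: dict = field(
        default_factory=lambda: dict(COLLECTOR_PROBS_DEFAULT)
    )
    wealth_sd: float = 1.0
    # DHS-style GPS jitter (used only by the border-buffer sensitivity study)
    jitter: bool = False
    jitter_rural_km: float = 5.0
    jitter_urban_km: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.lon_max <= self.lon_min or self.lat_max <= self.lat_min:
            raise ValueError("degenerate spatial extent")
        for name in ("weather_length_scale", "confounder_length_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        n_days = (pd.Timestamp(self.date_end) - pd.Timestamp(self.date_start)).days + 1
        span_needed = self.effect_window_days + (
            (pd.Timestamp(self.survey_end) - pd.Timestamp(self.survey_start)).days + 1
        )
        if n_days < span_needed:
            raise ValueError(
                "weather date range must cover effect_window_days plus the survey window"
            )

    @property
    def n_lon(self) -> int:
        return int(round((self.lon_max - self.lon_min) / self.cell_size))

    @property
    def n_lat(self) -> int:
        return int(round((self.lat_max - self.lat_min) / self.cell_size))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh)


# ---------------------------------------------------------------------------
# smooth random fields
# ---------------------------------------------------------------------------

def _smooth_unit_field(rng: np.random.Generator, shape, sigma_cells: float) -> np.ndarray:
    """Gaussian-kernel-smoothed white noise rescaled to unit pointwise variance.

    Smoothing uses periodic (wrap) boundaries so the field is stationary and
    the variance shrinkage of the kernel is exact: for a separable kernel with
    1-D weights w, smoothed white noise has variance (sum w^2) per axis.
    An infinite length scale returns the zero field (the limit of smoothing).
    """
    if not np.isfinite(sigma_cells):
        return np.zeros(shape)
    if sigma_cells <= 0:
        return rng.standard_normal(shape)
    # Pad the spatial dims well beyond the kernel support before smoothing on
    # a torus, then crop. Without padding a length scale comparable to the
    # domain would collapse the field to a near-constant (the kernel wraps
    # into itself), destroying the large-scale variation the field is meant
    # to carry.
    pad = int(np.ceil(6.0 * sigma_cells))
    spatial_axes = (len(shape) - 2, len(shape) - 1)
    padded = tuple(
        n + pad if ax in spatial_axes else n for ax, n in enumerate(shape)
    )
    white = rng.standard_normal(padded)
    sigma = tuple(sigma_cells if ax in spatial_axes else 0.0 for ax in range(len(shape)))
    smooth = ndimage.gaussian_filter(white, sigma=sigma, mode="wrap")
    scale = 1.0
    for ax in spatial_axes:
        imp = np.zeros(padded[ax])
        imp[padded[ax] // 2] = 1.0
        w = ndimage.gaussian_filter1d(imp, sigma_cells, mode="wrap")
        scale *= float(np.sum(w**2))
    crop = tuple(slice(0, n) for n in shape)
    return smooth[crop] / np.sqrt(scale)


def _seasonal(dates: pd.DatetimeIndex, amplitude: float, phase_doy: float) -> np.ndarray:
    doy = dates.dayofyear.to_numpy(dtype=float)
    return amplitude * np.sin(2.0 * np.pi * (doy - phase_doy) / 365.25)


def _structured_field(
    rng: np.random.Generator,
    config: "SimulationConfig",
    res: float,
    sd: float,
    trend_share: float,
    length_scale: float,
):
    """Spatial surface = random-direction linear gradient + smooth field.

    Both components are standardized so the surface has pointwise standard
    deviation ``sd`` with respect to a uniformly random location in the
    extent; ``trend_share`` is the variance share of the gradient. Returns
    ``(lattice, func)``: the surface sampled at lattice cell centers of
    resolution ``res``, and a continuous evaluator ``func(lon, lat)``
    (bilinear in the smooth part, exact in the trend).

    A linear gradient is the roughest-case large-scale confounder for naive
    pooled regression yet is exactly absorbed by the intercept of the
    differenced SFD regression: its adjacent-cell difference is constant.
    """
    n_lat = int(round((config.lat_max - config.lat_min) / res))
    n_lon = int(round((config.lon_max - config.lon_min) / res))
    smooth = _smooth_unit_field(rng, (n_lat, n_lon), length_scale / res)
    theta = rng.uniform(0.0, 2.0 * np.pi)
    cx = 0.5 * (config.lon_min + config.lon_max)
    cy = 0.5 * (config.lat_min + config.lat_max)
    lx = config.lon_max - config.lon_min
    ly = config.lat_max - config.lat_min
    norm = np.sqrt((np.cos(theta) ** 2 * lx**2 + np.sin(theta) ** 2 * ly**2) / 12.0)
    a_trend = sd * np.sqrt(trend_share)
    a_smooth = sd * np.sqrt(1.0 - trend_share)
    lat_c = config.lat_min + (np.arange(n_lat) + 0.5) * res
    lon_c = config.lon_min + (np.arange(n_lon) + 0.5) * res
    u_grid = (
        (lon_c[None, :] - cx) * np.cos(theta) + (lat_c[:, None] - cy) * np.sin(theta)
    ) / norm
    lattice = a_trend * u_grid + a_smooth * smooth

    interp = RegularGridInterpolator(
        (lat_c, lon_c), smooth, method="linear", bounds_error=False, fill_value=None
    )

    def func(lon, lat):
        lon = np.asarray(lon, float)
        lat = np.asarray(lat, float)
        u = ((lon - cx) * np.cos(theta) + (lat - cy) * np.sin(theta)) / norm
        pts = np.column_stack([np.ravel(lat), np.ravel(lon)])
        return a_trend * u + a_smooth * interp(pts).reshape(np.shape(lon))

    return lattice, func


def _tmax_climatology(config: "SimulationConfig"):
    """The time-constant tmax surface (lattice and evaluator), from its own
    fixed seed stream so it can be reconstructed independently."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(8)[0])
    return _structured_field(
        rng,
        config,
        res=config.cell_size,
        sd=config.tmax_spatial_sd,
        trend_share=config.weather_trend_share,
        length_scale=config.weather_length_scale,
    )


def simulate_weather(config: SimulationConfig) -> WeatherGrid:
    """Generate daily precipitation (cm/day) and tmax (degC) fields.

    Each variable is a time-constant smooth climatology plus a seasonal
    sinusoid plus smooth independent daily noise; precipitation is rectified
    at zero. Identical seeds give bit-identical output.
    """
    n_lat, n_lon = config.n_lat, config.n_lon
    if n_lat == 0 or n_lon == 0:
        raise ValueError("degenerate extent: zero grid cells")
    dates = pd.date_range(config.date_start, config.date_end, freq="D")
    sigma = config.weather_length_scale / config.cell_size

    children = np.random.SeedSequence(config.seed).spawn(8)
    _, rng_td, rng_pb, rng_pd = (np.random.default_rng(c) for c in children[:4])

    shape_t = (len(dates), n_lat, n_lon)
    tmax_base, _ = _tmax_climatology(config)
    tmax = (
        config.tmax_mean
        + tmax_base[None, :, :]
        + _seasonal(dates, config.tmax_seasonal_amplitude, config.seasonal_phase_doy)[
            :, None, None
        ]
        + config.tmax_daily_sd * _smooth_unit_field(rng_td, shape_t, sigma)
    )
    precip_base, _ = _structured_field(
        rng_pb,
        config,
        res=config.cell_size,
        sd=config.precip_spatial_sd,
        trend_share=config.weather_trend_share,
        length_scale=config.weather_length_scale,
    )
    precip = (
        config.precip_mean
        + precip_base[None, :, :]
        + _seasonal(
            dates, config.precip_seasonal_amplitude, config.seasonal_phase_doy + 182.6
        )[:, None, None]
        + config.precip_daily_sd * _smooth_unit_field(rng_pd, shape_t, sigma)
    )
    np.maximum(precip, 0.0, out=precip)
    return WeatherGrid(
        lon0=config.lon_min,
        lat0=config.lat_min,
        cell_size=config.cell_size,
        dates=dates,
        precip=precip,
        tmax=tmax,
    )


# ---------------------------------------------------------------------------
# true outcome model
# ---------------------------------------------------------------------------

class TrueModel(NamedTuple):
    """Ground-truth walk-time model: WT = alpha + bP*P + bT*T + C(lon,lat) + eps."""

    alpha: float
    beta_precip: float
    beta_temp: float
    noise_sd: float
    effect_window_days: int
    confounder: Callable[[np.ndarray, np.ndarray], np.ndarray]

    def confounder_at(self, lon, lat) -> np.ndarray:
        return self.confounder(np.asarray(lon, float), np.asarray(lat, float))


def _build_confounder(config: SimulationConfig, seed_seq) -> Callable:
    """Smooth confounder surface C(lon, lat) in minutes.

    A regional gradient plus a smooth field on a fine lattice (cell_size/4),
    from an RNG stream separate from (and independent of) the weather, with
    pointwise standard deviation ``confounder_amplitude``. In violation mode
    (``confounder_weather_mix`` > 0) the standardized tmax climatology is
    mixed in, correlating C with weather and breaking SFD identification.
    """
    rng = np.random.default_rng(seed_seq)
    _, own = _structured_field(
        rng,
        config,
        res=config.cell_size / 4.0,
        sd=config.confounder_amplitude,
        trend_share=config.confounder_trend_share,
        length_scale=config.confounder_length_scale,
    )
    if not config.confounder_weather_mix:
        return own
    m = float(config.confounder_weather_mix)
    _, tmax_f = _tmax_climatology(config)
    sd_t = max(config.tmax_spatial_sd, 1e-12)
    amp = config.confounder_amplitude

    def confounder(lon, lat):
        return np.sqrt(1 - m**2) * own(lon, lat) + m * amp * tmax_f(lon, lat) / sd_t

    return confounder


def true_model(config: SimulationConfig) -> TrueModel:
    """Instantiate the ground-truth model (confounder surface included)."""
    seed_conf = np.random.SeedSequence(config.seed).spawn(8)[5]
    return TrueModel(
        alpha=config.alpha,
        beta_precip=config.beta_precip,
        beta_temp=config.beta_temp,
        noise_sd=config.noise_sd,
        effect_window_days=config.effect_window_days,
        confounder=_build_confounder(config, seed_conf),
    )


# ---------------------------------------------------------------------------
# households
# ---------------------------------------------------------------------------

HOUSEHOLD_COLUMNS = [
    "cluster_id",
    "household_id",
    "country_survey_id",
    "country",
    "county",
    "lon",
    "lat",
    "survey_date",
    "walk_time_min",
    "source_type",
    "urban",
    "electricity_hh",
    "electricity_community",
    "wealth",
    "climate_zone",
    "collector",
]

_KM_PER_DEG_LAT = 111.195  # pi * 6371.0088 / 180


def simulate_households(config: SimulationConfig, grid: WeatherGrid) -> pd.DataFrame:
    """Place clusters uniformly in the extent and draw household covariates.

    All households of a cluster share coordinates and survey date. Countries
    are vertical bands of the extent; counties are 2x2-cell blocks within a
    country. Walk time and source type are left unset (NaN) for the dedicated
    assignment operations.
    """
    if not (
        grid.lon0 <= config.lon_min
        and grid.lat0 <= config.lat_min
        and grid.lon_max >= config.lon_max
        and grid.lat_max >= config.lat_max
    ):
        raise ValueError("weather grid does not cover the configured extent")
    earliest = pd.Timestamp(config.survey_start)
    if earliest - pd.Timedelta(days=config.max_lag_days) < grid.dates[0]:
        raise ValueError(
            "survey window begins less than max_lag_days after the weather start; "
            "lag windows would be undefined"
        )
    if config.n_clusters == 0:
        return pd.DataFrame(columns=HOUSEHOLD_COLUMNS)

    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(8)[4])
    n = config.n_clusters
    lon = rng.uniform(config.lon_min, config.lon_max, n)
    lat = rng.uniform(config.lat_min, config.lat_max, n)
    n_days = (pd.Timestamp(config.survey_end) - earliest).days + 1
    dates = earliest + pd.to_timedelta(rng.integers(0, n_days, n), unit="D")
    urban = rng.random(n) < config.p_urban
    if config.jitter:
        # uniform displacement within the DHS privacy radius (<=5 km rural,
        # <=2 km urban), applied to the published cluster coordinate
        radius_km = np.where(urban, config.jitter_urban_km, config.jitter_rural_km)
        theta = rng.uniform(0, 2 * np.pi, n)
        r = radius_km * np.sqrt(rng.random(n))
        lat = lat + (r * np.sin(theta)) / _KM_PER_DEG_LAT
        lon = lon + (r * np.cos(theta)) / (_KM_PER_DEG_LAT * np.cos(np.radians(lat)))
        lon = np.clip(lon, config.lon_min, np.nextafter(config.lon_max, -np.inf))
        lat = np.clip(lat, config.lat_min, np.nextafter(config.lat_max, -np.inf))

    band = (config.lon_max - config.lon_min) / config.n_countries
    country_idx = np.minimum(
        ((lon - config.lon_min) / band).astype(int), config.n_countries - 1
    )
    country = np.array([f"C{k:02d}" for k in country_idx])
    survey_id = np.array([f"{c}-S1" for c in country])
    block = 2 * config.cell_size
    county = np.array(
        [
            f"{c}-x{int((x - config.lon_min) // block)}y{int((y - config.lat_min) // block)}"
            for c, x, y in zip(country, lon, lat)
        ]
    )
    zones = list(config.climate_zone_probs)
    zprobs = np.array([config.climate_zone_probs[z] for z in zones], float)
    zone = rng.choice(zones, size=n, p=zprobs / zprobs.sum())

    m = config.households_per_cluster
    rows = {
        "cluster_id": np.repeat([f"cl{i:04d}" for i in range(n)], m),
        "household_id": [f"cl{i:04d}-h{j:03d}" for i in range(n) for j in range(m)],
        "country_survey_id": np.repeat(survey_id, m),
        "country": np.repeat(country, m),
        "county": np.repeat(county, m),
        "lon": np.repeat(lon, m),
        "lat": np.repeat(lat, m),
        "survey_date": np.repeat(dates, m),
        "urban": np.repeat(urban.astype(int), m),
        "climate_zone": np.repeat(zone, m),
    }
    df = pd.DataFrame(rows)
    p_elec = np.where(df["urban"] == 1, config.p_electricity_urban, config.p_electricity_rural)
    df["electricity_hh"] = (rng.random(len(df)) < p_elec).astype(int)
    df["electricity_community"] = df.groupby("cluster_id")["electricity_hh"].transform("max")
    df["wealth"] = rng.normal(0.0, config.wealth_sd, len(df)) + 0.8 * df["electricity_hh"]
    coll = list(config.collector_probs)
    cprobs = np.array([config.collector_probs[c] for c in coll], float)
    df["collector"] = rng.choice(coll, size=len(df), p=cprobs / cprobs.sum())
    df["walk_time_min"] = np.nan
    df["source_type"] = pd.Series([pd.NA] * len(df), dtype="object")
    return df[HOUSEHOLD_COLUMNS]


def _exposure_lookup(
    records: pd.DataFrame, exposures: pd.DataFrame, window_days: int
) -> pd.DataFrame:
    sub = exposures[exposures["window_days"] == window_days]
    sub = sub.set_index("household_id")
    missing = records.index[~records["household_id"].isin(sub.index)]
    if len(missing):
        hid = records.loc[missing[0], "household_id"]
        raise ValueError(
            f"no {window_days}-day exposure for record household_id={hid!r}"
        )
    return sub.loc[records["household_id"]]


def assign_walk_times(
    records: pd.DataFrame,
    exposures: pd.DataFrame,
    model: TrueModel,
    seed: int,
    floor: bool = True,
) -> pd.DataFrame:
    """Draw walk times from the ground-truth linear model.

    ``WT = alpha + beta_precip*P + beta_temp*T + C(lon, lat) + eps`` with
    ``eps ~ Normal(0, noise_sd^2)``, where P and T are the exposures at the
    model's effect window. Negative draws are floored at 0; the floored count
    is stored in ``result.attrs['n_floored']`` and a warning is emitted when
    more than 1% of records are affected (flooring censors the linear model).
    """
    out = records.copy()
    exp = _exposure_lookup(out, exposures, model.effect_window_days)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[0])
    wt = (
        model.alpha
        + model.beta_precip * exp["precip_cm_per_week"].to_numpy()
        + model.beta_temp * exp["tmax_mean_c"].to_numpy()
        + model.confounder_at(out["lon"].to_numpy(), out["lat"].to_numpy())
        + rng.normal(0.0, model.noise_sd, len(out))
    )
    n_floored = 0
    if floor:
        n_floored = int((wt < 0).sum())
        wt = np.maximum(wt, 0.0)
        if len(out) and n_floored / len(out) >= 0.01:
            warnings.warn(
                f"{n_floored}/{len(out)} walk times floored at 0 (>=1%); "
                "the linear model is noticeably censored",
                stacklevel=2,
            )
    out["walk_time_min"] = wt
    out.attrs["n_floored"] = n_floored
    return out


def assign_source_types(
    records: pd.DataFrame,
    exposures: pd.DataFrame,
    logit_coefficients: dict,
    seed: int,
    window_days: int = 365,
) -> pd.DataFrame:
    """Draw each record's source type from a multinomial logit in its exposures.

    ``logit_coefficients`` maps source type -> ``{"intercept": a, "precip": b,
    "tmax": c}``; log-odds are linear in the record's cm/week precipitation
    and mean tmax at ``window_days``. The vocabulary must come from the
    source-classification scheme used downstream.
    """
    out = records.copy()
    exp = _exposure_lookup(out, exposures, window_days)
    P = exp["precip_cm_per_week"].to_numpy()
    T = exp["tmax_mean_c"].to_numpy()
    types = list(logit_coefficients)
    eta = np.column_stack(
        [
            logit_coefficients[t].get("intercept", 0.0)
            + logit_coefficients[t].get("precip", 0.0) * P
            + logit_coefficients[t].get("tmax", 0.0) * T
            for t in types
        ]
    )
    eta = eta - eta.max(axis=1, keepdims=True)  # overflow-safe softmax
    p = np.exp(eta)
    denom = p.sum(axis=1, keepdims=True)
    if not np.all(np.isfinite(denom)) or np.any(denom <= 0):
        raise ValueError("source-type probabilities fail to normalize")
    p /= denom
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    u = rng.random(len(out))
    idx = (np.cumsum(p, axis=1) < u[:, None]).sum(axis=1)
    out["source_type"] = np.array(types, dtype=object)[idx]
    return out


# ---------------------------------------------------------------------------
# one-call pipeline
# ---------------------------------------------------------------------------

class SimulatedSurvey(NamedTuple):
    config: SimulationConfig
    grid: WeatherGrid
    records: pd.DataFrame
    exposures: pd.DataFrame
    truth: TrueModel


def simulate_survey(
    config: SimulationConfig,
    windows=None,
    source_coefficients: dict | None = None,
) -> SimulatedSurvey:
    """Run the full synthetic pipeline: weather, households, linkage, outcomes.

    ``windows`` defaults to the standard lag windows the configured weather
    span can support (those no longer than ``config.max_lag_days``).
    """
    if windows is None:
        windows = tuple(w for w in WINDOWS if w <= config.max_lag_days)
    grid = simulate_weather(config)
    records = simulate_households(config, grid)
    exposures = link_all(records, grid, windows=windows)
    model = true_model(config)
    records = assign_walk_times(records, exposures, model, seed=config.seed)
    if source_coefficients is None:
        source_coefficients = {
            "piped": {"intercept": 1.0, "precip": 0.15, "tmax": -0.05},
            "borehole": {"intercept": 0.0, "precip": -0.10, "tmax": 0.10},
            "surface": {"intercept": -0.5, "precip": 0.05, "tmax": -0.10},
            "unprotected_well": {"intercept": -0.5, "precip": 0.0, "tmax": 0.0},
        }
    records = assign_source_types(
        records,
        exposures,
        source_coefficients,
        seed=config.seed + 1,
        window_days=config.effect_window_days,
    )
    return SimulatedSurvey(config, grid, records, exposures, model)


def country_specs(config: SimulationConfig) -> dict:
    """Synthetic-country metadata for the filtering stage.

    Each country is a rectangle (a vertical band of the extent) with the
    survey collection window equal to the configured survey window.
    """
    band = (config.lon_max - config.lon_min) / config.n_countries
    specs = {}
    for k in range(config.n_countries):
        specs[f"C{k:02d}-S1"] = {
            "lon_min": config.lon_min + k * band,
            "lon_max": config.lon_min + (k + 1) * band,
            "lat_min": config.lat_min,
            "lat_max": config.lat_max,
            "start_date": config.survey_start,
            "end_date": config.survey_end,
        }
    return specs
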
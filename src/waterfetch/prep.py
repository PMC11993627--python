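"""Record filtering, water-source classification and descriptive summaries.

Exclusion rules are applied in a fixed order with first-match attribution:
missing walk time, GPS more than 10 km outside the record's country, survey
date outside the collection window padded by a two-month (61-day) buffer.

Source types are classified into improved / unimproved per JMP-style
definitions; uncategorized ("other"/unknown) types are treated as missing.

A note on the exceedance share: the survey walk-time variable is one-way,
while the headline share refers to round trips, so "round-trip > 30 min" is
computed as ``2 * walk_time_min > 30``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

_EARTH_RADIUS_KM = 6371.0088
BUFFER_DAYS = 61  # "two-month buffer", calendar-agnostic

IMPROVED_SOURCES = frozenset(
    {"borewell", "borehole", "piped", "rainwater", "protected_spring", "protected_well"}
)
UNIMPROVED_SOURCES = frozenset(
    {"bottled", "vendor", "unprotected_spring", "surface", "unprotected_well"}
)


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km on a spherical Earth."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def distance_to_rectangle_km(lon, lat, rect: dict) -> np.ndarray:
    """Distance (km) from points to an axis-aligned lon/lat rectangle; 0 inside.

    Computed as the great-circle distance to the nearest point of the
    rectangle (coordinates clamped to the rectangle edges), which is exact
    for points due east/west/north/south and a very good approximation at
    the ~10 km scales the exclusion rule uses.
    """
    lon = np.asarray(lon, float)
    lat = np.asarray(lat, float)
    clon = np.clip(lon, rect["lon_min"], rect["lon_max"])
    clat = np.clip(lat, rect["lat_min"], rect["lat_max"])
    return haversine_km(lon, lat, clon, clat)


@dataclass
class ExclusionLog:
    """Per-rule exclusion counts; rules attributed in order, first match wins."""

    counts: dict = field(
        default_factory=lambda: {
            "missing_walk_time": 0,
            "outside_country_10km": 0,
            "date_outside_buffered_window": 0,
        }
    )
    retained: int = 0
    total: int = 0

    def to_dict(self) -> dict:
        return {"counts": dict(self.counts), "retained": self.retained, "total": self.total}


def filter_records(
    records: pd.DataFrame, country_specs: dict, max_outside_km: float = 10.0
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the exclusion rules and return (retained records, log).

    ``country_specs`` maps country_survey_id to a dict with rectangle bounds
    (lon_min/lon_max/lat_min/lat_max) and collection dates
    (start_date/end_date). Unknown country_survey_id raises.
    """
    log = ExclusionLog(total=len(records))
    if len(records) == 0:
        return records.copy(), log
    unknown = set(records["country_survey_id"]) - set(country_specs)
    if unknown:
        raise ValueError(f"unknown country_survey_id(s): {sorted(unknown)}")

    excluded = pd.Series("", index=records.index, dtype=object)

    miss = records["walk_time_min"].isna()
    excluded[miss] = "missing_walk_time"

    dist = np.zeros(len(records))
    date_ok = np.ones(len(records), bool)
    sdate = pd.to_datetime(records["survey_date"])
    for sid, sub in records.groupby("country_survey_id", sort=False):
        spec = country_specs[sid]
        dist_sub = distance_to_rectangle_km(sub["lon"], sub["lat"], spec)
        dist[records.index.get_indexer(sub.index)] = dist_sub
        lo = pd.Timestamp(spec["start_date"]) - pd.Timedelta(days=BUFFER_DAYS)
        hi = pd.Timestamp(spec["end_date"]) + pd.Timedelta(days=BUFFER_DAYS)
        ok = (sdate.loc[sub.index] >= lo) & (sdate.loc[sub.index] <= hi)
        date_ok[records.index.get_indexer(sub.index)] = ok.to_numpy()

    far = pd.Series(dist > max_outside_km, index=records.index)
    excluded[(excluded == "") & far] = "outside_country_10km"
    bad_date = pd.Series(~date_ok, index=records.index)
    excluded[(excluded == "") & bad_date] = "date_outside_buffered_window"

    for rule in log.counts:
        log.counts[rule] = int((excluded == rule).sum())
    kept = records[excluded == ""].copy()
    log.retained = len(kept)
    return kept, log


def classify_source(source_type) -> str:
    """Map a raw source-type string to {improved, unimproved, missing}."""
    if source_type is None or (isinstance(source_type, float) and np.isnan(source_type)):
        return "missing"
    s = str(source_type).strip().lower()
    if s in IMPROVED_SOURCES:
        return "improved"
    if s in UNIMPROVED_SOURCES:
        return "unimproved"
    if s not in {"other", "", "missing", "nan", "<na>"}:
        warnings.warn(f"unknown source type {source_type!r} treated as missing", stacklevel=2)
    return "missing"


FEMALE_COLLECTORS = ("woman", "girl")


def _stratum_stats(wt: pd.Series) -> dict:
    wt = wt.dropna()
    n = len(wt)
    exceed = (2.0 * wt > 30.0).mean()
    return {
        "n": n,
        "mean_walk_time_min": float(wt.mean()),
        "median_walk_time_min": float(wt.median()),
        "sd_walk_time_min": float(wt.std(ddof=1)) if n > 1 else float("nan"),
        "share_roundtrip_gt30": float(exceed),
        "share_roundtrip_gt30_se": float(np.sqrt(exceed * (1 - exceed) / n)) if n else float("nan"),
    }


def summarize(records: pd.DataFrame) -> dict:
    """Descriptive summary: walk-time stats overall and by stratum, the
    round-trip > 30 min share, and the collector breakdown.

    Returns a nested dict; empty strata are reported as absent, not zero.
    The female collector share is the woman + girl share among records with
    a reported (non-missing) collector.
    """
    out: dict = {"overall": _stratum_stats(records["walk_time_min"])}
    for name, mask in [
        ("rural", records["urban"] == 0),
        ("urban", records["urban"] == 1),
    ]:
        sub = records.loc[mask, "walk_time_min"].dropna()
        if len(sub):
            out[name] = _stratum_stats(sub)
    if "climate_zone" in records:
        for zone, sub in records.groupby("climate_zone"):
            wt = sub["walk_time_min"].dropna()
            if len(wt):
                out[f"zone_{zone}"] = _stratum_stats(wt)
    if "collector" in records:
        coll = records["collector"].dropna()
        coll = coll[coll != "missing"]
        if len(coll):
            shares = (coll.value_counts() / len(coll)).to_dict()
            out["collector_shares"] = {k: float(v) for k, v in shares.items()}
            out["female_collector_share"] = float(
                sum(shares.get(c, 0.0) for c in FEMALE_COLLECTORS)
            )
    return out


def walktime_ttest(records: pd.DataFrame) -> dict:
    """Welch two-sample t-test of rural vs urban mean walk time (descriptive)."""
    rural = records.loc[records["urban"] == 0, "walk_time_min"].dropna()
    urban = records.loc[records["urban"] == 1, "walk_time_min"].dropna()
    t, p = stats.ttest_ind(rural, urban, equal_var=False)
    return {"t": float(t), "p": float(p), "n_rural": len(rural), "n_urban": len(urban)}


def walktime_var_ftest(records: pd.DataFrame) -> dict:
    """Classical F-test of equal rural vs urban walk-time variances (descriptive)."""
    rural = records.loc[records["urban"] == 0, "walk_time_min"].dropna()
    urban = records.loc[records["urban"] == 1, "walk_time_min"].dropna()
    f = rural.var(ddof=1) / urban.var(ddof=1)
    d1, d2 = len(rural) - 1, len(urban) - 1
    p_one = stats.f.sf(f, d1, d2) if f >= 1 else stats.f.cdf(f, d1, d2)
    return {"F": float(f), "p": float(min(1.0, 2 * p_one)), "df": (d1, d2)}
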
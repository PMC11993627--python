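"""Replicated spatial first differences (SFD).

The estimator pairs households across adjacent weather-grid cells, differences
outcome and exposure within each pair, pools the differenced rows across all
cell pairs of all country surveys into one regression

    dWT = beta0 + beta1 * dWV

per (lag window, exposure), and repeats the random pairing ``n_replicates``
times. The point estimate is the mean of the replicate slopes; the standard
deviation across replicates is reported as the standard error, with a normal
95% CI (mean +/- 1.96*SD). Any confounder that is spatially smooth at the
cell-adjacency scale differences away, which is the method's identification
argument.

Pairing conventions: differencing runs west-east (east minus west) or, as a
robustness check, north-south (north minus south); pairs join only records of
the same country survey; within one cell pair a replicate uses the maximum
number of disjoint pairs, min(|A|, |B|); by default a record is not reused
across different cell pairs within a replicate (cell pairs are processed in
random order and used records removed — ``reuse_across_cellpairs=True``
relaxes this).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .weather import EXPOSURE_COLUMNS, WINDOWS, WeatherGrid

_KM_PER_DEG_LAT = 111.195


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------

def enumerate_adjacent_cell_pairs(occupied_cells, direction: str):
    """List edge-adjacent occupied cell pairs along one axis.

    Returns ``[((r, c), (r, c+1)), ...]`` for direction "WE" (second cell is
    east) or ``[((r, c), (r+1, c)), ...]`` for "NS" (second cell is north).
    Each unordered pair appears once, with fixed orientation so differences
    are east-minus-west / north-minus-south. Diagonal neighbours are not
    adjacent.
    """
    if direction not in ("WE", "NS"):
        raise ValueError(f"direction must be 'WE' or 'NS', got {direction!r}")
    occ = {(int(r), int(c)) for r, c in occupied_cells}
    pairs = []
    for r, c in sorted(occ):
        nbr = (r, c + 1) if direction == "WE" else (r + 1, c)
        if nbr in occ:
            pairs.append(((r, c), nbr))
    return pairs


def draw_pairs(records_a, records_b, rng: np.random.Generator):
    """Uniformly random disjoint pairing of two record-index lists.

    Returns two arrays of equal length ``min(|A|, |B|)`` — the maximum number
    of pairs that avoids repeating observations within this cell pair. Either
    side empty gives empty output.
    """
    a = np.asarray(records_a)
    b = np.asarray(records_b)
    n = min(len(a), len(b))
    if n == 0:
        return a[:0], b[:0]
    sel_a = rng.choice(a, size=n, replace=False)
    sel_b = rng.choice(b, size=n, replace=False)
    return sel_a, sel_b


def difference(
    pairs: pd.DataFrame, values: pd.DataFrame, columns=None
) -> pd.DataFrame:
    """Difference per-record values across pairs (higher-index cell minus lower).

    ``pairs`` has integer columns ``idx_hi`` (east/north record) and
    ``idx_lo``; ``values`` is indexed by record position. Missing value rows
    raise, naming the pair.
    """
    if columns is None:
        columns = list(values.columns)
    for col_name in ("idx_hi", "idx_lo"):
        bad = ~np.isin(pairs[col_name].to_numpy(), values.index.to_numpy())
        if bad.any():
            i = int(np.nonzero(bad)[0][0])
            raise ValueError(
                f"pair {i}: record index {pairs[col_name].iloc[i]} missing from values"
            )
    hi = values.loc[pairs["idx_hi"].to_numpy(), columns].to_numpy(float)
    lo = values.loc[pairs["idx_lo"].to_numpy(), columns].to_numpy(float)
    return pd.DataFrame(hi - lo, columns=[f"d_{c}" for c in columns])


def fit_sfd(d_wv, d_wt, intercept: bool = True) -> tuple[float, float]:
    """OLS of differenced walk time on differenced exposure.

    Returns ``(beta0, beta1)``; ``beta0`` is 0.0 when ``intercept=False``.
    Constant ``d_wv`` raises a degenerate-variation error.
    """
    x = np.asarray(d_wv, float)
    y = np.asarray(d_wt, float)
    if x.size < 2:
        raise ValueError("need at least two differenced rows to fit the SFD line")
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate exposure variation: differenced exposure is constant")
    if intercept:
        mx, my = x.mean(), y.mean()
        beta1 = float(np.dot(x - mx, y - my) / np.dot(x - mx, x - mx))
        beta0 = float(my - beta1 * mx)
    else:
        beta1 = float(np.dot(x, y) / np.dot(x, x))
        beta0 = 0.0
    return beta0, beta1


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

@dataclass
class EstimateSummary:
    """Replicate-aggregated SFD estimate for one (exposure, window, stratum)."""

    exposure: str
    window_days: int
    direction: str
    stratum: str
    estimate: float  # mean replicate beta1
    se: float  # SD across replicates, reported as SE
    ci_low: float
    ci_high: float
    mean_beta0: float
    n_replicates: int
    mean_pairs: float


class SFDResults:
    """Container for replicate-aggregated SFD estimates.

    Attributes
    ----------
    estimates : pandas.DataFrame
        One row per (exposure, window, stratum) with columns
        exposure/window_days/direction/stratum/estimate/se/ci_low/ci_high/
        mean_beta0/n_replicates/mean_pairs.
    replicates : dict
        ``(exposure, window, stratum) -> ndarray`` of per-replicate slopes.
    """

    def __init__(self, estimates: pd.DataFrame, replicates: dict, direction: str):
        self.estimates = estimates
        self.replicates = replicates
        self.direction = direction

    def summary(self) -> str:
        lines = [
            "Spatial first differences — replicate-aggregated estimates",
            f"direction: {self.direction}   (SE = SD across replicates; CI = mean ± 1.96·SD)",
            "",
        ]
        lines.append(
            self.estimates.to_string(
                index=False,
                float_format=lambda v: f"{v: .4f}",
                columns=[
                    "exposure",
                    "window_days",
                    "stratum",
                    "estimate",
                    "se",
                    "ci_low",
                    "ci_high",
                    "n_replicates",
                    "mean_pairs",
                ],
            )
        )
        return "\n".join(lines)

    def plot(self, exposure: str, ax=None):
        """Errorbar plot of estimates by lag window for one exposure."""
        import matplotlib.pyplot as plt

        df = self.estimates[self.estimates["exposure"] == exposure]
        if ax is None:
            _, ax = plt.subplots()
        for stratum, sub in df.groupby("stratum"):
            ax.errorbar(
                sub["window_days"],
                sub["estimate"],
                yerr=1.96 * sub["se"],
                fmt="o",
                capsize=3,
                label=stratum,
            )
        ax.axhline(0.0, color="0.6", lw=0.8)
        ax.set_xlabel("lag window (days)")
        ax.set_ylabel(f"effect on walk time (min per unit {exposure})")
        ax.legend()
        return ax


class SpatialFirstDifferences:
    """Replicated SFD model over a household table and its exposure table.

    Parameters
    ----------
    records : DataFrame
        Filtered household records (must include cluster_id, household_id,
        country_survey_id, walk_time_min).
    exposures : DataFrame
        Lagged-exposure table from the linkage stage (one row per record x
        window, carrying cell_row/cell_col).
    windows : sequence of int
        Lag windows to fit; every record needs an exposure row per window.
    exposure_names : sequence of str
        Exposure variables to fit, one univariate model each.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        exposures: pd.DataFrame,
        windows=WINDOWS,
        exposure_names=EXPOSURE_COLUMNS,
    ):
        self.windows = tuple(int(w) for w in windows)
        self.exposure_names = tuple(exposure_names)
        self.records = records.reset_index(drop=True)
        n = len(self.records)
        self.wt = self.records["walk_time_min"].to_numpy(float)
        self.survey = self.records["country_survey_id"].to_numpy()

        # align exposures per window to the record order
        self._X: dict[int, dict[str, np.ndarray]] = {}
        cell_row = cell_col = None
        for w in self.windows:
            sub = exposures[exposures["window_days"] == w].set_index("household_id")
            missing = ~self.records["household_id"].isin(sub.index)
            if missing.any():
                hid = self.records.loc[missing.idxmax(), "household_id"]
                raise ValueError(f"record {hid!r} has no exposure at window {w}")
            aligned = sub.loc[self.records["household_id"]]
            self._X[w] = {
                name: aligned[name].to_numpy(float) for name in self.exposure_names
            }
            cell_row = aligned["cell_row"].to_numpy(int)
            cell_col = aligned["cell_col"].to_numpy(int)
        if n and cell_row is None:
            raise ValueError("no exposure windows supplied")
        self.cell_row = cell_row if cell_row is not None else np.zeros(0, int)
        self.cell_col = cell_col if cell_col is not None else np.zeros(0, int)

    # -- internals ----------------------------------------------------------
    def _cell_pairs(self, mask: np.ndarray, direction: str):
        """Cell-pair record-index lists for the records selected by ``mask``."""
        idx = np.nonzero(mask)[0]
        groups: dict = {}
        for i in idx:
            groups.setdefault(
                (self.survey[i], self.cell_row[i], self.cell_col[i]), []
            ).append(i)
        pairs = []
        by_survey: dict = {}
        for (sid, r, c) in groups:
            by_survey.setdefault(sid, set()).add((r, c))
        for sid in sorted(by_survey):
            for lo, hi in enumerate_adjacent_cell_pairs(by_survey[sid], direction):
                pairs.append(
                    (
                        np.asarray(groups[(sid, *lo)]),
                        np.asarray(groups[(sid, *hi)]),
                    )
                )
        return pairs

    def _resolve_strata(self, stratum) -> dict[str, np.ndarray]:
        n = len(self.records)
        if stratum is None:
            return {"all": np.ones(n, bool)}
        if isinstance(stratum, str):
            stratum = {stratum: stratum}
        out = {}
        for name, spec in stratum.items():
            if callable(spec):
                mask = np.asarray(spec(self.records), bool)
            elif isinstance(spec, str):
                mask = np.zeros(n, bool)
                mask[self.records.query(spec).index.to_numpy()] = True
            else:
                mask = np.asarray(spec, bool)
            out[name] = mask
        return out

    def _replicate_once(
        self, cell_pairs, rng: np.random.Generator, reuse_across_cellpairs: bool
    ):
        """One replicate's pooled pair draw; returns (idx_lo, idx_hi) arrays."""
        lo_all, hi_all = [], []
        order = rng.permutation(len(cell_pairs))
        if reuse_across_cellpairs:
            for k in order:
                a, b = cell_pairs[k]
                sa, sb = draw_pairs(a, b, rng)
                lo_all.append(sa)
                hi_all.append(sb)
        else:
            used = set()
            for k in order:
                a, b = cell_pairs[k]
                a = a[[i not in used for i in a]] if used else a
                b = b[[i not in used for i in b]] if used else b
                sa, sb = draw_pairs(a, b, rng)
                lo_all.append(sa)
                hi_all.append(sb)
                used.update(sa.tolist())
                used.update(sb.tolist())
        if lo_all:
            return np.concatenate(lo_all), np.concatenate(hi_all)
        return np.zeros(0, int), np.zeros(0, int)

    # -- fitting ------------------------------------------------------------
    def fit(
        self,
        direction: str = "WE",
        n_replicates: int = 1000,
        seed: int = 0,
        stratum=None,
        reuse_across_cellpairs: bool = False,
        intercept: bool = True,
        exposure_transform=None,
    ) -> SFDResults:
        """Run the replicated SFD analysis.

        Parameters
        ----------
        direction : {"WE", "NS"}
            Differencing axis (east minus west, or north minus south).
        n_replicates : int
            Number of random re-pairings (1000 in the headline analysis).
        seed : int
            Master seed; per-replicate streams are spawned from it so the
            whole run is reproducible and replicates independent.
        stratum : None | dict | str
            Restriction(s) applied to records *before* pairing: a dict of
            name -> (query string | boolean mask | callable), a single query
            string, or None for the full sample.
        reuse_across_cellpairs : bool
            Allow a record to appear in pairs of two different cell pairs
            within one replicate (default False).
        intercept : bool
            Keep the intercept in the differenced regression (default True).
        exposure_transform : callable, optional
            Applied to each aligned exposure array before differencing (used
            by the percentile-binned sensitivity variant).
        """
        strata = self._resolve_strata(stratum)
        children = np.random.SeedSequence(seed).spawn(n_replicates)
        rows, replicate_store = [], {}
        for name, mask in strata.items():
            cell_pairs = self._cell_pairs(mask, direction)
            max_pairs = sum(min(len(a), len(b)) for a, b in cell_pairs)
            if max_pairs == 0:
                warnings.warn(
                    f"stratum {name!r}: no usable adjacent-cell pairs; omitted",
                    stacklevel=2,
                )
                continue
            X = {
                (w, e): (
                    self._X[w][e]
                    if exposure_transform is None
                    else exposure_transform(self._X[w][e], w, e)
                )
                for w in self.windows
                for e in self.exposure_names
            }
            betas = {key: np.empty(n_replicates) for key in X}
            beta0s = {key: np.empty(n_replicates) for key in X}
            pair_counts = np.empty(n_replicates)
            for r in range(n_replicates):
                rng = np.random.default_rng(children[r])
                lo, hi = self._replicate_once(cell_pairs, rng, reuse_across_cellpairs)
                pair_counts[r] = len(lo)
                d_wt = self.wt[hi] - self.wt[lo]
                for key, x in X.items():
                    d_wv = x[hi] - x[lo]
                    b0, b1 = fit_sfd(d_wv, d_wt, intercept=intercept)
                    betas[key][r] = b1
                    beta0s[key][r] = b0
            for (w, e), b in betas.items():
                sd = float(b.std(ddof=1)) if n_replicates > 1 else 0.0
                mean = float(b.mean())
                rows.append(
                    EstimateSummary(
                        exposure=e,
                        window_days=w,
                        direction=direction,
                        stratum=name,
                        estimate=mean,
                        se=sd,
                        ci_low=mean - 1.96 * sd,
                        ci_high=mean + 1.96 * sd,
                        mean_beta0=float(beta0s[(w, e)].mean()),
                        n_replicates=n_replicates,
                        mean_pairs=float(pair_counts.mean()),
                    )
                )
                replicate_store[(e, w, name)] = b
        est = pd.DataFrame([r.__dict__ for r in rows])
        return SFDResults(est, replicate_store, direction)


def replicate_sfd(
    records: pd.DataFrame,
    exposures: pd.DataFrame,
    windows=WINDOWS,
    direction: str = "WE",
    n_replicates: int = 1000,
    seed: int = 0,
    stratum_spec=None,
    exposure_names=EXPOSURE_COLUMNS,
    **kwargs,
) -> SFDResults:
    """Functional entry point: build the model and fit (see
    :class:`SpatialFirstDifferences`)."""
    model = SpatialFirstDifferences(
        records, exposures, windows=windows, exposure_names=exposure_names
    )
    return model.fit(
        direction=direction,
        n_replicates=n_replicates,
        seed=seed,
        stratum=stratum_spec,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# sensitivity variants
# ---------------------------------------------------------------------------

def sfd_cell_means(
    records: pd.DataFrame,
    exposures: pd.DataFrame,
    windows=WINDOWS,
    direction: str = "WE",
    exposure_names=EXPOSURE_COLUMNS,
    intercept: bool = True,
) -> pd.DataFrame:
    """Deterministic SFD on grid-cell means (no resampling, all data used).

    Walk time and exposures are averaged per (survey, cell); the cell means
    are differenced across adjacent cells and fitted by one OLS per (window,
    exposure), with classical OLS standard errors.
    """
    import statsmodels.api as sm

    model = SpatialFirstDifferences(records, exposures, windows=windows,
                                    exposure_names=exposure_names)
    rows = []
    cell_key = pd.DataFrame(
        {
            "survey": model.survey,
            "row": model.cell_row,
            "col": model.cell_col,
        }
    )
    for w in model.windows:
        for e in model.exposure_names:
            df = cell_key.copy()
            df["wt"] = model.wt
            df["wv"] = model._X[w][e]
            means = df.groupby(["survey", "row", "col"], as_index=False).mean()
            d_wv, d_wt = [], []
            for sid, sub in means.groupby("survey"):
                occ = {
                    (int(r), int(c)): i
                    for i, (r, c) in enumerate(zip(sub["row"], sub["col"]))
                }
                sub = sub.reset_index(drop=True)
                for lo, hi in enumerate_adjacent_cell_pairs(occ, direction):
                    d_wv.append(sub.loc[occ[hi], "wv"] - sub.loc[occ[lo], "wv"])
                    d_wt.append(sub.loc[occ[hi], "wt"] - sub.loc[occ[lo], "wt"])
            x = np.asarray(d_wv)
            y = np.asarray(d_wt)
            if x.size < 2 or np.ptp(x) == 0.0:
                raise ValueError(
                    "degenerate exposure variation in cell-mean differences"
                )
            X = sm.add_constant(x) if intercept else x[:, None]
            res = sm.OLS(y, X).fit()
            slope = res.params[-1]
            se = res.bse[-1]
            rows.append(
                {
                    "exposure": e,
                    "window_days": w,
                    "direction": direction,
                    "stratum": "all",
                    "estimate": float(slope),
                    "se": float(se),
                    "ci_low": float(slope - 1.96 * se),
                    "ci_high": float(slope + 1.96 * se),
                    "n_cell_pairs": int(x.size),
                }
            )
    return pd.DataFrame(rows)


def sfd_binned(
    records: pd.DataFrame,
    exposures: pd.DataFrame,
    percentile: int,
    windows=WINDOWS,
    direction: str = "WE",
    n_replicates: int = 1000,
    seed: int = 0,
    exposure_names=EXPOSURE_COLUMNS,
    **kwargs,
) -> SFDResults:
    """SFD with exposures replaced by high-exposure indicators.

    Each exposure is replaced by ``1(WV >= q)`` where q is the stratum-wide
    ``percentile`` (75 or 90) computed once over the analysis set; the
    indicator then goes through the standard pairing/differencing pipeline.
    At desk scale an indicator can easily have no variation across the
    adjacent-cell pairs of a replicate, in which case the degenerate-
    variation error propagates.
    """
    if percentile not in (75, 90):
        raise ValueError("percentile must be 75 or 90")
    model = SpatialFirstDifferences(
        records, exposures, windows=windows, exposure_names=exposure_names
    )
    thresholds = {
        (w, e): np.percentile(model._X[w][e], percentile)
        for w in model.windows
        for e in model.exposure_names
    }

    def transform(x, w, e):
        return (x >= thresholds[(w, e)]).astype(float)

    return model.fit(
        direction=direction,
        n_replicates=n_replicates,
        seed=seed,
        exposure_transform=transform,
        **kwargs,
    )


def border_buffer_filter(
    records: pd.DataFrame,
    grid: WeatherGrid,
    rural_km: float = 5.0,
    urban_km: float = 2.0,
) -> pd.DataFrame:
    """Drop records near grid-cell borders (GPS-jitter sensitivity analysis).

    Records whose distance to the nearest cell edge is below 5 km (rural) or
    2 km (urban) are removed, so a jittered coordinate cannot have crossed a
    cell border.
    """
    lon = records["lon"].to_numpy(float)
    lat = records["lat"].to_numpy(float)
    s = grid.cell_size
    fx = (lon - grid.lon0) / s - np.floor((lon - grid.lon0) / s)
    fy = (lat - grid.lat0) / s - np.floor((lat - grid.lat0) / s)
    km_lon = _KM_PER_DEG_LAT * np.cos(np.radians(lat))
    dist_lon = np.minimum(fx, 1 - fx) * s * km_lon
    dist_lat = np.minimum(fy, 1 - fy) * s * _KM_PER_DEG_LAT
    edge_km = np.minimum(dist_lon, dist_lat)
    buffer_km = np.where(records["urban"].to_numpy() == 1, urban_km, rural_km)
    return records[edge_km >= buffer_km].copy()


def standard_strata(records: pd.DataFrame) -> dict[str, str]:
    """The stratifications reported in the headline analysis, as query strings."""
    from .prep import classify_source

    cls = records["source_type"].map(classify_source)
    return {
        "all": "walk_time_min == walk_time_min",
        "rural": "urban == 0",
        "rural_electricity": "urban == 0 and electricity_community == 1",
        "rural_no_electricity": "urban == 0 and electricity_community == 0",
        **{f"zone_{z}": f"climate_zone == '{z}'" for z in records["climate_zone"].unique()},
        "improved": (cls == "improved").to_numpy(),
        "unimproved": (cls == "unimproved").to_numpy(),
    }
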
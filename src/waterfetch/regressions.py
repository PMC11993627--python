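"""Comparison models: fixed-effects OLS and logistic source-use regressions.

These are the non-causal comparison analyses run alongside the SFD estimator:

* household-level OLS of walk time on a lagged weather exposure with
  categorical fixed effects for country, county, year and month, and
  cluster-robust (CR1) standard errors at the survey-cluster level;
* interaction variants adding an urban/electricity modifier;
* logistic regressions of source-type use on an exposure with country, year
  and month controls, reported as odds ratios per unit exposure.

Fixed effects are absorbed by iterated within-group demeaning (alternating
projections), which is algebraically identical to estimating the indicator
blocks (Frisch–Waugh–Lovell); the indicator path is retained as a
cross-check. The cluster-robust variance uses the CR1 small-sample factor
``G/(G-1) * (n-1)/(n-k)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .prep import classify_source

FE_FACTORS = ("country", "county", "year", "month")
_Z95 = 1.96


def _analysis_frame(
    records: pd.DataFrame, exposures: pd.DataFrame, window_days: int, exposure_name: str
) -> pd.DataFrame:
    sub = exposures[exposures["window_days"] == window_days].set_index("household_id")
    missing = ~records["household_id"].isin(sub.index)
    if missing.any():
        hid = records.loc[missing.idxmax(), "household_id"]
        raise ValueError(f"record {hid!r} has no exposure at window {window_days}")
    df = records.copy().reset_index(drop=True)
    df["wv"] = sub.loc[df["household_id"], exposure_name].to_numpy(float)
    dates = pd.to_datetime(df["survey_date"])
    df["year"] = dates.dt.year
    df["month"] = dates.dt.month
    return df


def _cr1_cluster_se(x_tilde: np.ndarray, resid: np.ndarray, groups, k_params: int) -> float:
    """CR1 sandwich SE for a single demeaned regressor."""
    g = pd.Series(resid * x_tilde).groupby(np.asarray(groups)).sum().to_numpy()
    n, G = len(resid), len(g)
    c = (G / (G - 1)) * ((n - 1) / (n - k_params))
    bread = float(np.dot(x_tilde, x_tilde))
    return float(np.sqrt(c * np.sum(g**2)) / bread)


def _absorb(df: pd.DataFrame, cols, factors, tol=1e-12, max_iter=500) -> pd.DataFrame:
    """Alternating-projection demeaning of ``cols`` over categorical factors."""
    work = df[list(cols)].astype(float).copy()
    scale = max(work.abs().to_numpy().max(), 1.0)
    for _ in range(max_iter):
        delta = 0.0
        for f in factors:
            means = work.groupby(df[f], observed=True).transform("mean")
            delta = max(delta, means.abs().to_numpy().max())
            work = work - means
        if delta < tol * scale:
            break
    return work


def _fe_rank(df: pd.DataFrame, factors) -> int:
    """Exact column rank of {intercept + factor indicator blocks}."""
    combos = df[list(factors)].drop_duplicates()
    mats = [np.ones((len(combos), 1))]
    for f in factors:
        mats.append(pd.get_dummies(combos[f], drop_first=True).to_numpy(float))
    return int(np.linalg.matrix_rank(np.hstack(mats)))


@dataclass
class FEResult:
    """Fixed-effects regression result for one (window, exposure)."""

    window_days: int
    exposure: str
    beta1: float
    se: float
    ci_low: float
    ci_high: float
    n: int
    n_clusters: int
    method: str

    def summary(self) -> str:
        return (
            f"FE OLS ({self.method}): walk_time ~ {self.exposure} "
            f"[window {self.window_days} d] + country/county/year/month FE\n"
            f"  beta1 = {self.beta1:.4f}  (cluster-robust SE {self.se:.4f}, "
            f"95% CI [{self.ci_low:.4f}, {self.ci_high:.4f}], "
            f"n={self.n}, clusters={self.n_clusters})"
        )


class FixedEffectsWalkTime:
    """Walk-time fixed-effects model for one exposure and lag window.

    ``fit(method="absorb")`` demeans within the four factor blocks;
    ``fit(method="dummies")`` estimates the indicator blocks explicitly.
    Both return identical slopes and CR1 cluster-robust SEs.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        exposures: pd.DataFrame,
        window_days: int,
        exposure_name: str,
        fe_factors=FE_FACTORS,
        cluster_col: str = "cluster_id",
    ):
        self.window_days = int(window_days)
        self.exposure_name = exposure_name
        self.fe_factors = tuple(fe_factors)
        self.cluster_col = cluster_col
        self.df = _analysis_frame(records, exposures, window_days, exposure_name).dropna(
            subset=["walk_time_min", "wv"]
        )

    def fit(self, method: str = "absorb") -> FEResult:
        df = self.df
        k_absorbed = _fe_rank(df, self.fe_factors)
        k = k_absorbed + 1  # + the exposure slope
        if method == "absorb":
            dm = _absorb(df, ["walk_time_min", "wv"], self.fe_factors)
            x = dm["wv"].to_numpy()
            y = dm["walk_time_min"].to_numpy()
            sxx = float(np.dot(x, x))
            if sxx <= 1e-10 * max(float(np.dot(df["wv"], df["wv"])), 1.0):
                raise ValueError(
                    "exposure is collinear with the fixed effects: no within variation"
                )
            beta1 = float(np.dot(x, y) / sxx)
            resid = y - beta1 * x
        elif method == "dummies":
            X = [df[["wv"]].to_numpy(float), np.ones((len(df), 1))]
            for f in self.fe_factors:
                X.append(pd.get_dummies(df[f], drop_first=True).to_numpy(float))
            X = np.hstack(X)
            if np.linalg.matrix_rank(X) < k:
                # drop redundant columns (nested factors); lstsq still gives
                # the unique slope because 'wv' is first and not in the span
                pass
            coef, *_ = np.linalg.lstsq(X, df["walk_time_min"].to_numpy(float), rcond=None)
            beta1 = float(coef[0])
            fitted = X @ coef
            resid = df["walk_time_min"].to_numpy(float) - fitted
            # FWL residualized regressor for the sandwich bread
            coef_x, *_ = np.linalg.lstsq(X[:, 1:], X[:, 0], rcond=None)
            x = X[:, 0] - X[:, 1:] @ coef_x
            if float(np.dot(x, x)) <= 1e-10 * max(float(np.dot(df["wv"], df["wv"])), 1.0):
                raise ValueError(
                    "exposure is collinear with the fixed effects: no within variation"
                )
        else:
            raise ValueError(f"unknown method {method!r}")
        se = _cr1_cluster_se(x, resid, df[self.cluster_col], k)
        return FEResult(
            window_days=self.window_days,
            exposure=self.exposure_name,
            beta1=beta1,
            se=se,
            ci_low=beta1 - _Z95 * se,
            ci_high=beta1 + _Z95 * se,
            n=len(df),
            n_clusters=df[self.cluster_col].nunique(),
            method=method,
        )


def fit_fixed_effects(
    records: pd.DataFrame,
    exposures: pd.DataFrame,
    window_days: int,
    exposure_name: str,
    method: str = "absorb",
    fe_factors=FE_FACTORS,
) -> FEResult:
    """Fit the four-block fixed-effects walk-time model (see
    :class:`FixedEffectsWalkTime`)."""
    return FixedEffectsWalkTime(
        records, exposures, window_days, exposure_name, fe_factors=fe_factors
    ).fit(method=method)


def fit_fe_interaction(
    records: pd.DataFrame,
    exposures: pd.DataFrame,
    window_days: int,
    exposure_name: str,
    modifier: str,
    adjust_wealth: bool = False,
    fe_factors=FE_FACTORS,
):
    """Fixed-effects model with a modifier main effect and modifier x WV term.

    ``modifier`` is "urban" or "electricity" (household flag); the returned
    statsmodels results object carries the interaction coefficient under
    ``"wv:mod"`` with cluster-robust SEs.
    """
    mod_col = {"urban": "urban", "electricity": "electricity_hh"}.get(modifier, modifier)
    df = _analysis_frame(records, exposures, window_days, exposure_name).dropna(
        subset=["walk_time_min", "wv"]
    )
    if df[mod_col].nunique() < 2:
        raise ValueError(f"modifier {modifier!r} has no variation")
    df["mod"] = df[mod_col].astype(float)
    terms = ["wv * mod"]
    terms += [f"C({f})" for f in fe_factors if df[f].nunique() > 1]
    if adjust_wealth:
        terms.append("wealth")
    formula = "walk_time_min ~ " + " + ".join(terms)
    res = smf.ols(formula, data=df).fit(
        cov_type="cluster", cov_kwds={"groups": df["cluster_id"]}
    )
    return res


@dataclass
class SourceUseResult:
    """Logistic source-use regression result (odds ratio per unit exposure)."""

    source: str
    window_days: int
    exposure: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    coef: float
    se: float
    n: int

    def summary(self) -> str:
        return (
            f"Logit: P(source={self.source}) ~ {self.exposure} [window "
            f"{self.window_days} d] + country/year/month\n"
            f"  OR = {self.odds_ratio:.4f} per unit "
            f"(95% CI [{self.ci_low:.4f}, {self.ci_high:.4f}], n={self.n})"
        )


def fit_source_logit(
    records: pd.DataFrame,
    exposures: pd.DataFrame,
    source_k: str,
    window_days: int,
    exposure_name: str,
    controls=("country", "year", "month"),
    cluster: bool = True,
) -> SourceUseResult:
    """Logistic regression of source-type use on one weather exposure.

    The outcome is ``1(source == source_k)``; ``source_k`` may be a raw type
    ("piped", "borehole", ...) or "improved"/"unimproved" via the JMP
    classification (missing classifications are dropped). Controls are
    categorical indicators; SEs are clustered at the survey cluster. The
    odds ratio is per 1-unit increase of the exposure (cm/week or degC).
    """
    df = _analysis_frame(records, exposures, window_days, exposure_name)
    if source_k in ("improved", "unimproved"):
        cls = df["source_type"].map(classify_source)
        df = df[cls != "missing"].copy()
        y = (df["source_type"].map(classify_source) == source_k).astype(int)
    else:
        df = df[df["source_type"].notna()].copy()
        y = (df["source_type"] == source_k).astype(int)
    if y.nunique() < 2:
        raise ValueError(f"outcome 1(source=={source_k!r}) has a single class")
    df["y"] = y.to_numpy()
    terms = ["wv"] + [f"C({c})" for c in controls if df[c].nunique() > 1]
    formula = "y ~ " + " + ".join(terms)
    model = smf.logit(formula, data=df)
    kwargs = {"disp": False, "maxiter": 200}
    if cluster:
        kwargs.update(cov_type="cluster", cov_kwds={"groups": df["cluster_id"]})
    try:
        res = model.fit(**kwargs)
    except Exception as err:  # statsmodels raises PerfectSeparation* variants
        if "separat" in str(err).lower() or "Singular" in str(err):
            raise ValueError(f"separation detected fitting source {source_k!r}") from err
        raise
    coef = float(res.params["wv"])
    se = float(res.bse["wv"])
    if not np.isfinite(coef) or abs(coef) > 30:
        raise ValueError(f"separation detected fitting source {source_k!r}")
    return SourceUseResult(
        source=source_k,
        window_days=window_days,
        exposure=exposure_name,
        odds_ratio=float(np.exp(coef)),
        ci_low=float(np.exp(coef - _Z95 * se)),
        ci_high=float(np.exp(coef + _Z95 * se)),
        coef=coef,
        se=se,
        n=len(df),
    )


@dataclass
class NaiveOLSResult:
    """Pooled OLS of walk time on an exposure — no spatial identification."""

    window_days: int
    exposure: str
    beta1: float
    se_classical: float
    se_cluster: float
    n: int


def naive_pooled_ols(
    records: pd.DataFrame,
    exposures: pd.DataFrame,
    window_days: int,
    exposure_name: str,
) -> NaiveOLSResult:
    """Naive pooled cross-sectional OLS (the estimator SFD exists to fix).

    Any spatially smooth confounder correlated with the exposure across the
    study region loads directly onto this slope.
    """
    df = _analysis_frame(records, exposures, window_days, exposure_name).dropna(
        subset=["walk_time_min", "wv"]
    )
    X = sm.add_constant(df["wv"].to_numpy(float))
    res = sm.OLS(df["walk_time_min"].to_numpy(float), X).fit()
    res_cl = res.get_robustcov_results(
        cov_type="cluster", groups=df["cluster_id"]
    )
    return NaiveOLSResult(
        window_days=window_days,
        exposure=exposure_name,
        beta1=float(res.params[1]),
        se_classical=float(res.bse[1]),
        se_cluster=float(res_cl.bse[1]),
        n=len(df),
    )
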
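"""Climate-scenario projections of the water-fetching burden.

Translates an estimated per-walk effect (minutes per degC or per cm/week)
into weekly household totals and exceedance-fraction shifts. The weekly
arithmetic multiplies the one-way per-walk effect by the number of
collection trips per day and 7 days per week; if the household's trips were
counted as round trips the figure would double — the one-way x trips x 7
convention is the one used here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ROUNDTRIP_THRESHOLD_MIN = 30.0


@dataclass
class ScenarioSpec:
    """One climate scenario.

    Exactly one of ``delta_precip_cm_week`` (absolute cm/week change) or
    ``delta_precip_frac`` (relative change, e.g. -0.10 for a 10% decrease;
    requires a mean precipitation level from data) may be set alongside
    ``delta_tmax_c``.
    """

    name: str
    delta_tmax_c: float | None = None
    delta_precip_cm_week: float | None = None
    delta_precip_frac: float | None = None
    trips_per_day: float = 4.0
    days_per_week: float = 7.0
    roundtrip_threshold_min: float = ROUNDTRIP_THRESHOLD_MIN

    def __post_init__(self) -> None:
        if self.trips_per_day <= 0:
            raise ValueError("trips_per_day must be positive")
        if self.delta_precip_cm_week is not None and self.delta_precip_frac is not None:
            raise ValueError("set at most one of absolute/relative precipitation delta")


def weekly_walktime_change(
    beta: float,
    delta: float,
    trips_per_day: float,
    days: float = 7.0,
    beta_units: str | None = None,
    delta_units: str | None = None,
) -> float:
    """Change in total weekly walk time (minutes/week), unrounded.

    ``beta`` is the one-way per-walk effect in minutes per unit of the
    weather variable, ``delta`` the scenario change in the same unit. The
    reporting layer rounds to the nearest minute. Optional unit labels are
    checked against each other when both are given.
    """
    if beta_units is not None and delta_units is not None and beta_units != delta_units:
        raise ValueError(
            f"unit mismatch: beta per {beta_units!r} but delta in {delta_units!r}"
        )
    return beta * delta * trips_per_day * days


def shifted_exceedance(
    walk_times,
    beta: float,
    delta: float,
    threshold: float = ROUNDTRIP_THRESHOLD_MIN,
) -> tuple[float, float]:
    """(baseline, shifted) fraction of households over the round-trip threshold.

    Walk times are one-way minutes; each is shifted by ``beta * delta`` and a
    household exceeds when ``2 * WT > threshold``.
    """
    wt = np.asarray(walk_times, float)
    wt = wt[~np.isnan(wt)]
    if wt.size == 0:
        raise ValueError("no walk times supplied")
    baseline = float(np.mean(2.0 * wt > threshold))
    shifted = float(np.mean(2.0 * (wt + beta * delta) > threshold))
    return baseline, shifted


def _resolve_delta(scenario: ScenarioSpec, exposure: str, mean_precip: float | None):
    if exposure.startswith("tmax"):
        return scenario.delta_tmax_c
    if scenario.delta_precip_cm_week is not None:
        return scenario.delta_precip_cm_week
    if scenario.delta_precip_frac is not None:
        if mean_precip is None:
            raise ValueError(
                "relative precipitation scenario requires a mean precipitation "
                "level from the exposure table"
            )
        return scenario.delta_precip_frac * mean_precip
    return None


def project_report(
    estimates: pd.DataFrame,
    scenarios,
    records: pd.DataFrame | None = None,
    exposures: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Cross scenarios with estimates into a projection table.

    For every (scenario, estimate) pair with matching units the table carries
    the weekly walk-time change with a CI range propagated linearly from the
    estimate's CI, and — when ``records`` are supplied — the baseline and
    shifted round-trip exceedance fractions.
    """
    rows = []
    for scenario in scenarios:
        for est in estimates.itertuples(index=False):
            mean_precip = None
            if exposures is not None and est.exposure.startswith("precip"):
                sub = exposures[exposures["window_days"] == est.window_days]
                mean_precip = float(sub[est.exposure].mean())
            delta = _resolve_delta(scenario, est.exposure, mean_precip)
            if delta is None:
                continue
            row = {
                "scenario": scenario.name,
                "exposure": est.exposure,
                "window_days": est.window_days,
                "delta": delta,
                "beta": est.estimate,
                "weekly_change_min": weekly_walktime_change(
                    est.estimate, delta, scenario.trips_per_day, scenario.days_per_week
                ),
                "weekly_change_ci_low": weekly_walktime_change(
                    est.ci_low, delta, scenario.trips_per_day, scenario.days_per_week
                ),
                "weekly_change_ci_high": weekly_walktime_change(
                    est.ci_high, delta, scenario.trips_per_day, scenario.days_per_week
                ),
            }
            if records is not None and len(records):
                base, shift = shifted_exceedance(
                    records["walk_time_min"],
                    est.estimate,
                    delta,
                    scenario.roundtrip_threshold_min,
                )
                row["baseline_exceedance"] = base
                row["shifted_exceedance"] = shift
            rows.append(row)
    return pd.DataFrame(rows)
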
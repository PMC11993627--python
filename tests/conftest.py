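"""Shared fixtures: tiny scripted grids and the session-scoped recovery study."""

import numpy as np
import pandas as pd
import pytest

import waterfetch as wf


def make_grid(
    n_lat=3,
    n_lon=3,
    n_days=40,
    lon0=0.0,
    lat0=0.0,
    cell_size=0.5,
    start="2016-01-01",
    precip_fn=None,
    tmax_fn=None,
):
    """Small grid with scripted weather: fn(day, row, col) -> value."""
    dates = pd.date_range(start, periods=n_days, freq="D")
    t, r, c = np.meshgrid(
        np.arange(n_days), np.arange(n_lat), np.arange(n_lon), indexing="ij"
    )
    precip = precip_fn(t, r, c) if precip_fn else np.full(t.shape, 0.1)
    tmax = tmax_fn(t, r, c) if tmax_fn else np.full(t.shape, 30.0)
    return wf.WeatherGrid(
        lon0=lon0,
        lat0=lat0,
        cell_size=cell_size,
        dates=dates,
        precip=np.asarray(precip, float),
        tmax=np.asarray(tmax, float),
    )


def make_records(specs, survey_date="2016-02-09", survey_id="C00-S1"):
    """Household rows from compact specs: (cluster_id, lon, lat, n, extra-dict)."""
    rows = []
    for spec in specs:
        cid, lon, lat, n, extra = (*spec, {})[:5] if len(spec) == 4 else spec
        for j in range(n):
            rows.append(
                {
                    "cluster_id": cid,
                    "household_id": f"{cid}-h{j}",
                    "country_survey_id": survey_id,
                    "country": survey_id.split("-")[0],
                    "county": "k0",
                    "lon": lon,
                    "lat": lat,
                    "survey_date": pd.Timestamp(survey_date),
                    "walk_time_min": 10.0,
                    "source_type": "piped",
                    "urban": 0,
                    "electricity_hh": 0,
                    "electricity_community": 0,
                    "wealth": 0.0,
                    "climate_zone": "arid",
                    "collector": "woman",
                    **extra,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture()
def toy_grid():
    return make_grid()


# ---------------------------------------------------------------------------
# the parameter-recovery study (shared by the acceptance and SFD suites)
# ---------------------------------------------------------------------------

RECOVERY_SEED = 42
TRUE_BETAS = {"precip_cm_per_week": -3.5, "tmax_mean_c": 0.76}
N_REPLICATES = 200


@pytest.fixture(scope="session")
def recovery_sim():
    """100 clusters x 25 households on a 10x10 grid of 0.5-degree cells,
    380 days of weather, 365-day true effects -3.5 and +0.76, smooth
    confounder of amplitude 20 min."""
    cfg = wf.SimulationConfig(seed=RECOVERY_SEED, confounder_amplitude=20.0)
    return wf.simulate_survey(cfg, windows=(365,))


@pytest.fixture(scope="session")
def recovery_fit_we(recovery_sim):
    return wf.replicate_sfd(
        recovery_sim.records,
        recovery_sim.exposures,
        windows=(365,),
        direction="WE",
        n_replicates=N_REPLICATES,
        seed=RECOVERY_SEED,
    )


@pytest.fixture(scope="session")
def recovery_fit_ns(recovery_sim):
    return wf.replicate_sfd(
        recovery_sim.records,
        recovery_sim.exposures,
        windows=(365,),
        direction="NS",
        n_replicates=N_REPLICATES,
        seed=RECOVERY_SEED,
    )
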
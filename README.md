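# waterfetch

Weather effects on household water-fetching walk times, estimated by
replicated **spatial first differences (SFD)**.

In much of Sub-Saharan Africa, households collect drinking water from sources
off premises, and the one-way walk time to the source (`WT`, minutes) responds
to recent weather: sustained rainfall recharges nearby sources and shortens
walks, sustained heat dries them and lengthens walks. Estimating that effect
from cross-sectional household surveys is confounded by everything else that
varies smoothly over space — wealth, infrastructure, hydrogeology. SFD removes
any confounder that is smooth at the scale of a 0.5° weather-grid cell by
differencing *adjacent* cells: households are randomly paired across
neighbouring cells (east minus west, or north minus south as a robustness
check), walk time and exposure are differenced within pairs, and the pooled
differences are fitted by

```
ΔWT_i = β0 + β1 · ΔWV_k,i
```

where `WV_k` is a lagged weather exposure: precipitation in **cm/week**
(window total divided by window length in weeks) or mean daily maximum
temperature in **°C**, over the 7/30/90/180/365 days preceding the survey
date. The random pairing is replicated (1000× in the headline configuration);
the point estimate is the replicate mean and the replicate standard deviation
is reported as the standard error. The package is aimed at researchers who
want the estimator, its sensitivity variants (cell means, percentile-binned
exposures, GPS-jitter border buffers), the fixed-effects and logistic
source-use comparison models, and a synthetic data generator with known
ground truth to validate all of it end to end — no external data downloads
required.

## Worked example

Generate a synthetic survey with known effects (−3.5 min per cm/week of
365-day precipitation, +0.76 min per °C of 365-day mean daily maximum
temperature, plus a 20-minute spatially smooth unobserved confounder), then
estimate by SFD and by naive pooled OLS:

```python
import waterfetch as wf

cfg = wf.SimulationConfig(seed=42, confounder_amplitude=20.0)
sim = wf.simulate_survey(cfg, windows=(365,))
fit = wf.replicate_sfd(sim.records, sim.exposures, windows=(365,),
                       direction="WE", n_replicates=200, seed=42)
print(fit.summary())
naive = wf.naive_pooled_ols(sim.records, sim.exposures, 365, "precip_cm_per_week")
print(f"naive pooled OLS, precip: {naive.beta1:.3f} (truth -3.5)")
```

```
Spatial first differences — replicate-aggregated estimates
direction: WE   (SE = SD across replicates; CI = mean ± 1.96·SD)

          exposure  window_days stratum  estimate      se  ci_low  ci_high  n_replicates  mean_pairs
precip_cm_per_week          365     all   -5.0725  1.1960 -7.4167  -2.7283           200    726.0000
       tmax_mean_c          365     all    0.1683  0.8177 -1.4343   1.7709           200    726.0000

naive pooled OLS, precip: 7.747 (truth -3.5)
```

Both SFD confidence intervals cover the generating coefficients, while the
naive pooled slope for precipitation is displaced to +7.7 by the smooth
confounder — the contrast the estimator exists to demonstrate. Downstream,
`wf.weekly_walktime_change(0.76, 4, 4, 7)` converts a per-walk temperature
effect into household burden: a 4 °C warming at 4 collection trips/day adds
85 minutes of walking per household per week (rounded from 85.12).

The same pipeline is scriptable from a shell:

```
waterfetch simulate --out-dir run/
waterfetch sfd --records run/households.csv --exposures run/exposures.csv \
    --windows 365 --replicates 1000 --seed 0 --out run/estimates.csv
waterfetch project --estimates run/estimates.csv --scenarios scenarios.yaml \
    --records run/households.csv --out run/projection.csv
```

See `docs/methods.md` for the model, the generator's design and the
conventions (window end, pairing rules, SD-as-SE aggregation).

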
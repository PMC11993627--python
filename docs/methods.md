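# Methods

## The estimand and the SFD estimator

The outcome is the one-way walk time `WT_i` (minutes) from a surveyed
household to its primary drinking-water source. Exposures `WV_k,i` are
aggregates of gridded daily weather over a lag window of 7, 30, 90, 180 or
365 days preceding the survey date: precipitation as the window total
divided by the window length in weeks (cm/week), temperature as the mean of
daily maxima (°C). By default the window ends the day *before* the survey
(exposure strictly precedes outcome); whether the survey day itself belongs
to the window is ambiguous in common usage, so it is a switch
(`include_survey_day`).

Spatial first differences identifies the effect of `WV` on `WT` under the
assumption that *changes* in unobserved confounders between adjacent grid
cells are not systematically related to changes in weather at that scale.
The procedure, per replicate:

1. Within each country survey, find all pairs of occupied cells sharing an
   edge along the chosen axis (west–east for the headline analysis,
   north–south as a robustness check). Orientation is fixed — east minus
   west, north minus south — so replicate estimates are comparable.
2. Within each cell pair, draw the maximum number of disjoint household
   pairs, `min(|A|, |B|)`, uniformly at random. By default a record is not
   reused across different cell pairs within a replicate: cell pairs are
   processed in random order and used records removed
   (`reuse_across_cellpairs=True` relaxes this; with chains of occupied
   cells the realized pair count is then exactly `Σ min(|A|,|B|)`).
3. Difference walk time and exposure within pairs, pool all differenced
   rows across cell pairs and country surveys, and fit one OLS per (window,
   exposure): `ΔWT = β0 + β1 ΔWV`. Temperature and precipitation are fitted
   in separate univariate models. The intercept is retained (a no-intercept
   switch exists): a constant `β0` absorbs any confounder component whose
   adjacent-cell difference is constant — in particular an arbitrary linear
   regional gradient, see below.

Replication re-draws the random pairing (1000× in the headline
configuration; the desk-scale studies here use 200). The point estimate is
the replicate mean; the standard deviation across replicates is reported as
the standard error and the 95% CI is mean ± 1.96·SD. This SD-as-SE
convention measures re-pairing variability around the full-data estimate,
not sampling variability of the underlying survey; it is the aggregation
convention of the replicated-pairing design and is used consistently
("MC SE" below). One master seed spawns independent per-replicate RNG
streams, so runs are bit-reproducible and replicates independent.

Sensitivity variants: `sfd_cell_means` differences (survey, cell)-level
means of outcome and exposure — a single deterministic regression per
window with classical OLS errors, using every record once;
`sfd_binned` replaces each exposure by the indicator of exceeding its
75th/90th percentile (computed once over the analysis set) before pairing —
at desk scale an indicator can have no variation across the drawn pairs, in
which case the degenerate-variation error propagates rather than being
silently skipped; `border_buffer_filter` drops records within 5 km (rural)
or 2 km (urban) of a cell edge, so GPS coordinates jittered for privacy
cannot have crossed a cell border.

## Comparison models

The fixed-effects regression `WT ~ WV + country + county + year + month`
(calendar months, one reference level per block) is a non-causal
benchmark. Fixed effects are absorbed by alternating-projection demeaning;
an explicit indicator-block path exists and agrees with the absorbed path
by the Frisch–Waugh–Lovell theorem (asserted to 1e−6 in the tests).
Standard errors are clustered at the survey cluster with the CR1
small-sample factor `G/(G−1)·(n−1)/(n−k)`, where `k` counts the absorbed
parameters by the exact rank of the fixed-effect design (factors may be
nested). Interaction variants add an urban or electricity modifier and its
product with `WV`, optionally adjusting for wealth. Logistic regressions of
source-type use (raw types, or improved/unimproved under JMP-style
classification) on one exposure with country/year/month controls report
odds ratios per unit exposure; perfect separation raises an explicit error.
Ordinary fits go through statsmodels; the SFD machinery is implemented
here.

## The synthetic data generator

The generator produces the structure the estimator assumes, with known
coefficients, so recovery is checkable exactly.

**Weather.** Daily fields on an edge-aligned 0.5° lattice:
`value(t, cell) = mean + climatology(cell) + seasonal(t) + daily_noise(t, cell)`,
with precipitation rectified at 0. The climatology is a random-direction
**linear regional gradient** plus a **smooth Gaussian field**
(Gaussian-kernel-smoothed white noise on a padded torus, exactly
standardized to unit pointwise variance; padding prevents the kernel from
wrapping into itself and collapsing the field to a constant when the length
scale is comparable to the domain). Daily noise is spatially smooth white
noise at the same length scale, independent across days; seasonality is a
sinusoid. The trend-plus-smooth decomposition mirrors real climate
surfaces (continental gradients plus local structure) and matters
statistically: the gradient gives the exposure large-scale variance that a
large-scale confounder can correlate with in any finite region, while the
smooth short-scale part provides the adjacent-cell contrast that gives SFD
its precision.

**Households.** Clusters are placed uniformly in the extent, all households
of a cluster sharing one GPS coordinate and survey date (as surveys publish
them); countries are vertical bands of the extent, counties 2×2-cell
blocks. Urban status, electricity (household flag; community flag = cluster
maximum), wealth (mildly correlated with electricity), climate zone and
water collector are drawn from configurable probabilities. An optional
jitter mode displaces cluster coordinates uniformly within the privacy
radius (≤5 km rural, ≤2 km urban) to exercise the border-buffer analysis.

**Outcomes.** `WT = α + β_P·P + β_T·T + C(lon, lat) + ε`,
`ε ~ N(0, σ²)`, where P and T are the *linked* exposures at the effect
window — so the generative coefficients are recoverable exactly regardless
of rectification or seasonality. The confounder `C` is an independent
trend-plus-smooth surface (trend share 0.8, length scale 1.5°, amplitude =
pointwise SD in minutes). Its gradient component biases naive pooled OLS
almost surely (the sample correlation of two independent gradients over a
region is bounded away from zero with high probability) yet contributes a
*constant* to every adjacent-cell difference, which the SFD intercept
absorbs exactly; its smooth component has no systematic cross-cell drift
(its mean adjacent-cell difference is zero across surfaces, verified by
simulation) and stays nearly constant at the 0.5° scale. A violation mode
(`confounder_weather_mix`) mixes the temperature climatology into `C`,
breaking the identifying assumption; the tests confirm SFD then becomes
biased. Negative walk-time draws are floored at zero with the floored count
recorded and a warning above 1% — flooring censors the linear model, so the
heavy-confounder study accepts a few percent of censoring rather than
biasing the location of the outcome scale.

Walk times here are a stylized linear model: the generator emulates the
spatial statistics the estimator cares about, not the skewed,
heaped-at-round-numbers distribution of reported walk times, survey
weighting, or real hydrology. Passing tests therefore validate the
estimator's identification and mechanics, not distributional realism.

### Default study conditions

| parameter | default | units | note |
|---|---|---|---|
| extent / cell | 5°×5° at 0.5° | degrees | 10×10 cells |
| weather span | 2015-01-01 – 2016-01-15 | days | 380 days; surveys in final fortnight |
| clusters × households | 100 × 25 | — | 2500 records |
| β_precip (365 d) | −3.5 | min/(cm/week) | effect window 365 d |
| β_temp (365 d) | +0.76 | min/°C | |
| α | 30 | min | |
| noise σ | 12 | min | |
| confounder amplitude | 10 (studies: 20) | min | trend share 0.8, length scale 1.5° |
| tmax | mean 31, spatial SD 2.0, seasonal 2.5, daily SD 1.5 | °C | length scale 0.5°, trend share 0.5 |
| precip | mean 0.30, spatial SD 0.15, seasonal 0.15, daily SD 0.25 | cm/day | rectified at 0 |

These are plausible magnitudes for the region and deliberately favorable to
a desk-scale demonstration: survey walk-time distributions are far more
dispersed, and the published analysis rests on ~10⁶ records where the
replicate SD is correspondingly tiny. The recovery study in the tests and
acceptance script uses 200 replicates; results are aggregated exactly as in
the headline configuration.

## Data preparation conventions

* Exclusions, in order with first-match attribution: missing walk time; GPS
  more than 10 km outside the record's country (distance to the country
  rectangle in synthetic mode, great-circle to the clamped point); survey
  date outside the collection window ± 61 days (a calendar-agnostic "two
  months").
* Source classification: improved = {borewell/borehole, piped, rainwater,
  protected spring, protected well}; unimproved = {bottled, vendor,
  unprotected spring, surface, unprotected well}; "other"/unknown → missing
  (with a warning for unknown vocabulary).
* The ">30 min round-trip" share is computed as `2 × one-way WT > 30`,
  since the survey variable is one-way.
* Real-mode precipitation arriving at 0.25° must be block-averaged 2×2 to
  the 0.5° temperature lattice (`aggregate_to_coarser`) so a single cell
  indexing serves both variables.
* Geodesic distances use a spherical haversine (R = 6371.0088 km); at the
  ≤10 km scales involved the flat/spherical discrepancy is negligible.
* Community electricity is the cluster-level maximum of the household flag
  — a definitional guess, flagged as such.

## Numerical choices and degenerate inputs

* Cell lookup is half-open floor arithmetic; a point exactly on a shared
  edge belongs to the higher-index cell.
* `fit_sfd` refuses a constant differenced exposure ("degenerate exposure
  variation") and fewer than two rows; empty strata are omitted with a
  warning rather than reported as zeros.
* Exposure conservation (`cm/week × weeks = window sum`) holds to 1e−9;
  demeaning convergence tolerance is 1e−12 relative, 500 iterations max.
* Logistic fits flag separation both from the optimizer and from
  coefficient magnitude (>30 on the log-odds scale).
* CIs throughout use the normal 1.96 factor, matching the replicate
  aggregation convention.

## Scenario arithmetic

`weekly_walktime_change(β, Δ, trips, days=7) = β·Δ·trips·days` converts a
one-way per-walk effect into minutes per household per week; with β = 0.76
min/°C, Δ = 4 °C and 4 trips/day this is 85.12 ≈ 85 min/week. The
convention multiplies the *one-way* effect by trips × days; if trips were
counted as round trips the figure would double. Exceedance shifts move each
walk time by β·Δ and recount `2·WT > 30`. Relative precipitation scenarios
("10% less rain") need a mean precipitation level, which is always taken
from the supplied exposure table, never hard-coded.

## Known limitations

* Adjacency is lattice-based; irregular geometries and higher-order
  differencing are out of scope, as are spatial-autocorrelation-robust
  (Conley) standard errors.
* Missing weather days are an error, not imputed; real-data ingestion
  beyond NetCDF-style grids and the CSV household schema is not provided.
* The SD-as-SE convention understates total uncertainty at small n; the
  desk-scale CIs here are honest about re-pairing noise only.
* Survey-weighted estimation and multinomial source-choice models are not
  implemented.
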
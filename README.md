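# flywaykit

Delineation of migratory-bird flyway corridors from location data, and
Bayesian quantification of how those corridors shift and narrow over
decades.

The package was built around the kind of data available for the
Aransas–Wood Buffalo whooping crane population — decades of verified
opportunistic sightings plus a few years of GPS telemetry along a
~3,900-km south–north flyway — but every stage is generic: any two tabular
location datasets (lat, lon, date; plus per-fix velocity for telemetry)
can be pushed through the same pipeline.

## What it computes

**Corridor delineation.** Locations are projected to an equidistant conic
plane (meters) and partitioned into `W` equal-height latitudinal analysis
windows.  Within window `w`, the corridor at core level `L ∈ {50, 75, 95}`
is the band between the symmetric easting percentiles

    [Q_w((100−L)/2),  Q_w(100−(100−L)/2)]

Percentiles estimated separately from sightings and telemetry are combined
as averages weighted by the per-window sample sizes, connected into west
and east boundary lines, and closed into a simple polygon.  Uncertainty
bands come from 1,000 bootstrap resamples of each dataset; the window
height is selected by minimising the polygon's patch fractal dimension
`FRAC = 2 ln(0.25 P) / ln A` among heights whose 95% corridor still
contains 95% of the data.

**Screening and QC.** Only confirmed sightings are used (Canadian records
dated 25 May–20 Aug are excluded as sedentary-season).  Telemetry tracks
pass three sequential per-bird filters — monotone timestamps, displacement
rate ≤ 100 km/h, removal of spike fixes with turn angle < 5° on legs
> 50 km — then ground fixes (velocity ≤ 2.6 m/s) are chained into stopover
sites broken by > 15 km moves; analysis locations are the site centroids
plus all in-flight fixes.

**Trend analysis.** Easting (or distance from the per-window median
centerline) is modelled as `x = α_w + β_w · t + ε`, `t` = years since 1942,
with per-window intercepts and slopes and one shared error variance,
sampled by Gibbs (conjugate normal / inverse-gamma updates).  Inference is
two-stage: a flat-prior fit to the sightings record; its posterior
coefficient means and variances become normal priors for the telemetry
fit, whose posterior is the inferential output.  Per-window slopes are
reported in km/year with 95% credible intervals, alongside bootstrap
median comparisons between the datasets (2010–2016) and predicted
positions for 1980 and 2014.

**Synthetic flyway.** `flywaykit.simulate` generates sightings and
telemetry with known ground truth (centerline drift, side-specific
contraction of half-normal lateral spreads, planted stopovers, optional
planted QC-rule violations), so every stage of the pipeline is testable
end-to-end without any external data.

## Worked example

```python
from flywaykit import (
    CorridorModel, SyntheticScenario, TwoStageTrendModel, assign_windows,
    assemble_migration_locations, classify_flight, cluster_stopovers,
    qc_telemetry, simulate_sightings, simulate_telemetry,
)
from flywaykit.windows import WindowGrid

scenario = SyntheticScenario()   # 13 x 300-km windows, eastward drift 1.2 km/yr,
                                 # west-flank contraction 0.9 km/yr
grid = WindowGrid(scenario.y_south_m, scenario.window_height_m, scenario.n_windows)

sightings, truth = simulate_sightings(scenario, n=5000, seed=42)
fixes, _ = simulate_telemetry(scenario, seed=43)

retained, rejected = qc_telemetry(fixes)
kind = classify_flight(retained["velocity_ms"].to_numpy())
telemetry = assemble_migration_locations(
    cluster_stopovers(retained[kind == "ground"]), retained[kind == "flight"]
)

corridors = CorridorModel(sightings, telemetry, grid=grid).fit(bootstrap=1000, seed=44)
print(corridors.summary().round(3))

opp = assign_windows(sightings, grid)
tel = assign_windows(telemetry, grid)
trend = TwoStageTrendModel(opp, tel, grid).fit(burn=2000, keep=10000, seed=45)
print(trend.slope_table().round(2).head(5))
```

Output:

```
            area_ha  mean_width_km  sd_width_km  min_width_km  max_width_km  frac_index  containment
level
50     4.085962e+07        104.768       28.838        62.420       143.182       1.086        0.495
75     7.340301e+07        188.213       46.709       125.167       266.521       1.064        0.732
95     1.316660e+08        337.605       76.778       221.429       443.451       1.044        0.928

        slope_mean_km_per_year  cl_lo  cl_hi  excludes_zero
window
1                         1.62   1.34   1.90           True
2                         1.79   1.51   2.06           True
3                         1.57   1.29   1.84           True
4                         1.52   1.24   1.80           True
5                         1.25   0.96   1.53           True
```

Reading it: the 95% core corridor is a 131.7-million-ha polygon averaging
338 km wide (narrowest 221 km, widest 443 km), with a near-rectangular
shape (fractal index 1.044) that contains 92.8% of the pooled locations
(the pooled containment sits below 0.95 because the telemetry-era corridor
has drifted east of the 75-year sighting record).  The per-window
positional slopes recover the generated trend — drift 1.2 plus half the
west contraction, 1.65 km/yr — with every 95% credible interval excluding
zero.

The same pipeline runs from the shell:

```sh
flywaykit simulate  --seed 7 --out run/
flywaykit delineate --seed 7 --out run/ --sightings run/sightings.csv --telemetry run/telemetry.csv
flywaykit trend     --seed 7 --out run/ --sightings run/sightings.csv --telemetry run/telemetry.csv
```

writing GeoJSON corridor polygons, per-window edge/slope CSV tables, the
resolved configuration and a JSON run report under `run/`.

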
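# gri-toolkit

Quantifying the resilience of grassland ecosystems — their capacity to
recover from stress — from satellite leaf-area-index (LAI) time series.

Grassland degradation monitoring usually tracks greenness trends; this
toolkit instead measures *recovery behaviour*. From a multi-year stack of
8-day growing-season LAI composites it builds, per pixel and year, a
**Grassland Resilience Index**

```
GRI = Ms / Rt
```

where an *abnormal period* is a run of months with monthly LAI below the
climatological band floor `MEAN_j − β·STD_j` (month-of-year mean and
standard deviation across the record), `Ms` is the depth of the run's
trough below that floor (the maximum stress the system recovered from, in
LAI units), and `Rt` is the number of months from the trough until LAI
re-enters the band. Deep stresses recovered quickly mean high resilience.
Annual attribution follows three rules: event GRI belongs to the year the
recovery began (also when recovery crosses a year boundary), multiple
events in a year are averaged, and event-free years inherit the previous
year's value.

Around that index the toolkit provides the full analysis pipeline used in
regional assessments:

* **`raster_io`** — ASCII-grid / NetCDF raster I/O, grid alignment and
  resampling, and the persistent-grassland mask (grassland in *every*
  year of the land-cover record).
* **`gri_core`** — monthly aggregation, climatology, anomaly detection,
  annual GRI and min–max normalization.
* **`trend_analysis`** — per-pixel Theil–Sen median slope with the
  Mann–Kendall test, classed into six trend types at |Z| = 1.96 / 2.58,
  plus ordinary least-squares slopes for climate layers.
* **`correlation`** — per-pixel Pearson correlation of GRI with annual
  temperature/precipitation, five significance classes and their area
  fractions.
* **`geodetector`** — factor detector of spatial stratified
  heterogeneity: q = 1 − SSW/SST per driving factor (latitude, MAT, MAP,
  GDP, population density), converted to relative contribution rates
  (RCR) summing to 100 %.
* **`synthetic_scene`** — a scene generator with exact ground truth
  (injected anomalies of known depth and duration, trending climate
  surfaces, structured socio-economic layers) so the whole pipeline is
  testable offline.
* **`reporting`** — annual mean series, grade maps and class-area tables.

## Worked example

```python
import numpy as np
from gri_toolkit import (SceneConfig, generate_scene, build_grassland_mask,
                         compute_gri, trend_map, factor_attribution,
                         latitude_layer, annual_mean_series,
                         class_area_table, rollup_trend_areas)
from gri_toolkit.raster_io import FactorLayer

scene = generate_scene(SceneConfig(seed=42))          # 40x40 px, 2000-2021
mask = build_grassland_mask([l.values for l in scene.landcover], grass_code=3)
gri_map, events = compute_gri(scene.stack, beta=1.0, mask=mask,
                              normalization_scope="global")
series = annual_mean_series(gri_map.raw, gri_map.years)
tm = trend_map(gri_map.normalized, scene.grid)
print(rollup_trend_areas(class_area_table(tm.classes, pixel_area_km2=0.25)))
```

prints (seed 42):

```
20349 anomaly events detected on 1360 persistent grassland pixels
mean annual GRI 0.015, overall change +9.75% (+0.443%/yr)
    group  pixels  area_km2   percent
 improved     540    135.00 39.705882
 degraded     569    142.25 41.838235
no_change     251     62.75 18.455882
```

Most detected events are small noise excursions below the band — that is
intrinsic to a one-standard-deviation band (about one month in six dips
below it) — while the 60 deep injected droughts dominate the index. The
roll-up table is the standard improved/degraded/no-change decomposition
of the trend-class map; its percents partition the valid grassland area.
Factor attribution of the mean GRI map works the same way:

```python
factors = [latitude_layer(scene.grid),
           FactorLayer(scene.grid, scene.mat.mean(axis=0), "continuous", "mat"),
           scene.gdp[2010], scene.pd_density[2010]]
att = factor_attribution(np.nanmean(gri_map.normalized, axis=0).ravel(),
                         factors, scene.grid)
```

yielding one `(scope, factor, q, rcr_percent)` row per factor, with RCR
summing to 100 %.

A thin CLI mirrors the library:

```sh
gri-toolkit generate --seed 42 --outdir scene/
gri-toolkit mask --landcover scene/landcover_*.asc --grass-code 3 --out mask.asc
gri-toolkit gri --stack scene/lai_stack.nc --mask mask.asc --outdir gri/
gri-toolkit trend --gri-dir gri/ --outdir trend/
```

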
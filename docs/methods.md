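# Methods

## The resilience index

The index treats resilience as recoverable stress per unit recovery time.
For each pixel, 8-day LAI composites of the May–September growing season
(20 per year, four per calendar month, days 121–273) are averaged to
monthly values. Across the years of the record each calendar month gets a
climatology `MEAN_j`, `STD_j` (population standard deviation by default:
the record is treated as the full reference period, not a sample; the
sample formula is available via `std_mode="sample"`). The *normal band*
is `MEAN_j ± β·STD_j`; only the lower bound matters. With the default
`β = 1.0` (the conventional one-standard-deviation band; the parameter is
mandatory in every output manifest) a maximal run of consecutive months
with monthly LAI strictly below the band floor is an *abnormal period*:

* `Ms` = band floor at the month of the run's LAI minimum minus that
  minimum (LAI units, > 0 by construction);
* `Rt` = observed growing-season months from the minimum (inclusive) to
  the first month back inside the band (exclusive), minimum 1.

October–April is unobserved, so consecutive growing seasons are
concatenated: a September excursion that re-enters the band the following
May has `Rt` counted in observed months only — counting unobserved winter
months would fabricate data. Runs that never re-enter the band within the
record (or that end at a data gap) have undefined `Rt`; they are emitted
with `resolved=False` and excluded from the index.

Annual attribution: each resolved event contributes `Ms/Rt` to the year
its recovery began (this is also the cross-year rule); a year with
several events takes their arithmetic mean; an event-free year inherits
the previous year's value (raw values are carried; normalization comes
after); years before the first computed value stay nodata, because the
carry-forward rule has no donor in year one.

Normalization is min–max to [0, 1]. Two scopes are exposed and recorded
in metadata: `per_year` (each annual map rescaled by its own spatial
extremes — the default for single-year maps) and `global` (one min/max
over the whole cube). Trend analysis must use the global scope (or the
raw cube): per-year rescaling pins every year's extremes to 0 and 1 and
destroys the temporal ordering a trend test needs. A degenerate scope
(all values equal) normalizes to 0 with a logged warning.

Because the band and the data shift together, the event statistics have
clean symmetries that the tests exercise: adding a constant to all LAI
changes nothing; scaling LAI by k > 0 scales `Ms` (hence raw GRI) by k
and leaves `Rt` and normalized GRI unchanged.

## Trend statistics

Per-pixel trends of the (globally normalized) GRI cube use the Theil–Sen
median slope — the median of all C(n,2) pairwise slopes, robust to up to
~29 % outliers — paired with the Mann–Kendall test:

```
S      = Σ_{i<j} sgn(x_j − x_i)
Var(S) = n(n−1)(2n+5)/18
Z      = (S−1)/√Var(S)   if S > 0;   0 if S = 0;   (S+1)/√Var(S) if S < 0
```

(the usual ascending-pair convention and continuity-corrected Z). Classes
combine the slope sign with |Z|: ≥ 2.58 extremely significant, ≥ 1.96
significant, otherwise modest, separately for improvement (slope > 0) and
degradation (slope < 0); an exactly zero slope is no-change. A tie
correction for Var(S) (−Σ t_k(t_k−1)(2t_k+5)/18) is off by default but
available — relevant because the carry-forward rule manufactures tied
years. Climate-element trends use the closed-form least-squares slope
against the year index instead; both estimators coincide on noiseless
lines, which the tests check. Missing years are handled per pixel by
complete-case subsetting; fewer than 3 valid years (2 for OLS) is nodata.

## Correlation with climate

Per pixel, the annual GRI series is paired complete-case with the annual
climate series and summarized by the Pearson coefficient. The paper-style
significance classes (p < 0.05 and 0.05 ≤ p < 0.1, each signed, plus
nonsignificant) need a test; the standard two-sided t on n−2 degrees of
freedom, `t = r√((n−2)/(1−r²))`, is used. The five classes are mutually
exclusive, so their area fractions partition the valid area — the
remainder beyond the four signed classes is reported explicitly as
`nonsignificant` rather than left implicit. Under the null the two signed
p < 0.05 classes together cover 5 % of pixels, verified by Monte Carlo.

## Geographical detector

The factor detector measures how much a categorical stratification of
space explains the GRI surface: `q = 1 − Σ n_i σ_i² / (n σ²)` with
population variances throughout (the decomposition `1 − SSW/SST` is exact
only with matching variance conventions, giving q ∈ [0, 1] identically).
Continuous factors are discretized first; the default is quantile
stratification with m = 5, the community default, which keeps strata
populated; equal-interval and a 1-D k-means variant of natural breaks are
available, and the choice is logged per run. Strata of size one
contribute zero within-stratum variance yet count toward n — they inflate
q, so a warning is raised. Per-factor q values are compared through the
relative contribution rate `RCR_i = q_i/Σq_j × 100 %`. The classical
F-test of the factor detector is not part of the reported method; an
optional permutation p-value for q is provided instead and is clearly an
extra diagnostic. Attribution runs per scope (whole region and optional
sub-regions, skipping scopes under 30 valid pixels) and per epoch; the
response is a single GRI map (one epoch's, or the multi-year mean for
spatial-distribution analysis).

## Grid handling

All analysis runs on the LAI grid. Finer categorical layers (land cover)
aggregate up by `fraction_threshold` with the convention *grass iff grass
fraction ≥ t* (default t = 0.5); coarser continuous layers (climate,
GDP, population density) come down by bilinear interpolation. Pixels are
row-major with row 0 at the north edge, and any pixel missing in any
input layer is excluded from every statistic (complete-case). The
latitude factor is synthesized from the grid geometry itself, so it is
reproducible from georeferencing alone. The persistent-grassland mask is
true only where the pixel is grassland in every land-cover year — adding
a year can only shrink it, a monotonicity property under test. Rasters
are single-band ESRI ASCII grids (text, with a JSON label sidecar for
class maps) and CF-style NetCDF-3 stacks; both round-trip bit-exactly.

## The synthetic scene

The generator emulates the statistical structure of the real inputs, not
their sensor physics. Defaults define the study conditions: a 40×40
scene, 22 years × 20 composites (440 planes), β = 1, a smooth seasonal
cycle `LAI = 0.4 + A·sin(π(m−4.5)/5)` peaking in July with amplitude
A ≈ 1.2 increasing northwards, additive Gaussian composite noise with
σ = 0.06 (~5 % of the amplitude), 60 injected anomaly events with depths
0.3–0.7 LAI and durations 1–4 months, 85 % of pixels persistently
grassland, linearly trending climate surfaces with latitudinal
(temperature) and longitudinal (precipitation) gradients, and
blob-structured GDP/population surfaces growing across epochs.

Injection is exact, not approximate: carving an event into a pixel-month
lowers that month's own climatology, so the designed values are solved by
fixed-point iteration per pixel until the *final* band floor minus the
trough equals the requested depth to ~1e-13. The trough sits at the event
start, the run recovers linearly below the floor, and the month after the
run is pinned at the seasonal baseline so the designed `Rt` is
unambiguous. Random placement enforces two feasibility guards: the trough
must stay below every run month's floor (seasonally varying floors
otherwise relocate the minimum), and it must undercut the pixel's lowest
monthly baseline by ≥ 0.12 LAI (4 composite-noise standard deviations) so
no noise dip in a neighbouring month can merge into the run and steal the
minimum. Composite noise is centred within event months, leaving designed
monthly means intact. The ground-truth table is produced by running the
package's own aggregation and detection on the noise-free stack, so at
σ = 0 pipeline output equals truth bit for bit, while designed depths are
independently checked to 1e-9.

What the generator does **not** emulate — and therefore what passing
tests do not establish about real data: sensor artifacts, cloud
contamination and retrieval noise structure (real LAI noise is neither
Gaussian nor independent), spatially correlated droughts spanning many
pixels, phenological shifts between years, mixed pixels at grassland
edges, and any coupling between the injected events and the climate
surfaces (the default scene's GRI–climate correlations are null by
construction).

## Numerical choices and limitations

* Monthly aggregation is the arithmetic mean of valid composites; a
  month with no valid composite is nodata, and a data gap terminates an
  abnormal run as unresolved rather than guessing.
* Climatology needs ≥ 2 valid years per pixel-month; trend needs ≥ 3
  years; correlation needs ≥ 3 paired years and non-constant series
  (constant series yield nodata with a warning).
* A one-standard-deviation band flags ~16 % of ordinary months as
  (shallow) anomalies under any roughly Gaussian interannual variation;
  the index tolerates this because shallow events carry small Ms, but
  event *counts* are therefore not comparable across β values.
* Test problem sizes (40×40 scenes, 10,000-series null suites, 200-
  instance brute-force comparisons) keep the full suite at a few seconds
  while leaving Monte-Carlo tolerances at 3 binomial standard errors.
* Raster support is deliberately minimal: axis-aligned north-up grids,
  equality-checked CRS strings, no reprojection. Harmonizing projected
  inputs is upstream work.
* The min–max normalization makes normalized values relative to the
  scene; cross-study comparisons should use raw GRI (LAI/month units).
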
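# Methods

This note records the modelling choices behind `lurkit`: what each stage
assumes, which parameters matter, what the synthetic scenes do and do not
emulate, and where the design was genuinely open.

## Data model and aggregation

Stations are identified points in a single projected planar CRS
(coordinates in metres); no geodesic computation occurs anywhere, so
real-data users must project longitude/latitude beforehand.  Daily
measurements are aggregated to annual (or monthly) station means; a
station-period is retained only if the fraction of calendar days with a
valid ozone value reaches the `completeness` threshold (default 0.75, the
common regulatory convention).  Each variable's mean uses the days on
which that variable is present, so covariate gaps do not discard ozone
information.  Modelling is annual: buffer predictors are static in time,
so a finer temporal resolution would only re-use the same spatial
contrasts.

Mixing-ratio to mass-concentration conversion uses
`μg/m³ = ppb × M / V_m` with M = 48.00 g/mol for ozone and
V_m = 24.45 L/mol (25 °C, 1 atm), both overridable.

## Buffer extraction

All disk tests use the closed boundary (distance ≤ r), making values at
exact boundaries deterministic.  The default radius ladder is
{25, 50, 100, 250, 500, 750, 1000, 1250, 1500, 1750, 2000, 2500, 3000,
3500, 4000, 4500, 5000} m; `dense_radii(step)` provides the full 25 m
grid for users who want it (it multiplies the candidate count ~12× while
adding near-duplicate columns, so the coarse ladder is the default).
Per primitive:

- **point counts** — exact Euclidean test;
- **line lengths** — exact per-segment clipping: the squared distance to
  the centre is quadratic in the segment parameter, so the in-disk
  interval comes from the roots of |p₀ + t·d − c|² = r²; zero-length
  segments contribute nothing;
- **polygon areas** — the layer's polygons are unioned once (never
  double-counting overlaps), then intersected with a regular 256-gon
  disk.  The inscribed-polygon area error is ≤ (2π/256)²/6 ≈ 1×10⁻⁴
  relative, inside the documented 0.05 % bound;
- **raster means** — mean of cell values whose *centres* fall in the
  disk (the common zonal-statistics default; area-weighting is out of
  scope).  No qualifying centre yields a missing value, and a disk
  entirely outside the extent additionally warns.

Static layers are treated as time-constant across all study years.

## Selection

Ordinary least squares is computed by `numpy.linalg.lstsq` with classical
t-test p-values; the test suite cross-checks estimates, p-values and VIFs
against statsmodels, and against longhand normal equations.  Degenerate
conventions: a constant response defines R² = 0; a zero-residual fit
gives p = 0 for nonzero coefficients; rank deficiency raises an error
naming the collinear columns.

The forward procedure seeds with the highest-R² direction-consistent
univariate candidate and then, each round, evaluates every remaining
candidate added alone to the current model.  Admissibility requires
p < `p_enter` (0.1), own-sign correctness, sign stability of previously
entered constrained terms (configurable off), and all VIFs <
`vif_max` (3).  The largest adjusted-R² gain wins; ties break by smaller
p, then lexicographic name, so selection is fully deterministic.  Entered
terms are never removed — real LUR tables retain terms whose p later
drifts above the entry gate, which is evidence against a backward pass.
"Incremental R²" is the gain in R² recorded when a term entered; the
values sum to the final R² by construction.  Adjusted-R² gain (not raw
R²) is the ranking criterion because raw R² cannot distinguish a genuine
contribution from the mechanical gain of any added column.

Missing data policy at fit time: rows with a missing response are
dropped; candidate columns that are constant or contain missing values on
the remaining rows are excluded from the pool.  Excluding (rather than
row-deleting) keeps every candidate comparison on one common row set, so
adjusted-R² gains are comparable across candidates.

The response may be fitted as-is (default) or log10-transformed
(`response_transform="log10"`), in which case predictions are
back-transformed to concentration units.

## Validation

Folds partition *stations*, never rows: all years of a held-out station
leave the training set together, so the CV statistic measures transfer
to unmonitored locations rather than interpolation between years of a
known site.  By default the entire selection procedure is re-run on each
training split ("reselect"), charging the CV statistic for selection
optimism; "refit" mode re-estimates a fixed term set for comparison.
Pooled CV R² is the squared Pearson correlation between pooled
out-of-fold predictions and observations; since this convention is not
universal, 1 − SSE/SST on the same pooled vectors is always reported
alongside.  External validation selects and fits on all periods strictly
before the holdout year and evaluates on the holdout rows only.

## Surface prediction

The fitted model is a pure function of location: buffer terms are
re-extracted at every grid-cell centre with the same engine used at the
stations.  Station-measured covariates have no observed value at
arbitrary cells, so the module requires one raster per covariate column
and ships an inverse-distance-weighting helper (power 2, all stations) to
build them from station values.  IDW is a deliberate, clearly separable
modelling choice, not part of the LUR model itself; cells with any
missing input receive the nodata sentinel.  Margins are computed as if
the supplied layers were complete beyond the data extent.

## Synthetic scenes

A scene emulates the statistical landscape the analysis assumes, on a
50 km × 50 km region with 73 stations in the six-class mix of a national
network (56 general, 5 traffic, 4 industrial, 2 national-park,
4 background, 2 other):

- temples (0.8 /km²) and cemeteries/crematoria (0.06 /km²) as homogeneous
  Poisson point processes — the temple intensity reflects the urbanized
  densities monitoring networks oversample rather than a whole-country
  average;
- power plants (10) and incinerators (20) as sparse point sources used
  via nearest-distance;
- major (150) and local (400) roads as random segments of 1–8 km;
- residential/industrial/forest/crop land use as random axis-aligned
  rectangles with field-plausible size ranges;
- an NDVI-like greenness field: a sum of 12 random plane-wave cosines
  with 5–25 km wavelengths on a 250 m grid, scaled to mean 0.45,
  SD 0.15;
- covariates per station-year: NOx = 18 + 6·z(road length @ 1 km) +
  year effect + noise (the titration *correlation* structure — no
  photochemistry is simulated), temperature ~ N(23, 1.5) °C,
  RH ~ N(75, 5) %.

The response is `intercept + Σ β_j x_j + N(0, σ)` with the x_j taken from
the buffer engine itself, so generation exercises the extraction path.
The default planted model gives NOx a 0.54 variance share and five
further terms small shares (0.08, 0.05, 0.04, 0.03, 0.02), mimicking the
"one dominant then a small tail" incremental-R² profile of national LUR
models; coefficients are solved from the shares so the total signal SD is
4 ppb around a 28 ppb mean, and σ is solved from
`var(signal)·(1 − R²)/R²` for a population R² of 0.75.  Replicate seeds
derive from a base seed by the counter scheme `base·1000 + i (mod 2³¹)`.

What the scenes do **not** emulate: real geography (clustered cities,
coastlines, mountain ranges), atmospheric chemistry or transport,
land-use survey vintages, monthly dynamics, and spatially correlated
measurement error.  Consequently, passing recovery tests shows the
*procedure* is sound under its own assumptions — unbiased extraction, a
linear signal, independent noise — not that a real archive would yield a
model of similar quality.

## Identifiability and the exactness regime

Adjacent radii of one layer are highly correlated, and greedy selection
with a VIF gate is not guaranteed to pick the exact planted radius: once
a neighbouring radius enters, the true column is often blocked
(correlation > 0.82 implies VIF > 3).  This is the dominant error mode in
recovery experiments and is intrinsic to buffer-ladder LUR, not an
implementation artifact.  The noiseless-exactness demonstrations
therefore use `identifiable_scene_config()` — the full 73-station network
but a single-radius ladder per layer — in which no candidate nearly
duplicates a planted term and the pipeline recovers the truth to machine
precision (CV and external R² = 1 within 1e-9).  At small station counts
chance correlations re-introduce the blocking effect even there, which is
why that configuration keeps the full network size.

## Problem sizes and numerical choices

The reference experiment is 20 replicates of the full scene (584
station-years, ~152 candidates) with site-grouped 10-fold CV per
replicate; unit-level checks use a 15 km, 16-station scene with an
11-radius ladder.  Tolerances: buffer line-length oracle agreement to
0.5 % (dense sampling at 1 cm); polygon areas to 3 Monte-Carlo standard
errors of a 10⁶-point oracle plus the 5×10⁻⁴ disk-polygonization bound;
raster means and point counts exact; incremental-R² conservation and
noiseless CV exactness at 1e-9.  Serialized scenes, models and reports
are byte-stable for fixed configuration and seed (floats via shortest
round-trip repr, keys sorted).

## Known limitations

- Greedy selection inherits the usual forward-selection caveats: p-values
  of selected terms are optimistic (no multiple-testing correction is
  applied, matching field practice), and the selected radius of a true
  layer can be off by one ladder step.
- The squared-Pearson CV convention ignores calibration (a biased but
  correlated predictor scores 1); the 1 − SSE/SST value reported
  alongside is the stricter measure.
- IDW covariate rasters smooth station covariates; surfaces inherit that
  smoothing in the covariate-driven component.
- Monthly aggregation is supported in the data layer, but modelling is
  annual by design (static predictors cannot resolve months).
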
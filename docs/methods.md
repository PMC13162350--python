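# Methods

## Model

The analysis treats a crop's climatic viability as an empirical envelope
question. Baseline monthly climate (mean temperature °C, precipitation
mm/month) is aggregated to annual values per grid cell: `T_ann` is the
unweighted mean of the twelve monthly means, `P_ann` the sum of the
twelve monthly totals. The **safe climate space** (SCS) of a crop is the
smallest region of the (`T_ann`, `P_ann`) plane containing at least a
coverage target (default 0.95) of the crop's baseline production mass;
the excluded tail represents marginal, low-yield cultivation. Future
climates — per-model monthly cubes averaged into a multimodel ensemble
mean, then annualized — are classified cell-by-cell: a cell is *outside*
the SCS when it exceeds either the temperature or the precipitation
limits (bounds inclusive: a value exactly at a limit is inside).
Exposure for a crop × region × scenario × period is the
production-weighted share of the region's cells classified outside.

Two envelope geometries are shipped because "the region containing 95% of
production" does not by itself determine a shape:

- **rectangular** (default): per-axis production-weighted quantile bounds
  at a symmetric tail mass α/2 per side, with α found by bisection so
  joint coverage is the smallest value ≥ target, followed by a greedy
  per-axis tightening to the next-inner distinct weighted-quantile
  candidate while coverage stays ≥ target. The greedy pass makes the
  envelope *minimal*: moving any single bound one candidate inward drops
  coverage below the target. Rectangular is the default because the
  classification rule names per-axis limits.
- **density**: a 2-D production-weighted histogram (default 100×100
  bins over the data range), bins retained in descending order of mass
  (ties broken by bin index) until cumulative mass reaches the target.
  This yields a tighter, possibly disconnected region; values outside
  the histogram's range are outside by definition.

Exceeding the envelope does not model yield: it flags where conditions
depart from the historical growing climate, with no adaptation, cultivar
change or CO2-fertilization response.

### Weighted quantile convention

All weighted quantiles (envelope bounds, three-class thresholds) use the
left-continuous inverse CDF: the smallest data value whose cumulative
mass reaches `q`·total, ties toward the smaller value. Results depend on
this convention at discrete mass points, so it is fixed package-wide.

### Holdridge life zones

As descriptive context, each cell is assigned a life zone on the two
axes the SCS carries: biotemperature (monthly temperatures clamped to
[0, 30] °C *before* averaging — the standard convention; the clamping
order matters and is fixed here) with log2-spaced class edges
{1.5, 3, 6, 12, 24} °C, and annual precipitation with edges
{62.5, 125, 250, 500, 1000, 2000, 4000, 8000} mm. Intervals are
half-open (low, high]; an exact edge value takes the lower class. The
potential-evapotranspiration axis of the full Holdridge triangle is not
used, and life zones do not enter the SCS classification.

### Carbon accounting

Cropland NPP is the literal four-factor product
`production × f_dry × f_shoot × f_carbon` (tonnes → Tg C via 1e-6). The
alternative harvest-index reading — dividing by `f_shoot` to scale
harvested mass up to whole-plant NPP — is available as
`shoot_as_divisor`; neither is asserted as the "right" reading, and the
default follows the multiplicative form. The per-crop fractions are
feedstock properties (dry-matter fraction of fresh harvest, shoot
allocation, carbon content of dry matter); the shipped defaults are
documented placeholders in literature-plausible ranges (e.g. grain
dry-matter ≈ 0.87–0.90, cassava roots ≈ 0.35, sugarcane stalks ≈ 0.30,
carbon fraction 0.45) and should be overridden from config for any
quantitative use. Negative-emission potential equals cropland NPP times
a capture efficiency defaulting to 1.0 — i.e. potential is crop carbon
uptake; life-cycle discounts are out of scope. Natural-vegetation NPP on
mixed cells is total NPP minus cropland NPP, clipped at zero with the
clip count reported, since differencing independently estimated rasters
can go negative and silent negatives would corrupt per-area summaries.
The projected loss of potential is `1 − Σ potential inside SCS / Σ
potential`, over a region, per scenario × period.

### Trade-off classification

Continuous layers are rescaled to percent of maximum and cut at the 25th
and 75th percentiles into low (< p25), medium (p25–p75 inclusive) and
high (> p75). These cut points give ≈ 25/50/25 cell shares — *not* equal
thirds; the implementation follows the stated percentile breaks and
documents the discrepancy rather than silently substituting terciles
(a `terciles` option provides a genuine 33.3/66.7 split). Threshold ties
go to medium. Percentiles are unweighted by default; cell-area weights
are available. Two class rasters combine into a 3×3 bivariate code
raster with an explicit legend. Regional summaries are area-true:
latitude-dependent cell areas come from the spherical-cap formula
`R²·Δλ·(sin φ_top − sin φ_bottom)` with R = 6371 km, and densities are
`(Σ stock / Σ area) × 100 km²`.

## Synthetic data: what it emulates and what it does not

The generator emulates the *structure* of the real inputs — regular
lat/lon grids, monthly stacking, multimodel spread, spatially
autocorrelated production concentrated in a climatic envelope, shared
nodata ("ocean") regions — not their physics. Random fields are smoothed
white noise (Gaussian kernel, width in cells, default σ = 2 for climate
and 1.5 for production/ecology), the simplest autocorrelated field with
a controllable length scale. Defaults define the study conditions:

| parameter | default | meaning |
|---|---|---|
| grid | 50×50, 30°S–30°N, 30°W–30°E | desk-scale, tropics mask and area weighting both exercised |
| equator T / gradient | 27 °C, 0.25 °C per °lat | domain spans ≈ 19.5–27 °C |
| equator P / gradient | 2000, 25 mm/yr per °lat | ≈ 700–2000 mm/yr |
| T noise / P noise | 1 °C / 250 mm | smooth spatial anomalies |
| n_models | 14 | multimodel ensemble size |
| inter-model sd | 0.3 °C | scalar per-model offset, shared across periods |
| scenarios | "2C" → +2.0 °C, "2.5C" → +2.5 °C by 2081–2100, four 20-year periods | warming ladders with mild drying |
| frac_outside_baseline | 0.05 | production mass planted beyond the true bounds, mirroring the trimmed 5% |
| ocean fraction | 0.2 | shared nodata mask |

Crop production is planted against known true envelope bounds: inside
cells share `1 − frac_outside` of the mass (log-normal smoothed
weights), cells beyond a margin buffer (10% of the bound width) hold the
rest, and a buffer strip stays empty so the two populations are
separated in climate space. Totals are conserved to ~1e-15 relative and
the outside fraction is exact by construction; every recorded truth is
recomputed from the generated rasters by direct inspection, never copied
from the request.

Planted-truth recovery uses a dedicated configuration: no
baseline-outside mass and *anchor cells* pinning 6% of mass at each of
the four climatic extremes of the inside population. Any single-bound
shrink then removes > 5% of mass, so the fitted 95% envelope coincides
exactly with the production hull and planted future outside fractions
(built by warming a mass-selected cell set beyond the upper temperature
bound) are recovered essentially exactly. The same configuration is used
for the warming-monotonicity checks: with the lower temperature bound at
the hull, uniform warming can only push cells past the *upper* limit, so
the outside share is non-decreasing in the warming magnitude. With an
arbitrary trimmed envelope this monotonicity can fail — cells below the
fitted lower bound re-enter the envelope as they warm — which is a real
property of envelope classification, not an artifact.

What passing tests on synthetic data do **not** show: realism of GCM
physics, bias correction, downscaling, crop calendars, irrigation, or
the actual climate sensitivity of any crop. They show the *method* is
correct: envelopes cover what they claim, classification matches the
stated rule, exposure recovers planted truth, accounting identities hold.

## Numerical choices

- Nodata is NaN in memory, a sentinel (−9999, declared in metadata) on
  disk. Nodata propagates: any missing month → missing annual cell; an
  ensemble-mean cell is missing iff any member is missing (keeps the
  effective model count uniform across cells). Production sitting on
  nodata climate is excluded from fitting and from the coverage
  denominator, with the excluded mass recorded on the envelope model.
- Envelope bisection runs 60 iterations on the tail mass (resolution
  ≈ 1e-18, i.e. exact at double precision); the greedy polish operates
  on distinct data values only.
- Classification bounds are inclusive on both sides; ensemble averaging
  precedes annualization (the operations commute, the order is fixed for
  reproducibility).
- Determinism: every generator draw order is documented; identical
  (seed, config) reproduce all CSV outputs bit-identically.
- The planted-future mode supports exactly one crop per run: one shared
  future climate cannot plant independent outside fractions for several
  crops simultaneously.
- Grid alignment assigns source cell centers to target cells:
  `nearest` for classes/masks, area-weighted `mean` for stocks,
  mass-conserving `sum` for production.

## Problem sizes

Tests and the acceptance script run the full study on the 50×50 default
grid (8 crops × 2 scenarios × 4 periods × 14 models), randomized envelope
checks on point sets up to n = 500, classification oracles on 100 random
50×50 grids, and recovery over 5 seeds × 4 planted fractions; the whole
suite completes in a few seconds on one CPU.

## Known limitations

- The rectangular envelope's per-axis bounds need not coincide with the
  true planted bounds when outside mass is asymmetric across axes: the
  fit may retain light outside mass on one axis and trim elsewhere
  (coverage, not geometry, is the contract).
- GeoTIFF support covers north-up, cell-center-registered WGS84 lat/lon
  rasters with the standard georeferencing tags; no projections, no
  rotation.
- NetCDF files use the classic format (scipy backend).
- Ecology layers are affine maps of smoothed Gaussian fields; their
  marginal distributions are not calibrated to real AGB/richness
  distributions, only their ranges, spatial autocorrelation and mutual
  correlation are controlled.
- Exposure treats production as fixed at baseline: no land reallocation,
  no yield response, no adaptation.
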
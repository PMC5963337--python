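# Methods

## Overview

`demogrid` estimates annual live births and pregnancies per ~1 km grid
cell. The chain is: population surface → women by reproductive age group
(via per-admin-unit proportion tables) → age-specific fertility rates from
the best available source → births per cell → uniform per-country rescaling
to national totals → pregnancies via per-country pregnancy-to-birth ratios.
Every stage is a pure function of grids and tables; the package ships a
synthetic-data generator that produces all inputs under known truth, so the
whole chain is testable with no external data.

## The master lattice

All grids use 30 arc-second cells (1/120°) in WGS84, anchored at
(−180°, +90°); a grid's origin must sit an integer number of cells from the
anchor (tolerance 1e−9°). Inputs off the lattice are **rejected, not
resampled**: the pipeline's core guarantee is count conservation, and any
resampling would silently break it. Cell membership is by cell centre and
values are area-independent counts (persons per cell), so no area weighting
appears anywhere. Arithmetic between grids masks a cell when either operand
is masked; masked values never enter sums.

GeoTIFF I/O is implemented on `tifffile`, reading and writing the standard
georeferencing tags (ModelPixelScale, ModelTiepoint, an EPSG:4326 GeoKey
directory) and the GDAL_NODATA convention — counts and rates as float64,
zone/country codes as int32.

### Nibble (nearest-valid allocation)

Zone rasters standardized to a country extent may leave cells without a
zone id. `nibble` assigns each such target cell the id of the nearest
assigned cell, with distance Euclidean in cell units and squared distances
computed in integer arithmetic, so the operation is exact. Ties are broken
by row-major scan order of the candidate source cells — a deterministic
rule chosen so the operation is exactly reproducible (geodesic distance
would change almost nothing at these scales but would forfeit exactness).
Already-assigned cells are never altered, which also makes the operation
idempotent. The implementation is a chunked vectorized search (memory-
bounded), not a distance transform, because library distance transforms do
not document their tie-breaking.

## Age–sex structure

The standardized table carries, per admin unit, both-sex proportions for
fourteen 5-year age groups (0–4 … 65+) and the overall male/female shares.
Women in group *g* are `pop · t_g · prop_f_t`: the sex ratio is applied as
an age-invariant factor because the standardized schema carries no
age-by-sex cross-tabulation; this is the only computation the table
supports, and it preserves the telescoping identity
`Σ_g t_g · (prop_m + prop_f) = 1`, which the layer-sum verification
exploits. Fractional persons are kept throughout — rounding would break
conservation under later rescaling. Row invariants (age proportions sum to
1, sex shares sum to 1, entries in [0,1]) are enforced at 1e−6.

## Women-years ASFR estimation

Given birth histories (woman's birth date, interview date, children's
birth dates, all as century-month codes cmc = 12·(year−1900)+month, plus
region, urban/rural stratum and a sampling weight):

* **Window**: the `window_months` (default 36) calendar months ending the
  month before interview; the interview month is excluded. Endpoint
  conventions are not universal; this one matches standard retrospective
  survey practice and makes the estimator an exact function of integers.
* **Age convention**: completed age, `(cmc − dob_cmc) // 12`, both for
  classifying a birth (mother's age in the birth month) and for exposure.
* **Exposure**: a woman contributes weight/12 woman-years to the group of
  her completed age for each window month in which that age is 15–49;
  months below 15 or above 49 contribute nothing.
* **Weights** multiply numerator and denominator alike (ratio estimator).
* Cells with zero exposure are reported absent (NaN), never zero.

Internally the denominator is accumulated as weighted month *counts* and
divided by 12 once at the end, so an independent woman-month enumeration
reproduces numerators and denominators exactly (no float-order effects);
the test suite holds the estimator to bit-exact agreement with such an
oracle.

Registered-births ASFRs are the elementwise quotient of births by age
group over the female denominators taken from the gridded age-sex
surfaces; denominators are used as given (no year-matching is attempted).
Zero births with zero women yields rate 0; positive births over zero women
is an error.

### Source hierarchy

`select_fertility_source` ranks: subnational ASFR with urban/rural split >
subnational ASFR > registered births by age group > national ASFR > crude
birth rate — age detail first, then spatial detail. The order is a pure
total order on the source tag; equal ranks resolve to the earliest listed.
Rates above 0.5 births/woman/year trigger a warning (range check), not an
error. Crude birth rates are stored births per person-year; the CLI accepts
per-1000 behind an explicit flag since most sources print per-1000.

### Rasterization

ASFRs are painted as constants over each region (and stratum). A cell is
urban when the urban-extent mask value ≥ 0.5 — a threshold rather than a
strict binary test so fractional masks are usable. Regions with an urban
row but no rural partner are rejected. The output's value set is exactly
the table's rates; no interpolation is ever introduced.

## Births and rescaling

`births_from_asfr` is the cellwise sum over the seven groups of women ×
rate; `births_from_cbr` multiplies the full population surface by the
crude rate. Each country is then rescaled by the single uniform factor
`target / pre_total` to its national annual-births estimate, treated as an
opaque annual target; countries without a target keep factor 1 (absent is
recorded explicitly, never as zero). A zero pre-total with a nonzero
target cannot be fixed by a uniform factor; it is flagged in the scale
report rather than redistributed, preserving auditability. Scaling is
idempotent (all factors 1 within 1e−12 on a second pass) and conserves
per-country totals to ≤1e−9 relative.

`compare_pre_adjustment` regresses pre-adjustment country totals on the
targets (least squares; countries with targets only) and reports R² — the
standard diagnostic of how far subnational sources drift from the national
series.

## Pregnancies

A country's pregnancy-to-birth ratio is
`(live_births + stillbirths + miscarriages + abortions) / live_births`,
built from the national components table (the live-births figure supplied
there, not the gridded total), hence ≥ 1 by construction. Countries
without components borrow the ratio of the nearest country with them —
minimum great-circle (haversine) distance between centroids, ties to the
lower country code. "Nearest by centroid distance + deterministic tie"
is a package design choice where several notions of geographic proximity
(adjacency, regional grouping) would be defensible; it makes fallback
provenance total and testable. The ratio multiplies the births surface
cellwise, so pregnancies dominate births pointwise and per-country totals
are exactly ratio × births totals. Gestation-length weighting (pregnant
women at a point in time) is out of scope.

## Synthetic worlds

`make_scenario` lays countries out as vertical stripes and zones as
horizontal bands inside them, with a one-cell nodata margin; defaults are a
48×72 window, 3 countries × 3 zones. Per-cell population is log-normal
(μ=3, σ=1 on the log scale, ~31 persons/cell median-ish skewed), mimicking
skewed settlement counts. Age proportions are Dirichlet draws around a
young-skewed pyramid; female share uniform on [0.49, 0.52]. True ASFR
schedules jitter a base schedule (default (0.05, 0.15, 0.18, 0.14, 0.09,
0.04, 0.01), peaking at 25–29) by ±20% per zone, with urban rates ×0.85
and rural ×1.15. Crude birth rates draw from [0.02, 0.04] per person-year.
National targets are the analytically expected pre-scaling totals times
log-normal noise (log-sd 0.05); one country's target is absent by default
to exercise the factor-1 path, and one country lacks pregnancy components
to exercise the fallback. Component magnitudes (stillbirths 0.5–3%,
miscarriages 8–15%, abortions 5–30% of live births) bracket published
national ranges. Everything derives from one seed and is byte-
deterministic on disk.

Birth histories are simulated by the mechanism the estimator inverts: all
women share one interview month, ages at interview uniform over 15–49
completed years, and each month from age 15 to the month before interview
carries an independent birth probability ASFR(current group)/12. No twins,
no postpartum infecundity, no mortality or migration: the monthly Bernoulli
hazard is the simplest mechanism whose women-years estimand equals the
input schedule, which is what recovery tests need. Passing tests therefore
show the estimator and plumbing are correct under the model's own
assumptions — they say nothing about date displacement, omission, or
heaping in real survey data, nor about spatial autocorrelation of
fertility, which the generator does not emulate.

## Problem sizes and numerical choices

Default test scenarios use 48×72 to 48×142 grids with 3–10 countries, and
recovery experiments use 4 regions × 10,000 women over a 36-month window —
sizes at which every stage completes in seconds while leaving estimator
standard errors small enough (≈0.002–0.006 per group) for meaningful
recovery checks. Conservation assertions use relative 1e−9 (scaling) and
1e−12 (idempotence, regression oracle agreement); lattice alignment uses
1e−9°; age-sex table invariants 1e−6. Recovery checks use 3 binomial
standard errors computed from observed exposure. Degenerate inputs are
errors, not silent defaults: empty clip selections, unfillable nibbles,
missing table rows (named by id), zero denominators with nonzero
numerators, and sub-2-point regressions all raise typed exceptions.

## Known limitations

* The sex split is age-invariant; where age-by-sex cross-tabulations exist
  they cannot be expressed in the standardized schema.
* The pregnancy ratio is national; subnational variation in stillbirth or
  abortion rates is not modelled.
* No uncertainty quantification: outputs are point surfaces.
* No temporal interpolation between source years; each table is used as
  dated.
* Imputed/displaced survey dates are taken at face value; only the exact
  women-years ratio on the given codes is implemented.
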
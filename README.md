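# demogrid

High-resolution (~1 km) gridded estimates of annual **live births** and
**pregnancies**, built by combining a gridded population surface with
subnational age–sex structure and whatever fertility data a country has —
survey birth histories, registered births by mother's age, national
age-specific fertility rates, or just a crude birth rate.

These surfaces are the denominators of maternal and newborn health metrics:
planning skilled birth attendance, estimating populations at risk during
outbreaks that threaten pregnant women, or computing subnational coverage
indicators all need to know *where* births and pregnancies happen, not just
national counts.

## The method

All layers live on a fixed global lattice of 30 arc-second cells (1/120°,
~1 km at the equator) anchored at (−180°, +90°) in WGS84. Inputs off this
lattice are rejected, never resampled — every stage conserves counts.

For each admin unit the standardized age–sex table carries the both-sex
proportion *t_g* in each 5-year age group and the overall female share
*p_f*. Women aged in group *g* in a cell are

    W_g(cell) = pop(cell) · t_g(zone(cell)) · p_f(zone(cell))

for the seven reproductive groups *g* ∈ {15–19, …, 45–49}. Summing all
age×sex layers reconstructs the population surface exactly — the built-in
verification (`verify_agesex_layers`).

Age-specific fertility rates (ASFR, annual births per woman) come from the
best available source, in this order: subnational ASFRs split urban/rural >
subnational ASFRs > registered births by age group (divided by the gridded
female denominators) > national ASFR vector > crude birth rate (CBR).
From survey birth histories ASFRs are estimated by the retrospective
**women-years** method: over the 36 calendar months before interview,

    ASFR_a = (weighted births to mothers of completed age in a)
             / (weighted woman-years lived at ages in a)

with all date arithmetic in century-month codes (cmc = 12·(year−1900) +
month), so ages in months are exact integers.

Births per cell are then `Σ_g W_g · ASFR_g` (or `pop · CBR`), each country
is rescaled by a single factor so its total matches the national annual
births estimate (countries without one keep their initial total), and
pregnancies are births times the per-country ratio

    (live births + stillbirths + miscarriages + abortions) / live births ≥ 1,

borrowed from the nearest country (great-circle centroid distance) where
components are unavailable.

A fully synthetic data generator (`demogrid.synthetic_data`) emits every
input — rasters, tables, and birth-history microdata simulated under known
true ASFRs — so the entire pipeline is testable offline.

## Worked example

```python
from demogrid import ScenarioConfig, make_scenario, run_scenario

scenario = make_scenario(ScenarioConfig(seed=42))   # 3 synthetic countries
result = run_scenario(scenario)

print(result.scale_report.round(2).to_string(index=False))
print(f"births total:      {result.births_scaled.total():9.1f} per year")
print(f"pregnancies total: {result.pregnancies.total():9.1f} per year")
print(result.provenance.round(3).to_string(index=False))
```

prints

```
 iso  pre_total  target  factor  flagged
  10     992.38 1002.02    1.01    False
  20     757.00  824.08    1.09    False
  30     705.01     NaN    1.00    False
births total:         2531.1 per year
pregnancies total:    3343.5 per year
 iso  ratio  source_iso
  10  1.290          10
  20  1.290          10
  30  1.401          30
```

Country 10 (urban/rural subnational ASFRs) and country 20 (registered
births) are rescaled to their national targets (factors 1.01 and 1.09);
country 30 (crude birth rate) has no national estimate, so its initial
total stands (factor 1, not flagged). Country 20 lacks pregnancy
components and borrows country 10's ratio of 1.29 pregnancies per live
birth — the provenance table records the source.

The same stages are available from the shell:

```bash
demogrid simulate --seed 42 --out world/
demogrid grid-info world/population.tif
demogrid births --mode cbr --pop world/population.tif --cbr 25 --per-thousand \
    --codes world/country_codes.tif --scale world/national_totals.csv \
    --report report.csv --out births.tif
demogrid pregnancies --births births.tif --codes world/country_codes.tif \
    --components world/pregnancy_components.csv --out pregnancies.tif
```

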
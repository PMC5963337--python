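"""End-to-end composition: scenario inputs -> births -> scaled births -> pregnancies.

Per country the fertility flavour decides the route: subnational ASFR tables
(urban/rural or not) are rasterized over the country's zones; registered
births are first divided by the gridded female denominators; a national
ASFR vector becomes a constant per-group surface; a crude birth rate
multiplies the population surface directly.  Per-country births surfaces
are assembled on the common lattice, rescaled to national totals, and
converted to pregnancies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agesex import REPRODUCTIVE_AGE_GROUPS, female_count_grid, women_counts_by_zone
from .births import CountryTotals, births_from_asfr, births_from_cbr, compare_pre_adjustment, scale_to_national
from .fertility import asfr_from_registered_births, rasterize_asfr
from .gridio import Grid, clip_to_country
from .pregnancies import PregnancyComponents, pregnancies_grid, ratio_provenance
from .synthetic_data import Scenario

__all__ = ["PipelineResult", "run_scenario"]


@dataclass
class PipelineResult:
    births_pre: Grid
    births_scaled: Grid
    scale_report: pd.DataFrame
    pre_adjustment_r2: float | None
    pregnancies: Grid
    provenance: pd.DataFrame


def _paste(target_values: np.ndarray, target_mask: np.ndarray, sub: Grid, full: Grid) -> None:
    r0, c0 = sub.cell_index()
    R0, C0 = full.cell_index()
    r, c = r0 - R0, c0 - C0
    h, w = sub.shape
    sel = ~sub.mask
    target_values[r : r + h, c : c + w][sel] = sub.values[sel]
    target_mask[r : r + h, c : c + w][sel] = False


def run_scenario(s: Scenario) -> PipelineResult:
    """Run the full births-and-pregnancies pipeline on a synthetic world."""
    births_v = np.zeros(s.pop.shape, dtype=np.float64)
    births_m = np.ones(s.pop.shape, dtype=bool)

    for iso in s.isos:
        pop_c = clip_to_country(s.pop, s.codes, iso)
        flavour = s.flavour[iso]
        if flavour == "cbr":
            b = births_from_cbr(pop_c, s.true_cbr[iso])
        else:
            zones_c = clip_to_country(s.zones, s.codes, iso)
            urban_c = clip_to_country(s.urban, s.codes, iso)
            females = {
                g: female_count_grid(pop_c, s.agesex, zones_c, g)
                for g in REPRODUCTIVE_AGE_GROUPS
            }
            if flavour in ("subnational_urban_rural", "subnational"):
                table = s.asfr_tables[iso]
            elif flavour == "registered_births":
                women = women_counts_by_zone(pop_c, s.agesex, zones_c)
                table = asfr_from_registered_births(s.registered_births[iso], women)
            else:  # national_asfr
                rows = []
                for zid in s.zone_ids[iso]:
                    row = {"ISO": iso, "region": zid, "rural_urban": "all", "year": ""}
                    row.update(
                        {
                            f"asfr_{g}": r
                            for g, r in zip(REPRODUCTIVE_AGE_GROUPS, s.national_asfr[iso])
                        }
                    )
                    rows.append(row)
                table = pd.DataFrame(rows)
            asfr = {
                g: rasterize_asfr(table, zones_c, g, urban_mask=urban_c)
                for g in REPRODUCTIVE_AGE_GROUPS
            }
            b = births_from_asfr(females, asfr)
        _paste(births_v, births_m, b, s.pop)

    births_pre = Grid(births_v, births_m, s.pop.origin, s.pop.cell_size)
    totals = CountryTotals(
        births={
            int(r["iso"]): (None if np.isnan(r["unpd_births"]) else float(r["unpd_births"]))
            for _, r in s.totals.iterrows()
        },
        population={int(r["iso"]): float(r["unpd_population"]) for _, r in s.totals.iterrows()},
    )
    births_scaled, report = scale_to_national(births_pre, s.codes, totals)
    r2 = None
    if report["target"].notna().sum() >= 2:
        r2 = compare_pre_adjustment(report)

    comps = PregnancyComponents.from_frame(s.components)
    pregnancies = pregnancies_grid(births_scaled, s.codes, comps)
    provenance = ratio_provenance(s.codes, comps)
    return PipelineResult(
        births_pre=births_pre,
        births_scaled=births_scaled,
        scale_report=report,
        pre_adjustment_r2=r2,
        pregnancies=pregnancies,
        provenance=provenance,
    )
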
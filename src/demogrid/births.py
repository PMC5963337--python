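"""Gridded births: multiply-and-sum, crude-birth-rate path, national rescaling.

Where age-specific fertility is available, the births surface is the sum
over the seven reproductive age groups of (women in group g per cell) x
(ASFR of group g at that cell).  Where only a crude birth rate exists, it
multiplies the total population surface directly.  Each country's surface is
then rescaled by a single uniform factor so that its total matches the
national estimate of annual births; countries without a national estimate
keep their initial total (factor 1).  The pre-adjustment comparison —
regressing initial country totals on the national estimates — is the
pipeline's standard diagnostic of how far the subnational sources drift
from the national series.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .agesex import REPRODUCTIVE_AGE_GROUPS
from .gridio import AlignmentError, Grid, GridError, grids_aligned

__all__ = [
    "BirthsError",
    "ArityError",
    "TotalsLookupError",
    "InsufficientDataError",
    "CountryTotals",
    "load_country_totals",
    "births_from_asfr",
    "births_from_cbr",
    "scale_to_national",
    "compare_pre_adjustment",
]


class BirthsError(GridError):
    """Base class for births-stage errors."""


class ArityError(BirthsError):
    """An incomplete set of age-group layers was supplied."""


class TotalsLookupError(BirthsError):
    """A country present in the code grid has no national-totals row."""


class InsufficientDataError(BirthsError):
    """Too few countries with targets for the diagnostic regression."""


@dataclass
class CountryTotals:
    """National annual births and population per country.

    ``births`` maps iso code to the national estimate of annual live births;
    countries without an estimate are recorded explicitly as ``None`` (never
    silently as zero).  ``population`` maps iso code to national persons.
    """

    births: Mapping[int, float | None]
    population: Mapping[int, float]

    def __post_init__(self) -> None:
        for iso, b in self.births.items():
            if b is not None and b < 0:
                raise BirthsError(f"negative national births for country {iso}")
        for iso, p in self.population.items():
            if p < 0:
                raise BirthsError(f"negative national population for country {iso}")


def load_country_totals(path: str | Path) -> CountryTotals:
    """Read a national-totals CSV (``iso,unpd_births,unpd_population``).

    An empty births field means "no national estimate available" and is kept
    distinct from zero.
    """
    df = pd.read_csv(path)
    need = {"iso", "unpd_births", "unpd_population"}
    if not need <= set(df.columns):
        raise BirthsError(f"totals table missing columns {sorted(need - set(df.columns))}")
    births = {
        int(r["iso"]): (None if pd.isna(r["unpd_births"]) else float(r["unpd_births"]))
        for _, r in df.iterrows()
    }
    pop = {int(r["iso"]): float(r["unpd_population"]) for _, r in df.iterrows()}
    return CountryTotals(births=births, population=pop)


def births_from_asfr(
    females: Mapping[str, Grid], asfr: Mapping[str, Grid]
) -> Grid:
    """Births per cell: sum over age groups of women(g) x ASFR(g).

    Both mappings must cover all seven reproductive age groups on one
    lattice window.  Units: births per year.
    """
    missing = [g for g in REPRODUCTIVE_AGE_GROUPS if g not in females or g not in asfr]
    if missing:
        raise ArityError(f"missing age-group layer(s): {missing}")
    first = females[REPRODUCTIVE_AGE_GROUPS[0]]
    total = np.zeros(first.shape, dtype=np.float64)
    mask = np.zeros(first.shape, dtype=bool)
    for g in REPRODUCTIVE_AGE_GROUPS:
        f, a = females[g], asfr[g]
        if not (grids_aligned(f, first) and grids_aligned(a, first)):
            raise AlignmentError(f"layer for group {g} not aligned with the others")
        mask |= f.mask | a.mask
        total += np.where(f.mask | a.mask, 0.0, f.values * a.values)
    total[mask] = 0.0
    return Grid(values=total, mask=mask, origin=first.origin, cell_size=first.cell_size)


def births_from_cbr(pop: Grid, cbr: float) -> Grid:
    """Births per cell from a crude birth rate: pop(cell) x cbr.

    ``cbr`` is births per person-year (all ages, both sexes).
    """
    if cbr < 0:
        raise BirthsError(f"crude birth rate must be nonnegative, got {cbr}")
    values = np.where(pop.mask, 0.0, pop.values.astype(np.float64) * cbr)
    return Grid(values=values, mask=pop.mask.copy(), origin=pop.origin, cell_size=pop.cell_size)


def scale_to_national(
    b: Grid, codes: Grid, totals: CountryTotals
) -> tuple[Grid, pd.DataFrame]:
    """Rescale each country's births so its total matches the national estimate.

    Every cell of country ``iso`` is multiplied by ``target / pre_total``;
    the factor is 1 where no target exists or where the initial total is
    zero (a zero initial total with a nonzero target cannot be redistributed
    by a uniform factor and is flagged in the report instead).

    Returns the scaled grid and a scale report with one row per country:
    ``iso, pre_total, target, factor, flagged``.
    """
    if not grids_aligned(b, codes):
        raise AlignmentError("births grid and country-code grid are not aligned")
    valid = (~b.mask) & (~codes.mask)
    isos = np.unique(codes.values[~codes.mask]).astype(np.int64)
    missing = [int(i) for i in isos if int(i) not in totals.births]
    if missing:
        raise TotalsLookupError(f"countries {missing} missing from national totals")

    values = b.values.astype(np.float64).copy()
    rows = []
    for iso in isos:
        sel = valid & (codes.values == iso)
        pre_total = float(values[sel].sum())
        target = totals.births.get(int(iso))
        flagged = False
        if target is None:
            factor = 1.0
        elif pre_total > 0:
            factor = target / pre_total
        else:
            factor = 1.0
            flagged = target > 0
        values[sel] *= factor
        rows.append(
            {
                "iso": int(iso),
                "pre_total": pre_total,
                "target": np.nan if target is None else float(target),
                "factor": factor,
                "flagged": flagged,
            }
        )
    report = pd.DataFrame(rows, columns=["iso", "pre_total", "target", "factor", "flagged"])
    scaled = Grid(values=values, mask=b.mask.copy(), origin=b.origin, cell_size=b.cell_size)
    return scaled, report


def compare_pre_adjustment(report: pd.DataFrame) -> float:
    """R^2 of pre-adjustment country totals against the national targets.

    Only countries with a target enter the least-squares fit; at least two
    are required.
    """
    sub = report.dropna(subset=["target"])
    if len(sub) < 2:
        raise InsufficientDataError(
            f"need >= 2 countries with national targets, have {len(sub)}"
        )
    fit = stats.linregress(sub["target"].to_numpy(), sub["pre_total"].to_numpy())
    return float(fit.rvalue**2)
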
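"""Gridded age-sex structure from per-admin-unit proportion tables.

Each admin unit (zone) carries a standardized row of proportions: the share
of the total (both-sex) population in each 5-year age group from 0-4 up to
65+, plus the overall male and female shares.  Multiplying the population
surface by ``t_g * prop_f_t`` of the cell's zone yields the surface of women
in age group ``g``; the seven groups 15-19 ... 45-49 are the reproductive
ages the fertility stages consume.

The sex split is applied as a constant factor across age groups (the sex
ratio is taken as age-invariant), which is exactly the computation the
standardized table schema supports.  All intermediate surfaces keep
fractional persons; conservation under later rescaling requires real-valued
counts.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .gridio import AlignmentError, Grid, GridError, grids_aligned

__all__ = [
    "ALL_AGE_GROUPS",
    "REPRODUCTIVE_AGE_GROUPS",
    "AGE_GROUP_BOUNDS",
    "AgeSexTableError",
    "RegionLookupError",
    "load_agesex_table",
    "validate_agesex_table",
    "count_grid",
    "female_count_grid",
    "verify_agesex_layers",
    "women_counts_by_zone",
]

#: The fourteen 5-year both-sex age groups of the standardized table.
ALL_AGE_GROUPS: tuple[str, ...] = tuple(
    f"{lo}_{lo + 4}" for lo in range(0, 65, 5)
) + ("65_plus",)

#: The seven reproductive 5-year groups (women aged 15-49).
REPRODUCTIVE_AGE_GROUPS: tuple[str, ...] = tuple(f"{lo}_{lo + 4}" for lo in range(15, 50, 5))

#: Closed integer age bounds per reproductive group.
AGE_GROUP_BOUNDS: dict[str, tuple[int, int]] = {
    g: (int(g.split("_")[0]), int(g.split("_")[1])) for g in REPRODUCTIVE_AGE_GROUPS
}

_PROP_TOL = 1e-6


class AgeSexTableError(GridError):
    """An age-sex proportion table violates its schema or invariants."""


class RegionLookupError(GridError):
    """A zone id present in a raster has no row in the matching table."""


def _age_columns() -> list[str]:
    return [f"t_{g}" for g in ALL_AGE_GROUPS]


def validate_agesex_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the standardized schema and its row invariants.

    Every row must have age-group proportions summing to 1 (tolerance 1e-6),
    male + female shares summing to 1, and all entries in [0, 1].
    """
    required = ["region", *_age_columns(), "prop_m_t", "prop_f_t"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise AgeSexTableError(f"age-sex table missing columns: {missing}")
    props = table[_age_columns() + ["prop_m_t", "prop_f_t"]].to_numpy(dtype=float)
    if (props < -_PROP_TOL).any() or (props > 1 + _PROP_TOL).any():
        raise AgeSexTableError("age-sex proportions must lie in [0, 1]")
    age_sums = table[_age_columns()].sum(axis=1).to_numpy(dtype=float)
    bad = np.flatnonzero(np.abs(age_sums - 1.0) > _PROP_TOL)
    if bad.size:
        raise AgeSexTableError(
            f"age-group proportions do not sum to 1 for region(s) "
            f"{table['region'].iloc[bad].tolist()} (sums {age_sums[bad]})"
        )
    sex_sums = (table["prop_m_t"] + table["prop_f_t"]).to_numpy(dtype=float)
    bad = np.flatnonzero(np.abs(sex_sums - 1.0) > _PROP_TOL)
    if bad.size:
        raise AgeSexTableError(
            f"male+female proportions do not sum to 1 for region(s) "
            f"{table['region'].iloc[bad].tolist()}"
        )
    if table["region"].duplicated().any():
        raise AgeSexTableError("duplicate region rows in age-sex table")
    return table


def load_agesex_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a standardized age-sex proportion CSV."""
    return validate_agesex_table(pd.read_csv(path))


def _zone_factor(table: pd.DataFrame, column: str, sex_column: str) -> Mapping[int, float]:
    t = table.set_index("region")
    return {
        int(region): float(row[column]) * float(row[sex_column])
        for region, row in t.iterrows()
    }


def count_grid(pop: Grid, table: pd.DataFrame, zones: Grid, group: str, sex: str) -> Grid:
    """Surface of persons of one sex in one 5-year age group.

    cell value = pop(cell) * t_group(zone(cell)) * prop_<sex>_t(zone(cell)).

    Parameters
    ----------
    group
        One of :data:`ALL_AGE_GROUPS`.
    sex
        ``"f"`` or ``"m"``.
    """
    if group not in ALL_AGE_GROUPS:
        raise AgeSexTableError(f"unknown age group {group!r}")
    if sex not in ("f", "m"):
        raise AgeSexTableError(f"sex must be 'f' or 'm', got {sex!r}")
    if not grids_aligned(pop, zones):
        raise AlignmentError("population and zone grids are not aligned")
    validate_agesex_table(table)

    factor = _zone_factor(table, f"t_{group}", f"prop_{sex}_t")
    mask = pop.mask | zones.mask
    valid = ~mask
    zone_ids = zones.values[valid].astype(np.int64)
    unknown = sorted(set(int(z) for z in np.unique(zone_ids)) - set(factor))
    if unknown:
        raise RegionLookupError(
            f"zone id(s) {unknown} present in zone raster but missing from age-sex table"
        )
    lut_ids = np.array(sorted(factor), dtype=np.int64)
    lut_vals = np.array([factor[int(i)] for i in lut_ids], dtype=np.float64)
    values = np.zeros(pop.shape, dtype=np.float64)
    values[valid] = pop.values[valid].astype(np.float64) * lut_vals[
        np.searchsorted(lut_ids, zone_ids)
    ]
    return Grid(values=values, mask=mask, origin=pop.origin, cell_size=pop.cell_size)


def female_count_grid(pop: Grid, table: pd.DataFrame, zones: Grid, group: str) -> Grid:
    """Women in a 5-year age group per cell (see :func:`count_grid`)."""
    return count_grid(pop, table, zones, group, "f")


def verify_agesex_layers(layers: Iterable[Grid], pop: Grid) -> float:
    """Layer-sum verification: max |sum of all age-sex layers - pop|.

    With a complete set of layers for both sexes the sum telescopes back to
    the population surface, since the per-zone age proportions and the sex
    proportions each sum to one; the returned residual (persons) should be at
    float round-off.
    """
    total = np.zeros(pop.shape, dtype=np.float64)
    mask = pop.mask.copy()
    for layer in layers:
        if not grids_aligned(layer, pop):
            raise AlignmentError("age-sex layer not aligned with population grid")
        mask |= layer.mask
        total += np.where(layer.mask, 0.0, layer.values)
    valid = ~mask
    if not valid.any():
        return 0.0
    return float(np.abs(total[valid] - pop.values[valid]).max())


def women_counts_by_zone(pop: Grid, table: pd.DataFrame, zones: Grid) -> pd.DataFrame:
    """Zonal totals of women per reproductive age group.

    Returns a frame indexed by zone id with one column per group in
    :data:`REPRODUCTIVE_AGE_GROUPS`; this is the denominator table for the
    registered-births fertility path.
    """
    from .gridio import zonal_sum

    frames = {}
    for g in REPRODUCTIVE_AGE_GROUPS:
        frames[g] = zonal_sum(female_count_grid(pop, table, zones, g), zones)
    out = pd.DataFrame(frames)
    out.index.name = "region"
    return out
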
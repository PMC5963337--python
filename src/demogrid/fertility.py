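"""Age-specific fertility rates from heterogeneous sources.

Four source flavours feed the pipeline, in decreasing order of preference:

1. subnational ASFR tables split by urban/rural stratum,
2. subnational ASFR tables without the split,
3. registered births per admin unit and 5-year age group (divided by the
   gridded female denominators),
4. a national ASFR vector, and finally
5. a crude birth rate (births per person-year, all ages and sexes).

Subnational ASFRs from survey birth histories use the retrospective
women-years estimator: for each region, stratum and 5-year age group ``a``,
the numerator is the (weighted) number of births occurring during the
reference window whose mother's completed age at the birth month fell in
``a``, and the denominator is the (weighted) number of woman-years lived in
``a`` during the window.  The window is the ``window_months`` calendar months
ending the month before interview (the interview month itself excluded).
All date arithmetic is in century-month codes, cmc = 12*(year-1900) + month,
so ages in months are exact integers and the estimator admits an exact
enumeration oracle.

Conventions (all integer-month arithmetic):

* a woman's completed age in years at month ``m`` is ``(m - dob_cmc) // 12``;
* a birth is classified by the mother's completed age in the birth month;
* exposure accrues only while the completed age is 15-49 — months lived
  below 15 or above 49 inside the window contribute to no group;
* sampling weights multiply numerator and denominator alike (ratio
  estimator); unweighted data is the all-weights-one special case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .agesex import AGE_GROUP_BOUNDS, REPRODUCTIVE_AGE_GROUPS
from .gridio import AlignmentError, Grid, grids_aligned

__all__ = [
    "ASFR_COLUMNS",
    "BIRTHS_COLUMNS",
    "FertilityError",
    "DataError",
    "SchemaError",
    "NoSourceError",
    "DivisionError",
    "BirthHistoryDataset",
    "WomenYearsEstimate",
    "cmc",
    "cmc_to_year_month",
    "completed_age_years",
    "estimate_asfr_from_histories",
    "asfr_from_registered_births",
    "SubnationalASFR",
    "RegisteredBirths",
    "NationalASFR",
    "CrudeBirthRate",
    "select_fertility_source",
    "rasterize_asfr",
    "load_asfr_table",
    "load_registered_births",
    "cbr_per_person",
]

#: ASFR table columns in the standardized subnational schema.
ASFR_COLUMNS = ["ISO", "region", "rural_urban"] + [
    f"asfr_{g}" for g in REPRODUCTIVE_AGE_GROUPS
] + ["year"]

#: Registered-births table columns in the standardized schema.
BIRTHS_COLUMNS = ["region", "ISO"] + [f"b_{g}" for g in REPRODUCTIVE_AGE_GROUPS] + ["year"]

#: Annual rates above this trigger a range-check warning (plausibility, not
#: validity: rates up to 1 birth/woman/year remain representable).
ASFR_WARN_THRESHOLD = 0.5

#: Urban/rural decision threshold applied to (possibly fractional) masks.
URBAN_MASK_THRESHOLD = 0.5

_MIN_AGE, _MAX_AGE = 15, 49


class FertilityError(Exception):
    """Base class for fertility-stage errors."""


class DataError(FertilityError):
    """Birth-history microdata violates its invariants."""


class SchemaError(FertilityError):
    """A fertility table violates its standardized schema."""


class NoSourceError(FertilityError):
    """No fertility source is available for selection."""


class DivisionError(FertilityError):
    """Registered births with a zero female denominator."""


# ---------------------------------------------------------------------------
# Century-month codes
# ---------------------------------------------------------------------------

def cmc(year: int, month: int) -> int:
    """Century-month code of a calendar month: ``12*(year-1900) + month``."""
    return 12 * (year - 1900) + month


def cmc_to_year_month(code: int) -> tuple[int, int]:
    """Inverse of :func:`cmc`."""
    return 1900 + (code - 1) // 12, (code - 1) % 12 + 1


def completed_age_years(dob_cmc: int | np.ndarray, at_cmc: int | np.ndarray):
    """Completed age in whole years at month ``at_cmc`` for birth ``dob_cmc``."""
    return (np.asarray(at_cmc) - np.asarray(dob_cmc)) // 12


# ---------------------------------------------------------------------------
# Birth-history microdata
# ---------------------------------------------------------------------------

@dataclass
class BirthHistoryDataset:
    """Survey birth histories: one row per woman plus her children's dates.

    Attributes
    ----------
    women
        Frame with columns ``woman_id, dob_cmc, interview_cmc, weight,
        region_id, stratum`` (stratum in {"urban", "rural", "all"}).
    births
        Frame with columns ``woman_id, child_dob_cmc`` — one row per child.
    """

    women: pd.DataFrame
    births: pd.DataFrame

    def __post_init__(self) -> None:
        w, b = self.women, self.births
        need_w = {"woman_id", "dob_cmc", "interview_cmc", "weight", "region_id", "stratum"}
        need_b = {"woman_id", "child_dob_cmc"}
        if not need_w <= set(w.columns):
            raise SchemaError(f"women frame missing {sorted(need_w - set(w.columns))}")
        if not need_b <= set(b.columns):
            raise SchemaError(f"births frame missing {sorted(need_b - set(b.columns))}")
        if len(w):
            if (w["dob_cmc"] <= 0).any() or (w["interview_cmc"] <= 0).any():
                raise DataError("century-month codes must be positive integers")
            age = (w["interview_cmc"] - w["dob_cmc"]) // 12
            bad = w.loc[(age < _MIN_AGE) | (age > _MAX_AGE), "woman_id"]
            if len(bad):
                raise DataError(
                    f"women outside ages {_MIN_AGE}-{_MAX_AGE} at interview: "
                    f"{bad.tolist()[:5]}"
                )
            if (w["weight"] <= 0).any():
                raise DataError("sampling weights must be positive")
        if len(b):
            joined = b.merge(w[["woman_id", "interview_cmc"]], on="woman_id", how="left")
            if joined["interview_cmc"].isna().any():
                raise DataError("birth rows reference unknown woman_id")
            late = joined["child_dob_cmc"] >= joined["interview_cmc"]
            if late.any():
                raise DataError(
                    f"{int(late.sum())} child birth date(s) on/after interview month"
                )

    @property
    def n_women(self) -> int:
        return len(self.women)


@dataclass
class WomenYearsEstimate:
    """Result of the women-years estimator with its raw components.

    ``numerators`` carry weighted birth counts and ``denominators`` weighted
    woman-years, both indexed by (region_id, stratum) with one column per
    age group.  ``table`` is the derived standardized ASFR table; group
    cells with zero exposure are absent (NaN) there.
    """

    numerators: pd.DataFrame
    denominators: pd.DataFrame
    table: pd.DataFrame
    window_months: int


def estimate_asfr_from_histories(
    data: BirthHistoryDataset,
    window_months: int = 36,
    iso: str | int = "",
    year: int | None = None,
) -> WomenYearsEstimate:
    """Retrospective women-years ASFR estimator over birth histories.

    For every (region, stratum, age group): rate = weighted births in the
    window to mothers of that completed age, divided by weighted woman-years
    of exposure at that age during the window.  Groups with zero exposure in
    a region/stratum are flagged absent (NaN), never zero.
    """
    if window_months < 1:
        raise DataError(f"window must be >= 1 month, got {window_months}")
    w = data.women.reset_index(drop=True)
    groups = list(REPRODUCTIVE_AGE_GROUPS)
    keys = w[["region_id", "stratum"]].drop_duplicates().sort_values(
        ["region_id", "stratum"]
    )
    index = pd.MultiIndex.from_frame(keys)
    num = pd.DataFrame(0.0, index=index, columns=groups)
    den = pd.DataFrame(0.0, index=index, columns=groups)
    if len(w) == 0:
        table = _components_to_table(num, den, iso, year)
        return WomenYearsEstimate(num, den, table, window_months)

    key_codes = pd.MultiIndex.from_frame(w[["region_id", "stratum"]]).map(
        {k: i for i, k in enumerate(index)}
    ).to_numpy()

    interview = w["interview_cmc"].to_numpy(np.int64)
    dob = w["dob_cmc"].to_numpy(np.int64)
    weight = w["weight"].to_numpy(np.float64)

    # Exposure: enumerate the window months of every woman at once.
    offsets = np.arange(1, window_months + 1, dtype=np.int64)
    months = interview[:, None] - offsets[None, :]          # (n_women, window)
    age = (months - dob[:, None]) // 12
    in_span = (age >= _MIN_AGE) & (age <= _MAX_AGE)
    gidx = np.clip((age - _MIN_AGE) // 5, 0, len(groups) - 1)
    flat_key = np.broadcast_to(key_codes[:, None], gidx.shape)[in_span] * len(groups) + gidx[in_span]
    flat_wt = np.broadcast_to(weight[:, None], gidx.shape)[in_span]
    den_flat = np.zeros(len(index) * len(groups))
    np.add.at(den_flat, flat_key, flat_wt)
    # Weighted month counts, converted to woman-years by one final division so
    # the arithmetic is reproducible by exact enumeration.
    den.iloc[:, :] = den_flat.reshape(len(index), len(groups)) / 12.0

    # Numerator: classify each birth by the mother's age in its month.
    b = data.births.merge(
        w[["woman_id", "dob_cmc", "interview_cmc", "weight", "region_id", "stratum"]],
        on="woman_id",
    )
    if len(b):
        bc = b["child_dob_cmc"].to_numpy(np.int64)
        biv = b["interview_cmc"].to_numpy(np.int64)
        in_window = (bc >= biv - window_months) & (bc <= biv - 1)
        bage = (bc - b["dob_cmc"].to_numpy(np.int64)) // 12
        ok = in_window & (bage >= _MIN_AGE) & (bage <= _MAX_AGE)
        bkey = pd.MultiIndex.from_frame(b[["region_id", "stratum"]]).map(
            {k: i for i, k in enumerate(index)}
        ).to_numpy()[ok]
        bg = ((bage[ok] - _MIN_AGE) // 5).astype(np.int64)
        num_flat = np.zeros(len(index) * len(groups))
        np.add.at(num_flat, bkey * len(groups) + bg, b["weight"].to_numpy(np.float64)[ok])
        num.iloc[:, :] = num_flat.reshape(len(index), len(groups))

    table = _components_to_table(num, den, iso, year)
    return WomenYearsEstimate(num, den, table, window_months)


def _components_to_table(
    num: pd.DataFrame, den: pd.DataFrame, iso: str | int, year: int | None
) -> pd.DataFrame:
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = num.to_numpy() / den.to_numpy()
    rates[den.to_numpy() == 0] = np.nan
    rows = []
    for (region, stratum), rate_row in zip(num.index, rates):
        row = {"ISO": iso, "region": region, "rural_urban": stratum}
        for g, r in zip(REPRODUCTIVE_AGE_GROUPS, rate_row):
            row[f"asfr_{g}"] = r
        row["year"] = year if year is not None else ""
        rows.append(row)
    table = pd.DataFrame(rows, columns=ASFR_COLUMNS)
    _warn_on_extreme_rates(table)
    return table


def _warn_on_extreme_rates(table: pd.DataFrame) -> None:
    cols = [f"asfr_{g}" for g in REPRODUCTIVE_AGE_GROUPS]
    rates = table[cols].to_numpy(dtype=float)
    if np.nanmax(rates, initial=0.0) > ASFR_WARN_THRESHOLD:
        warnings.warn(
            f"ASFR above {ASFR_WARN_THRESHOLD} births/woman/year present; "
            "check source data ranges",
            stacklevel=3,
        )


# ---------------------------------------------------------------------------
# Registered births path
# ---------------------------------------------------------------------------

def asfr_from_registered_births(
    births: pd.DataFrame, women: pd.DataFrame, year: int | None = None
) -> pd.DataFrame:
    """ASFRs from registered births divided by female denominators.

    Parameters
    ----------
    births
        Standardized registered-births table (``region, ISO, b_15_19 ...
        b_45_49, year``); counts of births per region and mother's age group.
    women
        Frame indexed by region with one column per reproductive age group:
        the number of women in the group (typically zonal sums of the gridded
        age-sex surfaces).

    Returns
    -------
    Standardized ASFR table with stratum ``"all"``.
    """
    missing = [c for c in BIRTHS_COLUMNS if c not in births.columns]
    if missing:
        raise SchemaError(f"registered-births table missing columns: {missing}")
    bcols = [f"b_{g}" for g in REPRODUCTIVE_AGE_GROUPS]
    if (births[bcols].to_numpy(dtype=float) < 0).any():
        raise SchemaError("registered birth counts must be nonnegative")
    rows = []
    for _, r in births.iterrows():
        region = r["region"]
        if region not in women.index:
            raise DivisionError(f"no female denominators for region {region!r}")
        row = {"ISO": r["ISO"], "region": region, "rural_urban": "all"}
        for g in REPRODUCTIVE_AGE_GROUPS:
            b_g = float(r[f"b_{g}"])
            w_g = float(women.loc[region, g])
            if b_g > 0 and w_g <= 0:
                raise DivisionError(
                    f"region {region!r}, group {g}: {b_g:g} births but "
                    f"{w_g:g} women"
                )
            row[f"asfr_{g}"] = 0.0 if b_g == 0 else b_g / w_g
        row["year"] = year if year is not None else r.get("year", "")
        rows.append(row)
    table = pd.DataFrame(rows, columns=ASFR_COLUMNS)
    _warn_on_extreme_rates(table)
    return table


# ---------------------------------------------------------------------------
# Source hierarchy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubnationalASFR:
    """Subnational ASFR table, optionally split urban/rural (ranks 1-2)."""

    table: pd.DataFrame
    has_urban_rural: bool = False

    @property
    def rank(self) -> int:
        return 0 if self.has_urban_rural else 1


@dataclass(frozen=True)
class RegisteredBirths:
    """Registered births per admin unit and age group (rank 3)."""

    table: pd.DataFrame
    rank: int = field(default=2, init=False)


@dataclass(frozen=True)
class NationalASFR:
    """A single national vector of the seven age-group rates (rank 4)."""

    rates: tuple[float, ...]
    rank: int = field(default=3, init=False)

    def __post_init__(self) -> None:
        if len(self.rates) != len(REPRODUCTIVE_AGE_GROUPS):
            raise SchemaError(
                f"national ASFR needs {len(REPRODUCTIVE_AGE_GROUPS)} rates, "
                f"got {len(self.rates)}"
            )


@dataclass(frozen=True)
class CrudeBirthRate:
    """National crude birth rate, births per person-year (rank 5)."""

    rate: float
    rank: int = field(default=4, init=False)

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise SchemaError(f"crude birth rate must be nonnegative, got {self.rate}")


FertilitySource = SubnationalASFR | RegisteredBirths | NationalASFR | CrudeBirthRate


def select_fertility_source(available: Sequence[FertilitySource]) -> FertilitySource:
    """Pick the preferred source under the age-detail/spatial-detail hierarchy.

    Order: subnational ASFR with urban/rural split > subnational ASFR >
    registered births by age group > national ASFR > crude birth rate.
    Deterministic and permutation-invariant (stable on equal ranks: the
    earliest-listed source of the best rank wins).
    """
    if not available:
        raise NoSourceError("no fertility source available")
    best = min(range(len(available)), key=lambda i: (available[i].rank, i))
    return available[best]


def cbr_per_person(value: float, per_thousand: bool = False) -> float:
    """Normalize a crude birth rate to births per person-year."""
    return value / 1000.0 if per_thousand else float(value)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def load_asfr_table(path: str | Path) -> pd.DataFrame:
    """Read a standardized subnational ASFR CSV (strata lower-cased)."""
    table = pd.read_csv(path)
    missing = [c for c in ASFR_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"ASFR table missing columns: {missing}")
    table["rural_urban"] = table["rural_urban"].astype(str).str.lower()
    rates = table[[f"asfr_{g}" for g in REPRODUCTIVE_AGE_GROUPS]].to_numpy(dtype=float)
    finite = rates[np.isfinite(rates)]
    if ((finite < 0) | (finite > 1)).any():
        raise SchemaError("ASFR values must lie in [0, 1] births/woman/year")
    _warn_on_extreme_rates(table)
    return table


def load_registered_births(path: str | Path) -> pd.DataFrame:
    """Read a standardized registered-births CSV."""
    table = pd.read_csv(path)
    missing = [c for c in BIRTHS_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"registered-births table missing columns: {missing}")
    return table


def rasterize_asfr(
    table: pd.DataFrame,
    zones: Grid,
    group: str,
    urban_mask: Grid | None = None,
    missing_ok: bool = False,
) -> Grid:
    """Paint per-region (and per-stratum) ASFRs onto the zone raster.

    For strata split urban/rural, a cell is urban when the urban-extent mask
    value is >= 0.5, rural otherwise; for ``"all"`` rows the mask is ignored.
    The output's value set is exactly the table's rates — no interpolation.
    With ``missing_ok``, zones absent from the table come back masked instead
    of raising (for country tables painted over a wider zone raster).
    """
    if group not in REPRODUCTIVE_AGE_GROUPS:
        raise SchemaError(f"unknown reproductive age group {group!r}")
    col = f"asfr_{group}"
    t = table.copy()
    t["rural_urban"] = t["rural_urban"].astype(str).str.lower()
    strata = set(t["rural_urban"])
    split = bool(strata & {"urban", "rural"})
    if split:
        if urban_mask is None:
            raise SchemaError("urban/rural ASFR rows present but no urban mask supplied")
        if not grids_aligned(zones, urban_mask):
            raise AlignmentError("urban mask not aligned with zone grid")
        per_region = t.groupby("region")["rural_urban"].apply(set)
        bad = [r for r, s in per_region.items() if s != {"urban", "rural"} and s != {"all"}]
        if bad:
            raise SchemaError(
                f"region(s) {bad} lack a matched urban/rural pair (or a single 'all' row)"
            )

    lookup: dict[tuple[int, str], float] = {}
    for _, r in t.iterrows():
        lookup[(int(r["region"]), r["rural_urban"])] = float(r[col])

    values = np.zeros(zones.shape, dtype=np.float64)
    mask = zones.mask.copy()
    valid = np.argwhere(~mask)
    for i, j in valid:
        zid = int(zones.values[i, j])
        if (zid, "all") in lookup:
            values[i, j] = lookup[(zid, "all")]
            continue
        stratum = "rural"
        if urban_mask is not None and not urban_mask.mask[i, j]:
            stratum = "urban" if urban_mask.values[i, j] >= URBAN_MASK_THRESHOLD else "rural"
        try:
            values[i, j] = lookup[(zid, stratum)]
        except KeyError:
            if missing_ok:
                mask[i, j] = True
                continue
            raise SchemaError(
                f"no ASFR row for region {zid} stratum {stratum!r}"
            ) from None
    return Grid(values=values, mask=mask, origin=zones.origin, cell_size=zones.cell_size)
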
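"""Pregnancies from births via per-country pregnancy-to-birth ratios.

A country's ratio is (live births + stillbirths + miscarriages + abortions)
divided by live births, built from national component estimates; it is 1
when no pregnancy is lost and always >= 1.  Countries without component
estimates borrow the ratio of the nearest country that has them — nearest
by great-circle distance between country centroids, ties broken toward the
lower country code so the fallback is deterministic.  The ratio multiplies
the births surface cellwise, so per-country pregnancy totals are exactly
ratio x births totals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .gridio import AlignmentError, Grid, GridError, grids_aligned

__all__ = [
    "PregnancyError",
    "NoRatioSourceError",
    "PregnancyComponents",
    "load_pregnancy_components",
    "pregnancy_ratio",
    "haversine_deg",
    "resolve_ratio",
    "pregnancies_grid",
    "ratio_provenance",
]

EARTH_RADIUS_KM = 6371.0


class PregnancyError(GridError):
    """Base class for pregnancy-stage errors."""


class NoRatioSourceError(PregnancyError):
    """No country has pregnancy components to borrow from."""


@dataclass(frozen=True)
class ComponentsEntry:
    """One country's national pregnancy components and centroid."""

    iso: int
    stillbirths: float
    miscarriages: float
    abortions: float
    live_births: float
    centroid: tuple[float, float]  # (longitude, latitude), degrees
    available: bool

    def __post_init__(self) -> None:
        for name in ("stillbirths", "miscarriages", "abortions", "live_births"):
            if getattr(self, name) < 0:
                raise PregnancyError(f"country {self.iso}: negative {name}")
        if self.available and self.live_births <= 0:
            raise PregnancyError(
                f"country {self.iso}: components marked available but live_births "
                f"= {self.live_births}"
            )


class PregnancyComponents:
    """Per-country component table with centroid-based fallback."""

    def __init__(self, entries: Mapping[int, ComponentsEntry]):
        self.entries = dict(entries)

    def __contains__(self, iso: int) -> bool:
        return iso in self.entries

    def __getitem__(self, iso: int) -> ComponentsEntry:
        return self.entries[iso]

    def available_isos(self) -> list[int]:
        return sorted(i for i, e in self.entries.items() if e.available)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PregnancyComponents":
        """Build from a frame in the components CSV schema."""
        entries = {}
        for _, r in df.iterrows():
            iso = int(r["iso"])
            entries[iso] = ComponentsEntry(
                iso=iso,
                stillbirths=float(r["stillbirths"]),
                miscarriages=float(r["miscarriages"]),
                abortions=float(r["abortions"]),
                live_births=float(r["live_births"]),
                centroid=(float(r["lon"]), float(r["lat"])),
                available=bool(r["available"]),
            )
        return cls(entries)


def load_pregnancy_components(path: str | Path) -> PregnancyComponents:
    """Read a components CSV (``iso,stillbirths,miscarriages,abortions,
    live_births,lon,lat,available``)."""
    df = pd.read_csv(path)
    need = {"iso", "stillbirths", "miscarriages", "abortions", "live_births", "lon", "lat", "available"}
    if not need <= set(df.columns):
        raise PregnancyError(
            f"components table missing columns {sorted(need - set(df.columns))}"
        )
    return PregnancyComponents.from_frame(df)


def pregnancy_ratio(entry: ComponentsEntry) -> float:
    """(live births + stillbirths + miscarriages + abortions) / live births."""
    if entry.live_births <= 0:
        raise PregnancyError(
            f"country {entry.iso}: pregnancy ratio undefined with live_births = "
            f"{entry.live_births}"
        )
    return (
        entry.live_births + entry.stillbirths + entry.miscarriages + entry.abortions
    ) / entry.live_births


def haversine_deg(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Great-circle distance in km between two (lon, lat) points in degrees."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dlat = p2 - p1
    dlon = np.radians(lon2 - lon1)
    a = np.sin(dlat / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlon / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def resolve_ratio(iso: int, table: PregnancyComponents) -> tuple[float, int]:
    """Ratio for a country, borrowing from the nearest available one if needed.

    Returns ``(ratio, source_iso)`` where ``source_iso`` records provenance
    (equal to ``iso`` when the country has its own components).  Equidistant
    candidates resolve to the lower country code.
    """
    if iso in table and table[iso].available:
        return pregnancy_ratio(table[iso]), iso
    candidates = table.available_isos()
    if not candidates:
        raise NoRatioSourceError("no country has pregnancy components available")
    if iso not in table:
        raise PregnancyError(f"country {iso} absent from components table (no centroid)")
    lon0, lat0 = table[iso].centroid
    best = min(
        candidates,
        key=lambda c: (haversine_deg(lon0, lat0, *table[c].centroid), c),
    )
    return pregnancy_ratio(table[best]), best


def ratio_provenance(codes: Grid, table: PregnancyComponents) -> pd.DataFrame:
    """Resolved ratio and its source country for every country in a code grid."""
    rows = []
    for iso in np.unique(codes.values[~codes.mask]).astype(np.int64):
        ratio, source = resolve_ratio(int(iso), table)
        rows.append({"iso": int(iso), "ratio": ratio, "source_iso": source})
    return pd.DataFrame(rows, columns=["iso", "ratio", "source_iso"])


def pregnancies_grid(b: Grid, codes: Grid, table: PregnancyComponents) -> Grid:
    """Pregnancies per cell: births(cell) x resolved ratio of the cell's country."""
    if not grids_aligned(b, codes):
        raise AlignmentError("births grid and country-code grid are not aligned")
    values = b.values.astype(np.float64).copy()
    mask = b.mask | codes.mask
    for iso in np.unique(codes.values[~codes.mask]).astype(np.int64):
        ratio, _ = resolve_ratio(int(iso), table)
        sel = (~mask) & (codes.values == iso)
        values[sel] *= ratio
    return Grid(values=values, mask=mask, origin=b.origin, cell_size=b.cell_size)
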
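"""Synthetic study worlds: every input the pipeline consumes, with known truth.

A scenario lays countries out as vertical stripes of the master lattice and
admin zones as horizontal bands within each stripe, then emits the full set
of pipeline inputs — a log-normal population raster, country-code and zone
rasters, an urban-extent mask, a standardized age-sex proportion table, one
fertility source per country (subnational ASFR split urban/rural,
registered births by age group, national ASFR vector, or crude birth rate),
national totals, and pregnancy components with centroids — while recording
all ground truth so recovery is testable without any external download.

Birth-history microdata is simulated by the mechanism the women-years
estimator inverts: each woman's months from age 15 to her interview are
traversed and a birth occurs in a month with probability ASFR(current age
group)/12, independently.  No twins, no postpartum infecundity: the
estimand of the monthly Bernoulli hazard is exactly the input ASFR, which
is the property recovery tests rely on.

Everything is driven by one integer seed and is byte-deterministic,
including the GeoTIFF, CSV and YAML files written to disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .agesex import ALL_AGE_GROUPS, REPRODUCTIVE_AGE_GROUPS
from .fertility import ASFR_COLUMNS, BIRTHS_COLUMNS, BirthHistoryDataset, cmc
from .gridio import MASTER_CELL_SIZE, Grid, write_grid

__all__ = [
    "DEFAULT_TRUE_ASFR",
    "ScenarioConfigError",
    "ScenarioConfig",
    "Scenario",
    "make_scenario",
    "simulate_birth_histories",
    "synthetic_scale_report",
]

#: Default true ASFR schedule (annual births per woman for ages 15-19 ...
#: 45-49): a broadly realistic developing-country schedule peaking at 25-29.
DEFAULT_TRUE_ASFR: tuple[float, ...] = (0.05, 0.15, 0.18, 0.14, 0.09, 0.04, 0.01)

_FLAVOURS = ("subnational_urban_rural", "registered_births", "cbr", "subnational", "national_asfr")

_DEFAULT_INTERVIEW_CMC = cmc(2015, 1)


class ScenarioConfigError(Exception):
    """A scenario configuration is internally inconsistent."""


@dataclass
class ScenarioConfig:
    """Knobs of a synthetic study world.

    Defaults give a compact 3-country world that exercises the three most
    distinct fertility paths (urban/rural subnational ASFRs, registered
    births, crude birth rate) on a 48 x 72 window of the master lattice.
    """

    seed: int = 0
    n_countries: int = 3
    zones_per_country: int = 3
    grid_shape: tuple[int, int] = (48, 72)
    origin: tuple[float, float] = (-80.0, 10.0)
    margin: int = 1
    #: log-normal parameters of per-cell population counts (persons).
    pop_mu: float = 3.0
    pop_sigma: float = 1.0
    #: share of each zone's cells flagged urban.
    urban_fraction: float = 0.3
    #: base annual ASFR schedule; per-zone jitter is applied around it.
    base_asfr: tuple[float, ...] = DEFAULT_TRUE_ASFR
    #: multiplicative jitter half-width on per-zone ASFR levels.
    asfr_jitter: float = 0.2
    #: urban rates run below rural rates by this factor pair.
    urban_factor: float = 0.85
    rural_factor: float = 1.15
    #: crude birth rate range for CBR countries (births per person-year).
    cbr_range: tuple[float, float] = (0.02, 0.04)
    #: log-sd of the noise between true pre-totals and national targets.
    target_noise_sd: float = 0.05
    #: fertility source flavour per country, cycled from this tuple.
    flavours: tuple[str, ...] = _FLAVOURS[:3]
    #: 1-based country positions whose national births target is absent.
    births_target_missing: tuple[int, ...] = (3,)
    #: 1-based country positions without pregnancy components (fallback path).
    components_missing: tuple[int, ...] = (2,)

    def validate(self) -> None:
        rows, cols = self.grid_shape
        if self.n_countries < 1 or self.zones_per_country < 1:
            raise ScenarioConfigError("need at least one country and one zone each")
        inner_rows = rows - 2 * self.margin
        inner_cols = cols - 2 * self.margin
        if inner_cols < self.n_countries:
            raise ScenarioConfigError(
                f"{self.n_countries} countries do not fit in {inner_cols} interior columns"
            )
        if inner_rows < self.zones_per_country:
            raise ScenarioConfigError(
                f"{self.zones_per_country} zones per country do not fit in "
                f"{inner_rows} interior rows"
            )
        for f in self.flavours:
            if f not in _FLAVOURS:
                raise ScenarioConfigError(f"unknown fertility flavour {f!r}")
        if not all(0.0 <= r <= 1.0 for r in self.base_asfr):
            raise ScenarioConfigError("base ASFRs must lie in [0, 1]")
        if not 0.0 <= self.urban_fraction <= 1.0:
            raise ScenarioConfigError("urban_fraction must lie in [0, 1]")


@dataclass
class Scenario:
    """A generated world: rasters, tables, and the truth that produced them."""

    config: ScenarioConfig
    isos: list[int]
    zone_ids: dict[int, list[int]]                  # iso -> zone ids
    flavour: dict[int, str]                         # iso -> fertility flavour
    pop: Grid
    codes: Grid
    zones: Grid
    urban: Grid
    agesex: pd.DataFrame
    #: truth: (zone_id, stratum) -> seven annual rates; stratum "all" rows are
    #: present for every zone alongside urban/rural where applicable.
    true_asfr: dict[tuple[int, str], tuple[float, ...]]
    true_cbr: dict[int, float]
    national_asfr: dict[int, tuple[float, ...]]
    asfr_tables: dict[int, pd.DataFrame]            # subnational countries
    registered_births: dict[int, pd.DataFrame]      # registered-births countries
    totals: pd.DataFrame                            # iso,unpd_births,unpd_population
    components: pd.DataFrame
    expected_pre_total: dict[int, float]
    paths: dict[str, Path] = field(default_factory=dict)


def _rng(seed: int, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, salt]))


def make_scenario(config: ScenarioConfig | None = None, outdir: str | Path | None = None) -> Scenario:
    """Generate a full synthetic world; optionally write all files to ``outdir``."""
    config = config or ScenarioConfig()
    config.validate()
    rows, cols = config.grid_shape
    m = config.margin
    inner_rows, inner_cols = rows - 2 * m, cols - 2 * m

    isos = [10 * (c + 1) for c in range(config.n_countries)]
    flavour = {
        iso: config.flavours[c % len(config.flavours)] for c, iso in enumerate(isos)
    }

    # --- country stripes and zone bands ------------------------------------
    codes_v = np.zeros((rows, cols), dtype=np.int32)
    zones_v = np.zeros((rows, cols), dtype=np.int32)
    outer = np.ones((rows, cols), dtype=bool)
    col_edges = m + np.round(np.linspace(0, inner_cols, config.n_countries + 1)).astype(int)
    row_edges = m + np.round(np.linspace(0, inner_rows, config.zones_per_country + 1)).astype(int)
    zone_ids: dict[int, list[int]] = {}
    for c, iso in enumerate(isos):
        c0, c1 = col_edges[c], col_edges[c + 1]
        codes_v[m : rows - m, c0:c1] = iso
        outer[m : rows - m, c0:c1] = False
        zone_ids[iso] = []
        for k in range(config.zones_per_country):
            zid = iso + k + 1
            zone_ids[iso].append(zid)
            zones_v[row_edges[k] : row_edges[k + 1], c0:c1] = zid

    origin = config.origin
    codes = Grid(codes_v, outer.copy(), origin)
    zones = Grid(zones_v, outer.copy(), origin)

    # --- population surface -------------------------------------------------
    rng = _rng(config.seed, 1)
    pop_v = rng.lognormal(config.pop_mu, config.pop_sigma, size=(rows, cols))
    pop = Grid(np.where(outer, 0.0, pop_v), outer.copy(), origin)

    # --- urban mask ----------------------------------------------------------
    rng = _rng(config.seed, 2)
    urban_v = np.zeros((rows, cols), dtype=np.int32)
    for iso in isos:
        for zid in zone_ids[iso]:
            cells = np.argwhere((zones_v == zid) & ~outer)
            n_urban = int(round(config.urban_fraction * len(cells)))
            if n_urban:
                pick = rng.choice(len(cells), size=n_urban, replace=False)
                urban_v[cells[pick, 0], cells[pick, 1]] = 1
    urban = Grid(urban_v, outer.copy(), origin)

    # --- age-sex proportion table -------------------------------------------
    rng = _rng(config.seed, 3)
    agesex_rows = []
    # Concentration favouring a young-skewed but plausible pyramid.
    base_conc = np.linspace(12.0, 3.0, len(ALL_AGE_GROUPS))
    for iso in isos:
        for zid in zone_ids[iso]:
            props = rng.dirichlet(base_conc)
            props = props / props.sum()
            prop_f = float(rng.uniform(0.49, 0.52))
            row = {"region": zid}
            row.update({f"t_{g}": float(p) for g, p in zip(ALL_AGE_GROUPS, props)})
            row["prop_m_t"] = 1.0 - prop_f
            row["prop_f_t"] = prop_f
            agesex_rows.append(row)
    agesex = pd.DataFrame(agesex_rows)

    # --- true fertility ------------------------------------------------------
    rng = _rng(config.seed, 4)
    base = np.asarray(config.base_asfr)
    true_asfr: dict[tuple[int, str], tuple[float, ...]] = {}
    for iso in isos:
        for zid in zone_ids[iso]:
            level = rng.uniform(1 - config.asfr_jitter, 1 + config.asfr_jitter)
            all_rates = np.clip(base * level, 0.0, 1.0)
            true_asfr[(zid, "all")] = tuple(float(x) for x in all_rates)
            true_asfr[(zid, "urban")] = tuple(
                float(x) for x in np.clip(all_rates * config.urban_factor, 0.0, 1.0)
            )
            true_asfr[(zid, "rural")] = tuple(
                float(x) for x in np.clip(all_rates * config.rural_factor, 0.0, 1.0)
            )
    true_cbr = {iso: float(_rng(config.seed, 5 + iso).uniform(*config.cbr_range)) for iso in isos}
    national_asfr = {
        iso: tuple(
            float(x)
            for x in np.clip(
                base * _rng(config.seed, 90 + iso).uniform(1 - config.asfr_jitter, 1 + config.asfr_jitter),
                0.0,
                1.0,
            )
        )
        for iso in isos
    }

    # --- per-country fertility source tables ---------------------------------
    year = 2015
    asfr_tables: dict[int, pd.DataFrame] = {}
    registered: dict[int, pd.DataFrame] = {}
    # Women per zone per reproductive group, from truth (margin-free totals).
    women_truth: dict[int, dict[str, float]] = {}
    ag = agesex.set_index("region")
    for iso in isos:
        for zid in zone_ids[iso]:
            sel = (zones_v == zid) & ~outer
            ztot = float(pop.values[sel].sum())
            women_truth[zid] = {
                g: ztot * float(ag.loc[zid, f"t_{g}"]) * float(ag.loc[zid, "prop_f_t"])
                for g in REPRODUCTIVE_AGE_GROUPS
            }
    for iso in isos:
        fl = flavour[iso]
        if fl in ("subnational_urban_rural", "subnational"):
            rows_t = []
            strata = ("urban", "rural") if fl == "subnational_urban_rural" else ("all",)
            for zid in zone_ids[iso]:
                for stratum in strata:
                    row = {"ISO": iso, "region": zid, "rural_urban": stratum}
                    for g, r in zip(REPRODUCTIVE_AGE_GROUPS, true_asfr[(zid, stratum)]):
                        row[f"asfr_{g}"] = r
                    row["year"] = year
                    rows_t.append(row)
            asfr_tables[iso] = pd.DataFrame(rows_t, columns=ASFR_COLUMNS)
        elif fl == "registered_births":
            rng_b = _rng(config.seed, 40 + iso)
            rows_b = []
            for zid in zone_ids[iso]:
                row = {"region": zid, "ISO": iso}
                for g, r in zip(REPRODUCTIVE_AGE_GROUPS, true_asfr[(zid, "all")]):
                    lam = r * women_truth[zid][g]
                    row[f"b_{g}"] = int(rng_b.poisson(lam))
                row["year"] = year
                rows_b.append(row)
            registered[iso] = pd.DataFrame(rows_b, columns=BIRTHS_COLUMNS)

    # --- expected pre-scaling births totals (exact, from the same truth) -----
    expected_pre_total: dict[int, float] = {}
    for iso in isos:
        fl = flavour[iso]
        sel_country = (codes_v == iso) & ~outer
        if fl in ("subnational_urban_rural", "subnational"):
            total = 0.0
            for zid in zone_ids[iso]:
                sel = (zones_v == zid) & ~outer
                for stratum_val, stratum in ((1, "urban"), (0, "rural")):
                    if fl == "subnational":
                        key = (zid, "all")
                        ssel = sel
                    else:
                        key = (zid, stratum)
                        ssel = sel & (urban_v == stratum_val)
                    ptot = float(pop.values[ssel].sum())
                    for g, r in zip(REPRODUCTIVE_AGE_GROUPS, true_asfr[key]):
                        total += ptot * float(ag.loc[zid, f"t_{g}"]) * float(ag.loc[zid, "prop_f_t"]) * r
                    if fl == "subnational":
                        break
            expected_pre_total[iso] = total
        elif fl == "registered_births":
            b = registered[iso]
            expected_pre_total[iso] = float(
                b[[f"b_{g}" for g in REPRODUCTIVE_AGE_GROUPS]].to_numpy().sum()
            )
        elif fl == "national_asfr":
            total = 0.0
            for zid in zone_ids[iso]:
                for g, r in zip(REPRODUCTIVE_AGE_GROUPS, national_asfr[iso]):
                    total += women_truth[zid][g] * r
            expected_pre_total[iso] = total
        else:  # cbr
            expected_pre_total[iso] = float(pop.values[sel_country].sum()) * true_cbr[iso]

    # --- national totals ------------------------------------------------------
    rng_t = _rng(config.seed, 6)
    totals_rows = []
    missing_isos = {isos[p - 1] for p in config.births_target_missing if 1 <= p <= len(isos)}
    for iso in isos:
        pop_total = float(pop.values[(codes_v == iso) & ~outer].sum())
        if iso in missing_isos:
            target = np.nan
        else:
            target = expected_pre_total[iso] * float(
                rng_t.lognormal(0.0, config.target_noise_sd)
            )
        totals_rows.append(
            {"iso": iso, "unpd_births": target, "unpd_population": pop_total}
        )
    totals = pd.DataFrame(totals_rows, columns=["iso", "unpd_births", "unpd_population"])

    # --- pregnancy components -------------------------------------------------
    rng_p = _rng(config.seed, 7)
    comp_missing = {isos[p - 1] for p in config.components_missing if 1 <= p <= len(isos)}
    comp_rows = []
    for c, iso in enumerate(isos):
        c0, c1 = col_edges[c], col_edges[c + 1]
        lon = origin[0] + (c0 + c1) / 2 * MASTER_CELL_SIZE
        lat = origin[1] - rows / 2 * MASTER_CELL_SIZE
        t = totals.set_index("iso").loc[iso, "unpd_births"]
        lb = expected_pre_total[iso] if np.isnan(t) else float(t)
        available = iso not in comp_missing
        comp_rows.append(
            {
                "iso": iso,
                "stillbirths": round(lb * float(rng_p.uniform(0.005, 0.03)), 3),
                "miscarriages": round(lb * float(rng_p.uniform(0.08, 0.15)), 3),
                "abortions": round(lb * float(rng_p.uniform(0.05, 0.30)), 3),
                "live_births": round(lb, 3),
                "lon": lon,
                "lat": lat,
                "available": available,
            }
        )
    components = pd.DataFrame(
        comp_rows,
        columns=["iso", "stillbirths", "miscarriages", "abortions", "live_births", "lon", "lat", "available"],
    )

    scenario = Scenario(
        config=config,
        isos=isos,
        zone_ids=zone_ids,
        flavour=flavour,
        pop=pop,
        codes=codes,
        zones=zones,
        urban=urban,
        agesex=agesex,
        true_asfr=true_asfr,
        true_cbr=true_cbr,
        national_asfr=national_asfr,
        asfr_tables=asfr_tables,
        registered_births=registered,
        totals=totals,
        components=components,
        expected_pre_total=expected_pre_total,
    )
    if outdir is not None:
        _write_scenario(scenario, Path(outdir))
    return scenario


def _write_scenario(s: Scenario, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    paths = s.paths
    for name, grid in (
        ("population", s.pop),
        ("country_codes", s.codes),
        ("zones", s.zones),
        ("urban_mask", s.urban),
    ):
        paths[name] = write_grid(grid, outdir / f"{name}.tif")
    paths["agesex"] = outdir / "agesex.csv"
    s.agesex.to_csv(paths["agesex"], index=False)
    for iso, table in sorted(s.asfr_tables.items()):
        paths[f"asfr_{iso}"] = outdir / f"asfr_{iso}.csv"
        table.to_csv(paths[f"asfr_{iso}"], index=False)
    for iso, table in sorted(s.registered_births.items()):
        paths[f"registered_births_{iso}"] = outdir / f"registered_births_{iso}.csv"
        table.to_csv(paths[f"registered_births_{iso}"], index=False)
    paths["totals"] = outdir / "national_totals.csv"
    s.totals.to_csv(paths["totals"], index=False)
    paths["components"] = outdir / "pregnancy_components.csv"
    s.components.to_csv(paths["components"], index=False)
    manifest = {
        "seed": s.config.seed,
        "n_countries": s.config.n_countries,
        "zones_per_country": s.config.zones_per_country,
        "grid_shape": list(s.config.grid_shape),
        "origin": list(s.config.origin),
        "isos": s.isos,
        "zone_ids": {int(k): [int(z) for z in v] for k, v in s.zone_ids.items()},
        "flavour": {int(k): v for k, v in s.flavour.items()},
        "true_cbr": {int(k): float(v) for k, v in s.true_cbr.items()},
        "national_asfr": {int(k): [float(x) for x in v] for k, v in s.national_asfr.items()},
        "true_asfr": {
            f"{zid}:{stratum}": [float(x) for x in rates]
            for (zid, stratum), rates in sorted(s.true_asfr.items())
        },
        "expected_pre_total": {int(k): float(v) for k, v in s.expected_pre_total.items()},
        "files": {k: str(v.name) for k, v in paths.items()},
    }
    paths["manifest"] = outdir / "manifest.yaml"
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Birth-history simulation
# ---------------------------------------------------------------------------

def simulate_birth_histories(
    true_asfr: Mapping[tuple[int, str], Sequence[float]],
    n_women_per_region: int,
    seed: int,
    interview_cmc: int = _DEFAULT_INTERVIEW_CMC,
    weighted: bool = False,
) -> BirthHistoryDataset:
    """Simulate survey birth histories under known age-specific rates.

    Every woman is interviewed at the common month ``interview_cmc``, her age
    there drawn uniformly over 15-49 completed years.  Her months from the
    month she turns 15 up to the month before interview are traversed; in a
    month at completed age ``a`` a birth occurs independently with
    probability ``ASFR(group of a) / 12``.

    Parameters
    ----------
    true_asfr
        ``(region_id, stratum) -> seven annual rates``; one simulated
        population per key.
    weighted
        When true, sampling weights are drawn uniform on [0.5, 1.5] instead
        of all-ones, exercising the weighted estimator path (the weighted
        estimand is unchanged since weights are independent of fertility).
    """
    if n_women_per_region < 1:
        raise ScenarioConfigError("need at least one woman per region")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    women_frames, birth_frames = [], []
    next_id = 0
    max_months = 35 * 12  # ages 15..49 inclusive
    for (region, stratum), rates in sorted(true_asfr.items()):
        rates = np.asarray(rates, dtype=np.float64)
        if rates.shape != (len(REPRODUCTIVE_AGE_GROUPS),):
            raise ScenarioConfigError(
                f"region {region}/{stratum}: need {len(REPRODUCTIVE_AGE_GROUPS)} rates"
            )
        if (rates < 0).any() or (rates > 1).any():
            raise ScenarioConfigError(f"region {region}/{stratum}: rates outside [0, 1]")
        n = n_women_per_region
        age_months = rng.integers(15 * 12, 50 * 12, size=n)     # completed months
        dob = interview_cmc - age_months
        weights = rng.uniform(0.5, 1.5, size=n) if weighted else np.ones(n)
        ids = next_id + np.arange(n)
        next_id += n

        # Month offset o after turning 15: completed age 15 + o // 12.
        offsets = np.arange(max_months)
        month = dob[:, None] + 15 * 12 + offsets[None, :]
        alive = month < interview_cmc                            # exposure so far
        p = rates[np.minimum(offsets // 60, len(rates) - 1)] / 12.0
        births_mask = alive & (rng.random((n, max_months)) < p[None, :])
        wi, mi = np.nonzero(births_mask)
        women_frames.append(
            pd.DataFrame(
                {
                    "woman_id": ids,
                    "dob_cmc": dob,
                    "interview_cmc": interview_cmc,
                    "weight": weights,
                    "region_id": region,
                    "stratum": stratum,
                }
            )
        )
        birth_frames.append(
            pd.DataFrame(
                {"woman_id": ids[wi], "child_dob_cmc": month[wi, mi]}
            )
        )
    women = pd.concat(women_frames, ignore_index=True)
    births = (
        pd.concat(birth_frames, ignore_index=True)
        if birth_frames
        else pd.DataFrame(columns=["woman_id", "child_dob_cmc"])
    )
    return BirthHistoryDataset(women=women, births=births)


def synthetic_scale_report(
    n_countries: int, noise_sd: float, seed: int, mean_births: float = 50_000.0
) -> pd.DataFrame:
    """A standalone scale report for diagnostic-regression checks.

    Targets are log-normal around ``mean_births``; pre-adjustment totals are
    the targets perturbed by multiplicative log-normal noise of log-sd
    ``noise_sd`` (0 gives a noiseless report).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    target = rng.lognormal(np.log(mean_births), 0.8, size=n_countries)
    pre = target * rng.lognormal(0.0, noise_sd, size=n_countries) if noise_sd > 0 else target.copy()
    return pd.DataFrame(
        {
            "iso": 10 * (np.arange(n_countries) + 1),
            "pre_total": pre,
            "target": target,
            "factor": target / pre,
            "flagged": False,
        }
    )
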
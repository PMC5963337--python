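"""Women-years ASFR estimation, source hierarchy, and rate rasterization."""

import warnings

import numpy as np
import pandas as pd
import pytest

from demogrid import (
    CrudeBirthRate,
    Grid,
    NationalASFR,
    RegisteredBirths,
    REPRODUCTIVE_AGE_GROUPS,
    SubnationalASFR,
    asfr_from_registered_births,
    estimate_asfr_from_histories,
    rasterize_asfr,
    select_fertility_source,
    simulate_birth_histories,
)
from demogrid.fertility import (
    ASFR_COLUMNS,
    BirthHistoryDataset,
    DataError,
    DivisionError,
    NoSourceError,
    SchemaError,
    cbr_per_person,
    cmc,
    cmc_to_year_month,
)

GROUPS = list(REPRODUCTIVE_AGE_GROUPS)


# ---------------------------------------------------------------------------
# Independent month-enumeration oracle
# ---------------------------------------------------------------------------

def women_years_oracle(women, births, window):
    """Exhaustive per-woman-month classification of exposure and births.

    Independent of the estimator: plain Python loops over every woman and
    every calendar month of the window, accumulating weighted month counts
    per (region, stratum, group); converted to woman-years by one final
    division by 12, mirroring exact integer-month bookkeeping.
    """
    num, den_months = {}, {}
    for w in women.itertuples():
        key = (w.region_id, w.stratum)
        num.setdefault(key, [0.0] * 7)
        den_months.setdefault(key, [0.0] * 7)
        for m in range(w.interview_cmc - window, w.interview_cmc):
            age = (m - w.dob_cmc) // 12
            if 15 <= age <= 49:
                den_months[key][(age - 15) // 5] += w.weight
    by_woman = women.set_index("woman_id")
    for b in births.itertuples():
        w = by_woman.loc[b.woman_id]
        if w.interview_cmc - window <= b.child_dob_cmc <= w.interview_cmc - 1:
            age = (b.child_dob_cmc - w.dob_cmc) // 12
            if 15 <= age <= 49:
                num[(w.region_id, w.stratum)][(age - 15) // 5] += w.weight
    den = {k: [m / 12.0 for m in v] for k, v in den_months.items()}
    return num, den


def _random_fixture(n_women, seed, dyadic_weights=True):
    """Small hand-rollable dataset with assorted ages, regions and weights."""
    rng = np.random.default_rng(seed)
    interview = cmc(2014, 7)
    age_months = rng.integers(15 * 12, 50 * 12, size=n_women)
    women = pd.DataFrame(
        {
            "woman_id": np.arange(n_women),
            "dob_cmc": interview - age_months,
            "interview_cmc": interview,
            "weight": rng.choice([0.5, 1.0, 1.5, 2.0], size=n_women)
            if dyadic_weights
            else np.ones(n_women),
            "region_id": rng.choice([1, 2], size=n_women),
            "stratum": rng.choice(["urban", "rural"], size=n_women),
        }
    )
    rows = []
    for w in women.itertuples():
        for _ in range(rng.integers(0, 4)):
            # anywhere from well before the window to the month before interview
            rows.append(
                {
                    "woman_id": w.woman_id,
                    "child_dob_cmc": int(rng.integers(w.dob_cmc + 13 * 12, interview)),
                }
            )
    births = pd.DataFrame(rows) if rows else pd.DataFrame(columns=["woman_id", "child_dob_cmc"])
    return BirthHistoryDataset(women=women, births=births)


class TestWomenYearsEstimator:
    def test_cmc_round_trip(self):
        assert cmc(1900, 1) == 1
        assert cmc(2015, 1) == 1381
        assert cmc_to_year_month(cmc(1987, 11)) == (1987, 11)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_exact_equivalence_with_enumeration_oracle(self, seed):
        data = _random_fixture(50, seed)
        est = estimate_asfr_from_histories(data, window_months=36)
        num_o, den_o = women_years_oracle(data.women, data.births, 36)
        for key in num_o:
            got_num = est.numerators.loc[key].to_numpy()
            got_den = est.denominators.loc[key].to_numpy()
            assert got_num.tolist() == num_o[key]      # exact, no tolerance
            assert got_den.tolist() == den_o[key]

    def test_zero_children_gives_zero_rates_positive_exposure(self):
        data = simulate_birth_histories({(1, "all"): (0.0,) * 7}, 400, seed=2)
        est = estimate_asfr_from_histories(data)
        assert (est.numerators.to_numpy() == 0).all()
        assert est.denominators.to_numpy().sum() > 0
        rates = est.table[[f"asfr_{g}" for g in GROUPS]].to_numpy(float)
        assert np.nansum(rates) == 0.0

    def test_zero_exposure_group_flagged_absent(self):
        # A single 21-year-old woman exposes only groups 15-19 and 20-24
        # inside a 36-month window; the rest must be NaN, not zero.
        women = pd.DataFrame(
            {
                "woman_id": [0],
                "dob_cmc": [cmc(1993, 1)],
                "interview_cmc": [cmc(2014, 6)],
                "weight": [1.0],
                "region_id": [1],
                "stratum": ["all"],
            }
        )
        data = BirthHistoryDataset(women, pd.DataFrame(columns=["woman_id", "child_dob_cmc"]))
        est = estimate_asfr_from_histories(data)
        row = est.table.iloc[0]
        assert not np.isnan(row["asfr_15_19"]) and not np.isnan(row["asfr_20_24"])
        assert np.isnan(row["asfr_25_29"]) and np.isnan(row["asfr_45_49"])

    def test_child_after_interview_rejected(self):
        women = pd.DataFrame(
            {
                "woman_id": [0],
                "dob_cmc": [cmc(1990, 1)],
                "interview_cmc": [cmc(2014, 6)],
                "weight": [1.0],
                "region_id": [1],
                "stratum": ["all"],
            }
        )
        births = pd.DataFrame({"woman_id": [0], "child_dob_cmc": [cmc(2014, 6)]})
        with pytest.raises(DataError, match="interview"):
            BirthHistoryDataset(women, births)

    def test_weighted_equals_oracle(self):
        data = _random_fixture(40, seed=5, dyadic_weights=True)
        est = estimate_asfr_from_histories(data, window_months=24)
        num_o, den_o = women_years_oracle(data.women, data.births, 24)
        for key in num_o:
            assert est.numerators.loc[key].tolist() == num_o[key]
            assert est.denominators.loc[key].tolist() == den_o[key]


class TestRecovery:
    def test_bias_shrinks_with_sample_size(self):
        truth = np.array([0.05, 0.15, 0.18, 0.14, 0.09, 0.04, 0.01])

        def errors(n, seed):
            d = simulate_birth_histories({(1, "all"): tuple(truth)}, n, seed=seed)
            est = estimate_asfr_from_histories(d)
            rates = est.table[[f"asfr_{g}" for g in GROUPS]].to_numpy(float)[0]
            return np.abs(rates - truth)

        # averaged over a few replicates so the comparison reflects bias and
        # variance rather than one draw
        e_small = np.mean([errors(1_000, s) for s in range(3)], axis=0)
        e_large = np.mean([errors(8_000, s) for s in range(3)], axis=0)
        assert (e_large < e_small).sum() >= 6


class TestRegisteredBirths:
    def _venezuela_row(self):
        return pd.DataFrame(
            [
                {
                    "region": 1,
                    "ISO": "VEN",
                    "b_15_19": 111,
                    "b_20_24": 101,
                    "b_25_29": 106,
                    "b_30_34": 58,
                    "b_35_39": 41,
                    "b_40_44": 12,
                    "b_45_49": 4,
                    "year": 2012,
                }
            ]
        )

    def test_division_by_thousand_women(self):
        women = pd.DataFrame({g: [1000.0] for g in GROUPS}, index=pd.Index([1], name="region"))
        out = asfr_from_registered_births(self._venezuela_row(), women)
        rates = out[[f"asfr_{g}" for g in GROUPS]].iloc[0].tolist()
        assert rates == pytest.approx([0.111, 0.101, 0.106, 0.058, 0.041, 0.012, 0.004])
        assert out["rural_urban"].iloc[0] == "all"

    def test_zero_births_zero_rates(self):
        b = self._venezuela_row()
        for g in GROUPS:
            b[f"b_{g}"] = 0
        women = pd.DataFrame({g: [500.0] for g in GROUPS}, index=pd.Index([1], name="region"))
        out = asfr_from_registered_births(b, women)
        assert (out[[f"asfr_{g}" for g in GROUPS]].to_numpy() == 0).all()

    def test_homogeneity_doubled_women_halved_rates(self):
        w1 = pd.DataFrame({g: [800.0] for g in GROUPS}, index=pd.Index([1], name="region"))
        w2 = 2 * w1
        a = asfr_from_registered_births(self._venezuela_row(), w1)
        b = asfr_from_registered_births(self._venezuela_row(), w2)
        cols = [f"asfr_{g}" for g in GROUPS]
        assert np.allclose(b[cols].to_numpy(), a[cols].to_numpy() / 2, rtol=0, atol=0)

    def test_zero_women_with_births_raises(self):
        women = pd.DataFrame({g: [0.0] for g in GROUPS}, index=pd.Index([1], name="region"))
        with pytest.raises(DivisionError, match="15_19"):
            asfr_from_registered_births(self._venezuela_row(), women)


class TestSourceHierarchy:
    def _sources(self):
        table = pd.DataFrame(columns=ASFR_COLUMNS)
        return {
            "sub_ur": SubnationalASFR(table, has_urban_rural=True),
            "sub": SubnationalASFR(table, has_urban_rural=False),
            "reg": RegisteredBirths(pd.DataFrame()),
            "nat": NationalASFR((0.05, 0.1, 0.1, 0.1, 0.05, 0.02, 0.01)),
            "cbr": CrudeBirthRate(0.03),
        }

    def test_national_beats_cbr(self):
        s = self._sources()
        assert select_fertility_source([s["cbr"], s["nat"]]) is s["nat"]

    def test_urban_rural_subnational_beats_registered(self):
        s = self._sources()
        assert select_fertility_source([s["reg"], s["sub_ur"]]) is s["sub_ur"]

    def test_single_source_returned(self):
        s = self._sources()
        assert select_fertility_source([s["cbr"]]) is s["cbr"]

    def test_full_order_and_permutation_invariance(self):
        s = self._sources()
        order = ["sub_ur", "sub", "reg", "nat", "cbr"]
        pool = [s[k] for k in order]
        rng = np.random.default_rng(0)
        for _ in range(10):
            perm = list(rng.permutation(len(pool)))
            assert select_fertility_source([pool[i] for i in perm]) is s["sub_ur"]
        for drop in range(len(order) - 1):
            remaining = [s[k] for k in order[drop + 1 :]]
            assert select_fertility_source(remaining) is s[order[drop + 1]]

    def test_empty_raises(self):
        with pytest.raises(NoSourceError):
            select_fertility_source([])

    def test_cbr_per_thousand_conversion(self):
        assert cbr_per_person(25.0, per_thousand=True) == pytest.approx(0.025)
        assert cbr_per_person(0.025) == 0.025


class TestRasterizeASFR:
    def _haiti_west(self):
        rows = []
        for stratum, rates in (
            ("URBAN", [0.03, 0.15, 0.17, 0.13, 0.08, 0.10, 0.00]),
            ("RURAL", [0.07, 0.18, 0.20, 0.19, 0.18, 0.07, 0.01]),
        ):
            row = {"ISO": "HTI", "region": 1, "rural_urban": stratum}
            row.update({f"asfr_{g}": r for g, r in zip(GROUPS, rates)})
            row["year"] = 2012
            rows.append(row)
        return pd.DataFrame(rows, columns=ASFR_COLUMNS)

    def _zone_and_mask(self, urban_value):
        nomask = np.zeros((1, 1), bool)
        zones = Grid(np.array([[1]], np.int32), nomask.copy(), (-73.0, 19.0))
        urban = Grid(np.array([[urban_value]], np.float64), nomask.copy(), (-73.0, 19.0))
        return zones, urban

    def test_urban_and_rural_cells_get_their_rates(self):
        zones, urban = self._zone_and_mask(1.0)
        out = rasterize_asfr(self._haiti_west(), zones, "20_24", urban_mask=urban)
        assert out.values[0, 0] == 0.15
        zones, rural = self._zone_and_mask(0.0)
        out = rasterize_asfr(self._haiti_west(), zones, "20_24", urban_mask=rural)
        assert out.values[0, 0] == 0.18

    def test_all_stratum_ignores_mask(self):
        rows = [{"ISO": "X", "region": 1, "rural_urban": "all", "year": 2015}]
        rows[0].update({f"asfr_{g}": 0.07 for g in GROUPS})
        table = pd.DataFrame(rows, columns=ASFR_COLUMNS)
        zones = Grid(np.full((3, 3), 1, np.int32), np.zeros((3, 3), bool), (0.0, 0.0))
        out = rasterize_asfr(table, zones, "30_34", urban_mask=None)
        assert (out.values == 0.07).all()

    def test_missing_rural_partner_rejected(self):
        table = self._haiti_west().iloc[:1]  # urban row only
        zones, urban = self._zone_and_mask(1.0)
        with pytest.raises(SchemaError, match="pair"):
            rasterize_asfr(table, zones, "20_24", urban_mask=urban)

    def test_mask_required_for_stratified_rows(self):
        zones, _ = self._zone_and_mask(1.0)
        with pytest.raises(SchemaError, match="urban mask"):
            rasterize_asfr(self._haiti_west(), zones, "20_24", urban_mask=None)

    def test_random_mask_matches_lookup_oracle(self):
        rng = np.random.default_rng(7)
        shape = (8, 8)
        zone_v = rng.choice([1, 2], size=shape).astype(np.int32)
        urban_v = rng.random(shape)
        nomask = np.zeros(shape, bool)
        zones = Grid(zone_v, nomask.copy(), (0.0, 0.0))
        urban = Grid(urban_v, nomask.copy(), (0.0, 0.0))
        rows = []
        rates = {}
        for region in (1, 2):
            for stratum in ("urban", "rural"):
                r = rng.uniform(0.01, 0.3, size=7)
                rates[(region, stratum)] = r
                row = {"ISO": "X", "region": region, "rural_urban": stratum, "year": 2015}
                row.update({f"asfr_{g}": v for g, v in zip(GROUPS, r)})
                rows.append(row)
        table = pd.DataFrame(rows, columns=ASFR_COLUMNS)
        out = rasterize_asfr(table, zones, "25_29", urban_mask=urban)
        for i in range(shape[0]):
            for j in range(shape[1]):
                stratum = "urban" if urban_v[i, j] >= 0.5 else "rural"
                assert out.values[i, j] == rates[(zone_v[i, j], stratum)][2]
        # output value set is exactly the table's rates — no interpolation
        assert set(np.unique(out.values)) <= {rates[k][2] for k in rates}

    def test_extreme_rate_warns(self):
        rows = [{"ISO": "X", "region": 1, "rural_urban": "all", "year": 2015}]
        rows[0].update({f"asfr_{g}": 0.7 for g in GROUPS})
        women = pd.DataFrame({g: [100.0] for g in GROUPS}, index=pd.Index([1], name="region"))
        b = pd.DataFrame(
            [{"region": 1, "ISO": "X", **{f"b_{g}": 70 for g in GROUPS}, "year": 2015}]
        )
        with pytest.warns(UserWarning, match="ASFR above"):
            asfr_from_registered_births(b, women)
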
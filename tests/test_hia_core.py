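"""Health impact function, regridding and stratification."""

import math

import numpy as np
import pandas as pd
import pytest

from smokehia.crfs import get_crf
from smokehia.exposure import FirePMSurface, isolate_fire
from smokehia.hia_core import (CRFSpec, RateAndPopulationGrid, beta_from_rr,
                               excess_admissions, regrid_population,
                               regrid_rates, round_half_up,
                               stratified_assessment)


def fire_surface(vals):
    return FirePMSurface(dx=np.asarray(vals, dtype=float), two_day_averaged=True)


def rp_grid(ynf, pop, county=None, outcome="respiratory"):
    ynf = np.asarray(ynf, dtype=float)
    if county is None:
        county = np.zeros_like(ynf, dtype=int)
    return RateAndPopulationGrid(ynf=ynf, pop=np.asarray(pop, dtype=float),
                                 county_id=county, outcome=outcome)


class TestBeta:
    def test_null_rate_ratio_gives_zero_beta(self):
        crf = CRFSpec("respiratory", "all", "WF", 1.0, 1.0, 1.0)
        assert beta_from_rr(crf) == 0.0

    @pytest.mark.parametrize("rr, pct", [
        (1.028, 2.8), (1.008, 0.8), (1.048, 4.8),   # wildfire-specific
        (1.0207, 2.07), (1.0189, 1.89),             # ambient
    ])
    def test_percent_increase_per_increment(self, rr, pct):
        crf = CRFSpec("respiratory", "all", "WF", rr, rr, rr)
        beta = beta_from_rr(crf)
        assert 100.0 * (math.exp(beta * 10.0) - 1.0) == pytest.approx(pct, abs=1e-9)

    def test_nonpositive_rr_rejected(self):
        with pytest.raises(ValueError):
            CRFSpec("respiratory", "all", "WF", -1.0, -1.0, -1.0)

    def test_ci_must_bracket_rr(self):
        with pytest.raises(ValueError, match="bracket"):
            CRFSpec("respiratory", "all", "WF", 1.05, 1.06, 1.10)


class TestRegridRates:
    def rates_df(self, rows):
        return pd.DataFrame(rows, columns=["county_id", "outcome", "annual_rate_per_100k"])

    def test_annual_365_gives_1e5_daily(self):
        df = self.rates_df([(0, "respiratory", 365.0)])
        ynf = regrid_rates(df, np.zeros((2, 2), dtype=int), "respiratory")
        np.testing.assert_allclose(ynf, 1.0e-5)

    def test_single_county_uniform(self):
        df = self.rates_df([(0, "asthma", 100.0)])
        ynf = regrid_rates(df, np.zeros((3, 4), dtype=int), "asthma")
        assert np.unique(ynf).size == 1

    def test_three_county_map_matches_scalar_lookup(self, rng):
        county = rng.integers(0, 3, size=(5, 5))
        df = self.rates_df([(c, "respiratory", 100.0 * (c + 1)) for c in range(3)])
        ynf = regrid_rates(df, county, "respiratory")
        for j in range(5):
            for i in range(5):
                expect = 100.0 * (county[j, i] + 1) / 100000.0 / 365.0
                assert ynf[j, i] == expect

    def test_missing_county_rejected_with_ids(self):
        df = self.rates_df([(0, "respiratory", 100.0)])
        county = np.array([[0, 1], [2, 0]])
        with pytest.raises(ValueError, match=r"\[1, 2\]"):
            regrid_rates(df, county, "respiratory")


class TestRegridPopulation:
    def test_equal_split_across_cells(self):
        df = pd.DataFrame({
            "tract_id": [0] * 4, "county_id": [0] * 4,
            "x": [0, 1, 0, 1], "y": [0, 0, 1, 1], "population": [100.0] * 4,
        })
        pop = regrid_population(df, (2, 2))
        np.testing.assert_array_equal(pop, np.full((2, 2), 25.0))

    def test_conservation_on_random_fixture(self, rng):
        rows = []
        for tract in range(6):
            cells = rng.choice(25, size=rng.integers(1, 5), replace=False)
            total = float(rng.integers(10, 1000))
            for c in cells:
                rows.append({"tract_id": tract, "county_id": 0,
                             "x": int(c % 5), "y": int(c // 5), "population": total})
        df = pd.DataFrame(rows)
        pop = regrid_population(df, (5, 5))
        totals = df.groupby("tract_id")["population"].first().sum()
        assert pop.sum() == pytest.approx(totals, rel=1e-12)

    def test_two_disjoint_tracts_hand_allocation(self):
        df = pd.DataFrame({
            "tract_id": [0, 0, 1], "county_id": [0, 0, 1],
            "x": [0, 1, 2], "y": [0, 0, 0], "population": [60.0, 60.0, 35.0],
        })
        pop = regrid_population(df, (1, 3))
        np.testing.assert_array_equal(pop, [[30.0, 30.0, 35.0]])

    def test_out_of_grid_tract_rejected(self):
        df = pd.DataFrame({"tract_id": [0], "county_id": [0],
                           "x": [5], "y": [0], "population": [10.0]})
        with pytest.raises(ValueError, match="outside"):
            regrid_population(df, (2, 2))


class TestExcessAdmissions:
    def test_zero_exposure_gives_zero_impact(self):
        dx = fire_surface(np.zeros((3, 2, 2)))
        rp = rp_grid(np.full((2, 2), 1e-5), np.full((2, 2), 1000.0))
        res = excess_admissions(dx, get_crf("respiratory"), rp)
        assert res.total == 0.0
        assert np.all(res.daily == 0.0)

    def test_null_crf_gives_zero_impact(self, rng):
        dx = fire_surface(rng.uniform(0, 30, size=(3, 2, 2)))
        rp = rp_grid(np.full((2, 2), 1e-5), np.full((2, 2), 1000.0))
        crf = CRFSpec("respiratory", "all", "WF", 1.0, 1.0, 1.0)
        assert excess_admissions(dx, crf, rp).total == 0.0

    def test_single_cell_hand_evaluation(self):
        # YNF = 1e-5/day, RR = 1.028 at ΔX = 10, Pop = 100,000
        dx = fire_surface([[[10.0]]])
        rp = rp_grid([[1e-5]], [[100000.0]])
        crf = CRFSpec("respiratory", "all", "WF", 1.028, 1.014, 1.041)
        assert excess_admissions(dx, crf, rp).total == pytest.approx(0.028, rel=1e-12)

    def test_linearity_in_population_and_rate(self, rng):
        dx = fire_surface(rng.uniform(0, 30, size=(4, 3, 3)))
        ynf = rng.uniform(1e-6, 1e-4, size=(3, 3))
        pop = rng.uniform(10, 1e4, size=(3, 3))
        crf = get_crf("respiratory")
        base = excess_admissions(dx, crf, rp_grid(ynf, pop)).total
        assert excess_admissions(dx, crf, rp_grid(2 * ynf, pop)).total == pytest.approx(2 * base, rel=1e-12)
        assert excess_admissions(dx, crf, rp_grid(ynf, 2 * pop)).total == pytest.approx(2 * base, rel=1e-12)

    def test_small_exposure_linear_approximation(self):
        crf = get_crf("respiratory")
        dx_val = 0.01 / crf.beta  # β·ΔX = 0.01
        dx = fire_surface([[[dx_val]]])
        rp = rp_grid([[1e-5]], [[1e5]])
        exact = excess_admissions(dx, crf, rp).total
        linear = 1e-5 * crf.beta * dx_val * 1e5
        assert exact == pytest.approx(linear, rel=0.01)

    def test_monotone_in_exposure(self):
        crf = get_crf("respiratory")
        rp = rp_grid([[1e-5]], [[1e5]])
        totals = [excess_admissions(fire_surface([[[v]]]), crf, rp).total
                  for v in (0.0, 5.0, 10.0, 20.0)]
        assert np.all(np.diff(totals) > 0)

    def test_county_partition_additivity(self, small_scenario):
        dx = isolate_fire(small_scenario.surfaces["datafusion"], small_scenario.ratio_bg)
        rp = small_scenario.rate_population_grid("respiratory")
        res = excess_admissions(dx, get_crf("respiratory"), rp)
        assert res.county_totals.sum() == pytest.approx(res.total, rel=1e-9)

    def test_matches_scalar_loop_oracle(self, small_scenario):
        dx = isolate_fire(small_scenario.surfaces["datafusion"], small_scenario.ratio_bg)
        rp = small_scenario.rate_population_grid("respiratory")
        crf = get_crf("respiratory")
        res = excess_admissions(dx, crf, rp)
        beta = math.log(crf.rr) / crf.increment
        for t in (0, dx.n_days - 1):
            for j in range(0, rp.ynf.shape[0], 3):
                for i in range(0, rp.ynf.shape[1], 3):
                    expect = rp.ynf[j, i] * math.expm1(beta * dx.dx[t, j, i]) * rp.pop[j, i]
                    assert res.dy[t, j, i] == expect

    def test_daily_not_averaged_rejected(self):
        dx = FirePMSurface(dx=np.ones((2, 1, 1)), two_day_averaged=False)
        rp = rp_grid([[1e-5]], [[10.0]])
        with pytest.raises(ValueError, match="2-day"):
            excess_admissions(dx, get_crf("respiratory"), rp)


class TestStratification:
    def test_partitioned_population_with_shared_crf_is_additive(self, rng):
        dx = fire_surface(rng.uniform(0, 25, size=(3, 4, 4)))
        ynf = np.full((4, 4), 2e-5)
        pop = rng.uniform(100, 5000, size=(4, 4))
        split = rng.uniform(0.2, 0.8, size=(4, 4))
        crf_all = get_crf("respiratory")
        shared = CRFSpec("respiratory", "young", "WF", crf_all.rr, crf_all.rr_lo, crf_all.rr_hi)
        shared2 = CRFSpec("respiratory", "old", "WF", crf_all.rr, crf_all.rr_lo, crf_all.rr_hi)
        res = stratified_assessment(
            dx, [shared, shared2],
            {"young": rp_grid(ynf, pop * split), "old": rp_grid(ynf, pop * (1 - split))})
        total_all = excess_admissions(dx, crf_all, rp_grid(ynf, pop)).total
        assert res["young"].total + res["old"].total == pytest.approx(total_all, rel=1e-12)

    def test_protective_rr_gives_negative_estimate(self):
        crf = get_crf("asthma", "WF", "ages_5_19")  # RR 0.999 < 1
        dx = fire_surface([[[10.0]]])
        res = excess_admissions(dx, crf, rp_grid([[1e-5]], [[1e6]]))
        assert res.total < 0

    def test_missing_subgroup_grid_rejected(self):
        crf = get_crf("asthma", "WF", "female")
        with pytest.raises(ValueError, match="subgroup"):
            stratified_assessment(fire_surface([[[1.0]]]), [crf], {})


class TestRounding:
    @pytest.mark.parametrize("x, expect", [
        (0.4, 0), (0.5, 1), (1.5, 2), (2.49, 2), (-0.5, -1), (-1.6, -2), (239.5, 240),
    ])
    def test_round_half_up(self, x, expect):
        assert round_half_up(x) == expect
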
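"""Synthetic-data generators: calibration, price bands, condition registry."""
import numpy as np
import pytest

import mupsim as m
from mupsim.categories import N_BEVERAGES, N_SUBGROUPS
from mupsim.harm import registry_from_json, registry_to_json
from mupsim.synthetic import (
    BandTargets,
    CalibrationTable,
    DEFAULT_BAND_TARGETS,
    band_shares,
)


class TestPopulationCalibration:
    def test_rejects_small_n_and_bad_shares(self):
        with pytest.raises(ValueError):
            m.generate_population(100, seed=0)
        bad = CalibrationTable(drinker_share_by_quintile=(0.3, 0.2, 0.1, 0.1, 0.1))
        with pytest.raises(ValueError):
            m.generate_population(2_000, bad, seed=0)

    def test_full_abstention_degenerate(self):
        cal = CalibrationTable(abstention_by_quintile=(1.0,) * 5)
        pop = m.generate_population(2_000, cal, seed=0)
        assert np.all(pop.total_units == 0)

    def test_same_seed_is_bit_identical(self):
        a = m.generate_population(2_000, seed=3)
        b = m.generate_population(2_000, seed=3)
        np.testing.assert_array_equal(a.units, b.units)
        np.testing.assert_array_equal(a.simd_quintile, b.simd_quintile)

    def test_marginals_match_calibration(self, pop_mid):
        """Abstention, drinker-group shares and mean units per drinker by
        SIMD quintile reproduce the calibration within Monte-Carlo slack."""
        cal = m.DEFAULT_CALIBRATION
        w = pop_mid.weight
        total = pop_mid.total_units
        for q in range(1, 6):
            mask = pop_mid.simd_quintile == q
            abst = np.average(total[mask] == 0, weights=w[mask])
            assert abst == pytest.approx(
                cal.abstention_by_quintile[q - 1], rel=0.05)
            d = mask & (total > 0)
            mean_units = np.average(total[d], weights=w[d])
            assert mean_units == pytest.approx(
                cal.mean_units_by_quintile[q - 1], rel=0.04)
        group = pop_mid.drinker_group
        drinkers = group > 0
        for gi, target in enumerate(cal.drinker_group_shares, start=1):
            share = np.average(group[drinkers] == gi, weights=w[drinkers])
            assert share == pytest.approx(target, rel=0.06)
        assert w.sum() == pytest.approx(cal.national_adult_population)

    def test_abstainer_iff_zero_units(self, pop_mid):
        group = pop_mid.drinker_group
        np.testing.assert_array_equal(group == 0, pop_mid.total_units == 0)

    def test_csv_round_trip(self, tmp_path):
        pop = m.generate_population(1_500, seed=5)
        path = tmp_path / "pop.csv"
        pop.to_csv(path)
        back = m.Population.from_csv(path)
        np.testing.assert_allclose(back.units, pop.units)
        np.testing.assert_array_equal(back.simd_quintile, pop.simd_quintile)


class TestPriceDistributions:
    def test_eight_thousand_distributions(self, pop_mid):
        ps = m.generate_price_distributions(pop_mid, seed=2)
        cells = set(zip(ps.subgroup_id.tolist(), ps.beverage_id.tolist()))
        assert len(cells) == N_SUBGROUPS * N_BEVERAGES == 8_000

    def test_band_targets_reproduced(self, pop_mid):
        """Population-weighted aggregate band shares under the £0.50 floor
        match the targets by drinker group and SIMD within ±0.5 pp."""
        ps = m.generate_price_distributions(pop_mid, seed=2)
        ps.set_from_original(0.50)
        got = band_shares(ps, pop_mid, by="drinker_group")
        want = np.array([DEFAULT_BAND_TARGETS.by_drinker_group[k]
                         for k in ("moderate", "hazardous", "harmful")])
        assert np.abs(got - want).max() < 0.005
        got_q = band_shares(ps, pop_mid, by="simd")
        want_q = np.array([DEFAULT_BAND_TARGETS.by_simd_quintile[q]
                           for q in range(1, 6)])
        assert np.abs(got_q - want_q).max() < 0.005

    def test_single_band_target_bounds_all_prices(self, pop_mid):
        targets = BandTargets(
            by_drinker_group={k: (0, 0, 0, 1.0) for k in
                              ("moderate", "hazardous", "harmful")},
            by_simd_quintile={q: (0, 0, 0, 1.0) for q in range(1, 6)},
        )
        ps = m.generate_price_distributions(
            pop_mid, targets, seed=2, sub_threshold_fraction=0.0)
        assert ps.price_pence.min() >= 80.0

    def test_two_band_toy_target_exact_by_tabulation(self, pop_mid):
        targets = BandTargets(
            by_drinker_group={k: (0.5, 0, 0, 0.5) for k in
                              ("moderate", "hazardous", "harmful")},
            by_simd_quintile={q: (0.5, 0, 0, 0.5) for q in range(1, 6)},
        )
        ps = m.generate_price_distributions(
            pop_mid, targets, seed=2, sub_threshold_fraction=0.0)
        # brute-force tabulation of one generated distribution
        sg = int(pop_mid.subgroup_id[pop_mid.total_units > 0][0])
        dist = ps.get(sg, 0)
        low = dist.shares[dist.prices < 0.60].sum()
        high = dist.shares[dist.prices >= 0.80].sum()
        assert low == pytest.approx(0.5, abs=1e-9)
        assert high == pytest.approx(0.5, abs=1e-9)

    def test_invalid_band_shares_rejected(self, pop_mid):
        targets = BandTargets(
            by_drinker_group={"moderate": (0.5, 0.2, 0.2, 0.2),
                              "hazardous": (0.5, 0.2, 0.2, 0.1),
                              "harmful": (0.5, 0.2, 0.2, 0.1)},
        )
        with pytest.raises(ValueError):
            m.generate_price_distributions(pop_mid, targets, seed=2)


class TestConditionRegistry:
    def test_minimal_registry_covers_all_categories(self):
        conds = m.generate_condition_registry(4, seed=0)
        assert sorted(c.category for c in conds) == sorted(
            ["wholly-chronic", "wholly-acute", "partial-chronic", "partial-acute"])

    def test_default_registry_has_45_conditions(self):
        conds = m.generate_condition_registry(seed=0)
        assert len(conds) == 45
        groups = {c.group for c in conds}
        assert groups == {"liver disease", "mental & behavioural due to alcohol",
                          "cancers", "cardiovascular", "injuries", "other"}

    def test_cardioprotective_condition_has_rr_below_one_at_low_intake(self):
        conds = m.generate_condition_registry(seed=0)
        ihd = next(c for c in conds if c.name == "ischaemic heart disease")
        assert m.relative_risk(ihd, 10.0) < 1.0
        assert m.relative_risk(ihd, 0.0) == pytest.approx(1.0)

    def test_too_few_conditions_rejected(self):
        with pytest.raises(ValueError):
            m.generate_condition_registry(3, seed=0)

    def test_json_round_trip(self, tmp_path):
        conds = m.generate_condition_registry(6, seed=1)
        path = tmp_path / "registry.json"
        registry_to_json(conds, path)
        back = registry_from_json(path)
        assert [c.name for c in back] == [c.name for c in conds]
        np.testing.assert_allclose(
            back[0].baseline_mortality, conds[0].baseline_mortality)


class TestOtherTables:
    def test_inflation_series(self):
        infl = m.generate_inflation_series()
        assert infl["RPI"].values[2017] == 1.0
        assert infl["RPI"].factor(2017, 2018) == pytest.approx(1.035)
        assert set(infl["CPIH"].values) == set(range(2017, 2041))

    def test_life_table_monotone_and_clipped(self):
        lt = m.generate_life_table()
        assert lt.remaining(18, 0) > lt.remaining(60, 0) > lt.remaining(99, 0)
        assert lt.remaining(150, 1) == lt.remaining(100, 1)

    def test_elasticity_csv_round_trip(self, tmp_path):
        es = m.generate_elasticities("base")
        p, c = tmp_path / "part.csv", tmp_path / "cond.csv"
        es.to_csv(p, c)
        back = m.ElasticitySet.from_csv(p, c)
        np.testing.assert_allclose(back.conditional, es.conditional)
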
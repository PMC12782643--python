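"""Risk functions, lags, PIF, death simulation, YLL."""
import numpy as np
import pandas as pd
import pytest

import mupsim as m
from mupsim.categories import N_BEVERAGES
from mupsim.harm import (
    Condition,
    N_STRATA,
    make_lag_curve,
    yll_rate,
)


def chronic(beta1, beta2=0.0, lag=None):
    return Condition(
        name="test", group="cancers", category="partial-chronic",
        risk_params={"beta1": beta1, "beta2": beta2},
        lag_curve=make_lag_curve(10) if lag is None else lag)


class TestEffectiveConsumption:
    def test_constant_history_is_current(self):
        hist = np.full(8, 12.0)
        assert m.effective_consumption(hist, make_lag_curve(10)) == pytest.approx(12.0)

    def test_step_change_partial_lag(self):
        """Step from 20 to 10 with cumulative lag 0.4 one year on: 16."""
        lag = np.array([0.1, 0.4, 1.0])
        hist = np.array([20.0, 10.0, 10.0])  # change one year ago
        assert m.effective_consumption(hist, lag) == pytest.approx(20 - 0.4 * 10)

    def test_instantaneous_lag_tracks_current(self):
        lag = make_lag_curve(1)
        hist = np.array([30.0, 5.0, 17.0])
        assert m.effective_consumption(hist, lag) == pytest.approx(17.0)

    def test_vectorised_matches_scalar(self):
        lag = make_lag_curve(10)
        H = np.abs(np.random.default_rng(0).normal(10, 4, size=(6, 50)))
        vec = m.effective_consumption(H, lag)
        for i in (0, 17, 49):
            assert vec[i] == pytest.approx(
                float(m.effective_consumption(H[:, i], lag)))

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            m.effective_consumption(np.empty((0,)), make_lag_curve(5))


class TestRelativeRisk:
    def test_partial_reference_level(self):
        assert m.relative_risk(chronic(0.02), 0.0) == pytest.approx(1.0)

    def test_log_linear_doubling(self):
        c = chronic(np.log(2) / 20)
        assert m.relative_risk(c, 20.0) == pytest.approx(2.0)

    def test_protective_cap(self):
        c = chronic(-0.01, 0.0003)
        assert m.relative_risk(c, 15.0) < 1.0
        assert m.relative_risk(c, 15.0, cap_protective=True) == pytest.approx(1.0)

    def test_wholly_attributable_zero_at_zero(self):
        c = Condition(
            name="w", group="liver disease", category="wholly-chronic",
            risk_params={"x_ref": 60.0, "gamma": 2.0}, lag_curve=make_lag_curve(10))
        assert m.relative_risk(c, 0.0) == 0.0
        assert m.relative_risk(c, 60.0) == pytest.approx(1.0)

    def test_negative_units_rejected(self):
        with pytest.raises(ValueError):
            m.relative_risk(chronic(0.01), -2.0)

    def test_occasion_model_consistency(self):
        om = m.OccasionModel()
        assert om.annual_binges(0.0) == 0.0
        u = np.array([5.0, 25.0, 70.0])
        # occasions x mean size recovers weekly units (annualised intake 52u)
        np.testing.assert_allclose(
            om.occasions_per_week(u) * om.mean_occasion_size(u), u)
        assert np.all(np.diff(om.annual_binges(u)) > 0)

    def test_lag_curve_invariants_enforced(self):
        with pytest.raises(ValueError):
            chronic(0.01, lag=np.array([0.5, 0.4, 1.0]))  # decreasing
        with pytest.raises(ValueError):
            chronic(0.01, lag=np.array([0.2, 0.6]))  # never reaches 1


class TestPIF:
    def test_null_comparison(self):
        rr = np.array([1.0, 2.0, 1.4])
        w = np.ones(3)
        assert m.potential_impact_fraction(rr, rr, w) == 0.0

    def test_hand_fraction(self):
        pif = m.potential_impact_fraction([1.0, 2.0], [1.0, 1.5], [1.0, 1.0])
        assert pif == pytest.approx(1 - 2.5 / 3)

    def test_all_reference_risk(self):
        assert m.potential_impact_fraction([1, 1], [1, 1], [2, 3]) == 0.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            m.potential_impact_fraction([0.0], [1.0], [1.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            m.potential_impact_fraction([], [], [])


def uniform_population(n, weight=1.0):
    units = np.zeros((n, N_BEVERAGES))
    return m.Population(
        age=np.full(n, 40), sex=np.zeros(n, dtype=np.int8),
        income_quintile=np.ones(n, dtype=np.int8),
        simd_quintile=np.ones(n, dtype=np.int8),
        smoking_group=np.zeros(n, dtype=np.int8),
        weight=np.full(n, weight), units=units,
    )


def tiny_ledger():
    conds = m.generate_condition_registry(4, seed=0)
    C = len(conds)
    return m.RateLedger(
        conditions=conds,
        mortality=np.zeros((C, N_STRATA)),
        morbidity=np.zeros((C, N_STRATA)),
    )


class TestSimulateDeaths:
    def test_zero_rates_no_deaths(self):
        pop = uniform_population(500)
        rec = m.simulate_deaths(
            pop, np.zeros((500, 4)), np.zeros(500),
            np.random.default_rng(0), tiny_ledger())
        assert len(rec) == 0
        assert pop.alive.all()

    def test_poisson_expectation(self):
        """10,000 individuals at hazard 0.01/yr: ~99.5 deaths expected."""
        counts = []
        for seed in range(100):
            pop = uniform_population(10_000)
            rec = m.simulate_deaths(
                pop, np.zeros((10_000, 4)), np.full(10_000, 0.01),
                np.random.default_rng(seed), tiny_ledger())
            counts.append(len(rec))
        expect = 10_000 * (1 - np.exp(-0.01))
        se = np.sqrt(expect / 100)
        assert abs(np.mean(counts) - expect) < 3 * se

    def test_doubling_rates_weakly_increases_deaths(self):
        n = 5_000
        base = np.full(n, 0.02)
        pop1, pop2 = uniform_population(n), uniform_population(n)
        u = np.random.default_rng(5).random(n)
        r1 = m.simulate_deaths(pop1, np.zeros((n, 4)), base,
                               np.random.default_rng(1), tiny_ledger(), uniforms=u)
        r2 = m.simulate_deaths(pop2, np.zeros((n, 4)), 2 * base,
                               np.random.default_rng(1), tiny_ledger(), uniforms=u)
        assert len(r2) >= len(r1)
        assert set(r1["id"]) <= set(r2["id"])  # nested under common randoms


class TestYLL:
    def test_no_deaths_zero(self):
        lt = m.generate_life_table()
        out = m.years_of_life_lost(pd.DataFrame(columns=["age", "sex", "weight"]), lt)
        assert out["yll"].sum() == 0
        assert yll_rate(0.0, 100_000) == 0.0

    def test_single_death_rate(self):
        lt = m.LifeTable(expectancy=np.vstack([
            np.maximum(0.0, 10.0 - 0.0 * np.arange(101))] * 2))
        rec = pd.DataFrame({"age": [50], "sex": [0], "weight": [1.0]})
        out = m.years_of_life_lost(rec, lt)
        assert out["yll"].iloc[0] == pytest.approx(10.0)
        assert yll_rate(out["yll"].sum(), 100_000) == pytest.approx(10.0)

    def test_younger_deaths_lose_more_years(self):
        lt = m.generate_life_table()
        rec = pd.DataFrame({"age": [30, 70], "sex": [1, 1], "weight": [1.0, 1.0]})
        out = m.years_of_life_lost(rec, lt)
        assert out["yll"].iloc[0] > out["yll"].iloc[1]


class TestHospitalisations:
    def test_expected_admissions_and_rate_scaling(self):
        from mupsim.harm import hospitalisation_counts
        w = np.full(1_000, 1.0)
        zero = np.zeros((1_000, 2))
        np.testing.assert_allclose(hospitalisation_counts(w, zero), [0.0, 0.0])
        morb = np.full((1_000, 2), 0.02)
        np.testing.assert_allclose(hospitalisation_counts(w, morb), [20.0, 20.0])
        halved = morb.copy()
        halved[:, 0] *= 0.5  # a PIF of 0.5 on one condition halves its admissions
        np.testing.assert_allclose(
            hospitalisation_counts(w, halved), [10.0, 20.0])
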
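"""Annual-cycle simulation: determinism, accounting, ageing, comparison."""
import numpy as np
import pandas as pd
import pytest
from dataclasses import replace as dc_replace

import mupsim as m
from mupsim.categories import N_BEVERAGES
from mupsim.engine import age_population
from mupsim.synthetic import DEFAULT_AGE_PROFILE


@pytest.fixture(scope="module")
def paired_runs(inputs_small):
    ctrl = m.run_scenario(inputs_small, m.CONTROL, seed=7)
    i65 = m.run_scenario(
        inputs_small, m.Scenario(name="0.65", threshold_2019=0.65), seed=7)
    return ctrl, i65


class TestDeterminismAndNull:
    def test_same_seed_bit_identical(self, inputs_small):
        a = m.run_scenario(inputs_small, m.CONTROL, seed=7, end_year=2025)
        b = m.run_scenario(inputs_small, m.CONTROL, seed=7, end_year=2025)
        for measure in a.tables:
            pd.testing.assert_frame_equal(a.tables[measure], b.tables[measure])

    def test_intervention_equal_to_control_differs_nowhere(self, inputs_small):
        """Common random numbers: a £0.50 'intervention' reproduces the
        control exactly, so every reported difference is zero."""
        ctrl = m.run_scenario(inputs_small, m.CONTROL, seed=7, end_year=2026)
        same = m.run_scenario(
            inputs_small, m.Scenario(name="alias", threshold_2019=0.50),
            seed=7, end_year=2026)
        comp = m.compare_scenarios(same, ctrl)
        for measure, df in comp.annual_diff.items():
            assert (df.to_numpy() == 0).all(), measure

    def test_null_dynamics_freeze_consumption_and_deaths(self, inputs_small):
        """Zero elasticities, flat age profile and zero hazards: consumption
        stays constant every year and nobody dies."""
        C = len(inputs_small.ledger.conditions)
        frozen = dc_replace(
            inputs_small,
            elasticities={"base": m.ElasticitySet(
                participation=np.zeros((10, 10)),
                conditional=np.zeros((10, 10)))},
            age_profile=np.ones(4),
            ledger=m.RateLedger(
                conditions=inputs_small.ledger.conditions,
                mortality=np.zeros_like(inputs_small.ledger.mortality),
                morbidity=np.zeros_like(inputs_small.ledger.morbidity),
            ),
        )
        res = m.run_scenario(
            frozen, m.Scenario(name="0.80", threshold_2019=0.80),
            seed=7, end_year=2026)
        units = res.annual("mean_units_per_drinker")["overall"]
        np.testing.assert_allclose(units, units.iloc[0], rtol=1e-9)
        assert (res.annual("deaths")["overall"] == 0).all()
        py = res.annual("person_years")["overall"]
        np.testing.assert_allclose(py, py.iloc[0], rtol=1e-12)


class TestAccounting:
    def test_population_conservation(self, paired_runs):
        """Initial weighted population = survivors + cumulative deaths,
        every year, both scenarios."""
        for res in paired_runs:
            py = res.annual("person_years")["overall"]
            deaths = res.annual("deaths")["overall"]
            for t in range(1, len(py)):
                assert py.iloc[t] == pytest.approx(
                    py.iloc[0] - deaths.iloc[:t].sum(), rel=1e-9)

    def test_person_years_consistent_with_weights(self, inputs_small, paired_runs):
        ctrl, _ = paired_runs
        assert ctrl.annual("person_years")["overall"].iloc[0] == pytest.approx(
            inputs_small.population.weight.sum())

    def test_quintile_columns_sum_to_overall(self, paired_runs):
        ctrl, _ = paired_runs
        for measure in ("deaths", "person_years", "hospitalisations", "yll"):
            df = ctrl.annual(measure)
            np.testing.assert_allclose(
                df[[1, 2, 3, 4, 5]].sum(axis=1), df["overall"], rtol=1e-9)

    def test_group_counts_sum_to_population(self, inputs_small, paired_runs):
        ctrl, _ = paired_runs
        counts = ctrl.annual("drinker_group_counts")
        py = ctrl.annual("person_years")["overall"]
        np.testing.assert_allclose(counts.sum(axis=1), py, rtol=1e-9)


class TestPolicyDirection:
    def test_intervention_reduces_consumption_every_policy_year(self, paired_runs):
        ctrl, i65 = paired_runs
        diff = (i65.annual("mean_units_per_drinker")["overall"]
                - ctrl.annual("mean_units_per_drinker")["overall"])
        assert (diff.loc[2019:] < 0).all()
        assert abs(diff.loc[:2018]).max() == 0

    def test_removal_has_opposite_sign(self, inputs_small, paired_runs):
        ctrl, i65 = paired_runs
        rem = m.run_scenario(
            inputs_small, m.Scenario(name="removed", threshold_2019=None), seed=7)
        comp_rem = m.compare_scenarios(rem, ctrl)
        comp_65 = m.compare_scenarios(i65, ctrl)
        assert comp_rem.consumption_pct_change["overall"] > 0
        assert comp_65.consumption_pct_change["overall"] < 0
        assert comp_rem.cumulative_death_change["overall"] >= 0
        assert comp_65.cumulative_death_change["overall"] <= 0


class TestAgeing:
    def _pop(self, age):
        units = np.zeros((1, N_BEVERAGES))
        units[0, 0] = 16.0
        return m.Population(
            age=np.array([age]), sex=np.array([1], dtype=np.int8),
            income_quintile=np.array([3], dtype=np.int8),
            simd_quintile=np.array([3], dtype=np.int8),
            smoking_group=np.array([0], dtype=np.int8),
            weight=np.array([1.0]), units=units)

    def test_within_band_unchanged(self):
        pop = self._pop(40)
        age_population(pop, DEFAULT_AGE_PROFILE)
        assert pop.age[0] == 41
        assert pop.total_units[0] == pytest.approx(16.0)

    def test_band_crossing_rescales_by_ratio(self):
        pop = self._pop(34)  # crosses 34 -> 35 into the next band
        profile = np.array([1.0, 12.0, 9.0, 1.0])
        age_population(pop, profile)
        assert pop.total_units[0] == pytest.approx(16.0 * 9.0 / 12.0)

    def test_abstainer_stays_zero(self):
        pop = self._pop(34)
        pop.units[:] = 0.0
        age_population(pop, DEFAULT_AGE_PROFILE)
        assert pop.total_units[0] == 0.0

    def test_zero_band_mean_left_unscaled(self):
        pop = self._pop(34)
        profile = np.array([1.0, 0.0, 9.0, 1.0])
        age_population(pop, profile)
        assert pop.total_units[0] == pytest.approx(16.0)


class TestComparison:
    def test_self_comparison_all_zero(self, paired_runs):
        ctrl, _ = paired_runs
        comp = m.compare_scenarios(ctrl, ctrl)
        for df in comp.annual_diff.values():
            assert (df.to_numpy() == 0).all()
        assert comp.consumption_pct_change["overall"] == 0

    def test_toy_cumulative_difference(self, paired_runs):
        ctrl, _ = paired_runs
        years = ctrl.years
        mk = lambda v: pd.DataFrame(
            {"overall": v, 1: v / 5, 2: v / 5, 3: v / 5, 4: v / 5, 5: v / 5},
            index=pd.Index(years, name="year"))
        a = m.ScenarioResult("a", 7, years, {"deaths": mk(100.0)})
        b = m.ScenarioResult("b", 7, years, {"deaths": mk(90.0)})
        diff = (b.tables["deaths"] - a.tables["deaths"])["overall"]
        assert diff.loc[years[:20]].sum() == pytest.approx(-200.0)

    def test_mismatched_horizons_rejected(self, inputs_small, paired_runs):
        ctrl, _ = paired_runs
        short = m.run_scenario(inputs_small, m.CONTROL, seed=7, end_year=2025)
        with pytest.raises(ValueError):
            m.compare_scenarios(short, ctrl)

    def test_quintile_share_of_change(self, paired_runs):
        ctrl, i65 = paired_runs
        comp = m.compare_scenarios(i65, ctrl)
        # expected deaths are continuous, so the change is nonzero even
        # when the simulated-death quantum yields a tie at small n
        shares = comp.quintile_share_of_change("expected_deaths")
        assert shares.sum() == pytest.approx(100.0)


class TestResultIO:
    def test_csv_round_trip(self, paired_runs, tmp_path):
        ctrl, _ = paired_runs
        path = tmp_path / "res.csv"
        ctrl.to_csv(path)
        back = m.ScenarioResult.from_csv(path)
        assert back.name == ctrl.name and back.years == ctrl.years
        pd.testing.assert_frame_equal(
            back.annual("deaths")[["overall", 1, 2, 3, 4, 5]],
            ctrl.annual("deaths")[["overall", 1, 2, 3, 4, 5]],
            check_names=False)
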
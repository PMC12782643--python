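"""Paired control/intervention annual-cycle microsimulation.

Each scenario runs on annual cycles from a pre-policy initialisation year
to the end of the horizon.  Within a year the engine uprates prices and
the MUP threshold, applies the policy transform to the price
distributions, converts the price contrast against the same-year control
scenario into consumption responses via elasticities, reassigns drinker
groups and subgroups, evaluates lagged relative risks, updates mortality
and hospitalisation rates with the Potential Impact Fraction, simulates
deaths, ages the survivors, and records outputs.

Control and intervention consume identical random streams (common random
numbers) so outcome differences reflect policy, not sampling noise.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .categories import (
    CONDITION_GROUPS,
    DRINKER_GROUPS,
    N_BEVERAGES,
    N_DRINKER_GROUPS,
)
from .consumption import ElasticitySet
from .harm import (
    OccasionModel,
    effective_consumption,
    simulate_deaths,
    years_of_life_lost,
)
from .population import Population
from .prices import PolicySchedule, build_schedule
from .synthetic import SimulationInputs

log = logging.getLogger(__name__)

QUINTILE_COLS = ["overall", 1, 2, 3, 4, 5]
GROUP_COLS = list(DRINKER_GROUPS)
CAUSE_COLS = list(CONDITION_GROUPS) + ["other causes"]


@dataclass(frozen=True)
class Scenario:
    """One policy scenario plus sensitivity flags.

    ``threshold_2019`` is the MUP level from the policy year onwards
    (None removes the MUP); the control scenario keeps £0.50.  From the
    year after the policy year every threshold is uprated in real terms
    by the MUP inflation index, so intervention and control differ only
    in the policy-year threshold level.
    """

    name: str
    threshold_2019: float | None = 0.50
    price_index: str = "RPI"          # SA1 overrides to CPIH
    elasticity_set: str = "base"      # SA2 selects "alternative"
    cap_protective_rr: bool = False   # SA4
    policy: PolicySchedule | None = None

    def schedule(self, inputs: SimulationInputs, start: int, end: int) -> PolicySchedule:
        if self.policy is not None:
            return self.policy
        return build_schedule(
            self.name, self.threshold_2019, inputs.inflation["CPIH"],
            start_year=start, end_year=end, price_index_name=self.price_index,
        )


CONTROL = Scenario(name="control", threshold_2019=0.50)


@dataclass(eq=False)
class ScenarioResult:
    """Per-year, per-stratum outcome ledger for one scenario run."""

    name: str
    seed: int
    years: list[int]
    tables: dict[str, pd.DataFrame]

    def annual(self, measure: str) -> pd.DataFrame:
        return self.tables[measure]

    def cumulative(self, measure: str) -> pd.Series:
        return self.tables[measure].sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for measure, df in self.tables.items():
            long = df.reset_index().melt(
                id_vars="year", var_name="stratum", value_name="value")
            long.insert(0, "measure", measure)
            rows.append(long)
        out = pd.concat(rows, ignore_index=True)
        out.insert(0, "scenario", self.name)
        out.insert(1, "seed", self.seed)
        return out

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ScenarioResult":
        tables = {}
        for measure, sub in df.groupby("measure", sort=False):
            wide = sub.pivot(index="year", columns="stratum", values="value")
            wide.columns = [
                int(c) if str(c).isdigit() else c for c in wide.columns]
            tables[measure] = wide
        years = sorted(df["year"].unique())
        return cls(
            name=str(df["scenario"].iloc[0]), seed=int(df["seed"].iloc[0]),
            years=[int(y) for y in years], tables=tables,
        )

    @classmethod
    def from_csv(cls, path) -> "ScenarioResult":
        return cls.from_frame(pd.read_csv(path))


def age_population(
    population: Population,
    age_profile: np.ndarray,
    extra_units: np.ndarray | None = None,
) -> None:
    """Age everyone by one year, in place.

    On crossing an age-band boundary an individual's beverage units are
    rescaled by the ratio of the new to old band's mean-consumption
    multiplier (abstainers stay at zero).  ``extra_units`` is an optional
    second (n, 10) array to rescale identically (e.g. a counterfactual
    consumption path).
    """
    old_band = population.age_band
    population.age = population.age + 1
    new_band = population.age_band
    crossed = new_band != old_band
    if not crossed.any():
        return
    old_mult = age_profile[old_band[crossed]]
    new_mult = age_profile[new_band[crossed]]
    bad = old_mult <= 0
    if bad.any():
        log.warning("zero old-band mean for %d individuals; left unscaled",
                    int(bad.sum()))
    ratio = np.where(bad, 1.0, new_mult / np.where(bad, 1.0, old_mult))
    population.units[crossed] *= ratio[:, None]
    if extra_units is not None:
        extra_units[crossed] *= ratio[:, None]


def _year_rng(seed: int, year: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, year, stream]))


def _distinct_lag_curves(conditions):
    curves, index = [], []
    for c in conditions:
        for i, lc in enumerate(curves):
            if len(lc) == len(c.lag_curve) and np.array_equal(lc, c.lag_curve):
                index.append(i)
                break
        else:
            index.append(len(curves))
            curves.append(np.asarray(c.lag_curve))
    return curves, np.asarray(index)


def _rr_from_effective(cond, eff, binges, occasion_model, cap):
    p = cond.risk_params
    if cond.category == "partial-chronic":
        rr = np.exp(p["beta1"] * eff + p.get("beta2", 0.0) * eff**2)
    elif cond.category == "partial-acute":
        rr = 1.0 + (p["rr_per_binge"] - 1.0) * binges
    elif cond.category == "wholly-chronic":
        rr = (eff / p["x_ref"]) ** p.get("gamma", 1.0)
    else:
        rr = binges / p["binge_ref"]
    if cap and not cond.wholly_attributable:
        rr = np.maximum(rr, 1.0)
    return rr


def run_scenario(
    inputs: SimulationInputs,
    scenario: Scenario,
    seed: int,
    start_year: int = 2017,
    end_year: int = 2040,
    policy_year: int = 2019,
) -> ScenarioResult:
    """Run one policy scenario over the full horizon.

    Consumption responses each year are driven by the price contrast
    against the same-year control-scenario prices, so the control run
    itself carries only underlying (ageing) dynamics and the intervention
    effect is a pure policy contrast.  All stochastic draws come from
    streams keyed by (seed, year, purpose) and are shared across
    scenarios run with the same seed.
    """
    inputs.validate()
    pop = inputs.population.copy()
    n = len(pop)
    elas: ElasticitySet = inputs.elasticities[scenario.elasticity_set]
    om: OccasionModel = inputs.occasion_model
    cap = scenario.cap_protective_rr
    price_index = inputs.inflation[scenario.price_index]
    sched = scenario.schedule(inputs, start_year, end_year)
    sched_ctrl = dc_replace(CONTROL, price_index=scenario.price_index).schedule(
        inputs, start_year, end_year)

    # price sets: scenario and same-year control references, both expressed
    # in the generator's basis year and de-uprated to the start year
    prices_scn = inputs.prices.copy()
    prices_ctrl = inputs.prices.copy()
    basis_factor = price_index.factor(inputs.price_basis_year, start_year)
    for ps in (prices_scn, prices_ctrl):
        ps.uprate(basis_factor)

    # persistent participation uniforms and the slice-level drinker profile
    u_part = _year_rng(seed, 0, 3).random(n)
    units_ctrl = pop.units.copy()
    slice_id0 = pop.subgroup_id // N_DRINKER_GROUPS  # 200 slices
    profile = _slice_drinker_profile(units_ctrl, slice_id0)

    conditions = inputs.ledger.conditions
    curves, curve_of = _distinct_lag_curves(conditions)
    acute_idx = [i for i, lc in enumerate(curves) if len(lc) == 1]

    hist_scn: list[np.ndarray] = [units_ctrl.sum(axis=1)]
    hist_ctrl: list[np.ndarray] = [units_ctrl.sum(axis=1)]
    sg_lookup = pop.subgroup_id.copy()

    rec = _Recorder()
    years = list(range(start_year, end_year + 1))
    for year in years:
        # (1) uprate prices; thresholds are nominal in the schedules
        if year > start_year:
            f = price_index.factor(year - 1, year)
            prices_scn.uprate(f)
            prices_ctrl.uprate(f)
        # (2) policy transform
        prices_scn.set_from_original(sched.threshold(year))
        prices_ctrl.set_from_original(sched_ctrl.threshold(year))

        # (3) price contrast vs control and elasticity responses
        mp_scn = prices_scn.mean_price()
        mp_ctrl = prices_ctrl.mean_price()
        with np.errstate(invalid="ignore", divide="ignore"):
            dp = 100.0 * (mp_scn - mp_ctrl) / mp_ctrl
        dp = np.nan_to_num(dp)
        part_resp = dp @ elas.participation.T   # (800, 10)
        cond_resp = dp @ elas.conditional.T

        units_scn = _apply_responses(
            units_ctrl, sg_lookup, slice_id0, part_resp, cond_resp,
            u_part, profile,
        )
        # (4) reassign drinker groups / subgroups
        pop.units = units_scn
        sg_lookup = pop.subgroup_id.copy()

        # (5) lag histories and effective consumption per distinct lag curve
        hist_scn.append(units_scn.sum(axis=1))
        hist_ctrl.append(units_ctrl.sum(axis=1))
        H_scn = np.asarray(hist_scn)
        H_ctrl = np.asarray(hist_ctrl)
        eff_scn = [effective_consumption(H_scn, lc) for lc in curves]
        eff_ctrl = [effective_consumption(H_ctrl, lc) for lc in curves]
        binges_scn = {i: om.annual_binges(eff_scn[i]) for i in acute_idx}
        binges_ctrl = {i: om.annual_binges(eff_ctrl[i]) for i in acute_idx}

        # (6) PIF-updated rates -> per-individual hazards
        alive = pop.alive
        idx = np.flatnonzero(alive)
        stratum = pop.stratum_id()[idx]
        w = pop.weight[idx]
        C = len(conditions)
        mort_h = np.zeros((len(idx), C))
        morb_h = np.zeros((len(idx), C))
        for ci, cond in enumerate(conditions):
            k = curve_of[ci]
            b_s = binges_scn.get(k)
            b_c = binges_ctrl.get(k)
            rr_s = _rr_from_effective(
                cond, eff_scn[k][idx], None if b_s is None else b_s[idx], om, cap)
            rr_c = _rr_from_effective(
                cond, eff_ctrl[k][idx], None if b_c is None else b_c[idx], om, cap)
            mean_rr_c = _stratum_mean(rr_c, stratum, w)
            denom = np.maximum(mean_rr_c[stratum], 1e-12)
            adj = rr_s / denom
            mort_h[:, ci] = inputs.ledger.mortality[ci, stratum] * adj
            morb_h[:, ci] = inputs.ledger.morbidity[ci, stratum] * adj
        bg_h = inputs.ledger.background_mortality[stratum]

        # person-years before removals (deaths count a full year)
        rec.quintiles("person_years", year, pop, idx, w)

        # (7) deaths (common random numbers across scenarios)
        u_death = _year_rng(seed, year, 1).random(n)[idx]
        u_cause = _year_rng(seed, year, 2).random(n)[idx]
        records = simulate_deaths(
            pop, mort_h, bg_h, _year_rng(seed, year, 4), inputs.ledger,
            uniforms=u_death, cause_uniforms=u_cause, year=year,
        )
        records = years_of_life_lost(records, inputs.life_table)
        p_death = 1.0 - np.exp(-(bg_h + mort_h.sum(axis=1)))

        # (9) record outputs for the year
        rec.consumption(year, pop, idx, w, units_scn, mp_scn, sg_lookup)
        rec.groups(year, pop, idx, w)
        rec.deaths(year, records)
        rec.quintile_values("expected_deaths", year, pop, idx, w * p_death)
        rec.quintile_values("hospitalisations", year, pop, idx,
                            w * morb_h.sum(axis=1))

        # (8) dynamic ageing with subgroup age-pattern rescaling
        age_population(pop, inputs.age_profile, extra_units=units_ctrl)
        units_scn = pop.units  # rescaled in place by age_population

    return ScenarioResult(
        name=scenario.name, seed=seed, years=years, tables=rec.tables())


def _slice_drinker_profile(units: np.ndarray, slice_id: np.ndarray) -> np.ndarray:
    """Mean beverage units of drinkers per 200-slice (subgroup sans drinker
    group); rows with no drinkers fall back to the overall drinker mean."""
    n_slices = 200
    total = units.sum(axis=1)
    drink = total > 0
    prof = np.zeros((n_slices, N_BEVERAGES))
    counts = np.bincount(slice_id[drink], minlength=n_slices).astype(float)
    for b in range(N_BEVERAGES):
        prof[:, b] = np.bincount(
            slice_id[drink], weights=units[drink, b], minlength=n_slices)
    overall = units[drink].mean(axis=0) if drink.any() else np.zeros(N_BEVERAGES)
    has = counts > 0
    prof[has] /= counts[has, None]
    prof[~has] = overall
    return prof


def _apply_responses(
    units_ctrl, sg_lookup, slice_id, part_resp, cond_resp, u_part, profile
):
    """Scenario consumption from the control path plus this year's responses."""
    units = units_ctrl.copy()
    total_ctrl = units_ctrl.sum(axis=1)
    drinker = total_ctrl > 0

    scale = np.clip(1.0 + cond_resp[sg_lookup] / 100.0, 0.0, None)
    units[drinker] = units_ctrl[drinker] * scale[drinker]

    # units-weighted participation response per individual
    mix = np.where(
        drinker[:, None], units_ctrl,
        profile[slice_id],
    )
    mix_tot = np.maximum(mix.sum(axis=1), 1e-12)
    p_overall = (mix * part_resp[sg_lookup]).sum(axis=1) / mix_tot

    exits = drinker & (p_overall < 0) & (u_part < -p_overall / 100.0)
    units[exits] = 0.0

    # abstainers enter drinking so the slice drinker share rises by p%
    n_d = np.bincount(slice_id[drinker], minlength=200).astype(float)
    n_a = np.bincount(slice_id[~drinker], minlength=200).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        odds = np.where(n_a > 0, n_d / n_a, 0.0)
    enter_p = np.clip((p_overall / 100.0) * odds[slice_id], 0.0, 1.0)
    entries = (~drinker) & (p_overall > 0) & (u_part < enter_p)
    if entries.any():
        units[entries] = profile[slice_id[entries]]
    return units


def _stratum_mean(values, stratum, weights, n_strata: int = 40):
    num = np.bincount(stratum, weights=weights * values, minlength=n_strata)
    den = np.bincount(stratum, weights=weights, minlength=n_strata)
    return num / np.maximum(den, 1e-300)


class _Recorder:
    def __init__(self):
        self.rows: dict[str, list[dict]] = {}

    def _row(self, measure, year):
        self.rows.setdefault(measure, [])
        row = {"year": year}
        self.rows[measure].append(row)
        return row

    def quintiles(self, measure, year, pop, idx, values):
        self.quintile_values(measure, year, pop, idx, values)

    def quintile_values(self, measure, year, pop, idx, values):
        row = self._row(measure, year)
        q = pop.simd_quintile[idx]
        row["overall"] = float(values.sum())
        for k in range(1, 6):
            row[k] = float(values[q == k].sum())

    def consumption(self, year, pop, idx, w, units_scn, mean_price, sg):
        total = units_scn.sum(axis=1)[idx]
        drink = total > 0
        q = pop.simd_quintile[idx]
        prices = np.nan_to_num(mean_price)[sg[idx]]
        spend = (units_scn[idx] * prices).sum(axis=1)
        row_u = self._row("mean_units_per_drinker", year)
        row_s = self._row("spend_per_drinker", year)
        for col, mask in [("overall", np.ones(len(idx), bool))] + [
            (k, q == k) for k in range(1, 6)
        ]:
            m = mask & drink
            if m.any():
                row_u[col] = float(np.average(total[m], weights=w[m]))
                row_s[col] = float(np.average(spend[m], weights=w[m]))
            else:
                row_u[col] = 0.0
                row_s[col] = 0.0

    def groups(self, year, pop, idx, w):
        row = self._row("drinker_group_counts", year)
        g = pop.drinker_group[idx]
        for gi, name in enumerate(GROUP_COLS):
            row[name] = float(w[g == gi].sum())

    def deaths(self, year, records: pd.DataFrame):
        for measure, sub in (
            ("deaths", records),
            ("deaths_wholly", records[records["wholly_attributable_cause"]]),
        ):
            row = self._row(measure, year)
            row["overall"] = float(sub["weight"].sum())
            for k in range(1, 6):
                row[k] = float(sub.loc[sub["simd_quintile"] == k, "weight"].sum())
        row = self._row("yll", year)
        row["overall"] = float(records["yll"].sum()) if len(records) else 0.0
        for k in range(1, 6):
            row[k] = (
                float(records.loc[records["simd_quintile"] == k, "yll"].sum())
                if len(records) else 0.0)
        row = self._row("deaths_by_group", year)
        for name in CAUSE_COLS:
            row[name] = (
                float(records.loc[records["condition_group"] == name, "weight"].sum())
                if len(records) else 0.0)

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {}
        for measure, rows in self.rows.items():
            df = pd.DataFrame(rows).set_index("year")
            out[measure] = df
        return out


# --------------------------------------------------------------------------
# Scenario comparison


@dataclass(eq=False)
class PolicyComparison:
    """Intervention-minus-control differences for every output series."""

    intervention: str
    control: str
    years: list[int]
    annual_diff: dict[str, pd.DataFrame]
    consumption_pct_change: pd.Series
    spending_pct_change: pd.Series
    drinker_group_pct_change: pd.Series
    cumulative_death_change: pd.Series
    cumulative_wholly_death_change: pd.Series
    cumulative_hosp_change: pd.Series
    yll_rate_change: pd.Series
    control_deaths: pd.Series
    control_wholly_deaths: pd.Series

    def quintile_share_of_change(self, measure: str = "deaths_wholly") -> pd.Series:
        """Each quintile's share (%) of the overall cumulative change."""
        cum = self.annual_diff[measure].sum(axis=0)
        total = cum["overall"]
        return pd.Series(
            {q: 100.0 * cum[q] / total if total else 0.0 for q in range(1, 6)})

    def deprivation_ratio(self) -> float:
        """Control-scenario deaths, most vs least deprived quintile."""
        return float(self.control_deaths[5] / self.control_deaths[1])


def compare_scenarios(
    intervention: ScenarioResult,
    control: ScenarioResult,
    policy_year: int = 2019,
) -> PolicyComparison:
    """Difference every output series of two runs of the same population.

    Requires identical horizons and seeds (the paired common-random-number
    contract); percentage changes for consumption, spending and drinker
    groups aggregate over the policy years.
    """
    if intervention.years != control.years:
        raise ValueError("scenario horizons do not match")
    if intervention.seed != control.seed:
        raise ValueError("paired comparison requires a shared seed")
    diff = {}
    for measure in intervention.tables:
        diff[measure] = intervention.tables[measure] - control.tables[measure]

    post = [y for y in intervention.years if y >= policy_year]

    def pct(measure, cols):
        i = intervention.tables[measure].loc[post, cols].sum(axis=0)
        c = control.tables[measure].loc[post, cols].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = 100.0 * (i - c) / c
        return out.fillna(0.0)

    yll_i = intervention.cumulative("yll")
    yll_c = control.cumulative("yll")
    py_i = intervention.cumulative("person_years")
    py_c = control.cumulative("person_years")
    yll_rate = 100_000.0 * (yll_i / py_i - yll_c / py_c)

    return PolicyComparison(
        intervention=intervention.name,
        control=control.name,
        years=intervention.years,
        annual_diff=diff,
        consumption_pct_change=pct("mean_units_per_drinker", QUINTILE_COLS),
        spending_pct_change=pct("spend_per_drinker", QUINTILE_COLS),
        drinker_group_pct_change=pct("drinker_group_counts", GROUP_COLS[1:]),
        cumulative_death_change=diff["deaths"].sum(axis=0),
        cumulative_wholly_death_change=diff["deaths_wholly"].sum(axis=0),
        cumulative_hosp_change=diff["hospitalisations"].sum(axis=0),
        yll_rate_change=yll_rate,
        control_deaths=control.cumulative("deaths"),
        control_wholly_deaths=control.cumulative("deaths_wholly"),
    )
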
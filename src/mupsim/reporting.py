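"""Report tables, in-table arithmetic helpers, and sensitivity analyses.

Turns a set of paired scenario comparisons into the appraisal's output
tables (consumption/spending change by deprivation quintile, drinker-group
movement, death and YLL changes by quintile, annual deaths averted by
condition group) and re-runs the appraisal under the four standard
sensitivity analyses: SA1 swaps the underlying price inflation index to
CPIH, SA2 swaps in the alternative elasticity matrices, SA3 upshifts
baseline consumption to a fraction of per-capita sales, SA4 caps all
relative risks below 1 at 1 (no cardioprotection).
"""
from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .engine import (
    CONTROL,
    PolicyComparison,
    Scenario,
    compare_scenarios,
    run_scenario,
)
from .population import Population
from .synthetic import SimulationInputs

SA_IDS = ("SA1", "SA2", "SA3", "SA4")


@dataclass(frozen=True)
class SensitivitySpec:
    """One declarative input override; the base case stays untouched.

    ``modification`` holds the single override for the spec id:
    SA1 {'price_index': 'CPIH'}; SA2 {'elasticity_set': 'alternative'};
    SA3 {'sales_total': units/capita/year, 'coverage': fraction};
    SA4 {'cap_protective_rr': True}.
    """

    id: str
    modification: dict

    def __post_init__(self) -> None:
        if self.id not in SA_IDS:
            raise ValueError(f"unknown sensitivity spec {self.id!r}")
        if not self.modification:
            raise ValueError("sensitivity spec needs exactly one modification")


def default_sensitivity_specs(
    sales_total: float = 900.0, coverage: float = 0.8
) -> list[SensitivitySpec]:
    return [
        SensitivitySpec("SA1", {"price_index": "CPIH"}),
        SensitivitySpec("SA2", {"elasticity_set": "alternative"}),
        SensitivitySpec("SA3", {"sales_total": sales_total, "coverage": coverage}),
        SensitivitySpec("SA4", {"cap_protective_rr": True}),
    ]


def upshift_consumption(
    population: Population, sales_total: float, coverage: float
) -> Population:
    """Scale every drinker's units so per-capita consumption equals
    ``coverage`` x per-capita annual sales (units/person/year).

    Abstainers stay at zero; the survey-implied per-capita total is the
    weighted mean of 52 x weekly units over all adults.
    """
    if not (0.0 < coverage <= 1.0):
        raise ValueError("coverage must be in (0, 1]")
    if sales_total <= 0:
        raise ValueError("sales total must be positive")
    implied = 52.0 * float(
        np.average(population.total_units, weights=population.weight))
    if implied == 0:
        raise ValueError("survey-implied consumption is zero; cannot upshift")
    factor = coverage * sales_total / implied
    out = population.copy()
    out.units *= factor
    return out


def upshift_factor(population: Population, sales_total: float, coverage: float) -> float:
    implied = 52.0 * float(
        np.average(population.total_units, weights=population.weight))
    return coverage * sales_total / implied


def run_sensitivity_suite(
    inputs: SimulationInputs,
    scenario: Scenario,
    specs: list[SensitivitySpec],
    seed: int,
    **run_kwargs,
) -> pd.DataFrame:
    """Run the base case plus each sensitivity re-run with identical seeds.

    Returns one row per analysis: consumption, spending and cumulative
    20-year overall/wholly-attributable death changes, side by side.
    """
    rows = []
    comparisons: dict[str, PolicyComparison] = {}

    def one(label: str, sim_inputs: SimulationInputs, scn: Scenario):
        ctrl = dc_replace(
            CONTROL,
            price_index=scn.price_index,
            elasticity_set=scn.elasticity_set,
            cap_protective_rr=scn.cap_protective_rr,
        )
        res_i = run_scenario(sim_inputs, scn, seed, **run_kwargs)
        res_c = run_scenario(sim_inputs, ctrl, seed, **run_kwargs)
        comp = compare_scenarios(res_i, res_c)
        comparisons[label] = comp
        rows.append({
            "analysis": label,
            "consumption_pct_change": comp.consumption_pct_change["overall"],
            "spending_pct_change": comp.spending_pct_change["overall"],
            "death_change": comp.cumulative_death_change["overall"],
            "wholly_death_change": comp.cumulative_wholly_death_change["overall"],
        })

    one("base", inputs, scenario)
    for spec in specs:
        mod = spec.modification
        if spec.id == "SA1":
            one(spec.id, inputs, dc_replace(scenario, price_index=mod["price_index"]))
        elif spec.id == "SA2":
            one(spec.id, inputs,
                dc_replace(scenario, elasticity_set=mod["elasticity_set"]))
        elif spec.id == "SA3":
            shifted = dc_replace(
                inputs,
                population=upshift_consumption(
                    inputs.population, mod["sales_total"], mod["coverage"]),
            )
            one(spec.id, shifted, scenario)
        elif spec.id == "SA4":
            one(spec.id, inputs, dc_replace(scenario, cap_protective_rr=True))
    df = pd.DataFrame(rows).set_index("analysis")
    df.attrs["comparisons"] = comparisons
    return df


# --------------------------------------------------------------------------
# In-table arithmetic helpers (report cells recomputable from raw series)


def quintile_share(change_in_quintile: float, overall_change: float) -> float:
    """A quintile's percentage share of an overall change."""
    if overall_change == 0:
        raise ZeroDivisionError("overall change is zero")
    return 100.0 * change_in_quintile / overall_change


def units_below_threshold(band_units: dict[str, float], threshold_pence: float) -> float:
    """Sum of units in price bands entirely below a threshold.

    ``band_units`` maps band labels like '50-60p' (or '80p+') to units;
    only bands whose upper edge is at or below the threshold count.
    """
    total = 0.0
    for label, units in band_units.items():
        if label.endswith("+"):
            continue
        upper = float(label.split("-")[1].rstrip("p/unit"))
        if upper <= threshold_pence:
            total += units
    return total


def percent_within(part: float, total: float) -> float:
    """Percentage of ``total`` accounted for by ``part``."""
    return 100.0 * part / total


def group_share(count: float, counts: dict[str, float]) -> float:
    """One drinker group's percentage share of all drinkers."""
    return 100.0 * count / sum(counts.values())


def round_like_report(value: float, decimals: int = 1) -> float:
    """Report cells are printed to one decimal place."""
    return float(np.round(value, decimals))


# --------------------------------------------------------------------------
# Appraisal output tables


def tabulate_paper_outputs(
    comparisons: dict[str, PolicyComparison],
) -> dict[str, pd.DataFrame]:
    """Build the appraisal's report bundle from scenario comparisons.

    Returns Table-1-shaped consumption and spending percentage changes by
    SIMD quintile, Table-3-shaped drinker-group count changes,
    Table-4/5-shaped cumulative death and YLL-rate changes by quintile,
    and the annual deaths-averted-by-condition-group series.
    """
    quintiles = ["overall", 1, 2, 3, 4, 5]
    cons, spend, groups, deaths, wholly, yll = [], [], [], [], [], []
    fig_rows = []
    for name, comp in comparisons.items():
        cons.append(pd.Series(comp.consumption_pct_change, name=name))
        spend.append(pd.Series(comp.spending_pct_change, name=name))
        groups.append(pd.Series(comp.drinker_group_pct_change, name=name))
        deaths.append(pd.Series(comp.cumulative_death_change, name=name))
        wholly.append(pd.Series(comp.cumulative_wholly_death_change, name=name))
        yll.append(pd.Series(comp.yll_rate_change, name=name))
        annual = comp.annual_diff["deaths_by_group"]
        long = annual.reset_index().melt(
            id_vars="year", var_name="condition_group", value_name="death_change")
        long.insert(0, "scenario", name)
        fig_rows.append(long)
    out = {
        "consumption_pct_change": pd.DataFrame(cons)[quintiles],
        "spending_pct_change": pd.DataFrame(spend)[quintiles],
        "drinker_group_pct_change": pd.DataFrame(groups),
        "death_change": pd.DataFrame(deaths)[quintiles],
        "wholly_death_change": pd.DataFrame(wholly)[quintiles],
        "yll_rate_change": pd.DataFrame(yll)[quintiles],
        "annual_deaths_by_group": pd.concat(fig_rows, ignore_index=True),
    }
    return out


def write_report_bundle(tables: dict[str, pd.DataFrame], outdir) -> None:
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        index = name != "annual_deaths_by_group"
        df.round(4).to_csv(outdir / f"{name}.csv", index=index)
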
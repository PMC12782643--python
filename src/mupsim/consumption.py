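"""Price-to-consumption engine: elasticities, drinker groups, spending.

Own- and cross-price elasticities translate a subgroup's percentage price
changes into percentage changes in drinking participation (the
probability of drinking at all) and in conditional consumption (amount
drunk among drinkers).  Conditional changes scale each drinker's
beverage-level units; participation changes move individuals between
abstention and drinking stochastically so the subgroup drinker share
moves by the stated percentage in expectation.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .categories import BEVERAGE_LABELS, N_BEVERAGES

if TYPE_CHECKING:  # pragma: no cover
    from .population import Population


@dataclass(frozen=True)
class DrinkerGroupThresholds:
    """Weekly-unit boundaries between drinker groups.

    Intervals are half-open, closed on the upper bound: moderate is
    (0, 14] units/week; hazardous (14, 35] for women and (14, 50] for
    men; harmful above.  Zero units is abstention.
    """

    moderate_upper: float = 14.0
    hazardous_upper_female: float = 35.0
    hazardous_upper_male: float = 50.0

    def __post_init__(self) -> None:
        if not (0 < self.moderate_upper < self.hazardous_upper_female
                <= self.hazardous_upper_male):
            raise ValueError("thresholds must satisfy 0 < moderate < female <= male")


def assign_drinker_group(
    total_units, sex, thresholds: DrinkerGroupThresholds | None = None
):
    """Map weekly units and sex to drinker-group index (0..3).

    0 abstainer, 1 moderate, 2 hazardous, 3 harmful.  Scalar or array.
    """
    thresholds = thresholds or DrinkerGroupThresholds()
    u = np.asarray(total_units, dtype=float)
    if np.any(u < 0):
        raise ValueError("weekly units must be non-negative")
    sex = np.asarray(sex)
    hazardous_upper = np.where(
        sex == 1, thresholds.hazardous_upper_male, thresholds.hazardous_upper_female
    )
    group = np.zeros(u.shape, dtype=np.int8)
    group[u > 0] = 1
    group[u > thresholds.moderate_upper] = 2
    group[u > hazardous_upper] = 3
    return group if group.ndim else np.int8(group)


@dataclass(frozen=True)
class ElasticitySet:
    """Paired 10x10 participation and conditional elasticity matrices.

    Row = affected beverage, column = beverage whose price changed.
    Tobacco rows/columns are conceptually part of the published matrices
    but fixed at zero for alcohol-only appraisals, so only the 10 alcohol
    categories are carried.
    """

    participation: np.ndarray
    conditional: np.ndarray
    name: str = "default"

    def __post_init__(self) -> None:
        for label, m in (("participation", self.participation),
                         ("conditional", self.conditional)):
            m = np.asarray(m, dtype=float)
            if m.shape != (N_BEVERAGES, N_BEVERAGES):
                raise ValueError(f"{label} matrix must be 10x10, got {m.shape}")
            if not np.all(np.isfinite(m)):
                raise ValueError(f"{label} matrix must be finite")
            object.__setattr__(self, label, m)

    def to_csv(self, participation_path, conditional_path) -> None:
        for path, m in ((participation_path, self.participation),
                        (conditional_path, self.conditional)):
            pd.DataFrame(m, index=BEVERAGE_LABELS, columns=BEVERAGE_LABELS).to_csv(path)

    @classmethod
    def from_csv(cls, participation_path, conditional_path, name="custom"):
        mats = []
        for path in (participation_path, conditional_path):
            df = pd.read_csv(path, index_col=0)
            if list(df.index) != list(BEVERAGE_LABELS) or list(df.columns) != list(
                BEVERAGE_LABELS
            ):
                raise ValueError(f"{path}: beverage headers must match the 10 categories")
            mats.append(df.to_numpy(float))
        return cls(participation=mats[0], conditional=mats[1], name=name)


def consumption_response(
    price_changes: np.ndarray, elasticities: ElasticitySet
) -> tuple[np.ndarray, np.ndarray]:
    """Percentage responses to percentage price changes.

    Element i of each output is sum_j e[i, j] * pct_price_change[j],
    evaluated separately for the participation and conditional matrices.
    Returns (participation_pct, conditional_pct).
    """
    dp = np.asarray(price_changes, dtype=float)
    if dp.shape[-1] != N_BEVERAGES:
        raise ValueError(f"expected {N_BEVERAGES} price changes, got {dp.shape}")
    if not np.all(np.isfinite(dp)):
        raise ValueError("price changes must be finite")
    part = dp @ elasticities.participation.T
    cond = dp @ elasticities.conditional.T
    return part, cond


def apply_response_to_individuals(
    population: "Population",
    members: np.ndarray,
    participation_pct: np.ndarray,
    conditional_pct: np.ndarray,
    rng: np.random.Generator,
    mean_drinker_units: np.ndarray | None = None,
) -> None:
    """Apply one subgroup's responses to its members, in place.

    ``members`` indexes individuals of one subgroup.  Drinkers' beverage
    units scale by (1 + conditional/100), floored at zero.  The overall
    participation change is the units-weighted mean of the per-beverage
    participation responses; drinkers exit (or abstainers enter, with the
    subgroup's mean drinker profile) by Bernoulli draws sized so the
    drinker share moves by that percentage in expectation.
    """
    units = population.units[members]
    total = units.sum(axis=1)
    drinkers = total > 0

    # conditional: scale drinkers' beverage-level units
    scale = np.clip(1.0 + np.asarray(conditional_pct) / 100.0, 0.0, None)
    units[drinkers] *= scale

    # participation: units-weighted average response across beverages
    mix_base = units[drinkers] if drinkers.any() else None
    if mix_base is not None and mix_base.sum() > 0:
        mix = mix_base.sum(axis=0) / mix_base.sum()
    elif mean_drinker_units is not None and mean_drinker_units.sum() > 0:
        mix = mean_drinker_units / mean_drinker_units.sum()
    else:
        mix = np.full(N_BEVERAGES, 1.0 / N_BEVERAGES)
    p_overall = float(np.dot(mix, participation_pct))

    n_d = int(drinkers.sum())
    n_a = len(members) - n_d
    if p_overall < 0 and n_d:
        exit_p = min(-p_overall / 100.0, 1.0)
        leaving = rng.random(n_d) < exit_p
        units[np.flatnonzero(drinkers)[leaving]] = 0.0
    elif p_overall > 0 and n_a and n_d:
        # drinker share rises by p%: expected entrants = n_d * p/100
        enter_p = min(n_d * (p_overall / 100.0) / n_a, 1.0)
        entering = rng.random(n_a) < enter_p
        profile = (
            mean_drinker_units
            if mean_drinker_units is not None
            else units[drinkers].mean(axis=0)
        )
        units[np.flatnonzero(~drinkers)[entering]] = profile

    population.units[members] = units


def spending_change(
    population: "Population",
    units_before: np.ndarray,
    units_after: np.ndarray,
    mean_price_before: np.ndarray,
    mean_price_after: np.ndarray,
    subgroup_before: np.ndarray | None = None,
    subgroup_after: np.ndarray | None = None,
) -> pd.Series:
    """Percentage change in mean weekly spend per drinker, by SIMD quintile.

    ``units_*`` are (n, 10) beverage units; ``mean_price_*`` are
    (800, 10) subgroup x beverage mean prices in £.  Spend per individual
    is the dot product of their units with their subgroup's mean prices;
    the per-quintile aggregate is survey-weighted over drinkers.  Returns
    a Series indexed by quintile 1..5 plus 'overall'.
    """
    sg_b = population.subgroup_id if subgroup_before is None else subgroup_before
    sg_a = population.subgroup_id if subgroup_after is None else subgroup_after
    prices_b = np.nan_to_num(mean_price_before)[sg_b]
    prices_a = np.nan_to_num(mean_price_after)[sg_a]
    spend_b = (units_before * prices_b).sum(axis=1)
    spend_a = (units_after * prices_a).sum(axis=1)
    w = population.weight
    out = {}
    for label, mask in _quintile_masks(population):
        db = (units_before[mask].sum(axis=1) > 0)
        da = (units_after[mask].sum(axis=1) > 0)
        mb = np.average(spend_b[mask][db], weights=w[mask][db]) if db.any() else 0.0
        ma = np.average(spend_a[mask][da], weights=w[mask][da]) if da.any() else 0.0
        out[label] = 100.0 * (ma - mb) / mb if mb else 0.0
    return pd.Series(out)


def _quintile_masks(population: "Population"):
    alive = population.alive
    yield "overall", alive
    for q in range(1, 6):
        yield q, alive & (population.simd_quintile == q)
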
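"""Consumption-to-harm model: risk functions, lags, PIF, deaths, YLL.

Each of the modelled health conditions is wholly or partially
attributable to alcohol and linked either to long-term consumption
(chronic) or to single drinking occasions (acute).  Partial conditions
carry a relative-risk curve with RR(0) = 1; wholly attributable
conditions carry an absolute-risk multiplier that is 0 at zero
consumption.  Changes in drinking feed through to disease rates with a
condition-specific lag, and stratum-level rates are updated with the
Potential Impact Fraction (PIF):

    PIF = 1 - sum(w * RR_new) / sum(w * RR_old)
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .categories import AGE_BANDS, CONDITION_GROUPS, N_SIMD

log = logging.getLogger(__name__)

CATEGORIES = ("wholly-chronic", "wholly-acute", "partial-chronic", "partial-acute")
N_STRATA = len(AGE_BANDS) * 2 * N_SIMD  # age band x sex x SIMD quintile = 40


def stratum_labels() -> pd.DataFrame:
    rows = []
    for a, band in enumerate(AGE_BANDS):
        for s, sex in enumerate(("female", "male")):
            for q in range(1, N_SIMD + 1):
                rows.append({"stratum": (a * 2 + s) * N_SIMD + q - 1,
                             "age_band": band, "sex": sex, "simd_quintile": q})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class OccasionModel:
    """Converts weekly units into a pattern of single drinking occasions.

    Occasion sizes are gamma distributed with shape ``shape`` and a mean
    that grows with weekly intake, ``mean_size = base_size + size_slope *
    weekly_units``; the weekly occasion count is weekly_units / mean_size,
    so expected annual intake is always 52 x weekly units.  A binge is an
    occasion above ``binge_units``.
    """

    base_size: float = 3.0      # units per occasion at light intake
    size_slope: float = 0.08    # growth of occasion size with weekly units
    shape: float = 2.0          # gamma shape of occasion sizes
    binge_units: float = 8.0    # single-occasion intake counted as a binge

    def mean_occasion_size(self, weekly_units):
        return self.base_size + self.size_slope * np.asarray(weekly_units, float)

    def occasions_per_week(self, weekly_units):
        u = np.asarray(weekly_units, float)
        return np.where(u > 0, u / self.mean_occasion_size(u), 0.0)

    def binge_probability(self, weekly_units):
        """P(occasion size > binge threshold) under the gamma size model."""
        scale = self.mean_occasion_size(weekly_units) / self.shape
        return stats.gamma.sf(self.binge_units, a=self.shape, scale=scale)

    def annual_binges(self, weekly_units):
        """Expected number of binge occasions per year."""
        u = np.asarray(weekly_units, float)
        out = 52.0 * self.occasions_per_week(u) * self.binge_probability(u)
        return np.where(u > 0, out, 0.0)


def make_lag_curve(full_lag_years: int) -> np.ndarray:
    """Piecewise-linear cumulative lag weights reaching 1 after ``full_lag_years``.

    Element d is the fraction of a consumption change's risk effect
    realised d years after the change; acute conditions use
    ``full_lag_years = 1`` (instantaneous).
    """
    if full_lag_years < 1:
        raise ValueError("full_lag_years must be >= 1")
    return np.minimum(np.arange(1, full_lag_years + 1) / full_lag_years, 1.0)


@dataclass(frozen=True)
class Condition:
    """One health condition with its risk function, lag and baseline rates.

    ``risk_params`` by category:
      partial-chronic: beta1 (log-RR per unit/week), beta2 (optional
        quadratic term; negative beta1 with positive beta2 gives the
        J-shaped curves reported for some cardiovascular conditions);
      partial-acute: rr_per_binge (RR multiplier per binge occasion);
      wholly-chronic: x_ref (units/week of the reference exposure), gamma
        (power of the absolute-risk multiplier (x / x_ref) ** gamma);
      wholly-acute: binge_ref (annual binges of the reference exposure).

    Baseline rates are per person-year over the 40 outcome strata
    (age band x sex x SIMD quintile).
    """

    name: str
    group: str
    category: str
    risk_params: dict
    lag_curve: np.ndarray
    baseline_mortality: np.ndarray = None
    baseline_morbidity: np.ndarray = None

    def __post_init__(self) -> None:
        if self.group not in CONDITION_GROUPS:
            raise ValueError(f"unknown condition group {self.group!r}")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        lag = np.asarray(self.lag_curve, dtype=float)
        if np.any(lag < 0) or np.any(lag > 1) or np.any(np.diff(lag) < 0):
            raise ValueError("lag weights must be in [0,1] and non-decreasing")
        if abs(lag[-1] - 1.0) > 1e-12:
            raise ValueError("lag curve must reach 1 at full lag-out")
        object.__setattr__(self, "lag_curve", lag)
        for attr in ("baseline_mortality", "baseline_morbidity"):
            v = getattr(self, attr)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if np.any(v < 0):
                    raise ValueError(f"{attr} must be non-negative")
                object.__setattr__(self, attr, v)

    @property
    def wholly_attributable(self) -> bool:
        return self.category.startswith("wholly")


def relative_risk(
    condition: Condition,
    units,
    occasion_model: OccasionModel | None = None,
    cap_protective: bool = False,
):
    """Relative risk (partial) or absolute-risk multiplier (wholly).

    Partial conditions return RR with RR(0) = 1; wholly attributable
    conditions return a multiplier that is 0 at zero consumption.  With
    ``cap_protective`` any RR below 1 is raised to 1 (the
    no-cardioprotection sensitivity).
    """
    u = np.asarray(units, dtype=float)
    if np.any(u < 0):
        raise ValueError("units must be non-negative")
    p = condition.risk_params
    if condition.category == "partial-chronic":
        rr = np.exp(p["beta1"] * u + p.get("beta2", 0.0) * u**2)
    elif condition.category == "partial-acute":
        om = occasion_model or OccasionModel()
        rr = 1.0 + (p["rr_per_binge"] - 1.0) * om.annual_binges(u)
    elif condition.category == "wholly-chronic":
        rr = (u / p["x_ref"]) ** p.get("gamma", 1.0)
    else:  # wholly-acute
        om = occasion_model or OccasionModel()
        rr = om.annual_binges(u) / p["binge_ref"]
    if cap_protective and not condition.wholly_attributable:
        rr = np.maximum(rr, 1.0)
    return rr


def effective_consumption(history, lag_curve) -> np.ndarray:
    """Lag-weighted consumption from a per-year history (oldest first).

    The earliest entry is treated as fully lagged in; each subsequent
    year-on-year change contributes in proportion to the cumulative lag
    weight at its age.  ``history`` may be a (T,) vector for one
    individual or a (T, n) array for a population; the last row is the
    current year (lag offset 0).
    """
    h = np.asarray(history, dtype=float)
    if h.ndim == 1:
        h = h[:, None]
        squeeze = True
    else:
        squeeze = False
    if h.shape[0] == 0:
        raise ValueError("history must be non-empty")
    lag = np.asarray(lag_curve, dtype=float)
    T = h.shape[0]
    eff = h[0].copy()
    for j in range(1, T):
        d = T - 1 - j
        w = 1.0 if d >= len(lag) else lag[d]
        eff += w * (h[j] - h[j - 1])
    eff = np.maximum(eff, 0.0)
    return eff[0] if squeeze and eff.shape == (1,) else (eff.ravel() if squeeze else eff)


def potential_impact_fraction(rr_old, rr_new, weights) -> float:
    """PIF = 1 - sum(w RR_new) / sum(w RR_old) over one exposure set."""
    rr_old = np.asarray(rr_old, float)
    rr_new = np.asarray(rr_new, float)
    w = np.asarray(weights, float)
    if rr_old.size == 0 or rr_new.size == 0:
        raise ValueError("exposure collections must be non-empty")
    denom = float(np.dot(w, rr_old))
    if denom == 0:
        raise ZeroDivisionError("old-exposure risk sums to zero")
    return 1.0 - float(np.dot(w, rr_new)) / denom


@dataclass
class RateLedger:
    """Current mortality/morbidity rates per person-year by stratum x condition.

    ``mortality`` and ``morbidity`` have shape (n_conditions, 40);
    ``background_mortality`` (40,) carries deaths from causes outside the
    condition registry so overall deaths and person-years are meaningful.
    """

    conditions: list[Condition]
    mortality: np.ndarray
    morbidity: np.ndarray
    background_mortality: np.ndarray = field(
        default_factory=lambda: np.zeros(N_STRATA)
    )

    def __post_init__(self) -> None:
        C = len(self.conditions)
        for attr in ("mortality", "morbidity"):
            v = np.asarray(getattr(self, attr), dtype=float)
            if v.shape != (C, N_STRATA):
                raise ValueError(f"{attr} must have shape ({C}, {N_STRATA})")
            if np.any(v < 0):
                raise ValueError(f"{attr} rates must be non-negative")
            setattr(self, attr, v)
        if np.any(self.background_mortality < 0):
            raise ValueError("background mortality must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        labels = stratum_labels()
        rows = []
        for c, cond in enumerate(self.conditions):
            df = labels.copy()
            df["condition"] = cond.name
            df["mortality_rate"] = self.mortality[c]
            df["morbidity_rate"] = self.morbidity[c]
            rows.append(df)
        bg = labels.copy()
        bg["condition"] = "_background"
        bg["mortality_rate"] = self.background_mortality
        bg["morbidity_rate"] = 0.0
        rows.append(bg)
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class LifeTable:
    """Remaining period life expectancy by (age, sex).

    ``expectancy`` has shape (2, max_age + 1) indexed [sex, age]; ages
    beyond the table use the terminal value.
    """

    expectancy: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.expectancy, dtype=float)
        if e.ndim != 2 or e.shape[0] != 2:
            raise ValueError("expectancy must have shape (2, n_ages)")
        if np.any(e < 0):
            raise ValueError("life expectancy must be non-negative")
        if np.any(np.diff(e, axis=1) > 1e-9):
            raise ValueError("life expectancy must be non-increasing in age")
        object.__setattr__(self, "expectancy", e)

    def remaining(self, age, sex):
        a = np.minimum(np.asarray(age, int), self.expectancy.shape[1] - 1)
        return self.expectancy[np.asarray(sex, int), a]

    def to_frame(self) -> pd.DataFrame:
        ages = np.arange(self.expectancy.shape[1])
        return pd.DataFrame({
            "age": np.tile(ages, 2),
            "sex": np.repeat(["female", "male"], len(ages)),
            "remaining_life_expectancy": np.concatenate(
                [self.expectancy[0], self.expectancy[1]]),
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LifeTable":
        e = np.zeros((2, int(df["age"].max()) + 1))
        for s, sex in enumerate(("female", "male")):
            sub = df[df["sex"] == sex].sort_values("age")
            e[s, sub["age"].to_numpy(int)] = sub["remaining_life_expectancy"].to_numpy()
        return cls(expectancy=e)


def simulate_deaths(
    population,
    condition_hazard: np.ndarray,
    background_hazard: np.ndarray,
    rng: np.random.Generator,
    ledger: RateLedger,
    uniforms: np.ndarray | None = None,
    cause_uniforms: np.ndarray | None = None,
    year: int | None = None,
) -> pd.DataFrame:
    """Draw this year's deaths and remove them from the population.

    ``condition_hazard`` is (n, C): each alive individual's per-condition
    hazard (baseline stratum rate times their normalised RR adjustment);
    ``background_hazard`` (n,) covers all other causes.  The annual death
    probability is 1 - exp(-total hazard), drawn per individual; the
    cause is allocated proportionally to the cause-specific hazards.
    Returns the death records (age, sex, SIMD, weight, cause, group).
    """
    alive_idx = np.flatnonzero(population.alive)
    n = len(alive_idx)
    if condition_hazard.shape[0] != n or background_hazard.shape[0] != n:
        raise ValueError("hazards must cover exactly the alive individuals")
    if np.any(condition_hazard < 0) or np.any(background_hazard < 0):
        log.warning("negative hazards clipped to zero")
        condition_hazard = np.clip(condition_hazard, 0.0, None)
        background_hazard = np.clip(background_hazard, 0.0, None)
    total = background_hazard + condition_hazard.sum(axis=1)
    p = 1.0 - np.exp(-total)
    u = rng.random(n) if uniforms is None else uniforms
    died = u < p
    dead_local = np.flatnonzero(died)
    if dead_local.size == 0:
        return _empty_death_frame()

    # cause allocation proportional to cause-specific hazards
    cu = (rng.random(dead_local.size) if cause_uniforms is None
          else cause_uniforms[dead_local])
    haz = np.column_stack(
        [background_hazard[dead_local], condition_hazard[dead_local]]
    )
    cum = np.cumsum(haz, axis=1)
    cum /= cum[:, -1:]
    cause_idx = (cu[:, None] > cum).sum(axis=1)  # 0 = background

    names = ["other causes"] + [c.name for c in ledger.conditions]
    groups = ["other causes"] + [c.group for c in ledger.conditions]
    wholly = [False] + [c.wholly_attributable for c in ledger.conditions]
    dead_global = alive_idx[dead_local]
    records = pd.DataFrame({
        "id": dead_global,
        "year": year,
        "age": population.age[dead_global],
        "sex": population.sex[dead_global],
        "simd_quintile": population.simd_quintile[dead_global],
        "weight": population.weight[dead_global],
        "cause": [names[i] for i in cause_idx],
        "condition_group": [groups[i] for i in cause_idx],
        "alcohol_attributable_cause": cause_idx > 0,
        "wholly_attributable_cause": [wholly[i] for i in cause_idx],
    })
    population.alive[dead_global] = False
    return records


def _empty_death_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {c: pd.Series(dtype=t) for c, t in (
            ("id", int), ("year", float), ("age", int), ("sex", int),
            ("simd_quintile", int), ("weight", float), ("cause", str),
            ("condition_group", str), ("alcohol_attributable_cause", bool),
            ("wholly_attributable_cause", bool))}
    )


def years_of_life_lost(death_records: pd.DataFrame, life_table: LifeTable) -> pd.DataFrame:
    """Attach weighted YLL (remaining life expectancy at death) to records."""
    out = death_records.copy()
    if len(out) == 0:
        out["yll"] = pd.Series(dtype=float)
        return out
    out["yll"] = life_table.remaining(
        out["age"].to_numpy(), out["sex"].to_numpy()
    ) * out["weight"].to_numpy()
    return out


def yll_rate(total_yll: float, person_years: float) -> float:
    """YLL per 100,000 person-years."""
    return 100_000.0 * total_yll / person_years if person_years else 0.0


def hospitalisation_counts(weights: np.ndarray, morbidity_hazard: np.ndarray) -> np.ndarray:
    """Expected admissions per condition: sum of weight x adjusted rate."""
    return weights @ morbidity_hazard


# --------------------------------------------------------------------------
# Registry (de)serialisation


def registry_to_json(conditions: list[Condition], path) -> None:
    payload = []
    for c in conditions:
        payload.append({
            "name": c.name,
            "group": c.group,
            "category": c.category,
            "risk_params": c.risk_params,
            "lag_curve": np.asarray(c.lag_curve).tolist(),
            "baseline_mortality": (
                None if c.baseline_mortality is None else c.baseline_mortality.tolist()),
            "baseline_morbidity": (
                None if c.baseline_morbidity is None else c.baseline_morbidity.tolist()),
        })
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def registry_from_json(path) -> list[Condition]:
    with open(path) as fh:
        payload = json.load(fh)
    out = []
    for d in payload:
        out.append(Condition(
            name=d["name"], group=d["group"], category=d["category"],
            risk_params=d["risk_params"], lag_curve=np.asarray(d["lag_curve"]),
            baseline_mortality=(
                None if d["baseline_mortality"] is None
                else np.asarray(d["baseline_mortality"])),
            baseline_morbidity=(
                None if d["baseline_morbidity"] is None
                else np.asarray(d["baseline_morbidity"])),
        ))
    return out
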
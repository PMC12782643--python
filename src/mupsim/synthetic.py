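"""Synthetic inputs: population, price distributions, conditions, rates.

The pipeline's real inputs (purchasing diaries, health-survey consumption,
registry mortality extracts, published elasticities) are not public.
This module generates statistically structured stand-ins: an
individual-level adult population calibrated to published baseline
marginals (abstention, drinker-group mix and mean consumption by
deprivation quintile), 8,000 price-paid distributions matching published
price-band shares, a 45-condition harm registry with plausible risk and
lag parameters, baseline mortality/hospitalisation rates with a
deprivation gradient, inflation index series, and a period life table.
All parameter values that are not calibrated to published marginals are
documented defaults, not estimates.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .categories import (
    AGE_BANDS,
    N_BEVERAGES,
    N_SIMD,
    N_SMOKING,
    N_SUBGROUPS,
    ON_TRADE_MASK,
    subgroup_drinker_group,
)
from .consumption import DrinkerGroupThresholds, ElasticitySet
from .harm import (
    Condition,
    LifeTable,
    N_STRATA,
    OccasionModel,
    RateLedger,
    make_lag_curve,
)
from .population import Population
from .prices import InflationSeries, PriceDistributionSet

# --------------------------------------------------------------------------
# Calibration tables (published baseline marginals are inputs)


@dataclass(frozen=True)
class CalibrationTable:
    """Baseline marginals the population generator must reproduce.

    Quintile vectors run from quintile 1 (least deprived) to quintile 5
    (most deprived).  ``drinker_share_by_quintile`` is each quintile's
    share of all drinkers and must sum to one, as must
    ``drinker_group_shares`` (moderate, hazardous, harmful shares of
    drinkers).
    """

    abstention_by_quintile: tuple = (0.121, 0.142, 0.175, 0.202, 0.239)
    drinker_share_by_quintile: tuple = (0.23, 0.22, 0.20, 0.19, 0.17)
    mean_units_by_quintile: tuple = (13.6, 11.4, 12.1, 11.2, 11.5)
    drinker_group_shares: tuple = (0.714, 0.246, 0.040)
    drinker_group_means: tuple = (4.8, 24.5, 63.9)
    national_adult_population: float = 4_319_367.0
    age_band_shares: tuple = (0.11, 0.17, 0.24, 0.48)
    female_share: float = 0.51
    income_simd_concordance: float = 0.60

    def validate(self) -> None:
        # published rows are printed to limited precision, so allow
        # rounding slack before rejecting
        for name, shares in (
            ("drinker_share_by_quintile", self.drinker_share_by_quintile),
            ("drinker_group_shares", self.drinker_group_shares),
            ("age_band_shares", self.age_band_shares),
        ):
            if abs(sum(shares) - 1.0) > 0.02:
                raise ValueError(f"{name} must sum to 1, got {sum(shares)}")
        if any(not (0.0 <= a <= 1.0) for a in self.abstention_by_quintile):
            raise ValueError("abstention rates must be in [0, 1]")

    def implied_simd_shares(self) -> np.ndarray:
        """Adult population share of each SIMD quintile implied by the
        drinker shares and abstention rates."""
        d = np.asarray(self.drinker_share_by_quintile, float)
        d = d / d.sum()  # printed rows carry rounding error
        a = np.asarray(self.abstention_by_quintile, float)
        drinking = 1.0 - a
        if np.all(drinking <= 0):  # fully abstinent: quintiles equal weight
            return np.full(5, 0.2)
        w = d / np.maximum(drinking, 1e-12)
        return w / w.sum()


PRICE_BANDS_PENCE = (50.0, 60.0, 70.0, 80.0)  # band lower edges; last is open
BAND_LABELS = ("50-60p", "60-70p", "70-80p", "80p+")


def _normalise_rows(rows: dict) -> dict:
    return {k: tuple(np.asarray(v, float) / np.sum(v)) for k, v in rows.items()}


@dataclass(frozen=True)
class BandTargets:
    """Share of units in each £0.10 price band, by drinker group and by
    SIMD quintile (aggregates under the £0.50 floor in the baseline year).

    Rows are (50-60p, 60-70p, 70-80p, 80p+) and must each sum to one.
    """

    by_drinker_group: dict = field(
        default_factory=lambda: _normalise_rows({
            "moderate": (1.3, 0.4, 0.3, 2.9),
            "hazardous": (10.8, 2.4, 1.6, 9.6),
            "harmful": (37.2, 7.3, 4.0, 15.4),
        })
    )
    by_simd_quintile: dict = field(
        default_factory=lambda: _normalise_rows({
            1: (5.5, 1.4, 0.9, 5.8),
            2: (4.6, 1.1, 0.8, 5.0),
            3: (5.2, 1.2, 0.8, 5.0),
            4: (5.0, 1.0, 0.6, 4.6),
            5: (5.3, 1.0, 0.6, 4.6),
        })
    )

    def validate(self) -> None:
        for label, rows in (("drinker group", self.by_drinker_group),
                            ("SIMD", self.by_simd_quintile)):
            for key, row in rows.items():
                row = np.asarray(row, float)
                if np.any(row < 0):
                    raise ValueError(f"{label} {key}: negative band share")
                if abs(row.sum() - 1.0) > 1e-6:
                    raise ValueError(f"{label} {key}: band shares must sum to 1")


DEFAULT_CALIBRATION = CalibrationTable()
DEFAULT_BAND_TARGETS = BandTargets()

# beverage mix of total weekly units by drinker group (off-trade x5 then
# on-trade x5); heavier drinkers skew towards cheap off-trade purchases
_BEVERAGE_MIX = {
    1: np.array([0.13, 0.02, 0.22, 0.10, 0.02, 0.20, 0.02, 0.18, 0.08, 0.03]),
    2: np.array([0.22, 0.05, 0.25, 0.15, 0.02, 0.15, 0.02, 0.08, 0.05, 0.01]),
    3: np.array([0.28, 0.12, 0.20, 0.245, 0.02, 0.07, 0.01, 0.025, 0.025, 0.005]),
}

# relative mean consumption by age band, used for ageing rescales
DEFAULT_AGE_PROFILE = np.array([1.10, 1.05, 1.00, 0.85])


# --------------------------------------------------------------------------
# Population


def _ipf(seed_matrix: np.ndarray, row_targets: np.ndarray,
         col_targets: np.ndarray, iters: int = 200) -> np.ndarray:
    m = seed_matrix.copy()
    for _ in range(iters):
        m *= (row_targets / np.maximum(m.sum(axis=1), 1e-300))[:, None]
        m *= (col_targets / np.maximum(m.sum(axis=0), 1e-300))[None, :]
    return m


def generate_population(
    n: int,
    calibration: CalibrationTable = DEFAULT_CALIBRATION,
    seed: int = 0,
    thresholds: DrinkerGroupThresholds | None = None,
    mix_concentration: float = 20.0,
) -> Population:
    """Generate ``n`` adults calibrated to the baseline marginal tables.

    At large n the realised abstention rate, drinker-group shares, and
    mean units per drinker reproduce the calibration within Monte-Carlo
    tolerance; survey weights sum to the configured national adult
    population.
    """
    if n < 1000:
        raise ValueError("population size must be at least 1,000")
    calibration.validate()
    thresholds = thresholds or DrinkerGroupThresholds()
    rng = np.random.default_rng(seed)

    # income uniform; SIMD joint with income via IPF so the SIMD marginal
    # matches the calibration-implied adult shares at the configured
    # income-SIMD concordance
    income = rng.integers(1, 6, size=n).astype(np.int8)
    conc = calibration.income_simd_concordance
    seed_m = np.full((5, 5), (1 - conc) / 4) + np.eye(5) * (conc - (1 - conc) / 4)
    joint = _ipf(seed_m, np.full(5, 0.2), calibration.implied_simd_shares())
    cond = joint / joint.sum(axis=1, keepdims=True)
    u = rng.random(n)
    simd = np.empty(n, dtype=np.int8)
    for q in range(5):
        m = income == q + 1
        simd[m] = 1 + np.searchsorted(np.cumsum(cond[q]), u[m], side="right")
    simd = np.clip(simd, 1, 5)

    # abstention by SIMD quintile, aligned: each quintile receives exactly
    # its calibrated abstainer count (rounded), with membership random
    drinker = np.ones(n, dtype=bool)
    u = rng.random(n)
    for q in range(5):
        members = np.flatnonzero(simd == q + 1)
        k = int(round(len(members) * calibration.abstention_by_quintile[q]))
        chosen = members[np.argsort(u[members], kind="stable")[:k]]
        drinker[chosen] = False

    # drinker group by quintile: hazardous/harmful shares scale with the
    # quintile's mean consumption so means match the calibration exactly
    gshare = np.asarray(calibration.drinker_group_shares, float)
    gmean = np.asarray(calibration.drinker_group_means, float)
    spread = gshare[1] * (gmean[1] - gmean[0]) + gshare[2] * (gmean[2] - gmean[0])
    lam = (np.asarray(calibration.mean_units_by_quintile) - gmean[0]) / spread
    group_probs = np.zeros((5, 3))
    group_probs[:, 1] = lam * gshare[1]
    group_probs[:, 2] = lam * gshare[2]
    group_probs[:, 0] = 1.0 - group_probs[:, 1:].sum(axis=1)
    if np.any(group_probs < 0):
        raise ValueError("calibration implies negative drinker-group shares")

    sex = (rng.random(n) >= calibration.female_share).astype(np.int8)
    group = np.zeros(n, dtype=np.int8)
    gu = rng.random(n)
    cum = np.cumsum(group_probs, axis=1)
    group[drinker] = 1 + (gu[drinker, None] > cum[simd[drinker] - 1][:, :2]).sum(axis=1)

    total = np.zeros(n)
    total[group == 1] = _draw_moderate(rng, (group == 1).sum(), gmean[0], thresholds)
    total[group == 2] = _draw_hazardous(
        rng, sex[group == 2], gmean[1], thresholds)
    total[group == 3] = _draw_harmful(rng, sex[group == 3], gmean[2], thresholds)

    # age, smoking
    band = rng.choice(4, size=n, p=np.asarray(calibration.age_band_shares))
    lo = np.array([18, 25, 35, 50])[band]
    hi = np.array([25, 35, 50, 85])[band]
    age = (lo + rng.random(n) * (hi - lo)).astype(int)
    smoking = rng.integers(0, N_SMOKING, size=n).astype(np.int8)

    # beverage-level apportionment: drinker-group mix with individual
    # Dirichlet variation
    units = np.zeros((n, N_BEVERAGES))
    for g in (1, 2, 3):
        m = group == g
        if not m.any():
            continue
        alpha = _BEVERAGE_MIX[g] * mix_concentration
        shares = rng.dirichlet(np.maximum(alpha, 1e-3), size=int(m.sum()))
        units[m] = shares * total[m, None]

    weight = np.full(n, calibration.national_adult_population / n)
    return Population(
        age=age, sex=sex, income_quintile=income, simd_quintile=simd,
        smoking_group=smoking, weight=weight, units=units,
        thresholds=thresholds,
    )


def _draw_moderate(rng, n, mean, thr):
    upper = thr.moderate_upper
    mu = mean / upper
    a = 1.2
    b = a * (1 - mu) / mu
    return upper * rng.beta(a, b, size=n)


def _draw_hazardous(rng, sex, mean, thr):
    lo = thr.moderate_upper
    hi = np.where(sex == 1, thr.hazardous_upper_male, thr.hazardous_upper_female)
    mu = (mean - lo) / (hi - lo)
    a = np.where(sex == 1, 1.2, 1.5)
    b = a * (1 - mu) / mu
    return lo + (hi - lo) * rng.beta(a, b)


def _draw_harmful(rng, sex, mean, thr):
    lo = np.where(sex == 1, thr.hazardous_upper_male, thr.hazardous_upper_female)
    return lo + rng.exponential(mean - lo)


# --------------------------------------------------------------------------
# Price distributions


def generate_price_distributions(
    population: Population,
    band_targets: BandTargets = DEFAULT_BAND_TARGETS,
    seed: int = 0,
    sub_threshold_fraction: float = 0.35,
    baseline_threshold: float = 0.50,
) -> PriceDistributionSet:
    """Build 8,000 original (never-censored) price-paid distributions.

    Band masses are allocated so that once the baseline £0.50 floor is
    applied (``set_from_original(0.50)``) the population-weighted
    aggregate band shares reproduce ``band_targets`` by drinker group and
    SIMD quintile.  ``sub_threshold_fraction`` of each distribution's
    50-60p band mass is given original prices below the floor (30-49p) so
    the baseline policy step is non-trivial.  Price points sit on a £0.01
    grid, uniform within band.
    """
    band_targets.validate()
    if not (0.0 <= sub_threshold_fraction < 1.0):
        raise ValueError("sub_threshold_fraction must be in [0, 1)")

    dg_rows = ["moderate", "hazardous", "harmful"]
    T_dg = np.array([band_targets.by_drinker_group[k] for k in dg_rows])
    T_sq = np.array([band_targets.by_simd_quintile[q] for q in range(1, 6)])

    # units mass by (drinker group - 1, simd - 1) and by subgroup x simd
    group = population.drinker_group
    sg = population.subgroup_id
    mass = population.weight * population.total_units
    drinkers = group > 0
    V = np.zeros((N_SUBGROUPS, N_SIMD))
    np.add.at(V, (sg[drinkers], population.simd_quintile[drinkers] - 1),
              mass[drinkers])
    sub_dg = subgroup_drinker_group(np.arange(N_SUBGROUPS))
    W = np.zeros((3, N_SIMD))
    for g in range(3):
        W[g] = V[sub_dg == g + 1].sum(axis=0)

    # IPF on (group, simd, band) cell shares so both weighted margins match
    C = np.broadcast_to(T_dg[:, None, :], (3, N_SIMD, 4)).copy()
    for _ in range(300):
        C /= np.maximum(C.sum(axis=2, keepdims=True), 1e-300)
        agg_q = np.einsum("gq,gqb->qb", W, C) / W.sum(axis=0)[:, None]
        C *= (T_sq / np.maximum(agg_q, 1e-300))[None, :, :]
        agg_g = np.einsum("gq,gqb->gb", W, C) / W.sum(axis=1, keepdims=True)
        C *= (T_dg / np.maximum(agg_g, 1e-300))[:, None, :]
    C /= np.maximum(C.sum(axis=2, keepdims=True), 1e-300)

    # deconvolve the income->SIMD mixing: subgroup distributions are keyed
    # by income-based subgroups whose members span SIMD quintiles, so
    # solve for cell profiles X with K @ X = C per drinker group
    X = C.copy()
    for g in range(3):
        rows = np.flatnonzero(sub_dg == g + 1)
        Vg = V[rows]
        tot = np.maximum(Vg.sum(axis=1, keepdims=True), 1e-300)
        K = (Vg.T @ (Vg / tot)) / np.maximum(W[g][:, None], 1e-300)
        try:
            sol = np.linalg.solve(K, C[g])
        except np.linalg.LinAlgError:
            sol = C[g]
        sol = np.clip(sol, 0.0, None)
        rowsum = sol.sum(axis=1, keepdims=True)
        degenerate = rowsum[:, 0] <= 0
        sol[degenerate] = C[g][degenerate]
        X[g] = sol / sol.sum(axis=1, keepdims=True)

    # subgroup band shares: SIMD mixture of the deconvolved profiles
    B = np.empty((N_SUBGROUPS, 4))
    overall = np.einsum("gq,gqb->b", W, C) / W.sum()
    for s in range(N_SUBGROUPS):
        g = sub_dg[s]
        if g == 0 or V[s].sum() <= 0:
            B[s] = overall
        else:
            B[s] = (V[s] / V[s].sum()) @ X[g - 1]

    return _materialise_price_points(B, sub_threshold_fraction, baseline_threshold)


def _materialise_price_points(
    B: np.ndarray, sub_fraction: float, baseline_threshold: float
) -> PriceDistributionSet:
    """Turn per-subgroup band shares into £0.01-grid price points."""
    del baseline_threshold  # bands are defined relative to the £0.50 floor
    grids_off = [
        np.arange(30.0, 50.0, 1.0),        # sub-threshold (original prices)
        np.arange(50.0, 60.0, 1.0),
        np.arange(60.0, 70.0, 1.0),
        np.arange(70.0, 80.0, 1.0),
        np.arange(80.0, 180.0, 10.0),      # open 80p+ band, off-trade tail
    ]
    grids_on = list(grids_off[:4]) + [np.arange(150.0, 450.0, 30.0)]

    sub_ids, bev_ids, prices, shares = [], [], [], []
    for s in range(N_SUBGROUPS):
        masses = np.array([
            B[s, 0] * sub_fraction,
            B[s, 0] * (1 - sub_fraction),
            B[s, 1], B[s, 2], B[s, 3],
        ])
        for b in range(N_BEVERAGES):
            grids = grids_on if ON_TRADE_MASK[b] else grids_off
            for gi, grid in enumerate(grids):
                if masses[gi] <= 1e-12:
                    continue
                k = len(grid)
                sub_ids.append(np.full(k, s, dtype=np.int64))
                bev_ids.append(np.full(k, b, dtype=np.int64))
                prices.append(grid)
                shares.append(np.full(k, masses[gi] / k))
    price = np.concatenate(prices)
    return PriceDistributionSet(
        subgroup_id=np.concatenate(sub_ids),
        beverage_id=np.concatenate(bev_ids),
        price_pence=price.copy(),
        original_pence=price.copy(),
        share=np.concatenate(shares),
    )


def band_shares(
    price_set: PriceDistributionSet,
    population: Population,
    by: str = "drinker_group",
) -> np.ndarray:
    """Population-weighted aggregate band shares of current prices.

    Each individual's units are spread over their subgroup's current
    price distribution.  ``by`` is 'drinker_group' (rows moderate,
    hazardous, harmful) or 'simd' (rows quintile 1..5).  Columns are the
    four bands (50-60p, 60-70p, 70-80p, 80p+); mass below 50p, if any,
    is folded into the first band.
    """
    edges = np.array([0.0, 60.0, 70.0, 80.0, np.inf])
    band_of_point = np.searchsorted(edges, price_set.price_pence, side="right") - 1
    cell = price_set._cell
    # per-cell band mass matrix (8000 x 4)
    M = np.zeros((N_SUBGROUPS * N_BEVERAGES, 4))
    np.add.at(M, (cell, band_of_point), price_set.share)
    per_subgroup = M.reshape(N_SUBGROUPS, N_BEVERAGES, 4)

    units = population.units  # (n, 10)
    mass = units * population.weight[:, None]
    sg = population.subgroup_id
    group = population.drinker_group
    if by == "drinker_group":
        keys, nrow = group - 1, 3
        sel = group > 0
    elif by == "simd":
        keys, nrow = population.simd_quintile - 1, 5
        sel = group > 0
    else:
        raise ValueError("by must be 'drinker_group' or 'simd'")
    out = np.zeros((nrow, 4))
    contrib = np.einsum("ib,ibk->ik", mass, per_subgroup[sg])
    np.add.at(out, keys[sel], contrib[sel])
    return out / np.maximum(out.sum(axis=1, keepdims=True), 1e-300)


# --------------------------------------------------------------------------
# Condition registry and baseline rates

_CANCERS = (
    "oral cavity cancer", "pharyngeal cancer", "laryngeal cancer",
    "oesophageal cancer", "liver cancer", "colon cancer", "rectal cancer",
    "female breast cancer", "pancreatic cancer", "stomach cancer",
)
_CARDIO = (
    ("hypertensive heart disease", 0.009, 0.0),
    ("ischaemic heart disease", -0.010, 0.00030),   # J-shaped
    ("ischaemic stroke", -0.008, 0.00026),          # J-shaped
    ("haemorrhagic stroke", 0.010, 0.0),
    ("cardiac arrhythmias", 0.007, 0.0),
    ("heart failure", 0.006, 0.0),
    ("peripheral arterial disease", 0.005, 0.0),
    ("aortic aneurysm", 0.004, 0.0),
)
_OTHER_CHRONIC = (
    ("liver cirrhosis", "liver disease", 0.030),
    ("chronic pancreatitis", "other", 0.018),
    ("epilepsy", "other", 0.008),
    ("type 2 diabetes", "other", 0.003),
    ("tuberculosis", "other", 0.010),
    ("psoriasis", "other", 0.005),
)
_INJURIES = (
    "road traffic injuries", "fall injuries", "drowning", "fire injuries",
    "accidental poisoning", "intentional self-harm", "assault",
    "occupational injuries", "sports injuries", "other transport injuries",
    "exposure and hypothermia", "other unintentional injuries",
)
_WHOLLY_CHRONIC = (
    ("alcoholic liver disease", "liver disease", 8.0e-5),
    ("alcohol dependence syndrome", "mental & behavioural due to alcohol", 5.0e-5),
    ("mental & behavioural disorders due to alcohol",
     "mental & behavioural due to alcohol", 3.0e-5),
    ("alcoholic cardiomyopathy", "cardiovascular", 8.0e-6),
    ("alcohol-induced pancreatitis", "other", 8.0e-6),
    ("degeneration of nervous system due to alcohol", "other", 5.0e-6),
)
_WHOLLY_ACUTE = (
    ("alcohol poisoning", "injuries", 6.0e-6),
    ("acute intoxication", "injuries", 3.0e-6),
    ("toxic effect of alcohol", "injuries", 2.0e-6),
)

# age multipliers by band for baseline rates
_AGE_MULT = {
    "chronic": np.array([0.10, 0.35, 1.0, 3.0]),
    "cancer": np.array([0.05, 0.20, 1.0, 4.0]),
    "acute": np.array([1.5, 1.2, 1.0, 0.7]),
    "wholly": np.array([0.3, 0.8, 1.3, 1.0]),
}
_SIMD_MULT = {
    "wholly": np.array([0.40, 0.62, 0.92, 1.30, 1.76]),
    "partial": np.array([0.80, 0.90, 1.00, 1.12, 1.28]),
}


def generate_condition_registry(
    n_conditions: int = 45, seed: int = 0
) -> list[Condition]:
    """Build the default 45-condition registry (or a smaller prefix).

    With fewer conditions requested, one condition per attribution
    category is kept first so every category stays represented.  Risk
    slopes are jittered ±10% by ``seed``; rates are attached per
    stratum with age, sex and deprivation gradients.
    """
    if n_conditions < 4:
        raise ValueError("need at least one condition per attribution category")
    rng = np.random.default_rng(seed)
    lag_chronic = make_lag_curve(10)
    lag_cancer = make_lag_curve(20)
    lag_acute = make_lag_curve(1)

    def jitter(x):
        return x * (1.0 + 0.1 * (2 * rng.random() - 1))

    conds: list[Condition] = []

    def add(name, group, category, params, lag, level):
        conds.append(_build_condition(name, group, category, params, lag, level, rng))

    # one per category first so small registries cover all four
    add(*_WHOLLY_CHRONIC[0][:2], "wholly-chronic",
        {"x_ref": 60.0, "gamma": 2.0}, lag_chronic, _WHOLLY_CHRONIC[0][2])
    add(*_WHOLLY_ACUTE[0][:2], "wholly-acute",
        {"binge_ref": 150.0}, lag_acute, _WHOLLY_ACUTE[0][2])
    add("liver cirrhosis", "liver disease", "partial-chronic",
        {"beta1": jitter(0.030)}, lag_chronic, 1.2e-4)
    add("road traffic injuries", "injuries", "partial-acute",
        {"rr_per_binge": 1.0 + jitter(0.008)}, lag_acute, 5.0e-5)

    for name, group, level in _WHOLLY_CHRONIC[1:]:
        add(name, group, "wholly-chronic",
            {"x_ref": 60.0, "gamma": jitter(2.0)}, lag_chronic, level)
    for name, group, level in _WHOLLY_ACUTE[1:]:
        add(name, group, "wholly-acute",
            {"binge_ref": 150.0}, lag_acute, level)
    for name in _CANCERS:
        add(name, "cancers", "partial-chronic",
            {"beta1": jitter(0.010)}, lag_cancer, 1.5e-4)
    for name, b1, b2 in _CARDIO:
        add(name, "cardiovascular", "partial-chronic",
            {"beta1": jitter(b1), "beta2": b2}, lag_chronic, 4.0e-4)
    for name, group, b1 in _OTHER_CHRONIC[1:]:
        add(name, group, "partial-chronic",
            {"beta1": jitter(b1)}, lag_chronic, 6.0e-5)
    for name in _INJURIES[1:]:
        add(name, "injuries", "partial-acute",
            {"rr_per_binge": 1.0 + jitter(0.006)}, lag_acute, 3.0e-5)

    return conds[:n_conditions]


def _build_condition(name, group, category, params, lag, level, rng) -> Condition:
    wholly = category.startswith("wholly")
    if category == "partial-chronic" and group == "cancers":
        age = _AGE_MULT["cancer"]
    elif wholly:
        age = _AGE_MULT["wholly"]
    elif category.endswith("acute"):
        age = _AGE_MULT["acute"]
    else:
        age = _AGE_MULT["chronic"]
    simd = _SIMD_MULT["wholly" if wholly else "partial"]
    sex_mult = np.array([0.75, 1.25]) if group != "cancers" else np.array([1.0, 1.0])

    mort = np.zeros(N_STRATA)
    for a in range(len(AGE_BANDS)):
        for s in range(2):
            for q in range(N_SIMD):
                mort[(a * 2 + s) * N_SIMD + q] = (
                    level * age[a] * sex_mult[s] * simd[q]
                )
    morb = mort * 12.0  # admissions an order of magnitude above deaths
    return Condition(
        name=name, group=group, category=category, risk_params=params,
        lag_curve=lag, baseline_mortality=mort, baseline_morbidity=morb,
    )


def generate_background_mortality() -> np.ndarray:
    """All-other-cause mortality by stratum: Gompertz in age with sex and
    deprivation gradients, per person-year."""
    band_ages = np.array([21.0, 29.5, 42.0, 67.0])
    base = 3.5e-5 * np.exp(0.11 * (band_ages - 18.0))
    sex_mult = np.array([0.85, 1.15])
    simd_mult = np.array([0.75, 0.90, 1.00, 1.15, 1.35])
    out = np.zeros(N_STRATA)
    for a in range(4):
        for s in range(2):
            for q in range(5):
                out[(a * 2 + s) * 5 + q] = base[a] * sex_mult[s] * simd_mult[q]
    return out


def build_rate_ledger(conditions: list[Condition]) -> RateLedger:
    return RateLedger(
        conditions=conditions,
        mortality=np.stack([c.baseline_mortality for c in conditions]),
        morbidity=np.stack([c.baseline_morbidity for c in conditions]),
        background_mortality=generate_background_mortality(),
    )


# --------------------------------------------------------------------------
# Inflation, life table, elasticities


def generate_inflation_series(
    rpi_rate: float = 0.035,
    cpih_rate: float = 0.025,
    start_year: int = 2017,
    end_year: int = 2040,
) -> dict[str, InflationSeries]:
    """Constant-rate RPI and CPIH index series, base 2017 = 1."""
    years = range(start_year, end_year + 1)
    return {
        "RPI": InflationSeries(
            "RPI", {y: (1 + rpi_rate) ** (y - start_year) for y in years}),
        "CPIH": InflationSeries(
            "CPIH", {y: (1 + cpih_rate) ** (y - start_year) for y in years}),
    }


def generate_life_table(max_age: int = 100) -> LifeTable:
    """Synthetic period life table: remaining expectancy declining ~0.82
    years per year of age from 63/59 (female/male) at age 18."""
    ages = np.arange(max_age + 1)
    female = np.maximum(1.5, 63.0 - 0.82 * np.maximum(ages - 18, 0))
    male = np.maximum(1.5, 59.0 - 0.82 * np.maximum(ages - 18, 0))
    return LifeTable(expectancy=np.stack([female, male]))


def generate_elasticities(which: str = "base") -> ElasticitySet:
    """Packaged synthetic elasticity matrices with conventional signs.

    'base' has own-price conditional elasticities around -0.5 (off-trade)
    to -0.9 (on-trade) with small positive cross effects; 'alternative'
    scales the base magnitudes down (a weaker-response matrix for the
    elasticity-swap sensitivity).  Published matrices can be supplied via
    :meth:`ElasticitySet.from_csv` instead.
    """
    own_cond = np.array([-0.50, -0.60, -0.40, -0.50, -0.60,
                         -0.80, -0.90, -0.70, -0.80, -0.90])
    cond = np.full((10, 10), 0.02)
    np.fill_diagonal(cond, own_cond)
    own_part = np.array([-0.10, -0.12, -0.08, -0.10, -0.12,
                         -0.15, -0.17, -0.13, -0.15, -0.17])
    part = np.full((10, 10), 0.005)
    np.fill_diagonal(part, own_part)
    if which == "base":
        return ElasticitySet(participation=part, conditional=cond, name="base")
    if which == "alternative":
        return ElasticitySet(
            participation=part * 0.35, conditional=cond * 0.35, name="alternative")
    raise ValueError(f"unknown elasticity set {which!r}")


# --------------------------------------------------------------------------
# Bundle


@dataclass
class SimulationInputs:
    """Everything one appraisal run needs, generated from a single seed."""

    population: Population
    prices: PriceDistributionSet
    conditions: list[Condition]
    ledger: RateLedger
    elasticities: dict[str, ElasticitySet]
    inflation: dict[str, InflationSeries]
    life_table: LifeTable
    occasion_model: OccasionModel
    age_profile: np.ndarray
    calibration: CalibrationTable
    price_basis_year: int = 2019

    def validate(self) -> None:
        required = {
            "population": self.population, "prices": self.prices,
            "conditions": self.conditions, "ledger": self.ledger,
            "elasticities": self.elasticities, "inflation": self.inflation,
            "life_table": self.life_table,
        }
        for name, value in required.items():
            if value is None:
                raise ValueError(f"missing input table: {name}")


def generate_inputs(
    n: int = 20_000,
    seed: int = 0,
    calibration: CalibrationTable = DEFAULT_CALIBRATION,
    band_targets: BandTargets = DEFAULT_BAND_TARGETS,
    n_conditions: int = 45,
) -> SimulationInputs:
    """Generate the full input bundle for a policy appraisal run."""
    ss = np.random.SeedSequence(seed)
    pop_seed, price_seed, cond_seed = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    ]
    population = generate_population(n, calibration, seed=pop_seed)
    prices = generate_price_distributions(population, band_targets, seed=price_seed)
    conditions = generate_condition_registry(n_conditions, seed=cond_seed)
    return SimulationInputs(
        population=population,
        prices=prices,
        conditions=conditions,
        ledger=build_rate_ledger(conditions),
        elasticities={
            "base": generate_elasticities("base"),
            "alternative": generate_elasticities("alternative"),
        },
        inflation=generate_inflation_series(),
        life_table=generate_life_table(),
        occasion_model=OccasionModel(),
        age_profile=DEFAULT_AGE_PROFILE.copy(),
        calibration=calibration,
    )
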